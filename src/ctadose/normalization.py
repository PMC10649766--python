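"""Min-max normalization of risk factors onto [-1, +1].

Every risk factor X (and the response, the CTA number of the left artery
divided by 400) is mapped by

    X* = (X - (X_max + X_min)/2) / ((X_max - X_min)/2)

so that the cohort minimum lands on -1 and the maximum on +1.  The map is
affine and strictly increasing, hence exactly invertible; predictions made
on the normalized scale are reported back in raw units through the inverse.

New patients may fall outside the derivation cohort's range.  The default
policy extrapolates (normalized values beyond +/-1) and logs a warning; the
``strict`` policy rejects such readings instead.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping

import numpy as np

from .errors import InvalidBoundsError, OutOfRangeError, ValidationError

logger = logging.getLogger(__name__)

#: Canonical factor order: four patient indices (age, BSA, HR, CO), three
#: facility settings (tube voltage, contrast volume, trigger delay), listed
#: in the fixed order the 29-term design expects.
FACTOR_IDS: tuple[str, ...] = ("age", "kvp", "bsa", "hr", "co", "cm", "dtt")

#: The response scale: CTA number of the left artery divided by the 400
#: target, so the optimum sits at 1.0.
RESPONSE_ID = "cta_la_over_400"

ALL_IDS: tuple[str, ...] = FACTOR_IDS + (RESPONSE_ID,)

#: Raw CTA numbers are divided by this before normalization.
RESPONSE_DIVISOR = 400.0

OutOfRangePolicy = Literal["allow", "strict"]


@dataclass(frozen=True)
class FactorBounds:
    """Raw-unit minimum and maximum for one factor (or the response)."""

    factor_id: str
    x_min: float
    x_max: float

    def __post_init__(self) -> None:
        if self.factor_id not in ALL_IDS:
            raise ValidationError(
                f"unknown factor id {self.factor_id!r}; expected one of {ALL_IDS}"
            )
        if not (math.isfinite(self.x_min) and math.isfinite(self.x_max)):
            raise InvalidBoundsError(f"{self.factor_id}: bounds must be finite")
        if not self.x_max > self.x_min:
            raise InvalidBoundsError(
                f"{self.factor_id}: x_max ({self.x_max}) must exceed x_min ({self.x_min})"
            )

    @property
    def center(self) -> float:
        return (self.x_max + self.x_min) / 2.0

    @property
    def half_range(self) -> float:
        return (self.x_max - self.x_min) / 2.0


def normalize(
    x: float | np.ndarray,
    bounds: FactorBounds,
    *,
    policy: OutOfRangePolicy = "allow",
) -> float | np.ndarray:
    """Map a raw reading onto the [-1, +1] scale defined by ``bounds``.

    Readings outside [x_min, x_max] extrapolate beyond +/-1 under the
    default policy (with a logged warning) and raise ``OutOfRangeError``
    under ``policy="strict"``.
    """
    arr = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValidationError(f"{bounds.factor_id}: non-finite reading")
    out_of_range = int(np.sum((arr < bounds.x_min) | (arr > bounds.x_max)))
    if out_of_range:
        if policy == "strict":
            raise OutOfRangeError(
                f"{bounds.factor_id}: {out_of_range} reading(s) outside "
                f"[{bounds.x_min}, {bounds.x_max}]"
            )
        logger.warning(
            "%s: %d reading(s) outside [%g, %g]; normalized value extrapolates beyond +/-1",
            bounds.factor_id,
            out_of_range,
            bounds.x_min,
            bounds.x_max,
        )
    # algebraically (x - center)/half_range, arranged so the bounds map to
    # exactly -1.0 and +1.0 in floating point
    result = (arr - bounds.x_min) / (bounds.x_max - bounds.x_min) * 2.0 - 1.0
    return float(result) if np.isscalar(x) or arr.ndim == 0 else result


def denormalize(x_star: float | np.ndarray, bounds: FactorBounds) -> float | np.ndarray:
    """Exact inverse of :func:`normalize`: raw = x* . half_range + center."""
    arr = np.asarray(x_star, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValidationError(f"{bounds.factor_id}: non-finite normalized value")
    result = arr * bounds.half_range + bounds.center
    return float(result) if np.isscalar(x_star) or arr.ndim == 0 else result


@dataclass(frozen=True)
class BoundsTable:
    """One :class:`FactorBounds` per factor plus one for the response scale.

    The response entry is on the CTA/400 scale (e.g. raw CTA 244..868 is
    stored as 0.61..2.17).
    """

    entries: Mapping[str, FactorBounds] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [fid for fid in ALL_IDS if fid not in self.entries]
        if missing:
            raise ValidationError(f"bounds table missing entries for {missing}")
        extra = [fid for fid in self.entries if fid not in ALL_IDS]
        if extra:
            raise ValidationError(f"bounds table has unknown entries {extra}")
        for fid, fb in self.entries.items():
            if fb.factor_id != fid:
                raise ValidationError(
                    f"bounds table key {fid!r} holds bounds for {fb.factor_id!r}"
                )

    @classmethod
    def from_pairs(cls, pairs: Mapping[str, tuple[float, float]]) -> "BoundsTable":
        return cls(
            {fid: FactorBounds(fid, lo, hi) for fid, (lo, hi) in pairs.items()}
        )

    def __getitem__(self, factor_id: str) -> FactorBounds:
        return self.entries[factor_id]

    @property
    def response(self) -> FactorBounds:
        return self.entries[RESPONSE_ID]

    def as_pairs(self) -> dict[str, tuple[float, float]]:
        return {fid: (self.entries[fid].x_min, self.entries[fid].x_max) for fid in ALL_IDS}


def derive_bounds(cohort: Iterable) -> BoundsTable:
    """Compute per-factor min/max over a cohort of patient records.

    The response bounds are taken over observed CTA/400 values; records
    without an observed CTA number are ignored for the response entry but
    must still carry all seven factors.  A factor that is constant across
    the cohort is degenerate and rejected by name.
    """
    records = list(cohort)
    if not records:
        raise ValidationError("cannot derive bounds from an empty cohort")
    entries: dict[str, FactorBounds] = {}
    for fid in FACTOR_IDS:
        values = [getattr(r, fid) for r in records]
        if any(v is None for v in values):
            raise ValidationError(f"cannot derive bounds: missing {fid} readings")
        lo, hi = min(values), max(values)
        if not hi > lo:
            raise InvalidBoundsError(f"factor {fid!r} is constant across the cohort")
        entries[fid] = FactorBounds(fid, float(lo), float(hi))
    responses = [r.cta_la / RESPONSE_DIVISOR for r in records if r.cta_la is not None]
    if len(responses) < 2:
        raise ValidationError(
            "cannot derive response bounds: need at least two observed CTA numbers"
        )
    lo, hi = min(responses), max(responses)
    if not hi > lo:
        raise InvalidBoundsError("response (CTA/400) is constant across the cohort")
    entries[RESPONSE_ID] = FactorBounds(RESPONSE_ID, float(lo), float(hi))
    return BoundsTable(entries)
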