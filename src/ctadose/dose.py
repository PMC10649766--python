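"""Stage 2: invert the fitted model for the contrast-media dose.

The fitted model is affine in the (normalized) contrast-media factor v6
once the other six factors are fixed.  Evaluating the predicted raw CTA
number at the cohort dose extremes (v6 = -1, i.e. cm_min, and v6 = +1,
i.e. cm_max) therefore determines the prediction at every intermediate
dose by exact linear interpolation, and the dose attaining a target CTA
number (default 400, the center of the 350-450 optimal imaging window)
follows from the two-point formula

    cm_expect = cm_min + (target - v8_min) / (v8_max - v8_min) * (cm_max - cm_min)

Because the model is affine in v6 and the response back-transform is
affine, re-predicting with cm = cm_expect returns the target exactly
(up to float roundoff) whenever the plan is unclipped.

Doses falling outside [cm_min, cm_max] are clipped and flagged by default
(the model's dose-linearity is only trusted inside the observed range);
``allow_extrapolation=True`` disables clipping.  A patient for whom more
contrast *lowers* the predicted CTA number (negative dose sensitivity) is
legal and surfaced via v8_at_cm_max < v8_at_cm_min, not an error.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np

from .errors import ValidationError, ZeroSensitivityError
from .model import (
    CoefficientSet,
    PatientRecord,
    cta_from_normalized,
    expand_design,
    normalize_record,
    predict_normalized,
)
from .normalization import BoundsTable, OutOfRangePolicy

logger = logging.getLogger(__name__)

DEFAULT_TARGET_CTA = 400.0

#: Relative sensitivity below which the dose is deemed to have no effect.
_SENSITIVITY_TOL = 1e-9


@dataclass(frozen=True)
class DosePlan:
    """Recommended contrast volume for one patient."""

    patient_id: str
    cm_min: float
    cm_max: float
    v8_at_cm_min: float
    v8_at_cm_max: float
    target_cta: float
    cm_expect: float
    achievable: bool
    clipped: bool


def interpolate_dose(
    cm_min: float,
    cm_max: float,
    v8_min: float,
    v8_max: float,
    target: float,
) -> float:
    """Two-point dose interpolation; v8_min/v8_max are the predicted raw CTA
    numbers at the minimal/maximal dose."""
    for name, v in (("cm_min", cm_min), ("cm_max", cm_max), ("v8_min", v8_min),
                    ("v8_max", v8_max), ("target", target)):
        if not np.isfinite(v):
            raise ValidationError(f"{name} must be finite")
    if not cm_max > cm_min:
        raise ValidationError(f"cm_max ({cm_max}) must exceed cm_min ({cm_min})")
    span = v8_max - v8_min
    if abs(span) <= _SENSITIVITY_TOL * max(abs(v8_max), abs(v8_min), 1.0):
        raise ZeroSensitivityError(
            "contrast-media dose does not influence this patient's predicted CTA number"
        )
    return cm_min + (target - v8_min) / span * (cm_max - cm_min)


def plan_dose(
    record: PatientRecord,
    coeffs: CoefficientSet,
    bounds: BoundsTable,
    target: float = DEFAULT_TARGET_CTA,
    *,
    allow_extrapolation: bool = False,
    policy: OutOfRangePolicy = "allow",
) -> DosePlan:
    """Plan the contrast volume for one patient.

    The patient's cm reading, if any, is ignored: the dose is the unknown.
    """
    cm_bounds = bounds["cm"]
    # normalize the six fixed factors; the cm slot is overwritten below
    probe = record if record.cm is not None else replace(record, cm=cm_bounds.x_min)
    v = normalize_record(probe, bounds, policy=policy)
    cm_idx = 5  # canonical factor order: age, kvp, bsa, hr, co, cm, dtt
    v_lo = v.copy()
    v_lo[cm_idx] = -1.0
    v_hi = v.copy()
    v_hi[cm_idx] = +1.0
    v8_min = cta_from_normalized(predict_normalized(v_lo, coeffs), bounds)
    v8_max = cta_from_normalized(predict_normalized(v_hi, coeffs), bounds)

    cm_expect = interpolate_dose(cm_bounds.x_min, cm_bounds.x_max, v8_min, v8_max, target)
    achievable = min(v8_min, v8_max) <= target <= max(v8_min, v8_max)
    clipped = False
    if not allow_extrapolation and not (cm_bounds.x_min <= cm_expect <= cm_bounds.x_max):
        cm_expect = float(np.clip(cm_expect, cm_bounds.x_min, cm_bounds.x_max))
        clipped = True
    return DosePlan(
        patient_id=record.patient_id,
        cm_min=cm_bounds.x_min,
        cm_max=cm_bounds.x_max,
        v8_at_cm_min=v8_min,
        v8_at_cm_max=v8_max,
        target_cta=target,
        cm_expect=cm_expect,
        achievable=achievable,
        clipped=clipped,
    )


def plan_cohort(
    records: Iterable[PatientRecord],
    coeffs: CoefficientSet,
    bounds: BoundsTable,
    target: float = DEFAULT_TARGET_CTA,
    *,
    allow_extrapolation: bool = False,
    policy: OutOfRangePolicy = "allow",
) -> tuple[list[DosePlan], list[tuple[str, Exception]]]:
    """Plan doses for a whole cohort.

    Per-patient failures (e.g. zero dose sensitivity) are collected and
    returned alongside the successful plans rather than aborting the batch.
    """
    recs = list(records)
    if not recs:
        raise ValidationError("cannot plan doses for an empty cohort")
    plans: list[DosePlan] = []
    failures: list[tuple[str, Exception]] = []
    for rec in recs:
        try:
            plans.append(
                plan_dose(
                    rec, coeffs, bounds, target,
                    allow_extrapolation=allow_extrapolation, policy=policy,
                )
            )
        except (ValidationError, ZeroSensitivityError) as exc:
            failures.append((rec.patient_id, exc))
    if plans:
        doses = [p.cm_expect for p in plans]
        logger.info(
            "planned %d/%d patients: dose range %.1f-%.1f c.c., %d clipped, %d unachievable",
            len(plans), len(recs), min(doses), max(doses),
            sum(p.clipped for p in plans), sum(not p.achievable for p in plans),
        )
    return plans, failures
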