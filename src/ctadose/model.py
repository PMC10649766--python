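"""The 29-term semi-empirical CTA-number model and its least-squares fit.

The predicted (normalized) CTA number of the left artery is a first-order
model in seven normalized risk factors v1..v7 with all 21 pairwise
cross-interaction products and a constant:

    v8 = a1 v1 + ... + a7 v7 + a8 v1 v2 + ... + a28 v6 v7 + a29

Triple and higher interactions are deliberately excluded; residual
higher-order structure is absorbed by the constant.  Coefficients are the
ordinary least-squares minimizer of phi = ||V a - y||^2 over the cohort
design matrix V (n x 29).  The solver uses a pivoted QR factorization; the
explicit normal-equations inverse (V'V)^-1 V'y defines the same minimizer
and is retained in the test-suite as an independent oracle only.

Rank deficiency is an error rather than silently resolved by a
pseudo-inverse: the downstream dose inversion assumes a unique coefficient
vector.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import scipy.linalg

from .errors import (
    IncompatibleModelError,
    RankDeficiencyError,
    UnderdeterminedError,
    ValidationError,
)
from .normalization import (
    FACTOR_IDS,
    RESPONSE_DIVISOR,
    BoundsTable,
    OutOfRangePolicy,
    denormalize,
    normalize,
)

N_FACTORS = 7
N_TERMS = 29

#: (i, j) index pairs of the 21 cross-interaction terms, in canonical order.
INTERACTION_PAIRS: tuple[tuple[int, int], ...] = tuple(
    itertools.combinations(range(N_FACTORS), 2)
)

_FACTOR_LETTERS = "ABCDEFG"

#: Canonical labels of the 29 design terms: main effects A..G (age, tube
#: voltage, BSA, HR, CO, CM, DTT), the 21 pairwise products, and the constant.
TERM_LABELS: tuple[str, ...] = tuple(_FACTOR_LETTERS) + tuple(
    f"{_FACTOR_LETTERS[i]}x{_FACTOR_LETTERS[j]}" for i, j in INTERACTION_PAIRS
) + ("Constant",)


@dataclass(frozen=True)
class PatientRecord:
    """One patient's raw risk-factor readings.

    ``cm`` (injected contrast volume) may be None for dose-planning
    records, where the dose is the unknown; ``cta_la`` (the observed CTA
    number of the left artery) may be None for prediction-only records.
    """

    patient_id: str
    age: float
    kvp: float
    bsa: float
    hr: float
    co: float
    dtt: float
    cm: float | None = None
    cta_la: float | None = None

    def __post_init__(self) -> None:
        for fid in FACTOR_IDS:
            v = getattr(self, fid)
            if v is None:
                if fid == "cm":
                    continue
                raise ValidationError(f"{self.patient_id}: missing {fid}")
            if not (math.isfinite(v) and v > 0):
                raise ValidationError(
                    f"{self.patient_id}: {fid} must be finite and positive, got {v}"
                )
        if self.cta_la is not None and not (
            math.isfinite(self.cta_la) and self.cta_la > 0
        ):
            raise ValidationError(
                f"{self.patient_id}: cta_la must be finite and positive, got {self.cta_la}"
            )

    def factor_values(self) -> tuple[float, ...]:
        if self.cm is None:
            raise ValidationError(f"{self.patient_id}: cm reading required here")
        return tuple(getattr(self, fid) for fid in FACTOR_IDS)


@dataclass(frozen=True)
class CoefficientSet:
    """The 29 model coefficients in canonical term order."""

    a: np.ndarray
    term_labels: tuple[str, ...] = TERM_LABELS

    def __post_init__(self) -> None:
        arr = np.asarray(self.a, dtype=float)
        object.__setattr__(self, "a", arr)
        if arr.shape != (N_TERMS,):
            raise IncompatibleModelError(
                f"expected {N_TERMS} coefficients, got shape {arr.shape}"
            )
        if not np.all(np.isfinite(arr)):
            raise ValidationError("coefficients must be finite")
        if tuple(self.term_labels) != TERM_LABELS:
            raise IncompatibleModelError(
                "coefficient labels disagree with the canonical 29-term order"
            )

    @property
    def constant(self) -> float:
        return float(self.a[-1])


@dataclass(frozen=True)
class FitDiagnostics:
    """Goodness-of-fit summary on the normalized response scale.

    ``loss_phi`` is the residual sum of squares; ``variance`` the
    coefficient of determination (fraction of response variance explained);
    ``r`` the observed-predicted correlation, so variance == r**2 for an
    intercept-containing least-squares fit.
    """

    loss_phi: float
    variance: float
    r: float
    n: int
    rank: int


def expand_design(v: Sequence[float]) -> np.ndarray:
    """Expand 7 normalized factor values into the 29-entry design row."""
    arr = np.asarray(v, dtype=float)
    if arr.shape != (N_FACTORS,):
        raise ValidationError(f"expected {N_FACTORS} factor values, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ValidationError("factor values must be finite")
    row = np.empty(N_TERMS)
    row[:N_FACTORS] = arr
    for k, (i, j) in enumerate(INTERACTION_PAIRS):
        row[N_FACTORS + k] = arr[i] * arr[j]
    row[-1] = 1.0
    return row


def design_matrix(v_matrix: np.ndarray) -> np.ndarray:
    """Vectorized :func:`expand_design` for an (n, 7) array of factors."""
    V = np.asarray(v_matrix, dtype=float)
    if V.ndim != 2 or V.shape[1] != N_FACTORS:
        raise ValidationError(f"expected an (n, {N_FACTORS}) array, got {V.shape}")
    if not np.all(np.isfinite(V)):
        raise ValidationError("factor values must be finite")
    n = V.shape[0]
    X = np.empty((n, N_TERMS))
    X[:, :N_FACTORS] = V
    for k, (i, j) in enumerate(INTERACTION_PAIRS):
        X[:, N_FACTORS + k] = V[:, i] * V[:, j]
    X[:, -1] = 1.0
    return X


def fit(design: np.ndarray, y: np.ndarray) -> tuple[CoefficientSet, FitDiagnostics]:
    """Least-squares fit of the 29 coefficients to normalized responses.

    Raises :class:`UnderdeterminedError` for n < 29 and
    :class:`RankDeficiencyError` (naming the collinear columns) when the
    design lacks full column rank.
    """
    X = np.asarray(design, dtype=float)
    yv = np.asarray(y, dtype=float)
    if X.ndim != 2 or X.shape[1] != N_TERMS:
        raise ValidationError(f"design must be (n, {N_TERMS}), got {X.shape}")
    if yv.shape != (X.shape[0],):
        raise ValidationError("response length does not match design rows")
    if not np.all(np.isfinite(X)) or not np.all(np.isfinite(yv)):
        raise ValidationError("design and response must be finite")
    n = X.shape[0]
    if n < N_TERMS:
        raise UnderdeterminedError(
            f"need at least {N_TERMS} patients to identify {N_TERMS} coefficients, got {n}"
        )

    # pivoted QR exposes both the rank and, on deficiency, the culprits
    _, R, piv = scipy.linalg.qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = max(X.shape) * np.finfo(float).eps * (diag[0] if diag.size else 0.0)
    rank = int(np.sum(diag > tol))
    if rank < N_TERMS:
        bad = tuple(TERM_LABELS[k] for k in sorted(piv[rank:]))
        raise RankDeficiencyError(
            f"design matrix is rank deficient (rank {rank} < {N_TERMS}); "
            f"collinear columns: {', '.join(bad)}",
            columns=bad,
        )

    a, *_ = np.linalg.lstsq(X, yv, rcond=None)
    pred = X @ a
    resid = yv - pred
    loss_phi = float(resid @ resid)
    sst = float(np.sum((yv - yv.mean()) ** 2))
    variance = 1.0 - loss_phi / sst if sst > 0 else 1.0
    if np.std(pred) > 0 and np.std(yv) > 0:
        r = float(np.corrcoef(yv, pred)[0, 1])
    else:
        r = 1.0 if loss_phi == 0.0 else 0.0
    coeffs = CoefficientSet(a)
    diag_out = FitDiagnostics(loss_phi=loss_phi, variance=variance, r=r, n=n, rank=rank)
    return coeffs, diag_out


def predict_normalized(v: Sequence[float], coeffs: CoefficientSet) -> float:
    """Predicted response on the normalized scale: design row . coefficients."""
    return float(expand_design(v) @ coeffs.a)


def normalize_record(
    record: PatientRecord,
    bounds: BoundsTable,
    *,
    policy: OutOfRangePolicy = "allow",
) -> np.ndarray:
    """Normalized 7-vector (v1..v7) for one patient."""
    return np.array(
        [
            normalize(getattr(record, fid), bounds[fid], policy=policy)
            for fid in FACTOR_IDS
        ]
    )


def cta_from_normalized(y_star: float, bounds: BoundsTable) -> float:
    """Map a normalized prediction back to a raw CTA number (x 400 scale)."""
    return float(denormalize(y_star, bounds.response)) * RESPONSE_DIVISOR


def normalized_from_cta(cta: float, bounds: BoundsTable, *, policy: OutOfRangePolicy = "allow") -> float:
    """Raw CTA number -> normalized response (inverse of cta_from_normalized)."""
    return float(normalize(cta / RESPONSE_DIVISOR, bounds.response, policy=policy))


def predict_cta(
    record: PatientRecord,
    coeffs: CoefficientSet,
    bounds: BoundsTable,
    *,
    policy: OutOfRangePolicy = "allow",
) -> float:
    """Predicted raw CTA number of the left artery for one patient."""
    v = normalize_record(record, bounds, policy=policy)
    return cta_from_normalized(predict_normalized(v, coeffs), bounds)


def fit_cohort(
    records: Iterable[PatientRecord],
    bounds: BoundsTable | None = None,
    *,
    policy: OutOfRangePolicy = "allow",
) -> tuple[CoefficientSet, FitDiagnostics, BoundsTable]:
    """Normalize a cohort, build its design and fit the model.

    When ``bounds`` is None they are derived from the cohort itself (the
    derivation-cohort workflow); pass explicit bounds to refit on a fixed
    scaling.
    """
    from .normalization import derive_bounds  # local import avoids cycle at module load

    recs = [r for r in records]
    if not recs:
        raise ValidationError("cannot fit an empty cohort")
    if any(r.cta_la is None for r in recs):
        raise ValidationError("every record in a fitting cohort needs an observed cta_la")
    if bounds is None:
        bounds = derive_bounds(recs)
    raw = np.array([[getattr(r, fid) for fid in FACTOR_IDS] for r in recs])
    V = np.column_stack(
        [normalize(raw[:, k], bounds[fid], policy=policy) for k, fid in enumerate(FACTOR_IDS)]
    )
    X = design_matrix(V)
    cta = np.array([r.cta_la for r in recs])
    y = normalize(cta / RESPONSE_DIVISOR, bounds.response, policy=policy)
    coeffs, diagnostics = fit(X, np.asarray(y))
    return coeffs, diagnostics, bounds
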