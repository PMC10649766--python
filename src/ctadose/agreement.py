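"""Per-patient agreement between observed and predicted CTA numbers.

The agreement statistic AT of a patient is the absolute relative deviation

    AT = |actual - predicted| / actual

of the CTA number of the left artery, reported in percent.  Verification
of a fitted model summarizes the per-patient ATs by their mean, sample
standard deviation and a binned histogram (2%-wide bins anchored at 0 by
default).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import ValidationError


@dataclass(frozen=True)
class AgreementResult:
    """Cohort agreement summary; all AT quantities are in percent."""

    per_patient_at: np.ndarray
    at_avg: float
    at_sd: float
    bin_edges: np.ndarray
    bin_counts: np.ndarray

    @property
    def n(self) -> int:
        return int(self.per_patient_at.size)


def at_statistic(actual: float, predicted: float) -> float:
    """Agreement fraction |actual - predicted| / actual (0 = perfect)."""
    if not np.isfinite(actual) or actual <= 0:
        raise ValidationError(f"actual CTA number must be positive, got {actual}")
    if not np.isfinite(predicted):
        raise ValidationError("predicted CTA number must be finite")
    return abs(actual - predicted) / actual


def summarize_agreement(
    actuals: Sequence[float],
    predicteds: Sequence[float],
    *,
    bin_width: float = 2.0,
) -> AgreementResult:
    """Mean, sample SD (n-1) and histogram of per-patient ATs in percent."""
    a = np.asarray(actuals, dtype=float)
    p = np.asarray(predicteds, dtype=float)
    if a.size == 0:
        raise ValidationError("agreement summary needs at least one patient")
    if a.shape != p.shape:
        raise ValidationError(f"length mismatch: {a.shape} actuals vs {p.shape} predictions")
    if bin_width <= 0:
        raise ValidationError("bin width must be positive")
    at_pct = np.array([at_statistic(ai, pi) for ai, pi in zip(a, p)]) * 100.0
    at_avg = float(at_pct.mean())
    at_sd = float(at_pct.std(ddof=1)) if at_pct.size > 1 else 0.0
    # right-open bins anchored at 0; top edge padded so the max is counted
    n_bins = max(1, int(np.ceil((at_pct.max() + 1e-12) / bin_width)))
    edges = np.arange(n_bins + 1) * bin_width
    counts, _ = np.histogram(at_pct, bins=edges)
    # np.histogram closes the last bin, so every AT is counted exactly once
    return AgreementResult(
        per_patient_at=at_pct,
        at_avg=at_avg,
        at_sd=at_sd,
        bin_edges=edges,
        bin_counts=counts,
    )
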