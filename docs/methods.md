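# Methods

## The model

The response is the CTA number of the left artery divided by 400 (so the
clinical target sits at 1.0), min–max normalized onto [−1, +1] together
with the seven risk factors:

| factor | symbol | units | reference cohort range |
|---|---|---|---|
| age | A (v1) | yr | 24–90 |
| tube voltage | B (v2) | kVp | 70–140 |
| body surface area | C (v3) | m² | 1.27–2.70 |
| heart rate | D (v4) | /min | 45–139 |
| cardiac output | E (v5) | L/min | 4.18–11.11 |
| contrast volume | F (v6) | c.c. | 17–75 |
| trigger delay | G (v7) | s | 2.00–5.13 |
| CTA(LA)/400 | v8 | — | 0.61–2.17 |

The model for the normalized response is first-order in each factor with
all 21 pairwise products and a constant (29 terms). Triple and higher
interactions are excluded: with every factor confined to [−1, +1] their
products are small, and whatever structure they carry is absorbed by the
constant. The model is consequently *affine in each single factor* when
the others are held fixed — the property stage 2 exploits.

The normalization is implemented as `(x − x_min)/(x_max − x_min)·2 − 1`,
which is algebraically the centered form but evaluates to exactly ±1.0 at
the bounds in floating point. Degenerate bounds (`x_max ≤ x_min`) are
rejected. New patients may fall outside the derivation range; the default
policy extrapolates beyond ±1 and logs a warning (the shipped verification
marginals are nearly but not exactly nested inside the derivation ranges),
and a strict policy rejects instead. Bounds are persisted inside the model
JSON next to the coefficients so a model can never be applied with
mismatched scaling.

## Fitting

Coefficients minimize Φ = Σ(obs − pred)² on the normalized response
scale. The minimizer is computed by QR-based least squares
(`numpy.linalg.lstsq`); the textbook normal-equations solution
(VᵀV)⁻¹Vᵀy is identical for full-rank designs and worse conditioned, so it
appears only as an independent oracle in the tests. Rank is determined
from a pivoted QR of the design; a deficient design raises an error naming
the collinear columns rather than silently picking one of infinitely many
solutions, because dose inversion needs a unique coefficient vector.
Fewer than 29 patients is likewise an error.

Diagnostics: Φ (residual sum of squares), `variance` (the coefficient of
determination 1 − Φ/SST), and r (observed–predicted correlation);
`variance = r²` for any intercept-containing OLS fit, which the tests
assert to 1e−9. Verification uses the agreement statistic
AT = |observed − predicted|/observed per patient, reported in percent and
summarized by mean, sample SD (n−1), and a histogram with 2%-wide bins
anchored at 0. AT is taken as an absolute deviation: the statistic is a
magnitude of disagreement and its conventional histogram is non-negative.

## Dose inversion

For a patient with the six non-dose factors fixed, the predicted raw CTA
number is evaluated with the normalized dose forced to −1 and +1 — i.e. at
the training cohort's dose extremes CM_min = 17 and CM_max = 75 c.c. — and
the dose attaining the target solves the two-point interpolation. Because
both the model (in v6) and the response back-transform are affine, an
unclipped plan is exact: re-predicting at the recommended dose returns the
target to float roundoff (the tests bound it by 1e−6 raw units).

Policy choices, surfaced in the `DosePlan` rather than hidden:

- doses outside [CM_min, CM_max] are clipped and flagged by default, since
  dose-linearity is only trusted inside the observed range; an
  `allow_extrapolation` switch disables clipping;
- a target outside the two extreme predictions is reported as
  `achievable=False`;
- negative dose sensitivity (more contrast lowering the predicted number,
  possible for unusual covariate combinations under interaction
  coefficients) is legal and visible as v8(CM_max) < v8(CM_min);
- a dose sensitivity of zero (relative |v8(CM_max) − v8(CM_min)| below
  1e−9) raises a zero-sensitivity error: the dose cannot steer this
  patient's prediction.

## Synthetic cohorts

The generator emulates the reference study's cohort structure without any
patient data. Factors are drawn independently from normal distributions
truncated to the reported [min, max] with the reported mean/SD
(inverse-CDF sampling); tube voltage is snapped to the clinical step set
{70, 80, 100, 120, 140} kVp, since scanners offer discrete settings.
Responses come from the reference coefficient set evaluated at the
record's normalized factors plus Gaussian noise with SD 0.084 on the
normalized scale — calibrated as √(3.184/450) so that a 450-patient fit
produces a residual loss of the published order (≈ nσ²). A CTA number is
an attenuation reading and must be positive; the ~0.4% of factor draws
whose response would come out non-positive have their noise resampled
and, failing that (e.g. at σ = 0), their factors redrawn — the simulated
population is conditioned on a physically possible response. All draws
derive from the spec's single seed, so identical specs give identical
cohorts.

What the generator does **not** emulate: the joint correlation structure
of real patients (an optional Gaussian-copula hook can couple factors,
e.g. heart rate with cardiac output, but defaults to independence), the
exact per-patient values of any real cohort, and the real response tails —
under independent marginals the interaction terms occasionally produce
more extreme responses than a clinical cohort would show. Passing tests
therefore demonstrate the pipeline's internal correctness (recovery,
exact inversion, calibration of scales), not clinical validity of the
reference coefficients.

Body surface area uses the Mosteller estimate √(H·W/3600) (H in cm, W in
kg); the radical is essential — without it plausible heights and weights
give values far outside the 1.27–2.70 m² cohort range.

## Problem sizes and numerical choices

The analysis scripts and tests use the study-scale cohorts (450 derivation,
112 verification, 65 planning); Monte-Carlo properties (loss calibration,
RMSE shrinkage with n, agreement level) use 5–20 seeded replicates, enough
for the order-of-magnitude bands they assert. Coefficient-recovery checks
use 1e−8 absolute tolerance (noiseless fits land near 1e−14); solver/oracle
agreement is asserted at 1e−6 relative; round trips of the normalization at
1e−9 of the factor range. Model files serialize floats at full round-trip
precision, and the patient-CSV reader parses cells with Python's
correctly-rounded `float()` (pandas' fast parser can be off by one ulp),
so simulate→fit→plan pipelines are byte-reproducible across runs.

## Known limitations

- The reference coefficient set is applied as published; no uncertainty
  (standard errors, CIs) is attached to it or to fitted coefficients, and
  no regularization or variable selection is offered.
- Dose planning is single-target inversion; there is no dose-minimization
  under a CTA window, and no pharmacokinetic model of bolus transit — the
  model is purely statistical.
- Published data-dependent figures (the exact Φ, R, AT values of the real
  cohorts) cannot be reproduced without the withheld clinical data; the
  package's synthetic analogs match them in structure and scale only.
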