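"""Seeded synthetic patient cohorts.

The clinical data behind the published coefficient set is not public, so
the package ships a generator that emulates its cohort structure: each of
the seven risk factors is drawn independently from a normal distribution
truncated to the reported [min, max] with the reported mean/SD, tube
voltage is snapped to the clinical step set {70, 80, 100, 120, 140} kVp,
and the observed CTA number is produced by the 29-term ground-truth model
plus Gaussian noise of SD ``residual_sd`` on the normalized response scale
(default 0.084, calibrated so a 450-patient fit lands near the published
residual loss).

Marginals are independent by default; real cohorts correlate some factors
(cardiac output is physiologically heart rate x stroke volume).  An
optional Gaussian-copula correlation matrix couples selected factors while
preserving the truncated-normal marginals; it defaults to the identity.
"""

from __future__ import annotations

import configparser
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .errors import CohortSpecError, ValidationError
from .model import CoefficientSet, PatientRecord, design_matrix, normalize_record
from .normalization import FACTOR_IDS, RESPONSE_DIVISOR, BoundsTable

#: Discrete tube-voltage settings offered by clinical CT scanners.
KVP_STEPS: tuple[float, ...] = (70.0, 80.0, 100.0, 120.0, 140.0)

#: Default residual noise SD on the normalized response scale.
DEFAULT_RESIDUAL_SD = 0.084


@dataclass(frozen=True)
class FactorMarginal:
    """Truncated-normal marginal for one factor, in raw units."""

    mean: float
    sd: float
    min: float
    max: float

    def __post_init__(self) -> None:
        for name, v in (("mean", self.mean), ("sd", self.sd),
                        ("min", self.min), ("max", self.max)):
            if not math.isfinite(v):
                raise CohortSpecError(f"{name} must be finite")
        if self.sd <= 0:
            raise CohortSpecError(f"sd must be positive, got {self.sd}")
        if not self.min < self.mean < self.max:
            raise CohortSpecError(
                f"infeasible truncation: mean {self.mean} outside ({self.min}, {self.max})"
            )


@dataclass(frozen=True)
class CohortSpec:
    """Everything needed to simulate one cohort reproducibly."""

    n: int
    seed: int
    marginals: Mapping[str, FactorMarginal]
    ground_truth: CoefficientSet
    bounds: BoundsTable
    residual_sd: float = DEFAULT_RESIDUAL_SD
    kvp_steps: tuple[float, ...] | None = KVP_STEPS
    correlation: np.ndarray | None = None  # optional Gaussian-copula matrix (7x7)

    def __post_init__(self) -> None:
        if self.n < 1:
            raise CohortSpecError(f"cohort size must be >= 1, got {self.n}")
        missing = [fid for fid in FACTOR_IDS if fid not in self.marginals]
        if missing:
            raise CohortSpecError(f"missing marginals for {missing}")
        if self.residual_sd < 0:
            raise CohortSpecError("residual_sd must be >= 0")
        if self.correlation is not None:
            C = np.asarray(self.correlation, dtype=float)
            if C.shape != (7, 7) or not np.allclose(C, C.T):
                raise CohortSpecError("correlation must be a symmetric 7x7 matrix")
            if np.linalg.eigvalsh(C).min() < -1e-10:
                raise CohortSpecError("correlation matrix must be positive semidefinite")
            object.__setattr__(self, "correlation", C)


def bsa_from_height_weight(height: float, weight: float) -> float:
    """Mosteller body surface area sqrt(H.W/3600), H in cm, W in kg."""
    if not (math.isfinite(height) and height > 0):
        raise ValidationError(f"height must be positive, got {height}")
    if not (math.isfinite(weight) and weight > 0):
        raise ValidationError(f"weight must be positive, got {weight}")
    return math.sqrt(height * weight / 3600.0)


def _truncnorm_ppf(u: np.ndarray, m: FactorMarginal) -> np.ndarray:
    a = (m.min - m.mean) / m.sd
    b = (m.max - m.mean) / m.sd
    return stats.truncnorm.ppf(u, a, b, loc=m.mean, scale=m.sd)


def _sample_factor_matrix(spec: CohortSpec, rng: np.random.Generator, n: int) -> np.ndarray:
    """(n, 7) raw factor readings drawn from the spec's marginals.

    Uses inverse-CDF sampling of the truncated normals so an optional
    Gaussian copula can impose correlation without changing the marginals.
    """
    z = rng.standard_normal((n, len(FACTOR_IDS)))
    if spec.correlation is not None:
        L = np.linalg.cholesky(spec.correlation + 1e-12 * np.eye(7))
        z = z @ L.T
    u = stats.norm.cdf(z)
    # keep strictly inside (0, 1) so ppf never returns the infinite tail
    u = np.clip(u, 1e-12, 1.0 - 1e-12)
    X = np.empty((n, len(FACTOR_IDS)))
    for k, fid in enumerate(FACTOR_IDS):
        m = spec.marginals[fid]
        x = _truncnorm_ppf(u[:, k], m)
        if fid == "kvp" and spec.kvp_steps is not None:
            steps = np.array([s for s in spec.kvp_steps if m.min <= s <= m.max])
            if steps.size == 0:
                raise CohortSpecError("no kvp step lies inside the kvp truncation range")
            x = steps[np.argmin(np.abs(x[:, None] - steps[None, :]), axis=1)]
        X[:, k] = np.clip(x, m.min, m.max)
    return X


def sample_factors(spec: CohortSpec) -> list[PatientRecord]:
    """Draw n patients' factor readings (responses unset).

    Identical spec (including seed) gives an identical cohort.
    """
    rng = np.random.default_rng([spec.seed, 0])
    X = _sample_factor_matrix(spec, rng, spec.n)
    width = len(str(spec.n))
    return [
        PatientRecord(
            patient_id=f"P{i + 1:0{width}d}",
            **{fid: float(X[i, k]) for k, fid in enumerate(FACTOR_IDS)},
        )
        for i in range(spec.n)
    ]


def attach_responses(records: Sequence[PatientRecord], spec: CohortSpec) -> list[PatientRecord]:
    """Attach observed CTA numbers generated by the ground-truth model.

    The true normalized response is the 29-term model at the record's
    normalized factors; observation noise is Normal(0, residual_sd) on the
    normalized scale; the raw CTA number is the denormalized response x 400.
    A CTA number is an attenuation reading and must be positive; for the
    rare factor combination (~0.4% under the default marginals) whose
    response would come out non-positive, the noise is resampled, and if
    that cannot help (e.g. residual_sd = 0) the patient's factor readings
    are redrawn from the marginals -- i.e. the cohort distribution is
    conditioned on a physically possible response.  Everything is driven
    by the spec's seed, so identical specs give identical cohorts.
    """
    if any(r.cm is None for r in records):
        raise ValidationError("every record needs a cm reading before responses")
    rng = np.random.default_rng([spec.seed, 1])
    resp = spec.bounds.response

    def true_response(rec: PatientRecord) -> float:
        v = normalize_record(rec, spec.bounds)
        return float((design_matrix(v[None, :]) @ spec.ground_truth.a)[0])

    out: list[PatientRecord] = []
    for rec in records:
        cta = None
        for _ in range(200):  # factor-redraw loop; virtually always 1 pass
            yt = true_response(rec)
            for _ in range(50):  # noise-resample loop
                y_obs = yt + (rng.standard_normal() * spec.residual_sd if spec.residual_sd else 0.0)
                candidate = (y_obs * resp.half_range + resp.center) * RESPONSE_DIVISOR
                if candidate > 0:
                    cta = candidate
                    break
                if spec.residual_sd == 0:
                    break
            if cta is not None:
                break
            x = _sample_factor_matrix(spec, rng, 1)[0]
            rec = replace(rec, **{fid: float(x[k]) for k, fid in enumerate(FACTOR_IDS)})
        if cta is None:
            raise CohortSpecError(f"{rec.patient_id}: could not generate a positive CTA number")
        out.append(replace(rec, cta_la=float(cta)))
    return out


def generate_cohort(spec: CohortSpec) -> list[PatientRecord]:
    """sample_factors followed by attach_responses."""
    return attach_responses(sample_factors(spec), spec)


# ---------------------------------------------------------------------------
# packaged cohort specifications


def _load_config(path: str | Path) -> tuple[dict[str, FactorMarginal], dict]:
    cp = configparser.ConfigParser()
    read = cp.read(path)
    if not read:
        raise CohortSpecError(f"cohort config not found: {path}")
    if "cohort" not in cp:
        raise CohortSpecError(f"{path}: missing [cohort] section")
    marginals: dict[str, FactorMarginal] = {}
    for fid in FACTOR_IDS:
        if fid not in cp:
            raise CohortSpecError(f"{path}: missing [{fid}] section")
        sec = cp[fid]
        try:
            marginals[fid] = FactorMarginal(
                mean=sec.getfloat("mean"), sd=sec.getfloat("sd"),
                min=sec.getfloat("min"), max=sec.getfloat("max"),
            )
        except (TypeError, ValueError) as exc:
            raise CohortSpecError(f"{path}: bad [{fid}] section: {exc}") from exc
    meta = dict(cp["cohort"])
    return marginals, meta


def spec_from_config(
    path: str | Path,
    *,
    seed: int,
    ground_truth: CoefficientSet,
    bounds: BoundsTable,
    n: int | None = None,
    residual_sd: float | None = None,
) -> CohortSpec:
    """Build a CohortSpec from a key/value config file.

    The config carries the marginals, default n, residual SD and kvp step
    policy; the ground-truth coefficients and scaling bounds come from a
    model artifact so generation and refitting always share one scaling.
    """
    marginals, meta = _load_config(path)
    cfg_n = int(meta.get("n", 0)) or None
    use_n = n if n is not None else cfg_n
    if use_n is None:
        raise CohortSpecError(f"{path}: no cohort size in config and none given")
    sd = residual_sd if residual_sd is not None else float(meta.get("residual_sd", DEFAULT_RESIDUAL_SD))
    steps_raw = meta.get("kvp_steps", "").split()
    steps = tuple(float(s) for s in steps_raw) if steps_raw else None
    return CohortSpec(
        n=use_n, seed=seed, marginals=marginals,
        ground_truth=ground_truth, bounds=bounds,
        residual_sd=sd, kvp_steps=steps,
    )


def _packaged(name: str) -> Path:
    import importlib.resources

    return Path(str(importlib.resources.files("ctadose.data") / name))


def derivation_cohort_spec(seed: int, *, n: int | None = None,
                           residual_sd: float | None = None) -> CohortSpec:
    """Spec emulating the 450-patient derivation cohort's marginals."""
    from .io import load_reference_model

    ref = load_reference_model()
    return spec_from_config(
        _packaged("derivation_cohort.cfg"), seed=seed, n=n,
        ground_truth=ref.coefficients, bounds=ref.bounds, residual_sd=residual_sd,
    )


def verification_cohort_spec(seed: int, *, n: int | None = None,
                             residual_sd: float | None = None) -> CohortSpec:
    """Spec emulating the 112-patient verification cohort's marginals.

    Responses are still generated from the reference model with the
    derivation-cohort scaling, as verification patients were scored with
    the derivation-cohort formula.
    """
    from .io import load_reference_model

    ref = load_reference_model()
    return spec_from_config(
        _packaged("verification_cohort.cfg"), seed=seed, n=n,
        ground_truth=ref.coefficients, bounds=ref.bounds, residual_sd=residual_sd,
    )
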