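"""File formats: patient CSV tables and model JSON artifacts.

A model artifact bundles the 29 coefficients with the factor bounds that
defined their normalization and the target CTA number, so a model can
never be applied with mismatched scaling.  See docs/formats.md for the
exact column and field names.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any, Iterable, Sequence

import numpy as np
import pandas as pd

from .agreement import AgreementResult
from .dose import DosePlan
from .errors import IncompatibleModelError, SchemaError, ValidationError
from .model import (
    TERM_LABELS,
    CoefficientSet,
    FitDiagnostics,
    PatientRecord,
)
from .normalization import ALL_IDS, FACTOR_IDS, BoundsTable

PATIENT_COLUMNS = ("patient_id",) + FACTOR_IDS + ("cta_la",)

#: Columns that may be blank: cm (unknown dose) and cta_la (no observation).
_OPTIONAL = {"cm", "cta_la"}


@dataclass(frozen=True)
class ModelArtifact:
    coefficients: CoefficientSet
    bounds: BoundsTable
    target_cta: float = 400.0
    diagnostics: FitDiagnostics | None = None
    metadata: dict[str, Any] = field(default_factory=dict)


def read_patient_csv(path: str | Path) -> list[PatientRecord]:
    """Read a patient table; cm and cta_la cells may be empty."""
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"patient file not found: {path}")
    # cells stay strings so float() does the correctly-rounded parse
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in PATIENT_COLUMNS if c not in df.columns and c not in _OPTIONAL]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    records: list[PatientRecord] = []
    problems: list[str] = []
    for idx, row in df.iterrows():
        line = idx + 2  # header is line 1
        kwargs: dict[str, Any] = {"patient_id": str(row["patient_id"])}
        ok = True
        for col in FACTOR_IDS + ("cta_la",):
            raw = row.get(col) if col in df.columns else None
            if raw is None or raw == "":
                if col in _OPTIONAL:
                    kwargs[col] = None
                    continue
                problems.append(f"line {line}: missing {col}")
                ok = False
                continue
            try:
                kwargs[col] = float(raw)
            except (TypeError, ValueError):
                problems.append(f"line {line}: non-numeric {col} value {raw!r}")
                ok = False
        if not ok:
            continue
        try:
            records.append(PatientRecord(**kwargs))
        except ValidationError as exc:
            problems.append(f"line {line}: {exc}")
    if problems:
        raise SchemaError(f"{path}: " + "; ".join(problems))
    return records


def write_patient_csv(records: Iterable[PatientRecord], path: str | Path) -> None:
    rows = []
    for r in records:
        row = {"patient_id": r.patient_id}
        for col in FACTOR_IDS + ("cta_la",):
            v = getattr(r, col)
            row[col] = "" if v is None else repr(v)
        rows.append(row)
    pd.DataFrame(rows, columns=list(PATIENT_COLUMNS)).to_csv(path, index=False)


def write_model(artifact: ModelArtifact, path: str | Path) -> None:
    """Serialize a model artifact as JSON with round-trip float precision."""
    payload: dict[str, Any] = {
        "term_labels": list(artifact.coefficients.term_labels),
        "coefficients": [float(a) for a in artifact.coefficients.a],
        "bounds": {fid: list(pair) for fid, pair in artifact.bounds.as_pairs().items()},
        "target_cta": artifact.target_cta,
        "metadata": dict(artifact.metadata),
    }
    if artifact.diagnostics is not None:
        payload["diagnostics"] = asdict(artifact.diagnostics)
    Path(path).write_text(json.dumps(payload, indent=1))


def read_model(path: str | Path) -> ModelArtifact:
    """Read and validate a model artifact.

    Rejects files whose term labels disagree with the canonical 29-term
    order or whose bounds do not cover every factor and the response.
    """
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"model file not found: {path}")
    try:
        payload = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise SchemaError(f"{path}: not valid JSON: {exc}") from exc
    for key in ("term_labels", "coefficients", "bounds"):
        if key not in payload:
            raise SchemaError(f"{path}: missing field {key!r}")
    if tuple(payload["term_labels"]) != TERM_LABELS:
        raise IncompatibleModelError(
            f"{path}: term labels disagree with the canonical 29-term order"
        )
    coeffs_raw = payload["coefficients"]
    if len(coeffs_raw) != len(TERM_LABELS):
        raise IncompatibleModelError(
            f"{path}: expected {len(TERM_LABELS)} coefficients, found {len(coeffs_raw)}"
        )
    coefficients = CoefficientSet(np.asarray(coeffs_raw, dtype=float))
    bounds_raw = payload["bounds"]
    missing = [fid for fid in ALL_IDS if fid not in bounds_raw]
    if missing:
        raise IncompatibleModelError(f"{path}: bounds missing for {missing}")
    bounds = BoundsTable.from_pairs({fid: tuple(bounds_raw[fid]) for fid in ALL_IDS})
    diagnostics = None
    if "diagnostics" in payload and payload["diagnostics"] is not None:
        diagnostics = FitDiagnostics(**payload["diagnostics"])
    return ModelArtifact(
        coefficients=coefficients,
        bounds=bounds,
        target_cta=float(payload.get("target_cta", 400.0)),
        diagnostics=diagnostics,
        metadata=dict(payload.get("metadata", {})),
    )


def load_reference_model() -> ModelArtifact:
    """The packaged reference coefficient set with its derivation-cohort bounds."""
    import importlib.resources

    res = importlib.resources.files("ctadose.data") / "reference_model.json"
    with importlib.resources.as_file(res) as p:
        return read_model(p)


def write_predictions_csv(
    records: Sequence[PatientRecord], predicted: Sequence[float], path: str | Path
) -> None:
    rows = [
        {
            "patient_id": r.patient_id,
            "cta_la": "" if r.cta_la is None else repr(r.cta_la),
            "predicted_cta": repr(float(p)),
        }
        for r, p in zip(records, predicted)
    ]
    pd.DataFrame(rows, columns=["patient_id", "cta_la", "predicted_cta"]).to_csv(
        path, index=False
    )


def write_agreement_csv(
    patient_ids: Sequence[str],
    actuals: Sequence[float],
    predicteds: Sequence[float],
    result: AgreementResult,
    path: str | Path,
) -> None:
    rows = [
        {
            "patient_id": pid,
            "actual": repr(float(a)),
            "predicted": repr(float(p)),
            "at_percent": repr(float(at)),
        }
        for pid, a, p, at in zip(patient_ids, actuals, predicteds, result.per_patient_at)
    ]
    pd.DataFrame(rows, columns=["patient_id", "actual", "predicted", "at_percent"]).to_csv(
        path, index=False
    )


def write_agreement_json(result: AgreementResult, path: str | Path) -> None:
    payload = {
        "n": result.n,
        "at_avg_percent": result.at_avg,
        "at_sd_percent": result.at_sd,
        "bin_edges_percent": [float(e) for e in result.bin_edges],
        "bin_counts": [int(c) for c in result.bin_counts],
    }
    Path(path).write_text(json.dumps(payload, indent=1))


DOSE_PLAN_COLUMNS = (
    "patient_id", "cm_min", "cm_max", "v8_at_cm_min", "v8_at_cm_max",
    "target_cta", "cm_expect", "achievable", "clipped",
)


def write_dose_plans_csv(plans: Sequence[DosePlan], path: str | Path) -> None:
    rows = []
    for p in plans:
        row = asdict(p)
        for k, v in row.items():
            if isinstance(v, float):
                row[k] = repr(v)
        rows.append(row)
    pd.DataFrame(rows, columns=list(DOSE_PLAN_COLUMNS)).to_csv(path, index=False)
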