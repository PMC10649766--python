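"""Verify the fitted model on the held-out verification cohort.

Predicts each verification patient's CTA number with the model fitted in
step 02 and summarizes the per-patient agreement AT = |obs - pred| / obs.
Writes the per-patient table and the summary JSON under results/.
"""

from pathlib import Path

import ctadose as cd
from ctadose.io import write_agreement_csv, write_agreement_json

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    artifact = cd.read_model(OUT / "fitted_model.json")
    records = cd.read_patient_csv(OUT / "cohort_verification.csv")
    actuals = [r.cta_la for r in records]
    preds = [
        cd.predict_cta(r, artifact.coefficients, artifact.bounds) for r in records
    ]
    result = cd.summarize_agreement(actuals, preds)
    write_agreement_csv(
        [r.patient_id for r in records], actuals, preds, result,
        OUT / "agreement.csv",
    )
    write_agreement_json(result, OUT / "agreement.json")
    below2 = int(result.bin_counts[0]) if result.bin_counts.size else 0
    print(
        f"verification (n={result.n}): AT_avg = {result.at_avg:.2f}%, "
        f"AT_sd = {result.at_sd:.2f}%, {below2}/{result.n} patients below 2%"
    )
    print("wrote results/agreement.csv and results/agreement.json")


if __name__ == "__main__":
    main()
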