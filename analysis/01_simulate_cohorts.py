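"""Simulate the three study cohorts.

Generates a 450-patient derivation cohort, a 112-patient verification
cohort and a 65-patient dose-planning ("testified") cohort from the
packaged marginals and the reference ground-truth model, and writes them
as patient CSVs under results/.
"""

from pathlib import Path

import numpy as np

import ctadose as cd

SEED = 20230
OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    OUT.mkdir(exist_ok=True)

    derivation = cd.generate_cohort(cd.derivation_cohort_spec(seed=SEED))
    verification = cd.generate_cohort(cd.verification_cohort_spec(seed=SEED + 1))
    # the dose-planning cohort carries no dose or response: those are planned
    planning_spec = cd.derivation_cohort_spec(seed=SEED + 2, n=65)
    planning = cd.sample_factors(planning_spec)

    for name, cohort in [
        ("cohort_derivation.csv", derivation),
        ("cohort_verification.csv", verification),
        ("cohort_planning.csv", planning),
    ]:
        cd.write_patient_csv(cohort, OUT / name)
        print(f"wrote {len(cohort):4d} patients -> results/{name}")

    ages = np.array([r.age for r in derivation])
    ctas = np.array([r.cta_la for r in derivation])
    print(
        f"derivation cohort: age {ages.min():.0f}-{ages.max():.0f} "
        f"(mean {ages.mean():.1f}), observed CTA {ctas.min():.0f}-{ctas.max():.0f} "
        f"(mean {ctas.mean():.0f})"
    )


if __name__ == "__main__":
    main()
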