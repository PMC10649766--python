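"""Dose inversion: two-point interpolation and per-patient planning."""

from dataclasses import replace

import numpy as np
import pytest

import ctadose as cd
from ctadose.errors import ValidationError, ZeroSensitivityError


class TestInterpolateDose:
    def test_worked_example(self):
        # dose extremes 17/75 c.c. predicting CTA 252/552; target 400
        assert cd.interpolate_dose(17, 75, 252, 552, 400) == pytest.approx(45.6, abs=0.05)

    @pytest.mark.parametrize("target, expected", [(252.0, 17.0), (552.0, 75.0)])
    def test_target_at_anchor_returns_extreme(self, target, expected):
        assert cd.interpolate_dose(17, 75, 252, 552, target) == pytest.approx(expected)

    def test_monotone_in_target(self):
        targets = np.linspace(260, 540, 15)
        doses = [cd.interpolate_dose(17, 75, 252, 552, t) for t in targets]
        assert np.all(np.diff(doses) > 0)
        # mirrored when more contrast lowers the predicted number
        doses_neg = [cd.interpolate_dose(17, 75, 552, 252, t) for t in targets]
        assert np.all(np.diff(doses_neg) < 0)

    def test_zero_sensitivity_rejected(self):
        with pytest.raises(ZeroSensitivityError):
            cd.interpolate_dose(17, 75, 400, 400, 420)

    def test_bad_dose_range_rejected(self):
        with pytest.raises(ValidationError):
            cd.interpolate_dose(75, 17, 252, 552, 400)


@pytest.fixture
def planning_record():
    return cd.PatientRecord(
        patient_id="t1", age=56, kvp=100, bsa=1.75, hr=72, co=6.3, dtt=3.1
    )


class TestPlanDose:
    def test_plan_uses_training_dose_extremes(self, reference_model, planning_record):
        plan = cd.plan_dose(
            planning_record, reference_model.coefficients, reference_model.bounds
        )
        assert plan.cm_min == 17.0 and plan.cm_max == 75.0
        assert plan.target_cta == 400.0

    def test_closed_loop_exactness(self, reference_model, planning_record):
        plan = cd.plan_dose(
            planning_record, reference_model.coefficients, reference_model.bounds
        )
        assert plan.achievable and not plan.clipped
        achieved = cd.predict_cta(
            replace(planning_record, cm=plan.cm_expect),
            reference_model.coefficients,
            reference_model.bounds,
        )
        assert abs(achieved - 400.0) < 1e-6

    def test_target_at_extreme_prediction_returns_extreme_dose(
        self, reference_model, planning_record
    ):
        probe = cd.plan_dose(
            planning_record, reference_model.coefficients, reference_model.bounds
        )
        plan = cd.plan_dose(
            planning_record,
            reference_model.coefficients,
            reference_model.bounds,
            target=probe.v8_at_cm_max,
        )
        assert plan.cm_expect == pytest.approx(probe.cm_max)

    def test_unachievable_target_flagged_and_clipped(
        self, reference_model, planning_record
    ):
        plan = cd.plan_dose(
            planning_record,
            reference_model.coefficients,
            reference_model.bounds,
            target=5000.0,
        )
        assert not plan.achievable
        assert plan.clipped
        assert plan.cm_min <= plan.cm_expect <= plan.cm_max

    def test_allow_extrapolation_disables_clipping(
        self, reference_model, planning_record
    ):
        plan = cd.plan_dose(
            planning_record,
            reference_model.coefficients,
            reference_model.bounds,
            target=5000.0,
            allow_extrapolation=True,
        )
        assert not plan.clipped
        assert plan.cm_expect > plan.cm_max or plan.cm_expect < plan.cm_min

    def test_ignores_recorded_cm_reading(self, reference_model, planning_record):
        with_cm = replace(planning_record, cm=40.0)
        p1 = cd.plan_dose(planning_record, reference_model.coefficients, reference_model.bounds)
        p2 = cd.plan_dose(with_cm, reference_model.coefficients, reference_model.bounds)
        assert p1.cm_expect == p2.cm_expect


class TestPlanCohort:
    def test_testified_cohort_closed_loop(self, reference_model):
        """Every achievable, unclipped plan in a 65-patient synthetic cohort
        drives the re-predicted CTA number to the target exactly."""
        spec = cd.derivation_cohort_spec(seed=77, n=65)
        cohort = cd.sample_factors(spec)
        plans, failures = cd.plan_cohort(
            cohort, reference_model.coefficients, reference_model.bounds, 400.0
        )
        assert len(plans) == 65 and not failures
        checked = 0
        for rec, plan in zip(cohort, plans):
            if plan.achievable and not plan.clipped:
                achieved = cd.predict_cta(
                    replace(rec, cm=plan.cm_expect),
                    reference_model.coefficients,
                    reference_model.bounds,
                )
                assert abs(achieved - 400.0) < 1e-6
                checked += 1
        assert checked > 30  # most patients can reach the target

    def test_identical_patients_get_identical_plans(self, reference_model):
        rec = cd.PatientRecord(
            patient_id="a", age=60, kvp=120, bsa=1.8, hr=75, co=6.5, dtt=3.5
        )
        cohort = [replace(rec, patient_id=f"a{i}") for i in range(4)]
        plans, _ = cd.plan_cohort(
            cohort, reference_model.coefficients, reference_model.bounds
        )
        assert len({p.cm_expect for p in plans}) == 1

    def test_empty_cohort_rejected(self, reference_model):
        with pytest.raises(ValidationError):
            cd.plan_cohort([], reference_model.coefficients, reference_model.bounds)

    def test_closed_loop_simulation_hits_target_on_average(self, reference_model):
        """Plan doses for a synthetic testified cohort, then regenerate the
        observed CTA numbers with residual noise: the achieved mean is near
        the 400 target and the spread is tens of raw units."""
        spec = cd.derivation_cohort_spec(seed=99, n=65)
        cohort = cd.sample_factors(spec)
        plans, _ = cd.plan_cohort(
            cohort, reference_model.coefficients, reference_model.bounds, 400.0
        )
        dosed = [
            replace(r, cm=p.cm_expect)
            for r, p in zip(cohort, plans)
            if p.achievable and not p.clipped
        ]
        dosed_spec = cd.CohortSpec(
            n=len(dosed),
            seed=spec.seed,
            marginals=spec.marginals,
            ground_truth=spec.ground_truth,
            bounds=spec.bounds,
            residual_sd=spec.residual_sd,
        )
        observed = [r.cta_la for r in cd.attach_responses(dosed, dosed_spec)]
        assert np.mean(observed) == pytest.approx(400.0, abs=15.0)
        assert 5.0 < np.std(observed) < 80.0
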