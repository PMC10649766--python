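"""Design expansion, least-squares fitting and prediction."""

import numpy as np
import pytest

import ctadose as cd
from ctadose.errors import (
    RankDeficiencyError,
    UnderdeterminedError,
    ValidationError,
)
from ctadose.model import INTERACTION_PAIRS, normalize_record

from conftest import normal_equations_oracle, random_full_rank_problem


class TestExpandDesign:
    def test_zero_input_gives_constant_only(self):
        row = cd.expand_design(np.zeros(7))
        assert row.shape == (29,)
        assert row[-1] == 1.0
        assert np.all(row[:-1] == 0.0)

    def test_all_ones(self):
        assert np.all(cd.expand_design(np.ones(7)) == 1.0)

    def test_interactions_are_products(self):
        rng = np.random.default_rng(7)
        v = rng.uniform(-1, 1, 7)
        row = cd.expand_design(v)
        assert np.allclose(row[:7], v)
        for k, (i, j) in enumerate(INTERACTION_PAIRS):
            assert row[7 + k] == v[i] * v[j]

    def test_wrong_arity_rejected(self):
        with pytest.raises(ValidationError):
            cd.expand_design([0.0] * 6)

    def test_design_matrix_matches_rowwise_expansion(self):
        rng = np.random.default_rng(8)
        V = rng.uniform(-1, 1, (11, 7))
        X = cd.design_matrix(V)
        assert X.shape == (11, 29)
        for i in range(11):
            assert np.allclose(X[i], cd.expand_design(V[i]))


class TestFit:
    def test_noiseless_recovery(self):
        rng = np.random.default_rng(1)
        V = rng.uniform(-1, 1, (60, 7))
        X = cd.design_matrix(V)
        a_true = rng.normal(size=29)
        coeffs, diag = cd.fit(X, X @ a_true)
        assert np.allclose(coeffs.a, a_true, atol=1e-8)
        assert diag.loss_phi < 1e-16 * X.shape[0]
        assert diag.rank == 29

    @pytest.mark.parametrize("n", [40, 450])
    def test_matches_normal_equations_oracle(self, n):
        """The QR-based solver equals the explicit (V'V)^-1 V'y minimizer."""
        for seed in range(10):
            rng = np.random.default_rng(1000 + seed)
            X, y, _ = random_full_rank_problem(rng, n)
            coeffs, _ = cd.fit(X, y)
            oracle = normal_equations_oracle(X, y)
            assert np.allclose(coeffs.a, oracle, rtol=1e-6, atol=1e-9)

    def test_row_order_invariance(self):
        rng = np.random.default_rng(2)
        X, y, _ = random_full_rank_problem(rng, 80)
        perm = rng.permutation(80)
        c1, _ = cd.fit(X, y)
        c2, _ = cd.fit(X[perm], y[perm])
        assert np.allclose(c1.a, c2.a, atol=1e-9)

    def test_residual_orthogonal_to_design(self):
        rng = np.random.default_rng(3)
        X, y, _ = random_full_rank_problem(rng, 120)
        coeffs, _ = cd.fit(X, y)
        resid = y - X @ coeffs.a
        assert np.max(np.abs(X.T @ resid)) < 1e-6 * X.shape[0]

    def test_variance_equals_r_squared(self):
        rng = np.random.default_rng(4)
        X, y, _ = random_full_rank_problem(rng, 200)
        _, diag = cd.fit(X, y)
        assert 0.0 <= diag.variance <= 1.0
        assert abs(diag.r) <= 1.0
        assert diag.variance == pytest.approx(diag.r**2, abs=1e-9)

    def test_underdetermined_rejected(self):
        rng = np.random.default_rng(5)
        X, y, _ = random_full_rank_problem(rng, 20)
        with pytest.raises(UnderdeterminedError):
            cd.fit(X, y)

    def test_rank_deficiency_names_collinear_columns(self):
        rng = np.random.default_rng(6)
        V = rng.uniform(-1, 1, (100, 7))
        V[:, 1] = V[:, 0]  # tube voltage duplicates age -> AxB == A^2 etc.
        X = cd.design_matrix(V)
        with pytest.raises(RankDeficiencyError) as exc_info:
            cd.fit(X, rng.normal(size=100))
        assert len(exc_info.value.columns) > 0


class TestPredict:
    def test_all_zero_factors_return_constant(self, reference_model):
        pred = cd.predict_normalized(np.zeros(7), reference_model.coefficients)
        assert pred == pytest.approx(-0.419399, abs=1e-12)

    def test_zero_coefficients_predict_zero(self):
        coeffs = cd.CoefficientSet(np.zeros(29))
        rng = np.random.default_rng(9)
        for _ in range(5):
            assert cd.predict_normalized(rng.uniform(-1, 1, 7), coeffs) == 0.0

    def test_affine_in_each_single_factor(self, reference_model):
        """With other factors fixed, the prediction at v_k=0 is the mean of
        the predictions at v_k=+1 and v_k=-1."""
        rng = np.random.default_rng(10)
        coeffs = reference_model.coefficients
        for k in range(7):
            v = rng.uniform(-1, 1, 7)
            v_mid, v_lo, v_hi = v.copy(), v.copy(), v.copy()
            v_mid[k], v_lo[k], v_hi[k] = 0.0, -1.0, 1.0
            mid = cd.predict_normalized(v_mid, coeffs)
            mean = 0.5 * (
                cd.predict_normalized(v_lo, coeffs) + cd.predict_normalized(v_hi, coeffs)
            )
            assert mid == pytest.approx(mean, abs=1e-12)

    @pytest.mark.parametrize(
        "y_star, raw", [(1.0, 868.0), (-1.0, 244.0), (0.0, 556.0)]
    )
    def test_response_back_transform(self, reference_model, y_star, raw):
        from ctadose.model import cta_from_normalized

        assert cta_from_normalized(y_star, reference_model.bounds) == pytest.approx(raw)

    def test_predict_cta_is_affine_in_normalized_prediction(self, reference_model):
        rec = cd.PatientRecord(
            patient_id="x", age=56, kvp=100, bsa=1.75, hr=72, co=6.3, cm=37, dtt=3.1
        )
        v = normalize_record(rec, reference_model.bounds)
        y_star = cd.predict_normalized(v, reference_model.coefficients)
        raw = cd.predict_cta(rec, reference_model.coefficients, reference_model.bounds)
        resp = reference_model.bounds.response
        assert raw == pytest.approx((y_star * resp.half_range + resp.center) * 400.0)


class TestPatientRecord:
    def test_rejects_non_positive_factor(self):
        with pytest.raises(ValidationError):
            cd.PatientRecord(
                patient_id="x", age=-5, kvp=100, bsa=1.7, hr=70, co=6, cm=40, dtt=3
            )

    def test_cm_may_be_missing_but_not_other_factors(self):
        rec = cd.PatientRecord(
            patient_id="x", age=50, kvp=100, bsa=1.7, hr=70, co=6, dtt=3
        )
        assert rec.cm is None
        with pytest.raises(ValidationError):
            rec.factor_values()
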