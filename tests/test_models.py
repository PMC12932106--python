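"""Response transforms, Scheffe/RSM fitting, and whole-model ANOVA."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from aavdoe import (
    anova_model,
    d_optimal_select,
    fit_rsm,
    fit_scheffe,
    log_vp,
    mass_to_copies,
    pct_full,
    predict,
)
from aavdoe.models import rsm_matrix, scheffe_matrix


class TestDerivedResponses:
    @pytest.mark.parametrize(
        "titer,time,expected",
        [(1e10, 1, 10.0), (2e9, 2, 9.0), (5e11, 2, 11.39794)],
    )
    def test_log_vp_values(self, titer, time, expected):
        assert log_vp(titer, time) == pytest.approx(expected, abs=1e-5)

    def test_log_vp_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            log_vp(0, 1)
        with pytest.raises(ValueError):
            log_vp(1e10, 0)

    @pytest.mark.parametrize(
        "vg,capsid,expected", [(5e10, 1e11, 50.0), (0, 1e11, 0.0)]
    )
    def test_pct_full_values(self, vg, capsid, expected):
        assert pct_full(vg, capsid) == pytest.approx(expected)

    def test_pct_full_above_100_flagged(self):
        with pytest.warns(UserWarning, match="inconsistency"):
            val = pct_full(1.2e11, 1e11)
        assert val == pytest.approx(120.0)

    def test_pct_full_rejects_zero_capsids(self):
        with pytest.raises(ValueError):
            pct_full(1e10, 0)

    def test_scale_consistency(self):
        # doubling both titers leaves %full unchanged; doubling vg adds log10(2)
        assert pct_full(2 * 5e10, 2 * 1e11) == pct_full(5e10, 1e11)
        assert log_vp(2e10, 1) - log_vp(1e10, 1) == pytest.approx(np.log10(2))

    @pytest.mark.parametrize(
        "mass,length,expected",
        [(0.0, 500, 0.0), (1.0, 1000, 9.2648e11), (2.0, 19306, 9.598e10)],
    )
    def test_mass_to_copies(self, mass, length, expected):
        assert mass_to_copies(mass, length) == pytest.approx(expected, rel=1e-3)

    def test_mass_to_copies_single_stranded(self):
        # ssDNA at 330 g/mol/base roughly doubles the copy number
        ratio = mass_to_copies(1, 1000, double_stranded=False) / mass_to_copies(1, 1000)
        assert ratio == pytest.approx(650 / 330)

    def test_mass_to_copies_rejects_bad_length(self):
        with pytest.raises(ValueError):
            mass_to_copies(1.0, 0)


@pytest.fixture(scope="module")
def md10(candidates_module):
    return d_optimal_select(candidates_module, n_runs=10, seed=2)


@pytest.fixture(scope="module")
def candidates_module():
    from aavdoe import MixtureBounds, simplex_candidates

    return simplex_candidates(MixtureBounds(), 0.05)


class TestScheffeFit:
    def test_noiseless_round_trip(self, md10, rng):
        beta = rng.normal(size=6)
        y = scheffe_matrix(md10.runs) @ beta
        model = fit_scheffe(md10, y)
        np.testing.assert_allclose(model.coef, beta, atol=1e-8)

    def test_pure_blend_prediction_is_linear_coefficient(self, md10, rng):
        beta = rng.normal(size=6)
        model = fit_scheffe(md10, scheffe_matrix(md10.runs) @ beta)
        for i, e_i in enumerate(np.eye(3)):
            assert model.predict(e_i[None, :])[0] == pytest.approx(beta[i], abs=1e-8)

    def test_underdetermined_rejected(self, md10):
        with pytest.raises(ValueError, match="at least 6"):
            fit_scheffe(md10.runs[:5], np.zeros(5))

    def test_rank_deficiency_named(self):
        runs = np.tile(np.array([[0.4, 0.3, 0.3]]), (8, 1))
        with pytest.raises(np.linalg.LinAlgError, match="rank deficient"):
            fit_scheffe(runs, np.zeros(8))

    def test_off_simplex_prediction_rejected(self, md10, rng):
        model = fit_scheffe(md10, rng.normal(size=md10.n_runs))
        with pytest.raises(ValueError, match="sum to 1"):
            model.predict(np.array([[0.5, 0.5, 0.5]]))

    def test_blend_term_prediction(self, md10):
        # surface with only the pHelper*pRepCap blending term = 4
        beta = np.array([0, 0, 0, 4.0, 0, 0])
        model = fit_scheffe(md10, scheffe_matrix(md10.runs) @ beta)
        assert model.predict(np.array([[0.5, 0.5, 0.0]]))[0] == pytest.approx(1.0)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_round_trip_property(self, md10, seed):
        beta = np.random.default_rng(seed).normal(scale=5, size=6)
        model = fit_scheffe(md10, scheffe_matrix(md10.runs) @ beta)
        np.testing.assert_allclose(model.coef, beta, atol=1e-8)


class TestRSMFit:
    def test_exact_recovery_on_nine_point_fccd(self, fccd9):
        beta = np.array([2.0, 3.0, -1.0, 0.5, -0.25, 1.0])
        y = rsm_matrix(fccd9.coded_runs) @ beta
        model = fit_rsm(fccd9, y)
        np.testing.assert_allclose(model.coef, beta, atol=1e-8)
        assert model.beta0 == pytest.approx(2.0)
        np.testing.assert_allclose(model.beta_interact, [1.0], atol=1e-8)

    def test_constant_surface(self, fccd9):
        model = fit_rsm(fccd9, np.full(9, 7.25))
        assert model.beta0 == pytest.approx(7.25)
        np.testing.assert_allclose(model.coef[1:], 0.0, atol=1e-10)

    def test_saturated_design_flags_zero_residual_df(self):
        coded = np.array([[-1, -1], [-1, 1], [1, -1], [1, 1], [0, 0], [1, 0]], float)
        y = np.arange(6, dtype=float)
        model = fit_rsm(coded, y)
        table = anova_model(model)
        assert table.df_residual == 0
        assert np.isnan(table.p_value)

    def test_intercept_only_predicts_constant(self, fccd9, rng):
        model = fit_rsm(fccd9, np.full(9, 3.5))
        pts = rng.uniform(-1, 1, size=(20, 2))
        np.testing.assert_allclose(model.predict(pts), 3.5, atol=1e-10)


class TestPredict:
    def test_matches_manual_polynomial_evaluation(self, fccd9, rng):
        beta = rng.normal(size=6)
        model = fit_rsm(fccd9, rsm_matrix(fccd9.coded_runs) @ beta)
        pts = rng.uniform(-1, 1, size=(100, 2))
        x1, x2 = pts[:, 0], pts[:, 1]
        manual = (
            beta[0] + beta[1] * x1 + beta[2] * x2
            + beta[3] * x1**2 + beta[4] * x2**2 + beta[5] * x1 * x2
        )
        np.testing.assert_allclose(predict(model, pts), manual, atol=1e-10)


class TestAnova:
    def test_perfect_signal_dominates(self, md10):
        beta = np.array([10, 8, 6, 4, -4, 2.0])
        y = scheffe_matrix(md10.runs) @ beta + 1e-9 * np.arange(md10.n_runs)
        table = anova_model(fit_scheffe(md10, y))
        assert table.p_value < 1e-10

    def test_sum_of_squares_identity(self, md10, rng):
        y = rng.normal(size=md10.n_runs)
        model = fit_scheffe(md10, y)
        table = anova_model(model)
        total = float(np.sum((y - y.mean()) ** 2))
        assert table.ss_model + table.ss_residual == pytest.approx(total, rel=1e-8)

    def test_degrees_of_freedom_partition(self, md10, rng):
        table = anova_model(fit_scheffe(md10, rng.normal(size=md10.n_runs)))
        # mean-corrected partition: model df + residual df = n - 1
        assert table.df_model + table.df_residual == md10.n_runs - 1

    def test_type_one_error_quick(self, md10):
        # small-n sanity run; the calibrated 1000-rep check lives in acceptance
        rng = np.random.default_rng(0)
        rejections = 0
        reps = 200
        for _ in range(reps):
            y = rng.standard_normal(md10.n_runs)
            if anova_model(fit_scheffe(md10.runs, y), y).p_value < 0.05:
                rejections += 1
        assert 0.01 <= rejections / reps <= 0.12

    def test_confidence_interval_contains_truth_noiseless(self, md10):
        beta = np.array([1.0, 2.0, 3.0, -1.0, 0.5, 0.25])
        y = scheffe_matrix(md10.runs) @ beta
        y = y + 1e-6 * np.random.default_rng(1).standard_normal(md10.n_runs)
        ci = fit_scheffe(md10, y).conf_int()
        assert np.all(ci[:, 0] <= beta + 1e-4)
        assert np.all(beta - 1e-4 <= ci[:, 1])
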