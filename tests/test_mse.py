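"""Log-linear fitting, BIC weighting, profile intervals and the BMA."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mselink import (
    ContingencyTable,
    EstimationError,
    ModelSpec,
    ThreeListMSE,
    estimate_m000,
    fit_loglinear,
    list_sensitivity,
    model_average,
    model_bic,
    mse_estimate,
    posterior_probs,
    profile_interval,
)
from mselink.mse import FittedModel

from conftest import random_positive_tables

# Published eight-model comparison for the Sudan 2018-19 demonstrations
# cohort (Dec 2018 - Feb 2019, n_obs = 69): per-model BIC, m_000, posterior.
PUBLISHED_BIC = (0.30, -5.07, 4.53, 0.30, -2.87, -2.77, 4.45, 0.0)
PUBLISHED_M000 = (2.0, 5.0, 2.0, 1.0, 16.0, 2.0, 1.0, 7.0)
PUBLISHED_POSTERIOR = (0.036, 0.531, 0.004, 0.036, 0.177, 0.168, 0.005, 0.042)


class TestModelSpec:
    def test_exactly_eight_models_with_expected_df(self):
        specs = ModelSpec.all_specs()
        assert len(specs) == len(set(specs)) == 8
        assert [s.df for s in specs] == [3, 2, 2, 2, 1, 1, 1, 0]
        assert specs[-1].is_saturated

    def test_interaction_terms_canonicalize(self):
        assert ModelSpec(("jk", "ij")).interactions == ("ij", "jk")
        with pytest.raises(ValueError):
            ModelSpec(("xy",))


class TestFitLoglinear:
    def test_saturated_fit_reproduces_observed_cells(self, moderate_table):
        fm = fit_loglinear(moderate_table, ModelSpec(("ij", "ik", "jk")))
        assert np.allclose(fm.fitted_cells, moderate_table.counts(), atol=1e-7)
        assert fm.deviance_G2 == 0.0
        assert fm.bic == 0.0

    def test_independence_fit_on_perfect_independence_pattern(self, independence_table):
        fm = fit_loglinear(independence_table, ModelSpec(()))
        assert fm.deviance_G2 == pytest.approx(0.0, abs=1e-8)
        assert np.allclose(fm.fitted_cells, independence_table.counts(), atol=1e-6)
        assert fm.m_000 == pytest.approx(1.0, abs=1e-8)

    def test_strong_dependence_shows_up_in_deviance(self):
        # heavy ij overlap that independence cannot explain
        t = ContingencyTable.from_counts(
            {"111": 30, "110": 40, "101": 6, "011": 6, "100": 8, "010": 8, "001": 30}
        )
        fm = fit_loglinear(t, ModelSpec(()))
        from scipy.stats import chi2

        assert fm.deviance_G2 > chi2.ppf(0.95, df=3)

    def test_fitted_margins_match_observed_sufficient_statistics(self, moderate_table):
        for spec in ModelSpec.all_specs():
            fm = fit_loglinear(moderate_table, spec)
            X = spec.design_matrix()
            assert np.allclose(X.T @ fm.fitted_cells, X.T @ moderate_table.counts(), atol=1e-6)

    def test_statsmodels_glm_agrees(self, moderate_table):
        sm = pytest.importorskip("statsmodels.api")
        x = moderate_table.counts()
        for spec in ModelSpec.all_specs():
            X = spec.design_matrix()
            glm = sm.GLM(x, X, family=sm.families.Poisson()).fit()
            fm = fit_loglinear(moderate_table, spec)
            assert np.allclose(fm.fitted_cells, glm.fittedvalues, rtol=1e-6)


class TestEstimateM000:
    def test_all_unit_cells_give_one(self):
        fm = FittedModel(
            spec=ModelSpec(()), fitted_cells=np.ones(7), coefficients=np.zeros(4),
            m_000=1.0, deviance_G2=0.0, df=3, bic=0.0, converged=True, n_obs=7,
        )
        assert estimate_m000(fm) == pytest.approx(1.0)

    def test_cross_ratio_arithmetic(self):
        cells = dict(
            m_111=8.0, m_110=4.0, m_101=4.0, m_011=4.0, m_100=2.0, m_010=2.0, m_001=2.0
        )
        order = ("m_111", "m_110", "m_101", "m_011", "m_100", "m_010", "m_001")
        fm = FittedModel(
            spec=ModelSpec(()), fitted_cells=np.array([cells[k] for k in order]),
            coefficients=np.zeros(4), m_000=1.0, deviance_G2=0.0, df=3, bic=0.0,
            converged=True, n_obs=26,
        )
        assert estimate_m000(fm) == pytest.approx(8 * 2 * 2 * 2 / (4 * 4 * 4))

    def test_zero_denominator_cell_is_named(self):
        fm = FittedModel(
            spec=ModelSpec(()), fitted_cells=np.array([1, 1, 0, 1, 1, 1, 1.0]),
            coefficients=np.zeros(4), m_000=np.inf, deviance_G2=0.0, df=3, bic=0.0,
            converged=True, n_obs=6,
        )
        with pytest.raises(EstimationError, match="m_101"):
            estimate_m000(fm)

    def test_ratio_equals_exp_intercept_for_every_model(self):
        for t in random_positive_tables(5, seed=42):
            for spec in ModelSpec.all_specs():
                fm = fit_loglinear(t, spec)
                assert estimate_m000(fm) == pytest.approx(
                    math.exp(fm.coefficients[0]), rel=1e-7
                )


class TestModelBic:
    def test_deviance_minus_penalty_credit(self):
        assert model_bic(13.0, 3, 69) == pytest.approx(13.0 - 3 * math.log(69))
        assert model_bic(13.0, 3, 69) == pytest.approx(0.30, abs=0.005)

    def test_saturated_is_zero_for_any_n(self):
        assert model_bic(0.0, 0, 69) == 0.0
        assert model_bic(0.0, 0, 5000) == 0.0

    def test_zero_observations_rejected(self):
        with pytest.raises(ValueError):
            model_bic(1.0, 1, 0)


class TestPosteriorProbs:
    def test_published_bic_column_reproduces_published_posteriors(self):
        w = posterior_probs(PUBLISHED_BIC)
        assert np.allclose(np.round(w.probs, 3), PUBLISHED_POSTERIOR, atol=1e-12)

    def test_equal_bics_give_uniform_weights(self):
        w = posterior_probs([3.3] * 8)
        assert np.allclose(w.probs, 1 / 8)

    def test_dominant_model_takes_all_weight(self):
        w = posterior_probs([-1e6] + [0.0] * 7)
        assert w[0] == pytest.approx(1.0)

    def test_non_finite_bic_rejected(self):
        with pytest.raises(ValueError):
            posterior_probs([0.0, np.nan] + [0.0] * 6)

    @given(
        bics=st.lists(st.floats(-30, 30), min_size=8, max_size=8),
        shift=st.floats(-100, 100),
    )
    @settings(deadline=None, max_examples=50)
    def test_shift_invariance(self, bics, shift):
        w0 = posterior_probs(bics)
        w1 = posterior_probs([b + shift for b in bics])
        assert np.allclose(w0.probs, w1.probs, atol=1e-12)


class TestModelAverage:
    def test_published_columns_average_to_about_six(self):
        w = posterior_probs(PUBLISHED_BIC)
        avg = model_average(PUBLISHED_M000, w)
        assert avg == pytest.approx(6.24, abs=0.01)
        assert round(avg) == 6

    def test_constant_estimates_are_fixed_points(self):
        w = posterior_probs(list(PUBLISHED_BIC))
        assert model_average([3.7] * 8, w) == pytest.approx(3.7)

    def test_point_mass_weight_selects_that_model(self):
        w = posterior_probs([0.0] + [1e6] * 7)
        assert model_average([11.0, 2, 2, 2, 2, 2, 2, 2], w) == pytest.approx(11.0)

    def test_misaligned_inputs_rejected(self):
        with pytest.raises(ValueError, match="misaligned"):
            model_average([1.0, 2.0], posterior_probs(PUBLISHED_BIC))


class TestProfileInterval:
    def test_interval_contains_point_estimate(self, moderate_table):
        for spec in (ModelSpec(()), ModelSpec(("ij",))):
            fm = fit_loglinear(moderate_table, spec)
            lo, hi = profile_interval(moderate_table, spec)
            assert lo <= fm.m_000 <= hi

    def test_intervals_nest_as_level_grows(self, moderate_table):
        widths = []
        for level in (0.80, 0.90, 0.95, 0.99):
            lo, hi = profile_interval(moderate_table, ModelSpec(()), level=level)
            widths.append((lo, hi))
        for (lo_a, hi_a), (lo_b, hi_b) in zip(widths, widths[1:]):
            assert lo_b <= lo_a + 1e-9 and hi_b >= hi_a - 1e-9

    def test_near_point_mass_table_collapses_interval(self):
        # overwhelming overlap, tiny singles: almost nobody is unseen
        t = ContingencyTable.from_counts(
            {"111": 500, "110": 40, "101": 40, "011": 40, "100": 1, "010": 1, "001": 1}
        )
        lo, hi = profile_interval(t, ModelSpec(()))
        assert hi - lo <= 2.0
        assert lo <= 1.0

    def test_deviance_cutoff_option(self, moderate_table):
        lo, hi = profile_interval(moderate_table, ModelSpec(()), method="deviance")
        fm = fit_loglinear(moderate_table, ModelSpec(()))
        assert lo <= fm.m_000 <= hi

    def test_no_interaction_estimator_bias_and_coverage(self):
        # independent lists, N = 100, p = (0.7, 0.6, 0.6): the no-interaction
        # model should be nearly unbiased and its 95% profile interval should
        # cover the realized unseen count at close to nominal rate
        rng = np.random.default_rng(2025)
        p = np.array([0.7, 0.6, 0.6])
        cell_p = {}
        for h in [(a, b, c) for a in (0, 1) for b in (0, 1) for c in (0, 1)]:
            cell_p[h] = float(np.prod([pi if hi else 1 - pi for pi, hi in zip(p, h)]))
        order = [(1, 1, 1), (1, 1, 0), (1, 0, 1), (0, 1, 1), (1, 0, 0), (0, 1, 0), (0, 0, 1), (0, 0, 0)]
        probs = [cell_p[h] for h in order]
        reps, hits, est = 500, 0, []
        for _ in range(reps):
            draw = rng.multinomial(100, probs)
            t = ContingencyTable.from_counts(dict(zip(["111", "110", "101", "011", "100", "010", "001"], draw[:7])))
            true_unseen = int(draw[7])
            fm = fit_loglinear(t, ModelSpec(()))
            lo, hi = profile_interval(t, ModelSpec(()))
            est.append(fm.m_000)
            hits += lo <= true_unseen <= hi
        expected_unseen = 100 * cell_p[(0, 0, 0)]
        assert abs(np.mean(est) - expected_unseen) / expected_unseen <= 0.05
        assert 0.93 <= hits / reps <= 0.97


class TestMseEstimate:
    def test_results_satisfy_basic_contracts(self, moderate_table):
        res = mse_estimate(moderate_table)
        assert res.N_hat >= res.n_obs
        assert res.interval[0] >= res.n_obs
        assert sum(res.weights) == pytest.approx(1.0)
        assert len(res.per_model) == 8
        for fm in res.per_model:
            lo, hi = fm.interval_m000
            assert lo <= hi

    def test_all_zero_table_rejected(self):
        t = ContingencyTable.from_counts({})
        with pytest.raises(EstimationError, match="nothing observed"):
            mse_estimate(t)

    def test_label_permutation_invariance(self, moderate_table):
        base = mse_estimate(moderate_table)
        # swap lists i and k: cells permute accordingly
        swapped = ContingencyTable.from_counts(
            {
                "111": moderate_table.x_111,
                "110": moderate_table.x_011,
                "101": moderate_table.x_101,
                "011": moderate_table.x_110,
                "100": moderate_table.x_001,
                "010": moderate_table.x_010,
                "001": moderate_table.x_100,
            }
        )
        other = mse_estimate(swapped)
        key = lambda fm: (fm.df, round(fm.deviance_G2, 8), round(fm.bic, 8), round(fm.m_000, 8))
        assert sorted(map(key, base.per_model)) == sorted(map(key, other.per_model))
        assert base.m_000_avg == pytest.approx(other.m_000_avg, abs=1e-8)

    def test_more_overlap_means_fewer_unseen(self):
        cells = {"111": 10, "110": 8, "101": 8, "011": 8, "100": 6, "010": 6, "001": 6}
        prev = np.inf
        for x111 in (5, 10, 20, 40):
            cells["111"] = x111
            fm = fit_loglinear(ContingencyTable.from_counts(cells), ModelSpec(()))
            assert fm.m_000 < prev
            prev = fm.m_000

    def test_continuity_auto_handles_empty_cell(self):
        # an empty 011 cell puts the saturated cross-ratio at infinity; the
        # auto continuity correction keeps every point estimate finite, and
        # models whose profile stays improper are truncated with a warning
        t = ContingencyTable.from_counts(
            {"111": 20, "110": 12, "101": 12, "011": 0, "100": 9, "010": 6, "001": 6}
        )
        from mselink.mse import BoundaryWarning

        with pytest.warns(BoundaryWarning):
            res = mse_estimate(t, continuity="auto")
        assert np.isfinite(res.m_000_avg)
        assert res.interval[1] > res.interval[0]

    def test_model_class_wraps_pipeline(self, moderate_table):
        res = ThreeListMSE(moderate_table).fit()
        direct = mse_estimate(moderate_table)
        assert res.m_000_avg == pytest.approx(direct.m_000_avg)
        text = res.summary()
        assert "saturated" in text and "N_hat" in text

    def test_from_dataframe_and_csv_constructors(self, tmp_path, moderate_table):
        path = tmp_path / "t.csv"
        moderate_table.write_csv(path)
        from_csv = ThreeListMSE.from_csv(path)
        assert from_csv.table.counts().tolist() == moderate_table.counts().tolist()
        import pandas as pd

        frame = pd.read_csv(path)
        from_frame = ThreeListMSE.from_dataframe(frame)
        assert from_frame.table.counts().tolist() == moderate_table.counts().tolist()


class TestSensitivity:
    def _results_like(self, counts, m000, lo, hi):
        t = ContingencyTable.from_counts(counts)
        res = mse_estimate(t)
        # override averaged quantities with the published ones to test the
        # sensitivity arithmetic in isolation
        res.m_000_avg = m000
        res.interval_m000 = (lo, hi)
        return t, res

    def test_combined_sensitivity_rounds_to_published_percent(self):
        counts = {"111": 9, "110": 10, "101": 10, "011": 10, "100": 10, "010": 10, "001": 10}
        t, res = self._results_like(counts, m000=6.0, lo=2.0, hi=31.0)
        s = list_sensitivity(t, res, "combined")
        assert s.n_captured == 69
        assert s.percent == 92
        assert s.percent_interval == (69, 97)

    def test_capture_everything_gives_full_sensitivity(self):
        counts = {"111": 9, "110": 10, "101": 10, "011": 10, "100": 10, "010": 10, "001": 10}
        t, res = self._results_like(counts, m000=0.0, lo=0.0, hi=0.0)
        s = list_sensitivity(t, res, "combined")
        assert s.percent == 100

    def test_single_list_sensitivity_uses_list_margin(self):
        counts = {"111": 9, "110": 16, "101": 16, "011": 4, "100": 14, "010": 5, "001": 5}
        t, res = self._results_like(counts, m000=6.24, lo=2.0, hi=31.0)
        s = list_sensitivity(t, res, "A")
        assert s.n_captured == t.captured_on("A") == 55
        assert s.percent == 73
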