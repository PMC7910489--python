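import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from hicwaves.qlstats import (
    bh_adjust,
    classify_patterns,
    estimate_common_dispersion,
    fit_nb_glm,
    oneway_design,
    ql_f_test,
    squeeze_ql_dispersions,
    transition_contrasts,
    treat_test,
)


@pytest.fixture
def design_2x2():
    X, levels = oneway_design(["a", "a", "b", "b"])
    return X, levels


def _nb(rng, mu, phi, size):
    n = 1.0 / phi
    return rng.negative_binomial(n, n / (n + mu), size=size).astype(float)


class TestNbGlmFit:
    def test_intercept_only_mean_is_sample_mean(self):
        fit = fit_nb_glm(np.array([[4.0, 6.0]]), np.ones((2, 1)), dispersion=0.1)
        assert np.allclose(fit.fitted_means, 5.0, atol=1e-6)

    def test_two_group_saturated_logfc(self, design_2x2):
        X, _ = design_2x2
        fit = fit_nb_glm(np.array([[10.0, 10.0, 20.0, 20.0]]), X, dispersion=0.05)
        logfc = (fit.coefficients @ np.array([-1.0, 1.0])) / np.log(2)
        assert logfc[0] == pytest.approx(1.0, abs=1e-6)

    def test_all_zero_feature_at_lower_bound(self, design_2x2):
        X, _ = design_2x2
        fit = fit_nb_glm(np.zeros((1, 4)), X, dispersion=0.1)
        assert fit.deviance[0] == 0.0
        assert np.all(fit.coefficients[0] <= -29.0)

    def test_poisson_limit_matches_nb_at_zero_dispersion(self, design_2x2):
        X, _ = design_2x2
        y = np.array([[3.0, 8.0, 11.0, 6.0]])
        f0 = fit_nb_glm(y, X, dispersion=0.0)
        # saturated one-way fit: group means regardless of dispersion
        assert np.allclose(f0.fitted_means, [[5.5, 5.5, 8.5, 8.5]], atol=1e-6)

    def test_offsets_shift_coefficients(self):
        y = np.array([[10.0, 20.0]])
        fit = fit_nb_glm(y, np.ones((2, 1)), offsets=np.log([[1.0, 2.0]]), dispersion=0.0)
        # with offsets absorbing the doubling, a common rate of 10 fits both
        assert np.allclose(fit.fitted_means, [[10.0, 20.0]], atol=1e-5)

    def test_negative_counts_rejected(self, design_2x2):
        X, _ = design_2x2
        with pytest.raises(ValueError):
            fit_nb_glm(np.array([[-1.0, 1, 1, 1]]), X)


class TestCommonDispersion:
    def test_poisson_counts_give_near_zero(self, design_2x2):
        X, _ = design_2x2
        rng = np.random.default_rng(21)
        y = rng.poisson(100.0, size=(200, 4)).astype(float)
        assert estimate_common_dispersion(y, X) < 0.01

    def test_recovers_true_dispersion(self, design_2x2):
        X, _ = design_2x2
        rng = np.random.default_rng(22)
        y = _nb(rng, 100.0, 0.1, (300, 4))
        est = estimate_common_dispersion(y, X)
        assert 0.05 <= est <= 0.2

    def test_identical_replicates_hit_lower_bound(self, design_2x2):
        X, _ = design_2x2
        y = np.tile([[50.0, 50.0, 80.0, 80.0]], (50, 1))
        assert estimate_common_dispersion(y, X) <= 2e-6

    def test_no_replication_rejected(self):
        X, _ = oneway_design(["a", "b"])
        with pytest.raises(ValueError):
            estimate_common_dispersion(np.ones((10, 2)), X)


class TestSqueeze:
    def _fit(self, y, X, disp=0.05):
        return fit_nb_glm(y, X, dispersion=disp)

    def test_equal_raw_values_give_infinite_prior(self, design_2x2):
        X, _ = design_2x2

        class Fake:
            residual_df = 4
            deviance = np.full(50, 4 * 0.7)

        ql = squeeze_ql_dispersions(Fake(), trend="none")
        assert np.isinf(ql.prior_df)
        assert np.allclose(ql.squeezed, 0.7, rtol=1e-6)

    def test_forced_zero_prior_df_returns_raw(self, design_2x2):
        X, _ = design_2x2
        rng = np.random.default_rng(3)
        fit = self._fit(_nb(rng, 50, 0.05, (100, 4)), X)
        ql = squeeze_ql_dispersions(fit, trend="none", prior_df=0)
        assert np.allclose(ql.squeezed, ql.raw)

    def test_squeezed_is_convex_combination(self, design_2x2):
        X, _ = design_2x2
        rng = np.random.default_rng(4)
        fit = self._fit(_nb(rng, 60, 0.08, (300, 4)), X)
        ql = squeeze_ql_dispersions(fit, abundance=np.log2(fit.counts.mean(1) + 0.5))
        lo = np.minimum(ql.raw, ql.trend) - 1e-12
        hi = np.maximum(ql.raw, ql.trend) + 1e-12
        assert np.all((ql.squeezed >= lo) & (ql.squeezed <= hi))

    def test_prior_df_recovered_within_factor_two(self):
        d0, d1 = 10.0, 6
        s2 = 0.8 * stats.f.rvs(d1, d0, size=3000, random_state=17)

        class Fake:
            residual_df = d1
            deviance = s2 * d1

        ql = squeeze_ql_dispersions(Fake(), trend="none")
        assert d0 / 2 <= ql.prior_df <= d0 * 2


class TestQlFTest:
    def test_identical_groups_are_null(self, design_2x2):
        X, levels = design_2x2
        y = np.tile([[30.0, 35.0, 30.0, 35.0]], (20, 1))
        fit = fit_nb_glm(y, X, dispersion=0.05)
        ql = squeeze_ql_dispersions(fit, trend="none")
        res = ql_f_test(fit, ql, np.array([-1.0, 1.0]))
        assert np.allclose(res["logFC"], 0.0, atol=1e-8)
        assert np.allclose(res["statistic"], 0.0, atol=1e-8)
        assert np.allclose(res["p"], 1.0)

    def test_null_pvalues_uniform(self, design_2x2):
        X, _ = design_2x2
        rng = np.random.default_rng(8)
        y = _nb(rng, 80, 0.05, (500, 4))
        fit = fit_nb_glm(y, X, dispersion=estimate_common_dispersion(y, X))
        ql = squeeze_ql_dispersions(fit, abundance=np.log2(y.mean(1) + 0.5))
        res = ql_f_test(fit, ql, np.array([-1.0, 1.0]))
        assert stats.kstest(res["p"], "uniform").pvalue > 0.01

    def test_large_effect_ranks_first(self, design_2x2):
        X, _ = design_2x2
        rng = np.random.default_rng(9)
        y = _nb(rng, 50, 0.01, (200, 4))
        y[7, 2:] *= 16.0
        fit = fit_nb_glm(y, X, dispersion=0.01)
        ql = squeeze_ql_dispersions(fit, trend="none")
        res = ql_f_test(fit, ql, np.array([-1.0, 1.0]))
        assert res["p"].idxmin() == 7


class TestTreat:
    def test_threshold_one_reduces_to_f_test(self, design_2x2):
        X, _ = design_2x2
        rng = np.random.default_rng(10)
        y = _nb(rng, 60, 0.05, (300, 4))
        fit = fit_nb_glm(y, X, dispersion=0.04)
        ql = squeeze_ql_dispersions(fit, trend="none")
        c = np.array([-1.0, 1.0])
        p_f = ql_f_test(fit, ql, c)["p"].to_numpy()
        p_t = treat_test(fit, ql, c, fc_threshold=1.0)["p"].to_numpy()
        assert np.max(np.abs(p_f - p_t)) < 1e-10

    def test_interior_of_null_gives_large_p(self, design_2x2):
        X, _ = design_2x2
        y = np.tile([[1000.0, 1005.0, 1010.0, 1000.0]], (30, 1))
        fit = fit_nb_glm(y, X, dispersion=1e-4)
        ql = squeeze_ql_dispersions(fit, trend="none")
        res = treat_test(fit, ql, np.array([-1.0, 1.0]), fc_threshold=1.5)
        assert np.all(res["p"] > 0.9)

    def test_power_for_fourfold_change_at_threshold(self, design_2x2):
        """A true 4-fold change clears TREAT(1.5) at FDR 5% in most replicates."""
        X, _ = design_2x2
        detected = 0
        n_rep = 50
        for rep in range(n_rep):
            rng = np.random.default_rng(1000 + rep)
            y = _nb(rng, 100, 0.02, (150, 4))
            y[0, 2:] *= 4.0
            fit = fit_nb_glm(y, X, dispersion=0.02)
            ql = squeeze_ql_dispersions(fit, trend="none")
            res = treat_test(fit, ql, np.array([-1.0, 1.0]), fc_threshold=1.5)
            if res["fdr"][0] < 0.05:
                detected += 1
        assert detected >= 0.9 * n_rep

    def test_threshold_monotonicity(self, design_2x2):
        X, _ = design_2x2
        rng = np.random.default_rng(12)
        y = _nb(rng, 80, 0.05, (200, 4))
        y[:20, 2:] *= 3
        fit = fit_nb_glm(y, X, dispersion=0.05)
        ql = squeeze_ql_dispersions(fit, trend="none")
        c = np.array([-1.0, 1.0])
        counts = [
            int((treat_test(fit, ql, c, fc_threshold=fc)["fdr"] < 0.05).sum())
            for fc in (1.0, 1.2, 1.5, 2.0)
        ]
        assert counts == sorted(counts, reverse=True)


class TestBhAdjust:
    def test_textbook_example(self):
        assert np.allclose(bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        assert bh_adjust([0.2])[0] == pytest.approx(0.2)

    def test_all_ones_capped(self):
        assert np.all(bh_adjust([1.0, 1.0, 1.0]) == 1.0)

    def test_nan_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.1, np.nan])

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=40))
    def test_matches_brute_force_step_up(self, ps):
        p = np.asarray(ps)
        m = len(p)
        # independent brute-force step-up definition
        expected = np.empty(m)
        order = np.argsort(p, kind="stable")
        prev = 1.0
        for rank_from_top in range(m, 0, -1):
            i = order[rank_from_top - 1]
            val = min(prev, p[i] * m / rank_from_top, 1.0)
            expected[i] = val
            prev = val
        assert np.allclose(bh_adjust(p), expected, atol=1e-12)


class TestClassifyPatterns:
    def _mk(self, fdrs, logfcs):
        return {
            f"t{k}": pd.DataFrame(
                {"feature_id": ["f1"], "logFC": [logfcs[k]], "statistic": [1.0],
                 "p": [0.5], "fdr": [fdrs[k]]}
            )
            for k in range(len(fdrs))
        }

    def test_single_significant_transition(self):
        pats = classify_patterns(self._mk([0.01, 0.2, 0.2, 0.2, 0.2], [1, 1, 1, 1, 1]))
        assert pats.loc["f1"].tolist() == [1, 0, 0, 0, 0]

    def test_boundary_fdr_is_strict(self):
        pats = classify_patterns(self._mk([0.05, 0.04999], [1, -1]))
        assert pats.loc["f1"].tolist() == [0, -1]

    def test_mixed_directions(self):
        pats = classify_patterns(self._mk([0.01, 0.01], [1.0, -2.0]))
        assert pats.loc["f1"].tolist() == [1, -1]

    def test_missing_feature_rejected(self):
        res = self._mk([0.01, 0.01], [1, 1])
        res["t1"] = res["t1"].assign(feature_id=["other"])
        with pytest.raises(ValueError):
            classify_patterns(res)


class TestDesign:
    def test_oneway_rows_sum_to_one(self):
        X, levels = oneway_design(["a", "a", "b", "c"])
        assert np.allclose(X.sum(axis=1), 1.0)
        assert levels == ["a", "b", "c"]

    def test_transition_contrasts_consecutive(self):
        cons = transition_contrasts(["a", "b", "c"])
        assert list(cons) == ["a->b", "b->c"]
        assert cons["a->b"].tolist() == [-1, 1, 0]
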