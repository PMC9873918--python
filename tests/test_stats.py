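"""Core statistics: log-CPM weights, WLS, moderation, multiplicity, ranks."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from colitraj import stats
from colitraj.io import CountMatrix


def _cm(arr, samples=None):
    arr = np.asarray(arr)
    idx = [f"g{i}" for i in range(arr.shape[0])]
    cols = samples or [f"s{j}" for j in range(arr.shape[1])]
    return CountMatrix(pd.DataFrame(arr, index=idx, columns=cols))


class TestLogCPM:
    def test_zero_count_hand_value(self):
        # log2(0.5 / 1e6 * 1e6) = log2(0.5) = -1
        e = stats.logcpm(np.array([[0.0]]), np.array([999_999.0]))
        assert e[0, 0] == pytest.approx(-1.0)

    def test_count_one_hand_value(self):
        # log2(1.5 / 4e6 * 1e6) = log2(0.375)
        e = stats.logcpm(np.array([[1.0]]), np.array([3_999_999.0]))
        assert e[0, 0] == pytest.approx(np.log2(0.375), abs=1e-9)

    def test_few_features_fall_back_to_unit_weights(self):
        rngl = np.random.default_rng(0)
        cm = _cm(rngl.poisson(50, size=(10, 8)))
        with pytest.warns(UserWarning, match="unit weights"):
            we = stats.logcpm_transform(cm)
        assert np.all(we.weights == 1.0)

    def test_homoscedastic_data_gives_near_constant_weights(self, rng):
        # equal-mean Poisson rows: flat mean-variance trend
        cm = _cm(rng.poisson(500, size=(300, 20)))
        we = stats.logcpm_transform(cm)
        w = we.weights
        med = np.median(w)
        assert w.max() <= 1.2 * med and w.min() >= 0.8 * med  # within 20%


class TestWeightedLM:
    def _design(self, groups):
        return pd.DataFrame({"intercept": 1.0, "disease": groups},
                            index=[f"s{j}" for j in range(len(groups))])

    def test_group_coefficient_is_mean_difference(self, rng):
        E = rng.normal(size=(20, 10))
        we = stats.WeightedExpression(
            pd.DataFrame(E, index=[f"g{i}" for i in range(20)],
                         columns=[f"s{j}" for j in range(10)]),
            np.ones_like(E),
        )
        groups = np.array([0, 0, 0, 0, 0, 1, 1, 1, 1, 1], dtype=float)
        fit = stats.fit_weighted_lm(we, self._design(groups))
        expected = E[:, 5:].mean(axis=1) - E[:, :5].mean(axis=1)
        np.testing.assert_allclose(fit.coefficients["disease"], expected, atol=1e-10)

    def test_weight_rescaling_leaves_coefficients_unchanged(self, rng):
        E = rng.normal(size=(15, 8))
        idx = [f"g{i}" for i in range(15)]
        cols = [f"s{j}" for j in range(8)]
        groups = np.array([0, 0, 0, 0, 1, 1, 1, 1], dtype=float)
        W = rng.uniform(0.5, 2.0, size=E.shape)
        f1 = stats.fit_weighted_lm(
            stats.WeightedExpression(pd.DataFrame(E, idx, cols), W),
            self._design(groups))
        f2 = stats.fit_weighted_lm(
            stats.WeightedExpression(pd.DataFrame(E, idx, cols), 2.0 * W),
            self._design(groups))
        np.testing.assert_allclose(f1.coefficients, f2.coefficients, atol=1e-10)

    def test_rank_deficient_design_lists_aliased_columns(self, rng):
        E = rng.normal(size=(10, 6))
        we = stats.WeightedExpression(
            pd.DataFrame(E, [f"g{i}" for i in range(10)],
                         [f"s{j}" for j in range(6)]),
            np.ones_like(E))
        design = pd.DataFrame({"intercept": np.ones(6), "dup": np.ones(6)},
                              index=we.E.columns)
        with pytest.raises(ValueError, match="rank deficient"):
            stats.fit_weighted_lm(we, design)


class TestModeration:
    def _fit_from_variances(self, s2, df=10, n_coef=1):
        g = len(s2)
        idx = [f"g{i}" for i in range(g)]
        return stats.LinearFit(
            coefficients=pd.DataFrame(np.ones((g, n_coef)), idx, ["disease"]),
            stdev_unscaled=pd.DataFrame(np.ones((g, n_coef)), idx, ["disease"]),
            sigma=pd.Series(np.sqrt(s2), idx),
            df_residual=pd.Series(np.full(g, float(df)), idx),
            design=pd.DataFrame(),
            cov_unscaled=np.ones((g, 1, 1)),
        )

    def test_identical_variances_posterior_is_fixed_point(self):
        fit = self._fit_from_variances(np.full(50, 2.5))
        mod = stats.moderate(fit)
        assert np.isinf(mod.df_prior)
        np.testing.assert_allclose(mod.var_post, 2.5)

    def test_zero_prior_df_limit_equals_ordinary_t(self, rng):
        s2 = rng.chisquare(10, 200) / 10
        fit = self._fit_from_variances(s2)
        post = stats.squeeze_var(s2, np.full(200, 10.0), df_prior=0.0, var_prior=1.0)
        np.testing.assert_allclose(post, s2)  # d0 -> 0: no shrinkage

    def test_prior_df_recovered_within_25_percent(self, rng):
        d0_true, s0_true, df = 4.0, 1.0, 10
        sigma2 = d0_true * s0_true / rng.chisquare(d0_true, 5000)
        s2 = sigma2 * rng.chisquare(df, 5000) / df
        d0, s0 = stats.fit_f_dist(s2, np.full(5000, float(df)))
        assert abs(d0 - d0_true) / d0_true < 0.25
        assert abs(s0 - s0_true) < 0.3

    def test_null_moderated_p_uniform(self, rng):
        # pure-noise expression, two groups: p-values should be uniform
        E = rng.normal(size=(2000, 12))
        we = stats.WeightedExpression(
            pd.DataFrame(E, [f"g{i}" for i in range(2000)],
                         [f"s{j}" for j in range(12)]),
            np.ones_like(E))
        design = pd.DataFrame(
            {"intercept": 1.0, "disease": [0.0] * 6 + [1.0] * 6},
            index=we.E.columns)
        fit = stats.fit_weighted_lm(we, design)
        mod = stats.moderate(fit, ["disease"])
        ks = sps.kstest(mod.p["disease"].to_numpy(), "uniform")
        assert ks.statistic < 0.05


class TestBH:
    def test_single_p(self):
        np.testing.assert_allclose(stats.bh_adjust([0.05]), [0.05])

    def test_step_up_hand_example(self):
        np.testing.assert_allclose(
            stats.bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)

    def test_all_one(self):
        np.testing.assert_allclose(stats.bh_adjust([1.0, 1.0, 1.0]), [1.0] * 3)

    def test_nan_propagates_with_warning(self):
        with pytest.warns(UserWarning):
            q = stats.bh_adjust([0.01, np.nan, 0.5])
        assert np.isnan(q[1]) and not np.isnan(q[0])

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=30))
    def test_matches_statsmodels_and_dominates_p(self, p):
        from statsmodels.stats.multitest import multipletests

        q = stats.bh_adjust(p)
        _, q_ref, _, _ = multipletests(p, method="fdr_bh")
        np.testing.assert_allclose(q, q_ref, atol=1e-12)
        assert np.all(q >= np.asarray(p) - 1e-12)


class TestSimes:
    def test_hand_examples(self):
        assert stats.simes_combine([0.01, 0.04]) == pytest.approx(0.02)
        assert stats.simes_combine([0.001, 0.5, 0.9]) == pytest.approx(0.003)

    def test_single_p_identity(self):
        assert stats.simes_combine([0.3]) == pytest.approx(0.3)

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            stats.simes_combine([])

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.floats(min_value=1e-6, max_value=1), min_size=1, max_size=20))
    def test_never_exceeds_bonferroni(self, p):
        assert stats.simes_combine(p) <= min(len(p) * min(p), 1.0) + 1e-12


class TestSpearman:
    def test_monotone_pairs(self):
        rho, _ = stats.spearman([1, 2, 3, 4], [10, 20, 30, 40])
        assert rho == pytest.approx(1.0)
        rho, _ = stats.spearman([1, 2, 3, 4], [4, 3, 2, 1])
        assert rho == pytest.approx(-1.0)

    def test_rho_matches_scipy(self, rng):
        for n in (5, 8, 15):
            x, y = rng.normal(size=n), rng.normal(size=n)
            rho, _ = stats.spearman(x, y)
            assert rho == pytest.approx(sps.spearmanr(x, y).statistic, abs=1e-12)

    def test_exact_p_matches_brute_force_enumeration(self, rng):
        from itertools import permutations

        for n in (4, 5, 6):
            x, y = rng.normal(size=n), rng.normal(size=n)
            rho, p = stats.spearman(x, y)
            rx, ry = sps.rankdata(x), sps.rankdata(y)
            obs = abs(np.corrcoef(rx, ry)[0, 1])
            hits = total = 0
            for perm in permutations(range(n)):
                r = abs(np.corrcoef(rx, ry[list(perm)])[0, 1])
                hits += r >= obs - 1e-12
                total += 1
            assert p == pytest.approx(hits / total, abs=1e-12)

    def test_constant_vector_undefined(self):
        rho, p = stats.spearman([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        assert np.isnan(rho) and np.isnan(p)


class TestHypergeom:
    def test_enumeration_small_universe(self, rng):
        # exhaustive check of P(overlap >= k) for all draws in a 10-universe
        from itertools import combinations
        from math import comb

        universe = list(range(10))
        A = set(universe[:5])
        for b_size in (3, 5):
            for k in range(0, min(5, b_size) + 1):
                count = sum(
                    1 for B in combinations(universe, b_size)
                    if len(A & set(B)) >= k
                )
                expected = count / comb(10, b_size)
                assert stats.hypergeom_overlap_p(k, 5, b_size, 10) == pytest.approx(
                    expected, abs=1e-12)

    def test_full_overlap_half_universe(self):
        # 1 / C(10,5) = 1/252
        assert stats.hypergeom_overlap_p(5, 5, 5, 10) == pytest.approx(1 / 252)
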