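import itertools
import math

import numpy as np
import pandas as pd
import pytest

from kataegion.assoc import (
    bh_fdr,
    fisher_exact_2x2,
    prevalence_percent,
    stepwise_glm,
    wilcoxon_rank_sum,
)


def fisher_oracle(a, b, c, d):
    """Exhaustive hypergeometric enumeration at fixed margins."""
    n, r1, c1 = a + b + c + d, a + b, a + c

    def pmf(x):
        return math.comb(r1, x) * math.comb(n - r1, c1 - x) / math.comb(n, c1)

    lo, hi = max(0, c1 - (n - r1)), min(r1, c1)
    p_obs = pmf(a)
    return sum(pmf(x) for x in range(lo, hi + 1) if pmf(x) <= p_obs * (1 + 1e-7))


class TestFisher:
    def test_known_table(self):
        oddsr, p = fisher_exact_2x2([[3, 1], [1, 3]])
        assert oddsr == pytest.approx(9.0)
        assert p == pytest.approx(fisher_oracle(3, 1, 1, 3), rel=1e-9)

    def test_independence(self):
        oddsr, p = fisher_exact_2x2([[5, 5], [5, 5]])
        assert oddsr == pytest.approx(1.0)
        assert p == pytest.approx(1.0)

    def test_zero_cell_finite_or(self):
        oddsr, p = fisher_exact_2x2([[0, 4], [4, 0]])
        assert math.isfinite(oddsr) and oddsr > 0
        assert 0 < p <= 1

    def test_negative_counts_error(self):
        with pytest.raises(ValueError):
            fisher_exact_2x2([[-1, 2], [3, 4]])

    def test_oracle_equivalence_all_small_tables(self):
        # every 2x2 table with total <= 14 (scipy agreement checked separately)
        for total in range(1, 15):
            for a, b, c in itertools.product(range(total + 1), repeat=3):
                d = total - a - b - c
                if d < 0:
                    continue
                _, p = fisher_exact_2x2([[a, b], [c, d]])
                assert p == pytest.approx(fisher_oracle(a, b, c, d), rel=1e-9, abs=1e-12)

    def test_matches_scipy_on_random_tables(self, rng):
        from scipy.stats import fisher_exact

        for _ in range(50):
            a, b, c, d = (int(x) for x in rng.integers(0, 25, size=4))
            _, p = fisher_exact_2x2([[a, b], [c, d]])
            _, p_sp = fisher_exact([[a, b], [c, d]])
            assert p == pytest.approx(p_sp, rel=1e-6, abs=1e-12)


class TestWilcoxon:
    def test_identical_samples(self):
        _, p = wilcoxon_rank_sum([1, 2, 3], [1, 2, 3])
        assert p >= 0.99

    def test_extreme_separation_exact(self):
        w, p = wilcoxon_rank_sum([1, 2, 3], [10, 11, 12])
        assert w == 6.0  # minimal possible rank sum 1+2+3
        assert p == pytest.approx(2 / math.comb(6, 3))

    def test_symmetry(self, rng):
        x, y = rng.normal(0, 1, 8), rng.normal(0.5, 1, 9)
        _, p1 = wilcoxon_rank_sum(x, y)
        _, p2 = wilcoxon_rank_sum(y, x)
        assert p1 == pytest.approx(p2)

    def test_exact_matches_scipy_small(self, rng):
        from scipy.stats import mannwhitneyu

        for _ in range(20):
            x = rng.normal(size=5)
            y = rng.normal(0.8, 1, size=6)
            _, p = wilcoxon_rank_sum(x, y, exact_below_n=12)
            p_sp = mannwhitneyu(x, y, method="exact").pvalue
            assert p == pytest.approx(p_sp, rel=1e-9)

    def test_large_sample_normal_approx(self, rng):
        x = rng.normal(0, 1, 60)
        y = rng.normal(1.2, 1, 60)
        _, p = wilcoxon_rank_sum(x, y)
        assert p < 1e-6

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            wilcoxon_rank_sum([], [1.0])


class TestBhFdr:
    def test_single_value_identity(self):
        np.testing.assert_allclose(bh_fdr([0.03]), [0.03])

    def test_hand_computed_stepup(self):
        np.testing.assert_allclose(bh_fdr([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_hand_computed_mixed(self):
        # ranks: 0.005*4/1=0.02, 0.04*4/2=0.08, 0.2*4/3=0.2667, 0.9*4/4=0.9
        np.testing.assert_allclose(
            bh_fdr([0.9, 0.005, 0.2, 0.04]), [0.9, 0.02, 0.26666667, 0.08], rtol=1e-6
        )

    def test_properties(self, rng):
        p = rng.uniform(size=25)
        adj = bh_fdr(p)
        assert np.all(adj >= p - 1e-12)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-12)

    def test_order_invariance(self, rng):
        p = rng.uniform(size=15)
        perm = rng.permutation(15)
        np.testing.assert_allclose(bh_fdr(p)[perm], bh_fdr(p[perm]))

    def test_matches_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests

        p = rng.uniform(size=30)
        _, adj_sm, _, _ = multipletests(p, method="fdr_bh")
        np.testing.assert_allclose(bh_fdr(p), adj_sm)

    def test_out_of_range_errors(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.2])


def _logistic_frame(rng, n=300, beta=1.5):
    X = rng.normal(size=(n, 4))
    p = 1 / (1 + np.exp(-(-0.5 + beta * X[:, 0])))
    df = pd.DataFrame(X, columns=["true_cov", "n1", "n2", "n3"])
    df["presence"] = (rng.random(n) < p).astype(int)
    return df


class TestStepwiseGlm:
    COVS = ["true_cov", "n1", "n2", "n3"]

    def test_true_covariate_selected(self, rng):
        df = _logistic_frame(rng)
        res = stepwise_glm(df, "presence", self.COVS, family="logistic")
        assert "true_cov" in res.selected
        assert res.ratios["true_cov"] > 1

    def test_all_noise_rarely_selects_much(self):
        # under the null, AIC admits a noise covariate iff its likelihood-ratio
        # chi-square exceeds 2, so the intercept-only rate with 4 candidates is
        # (1 - P(chi2_1 > 2))^4 ~= 0.50; check the empirical rate sits in a
        # generous band around that and that selected models stay small
        empty = 0
        n_selected = []
        for rep in range(30):
            rng = np.random.default_rng(500 + rep)
            df = _logistic_frame(rng, beta=0.0)
            res = stepwise_glm(df, "presence", self.COVS, family="logistic")
            empty += len(res.selected) == 0
            n_selected.append(len(res.selected))
        assert 0.25 <= empty / 30 <= 0.80
        assert np.mean(n_selected) < 1.5

    def test_intercept_only_aic_closed_form(self, rng):
        df = _logistic_frame(rng)
        y = df["presence"].to_numpy()
        res = stepwise_glm(df, "presence", [], family="logistic")
        phat = y.mean()
        ll = y.sum() * np.log(phat) + (len(y) - y.sum()) * np.log(1 - phat)
        assert res.aic == pytest.approx(-2 * ll + 2, rel=1e-6)

    def test_negative_binomial_burden(self, rng):
        n = 400
        x = rng.normal(size=n)
        mu = np.exp(0.3 + 0.8 * x)
        y = rng.negative_binomial(2, 2 / (2 + mu))
        df = pd.DataFrame({"burden": y, "x": x, "noise": rng.normal(size=n)})
        res = stepwise_glm(df, "burden", ["x", "noise"], family="negative_binomial")
        assert "x" in res.selected
        assert res.params["x"] == pytest.approx(0.8, abs=0.25)

    def test_log_transform_applied(self, rng):
        n = 300
        sv = rng.integers(1, 500, size=n).astype(float)
        mu = np.exp(0.1 + 0.5 * np.log1p(sv))
        y = rng.poisson(mu)
        df = pd.DataFrame({"burden": y, "sv_burden": sv})
        res = stepwise_glm(df, "burden", ["sv_burden"], family="negative_binomial",
                           transforms={"sv_burden": "log"})
        assert res.params["sv_burden"] == pytest.approx(0.5, abs=0.15)

    def test_correlated_covariate_excluded(self, rng):
        df = _logistic_frame(rng)
        df["tmb"] = 0.9 * df["true_cov"] + 0.1 * rng.normal(size=len(df))
        res = stepwise_glm(df, "presence", ["true_cov", "tmb", "n1"], family="logistic",
                           corr_cutoff=0.6)
        names = [e[0] for e in res.excluded_correlated]
        assert names == ["tmb"]  # later-listed member of the pair is dropped

    def test_incomplete_rows_dropped_and_counted(self, rng):
        df = _logistic_frame(rng)
        df.loc[:2, "n1"] = np.nan
        res = stepwise_glm(df, "presence", self.COVS, family="logistic")
        assert res.n_dropped_incomplete == 3

    def test_trace_reproducible(self, rng):
        df = _logistic_frame(rng)
        r1 = stepwise_glm(df, "presence", self.COVS, family="logistic")
        r2 = stepwise_glm(df, "presence", self.COVS, family="logistic")
        assert r1.trace == r2.trace and r1.selected == r2.selected

    def test_unknown_family_errors(self, rng):
        with pytest.raises(ValueError):
            stepwise_glm(_logistic_frame(rng), "presence", self.COVS, family="poisson")

    def test_separation_fallback(self):
        rng = np.random.default_rng(3)
        n = 80
        x = rng.normal(size=n)
        df = pd.DataFrame({"x": x, "presence": (x > 0).astype(int)})
        res = stepwise_glm(df, "presence", ["x"], family="logistic")
        assert res.separation_fallback or all(np.isfinite(v) for v in res.params.values())


class TestPrevalence:
    def test_rounding(self):
        assert prevalence_percent(65, 188) == 34.6
        assert prevalence_percent(174, 249) == 69.9

    def test_validation(self):
        with pytest.raises(ValueError):
            prevalence_percent(5, 0)
        with pytest.raises(ValueError):
            prevalence_percent(10, 5)
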