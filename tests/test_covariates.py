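"""Diet pruning, scalar regressions, best subsets and joint functional fits."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import growthmicro as gm
from growthmicro.covariates import (
    best_subset,
    joint_fosr,
    kruskal_by_factor,
    multi_regression,
    prune_correlated,
)
from growthmicro.errors import InvalidArgumentError, JoinError, SingularDesignError


class TestPrune:
    def test_planted_collinearity_dropped(self):
        cov = gm.gen_covariates(150, seed=2)
        res = prune_correlated(cov.diet, cutoff=0.7)
        assert len(res.retained) == 8
        dropped = {d[0] for d in res.dropped}
        assert dropped == {"milk", "vegetables_no_potato"}

    def test_cutoff_one_drops_nothing(self):
        cov = gm.gen_covariates(60, seed=3)
        res = prune_correlated(cov.diet, cutoff=1.0)
        assert res.retained == list(cov.diet.columns)

    def test_duplicated_column_dropped(self):
        rng = np.random.default_rng(4)
        x = rng.poisson(5.0, size=50)
        table = pd.DataFrame({"a": x, "b": rng.poisson(3.0, size=50), "c": x})
        res = prune_correlated(table, cutoff=0.7)
        assert res.retained == ["a", "b"]
        assert res.dropped[0][:2] == ("c", "a")

    def test_idempotent(self):
        cov = gm.gen_covariates(100, seed=5)
        first = prune_correlated(cov.diet)
        second = prune_correlated(cov.diet[first.retained])
        assert second.retained == first.retained

    def test_constant_column_retained_not_compared(self):
        table = pd.DataFrame({"a": [3, 3, 3, 3], "b": [1, 2, 3, 4]})
        res = prune_correlated(table)
        assert res.retained == ["a", "b"]


class TestMultiRegression:
    def test_exact_linear_fit(self):
        rng = np.random.default_rng(1)
        X = pd.DataFrame({"x": rng.normal(size=30)})
        y = 2.0 * X["x"] + 1.0
        fit = multi_regression(y, X)
        assert fit.rsquared_adj == pytest.approx(1.0)
        assert fit.params["x"] == pytest.approx(2.0)

    def test_hand_computed_bivariate_slope(self):
        # 5-point fit against the closed-form normal equations
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        y = np.array([2.1, 3.9, 6.2, 8.1, 9.8])
        slope = ((x - x.mean()) @ (y - y.mean())) / ((x - x.mean()) ** 2).sum()
        fit = multi_regression(y, pd.DataFrame({"x": x}))
        assert fit.params["x"] == pytest.approx(slope)

    def test_adjusted_r2_identity(self):
        rng = np.random.default_rng(2)
        X = pd.DataFrame(rng.normal(size=(40, 3)), columns=list("abc"))
        y = X["a"] + rng.normal(size=40)
        fit = multi_regression(y, X)
        n, p = 40, 3
        expected = 1 - (1 - fit.rsquared) * (n - 1) / (n - p - 1)
        assert fit.rsquared_adj == pytest.approx(expected, abs=1e-12)

    def test_overall_f_p_uniform_under_null(self):
        rng = np.random.default_rng(3)
        pvals = []
        X = pd.DataFrame(rng.normal(size=(50, 2)), columns=["a", "b"])
        for _ in range(300):
            y = rng.normal(size=50)
            pvals.append(multi_regression(y, X).f_pvalue)
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_rank_deficiency_rejected(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=30)
        X = pd.DataFrame({"a": x, "b": 2 * x})
        with pytest.raises(SingularDesignError):
            multi_regression(rng.normal(size=30), X)

    def test_too_small_sample_rejected(self):
        X = pd.DataFrame(np.eye(3), columns=list("abc"))
        with pytest.raises(InvalidArgumentError):
            multi_regression([1.0, 2.0, 3.0], X)


class TestBestSubset:
    def test_enumeration_count(self):
        rng = np.random.default_rng(5)
        X = pd.DataFrame(rng.normal(size=(30, 2)), columns=["a", "b"])
        y = X["a"] + 0.1 * rng.normal(size=30)
        res = best_subset(y, X)
        assert res.n_subsets == 4

    def test_bic_matches_independent_brute_force(self):
        # independent code path: statsmodels OLS llf-based BIC over all subsets
        import itertools

        import statsmodels.api as sm

        rng = np.random.default_rng(6)
        p = 5
        X = pd.DataFrame(rng.normal(size=(60, p)),
                         columns=[f"x{j}" for j in range(p)])
        y = 1.5 * X["x2"] - X["x4"] + rng.normal(size=60)
        res = best_subset(y, X, criterion="BIC")
        best_val, best_combo = np.inf, None
        n = len(y)
        for size in range(p + 1):
            for combo in itertools.combinations(X.columns, size):
                Xd = sm.add_constant(X[list(combo)], has_constant="add")
                ols = sm.OLS(np.asarray(y), Xd).fit()
                # same Gaussian BIC up to an additive constant in n only
                bic = n * np.log(ols.ssr / n) + (len(combo) + 1) * np.log(n)
                if bic < best_val:
                    best_val, best_combo = bic, combo
        assert set(res.selected) == set(best_combo)
        assert res.criterion_value == pytest.approx(best_val)

    def test_planted_predictor_selected(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(100 + seed)
            X = pd.DataFrame(rng.normal(size=(300, 10)),
                             columns=[f"x{j}" for j in range(10)])
            y = 2.0 * X["x3"] + rng.normal(size=300)
            if best_subset(y, X).selected == ("x3",):
                hits += 1
        assert hits >= 18

    def test_pure_noise_prefers_intercept_only(self):
        empty = 0
        for seed in range(20):
            rng = np.random.default_rng(200 + seed)
            X = pd.DataFrame(rng.normal(size=(150, 6)),
                             columns=[f"x{j}" for j in range(6)])
            y = rng.normal(size=150)
            empty += best_subset(y, X).selected == ()
        assert empty >= 12  # intercept-only wins most often under BIC

    def test_too_many_covariates_refused(self):
        X = pd.DataFrame(np.zeros((30, 21)),
                         columns=[f"x{j}" for j in range(21)])
        with pytest.raises(InvalidArgumentError, match="pre-screen"):
            best_subset(np.zeros(30), X)


def test_kruskal_wallis_factor():
    rng = np.random.default_rng(7)
    factor = np.repeat(["a", "b", "c"], 30)
    null_p = kruskal_by_factor(rng.normal(size=90), factor)
    shifted = np.concatenate([rng.normal(size=30), rng.normal(size=30),
                              rng.normal(3.0, 1.0, size=30)])
    alt_p = kruskal_by_factor(shifted, factor)
    assert alt_p < 0.001 < null_p


class TestJointFoSR:
    def _setup(self, n=80, T=74, seed=8, confounded=False, suppressed=False):
        rng = np.random.default_rng(seed)
        grid = np.linspace(0, 730, T)
        u = grid / 730
        ids = pd.Index([f"c{i:03d}" for i in range(n)], name="child_id")
        diet = pd.Series(rng.normal(size=n), index=ids, name="fruit")
        if confounded:
            micro = 0.9 * diet + 0.4 * rng.normal(size=n)
            signal = np.outer(diet, 0.06 * np.sin(np.pi * u))
        elif suppressed:
            micro = pd.Series(rng.normal(size=n), index=ids)
            signal = (np.outer(micro, 0.04 * np.sin(np.pi * u))
                      - np.outer(diet, 0.06 * np.sin(np.pi * u)))
            micro = micro + 0.8 * diet  # observed summary contaminated by diet
        else:
            micro = pd.Series(rng.normal(size=n), index=ids)
            signal = np.outer(micro, 0.04 * np.sin(np.pi * u))
        micro = pd.Series(np.asarray(micro), index=ids, name="gut_diversity")
        Y = pd.DataFrame(0.1 + signal + 0.02 * rng.normal(size=(n, T)),
                         index=ids, columns=grid)
        return Y, micro, diet.to_frame()

    def test_zero_diet_column_leaves_fit_unchanged(self):
        Y, micro, diet = self._setup()
        zeros = pd.DataFrame({"never_eaten": np.zeros(len(Y))}, index=Y.index)
        base = gm.fit_fosr(Y, micro.to_frame(), mc_draws=2000)
        joint = joint_fosr(Y, micro, zeros, mc_draws=2000)
        np.testing.assert_allclose(joint.coefficient("gut_diversity"),
                                   base.coefficient("gut_diversity"),
                                   atol=1e-8)

    def test_confounding_attenuates_microbiota_signal(self):
        Y, micro, diet = self._setup(confounded=True, n=150)
        marginal = gm.fit_fosr(Y, micro.to_frame(), mc_draws=5000)
        joint = joint_fosr(Y, micro, diet, mc_draws=5000)
        assert (joint.pvalues["gut_diversity"]["Choi"]
                > marginal.pvalues["gut_diversity"]["Choi"])

    def test_suppression_sharpens_microbiota_signal(self):
        Y, micro, diet = self._setup(suppressed=True, n=150)
        marginal = gm.fit_fosr(Y, micro.to_frame(), mc_draws=5000)
        joint = joint_fosr(Y, micro, diet, mc_draws=5000)
        assert (joint.pvalues["gut_diversity"]["Choi"]
                < marginal.pvalues["gut_diversity"]["Choi"])

    def test_id_mismatch_lists_orphans(self):
        Y, micro, diet = self._setup()
        bad = diet.iloc[:-5]
        with pytest.raises(JoinError) as err:
            joint_fosr(Y, micro, bad)
        assert len(err.value.orphans) == 5
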