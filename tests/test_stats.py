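"""Regression, nonparametric tests and repeatability statistics."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from choromel import stats as S
from choromel.cohort import synthesize_cohort, synthesize_repeats


class TestSimpleLinreg:
    def test_perfect_fit(self):
        x = np.arange(10.0)
        res = S.simple_linreg(x, 2 * x + 1)
        assert res.r == pytest.approx(1.0)
        assert res.p < 1e-10

    def test_perfect_inverse(self):
        x = np.arange(10.0)
        assert S.simple_linreg(x, -x).r == pytest.approx(-1.0)

    def test_independent_draws_near_zero(self):
        rng = np.random.default_rng(42)
        x = rng.standard_normal(10_000)
        y = rng.standard_normal(10_000)
        assert abs(S.simple_linreg(x, y).r) < 0.03

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            S.simple_linreg(np.ones(10), np.arange(10.0))


class TestStepwise:
    def test_strong_single_predictor(self):
        rng = np.random.default_rng(0)
        x1 = rng.standard_normal(200)
        x2 = rng.standard_normal(200)
        y = 3 * x1 + rng.standard_normal(200) * 1e-3
        res = S.stepwise_mlr(y, pd.DataFrame({"x1": x1, "x2": x2}))
        assert res.retained == ["x1"]
        assert res.coef.loc["x1", "beta"] == pytest.approx(1.0, abs=0.01)
        assert not res.coef.loc["x2", "retained"]

    def test_null_predictors_usually_all_removed(self):
        """Two pure-noise predictors at p_enter = 0.05: the retained set is
        empty in ≥ 90% of seeded replicates."""
        rng = np.random.default_rng(7)
        empty = 0
        n_rep = 300
        for _ in range(n_rep):
            y = rng.standard_normal(100)
            X = pd.DataFrame(rng.standard_normal((100, 2)), columns=["a", "b"])
            if not S.stepwise_mlr(y, X).retained:
                empty += 1
        assert empty / n_rep >= 0.90

    def test_single_predictor_matches_simple_regression(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal(50)
        y = 0.5 * x + rng.standard_normal(50)
        res_step = S.stepwise_mlr(y, pd.DataFrame({"x": x}), p_enter=1.0001)
        res_simple = S.simple_linreg(x, y)
        assert res_step.coef.loc["x", "p"] == pytest.approx(res_simple.p, rel=1e-9)

    def test_rescaling_invariance(self):
        rng = np.random.default_rng(5)
        X = pd.DataFrame(rng.standard_normal((120, 3)), columns=list("abc"))
        y = 2 * X["a"] - 1.5 * X["c"] + rng.standard_normal(120)
        base = S.stepwise_mlr(y, X)
        scaled = X * [1000.0, 0.01, 7.0] + [5.0, -3.0, 0.0]
        res = S.stepwise_mlr(y, scaled)
        assert res.retained == base.retained
        np.testing.assert_allclose(
            res.coef["beta"].to_numpy(), base.coef["beta"].to_numpy(), rtol=1e-8
        )

    def test_collinear_predictors_rejected(self):
        rng = np.random.default_rng(1)
        a = rng.standard_normal(50)
        X = pd.DataFrame({"a": a, "b": 2 * a})
        with pytest.raises(ValueError, match="collinear"):
            S.stepwise_mlr(rng.standard_normal(50), X)


def _wilcoxon_bruteforce(d):
    """Exact two-sided p by enumerating all 2^n sign assignments."""
    d = np.asarray(d, float)
    d = d[d != 0]
    ranks = sps.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    n = len(d)
    ws = np.array(
        [np.sum(ranks[list(signs)]) for signs in _subsets(n)]
    )
    p_le = np.mean(ws <= w_obs + 1e-9)
    p_ge = np.mean(ws >= w_obs - 1e-9)
    return min(1.0, 2 * min(p_le, p_ge))


def _subsets(n):
    for mask in range(2**n):
        yield [i for i in range(n) if mask >> i & 1]


class TestWilcoxon:
    def test_balanced_signs_give_unity(self):
        d = np.array([1.0, -1.0, 2.0, -2.0, 3.0, -3.0])
        assert S.wilcoxon_signed_rank(d, mode="exact") == 1.0

    def test_all_positive_n8(self):
        d = np.arange(1.0, 9.0)
        assert S.wilcoxon_signed_rank(d, mode="exact") == pytest.approx(2 / 2**8)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_exact_matches_bruteforce(self, seed):
        rng = np.random.default_rng(seed)
        for n in (5, 8, 10, 12):
            d = np.round(rng.standard_normal(n) + 0.3, 1)
            d = d[d != 0]
            if len(d) < 5:
                continue
            mine = S.wilcoxon_signed_rank(d, mode="exact")
            brute = _wilcoxon_bruteforce(d)
            assert mine == pytest.approx(brute, abs=1e-12)

    def test_exact_matches_scipy_without_ties(self):
        rng = np.random.default_rng(9)
        d = rng.standard_normal(15)
        mine = S.wilcoxon_signed_rank(d, mode="exact")
        ref = sps.wilcoxon(d, mode="exact").pvalue
        assert mine == pytest.approx(ref, abs=1e-12)

    def test_approx_close_to_exact(self):
        rng = np.random.default_rng(4)
        for _ in range(10):
            d = rng.standard_normal(12) + 0.3
            exact = S.wilcoxon_signed_rank(d, mode="exact")
            approx = S.wilcoxon_signed_rank(d, mode="approx")
            assert approx == pytest.approx(exact, abs=0.02)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            S.wilcoxon_signed_rank(np.zeros(10))


class TestFriedman:
    def test_identical_columns(self):
        mat = np.tile(np.arange(10.0)[:, None], (1, 4))
        chi2, p, pairs = S.friedman_with_posthoc(mat)
        assert chi2 == 0.0
        assert p == 1.0

    def test_shifted_column_detected(self):
        rng = np.random.default_rng(11)
        mat = rng.standard_normal((50, 4))
        mat[:, 2] += 3.0
        chi2, p, pairs = S.friedman_with_posthoc(
            pd.DataFrame(mat, columns=list("abcd"))
        )
        assert p < 0.001
        with_c = pairs[(pairs["a"] == "c") | (pairs["b"] == "c")]
        assert (with_c["p_bonferroni"] < 0.05).all()

    def test_bonferroni_is_raw_times_npairs(self):
        rng = np.random.default_rng(2)
        mat = rng.standard_normal((20, 5))
        _, _, pairs = S.friedman_with_posthoc(mat)
        n_pairs = 5 * 4 // 2
        np.testing.assert_allclose(
            pairs["p_bonferroni"], np.minimum(1.0, pairs["p_raw"] * n_pairs)
        )

    def test_matches_scipy_without_ties(self):
        rng = np.random.default_rng(8)
        mat = rng.standard_normal((30, 4))
        chi2, p, _ = S.friedman_with_posthoc(mat)
        ref = sps.friedmanchisquare(*mat.T)
        assert chi2 == pytest.approx(ref.statistic, rel=1e-10)
        assert p == pytest.approx(ref.pvalue, rel=1e-10)

    def test_too_few_conditions(self):
        with pytest.raises(ValueError):
            S.friedman_with_posthoc(np.zeros((10, 2)))


class TestCoefficientOfVariation:
    def test_identical_measurements(self):
        cv, (mean, sd) = S.coefficient_of_variation(np.full((3, 4), 5.0))
        assert (cv == 0).all() and mean == 0

    def test_hand_computed(self):
        cv, _ = S.coefficient_of_variation(np.array([[1.0, 1.0, 1.0, 2.0]]))
        assert cv[0] == pytest.approx(0.4)

    def test_scale_invariance(self):
        rng = np.random.default_rng(6)
        reps = rng.uniform(1, 2, size=(8, 4))
        cv1, _ = S.coefficient_of_variation(reps)
        cv2, _ = S.coefficient_of_variation(reps * 10)
        np.testing.assert_allclose(cv1, cv2)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            S.coefficient_of_variation(np.array([[1.0, -1.0]]))


class TestSyntheticCohort:
    def test_sign_pattern_recovered(self):
        """Built-in effects: thickness falls with age and axial length,
        occupancy rises with age, MeCh tracks thickness."""
        df = synthesize_cohort(105, seed=0)
        r = lambda a, b: S.simple_linreg(df[a], df[b]).r
        assert r("age_y", "choroidal_thickness_um") < 0
        assert r("axial_length_mm", "choroidal_thickness_um") < 0
        assert r("age_y", "occupancy") > 0
        assert r("choroidal_thickness_um", "mech_thickness_um") > 0

    def test_repeats_cv_near_target(self):
        df = synthesize_cohort(50, seed=1)
        reps = synthesize_repeats(df["choroidal_thickness_um"], cv=0.026, seed=2)
        cv, (mean, sd) = S.coefficient_of_variation(reps)
        assert mean == pytest.approx(0.026, abs=0.01)
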