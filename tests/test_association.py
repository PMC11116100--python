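"""Regression models and Benjamini-Hochberg adjustment."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from triopgs.association import (
    adjust_fdr,
    attach_fdr,
    fit_interaction,
    fit_multivariable,
    fit_trio_joint,
    fit_univariate,
)


def bh_brute_force(p):
    """Independent BH oracle: adjusted_i = min over j with p_j >= p_i of
    p_(j) * m / rank(j), computed by direct double loop."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order]
    adj = np.empty(m)
    for i in range(m):
        adj[i] = min(min(ranked[j] * m / (j + 1) for j in range(i, m)), 1.0)
    out = np.empty(m)
    out[order] = adj
    return out


class TestAdjustFdr:
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=40))
    @settings(max_examples=200, deadline=None)
    def test_agrees_with_brute_force(self, pvals):
        np.testing.assert_allclose(adjust_fdr(pvals), bh_brute_force(pvals), atol=1e-12)

    def test_agrees_with_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(0)
        p = rng.random(50)
        np.testing.assert_allclose(
            adjust_fdr(p), multipletests(p, method="fdr_bh")[1], atol=1e-12
        )

    def test_single_p_unchanged(self):
        assert adjust_fdr([0.3])[0] == pytest.approx(0.3)

    def test_order_invariance(self):
        p = [0.04, 0.3, 0.01, 0.8]
        a = adjust_fdr(p)
        perm = [3, 1, 0, 2]
        b = adjust_fdr([p[i] for i in perm])
        np.testing.assert_allclose(a[perm], b)

    def test_family_grouping(self):
        p = [0.01, 0.04, 0.01, 0.04]
        fams = ["a", "a", "b", "b"]
        grouped = adjust_fdr(p, fams)
        np.testing.assert_allclose(grouped[:2], adjust_fdr(p[:2]))
        np.testing.assert_allclose(grouped[2:], adjust_fdr(p[2:]))

    def test_invalid_inputs(self):
        with pytest.raises(ValueError, match="empty"):
            adjust_fdr([])
        with pytest.raises(ValueError, match="0, 1"):
            adjust_fdr([1.2])


def _sim_logistic(n, beta, rng):
    x = rng.standard_normal(n)
    eta = -1.0 + beta * x
    y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
    return x, y


class TestUnivariate:
    def test_linear_recovers_known_slope(self, rng):
        n = 5000
        x = rng.standard_normal(n)
        y = 0.4 * x + rng.standard_normal(n)
        res = fit_univariate(x, y, family="linear")
        assert res.estimate == pytest.approx(0.4, abs=3 * res.se)
        assert res.ci_low < 0.4 < res.ci_high
        # with no covariates the incremental R2 is the plain model R2
        assert res.delta_r2 == pytest.approx(0.16 / 1.16, abs=0.03)

    def test_logistic_or_and_ci_reconstruction(self, rng):
        x, y = _sim_logistic(4000, 0.3, rng)
        res = fit_univariate(x, y, family="logistic")
        assert res.odds_ratio == pytest.approx(np.exp(res.estimate))
        assert res.or_ci_low == pytest.approx(np.exp(res.estimate - 1.959963984540054 * res.se))
        assert res.ci_low < 0.3 < res.ci_high

    def test_delta_r2_incremental(self, rng):
        n = 3000
        cov = rng.standard_normal((n, 2))
        x = rng.standard_normal(n)
        y = 0.5 * x + cov @ [0.3, -0.2] + rng.standard_normal(n)
        res = fit_univariate(x, y, cov, family="linear")
        expected = 0.25 / (0.25 + 0.09 + 0.04 + 1.0)
        assert res.delta_r2 == pytest.approx(expected, abs=0.03)

    def test_complete_case_n(self, rng):
        x = rng.standard_normal(100)
        y = (rng.random(100) < 0.5).astype(float)
        x[:5] = np.nan
        res = fit_univariate(x, y, family="logistic")
        assert res.n == 95

    def test_too_few_cases(self, rng):
        with pytest.raises(ValueError, match="complete cases"):
            fit_univariate(rng.standard_normal(10), np.ones(10), family="linear")

    def test_zero_variance_predictor(self, rng):
        y = (rng.random(100) < 0.5).astype(float)
        with pytest.raises(ValueError, match="zero-variance"):
            fit_univariate(np.ones(100), y, family="logistic")

    def test_single_class_outcome(self, rng):
        with pytest.raises(ValueError, match="both classes"):
            fit_univariate(rng.standard_normal(100), np.zeros(100), family="logistic")

    def test_perfect_separation_explicit_error(self):
        x = np.concatenate([np.full(40, -2.0), np.full(40, 2.0)])
        x += np.linspace(0, 0.01, 80)  # non-constant within class
        y = (x > 0).astype(float)
        with pytest.raises(ValueError, match="separation"):
            fit_univariate(x, y, family="logistic")

    def test_constant_covariates_dropped(self, rng):
        x = rng.standard_normal(200)
        y = 0.3 * x + rng.standard_normal(200)
        res_none = fit_univariate(x, y, family="linear")
        res_zero = fit_univariate(x, y, np.zeros((200, 3)), family="linear")
        assert res_zero.estimate == pytest.approx(res_none.estimate)
        assert res_zero.se == pytest.approx(res_none.se)

    def test_logistic_effect_size_recovery(self):
        """Simulated per-SD log-OR of 0.19 (OR ~ 1.21, a typical mood-PGS
        magnitude) at n=4338 is recovered in the mean over 50 replicates."""
        rng = np.random.default_rng(7)
        ors = []
        for _ in range(50):
            x, y = _sim_logistic(4338, 0.19, rng)
            ors.append(fit_univariate(x, y, family="logistic").odds_ratio)
        assert abs(np.mean(ors) - np.exp(0.19)) < 0.03

    def test_type_i_error_calibration(self):
        """Null score, n=400, 200 replicates: rejection rate within 2 binomial
        SE of alpha = 0.05."""
        rng = np.random.default_rng(99)
        reps, n, alpha = 200, 400, 0.05
        rejections = 0
        for _ in range(reps):
            x = rng.standard_normal(n)
            y = rng.standard_normal(n)
            rejections += fit_univariate(x, y, family="linear").p < alpha
        rate = rejections / reps
        assert abs(rate - alpha) < 2 * np.sqrt(alpha * (1 - alpha) / reps)


class TestInteraction:
    def test_affine_invariance_of_sex_coding(self, rng):
        n = 1000
        x = rng.standard_normal(n)
        sex01 = rng.integers(0, 2, n).astype(float)
        y = (rng.random(n) < 1 / (1 + np.exp(-(-0.5 + 0.3 * x + 0.4 * x * sex01)))).astype(float)
        r1 = fit_interaction(x, y, sex01)["interaction"]
        r2 = fit_interaction(x, y, sex01 + 1.0)["interaction"]
        assert r1.estimate == pytest.approx(r2.estimate)
        assert r1.se == pytest.approx(r2.se)

    def test_single_sex_stratum_pattern(self, rng):
        """Male-only effect: stratified ORs recover OR > 1 in males and
        OR ~ 1 in females."""
        n = 6000
        x = rng.standard_normal(n)
        male = rng.integers(0, 2, n).astype(float)
        eta = -1.0 + 0.6 * x * male
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
        out = fit_interaction(x, y, male)
        or_female = out["stratum_0"].odds_ratio
        or_male = out["stratum_1"].odds_ratio
        assert or_male > 1.3
        assert out["stratum_0"].or_ci_low < 1.0 < out["stratum_0"].or_ci_high
        assert out["interaction"].p < 0.05
        assert or_male > or_female

    def test_single_sex_rejected(self, rng):
        x = rng.standard_normal(100)
        y = (rng.random(100) < 0.5).astype(float)
        with pytest.raises(ValueError, match="two levels"):
            fit_interaction(x, y, np.ones(100))


class TestTrioJoint:
    def test_null_parent_coefficients(self, rng):
        n = 4000
        child = rng.standard_normal(n)
        mother = 0.5 * child + rng.standard_normal(n) * np.sqrt(0.75)
        father = 0.5 * child + rng.standard_normal(n) * np.sqrt(0.75)
        y = 0.3 * child + rng.standard_normal(n)
        out = fit_trio_joint(child, mother, father, y, family="linear")
        assert abs(out["child"].estimate - 0.3) < 3 * out["child"].se
        for parent in ("mother", "father"):
            assert abs(out[parent].estimate) < 3 * out[parent].se

    def test_requires_complete_trios(self, rng):
        child = rng.standard_normal(40)
        child[:20] = np.nan
        with pytest.raises(ValueError, match="complete trios"):
            fit_trio_joint(child, child, child, child, family="linear")


class TestMultivariable:
    def test_identical_scores_rejected(self, rng):
        x = rng.standard_normal(200)
        scores = pd.DataFrame({"a": x, "b": x})
        y = (rng.random(200) < 0.5).astype(float)
        with pytest.raises(ValueError, match="singular|collinear"):
            fit_multivariable(scores, y)

    def test_conditional_estimates_separate_causal_score(self, rng):
        n = 6000
        a = rng.standard_normal(n)
        b = 0.5 * a + np.sqrt(0.75) * rng.standard_normal(n)
        y = 0.4 * a + rng.standard_normal(n)
        out = fit_multivariable(pd.DataFrame({"a": a, "b": b}), y, family="linear")
        assert abs(out["a"].estimate - 0.4) < 3 * out["a"].se
        assert abs(out["b"].estimate) < 3 * out["b"].se

    def test_independent_scores_match_univariate(self, rng):
        n = 3000
        scores = pd.DataFrame({f"s{i}": rng.standard_normal(n) for i in range(3)})
        y = 0.2 * scores["s0"].to_numpy() + rng.standard_normal(n)
        multi = fit_multivariable(scores, y, family="linear")
        uni = fit_univariate(scores["s0"].to_numpy(), y, family="linear")
        assert multi["s0"].estimate == pytest.approx(uni.estimate, abs=0.02)


def test_attach_fdr_monotone(rng):
    results = [
        fit_univariate(rng.standard_normal(100), rng.standard_normal(100), family="linear")
        for _ in range(6)
    ]
    attach_fdr(results)
    for r in results:
        assert r.p_fdr >= r.p - 1e-15
        assert r.p_fdr <= 1.0
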