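import numpy as np
import pytest
from scipy import stats as sps

from csnet.stats import (
    PairedSample,
    logistic_fit,
    mixed_anova_2x2,
    paired_t,
    pearson,
    residualize,
    sign_test,
    zscore,
)


class TestZscore:
    def test_three_point_example(self):
        z, spec = zscore([1.0, 2.0, 3.0])
        assert np.allclose(z, [-1.0, 0.0, 1.0])
        assert spec.mean == 2.0 and spec.sd == 1.0

    def test_output_standardized(self, rng):
        z, _ = zscore(rng.normal(5, 3, 50))
        assert z.mean() == pytest.approx(0.0, abs=1e-12)
        assert z.std(ddof=1) == pytest.approx(1.0, abs=1e-12)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            zscore([5.0, 5.0, 5.0])


class TestResidualize:
    def test_exact_linear_relation_gives_zero_residuals(self):
        x = np.arange(10.0)
        assert np.allclose(residualize(2 * x + 1, x), 0.0, atol=1e-10)

    def test_orthogonal_predictor_gives_centered_y(self):
        x = np.array([-1.0, 0.0, 1.0, -1.0, 0.0, 1.0])
        y = np.array([1.0, -2.0, 1.0, 1.0, -2.0, 1.0])  # zero covariance with x
        assert np.allclose(residualize(y, x), y - y.mean(), atol=1e-10)

    def test_matches_normal_equations_oracle(self):
        x = np.array([0.2, 1.5, 2.1, 3.3, 4.0, 5.8])
        y = np.array([1.0, 0.4, 2.2, 1.9, 3.5, 2.8])
        design = np.column_stack([np.ones(6), x])
        beta = np.linalg.inv(design.T @ design) @ design.T @ y
        assert np.allclose(residualize(y, x), y - design @ beta, atol=1e-10)

    def test_residuals_orthogonal_to_predictor(self, rng):
        for _ in range(5):
            x = rng.normal(size=40)
            y = rng.normal(size=40)
            r = residualize(y, x)
            assert abs(r @ x) < 1e-8
            assert abs(r.sum()) < 1e-8

    def test_constant_predictor_rejected(self):
        with pytest.raises(ValueError):
            residualize([1.0, 2.0, 3.0], [4.0, 4.0, 4.0])


class TestPearson:
    def test_perfect_positive(self):
        x = np.arange(5.0)
        assert pearson(x, 3 * x).statistic == pytest.approx(1.0)

    def test_perfect_negative(self):
        x = np.arange(5.0)
        assert pearson(x, -x).statistic == pytest.approx(-1.0)

    def test_matches_covariance_formula_oracle(self, rng):
        x = rng.normal(size=30)
        y = 0.4 * x + rng.normal(size=30)
        res = pearson(x, y)
        r_manual = np.cov(x, y, ddof=1)[0, 1] / (np.std(x, ddof=1) * np.std(y, ddof=1))
        assert res.statistic == pytest.approx(r_manual, abs=1e-12)
        t = r_manual * np.sqrt(28 / (1 - r_manual**2))
        assert res.p == pytest.approx(2 * sps.t.sf(abs(t), 28), rel=1e-9)
        assert res.df == 28

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            pearson([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestPairedT:
    def test_symmetric_differences_give_zero(self):
        cs = np.array([1.0, -1.0, 1.0, -1.0])
        assert paired_t((cs, np.zeros(4))).statistic == pytest.approx(0.0)

    def test_matches_hand_formula_on_eight_pairs(self):
        cs = np.array([0.3, -0.2, 0.5, 0.1, 0.0, 0.7, -0.1, 0.4])
        te = np.array([0.1, 0.0, 0.2, -0.3, 0.1, 0.2, 0.0, 0.1])
        d = cs - te
        t_manual = d.mean() / (d.std(ddof=1) / np.sqrt(8))
        res = paired_t((cs, te))
        assert res.statistic == pytest.approx(t_manual, abs=1e-12)
        assert res.df == 7
        assert res.effect == pytest.approx(d.mean() / d.std(ddof=1), abs=1e-12)
        assert res.p == pytest.approx(2 * sps.t.sf(abs(t_manual), 7), rel=1e-9)

    def test_agrees_with_scipy(self, rng):
        cs, te = rng.normal(size=25), rng.normal(size=25)
        res = paired_t((cs, te))
        ref = sps.ttest_rel(cs, te)
        assert res.statistic == pytest.approx(ref.statistic, abs=1e-10)
        assert res.p == pytest.approx(ref.pvalue, abs=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            paired_t((np.ones(4), np.zeros(4)))

    def test_direction_subsetting(self):
        sample = PairedSample(
            np.array([1.0, 2.0, 5.0, 6.0]),
            np.array([0.0, 1.0, 1.0, 3.0]),
            np.array(["x", "x", "y", "y"]),
        )
        assert paired_t(sample, "y").n == 2


def independent_two_sample_t(d1, d2):
    """Pooled-variance two-sample t, coded independently of the ANOVA."""
    n1, n2 = len(d1), len(d2)
    sp2 = ((n1 - 1) * np.var(d1, ddof=1) + (n2 - 1) * np.var(d2, ddof=1)) / (n1 + n2 - 2)
    return (np.mean(d1) - np.mean(d2)) / np.sqrt(sp2 * (1 / n1 + 1 / n2))


class TestMixedAnova:
    def test_interaction_equals_squared_two_sample_t(self, rng):
        for _ in range(5):
            n1, n2 = int(rng.integers(5, 40)), int(rng.integers(5, 40))
            cs = rng.normal(size=n1 + n2)
            te = rng.normal(size=n1 + n2)
            direction = np.array(["d1"] * n1 + ["d2"] * n2)
            sample = PairedSample(cs, te, direction)
            res = mixed_anova_2x2(sample)
            d = cs - te
            t = independent_two_sample_t(d[:n1], d[n1:])
            assert res["interaction"].statistic == pytest.approx(t**2, abs=1e-8)
            assert res["interaction"].df == (1, n1 + n2 - 2)

    def test_switching_effect_detected(self, rng):
        n = 60
        te = rng.normal(size=n)
        cs = te + 1.0 + rng.normal(scale=0.3, size=n)
        sample = PairedSample(cs, te, np.array(["d1"] * 30 + ["d2"] * 30))
        res = mixed_anova_2x2(sample)
        assert res["switching"].p < 1e-6

    def test_direction_effect_detected(self, rng):
        base = np.concatenate([np.zeros(30), 3 * np.ones(30)])
        cs = base + rng.normal(scale=0.3, size=60)
        te = base + rng.normal(scale=0.3, size=60)
        sample = PairedSample(cs, te, np.array(["d1"] * 30 + ["d2"] * 30))
        assert mixed_anova_2x2(sample)["direction"].p < 1e-6

    def test_requires_exactly_two_directions(self):
        sample = PairedSample(np.ones(3), np.zeros(3), np.array(["a", "a", "a"]))
        with pytest.raises(ValueError):
            mixed_anova_2x2(sample)


class TestSignTest:
    def test_balanced_counts_give_zero(self):
        res = sign_test(7, 7)
        assert res.statistic == 0.0
        assert res.p == pytest.approx(1.0)

    def test_formula(self):
        res = sign_test(30, 10)
        assert res.statistic == pytest.approx(400 / 40)
        assert res.p == pytest.approx(sps.chi2.sf(10.0, 1))

    def test_empty_counts_rejected(self):
        with pytest.raises(ValueError):
            sign_test(0, 0)


def irls_logistic_oracle(y, x, iters=50):
    """Independently coded Newton/IRLS steps for a slope+intercept logistic fit."""
    X = np.column_stack([np.ones(len(x)), x])
    beta = np.zeros(2)
    for _ in range(iters):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        W = mu * (1 - mu)
        H = X.T @ (W[:, None] * X)
        g = X.T @ (y - mu)
        beta = beta + np.linalg.solve(H, g)
    cov = np.linalg.inv(X.T @ (W[:, None] * X))
    return beta, np.sqrt(np.diag(cov))


class TestLogisticFit:
    def test_independent_predictor_gives_near_zero_slope(self):
        x = np.tile([0.0, 1.0], 50)
        y = np.tile([0, 1, 1, 0], 25)
        res = logistic_fit(y, x)
        assert res.extra["B"] == pytest.approx(0.0, abs=1e-6)

    def test_parameter_recovery(self):
        rng = np.random.default_rng(11)
        x = rng.normal(size=5000)
        p = 1.0 / (1.0 + np.exp(-(0.3 - 0.5 * x)))
        y = (rng.random(5000) < p).astype(int)
        res = logistic_fit(y, x)
        assert res.extra["B"] == pytest.approx(-0.5, abs=0.1)
        assert res.extra["converged"]

    def test_matches_irls_oracle(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=200)
        y = (rng.random(200) < 1 / (1 + np.exp(-x))).astype(int)
        beta, se = irls_logistic_oracle(y.astype(float), x)
        res = logistic_fit(y, x)
        assert res.extra["B"] == pytest.approx(beta[1], abs=1e-6)
        assert res.extra["intercept"] == pytest.approx(beta[0], abs=1e-6)
        assert res.extra["se"] == pytest.approx(se[1], abs=1e-6)
        assert res.statistic == pytest.approx((beta[1] / se[1]) ** 2, rel=1e-4)

    def test_cox_snell_r2_definition(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=300)
        y = (rng.random(300) < 1 / (1 + np.exp(-2 * x))).astype(int)
        res = logistic_fit(y, x)
        # recompute from the null and full log-likelihoods
        import statsmodels.api as sm

        full = sm.Logit(y, sm.add_constant(x)).fit(disp=False)
        r2 = 1 - np.exp((full.llnull - full.llf) * 2 / 300)
        assert res.extra["r2_cox_snell"] == pytest.approx(r2, abs=1e-8)
        assert 0 <= res.extra["r2_cox_snell"] <= 1

    def test_perfect_separation_flagged(self):
        x = np.array([-2.0, -1.5, -1.0, 1.0, 1.5, 2.0])
        y = np.array([0, 0, 0, 1, 1, 1])
        res = logistic_fit(y, x)
        assert res.extra["converged"] is False

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            logistic_fit(np.ones(6), np.arange(6.0))
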