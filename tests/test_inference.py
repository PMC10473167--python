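import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from gazedyn.inference import (
    ModelSpec,
    compare_models,
    correlation_panel,
    fit_model,
    individual_differences,
    spread_recurrence_summary,
)
from gazedyn.inference.families import get_family
from gazedyn.inference.model import _build_design, _Posterior


def hierarchical_data(family, slope, P=20, T=120, seed=0, sd_int=0.5, sd_slope=0.2, b0=None):
    """Simulate per-trial data directly from a family with known coefficients."""
    rng = np.random.default_rng(seed)
    k = np.tile(np.repeat([1.0, 2, 3, 4], T // 4), P)
    pid = np.repeat(np.arange(P), T)
    kc = k - k.mean()
    u0 = rng.normal(0, sd_int, P)
    u1 = rng.normal(0, sd_slope, P)
    fam = get_family(family)
    if family == "zoib":
        eta = (0.3 if b0 is None else b0) + slope * kc + u0[pid] + u1[pid] * kc
        extra = np.array([np.log(0.05 / 0.95), 0.0, np.log(8.0)])
    elif family == "exgaussian":
        eta = (90.0 if b0 is None else b0) + slope * kc + u0[pid] + u1[pid] * kc
        extra = np.array([np.log(25.0), np.log(40.0)])
    else:
        eta = (2.0 if b0 is None else b0) + slope * kc + u0[pid] + u1[pid] * kc
        extra = np.zeros(0)
    y = fam.simulate(eta, extra, rng)
    return pd.DataFrame({"participant": pid, "segments": k, "y": y})


class TestFamilies:
    """Log-densities and gradients against independent references."""

    def test_exgaussian_matches_scipy_exponnorm(self, rng):
        fam = get_family("exgaussian")
        y = rng.uniform(10, 400, 50)
        eta = rng.uniform(50, 200, 50)
        sigma, tau = 22.0, 55.0
        extra = np.log([sigma, tau])
        ours = fam.loglik(y, eta, extra)
        ref = stats.exponnorm.logpdf(y, K=tau / sigma, loc=eta, scale=sigma)
        np.testing.assert_allclose(ours, ref, rtol=1e-8)

    def test_zoib_matches_manual_mixture(self, rng):
        fam = get_family("zoib")
        alpha, gamma, phi = 0.15, 0.4, 7.0
        extra = np.array([np.log(alpha / (1 - alpha)), np.log(gamma / (1 - gamma)), np.log(phi)])
        y = np.array([0.0, 1.0, 0.3, 0.8])
        eta = np.array([0.5, 0.5, 0.2, -0.4])
        mu = 1 / (1 + np.exp(-eta))
        expected = np.array(
            [
                np.log(alpha * (1 - gamma)),
                np.log(alpha * gamma),
                np.log(1 - alpha) + stats.beta.logpdf(0.3, mu[2] * phi, (1 - mu[2]) * phi),
                np.log(1 - alpha) + stats.beta.logpdf(0.8, mu[3] * phi, (1 - mu[3]) * phi),
            ]
        )
        np.testing.assert_allclose(fam.loglik(y, eta, extra), expected, rtol=1e-9)

    def test_bernoulli_matches_scipy(self, rng):
        fam = get_family("bernoulli")
        y = (rng.random(30) < 0.5).astype(float)
        eta = rng.normal(0, 2, 30)
        ref = stats.bernoulli.logpmf(y, 1 / (1 + np.exp(-eta)))
        np.testing.assert_allclose(fam.loglik(y, eta, np.zeros(0)), ref, rtol=1e-8)

    @pytest.mark.parametrize("family", ["bernoulli", "zoib", "exgaussian"])
    def test_analytic_gradients_match_finite_differences(self, family, rng):
        fam = get_family(family)
        n = 40
        if family == "zoib":
            y = np.concatenate([[0.0, 1.0], rng.beta(2, 2, n - 2)])
            extra = np.array([-1.5, 0.3, np.log(6.0)])
        elif family == "exgaussian":
            y = rng.uniform(20, 300, n)
            extra = np.log([30.0, 50.0])
        else:
            y = (rng.random(n) < 0.6).astype(float)
            extra = np.zeros(0)
        eta = rng.normal(0 if family != "exgaussian" else 100.0, 1.0, n)

        _, deta, dextra = fam.loglik_grad(y, eta, extra)
        h = 1e-6
        for i in rng.choice(n, 5, replace=False):
            ep, em = eta.copy(), eta.copy()
            ep[i] += h
            em[i] -= h
            fd = (fam.loglik(y, ep, extra).sum() - fam.loglik(y, em, extra).sum()) / (2 * h)
            assert deta[i] == pytest.approx(fd, rel=1e-4, abs=1e-6)
        for j in range(len(extra)):
            ep, em = extra.copy(), extra.copy()
            ep[j] += h
            em[j] -= h
            fd = (fam.loglik(y, eta, ep).sum() - fam.loglik(y, eta, em).sum()) / (2 * h)
            assert dextra[j] == pytest.approx(fd, rel=1e-4, abs=1e-5)

    @pytest.mark.parametrize("family", ["bernoulli", "zoib", "exgaussian"])
    def test_curvature_matches_finite_difference_of_gradient(self, family, rng):
        fam = get_family(family)
        if family == "zoib":
            y = rng.beta(2, 2, 20)
            extra = np.array([-1.5, 0.3, np.log(6.0)])
            eta = rng.normal(0, 1, 20)
        elif family == "exgaussian":
            y = rng.uniform(20, 300, 20)
            extra = np.log([30.0, 50.0])
            eta = rng.normal(100, 20, 20)
        else:
            y = (rng.random(20) < 0.6).astype(float)
            extra = np.zeros(0)
            eta = rng.normal(0, 1, 20)
        w = fam.eta_curvature(y, eta, extra)
        h = 1e-5
        _, gp, _ = fam.loglik_grad(y, eta + h, extra)
        _, gm, _ = fam.loglik_grad(y, eta - h, extra)
        np.testing.assert_allclose(w, -(gp - gm) / (2 * h), rtol=1e-3, atol=1e-6)


class TestJointPosteriorGradient:
    def test_analytic_gradient_matches_finite_differences(self, rng):
        data = hierarchical_data("zoib", -0.3, P=5, T=16, seed=2)
        design = _build_design(data, ModelSpec(response="y", family="zoib"))
        post = _Posterior(design)
        theta = post.init(rng) + 0.05 * rng.standard_normal(post.dim)
        _, grad = post.log_post_grad(theta)
        h = 1e-6
        for i in rng.choice(post.dim, 12, replace=False):
            tp, tm = theta.copy(), theta.copy()
            tp[i] += h
            tm[i] -= h
            fd = (post.log_post(tp) - post.log_post(tm)) / (2 * h)
            assert grad[i] == pytest.approx(fd, rel=1e-3, abs=1e-4)


class TestFitModel:
    def test_recovers_known_zoib_slope(self):
        data = hierarchical_data("zoib", -0.4, seed=42)
        fit = fit_model(data, ModelSpec(response="y", family="zoib", seed=0))
        lo, hi = fit.coefficient_ci("segments")
        assert lo <= -0.4 <= hi
        assert fit.diagnostics["converged"]

    def test_null_slope_gives_absent_effect(self):
        data = hierarchical_data("zoib", 0.0, seed=7, sd_slope=0.0)
        fit = fit_model(data, ModelSpec(response="y", family="zoib", seed=0))
        assert not fit.effect_present("segments")

    def test_binomial_sign_recovery(self):
        data = hierarchical_data("bernoulli", -0.45, seed=5)
        fit = fit_model(data, ModelSpec(response="y", family="bernoulli", seed=0))
        assert fit.coefficients.loc["segments", "median"] < 0
        assert fit.effect_present("segments")

    def test_percentage_response_rescaled_for_beta_family(self):
        data = hierarchical_data("zoib", -0.4, P=8, T=40, seed=1)
        data["y"] = data["y"] * 100.0  # stored as percentages
        fit = fit_model(data, ModelSpec(response="y", family="zoib", seed=0))
        assert fit.response_scaled
        lo, hi = fit.coefficient_ci("segments")
        assert lo < -0.1 and hi < 0.2  # slope estimated on the unit scale

    def test_matches_glmmtmb_marginal_laplace(self, tmp_path):
        """Independent GLMM oracle: same model fit by R glmmTMB."""
        data = hierarchical_data("bernoulli", -0.5, P=8, T=60, seed=3, sd_slope=0.0)
        fit = fit_model(
            data, ModelSpec(response="y", family="bernoulli", random_slope_on=None, seed=0)
        )
        csv = tmp_path / "d.csv"
        data.to_csv(csv, index=False)
        script = tmp_path / "m.R"
        script.write_text(
            textwrap.dedent(
                f"""
                suppressMessages(library(glmmTMB))
                d <- read.csv('{csv}')
                d$kc <- d$segments - mean(d$segments)
                m <- glmmTMB(y ~ kc + (1|participant), family=binomial, data=d)
                co <- summary(m)$coefficients$cond
                cat(co['kc','Estimate'], co['kc','Std. Error'], '\\n')
                """
            )
        )
        out = subprocess.run(
            ["Rscript", str(script)], capture_output=True, text=True, check=True
        )
        est, se = map(float, out.stdout.split())
        ours = fit.coefficients.loc["segments", "median"]
        lo, hi = fit.coefficient_ci("segments")
        assert ours == pytest.approx(est, abs=0.5 * se)
        assert (hi - lo) / 2 == pytest.approx(1.96 * se, rel=0.35)

    def test_laplace_agrees_with_emcee_sampling(self):
        data = hierarchical_data("bernoulli", -0.5, P=6, T=48, seed=3, sd_slope=0.0)
        spec = dict(response="y", family="bernoulli", random_slope_on=None)
        la = fit_model(data, ModelSpec(seed=0, **spec))
        mc = fit_model(data, ModelSpec(seed=0, sampler="emcee", **spec))
        m_la = la.coefficients.loc["segments", "median"]
        m_mc = mc.coefficients.loc["segments", "median"]
        lo, hi = mc.coefficient_ci("segments")
        assert m_la == pytest.approx(m_mc, abs=0.5 * (hi - lo))

    def test_missing_columns_raise(self):
        data = hierarchical_data("bernoulli", 0.0, P=3, T=8)
        with pytest.raises(KeyError):
            fit_model(data, ModelSpec(response="nope", family="bernoulli"))
        with pytest.raises(KeyError):
            fit_model(data, ModelSpec(response="y", family="bernoulli", fixed_effects=["zzz"]))

    def test_single_participant_rejected(self):
        data = hierarchical_data("bernoulli", 0.0, P=1, T=8)
        with pytest.raises(ValueError):
            fit_model(data, ModelSpec(response="y", family="bernoulli"))


class TestCompareModels:
    def test_model_compared_with_itself_is_zero(self):
        data = hierarchical_data("bernoulli", -0.4, P=6, T=40, seed=2)
        fit = fit_model(data, ModelSpec(response="y", family="bernoulli", seed=0))
        cmp = compare_models(fit, fit)
        assert cmp.elpd_diff == pytest.approx(0.0, abs=1e-9)

    def test_spurious_predictor_adds_no_predictive_power(self):
        data = hierarchical_data("bernoulli", -0.4, P=10, T=60, seed=4)
        rng = np.random.default_rng(0)
        data["dvn"] = rng.integers(0, 2, len(data)).astype(float)  # pure noise
        reduced = fit_model(data, ModelSpec(response="y", family="bernoulli", seed=0))
        augmented = fit_model(
            data,
            ModelSpec(response="y", family="bernoulli", fixed_effects=["segments", "dvn"], seed=0),
        )
        cmp = compare_models(augmented, reduced)
        assert abs(cmp.elpd_diff) < max(4.0, 2.0 * cmp.se_diff + 2.0)
        assert not cmp.favors_a()

    def test_real_predictor_is_favored(self):
        rng = np.random.default_rng(1)
        data = hierarchical_data("bernoulli", 0.0, P=10, T=80, seed=9)
        x = rng.normal(0, 1, len(data))
        flip = 1 / (1 + np.exp(-(2.0 * x)))
        data["y"] = (rng.random(len(data)) < flip).astype(float)
        data["x"] = x
        reduced = fit_model(data, ModelSpec(response="y", family="bernoulli", seed=0))
        augmented = fit_model(
            data,
            ModelSpec(response="y", family="bernoulli", fixed_effects=["segments", "x"], seed=0),
        )
        cmp = compare_models(augmented, reduced)
        assert cmp.favors_a()

    def test_mismatched_data_rejected(self):
        a = fit_model(
            hierarchical_data("bernoulli", 0.0, P=4, T=20, seed=1),
            ModelSpec(response="y", family="bernoulli", seed=0),
        )
        b = fit_model(
            hierarchical_data("bernoulli", 0.0, P=4, T=20, seed=2),
            ModelSpec(response="y", family="bernoulli", seed=0),
        )
        with pytest.raises(ValueError):
            compare_models(a, b)


class TestIndividualDifferences:
    def test_homogeneous_population_gives_small_sd(self):
        data = hierarchical_data("bernoulli", -0.3, P=12, T=80, seed=3, sd_int=0.0, sd_slope=0.0)
        fit = fit_model(data, ModelSpec(response="y", family="bernoulli", seed=0))
        idiff = individual_differences(fit, data)
        assert idiff.sd_intercept[0] < 0.3  # posterior median near zero

    def test_heterogeneous_population_sd_recovered(self):
        data = hierarchical_data("bernoulli", -0.3, P=20, T=120, seed=8, sd_int=1.2, sd_slope=0.0)
        fit = fit_model(data, ModelSpec(response="y", family="bernoulli", seed=0))
        med, lo, hi = individual_differences(fit).sd_intercept
        assert lo <= 1.2 <= hi

    def test_reports_response_range(self):
        data = hierarchical_data("bernoulli", -0.3, P=8, T=40, seed=3)
        fit = fit_model(data, ModelSpec(response="y", family="bernoulli", seed=0))
        idiff = individual_differences(fit, data)
        means = data.groupby("participant")["y"].mean()
        assert idiff.response_range == (pytest.approx(means.min()), pytest.approx(means.max()))


class TestCorrelationPanel:
    def test_variable_with_itself(self, rng):
        df = pd.DataFrame(rng.normal(size=(30, 3)), columns=["a", "b", "c"])
        panel = correlation_panel(df)
        assert all(panel.r.loc[c, c] == 1.0 for c in "abc")

    def test_independent_columns_rarely_flagged(self):
        flagged = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            df = pd.DataFrame(rng.normal(size=(40, 5)), columns=list("abcde"))
            if correlation_panel(df).significant_pairs():
                flagged += 1
        assert flagged <= 1  # adjusted alpha 0.01 over 10 pairs

    def test_shared_latent_factor_flags_all_pairs(self, rng):
        f = rng.normal(size=60)
        df = pd.DataFrame(
            {c: 0.9 * f + 0.3 * rng.normal(size=60) for c in ["rec", "det", "corm"]}
        )
        df["unrelated"] = rng.normal(size=60)
        panel = correlation_panel(df)
        pairs = set(panel.significant_pairs())
        assert {("rec", "det"), ("rec", "corm"), ("det", "corm")} <= pairs
        assert not any("unrelated" in p for p in pairs)

    def test_too_few_participants_raises(self, rng):
        df = pd.DataFrame(rng.normal(size=(3, 3)), columns=list("abc"))
        with pytest.raises(ValueError):
            correlation_panel(df)


class TestQuadrants:
    def test_counts_and_flag(self):
        trials = pd.DataFrame(
            {
                "recurrence": [10.0, 60.0, 80.0, 20.0],
                "spread_px": [50.0, 50.0, 40.0, 300.0],
            }
        )
        q = spread_recurrence_summary(trials, rec_cut=50.0, spread_cut=104.0)
        assert (
            q.low_rec_low_spread,
            q.low_rec_high_spread,
            q.high_rec_low_spread,
            q.high_rec_high_spread,
        ) == (1, 1, 2, 0)
        assert q.upper_right_empty

    def test_zero_recurrence_everywhere(self):
        trials = pd.DataFrame({"recurrence": [0.0] * 5, "spread_px": [10, 50, 150, 200, 300.0]})
        q = spread_recurrence_summary(trials, spread_cut=104.0)
        assert q.high_rec_low_spread == 0 and q.high_rec_high_spread == 0

    def test_spread_cut_defaults_to_threshold_column(self):
        trials = pd.DataFrame(
            {"recurrence": [60.0], "spread_px": [120.0], "d": [104.0]}
        )
        q = spread_recurrence_summary(trials)
        assert q.spread_cut == 104.0 and q.high_rec_high_spread == 1
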