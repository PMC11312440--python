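"""ComBat-family harmonization: constraints, identities, nesting, parameter
recovery, EB shrinkage behavior, and determinism."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from combatls import (
    ComBatHarmonizer,
    Linear,
    eb_shrink,
    fit_mean_model,
    fit_scale_model,
    harmonize,
    standardize,
    with_batch,
)
from combatls.harmonize import _onehot
from conftest import small_config
from combatls import generate_cohort, assign_sites_weighted


def _cov(n, rng):
    return pd.DataFrame({
        "age": rng.uniform(50, 80, n) * 365.25,
        "sex": rng.integers(0, 2, n),
    })


# ---------------------------------------------------------------------------
# mean model
# ---------------------------------------------------------------------------

class TestMeanModel:
    def test_single_batch_gamma_is_zero(self):
        rng = np.random.default_rng(0)
        y = rng.standard_normal((50, 2))
        fit = fit_mean_model(y, _cov(50, rng), [Linear("age"), Linear("sex")],
                             np.zeros(50, dtype=int), np.array([50.0]))
        np.testing.assert_allclose(fit.gamma_hat, 0.0, atol=1e-12)

    def test_two_equal_batches_closed_form(self):
        n = 40
        y = np.full((2 * n, 1), 3.0)
        y[n:] += 1.0  # shift on batch B only
        batch_idx = np.repeat([0, 1], n)
        fit = fit_mean_model(
            y, pd.DataFrame(index=range(2 * n)), [], batch_idx,
            np.array([float(n), float(n)]),
        )
        np.testing.assert_allclose(fit.gamma_hat[:, 0], [-0.5, 0.5], atol=1e-10)
        np.testing.assert_allclose(fit.alpha, 3.5, atol=1e-10)

    def test_matches_independent_ols(self):
        """Unpenalized mean model equals a statsmodels OLS on the same design."""
        rng = np.random.default_rng(3)
        n = 300
        cov = _cov(n, rng)
        batch_idx = rng.integers(0, 3, n)
        n_i = np.bincount(batch_idx).astype(float)
        y = rng.standard_normal((n, 1)) + 0.01 * cov["age"].to_numpy()[:, None] / 365
        fit = fit_mean_model(y, cov, [Linear("age"), Linear("sex")], batch_idx, n_i)
        x_sm = np.column_stack([
            _onehot(batch_idx, 3), cov["age"], cov["sex"],
        ])
        ols = sm.OLS(y[:, 0], x_sm).fit()
        np.testing.assert_allclose(
            fit.gamma_hat[:, 0], ols.params[:3] - (n_i / n) @ ols.params[:3],
            atol=1e-8,
        )
        np.testing.assert_allclose(fit.beta[:, 0], ols.params[3:], atol=1e-8)

    def test_null_covariate_coverage(self):
        """With a covariate that has no true effect, the fitted coefficient
        lands within 3 SE of zero in >= 95% of seeded replications."""
        n, reps = 500, 100
        rng = np.random.default_rng(42)
        cov = _cov(n, rng)
        batch_idx = rng.integers(0, 2, n)
        n_i = np.bincount(batch_idx).astype(float)
        x_sm = np.column_stack([_onehot(batch_idx, 2), cov["age"], cov["sex"]])
        hits = 0
        for _ in range(reps):
            y = rng.standard_normal((n, 1))
            fit = fit_mean_model(y, cov, [Linear("age"), Linear("sex")],
                                 batch_idx, n_i)
            se = sm.OLS(y[:, 0], x_sm).fit().bse[3]  # sex coefficient SE
            hits += abs(fit.beta[1, 0]) < 3 * se
        assert hits >= 95


# ---------------------------------------------------------------------------
# scale model
# ---------------------------------------------------------------------------

class TestScaleModel:
    def test_log_delta_constraint(self, three_site_cohort):
        cohort, _ = three_site_cohort
        _, est = harmonize(cohort, method="combat_ls")
        np.testing.assert_allclose(
            est.n_per_batch_ @ np.log(est.delta_hat_), 0.0, atol=1e-8
        )

    def test_parameter_recovery_zeta_eta(self):
        """log(SD) = 0.5 + 0.3*sex recovered within 10% (mean of 20 seeds)."""
        n = 5000
        zetas, etas = [], []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            sex = rng.integers(0, 2, n)
            resid = np.exp(0.5 + 0.3 * sex) * rng.standard_normal(n)
            fit = fit_scale_model(
                resid[:, None], pd.DataFrame({"sex": sex}), [Linear("sex")],
                np.zeros(n, dtype=int), np.array([float(n)]),
            )
            site_const = fit.zeta[0]  # single site: zeta is the constant
            zetas.append(site_const)
            etas.append(fit.eta[0, 0])
        assert abs(np.mean(zetas) - 0.5) < 0.05
        assert abs(np.mean(etas) - 0.3) < 0.03

    def test_null_scale_effect(self):
        """Homoskedastic residuals: eta stays within 3 SE of zero."""
        n = 2000
        rng = np.random.default_rng(7)
        sex = rng.integers(0, 2, n)
        resid = rng.standard_normal(n)
        fit = fit_scale_model(
            resid[:, None], pd.DataFrame({"sex": sex}), [Linear("sex")],
            np.zeros(n, dtype=int), np.array([float(n)]),
        )
        # asymptotic SE of a log-SD coefficient is ~ 1/sqrt(2 n_group)
        se = np.sqrt(1.0 / (2 * (sex == 1).sum()) + 1.0 / (2 * (sex == 0).sum()))
        assert abs(fit.eta[0, 0]) < 3 * se

    def test_site_sd_ratio_recovered(self):
        """Doubled residual SD at site B shows up as delta_B/delta_A = 2."""
        n = 5000
        rng = np.random.default_rng(9)
        batch_idx = rng.integers(0, 2, 2 * n)
        resid = rng.standard_normal((2 * n, 1)) * np.where(batch_idx == 1, 2.0, 1.0)[:, None]
        fit = fit_scale_model(
            resid, pd.DataFrame(index=range(2 * n)), [], batch_idx,
            np.bincount(batch_idx).astype(float),
        )
        ratio = fit.delta_hat[1, 0] / fit.delta_hat[0, 0]
        # oracle: root-mean-square ratio (ML variance estimates, means not removed)
        rms = lambda v: np.sqrt(np.mean(v**2))
        sample_ratio = rms(resid[batch_idx == 1]) / rms(resid[batch_idx == 0])
        assert ratio == pytest.approx(sample_ratio, rel=1e-10)
        assert ratio == pytest.approx(2.0, rel=0.05)


# ---------------------------------------------------------------------------
# standardization and back-transform
# ---------------------------------------------------------------------------

class TestStandardize:
    def test_roundtrip_is_identity(self, three_site_cohort):
        cohort, _ = three_site_cohort
        _, est = harmonize(cohort, method="combat_ls")
        y = cohort.features.to_numpy(float)
        cov = cohort.covariates.reset_index(drop=True)
        z, mu_hat, denom = standardize(y, est.mean_fit_, est.scale_fit_, cov)
        np.testing.assert_allclose(z * denom + mu_hat, y, atol=1e-10)

    def test_zero_residual_gives_zero_z(self):
        rng = np.random.default_rng(1)
        n = 200
        cov = _cov(n, rng)
        y = rng.standard_normal((n, 1))
        batch_idx = np.zeros(n, dtype=int)
        n_i = np.array([float(n)])
        mean_fit = fit_mean_model(y, cov, [Linear("age")], batch_idx, n_i)
        scale_fit = fit_scale_model(
            y - mean_fit.predict(cov), cov, [], batch_idx, n_i
        )
        fitted = mean_fit.predict(cov)
        z, _, _ = standardize(fitted, mean_fit, scale_fit, cov)
        np.testing.assert_allclose(z, 0.0, atol=1e-12)


# ---------------------------------------------------------------------------
# empirical Bayes
# ---------------------------------------------------------------------------

def _eb_setup(gamma, delta, n_per_site=50, seed=0):
    """Build standardized data consistent with the given site parameters."""
    rng = np.random.default_rng(seed)
    m, k = gamma.shape
    batch_idx = np.repeat(np.arange(m), n_per_site)
    z = gamma[batch_idx] + delta[batch_idx] * rng.standard_normal((m * n_per_site, k))
    n_i = np.full(m, float(n_per_site))
    return z, batch_idx, n_i


class TestEBShrink:
    def test_identical_estimates_are_fixed_point(self):
        gamma = np.full((2, 5), 0.3)
        delta = np.ones((2, 5))
        z, batch_idx, n_i = _eb_setup(gamma, delta)
        g_star, d_star = eb_shrink(z, batch_idx, n_i, gamma, delta)
        np.testing.assert_array_equal(g_star, gamma)
        np.testing.assert_array_equal(d_star, delta)

    def test_outlier_shrinks_toward_prior_mean(self):
        rng = np.random.default_rng(4)
        gamma = np.concatenate([rng.normal(0.2, 0.01, (1, 9)),
                                [[2.0]]], axis=1)  # one outlier feature
        gamma = np.vstack([gamma, -gamma])
        delta = np.ones_like(gamma)
        z, batch_idx, n_i = _eb_setup(gamma, delta, n_per_site=10)
        g_star, _ = eb_shrink(z, batch_idx, n_i, gamma, delta)
        prior_mean = gamma[0].mean()
        assert abs(g_star[0, -1] - prior_mean) < abs(gamma[0, -1] - prior_mean)

    def test_large_sites_leave_estimates_alone(self):
        rng = np.random.default_rng(5)
        gamma = rng.normal(0, 0.5, (2, 6))
        gamma -= gamma.mean(axis=0)
        delta = np.exp(rng.normal(0, 0.2, (2, 6)))
        z, batch_idx, n_i = _eb_setup(gamma, delta, n_per_site=10_000, seed=6)
        g_star, d_star = eb_shrink(z, batch_idx, n_i, gamma, delta)
        np.testing.assert_allclose(g_star, gamma, rtol=0.01, atol=0.01)

    def test_small_group_skipped_with_warning(self):
        gamma = np.array([[0.5], [-0.5]])
        delta = np.ones((2, 1))
        z, batch_idx, n_i = _eb_setup(gamma, delta)
        with pytest.warns(UserWarning, match="fewer than 2 features"):
            g_star, d_star = eb_shrink(z, batch_idx, n_i, gamma, delta)
        np.testing.assert_array_equal(g_star, gamma)


# ---------------------------------------------------------------------------
# end-to-end estimator invariants
# ---------------------------------------------------------------------------

class TestHarmonizer:
    @pytest.mark.parametrize("method", ["combat", "combat_nocov", "combat_gam",
                                        "combat_ls"])
    def test_single_batch_identity(self, pooled_cohort, method):
        cohort, _ = pooled_cohort
        with pytest.warns(UserWarning, match="only one batch"):
            out, _ = harmonize(cohort, method=method)
        x = cohort.features.to_numpy()
        rel = np.abs(out.features.to_numpy() - x) / np.abs(x)
        assert rel.max() < 1e-8

    def test_nocov_equals_combat_with_empty_terms(self, three_site_cohort):
        cohort, _ = three_site_cohort
        a, _ = harmonize(cohort, method="combat_nocov")
        b, _ = harmonize(cohort, method="combat", mean_terms=[])
        np.testing.assert_array_equal(a.features.to_numpy(), b.features.to_numpy())

    def test_ls_with_empty_scale_terms_matches_gam(self, three_site_cohort):
        cohort, _ = three_site_cohort
        a, _ = harmonize(cohort, method="combat_ls", scale_terms=[])
        b, _ = harmonize(cohort, method="combat_gam")
        np.testing.assert_allclose(
            a.features.to_numpy(), b.features.to_numpy(), atol=1e-6
        )

    def test_constraints(self, three_site_cohort):
        cohort, _ = three_site_cohort
        _, est = harmonize(cohort, method="combat_ls")
        np.testing.assert_allclose(est.n_per_batch_ @ est.gamma_hat_, 0, atol=1e-8)
        np.testing.assert_allclose(
            est.n_per_batch_ @ np.log(est.delta_hat_), 0, atol=1e-8
        )

    def test_batch_moments_matched_after_harmonization(self):
        """Two sites differing only by shift and scale end up with matching
        per-site moments (no covariates in play)."""
        rng = np.random.default_rng(10)
        n = 2000
        batch = np.repeat(["A", "B"], n)
        y = rng.standard_normal(2 * n)
        y[n:] = 1.5 + 2.0 * y[n:]
        est = ComBatHarmonizer(method="combat_nocov", eb=False)
        out = est.fit_transform(y[:, None], batch=batch)
        a, b = out[:n, 0], out[n:, 0]
        assert abs(a.mean() - b.mean()) < 0.01 * max(1, abs(a.mean()))
        assert abs(a.std() / b.std() - 1) < 0.01

    def test_scale_preservation_vs_pooling(self):
        """ComBatLS recovers the generating M/F residual-SD ratio; linear
        ComBat on 4:1 imbalanced sites pulls it toward the pooled compromise."""
        cohort, truth = generate_cohort(small_config(5000, 4,
                                                     eta_sex=float(np.log(1.5))),
                                        seed=31)
        probs = np.array([[0.2, 0.8], [0.8, 0.2]])
        labels = assign_sites_weighted(truth.sex, probs=probs, seed=32)
        cohort = with_batch(cohort, labels)
        male = truth.sex == 1

        def ratio(values):
            r = values - truth.mean
            return float(np.mean(np.std(r[male], axis=0) / np.std(r[~male], axis=0)))

        h_ls, _ = harmonize(cohort, method="combat_ls")
        h_lin, _ = harmonize(cohort, method="combat")
        r_ls = ratio(h_ls.features.to_numpy())
        r_lin = ratio(h_lin.features.to_numpy())
        assert abs(r_ls - 1.5) < 0.15
        assert r_lin < r_ls  # attenuated toward 1

    def test_residual_site_means_removed(self):
        """With known injected site effects at n=2000/site, per-site means of
        the standardized residuals agree within 0.02 SD after harmonization."""
        from combatls import inject_site_effects

        cohort, truth = generate_cohort(small_config(6000, 4), seed=55)
        probs = np.full((2, 3), 1 / 3)
        labels = assign_sites_weighted(truth.sex, probs=probs, seed=56)
        cohort = with_batch(cohort, labels)
        levels = sorted(np.unique(labels))
        observed = inject_site_effects(
            cohort, truth, dict(zip(levels, (-1.0, 0.0, 1.0))),
            {lev: 1.0 for lev in levels},
        )
        out, est = harmonize(observed, method="combat_ls")
        cov = cohort.covariates.reset_index(drop=True)
        z = (out.features.to_numpy() - est.mean_fit_.predict(cov)) / (
            est.scale_fit_.predict_sd(cov)
        )
        overall = z.mean(axis=0)
        for lev in levels:
            site_means = z[labels == lev].mean(axis=0)
            assert np.abs(site_means - overall).max() < 0.02

    def test_determinism(self, three_site_cohort):
        cohort, _ = three_site_cohort
        a, _ = harmonize(cohort, method="combat_ls")
        b, _ = harmonize(cohort, method="combat_ls")
        np.testing.assert_array_equal(a.features.to_numpy(), b.features.to_numpy())

    def test_small_batch_rejected(self, pooled_cohort):
        cohort, _ = pooled_cohort
        labels = np.array(["A"] * (cohort.n_subjects - 2) + ["B", "B"])
        small = with_batch(cohort, labels)
        with pytest.raises(ValueError, match="3 subjects"):
            harmonize(small, method="combat_ls")

    def test_refit_application_and_json_roundtrip(self, three_site_cohort, tmp_path):
        cohort, _ = three_site_cohort
        out, est = harmonize(cohort, method="combat_ls")
        est.save(tmp_path / "fit.json")
        back = ComBatHarmonizer.load(tmp_path / "fit.json")
        redo = back.transform(
            cohort.features.to_numpy(float),
            covariates=cohort.covariates,
            batch=cohort.batch.to_numpy(),
        )
        np.testing.assert_allclose(redo, out.features.to_numpy(), rtol=1e-10)

    def test_scale_terms_rejected_outside_ls(self, three_site_cohort):
        cohort, _ = three_site_cohort
        with pytest.raises(ValueError, match="combat_ls"):
            harmonize(cohort, method="combat_gam", scale_terms=[Linear("sex")])
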