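"""Exactness of the per-feature conjugate + quadrature posterior engine."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from shrinkht import (
    Gaussian,
    PriorSet,
    build_design,
    conditional_beta_posterior,
    marginal_posterior,
)
from conftest import make_feature, make_design_frame


# ---------------------------------------------------------------------------
# design construction
# ---------------------------------------------------------------------------


class TestBuildDesign:
    def test_design_layout_validates(self):
        f = build_design(make_design_frame([1.0, 2, 3, 4, 5, 6]))
        assert f.n_obs == 6
        assert f.n_assays == 3
        assert f.n_coef == 4
        np.testing.assert_array_equal(f.offsets, np.zeros(6))
        X = f.design_matrix()
        np.testing.assert_array_equal(X[:, 0], np.ones(6))
        np.testing.assert_array_equal(X[:, 1], [0, 1, 0, 1, 0, 1])

    def test_offsets_read_when_present(self):
        f = build_design(make_design_frame(np.arange(6.0), offsets=np.full(6, 0.5)))
        np.testing.assert_array_equal(f.offsets, np.full(6, 0.5))

    def test_duplicate_cell_is_structural_error(self):
        df = make_design_frame(np.arange(6.0))
        df.loc[0, ["treatment", "assay"]] = [2, 1]  # now two (treated, assay 1) rows
        with pytest.raises(ValueError, match="missing design cell|duplicated"):
            build_design(df)

    def test_missing_cell_names_the_cell(self):
        df = make_design_frame(np.arange(6.0)).drop(index=3)
        with pytest.raises(ValueError, match=r"treatment=2, assay=2"):
            build_design(df)

    def test_non_numeric_value_is_parse_error(self):
        df = make_design_frame(np.arange(6.0)).astype({"value": object})
        df.loc[2, "value"] = "NA?"
        with pytest.raises(ValueError, match="non-numeric"):
            build_design(df)

    def test_replicated_cells_allowed_for_controls(self):
        df = pd.concat([make_design_frame(np.arange(6.0))] * 3, ignore_index=True)
        f = build_design(df, allow_replicates=True)
        assert f.n_obs == 18


# ---------------------------------------------------------------------------
# conditional conjugate posterior
# ---------------------------------------------------------------------------


def brute_force_posterior(feature, priors, sigma2, half_width=8.0, n_grid=41):
    """4-D trapezoid integration of the unnormalized posterior.

    The analytic solution is used only to place the integration box; all
    moments come from the grid.  Trapezoid rules converge exponentially
    for Gaussian integrands, so 41 points per axis is ample for 1e-6.
    """
    ref = conditional_beta_posterior(feature, priors, sigma2)
    sds = np.sqrt(np.diag(ref.covariance))
    axes = [
        np.linspace(m - half_width * s, m + half_width * s, n_grid)
        for m, s in zip(ref.mean, sds)
    ]
    grids = np.meshgrid(*axes, indexing="ij")
    B = np.stack([g.ravel() for g in grids], axis=1)  # (M, 4)
    X = feature.design_matrix()
    r = feature.centered_values()
    resid = r[None, :] - B @ X.T
    loglik = -0.5 * np.sum(resid**2, axis=1) / sigma2
    m0 = priors.coef_prior_mean(4)
    v0 = priors.coef_prior_variance(4)
    logprior = -0.5 * np.sum((B - m0) ** 2 / v0, axis=1)
    w = np.exp(loglik + logprior - np.max(loglik + logprior)).reshape(grids[0].shape)
    # trapezoid weights per axis
    for ax, pts in enumerate(axes):
        tw = np.gradient(pts)
        tw[0] *= 0.5
        tw[-1] *= 0.5
        shape = [1] * 4
        shape[ax] = n_grid
        w = w * tw.reshape(shape)
    w = w.ravel()
    w /= w.sum()
    mean = w @ B
    dev = B - mean
    cov = (w[:, None] * dev).T @ dev
    return mean, cov


class TestConditionalPosterior:
    def test_balanced_data_gives_zero_treatment_effect(self):
        # identical treated/untreated value within each assay
        f = make_feature([1.0, 1.0, 2.0, 2.0, 3.0, 3.0])
        priors = PriorSet(0.09, 12, 1, Gaussian(0.0, 0.25))
        post = conditional_beta_posterior(f, priors, 0.2)
        # exact only in the infinite-vague-intercept limit; 1e-6 at var 1e6
        assert post.mean[1] == pytest.approx(0.0, abs=1e-6)

    def test_degenerate_treat_prior_collapses_to_point_mass(self, random_feature):
        priors = PriorSet(0.09, 12, 1, Gaussian(0.3, 0.0))
        post = conditional_beta_posterior(random_feature, priors, 0.2)
        assert post.mean[1] == pytest.approx(0.3)
        assert post.covariance[1, 1] == 0.0

    def test_zero_tau2_pins_assay_coefficients(self, random_feature):
        priors = PriorSet(0.0, 12, 1, Gaussian(0.0, 0.25))
        post = conditional_beta_posterior(random_feature, priors, 0.2)
        assert post.mean[2] == post.mean[3] == 0.0
        assert post.covariance[2:, 2:].sum() == 0.0

    @pytest.mark.parametrize("seed", [1, 2])
    def test_matches_brute_force_grid_integration(self, seed, moderate_priors):
        rng = np.random.default_rng(seed)
        f = make_feature(rng.normal(-0.3, 0.6, size=6))
        post = conditional_beta_posterior(f, moderate_priors, 0.3)
        mean, cov = brute_force_posterior(f, moderate_priors, 0.3)
        np.testing.assert_allclose(post.mean, mean, atol=1e-6)
        np.testing.assert_allclose(post.covariance, cov, atol=1e-6)


# ---------------------------------------------------------------------------
# marginal posterior (sigma^2 quadrature)
# ---------------------------------------------------------------------------


class TestMarginalPosterior:
    def test_concentrated_gamma_matches_conditional_at_one(self, random_feature):
        priors = PriorSet(0.09, 1e8, 1e8, Gaussian(-0.2, 0.25))
        marg = marginal_posterior(random_feature, priors)
        cond = conditional_beta_posterior(random_feature, priors, 1.0)
        assert marg.treat_moments[0] == pytest.approx(cond.mean[1], abs=1e-4)
        assert marg.treat_moments[1] == pytest.approx(cond.covariance[1, 1], abs=1e-4)

    def test_symmetric_null_feature_gives_half(self):
        f = make_feature([1.0, 1.0, 2.0, 2.0, 3.0, 3.0])
        priors = PriorSet(0.09, 12, 1, Gaussian(0.0, 0.25))
        marg = marginal_posterior(f, priors)
        assert marg.treat_prob_positive() == pytest.approx(0.5, abs=1e-6)

    def test_treat_density_normalized(self, random_feature, moderate_priors):
        marg = marginal_posterior(random_feature, moderate_priors)
        assert marg.treat_density.integral() == pytest.approx(1.0, abs=1e-6)
        assert marg.precision_weights.sum() == pytest.approx(1.0, abs=1e-10)

    def test_matches_gibbs_sampler(self, moderate_priors):
        """Long-run MCMC oracle for P(beta_treat > 0 | Y).

        2000 independent chains x 600 sweeps (100 burn-in) = 1e6 draws;
        the chains are independent, so the Monte-Carlo error of the
        pooled estimate follows from the spread of per-chain estimates.
        """
        rng = np.random.default_rng(7)
        f = make_feature(rng.normal(-0.3, 0.5, size=6))
        marg = marginal_posterior(f, moderate_priors)

        X = f.design_matrix()
        r = f.centered_values()
        m0 = moderate_priors.coef_prior_mean(4)
        v0 = moderate_priors.coef_prior_variance(4)
        a1, a2 = moderate_priors.alpha1, moderate_priors.alpha2
        n_chain, n_iter, burn = 2000, 600, 100
        lam = rng.gamma(a1, 1.0 / a2, size=n_chain)
        XtX = X.T @ X
        Xtr = X.T @ r
        hits = np.zeros(n_chain)
        count = 0
        for it in range(n_iter):
            prec = lam[:, None, None] * XtX[None] + np.diag(1.0 / v0)[None]
            cov = np.linalg.inv(prec)
            mean = np.einsum(
                "cij,cj->ci", cov, lam[:, None] * Xtr[None] + (m0 / v0)[None]
            )
            L = np.linalg.cholesky(cov)
            beta = mean + np.einsum(
                "cij,cj->ci", L, rng.standard_normal((n_chain, 4))
            )
            resid = r[None, :] - beta @ X.T
            rss = np.sum(resid**2, axis=1)
            lam = rng.gamma(a1 + 3.0, 1.0 / (a2 + 0.5 * rss))
            if it >= burn:
                hits += beta[:, 1] > 0
                count += 1
        per_chain = hits / count
        est = per_chain.mean()
        se = per_chain.std(ddof=1) / np.sqrt(n_chain)
        assert marg.treat_prob_positive() == pytest.approx(est, abs=4 * se + 5e-4)


class TestEngineInvariants:
    def test_quadrature_grid_refinement_is_converged(self, random_feature, moderate_priors):
        from shrinkht.model_core import sigma2_quadrature_grid

        p = {}
        for size in (128, 256):
            grid, _ = sigma2_quadrature_grid(
                moderate_priors.alpha1, moderate_priors.alpha2, size=size
            )
            marg = marginal_posterior(random_feature, moderate_priors, sigma2_grid=grid)
            p[size] = marg.treat_prob_positive()
        assert abs(p[128] - p[256]) < 1e-4

    def test_offset_shift_invariance(self, rng, moderate_priors):
        y = rng.normal(0.0, 0.5, size=6)
        f0 = make_feature(y)
        f1 = make_feature(y + 2.7, offsets=np.full(6, 2.7))
        m0 = marginal_posterior(f0, moderate_priors)
        m1 = marginal_posterior(f1, moderate_priors)
        np.testing.assert_allclose(m0.coef_mean, m1.coef_mean, atol=1e-10)
        assert m0.treat_prob_positive() == pytest.approx(
            m1.treat_prob_positive(), abs=1e-10
        )

    def test_vague_prior_limit_recovers_least_squares(self, rng):
        y = rng.normal(0.0, 0.5, size=6)
        f = make_feature(y)
        priors = PriorSet(1e6, 1e-3, 1e-3, Gaussian(0.0, 1e6), intercept_variance=1e6)
        marg = marginal_posterior(f, priors)
        ols, *_ = np.linalg.lstsq(f.design_matrix(), y, rcond=None)
        np.testing.assert_allclose(marg.coef_mean, ols, atol=1e-3)
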