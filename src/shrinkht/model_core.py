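"""Per-feature Gaussian linear model with shrinkage priors, solved exactly.

Each feature (siRNA) in a screen contributes a handful of observations
``Y_jk = offset_jk + b0 + b_j^treat + b_k^assay + eps_jk`` with Gaussian
errors, a treatment factor (j = 1 untreated, j = 2 treated; corner
constraint ``b_1^treat = 0``), an assay/replicate nuisance factor
(``b_1^assay = 0``; remaining levels share a central Gaussian prior with
variance tau^2), a prior on the treatment effect (Gaussian, or a grid
density after nonparametric reweighting), and a Gamma(shape, rate) prior
on the error precision ``sigma^-2``.

Conditional on sigma^2 the coefficient posterior is Gaussian by conjugacy;
the marginal posterior is obtained by 1-D quadrature over sigma^2 on a grid
spanning the Gamma prior.  The only approximation anywhere is that 1-D
quadrature, so it is kept cheap and dense (128 log-spaced points).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import linalg, stats
from scipy.special import logsumexp

__all__ = [
    "DEFAULT_INTERCEPT_VARIANCE",
    "DEFAULT_SIGMA2_GRID_SIZE",
    "DEFAULT_BETA_GRID_SIZE",
    "GridDensity",
    "Gaussian",
    "FeatureData",
    "PriorSet",
    "ConditionalPosterior",
    "MarginalPosterior",
    "build_design",
    "sigma2_quadrature_grid",
    "conditional_beta_posterior",
    "marginal_posterior",
    "BatchPosteriors",
    "marginal_posteriors_batch",
]

# Vague-prior default for the intercept; the treatment/assay priors start
# equally vague before empirical-Bayes estimation tightens them.
DEFAULT_INTERCEPT_VARIANCE = 1e6
DEFAULT_SIGMA2_GRID_SIZE = 128
DEFAULT_BETA_GRID_SIZE = 512
# Quantile range of the Gamma precision prior covered by the quadrature grid.
_GAMMA_QUANTILE_EPS = 1e-6
# Hard clip for the precision grid so that near-improper priors (shape and
# rate -> 0, used for initialization) still yield a finite grid.
_PRECISION_CLIP = (1e-9, 1e9)


# ---------------------------------------------------------------------------
# Grid densities
# ---------------------------------------------------------------------------


@dataclass
class GridDensity:
    """A univariate density represented on a finite, strictly increasing grid.

    ``log_density`` holds log f at the grid points; between points the
    density is treated as piecewise linear (trapezoid quadrature is then
    exact), which is also the natural representation for log-concave fits
    whose *log* is piecewise linear.
    """

    support: np.ndarray
    log_density: np.ndarray

    def __post_init__(self) -> None:
        self.support = np.asarray(self.support, dtype=float)
        self.log_density = np.asarray(self.log_density, dtype=float)
        if self.support.ndim != 1 or self.support.shape != self.log_density.shape:
            raise ValueError("support and log_density must be 1-D and equal length")
        if self.support.size < 2:
            raise ValueError("grid needs at least 2 points")
        if not np.all(np.diff(self.support) > 0):
            raise ValueError("support must be strictly increasing")

    # -- basic calculus ----------------------------------------------------

    @property
    def density(self) -> np.ndarray:
        return np.exp(self.log_density)

    def integral(self) -> float:
        return float(np.trapezoid(self.density, self.support))

    def normalize(self) -> "GridDensity":
        """Return a copy scaled to integrate to one (trapezoid)."""
        shift = np.max(self.log_density)
        if not np.isfinite(shift):
            raise ValueError("log_density contains no finite mass")
        z = np.trapezoid(np.exp(self.log_density - shift), self.support)
        return GridDensity(self.support, self.log_density - shift - np.log(z))

    def mean(self) -> float:
        f = self.density
        return float(np.trapezoid(self.support * f, self.support) / np.trapezoid(f, self.support))

    def variance(self) -> float:
        f = self.density
        z = np.trapezoid(f, self.support)
        m = np.trapezoid(self.support * f, self.support) / z
        return float(np.trapezoid((self.support - m) ** 2 * f, self.support) / z)

    def sd(self) -> float:
        return float(np.sqrt(self.variance()))

    def tail_prob(self, x: float) -> float:
        """P(X > x) under the piecewise-linear density (exact partial cells)."""
        s, f = self.support, self.density
        if x <= s[0]:
            return float(np.trapezoid(f, s))
        if x >= s[-1]:
            return 0.0
        i = int(np.searchsorted(s, x, side="right")) - 1
        # full cells to the right of cell i
        total = float(np.trapezoid(f[i + 1 :], s[i + 1 :])) if i + 2 <= s.size else 0.0
        # partial cell [x, s[i+1]]
        t = (x - s[i]) / (s[i + 1] - s[i])
        fx = f[i] + t * (f[i + 1] - f[i])
        total += 0.5 * (fx + f[i + 1]) * (s[i + 1] - x)
        return total

    def prob_below(self, x: float) -> float:
        """P(X <= x), integrated from the left (no cancellation for small values)."""
        s, f = self.support, self.density
        if x <= s[0]:
            return 0.0
        if x >= s[-1]:
            return float(np.trapezoid(f, s))
        i = int(np.searchsorted(s, x, side="right")) - 1
        total = float(np.trapezoid(f[: i + 1], s[: i + 1])) if i >= 1 else 0.0
        t = (x - s[i]) / (s[i + 1] - s[i])
        fx = f[i] + t * (f[i + 1] - f[i])
        total += 0.5 * (f[i] + fx) * (x - s[i])
        return total

    def cdf_grid(self) -> np.ndarray:
        """Cumulative integral at each grid point (starts at 0)."""
        f = self.density
        cells = 0.5 * (f[1:] + f[:-1]) * np.diff(self.support)
        return np.concatenate([[0.0], np.cumsum(cells)])

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        """Inverse-CDF sampling (linear interpolation of the CDF)."""
        cdf = self.cdf_grid()
        cdf = cdf / cdf[-1]
        cdf = np.maximum.accumulate(cdf)
        u = rng.uniform(0.0, 1.0, size=n)
        return np.interp(u, cdf, self.support)

    def tv_distance(self, other: "GridDensity") -> float:
        if not np.array_equal(self.support, other.support):
            raise ValueError("TV distance requires a shared support grid")
        return 0.5 * float(
            np.trapezoid(np.abs(self.density - other.density), self.support)
        )

    def is_log_concave(self, tol: float = 1e-8) -> bool:
        """Check that successive slopes of log f are non-increasing."""
        finite = np.isfinite(self.log_density)
        s, ld = self.support[finite], self.log_density[finite]
        if s.size < 3:
            return True
        slopes = np.diff(ld) / np.diff(s)
        return bool(np.all(np.diff(slopes) <= tol))

    # -- construction / IO -------------------------------------------------

    @classmethod
    def from_gaussian(cls, mu: float, variance: float, support: np.ndarray) -> "GridDensity":
        support = np.asarray(support, dtype=float)
        ld = -0.5 * np.log(2 * np.pi * variance) - 0.5 * (support - mu) ** 2 / variance
        return cls(support, ld).normalize()

    def to_csv(self, path) -> None:
        pd.DataFrame({"support": self.support, "log_density": self.log_density}).to_csv(
            path, index=False
        )

    @classmethod
    def from_csv(cls, path) -> "GridDensity":
        df = pd.read_csv(path)
        return cls(df["support"].to_numpy(), df["log_density"].to_numpy())


@dataclass(frozen=True)
class Gaussian:
    """A Gaussian prior, N(mean, variance)."""

    mean: float
    variance: float

    def __post_init__(self) -> None:
        if self.variance < 0:
            raise ValueError("variance must be >= 0")


# ---------------------------------------------------------------------------
# Feature data and priors
# ---------------------------------------------------------------------------


@dataclass
class FeatureData:
    """Observations for one feature, with corner-constrained factor coding.

    Coefficient order throughout: intercept, treatment (level 2), then
    assay levels 2..K.  The first treatment and assay levels are the
    reference (coefficients fixed at zero).
    """

    feature_id: str
    values: np.ndarray
    treatment: np.ndarray
    assay: np.ndarray
    offsets: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.treatment = np.asarray(self.treatment, dtype=int)
        self.assay = np.asarray(self.assay, dtype=int)
        self.offsets = np.asarray(self.offsets, dtype=float)
        n = self.values.size
        if not (self.treatment.size == self.assay.size == self.offsets.size == n):
            raise ValueError("values, treatment, assay, offsets must share length")
        if not np.isfinite(self.values).all():
            raise ValueError(f"feature {self.feature_id}: non-finite values")
        if not np.isfinite(self.offsets).all():
            raise ValueError(f"feature {self.feature_id}: non-finite offsets")
        if not np.isin(self.treatment, [1, 2]).all():
            raise ValueError("treatment labels must be 1 (untreated) or 2 (treated)")
        if self.assay.min() != 1:
            raise ValueError("assay labels must start at 1")

    @property
    def n_obs(self) -> int:
        return self.values.size

    @property
    def n_assays(self) -> int:
        return int(self.assay.max())

    @property
    def n_coef(self) -> int:
        return 1 + 1 + (self.n_assays - 1)

    def design_matrix(self) -> np.ndarray:
        """N x p design with columns [1, treat==2, assay==2, ..., assay==K]."""
        cols = [np.ones(self.n_obs), (self.treatment == 2).astype(float)]
        for k in range(2, self.n_assays + 1):
            cols.append((self.assay == k).astype(float))
        return np.column_stack(cols)

    def centered_values(self) -> np.ndarray:
        return self.values - self.offsets


@dataclass
class PriorSet:
    """All priors of the per-feature model.

    tau2 is the variance of the assay-effect prior (tau2 = 0 pins the assay
    coefficients at zero); (alpha1, alpha2) are the shape and rate of the
    Gamma prior on the error precision; treat_prior is a Gaussian during
    the joint parametric stage, or a GridDensity after nonparametric
    reweighting (grid priors only enter downstream via reweighting).
    """

    tau2: float
    alpha1: float
    alpha2: float
    treat_prior: Gaussian | GridDensity
    intercept_variance: float = DEFAULT_INTERCEPT_VARIANCE

    def __post_init__(self) -> None:
        if self.tau2 < 0:
            raise ValueError("tau2 must be >= 0")
        if self.alpha1 <= 0 or self.alpha2 <= 0:
            raise ValueError("Gamma shape and rate must be > 0")
        if self.intercept_variance <= 0:
            raise ValueError("intercept_variance must be > 0")
        if isinstance(self.treat_prior, GridDensity):
            if abs(self.treat_prior.integral() - 1.0) > 1e-6:
                raise ValueError("grid treat_prior must integrate to 1")

    @classmethod
    def vague(cls, variance: float = DEFAULT_INTERCEPT_VARIANCE) -> "PriorSet":
        """Vague starting priors: huge variances, near-improper precision prior."""
        return cls(
            tau2=variance,
            alpha1=1e-3,
            alpha2=1e-3,
            treat_prior=Gaussian(0.0, variance),
            intercept_variance=variance,
        )

    def _gaussian_treat(self) -> Gaussian:
        if not isinstance(self.treat_prior, Gaussian):
            raise TypeError(
                "this operation requires a Gaussian treatment prior; grid "
                "priors enter only via posterior reweighting"
            )
        return self.treat_prior

    def coef_prior_mean(self, n_coef: int) -> np.ndarray:
        tp = self._gaussian_treat()
        m = np.zeros(n_coef)
        m[1] = tp.mean
        return m

    def coef_prior_variance(self, n_coef: int) -> np.ndarray:
        tp = self._gaussian_treat()
        v = np.empty(n_coef)
        v[0] = self.intercept_variance
        v[1] = tp.variance
        v[2:] = self.tau2
        return v


@dataclass
class ConditionalPosterior:
    """Gaussian posterior of the coefficient vector given sigma^2."""

    mean: np.ndarray
    covariance: np.ndarray
    sigma2: float
    log_marginal_likelihood: float


@dataclass
class MarginalPosterior:
    """Posterior with the error variance marginalized out by quadrature.

    The treatment-effect posterior is a mixture of the conditional
    Gaussians; ``treat_density`` materializes it on a beta grid.
    ``precision_grid``/``precision_weights`` give the discrete posterior of
    sigma^2 on the quadrature grid.
    """

    feature_id: str
    treat_density: GridDensity
    treat_moments: tuple[float, float]
    assay_moments: list[tuple[float, float]]
    coef_mean: np.ndarray
    coef_cov: np.ndarray
    precision_grid: np.ndarray  # sigma^2 values
    precision_weights: np.ndarray
    log_marginal_likelihood: float

    @property
    def sigma2_mean(self) -> float:
        return float(np.sum(self.precision_grid * self.precision_weights))

    def treat_prob_positive(self, reference: float = 0.0) -> float:
        return self.treat_density.tail_prob(reference)


# ---------------------------------------------------------------------------
# Design construction
# ---------------------------------------------------------------------------


def build_design(
    feature_table: pd.DataFrame,
    feature_id: str | None = None,
    allow_replicates: bool = False,
) -> FeatureData:
    """Validate one feature's rows and return corner-coded :class:`FeatureData`.

    The table needs columns ``feature_id, treatment, assay, value`` and an
    optional ``offset`` (missing -> all zero).  Every (treatment, assay)
    cell of the 2 x K design must be present; duplicated cells are a
    structural error unless ``allow_replicates`` (used for control fits
    which pool many wells per cell).
    """
    df = feature_table
    required = {"feature_id", "treatment", "assay", "value"}
    missing_cols = required - set(df.columns)
    if missing_cols:
        raise ValueError(f"missing columns: {sorted(missing_cols)}")
    ids = df["feature_id"].unique()
    if feature_id is None:
        if len(ids) != 1:
            raise ValueError("feature_table must contain exactly one feature_id")
        feature_id = str(ids[0])
    else:
        df = df[df["feature_id"] == feature_id]
        if df.empty:
            raise ValueError(f"feature {feature_id!r} not found")

    values = pd.to_numeric(df["value"], errors="coerce").to_numpy(dtype=float)
    if np.isnan(values).any():
        bad = df.loc[np.isnan(values), "value"].tolist()
        raise ValueError(f"non-numeric values for feature {feature_id!r}: {bad}")
    treatment = df["treatment"].to_numpy(dtype=int)
    assay = df["assay"].to_numpy(dtype=int)
    offsets = (
        pd.to_numeric(df["offset"]).to_numpy(dtype=float)
        if "offset" in df.columns
        else np.zeros(len(df))
    )

    n_assays = int(assay.max()) if assay.size else 0
    for j in (1, 2):
        for k in range(1, n_assays + 1):
            count = int(np.sum((treatment == j) & (assay == k)))
            if count == 0:
                raise ValueError(
                    f"feature {feature_id!r}: missing design cell "
                    f"(treatment={j}, assay={k})"
                )
            if count > 1 and not allow_replicates:
                raise ValueError(
                    f"feature {feature_id!r}: duplicated design cell "
                    f"(treatment={j}, assay={k})"
                )
    return FeatureData(str(feature_id), values, treatment, assay, offsets)


# ---------------------------------------------------------------------------
# Conditional (sigma^2 fixed) conjugate posterior
# ---------------------------------------------------------------------------


def _split_free_fixed(prior_var: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    free = prior_var > 0
    return free, ~free


def conditional_beta_posterior(
    feature: FeatureData, priors: PriorSet, sigma2: float
) -> ConditionalPosterior:
    """Exact Gaussian posterior of the coefficients given the error variance.

    Coordinates with zero prior variance (e.g. tau2 = 0) are treated as
    fixed at their prior mean — a degenerate prior, not an error.  The
    returned ``log_marginal_likelihood`` is log p(y | sigma2), used as the
    quadrature weight upstream.
    """
    if sigma2 <= 0:
        raise ValueError("sigma2 must be > 0")
    X = feature.design_matrix()
    p = feature.n_coef
    m0 = priors.coef_prior_mean(p)
    v0 = priors.coef_prior_variance(p)
    free, fixed = _split_free_fixed(v0)

    r = feature.centered_values() - X[:, fixed] @ m0[fixed]
    Xf = X[:, free]
    pf = int(free.sum())

    mean = m0.copy()
    cov = np.zeros((p, p))
    if pf:
        prec = Xf.T @ Xf / sigma2 + np.diag(1.0 / v0[free])
        try:
            cho = linalg.cho_factor(prec)
        except linalg.LinAlgError as exc:  # pragma: no cover - pathological
            raise linalg.LinAlgError(f"singular system for {feature.feature_id}") from exc
        rhs = Xf.T @ r / sigma2 + m0[free] / v0[free]
        mean_f = linalg.cho_solve(cho, rhs)
        cov_f = linalg.cho_solve(cho, np.eye(pf))
        cov_f = 0.5 * (cov_f + cov_f.T)
        mean[free] = mean_f
        cov[np.ix_(free, free)] = cov_f
        # log p(y|sigma2): y - (fixed part) ~ N(Xf m0f, sigma2 I + Xf V0 Xf')
        V = sigma2 * np.eye(feature.n_obs) + (Xf * v0[free]) @ Xf.T
        cho_v = linalg.cho_factor(V)
        d = r - Xf @ m0[free]
        quad = d @ linalg.cho_solve(cho_v, d)
        logdet = 2.0 * np.sum(np.log(np.diag(cho_v[0])))
        lml = -0.5 * (feature.n_obs * np.log(2 * np.pi) + logdet + quad)
    else:
        lml = stats.norm.logpdf(r, scale=np.sqrt(sigma2)).sum()
    return ConditionalPosterior(mean, cov, float(sigma2), float(lml))


# ---------------------------------------------------------------------------
# Quadrature over sigma^2
# ---------------------------------------------------------------------------


def sigma2_quadrature_grid(
    alpha1: float,
    alpha2: float,
    size: int = DEFAULT_SIGMA2_GRID_SIZE,
) -> tuple[np.ndarray, np.ndarray]:
    """Log-spaced sigma^2 grid spanning the Gamma(alpha1, alpha2) precision prior.

    Returns ``(sigma2_values, log_prior_weights)`` where the weights are the
    (normalized) trapezoid masses of the precision prior on the grid.
    """
    lam_lo = stats.gamma.ppf(_GAMMA_QUANTILE_EPS, alpha1, scale=1.0 / alpha2)
    lam_hi = stats.gamma.ppf(1.0 - _GAMMA_QUANTILE_EPS, alpha1, scale=1.0 / alpha2)
    lam_lo = max(lam_lo, _PRECISION_CLIP[0])
    lam_hi = min(max(lam_hi, lam_lo * 10), _PRECISION_CLIP[1])
    lam = np.logspace(np.log10(lam_lo), np.log10(lam_hi), size)
    logpdf = stats.gamma.logpdf(lam, alpha1, scale=1.0 / alpha2)
    # trapezoid cell widths (midpoint spacing)
    edges = np.empty(size + 1)
    edges[1:-1] = 0.5 * (lam[1:] + lam[:-1])
    edges[0], edges[-1] = lam[0], lam[-1]
    widths = np.diff(edges)
    logw = logpdf + np.log(widths)
    logw -= logsumexp(logw)
    return 1.0 / lam, logw


def _default_beta_grid(
    means: np.ndarray, sds: np.ndarray, size: int = DEFAULT_BETA_GRID_SIZE
) -> np.ndarray:
    lo = np.min(means - 8.0 * sds)
    hi = np.max(means + 8.0 * sds)
    return np.linspace(lo, hi, size)


def _mixture_density(
    grid: np.ndarray, means: np.ndarray, sds: np.ndarray, log_weights: np.ndarray
) -> GridDensity:
    z = (grid[None, :] - means[:, None]) / sds[:, None]
    logpdf = -0.5 * z**2 - np.log(sds[:, None]) - 0.5 * np.log(2 * np.pi)
    ld = logsumexp(logpdf + log_weights[:, None], axis=0)
    return GridDensity(grid, ld).normalize()


def marginal_posterior(
    feature: FeatureData,
    priors: PriorSet,
    sigma2_grid: np.ndarray | None = None,
    beta_grid: np.ndarray | None = None,
) -> MarginalPosterior:
    """Marginal posterior over all coefficients, mixing over the sigma^2 grid.

    The mixture weight of grid point g is proportional to the precision
    prior mass at g times the conditional marginal likelihood p(y|sigma2_g).
    """
    if sigma2_grid is None:
        sigma2, log_prior_w = sigma2_quadrature_grid(priors.alpha1, priors.alpha2)
    else:
        sigma2 = np.asarray(sigma2_grid, dtype=float)
        lam = 1.0 / sigma2
        order = np.argsort(lam)
        lam_sorted = lam[order]
        logpdf = stats.gamma.logpdf(lam_sorted, priors.alpha1, scale=1.0 / priors.alpha2)
        edges = np.empty(lam_sorted.size + 1)
        edges[1:-1] = 0.5 * (lam_sorted[1:] + lam_sorted[:-1])
        edges[0], edges[-1] = lam_sorted[0], lam_sorted[-1]
        logw_sorted = logpdf + np.log(np.diff(edges))
        log_prior_w = np.empty_like(logw_sorted)
        log_prior_w[order] = logw_sorted - logsumexp(logw_sorted)

    conds = [conditional_beta_posterior(feature, priors, s2) for s2 in sigma2]
    clml = np.array([c.log_marginal_likelihood for c in conds])
    logw = log_prior_w + clml
    total = logsumexp(logw)
    if not np.isfinite(total):
        raise FloatingPointError(
            "quadrature weights underflowed on the whole sigma^2 grid; "
            "widen the grid (check alpha1/alpha2)"
        )
    logw -= total
    w = np.exp(logw)

    p = feature.n_coef
    means = np.stack([c.mean for c in conds])  # (G, p)
    covs = np.stack([c.covariance for c in conds])  # (G, p, p)
    coef_mean = w @ means
    dev = means - coef_mean
    coef_cov = np.einsum("g,gij->ij", w, covs) + np.einsum(
        "g,gi,gj->ij", w, dev, dev
    )

    t_means = means[:, 1]
    t_sds = np.sqrt(np.maximum(covs[:, 1, 1], 1e-300))
    if beta_grid is None:
        beta_grid = _default_beta_grid(t_means, t_sds)
    treat_density = _mixture_density(beta_grid, t_means, t_sds, logw)

    assay_moments = []
    for k in range(2, p):
        mk = float(w @ means[:, k])
        vk = float(w @ (covs[:, k, k] + means[:, k] ** 2) - mk**2)
        assay_moments.append((mk, max(vk, 0.0)))
    treat_m = float(coef_mean[1])
    treat_v = float(max(coef_cov[1, 1], 0.0))

    return MarginalPosterior(
        feature_id=feature.feature_id,
        treat_density=treat_density,
        treat_moments=(treat_m, treat_v),
        assay_moments=assay_moments,
        coef_mean=coef_mean,
        coef_cov=0.5 * (coef_cov + coef_cov.T),
        precision_grid=sigma2,
        precision_weights=w,
        log_marginal_likelihood=float(total),
    )


# ---------------------------------------------------------------------------
# Batch engine for identically designed features
# ---------------------------------------------------------------------------


@dataclass
class BatchPosteriors:
    """Marginal posteriors of many features sharing one design matrix.

    Conditional covariances depend on sigma^2 only, not on the data, so the
    per-sigma^2 linear algebra is done once and reused across all features.
    Used by the iterative empirical-Bayes loop, where only moments and the
    precision mixture weights are needed per iteration.
    """

    feature_ids: list[str]
    design: np.ndarray
    sigma2_grid: np.ndarray
    weights: np.ndarray  # (n_features, G)
    cond_means: np.ndarray  # (G, p, n_features)
    cond_covs: np.ndarray  # (G, p, p)
    log_marginal_likelihood: np.ndarray  # (n_features,)

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    @property
    def n_coef(self) -> int:
        return self.design.shape[1]

    def treat_component_params(self) -> tuple[np.ndarray, np.ndarray]:
        """Per-feature component means (n, G) and shared sds (G,) for beta_treat."""
        return self.cond_means[:, 1, :].T, np.sqrt(np.maximum(self.cond_covs[:, 1, 1], 1e-300))

    def treat_moments(self) -> tuple[np.ndarray, np.ndarray]:
        m_comp, s_comp = self.treat_component_params()
        m = np.sum(self.weights * m_comp, axis=1)
        v = np.sum(self.weights * (s_comp[None, :] ** 2 + m_comp**2), axis=1) - m**2
        return m, np.maximum(v, 0.0)

    def assay_moments(self) -> tuple[np.ndarray, np.ndarray]:
        """Means and variances (n_features, K-1) of the free assay coefficients."""
        p = self.n_coef
        ms, vs = [], []
        for k in range(2, p):
            mk_comp = self.cond_means[:, k, :].T  # (n, G)
            vk_comp = self.cond_covs[:, k, k]  # (G,)
            mk = np.sum(self.weights * mk_comp, axis=1)
            vk = np.sum(self.weights * (vk_comp[None, :] + mk_comp**2), axis=1) - mk**2
            ms.append(mk)
            vs.append(np.maximum(vk, 0.0))
        return np.column_stack(ms), np.column_stack(vs)

    def sigma2_means(self) -> np.ndarray:
        return self.weights @ self.sigma2_grid

    def coef_mean_cov(self, i: int) -> tuple[np.ndarray, np.ndarray]:
        w = self.weights[i]
        means = self.cond_means[:, :, i]  # (G, p)
        coef_mean = w @ means
        dev = means - coef_mean
        cov = np.einsum("g,gij->ij", w, self.cond_covs) + np.einsum(
            "g,gi,gj->ij", w, dev, dev
        )
        return coef_mean, 0.5 * (cov + cov.T)

    def shared_beta_grid(self, size: int = 1024) -> np.ndarray:
        m_comp, s_comp = self.treat_component_params()
        lo = float(np.min(m_comp - 8.0 * s_comp[None, :]))
        hi = float(np.max(m_comp + 8.0 * s_comp[None, :]))
        return np.linspace(lo, hi, size)

    def treat_densities(self, beta_grid: np.ndarray) -> list[GridDensity]:
        m_comp, s_comp = self.treat_component_params()
        out = []
        logw_all = np.log(np.maximum(self.weights, 1e-300))
        for i in range(self.n_features):
            out.append(
                _mixture_density(beta_grid, m_comp[i], s_comp, logw_all[i])
            )
        return out

    def sample_precisions(self, rng: np.random.Generator, draws_per_feature: int) -> np.ndarray:
        """Pooled draws of sigma^-2 from each feature's grid posterior."""
        lam = 1.0 / self.sigma2_grid
        n, G = self.weights.shape
        cum = np.cumsum(self.weights, axis=1)
        cum /= cum[:, -1][:, None]
        u = rng.uniform(size=(n, draws_per_feature))
        idx = np.empty((n, draws_per_feature), dtype=int)
        for i in range(n):
            idx[i] = np.searchsorted(cum[i], u[i])
        return lam[np.clip(idx, 0, G - 1)].ravel()

    def to_marginal_posteriors(self, beta_grid: np.ndarray | None = None) -> list[MarginalPosterior]:
        if beta_grid is None:
            beta_grid = self.shared_beta_grid()
        densities = self.treat_densities(beta_grid)
        tm, tv = self.treat_moments()
        am, av = self.assay_moments()
        out = []
        for i, fid in enumerate(self.feature_ids):
            coef_mean, coef_cov = self.coef_mean_cov(i)
            out.append(
                MarginalPosterior(
                    feature_id=fid,
                    treat_density=densities[i],
                    treat_moments=(float(tm[i]), float(tv[i])),
                    assay_moments=[(float(am[i, k]), float(av[i, k])) for k in range(am.shape[1])],
                    coef_mean=coef_mean,
                    coef_cov=coef_cov,
                    precision_grid=self.sigma2_grid,
                    precision_weights=self.weights[i],
                    log_marginal_likelihood=float(self.log_marginal_likelihood[i]),
                )
            )
        return out


def _check_shared_design(features: Sequence[FeatureData]) -> np.ndarray:
    X0 = features[0].design_matrix()
    for f in features[1:]:
        if f.n_obs != features[0].n_obs or not np.array_equal(f.design_matrix(), X0):
            raise ValueError("batch path requires an identical design across features")
    return X0


def _batch_conditionals(
    X0: np.ndarray,
    R: np.ndarray,
    priors: PriorSet,
    sigma2: np.ndarray,
    want_moments: bool = True,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Conditional posterior moments and log p(y|sigma2) for a value grid.

    ``R`` is the (N, n_features) matrix of offset-centered responses.
    Returns (cond_means (G,p,n), cond_covs (G,p,p), clml (G,n)); the
    moment arrays are empty when ``want_moments`` is False.
    """
    N, n = R.shape
    p = X0.shape[1]
    G = sigma2.size
    m0 = priors.coef_prior_mean(p)
    v0 = priors.coef_prior_variance(p)
    free, fixed = _split_free_fixed(v0)
    Xf = X0[:, free]
    R = R - (X0[:, fixed] @ m0[fixed])[:, None]

    cond_means = np.zeros((G, p, n) if want_moments else (0, p, n))
    cond_covs = np.zeros((G, p, p) if want_moments else (0, p, p))
    clml = np.empty((G, n))
    if free.any():
        XtX = Xf.T @ Xf
        XtR = Xf.T @ R  # (pf, n)
        prior_prec = np.diag(1.0 / v0[free])
        prior_term = (m0[free] / v0[free])[:, None]
        D = R - (Xf @ m0[free])[:, None]
        for g, s2 in enumerate(sigma2):
            if want_moments:
                prec = XtX / s2 + prior_prec
                cho = linalg.cho_factor(prec)
                cov_f = linalg.cho_solve(cho, np.eye(int(free.sum())))
                means_f = linalg.cho_solve(cho, XtR / s2 + prior_term)
                cond_covs[g][np.ix_(free, free)] = 0.5 * (cov_f + cov_f.T)
                M = np.zeros((p, n))
                M[free] = means_f
                M[fixed] = m0[fixed][:, None]
                cond_means[g] = M
            V = s2 * np.eye(N) + (Xf * v0[free]) @ Xf.T
            cho_v = linalg.cho_factor(V)
            quad = np.sum(D * linalg.cho_solve(cho_v, D), axis=0)
            logdet = 2.0 * np.sum(np.log(np.diag(cho_v[0])))
            clml[g] = -0.5 * (N * np.log(2 * np.pi) + logdet + quad)
    else:  # all coefficients fixed
        for g, s2 in enumerate(sigma2):
            if want_moments:
                cond_means[g] = m0[:, None]
            clml[g] = stats.norm.logpdf(R, scale=np.sqrt(s2)).sum(axis=0)
    return cond_means, cond_covs, clml


def conditional_lml_batch(
    features: Sequence[FeatureData], priors: PriorSet, sigma2_values: np.ndarray
) -> np.ndarray:
    """log p(y_i | sigma2_g) for every feature and sigma2 value, (G, n).

    Independent of the precision prior — used to re-estimate (alpha1,
    alpha2) by direct marginal maximum likelihood.
    """
    X0 = _check_shared_design(features)
    R = np.stack([f.centered_values() for f in features], axis=1)
    _, _, clml = _batch_conditionals(
        X0, R, priors, np.asarray(sigma2_values, dtype=float), want_moments=False
    )
    return clml


def marginal_posteriors_batch(
    features: Sequence[FeatureData],
    priors: PriorSet,
    sigma2_grid: np.ndarray | None = None,
) -> BatchPosteriors:
    """Vectorized :func:`marginal_posterior` for features sharing one design."""
    X0 = _check_shared_design(features)
    if sigma2_grid is None:
        sigma2, log_prior_w = sigma2_quadrature_grid(priors.alpha1, priors.alpha2)
    else:
        raise NotImplementedError("custom grids go through marginal_posterior")
    R = np.stack([f.centered_values() for f in features], axis=1)  # (N, n)
    cond_means, cond_covs, clml = _batch_conditionals(X0, R, priors, sigma2)

    logw = log_prior_w[:, None] + clml  # (G, n)
    totals = logsumexp(logw, axis=0)
    if not np.isfinite(totals).all():
        raise FloatingPointError("quadrature weights underflowed; widen the sigma^2 grid")
    weights = np.exp(logw - totals).T  # (n, G)
    return BatchPosteriors(
        feature_ids=[f.feature_id for f in features],
        design=X0,
        sigma2_grid=sigma2,
        weights=weights,
        cond_means=cond_means,
        cond_covs=cond_covs,
        log_marginal_likelihood=totals,
    )
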