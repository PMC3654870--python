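"""Nonparametric, log-concave prior for the treatment effect.

The treatment-effect prior F_NP is estimated by iterated pooling: draw a
large sample from the equal-weight mixture of the per-feature posteriors,
fit the log-concave maximum-likelihood density to it (log-concavity
stabilizes the tails), and reweight every posterior from the old prior to
the new one via

    pi*(beta | Y)  propto  pi(beta | Y) * pi*(beta) / pi(beta),

repeating until the prior stops moving in total variation.

The log-concave MLE has a piecewise-linear log-density with knots at the
(binned) sample points; it is computed here as a convex program — maximize
sum_j w_j phi_j - integral exp(phi) over concave piecewise-linear phi —
with analytic gradient and sparse tridiagonal Hessian, followed by an
exact pool-adjacent-violators projection of the slopes so the concavity
certificate holds to machine precision.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, sparse, stats
from sklearn.isotonic import IsotonicRegression

from .model_core import GridDensity

__all__ = [
    "GridDensity",
    "logconcave_mle",
    "reweight_posterior",
    "np_prior_iterate",
    "NPPriorResult",
    "grid_log_likelihood",
]

_MAX_KNOTS = 201


# ---------------------------------------------------------------------------
# Segment integrals of exp(piecewise-linear phi) and their derivatives
# ---------------------------------------------------------------------------
# For a segment [x0, x1] with phi(x0)=a, phi(x1)=b, h=x1-x0, d=b-a:
#   I = h e^a g(d),       g(d)  = (e^d - 1)/d
#   dI/da = h e^a (g-g'), dI/db = h e^a g'
# with g'(d) = (e^d (d-1) + 1)/d^2, g''(d) = (e^d (d^2-2d+2) - 2)/d^3.
# Taylor series keep the small-|d| case stable.


def _g_funcs(d: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    d = np.asarray(d, dtype=float)
    small = np.abs(d) < 1e-4
    ds = np.where(small, 0.0, d)
    with np.errstate(invalid="ignore"):
        ed = np.exp(ds)
        g = (ed - 1.0) / ds
        g1 = (ed * (ds - 1.0) + 1.0) / ds**2
        g2 = (ed * (ds**2 - 2.0 * ds + 2.0) - 2.0) / ds**3
    t = d
    g_s = 1.0 + t / 2 + t**2 / 6 + t**3 / 24
    g1_s = 0.5 + t / 3 + t**2 / 8 + t**3 / 30
    g2_s = 1.0 / 3 + t / 4 + t**2 / 10 + t**3 / 36
    return (
        np.where(small, g_s, g),
        np.where(small, g1_s, g1),
        np.where(small, g2_s, g2),
    )


def _objective(phi: np.ndarray, knots: np.ndarray, w: np.ndarray):
    h = np.diff(knots)
    a, b = phi[:-1], phi[1:]
    d = b - a
    g, g1, _ = _g_funcs(d)
    with np.errstate(over="ignore", invalid="ignore"):
        ea = np.exp(a)
        seg = h * ea * g
        f = -float(w @ phi) + float(seg.sum())
        grad = -w.copy()
        grad[:-1] += h * ea * (g - g1)
        grad[1:] += h * ea * g1
    if not np.isfinite(f):
        f = 1e300
    grad = np.nan_to_num(grad, nan=0.0, posinf=1e300, neginf=-1e300)
    return f, grad


def _hessian(phi: np.ndarray, knots: np.ndarray, w: np.ndarray) -> sparse.csr_matrix:
    h = np.diff(knots)
    a, b = phi[:-1], phi[1:]
    d = b - a
    g, g1, g2 = _g_funcs(d)
    with np.errstate(over="ignore", invalid="ignore"):
        ea = np.exp(a)
        haa = np.nan_to_num(h * ea * (g - 2 * g1 + g2), posinf=1e300)
        hab = np.nan_to_num(h * ea * (g1 - g2), posinf=1e300)
        hbb = np.nan_to_num(h * ea * g2, posinf=1e300)
    m = phi.size
    diag = np.zeros(m)
    diag[:-1] += haa
    diag[1:] += hbb
    return sparse.diags([hab, diag, hab], offsets=[-1, 0, 1], format="csr")


def _bin_samples(x: np.ndarray, max_knots: int) -> tuple[np.ndarray, np.ndarray]:
    """Reduce samples to weighted quantile knots (weights sum to 1)."""
    x = np.sort(np.asarray(x, dtype=float))
    if x.size <= max_knots:
        knots, counts = np.unique(x, return_counts=True)
        return knots, counts / counts.sum()
    q = np.linspace(0.0, 1.0, max_knots)
    knots = np.quantile(x, q)
    w = np.full(max_knots, 1.0 / (max_knots - 1))
    w[0] = w[-1] = 0.5 / (max_knots - 1)
    knots, idx = np.unique(knots, return_index=True)
    if knots.size < max_knots:  # ties collapsed: accumulate their weight
        w_full = np.full(max_knots, 1.0 / (max_knots - 1))
        w_full[0] = w_full[-1] = 0.5 / (max_knots - 1)
        groups = np.searchsorted(knots, np.quantile(x, q))
        w = np.bincount(groups, weights=w_full, minlength=knots.size)
    return knots, w / w.sum()


def _project_concave(knots: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """Project phi onto exactly concave piecewise-linear functions (PAV on slopes)."""
    h = np.diff(knots)
    slopes = np.diff(phi) / h
    iso = IsotonicRegression(increasing=False)
    slopes_proj = iso.fit_transform(np.arange(slopes.size), slopes, sample_weight=h)
    out = np.empty_like(phi)
    out[0] = phi[0]
    out[1:] = phi[0] + np.cumsum(slopes_proj * h)
    return out


def logconcave_mle(
    samples: np.ndarray,
    grid: np.ndarray,
    max_knots: int = _MAX_KNOTS,
) -> GridDensity:
    """Log-concave maximum-likelihood density, evaluated on ``grid``.

    Samples beyond ``max_knots`` distinct values are reduced to weighted
    quantile knots first.  Outside the knot range the log-density is
    extrapolated linearly with the edge slopes (licensed by log-concavity)
    and the result is renormalized on the grid.
    """
    x = np.asarray(samples, dtype=float).ravel()
    if np.unique(x).size < 10:
        raise ValueError("need at least 10 distinct samples for the log-concave MLE")
    knots, w = _bin_samples(x, max_knots)
    m = knots.size

    # Feasible start: log-density of a moment-matched Gaussian (strictly concave)
    mu = float(w @ knots)
    sd = float(np.sqrt(max(w @ (knots - mu) ** 2, 1e-12)))
    phi0 = stats.norm.logpdf(knots, loc=mu, scale=sd)

    # concavity: slope_j - slope_{j+1} >= 0, linear in phi
    h = np.diff(knots)
    rows, cols, vals = [], [], []
    for j in range(m - 2):
        rows += [j, j, j]
        cols += [j, j + 1, j + 2]
        vals += [-1.0 / h[j], 1.0 / h[j] + 1.0 / h[j + 1], -1.0 / h[j + 1]]
    A = sparse.csr_matrix((vals, (rows, cols)), shape=(m - 2, m))
    constraint = optimize.LinearConstraint(A, 0.0, np.inf)

    res = optimize.minimize(
        _objective,
        phi0,
        args=(knots, w),
        jac=True,
        hess=lambda phi, *a: _hessian(phi, knots, w),
        method="trust-constr",
        constraints=[constraint],
        options={"gtol": 1e-10, "xtol": 1e-12, "maxiter": 1000},
    )
    phi = _project_concave(knots, res.x)
    # renormalize exactly over the knot range
    g, _, _ = _g_funcs(np.diff(phi))
    z = float(np.sum(np.diff(knots) * np.exp(phi[:-1]) * g))
    phi -= np.log(z)

    grid = np.asarray(grid, dtype=float)
    ld = np.interp(grid, knots, phi)
    slopes = np.diff(phi) / np.diff(knots)
    s_left = max(slopes[0], 1e-8)
    s_right = min(slopes[-1], -1e-8)
    left = grid < knots[0]
    right = grid > knots[-1]
    ld[left] = phi[0] + s_left * (grid[left] - knots[0])
    ld[right] = phi[-1] + s_right * (grid[right] - knots[-1])
    return GridDensity(grid, ld).normalize()


def grid_log_likelihood(density: GridDensity, samples: np.ndarray) -> float:
    """Sum of log f at the samples (linear interpolation of log f)."""
    return float(
        np.sum(np.interp(samples, density.support, density.log_density))
    )


# ---------------------------------------------------------------------------
# Posterior reweighting between priors
# ---------------------------------------------------------------------------


def reweight_posterior(
    post: GridDensity, old_prior: GridDensity, new_prior: GridDensity
) -> GridDensity:
    """Move a posterior from ``old_prior`` to ``new_prior`` on a shared grid.

    Pointwise product-ratio identity, renormalized.  The old prior must be
    positive wherever the posterior carries mass.
    """
    if not (
        np.array_equal(post.support, old_prior.support)
        and np.array_equal(post.support, new_prior.support)
    ):
        raise ValueError("post, old_prior and new_prior must share the support grid")
    if np.array_equal(old_prior.log_density, new_prior.log_density):
        return GridDensity(post.support.copy(), post.log_density.copy())
    rel_post = np.exp(post.log_density - np.max(post.log_density))
    dead_old = ~np.isfinite(old_prior.log_density) | (old_prior.log_density < -700)
    if np.any(dead_old & (rel_post > 1e-10)):
        raise ValueError("old prior has zero density where the posterior has mass")
    with np.errstate(invalid="ignore"):
        ld = post.log_density + new_prior.log_density - old_prior.log_density
    ld[dead_old] = -np.inf
    ld = np.where(np.isfinite(ld), ld, -np.inf)
    finite_max = np.max(ld[np.isfinite(ld)])
    ld = np.maximum(ld, finite_max - 745.0)  # keep exp() finite
    return GridDensity(post.support, ld).normalize()


# ---------------------------------------------------------------------------
# Marginal iterative procedure
# ---------------------------------------------------------------------------


@dataclass
class NPPriorResult:
    prior: GridDensity
    posteriors: list[GridDensity]
    tv_trace: list[float]
    converged: bool


def np_prior_iterate(
    posteriors: list[GridDensity],
    current_prior: GridDensity,
    max_iter: int = 10,
    tol: float = 1e-3,
    draws_per_feature: int = 100,
    seed: int | np.random.Generator | None = 0,
) -> NPPriorResult:
    """Alternate log-concave prior fitting and posterior reweighting.

    ``posteriors`` are the per-feature treatment-effect posteriors computed
    under ``current_prior`` (the parametric prior from the joint stage).
    Each iteration pools ``draws_per_feature`` draws per feature from the
    equal-weight mixture of current posteriors, fits the log-concave MLE on
    the shared grid, and reweights the original posteriors to the new
    prior (reweighting composes, so going through the original posterior
    each time avoids accumulating grid error).  Stops when the total
    variation between successive priors drops below ``tol``.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    grid = current_prior.support
    for p in posteriors:
        if not np.array_equal(p.support, grid):
            raise ValueError("all posteriors must share the prior's support grid")
    orig_posteriors = posteriors
    orig_prior = current_prior
    current = current_prior
    current_posts = posteriors
    tv_trace: list[float] = []
    converged = False
    for _ in range(max_iter):
        pooled = np.concatenate(
            [p.sample(rng, draws_per_feature) for p in current_posts]
        )
        new_prior = logconcave_mle(pooled, grid)
        tv = new_prior.tv_distance(current)
        tv_trace.append(tv)
        current_posts = [
            reweight_posterior(p, orig_prior, new_prior) for p in orig_posteriors
        ]
        current = new_prior
        if tv < tol:
            converged = True
            break
    return NPPriorResult(current, current_posts, tv_trace, converged)
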