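"""One-sided posterior inference: p0, BFDR, effective parameters, eqN.

In the positive-control comparison the quantity of interest is whether a
feature's treatment effect exceeds the control's, i.e. beta_treat > 0, so
all tests are one-sided.  The posterior tail probability
``p0 = 1 - P(beta_treat > 0 | Y)`` plays the role of a local false
discovery rate; averaging it over a selection ``{p0 <= t}`` gives the
Bayesian FDR.  Two-sided selection would be badly biased here because most
features are *weaker* than the positive control.

The effective number of parameters p* (pD) is the mean posterior deviance
minus the deviance at the posterior mean, with sigma^2 plugged in at its
posterior mean (sigma is a hyperparameter of the hierarchy and does not
contribute).  For the Gaussian model this reduces to
``p* = tr(X'X Cov(beta | Y)) / sigma2_hat``; with flat priors it equals
the number of free coefficients.  ``eqN = N / p*`` is the equivalent
number of replicates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model_core import FeatureData, GridDensity, MarginalPosterior, PriorSet

__all__ = [
    "InferenceRecord",
    "BfdrResult",
    "EqnResult",
    "p0",
    "bfdr",
    "relative_test",
    "effective_params",
    "eqn",
    "results_table",
]


@dataclass
class InferenceRecord:
    feature_id: str
    post_mean: float  # shrunken beta_treat estimate, log2 scale
    p0: float
    bfdr_at_threshold: float | None
    significant: bool


@dataclass
class BfdrResult:
    """Selection at a p0 threshold; ``value`` is None when nothing is selected
    (an explicit missing marker — never 0, which would fake certainty)."""

    selected: np.ndarray
    value: float | None

    @property
    def n_selected(self) -> int:
        return int(self.selected.sum())


@dataclass
class EqnResult:
    scenario: str
    p_star: float
    eqn: float
    N: int

    def __post_init__(self) -> None:
        assert abs(self.eqn - self.N / self.p_star) < 1e-12


def p0(post: GridDensity) -> float:
    """1 - P(beta > 0 | Y) from a normalized grid density."""
    total = post.integral()
    if abs(total - 1.0) > 1e-4:
        raise ValueError(f"density is not normalized (integral = {total:.6f})")
    return float(np.clip(post.prob_below(0.0) / total, 0.0, 1.0))


def bfdr(p0_values: np.ndarray, threshold: float) -> BfdrResult:
    """Select features with p0 <= t; BFDR is the mean selected p0."""
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must be in (0, 1)")
    p = np.asarray(p0_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p0 values must lie in [0, 1]")
    selected = p <= threshold
    value = float(p[selected].mean()) if selected.any() else None
    return BfdrResult(selected, value)


def relative_test(posteriors: list[GridDensity], reference: float) -> np.ndarray:
    """Per-feature 1 - P(beta > reference | Y), e.g. with the prior mean as
    reference; the values feed :func:`bfdr` unchanged."""
    if not np.isfinite(reference):
        raise ValueError("reference must be finite")
    out = np.empty(len(posteriors))
    for i, post in enumerate(posteriors):
        total = post.integral()
        out[i] = np.clip(post.prob_below(reference) / total, 0.0, 1.0)
    return out


def effective_params(
    feature: FeatureData, priors: PriorSet, posterior: MarginalPosterior
) -> float:
    """Effective number of parameters pD, with sigma^2 fixed at its
    posterior mean.

    With the error variance plugged in (it is a hyperparameter of the
    hierarchy and does not count toward p*), the mean posterior deviance
    minus the deviance at the posterior mean reduces to
    ``tr(X'X Cov(beta | Y, sigma2_hat)) / sigma2_hat`` — the ridge
    effective degrees of freedom.  Under flat coefficient priors this is
    exactly the number of free coefficients.
    """
    from .model_core import conditional_beta_posterior

    X = feature.design_matrix()
    sigma2_hat = posterior.sigma2_mean
    cond = conditional_beta_posterior(feature, priors, sigma2_hat)
    p_star = float(np.trace(X.T @ X @ cond.covariance) / sigma2_hat)
    if not np.isfinite(p_star):
        raise FloatingPointError("non-finite deviance in pD computation")
    return p_star


def eqn(p_star: float, N: int) -> float:
    """Equivalent number of replicates, N / p*."""
    if p_star <= 0:
        raise ValueError("p_star must be > 0")
    return N / p_star


def results_table(
    posteriors: list[MarginalPosterior],
    threshold: float = 0.1,
    reference: float = 0.0,
    densities: list[GridDensity] | None = None,
) -> pd.DataFrame:
    """Per-feature inference table (stable column order).

    Columns: feature_id, post_mean, p0, bfdr, significant, fold_change
    (2^post_mean; values are log2 scale throughout).  When ``densities``
    is given (e.g. posteriors reweighted to the nonparametric prior) they
    replace each feature's treatment-effect posterior.
    """
    if densities is None:
        densities = [p.treat_density for p in posteriors]
        post_means = [float(p.treat_moments[0]) for p in posteriors]
    else:
        if len(densities) != len(posteriors):
            raise ValueError("densities must match posteriors one-to-one")
        post_means = [d.mean() for d in densities]
    p0_vals = relative_test(densities, reference)
    sel = bfdr(p0_vals, threshold)
    records = []
    for i, post in enumerate(posteriors):
        records.append(
            InferenceRecord(
                feature_id=post.feature_id,
                post_mean=post_means[i],
                p0=float(p0_vals[i]),
                bfdr_at_threshold=sel.value,
                significant=bool(sel.selected[i]),
            )
        )
    df = pd.DataFrame(
        {
            "feature_id": [r.feature_id for r in records],
            "post_mean": [r.post_mean for r in records],
            "p0": [r.p0 for r in records],
            "bfdr": [np.nan if r.bfdr_at_threshold is None else r.bfdr_at_threshold
                     for r in records],
            "significant": [r.significant for r in records],
            "fold_change": [2.0 ** r.post_mean for r in records],
        }
    )
    return df
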