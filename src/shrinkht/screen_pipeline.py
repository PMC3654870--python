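"""End-to-end screen analysis: normalization, control offsets, shrinkage fit.

A screen dataset is a table of wells (feature id, assay, treatment, raw
viability value, control flags).  The pipeline log2-transforms the values,
removes plate/assay effects by least squares across all screens jointly,
anchors the treatment scale by fitting the per-feature model to the
positive-control wells with vague priors (the resulting treatment-by-assay
effects become known offsets; their uncertainty is small because controls
are numerous and is not propagated), and then runs the empirical-Bayes
shrinkage fit and one-sided BFDR inference on every feature.

Four shrinkage scenarios are supported: "flat" (no shrinkage), "sigma"
(error precision only), "sigma+treat" (precision and treatment effect,
optionally with the nonparametric prior), and "full" (all of the above
plus the assay effects).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .inference import effective_params, eqn, results_table
from .model_core import (
    FeatureData,
    Gaussian,
    GridDensity,
    MarginalPosterior,
    PriorSet,
    build_design,
)
from .nonparametric_prior import NPPriorResult, np_prior_iterate
from .prior_estimation import HyperParams, joint_iterate

logger = logging.getLogger("shrinkht")

__all__ = [
    "ScreenDataset",
    "OffsetTable",
    "AnalysisConfig",
    "ScreenResult",
    "normalize_plates",
    "compute_offsets",
    "apply_offsets",
    "build_features",
    "run_analysis",
    "SCENARIOS",
]

SCENARIOS = {
    "1": "flat",
    "2": "sigma",
    "3": "sigma+treat",
    "4": "full",
    "flat": "flat",
    "sigma": "sigma",
    "sigma+treat": "sigma+treat",
    "full": "full",
}


@dataclass
class ScreenDataset:
    """Well-level screen data.

    ``wells`` columns: feature_id, assay, treatment, value, and optional
    is_pos_control / is_neg_control booleans, plate label, offset.
    ``log_scale`` records whether values are already log2 (after
    normalization) or raw fluorescence/viability readouts.
    """

    wells: pd.DataFrame
    log_scale: bool = False

    def __post_init__(self) -> None:
        required = {"feature_id", "assay", "treatment", "value"}
        missing = required - set(self.wells.columns)
        if missing:
            raise ValueError(f"wells table missing columns: {sorted(missing)}")

    @property
    def n_assays(self) -> int:
        return int(self.wells["assay"].max())

    def control_mask(self, which: str = "positive") -> np.ndarray:
        col = {"positive": "is_pos_control", "negative": "is_neg_control"}[which]
        if col not in self.wells.columns:
            return np.zeros(len(self.wells), dtype=bool)
        return self.wells[col].astype(bool).to_numpy()

    def to_csv(self, path) -> None:
        self.wells.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, log_scale: bool = False) -> "ScreenDataset":
        sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
        return cls(pd.read_csv(path, sep=sep), log_scale=log_scale)


@dataclass
class OffsetTable:
    """Estimated control effect per (treatment, assay) cell, log2 scale."""

    table: pd.DataFrame  # columns treatment, assay, offset, sd

    def __post_init__(self) -> None:
        if not np.isfinite(self.table["offset"]).all():
            raise ValueError("offsets must be finite")

    def lookup(self, treatment: np.ndarray, assay: np.ndarray) -> np.ndarray:
        key = self.table.set_index(["treatment", "assay"])["offset"]
        return np.array([key[(int(j), int(k))] for j, k in zip(treatment, assay)])

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Normalization and offsets
# ---------------------------------------------------------------------------


def normalize_plates(dataset: ScreenDataset) -> ScreenDataset:
    """Log2-transform and remove plate/assay effects by joint least squares.

    The plate factor is the ``plate`` column when present, otherwise the
    (treatment, assay) screen combination.  With a single categorical
    factor the least-squares effects are the plate means, so each plate is
    centered while the overall mean is preserved.  Already-normalized
    (log-scale) data are only re-centered, making the operation idempotent.
    """
    df = dataset.wells.copy()
    values = df["value"].to_numpy(dtype=float)
    if not dataset.log_scale:
        bad = values <= 0
        if bad.any():
            raise ValueError(
                f"non-positive raw values in wells {np.flatnonzero(bad).tolist()[:20]}"
            )
        values = np.log2(values)
    if "plate" in df.columns:
        plate = df["plate"].astype(str)
    else:
        plate = df["treatment"].astype(str) + ":" + df["assay"].astype(str)
    grand = values.mean()
    effects = pd.Series(values).groupby(plate.to_numpy()).transform("mean").to_numpy()
    df["value"] = values - effects + grand
    return ScreenDataset(df, log_scale=True)


def compute_offsets(dataset: ScreenDataset, which: str = "positive") -> OffsetTable:
    """Fit the per-feature model to the control wells with vague priors.

    The offset for cell (j, k) is the posterior-mean control effect
    ``b_j^treat + b_k^assay`` (zero for the reference cell); the intercept
    is deliberately excluded so a constant shift of all control values
    changes no offset.  Uncertainty is not propagated further.
    """
    if not dataset.log_scale:
        raise ValueError("compute offsets after normalization (log2 scale)")
    mask = dataset.control_mask(which)
    ctrl = dataset.wells[mask]
    if ctrl.empty:
        raise ValueError(f"no {which}-control wells present")
    table = ctrl[["treatment", "assay", "value"]].copy()
    table["feature_id"] = "__control__"
    feature = build_design(table, allow_replicates=True)
    priors = PriorSet.vague()
    from .model_core import marginal_posterior

    post = marginal_posterior(feature, priors)
    K = feature.n_assays
    rows = []
    for j in (1, 2):
        for k in range(1, K + 1):
            sel = np.zeros(feature.n_coef)
            if j == 2:
                sel[1] = 1.0
            if k >= 2:
                sel[1 + k - 1] = 1.0
            off = float(sel @ post.coef_mean)
            sd = float(np.sqrt(max(sel @ post.coef_cov @ sel, 0.0)))
            rows.append({"treatment": j, "assay": k, "offset": off, "sd": sd})
    return OffsetTable(pd.DataFrame(rows))


def apply_offsets(dataset: ScreenDataset, offsets: OffsetTable) -> ScreenDataset:
    df = dataset.wells.copy()
    df["offset"] = offsets.lookup(
        df["treatment"].to_numpy(), df["assay"].to_numpy()
    )
    return ScreenDataset(df, log_scale=dataset.log_scale)


def build_features(dataset: ScreenDataset, exclude_controls: bool = True) -> list[FeatureData]:
    df = dataset.wells
    if exclude_controls:
        drop = dataset.control_mask("positive") | dataset.control_mask("negative")
        df = df[~drop]
    return [
        build_design(group) for _, group in df.groupby("feature_id", sort=True)
    ]


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------


@dataclass
class AnalysisConfig:
    """Pipeline configuration; a flat key-value (YAML) file maps onto it."""

    scenario: str = "full"
    bfdr_threshold: float = 0.1
    seed: int = 0
    max_iter: int = 20
    tol: float = 1e-3
    np_max_iter: int = 10
    np_tol: float = 1e-3
    use_nonparametric: bool = True
    normalize: bool = True
    offsets_from: str | None = "positive"  # "positive", "negative", or None
    relative_to_prior_mean: bool = False
    draws_per_feature: int = 200
    np_draws_per_feature: int = 100

    def __post_init__(self) -> None:
        key = str(self.scenario)
        if key not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.scenario!r}")
        self.scenario = SCENARIOS[key]

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        import dataclasses

        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh)


@dataclass
class ScreenResult:
    results: pd.DataFrame
    hyperparams: HyperParams
    posteriors: list[MarginalPosterior]
    np_result: NPPriorResult | None
    offsets: OffsetTable | None
    config: AnalysisConfig

    def write(self, prefix: str) -> None:
        self.results.to_csv(f"{prefix}_results.csv", index=False)
        self.hyperparams.write_trace(f"{prefix}_trace.csv")
        if self.np_result is not None:
            self.np_result.prior.to_csv(f"{prefix}_np_prior.csv")
        if self.offsets is not None:
            self.offsets.to_csv(f"{prefix}_offsets.csv")


def run_analysis(dataset: ScreenDataset, config: AnalysisConfig) -> ScreenResult:
    """Normalize -> offsets -> joint EB fit -> nonparametric prior -> inference."""
    rng = np.random.default_rng(config.seed)
    ds = dataset
    try:
        if config.normalize:
            ds = normalize_plates(ds)
    except Exception as exc:
        raise RuntimeError(f"normalization stage failed: {exc}") from exc

    offsets = None
    try:
        if config.offsets_from:
            offsets = compute_offsets(ds, config.offsets_from)
            ds = apply_offsets(ds, offsets)
    except Exception as exc:
        raise RuntimeError(f"offset stage failed: {exc}") from exc

    features = build_features(ds)

    scenario = config.scenario
    estimate = {
        "flat": dict(estimate_tau2=False, estimate_treat=False, estimate_precision=False),
        "sigma": dict(estimate_tau2=False, estimate_treat=False, estimate_precision=True),
        "sigma+treat": dict(estimate_tau2=False, estimate_treat=True, estimate_precision=True),
        "full": dict(estimate_tau2=True, estimate_treat=True, estimate_precision=True),
    }[scenario]
    any_update = any(estimate.values())
    try:
        hp, posteriors = joint_iterate(
            features,
            max_iter=config.max_iter if any_update else 0,
            tol=config.tol,
            draws_per_feature=config.draws_per_feature,
            seed=rng,
            **estimate,
        )
    except Exception as exc:
        raise RuntimeError(f"joint estimation stage failed: {exc}") from exc

    np_result = None
    densities = None
    if config.use_nonparametric and scenario in ("sigma+treat", "full"):
        try:
            grid = posteriors[0].treat_density.support
            param_prior = GridDensity.from_gaussian(hp.treat_mu, hp.treat_omega2, grid)
            np_result = np_prior_iterate(
                [p.treat_density for p in posteriors],
                param_prior,
                max_iter=config.np_max_iter,
                tol=config.np_tol,
                draws_per_feature=config.np_draws_per_feature,
                seed=rng,
            )
            densities = np_result.posteriors
        except Exception as exc:
            raise RuntimeError(f"nonparametric prior stage failed: {exc}") from exc

    try:
        if config.relative_to_prior_mean:
            prior = np_result.prior if np_result is not None else None
            reference = prior.mean() if prior is not None else hp.treat_mu
        else:
            reference = 0.0
        results = results_table(
            posteriors,
            threshold=config.bfdr_threshold,
            reference=reference,
            densities=densities,
        )
        priors = hp.prior_set()
        p_stars = np.array(
            [effective_params(f, priors, p) for f, p in zip(features, posteriors)]
        )
        results["p_star"] = p_stars
        results["eqn"] = np.array([eqn(ps, f.n_obs) for ps, f in zip(p_stars, features)])
    except Exception as exc:
        raise RuntimeError(f"inference stage failed: {exc}") from exc

    logger.info(
        "analysis complete: scenario=%s, %d features, %d selected at BFDR<=%.3g",
        scenario,
        len(features),
        int(results["significant"].sum()),
        config.bfdr_threshold,
    )
    return ScreenResult(results, hp, posteriors, np_result, offsets, config)
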