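"""Plate normalization, control offsets, and the end-to-end analysis."""

import warnings

import numpy as np
import pandas as pd
import pytest

from shrinkht import (
    AnalysisConfig,
    ScreenDataset,
    apply_offsets,
    build_features,
    compute_offsets,
    normalize_plates,
    run_analysis,
)
from shrinkht.simulation_eval import (
    DESIGN_ASSAY,
    DESIGN_TREATMENT,
    COMPARISON_FAMILIES,
    simulate_comparison,
)


def make_wells(values, treatment, assay, plate=None, **flags):
    df = pd.DataFrame(
        {
            "feature_id": [f"f{i}" for i in range(len(values))],
            "treatment": treatment,
            "assay": assay,
            "value": values,
        }
    )
    if plate is not None:
        df["plate"] = plate
    for k, v in flags.items():
        df[k] = v
    return ScreenDataset(df)


def control_dataset(effects, n_per_cell=40, noise=0.02, seed=0, shift=0.0):
    """Positive-control wells with known treatment-by-assay effects.

    ``effects`` maps (treatment, assay) -> true log2 effect (reference
    cell (1, 1) should be 0).
    """
    rng = np.random.default_rng(seed)
    rows = []
    for (j, k), e in effects.items():
        for _ in range(n_per_cell):
            rows.append(
                {
                    "feature_id": "posctrl",
                    "treatment": j,
                    "assay": k,
                    "value": shift + e + rng.normal(0, noise),
                    "is_pos_control": True,
                }
            )
    return ScreenDataset(pd.DataFrame(rows), log_scale=True)


TRUE_EFFECTS = {
    (1, 1): 0.0, (1, 2): 0.1, (1, 3): -0.2,
    (2, 1): -0.8, (2, 2): -0.7, (2, 3): -1.0,
}


class TestNormalization:
    def test_single_plate_recenters_only(self):
        raw = np.array([2.0, 4.0, 8.0, 16.0])
        ds = make_wells(raw, [1, 2, 1, 2], [1, 1, 1, 1], plate=["p"] * 4)
        out = normalize_plates(ds)
        logv = np.log2(raw)
        np.testing.assert_allclose(out.wells["value"], logv, atol=1e-12)

    def test_known_plate_shift_recovered_exactly(self):
        rng = np.random.default_rng(1)
        base = rng.uniform(1.0, 4.0, size=12)
        d = 0.73  # log2 shift of plate B
        values = np.concatenate([base, base * 2**d])
        ds = make_wells(
            values, [1, 2] * 12, [1, 1, 2, 2, 3, 3] * 4,
            plate=["A"] * 12 + ["B"] * 12,
        )
        out = normalize_plates(ds)
        v = out.wells["value"].to_numpy()
        est_shift = v[12:].mean() - v[:12].mean()
        assert est_shift == pytest.approx(0.0, abs=1e-10)
        # removed effect equals the injected d
        raw_shift = np.log2(values[12:]).mean() - np.log2(values[:12]).mean()
        assert raw_shift == pytest.approx(d, abs=1e-10)

    def test_constant_data_stay_constant(self):
        ds = make_wells(np.full(8, 4.0), [1, 2] * 4, [1, 1, 2, 2, 3, 3, 1, 1])
        out = normalize_plates(ds)
        np.testing.assert_allclose(out.wells["value"], 2.0, atol=1e-12)

    def test_idempotence(self):
        rng = np.random.default_rng(2)
        ds = make_wells(rng.uniform(0.5, 5.0, 24), [1, 2] * 12, [1, 1, 2, 2, 3, 3] * 4)
        once = normalize_plates(ds)
        twice = normalize_plates(once)
        np.testing.assert_allclose(
            once.wells["value"], twice.wells["value"], atol=1e-12
        )

    def test_nonpositive_raw_values_rejected(self):
        ds = make_wells([1.0, -2.0, 3.0, 4.0], [1, 2, 1, 2], [1, 1, 2, 2])
        with pytest.raises(ValueError, match="non-positive"):
            normalize_plates(ds)


class TestOffsets:
    def test_known_effects_recovered(self):
        ds = control_dataset(TRUE_EFFECTS, seed=3)
        table = compute_offsets(ds).table.set_index(["treatment", "assay"])
        for (j, k), e in TRUE_EFFECTS.items():
            row = table.loc[(j, k)]
            assert abs(row["offset"] - e) < max(3 * row["sd"], 0.02)

    def test_null_controls_give_zero_offsets(self):
        ds = control_dataset({k: 0.0 for k in TRUE_EFFECTS}, seed=4)
        table = compute_offsets(ds).table
        assert np.all(np.abs(table["offset"]) < 0.02)

    def test_constant_shift_changes_no_offset(self):
        ds0 = control_dataset(TRUE_EFFECTS, seed=5)
        ds1 = control_dataset(TRUE_EFFECTS, seed=5, shift=3.3)
        t0 = compute_offsets(ds0).table["offset"].to_numpy()
        t1 = compute_offsets(ds1).table["offset"].to_numpy()
        np.testing.assert_allclose(t0, t1, atol=1e-6)

    def test_missing_control_cell_errors(self):
        effects = dict(TRUE_EFFECTS)
        effects.pop((2, 3))
        ds = control_dataset(effects, seed=6)
        with pytest.raises(ValueError, match="missing design cell"):
            compute_offsets(ds)

    def test_offsets_remove_control_treatment_effect(self):
        """Refitting the controls with the offsets applied leaves ~zero
        residual treatment effect."""
        ds = control_dataset(TRUE_EFFECTS, seed=7)
        offsets = compute_offsets(ds)
        corrected = apply_offsets(ds, offsets)
        from shrinkht import PriorSet, marginal_posterior
        from shrinkht.model_core import build_design

        ctrl = build_design(corrected.wells, allow_replicates=True)
        priors = PriorSet.vague()
        post = marginal_posterior(ctrl, priors)
        assert abs(post.treat_moments[0]) < 3 * np.sqrt(post.treat_moments[1]) + 1e-3


def screen_from_simulation(n_features=30, seed=0):
    """Raw-scale screen: simulated features plus positive-control wells."""
    data = simulate_comparison(
        COMPARISON_FAMILIES["halfnormal_0.47"], n_features=n_features, seed=seed
    )
    rng = np.random.default_rng(seed + 100)
    rows = []
    for f in data.features:
        for v, j, k in zip(f.values, f.treatment, f.assay):
            rows.append(
                {
                    "feature_id": f.feature_id, "treatment": j, "assay": k,
                    "value": float(2.0 ** v), "is_pos_control": False,
                }
            )
    for (j, k), e in TRUE_EFFECTS.items():
        for _ in range(30):
            rows.append(
                {
                    "feature_id": "posctrl", "treatment": j, "assay": k,
                    "value": float(2.0 ** (e + rng.normal(0, 0.05))),
                    "is_pos_control": True,
                }
            )
    return ScreenDataset(pd.DataFrame(rows))


class TestRunAnalysis:
    def test_flat_scenario_eqn_is_constant(self):
        ds = screen_from_simulation(seed=1)
        cfg = AnalysisConfig(scenario="flat", seed=1)
        res = run_analysis(ds, cfg)
        np.testing.assert_allclose(res.results["eqn"], 1.5, atol=1e-3)

    def test_full_scenario_runs_and_is_deterministic(self, tmp_path):
        ds = screen_from_simulation(seed=2)
        cfg = AnalysisConfig(
            scenario="full", seed=7, max_iter=3, np_max_iter=2,
            draws_per_feature=50, np_draws_per_feature=50,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            res1 = run_analysis(ds, cfg)
            res2 = run_analysis(ds, cfg)
        p1, p2 = tmp_path / "a.csv", tmp_path / "b.csv"
        res1.results.to_csv(p1, index=False)
        res2.results.to_csv(p2, index=False)
        assert p1.read_bytes() == p2.read_bytes()
        assert res1.np_result is not None
        assert set(res1.results.columns) >= {
            "feature_id", "post_mean", "p0", "bfdr", "significant",
            "fold_change", "eqn",
        }

    def test_stage_errors_are_labelled(self):
        ds = screen_from_simulation(seed=3)
        ds.wells.loc[0, "value"] = -1.0
        with pytest.raises(RuntimeError, match="normalization stage"):
            run_analysis(ds, AnalysisConfig(scenario="flat"))

    def test_scenario_aliases(self):
        assert AnalysisConfig(scenario="2").scenario == "sigma"
        with pytest.raises(ValueError):
            AnalysisConfig(scenario="5")
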