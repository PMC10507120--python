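"""Benchmark procedures that measure the pipeline against its generator.

Each function regenerates its synthetic inputs from a seed, runs the
relevant stage(s), and returns summary numbers. They are used both by the
test suite and by ``scripts/acceptance.py``; the defaults are the standard
study conditions (frame and cohort sizes, rare fractions, hot-pixel rate,
fold changes) used throughout the package.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from liquidimc import imc_preprocess, imc_quant, rarecell, stats
from liquidimc.datatypes import ImageStack
from liquidimc.imc_preprocess import CellMask
from liquidimc.panel import TARGET_MARKERS, default_panel
from liquidimc.pipeline import run_full_pipeline, write_pipeline_outputs
from liquidimc.profiles import CohortConfig, default_profiles
from liquidimc.synthetic import generate_if_frame, generate_imc_roi, sample_expression_table

__all__ = [
    "quantify_oracle_error",
    "hot_pixel_benchmark",
    "rare_cell_benchmark",
    "null_calibration",
    "elevated_marker_power",
    "pipeline_determinism",
]


def quantify_oracle_error(seed: int = 0, n_fixtures: int = 20) -> float:
    """Max |quantify - brute-force pixel loop| over random 10x10 fixtures."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_fixtures):
        labels = np.zeros((10, 10), dtype=np.int32)
        flat = rng.choice(100, size=32, replace=False)
        for i, f in enumerate(flat):
            labels.flat[f] = (i % 4) + 1
        data = rng.poisson(5, (3, 10, 10)).astype(float)
        stack = ImageStack(data, ("a", "b", "c"))
        masks = CellMask(
            cell_labels=labels, nucleus_labels=labels, negative_mask=labels == 0
        )
        table = imc_quant.quantify(stack, masks)
        for _, row in table.iterrows():
            sel = labels == row["cell_id"]
            for ch in stack.channels:
                oracle = float(stack.channel(ch)[sel].sum()) / int(sel.sum())
                worst = max(worst, abs(row[ch] - oracle))
    return worst


def hot_pixel_benchmark(
    seed: int = 0, n_rois: int = 3, hot_pixel_rate: float = 1e-4
) -> tuple[float, float, int]:
    """(fraction of injected hot pixels removed, fraction of clean pixels
    altered, number of hot pixels) over the standard synthetic ROI set."""
    profiles = list(default_profiles().values())
    removed = hot = altered = clean = 0
    for k in range(n_rois):
        stack, truth = generate_imc_roi(
            profiles, seed=seed + k, hot_pixel_rate=hot_pixel_rate
        )
        cleaned = imc_preprocess.remove_hot_pixels(stack)
        hp = truth.hot_pixels
        hot_mask = np.zeros(stack.data.shape, dtype=bool)
        hot_mask[hp["channel"], hp["y"], hp["x"]] = True
        changed = cleaned.data != stack.data
        removed += int((changed & hot_mask).sum())
        hot += int(hot_mask.sum())
        altered += int((changed & ~hot_mask).sum())
        clean += int((~hot_mask).sum())
    return removed / hot, altered / clean, hot


def rare_cell_benchmark(
    seed: int = 0,
    n_seeds: int = 10,
    n_cells: int = 1000,
    rare_fractions: tuple[float, ...] = (0.01, 0.02, 0.03, 0.04, 0.05),
    texture: bool = True,
) -> tuple[float, float, int]:
    """Pooled (recall, precision, n_rare) of rare-cell detection + refinement.

    Each replicate draws a fresh frame at one of the configured rare
    fractions; detected cells are matched to ground-truth plasma cells by
    nearest centroid within 6 px.
    """
    tp = fp = fn = 0
    for k in range(n_seeds):
        rf = rare_fractions[k % len(rare_fractions)]
        stack, truth = generate_if_frame(n_cells, rf, seed=seed + k)
        labels = rarecell.segment_nuclei(stack.channel("DAPI"))
        features = rarecell.extract_features(stack, labels, texture=texture)
        flags = rarecell.detect_rare(
            features, rare_cluster_max_fraction=0.06, n_clusters=5
        )
        refined = rarecell.knn_refine(features, flags, k=5)
        cy = features.values["centroid_y"].to_numpy()
        cx = features.values["centroid_x"].to_numpy()
        pc = truth.cells[truth.cells["cell_type"] == "PC"]
        tree = cKDTree(np.c_[cy, cx])
        d, idx = tree.query(np.c_[pc["y"], pc["x"]])
        hits = np.zeros(len(cy), dtype=bool)
        hits[idx[d < 6]] = True
        tp += int((refined & hits).sum())
        fp += int((refined & ~hits).sum())
        fn += int((~refined & hits).sum())
    recall = tp / (tp + fn) if tp + fn else 0.0
    precision = tp / (tp + fp) if tp + fp else 0.0
    return recall, precision, tp + fn


def _compare_once(
    seed: int, fold_change: float, pcs_per_sample: int, wbcs_per_sample: int = 60
) -> pd.DataFrame:
    config = CohortConfig.default(seed=seed, fold_change=fold_change)
    table, manifest = sample_expression_table(
        config, pcs_per_sample=pcs_per_sample, wbcs_per_sample=wbcs_per_sample
    )
    markers = list(default_panel().markers)
    normalized, params = imc_quant.normalize(table, markers)
    thresholds = imc_quant.compute_positivity_thresholds(
        table, markers, norm_params=params
    )
    gated, _ = imc_quant.gate_populations(
        normalized, markers, thresholds=thresholds
    )
    return stats.compare_markers(gated, manifest, list(TARGET_MARKERS))


def null_calibration(
    seed: int = 0, n_reps: int = 200, pcs_per_sample: int = 40
) -> tuple[float, int]:
    """Fraction of significant markers under the null (fold change 1.0).

    Returns (fraction, number of tests). With a calibrated test the fraction
    sits inside the binomial confidence band around alpha = 0.05.
    """
    sig = tot = 0
    for rep in range(n_reps):
        comp = _compare_once(seed + rep, 1.0, pcs_per_sample)
        sig += int(comp["significant"].sum())
        tot += len(comp)
    return sig / tot, tot


def elevated_marker_power(
    seed: int = 0, n_reps: int = 20, pcs_per_sample: int = 70
) -> tuple[float, int]:
    """Seed-averaged power to flag all three 3x-elevated markers.

    With the default cohort (3 precursor / 4 disease samples) the pooled
    plasma-cell groups exceed 200 cells per condition.
    """
    hits = 0
    for rep in range(n_reps):
        comp = _compare_once(100_000 + seed + rep, 3.0, pcs_per_sample)
        flagged = set(comp.loc[comp["significant"], "marker"])
        hits += int({"BCMA", "ICAM3", "CD221"} <= flagged)
    return hits / n_reps, n_reps


def pipeline_determinism(seed: int = 0, out_dir=None) -> tuple[bool, int]:
    """Run simulate -> detect -> quantify -> compare twice; byte-compare.

    Returns (identical, number of output tables compared). If *out_dir* is
    given the two runs are written there (subdirectories run1/ and run2/)
    and compared file by file; otherwise the comparison is in memory via
    each table's CSV serialization.
    """
    import io as _io

    def serialize(result) -> dict[str, bytes]:
        out = {}
        for name, df in {
            "manifest": result.manifest,
            "classified": result.classified,
            "enum_sample": result.enumeration_per_sample,
            "enum_condition": result.enumeration_per_condition,
            "expression": result.expression,
            "comparison": result.comparison,
            "correlation": result.correlation,
            "micro_sample": result.micro_per_sample,
            "micro_condition": result.micro_per_condition,
        }.items():
            buf = _io.StringIO()
            df.to_csv(buf, index=False)
            out[name] = buf.getvalue().encode()
        return out

    r1 = run_full_pipeline(seed=seed)
    r2 = run_full_pipeline(seed=seed)
    s1, s2 = serialize(r1), serialize(r2)
    if out_dir is not None:
        from pathlib import Path

        write_pipeline_outputs(r1, Path(out_dir) / "run1")
        write_pipeline_outputs(r2, Path(out_dir) / "run2")
    identical = all(s1[k] == s2[k] for k in s1)
    return identical, len(s1)
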