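"""End-to-end orchestration: simulate -> detect -> quantify -> compare.

These wrappers chain the stage modules exactly as the analysis scripts do,
so tests and the acceptance machinery exercise one code path. Everything is
driven by a single integer seed and is deterministic end to end.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from liquidimc import imc_preprocess, imc_quant, rarecell, stats
from liquidimc.datatypes import ImageStack, SyntheticGroundTruth
from liquidimc.panel import CLINICAL_MARKERS, TARGET_MARKERS, default_panel
from liquidimc.profiles import CohortConfig
from liquidimc.synthetic import (
    CELL_RADIUS_FACTOR,
    CohortData,
    IFFrameParams,
    generate_cohort,
    _axes_from_radius,
    _ellipse_m2,
    _patch_bounds,
)

__all__ = [
    "training_labels_from_truth",
    "detect_frame",
    "run_if_stage",
    "run_imc_stage",
    "run_comparison",
    "PipelineResult",
    "run_full_pipeline",
    "write_pipeline_outputs",
]


def training_labels_from_truth(
    truth: SyntheticGroundTruth,
    factor: int = 2,
    background_stride: int = 4,
) -> np.ndarray:
    """Sparse pixel labels (1 nuclei, 2 membrane, 3 background) from truth.

    Labels are produced at the *factor*-upscaled geometry: nucleus cores
    (normalized elliptical radius m <= 0.7), membrane annuli
    (1.05 <= m <= 1.5) and background pixels far from every cell (sampled on
    a stride grid). This stands in for the interactive brush strokes a
    trainable pixel classifier would normally receive.
    """
    h, w = truth.shape
    h, w = h * factor, w * factor
    labels = np.zeros((h, w), dtype=np.uint8)
    near = np.zeros((h, w), dtype=bool)
    for _, cell in truth.cells.iterrows():
        a, b = _axes_from_radius(cell["radius_px"] * factor, cell["eccentricity"])
        centre = (cell["y"] * factor, cell["x"] * factor)
        theta = cell["orientation"]
        extent = 2.2 * max(a, b) + 1
        y0, y1, x0, x1 = _patch_bounds((h, w), centre, extent)
        m2 = _ellipse_m2((y1 - y0, x1 - x0), centre, a, b, theta, (y0, x0))
        patch = labels[y0:y1, x0:x1]
        patch[(m2 >= 1.05**2) & (m2 <= (CELL_RADIUS_FACTOR - 0.1) ** 2)] = 2
        patch[m2 <= 0.7**2] = 1
        near[y0:y1, x0:x1] |= m2 <= (CELL_RADIUS_FACTOR + 0.6) ** 2
    bg = np.zeros((h, w), dtype=bool)
    bg[::background_stride, ::background_stride] = True
    labels[bg & ~near & (labels == 0)] = 3
    return labels


# ---------------------------------------------------------------------------
# IF stage


def detect_frame(
    stack: ImageStack,
    sample_id: str,
    n_components: int = 350,
    rare_cluster_max_fraction: float = 0.06,
    n_clusters: int = 5,
    knn_k: int = 5,
    texture: bool = True,
    roi_px: int = 400,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full rare-cell detection on one IF frame.

    Returns ``(classified cells, selected ROIs)``.
    """
    labels = rarecell.segment_nuclei(stack.channel("DAPI"))
    if labels.max() < 2:
        empty = pd.DataFrame(
            columns=[
                "label",
                "centroid_y",
                "centroid_x",
                "area",
                "eccentricity",
                "channel_class",
                "rare",
                "morphologically_distinct",
                "sample_id",
            ]
        )
        return empty, rarecell.select_rois(empty.assign(label=[]), stack.shape, roi_px)
    features = rarecell.extract_features(stack, labels, texture=texture)
    flags = rarecell.detect_rare(
        features,
        n_components=n_components,
        rare_cluster_max_fraction=rare_cluster_max_fraction,
        n_clusters=n_clusters,
    )
    refined = rarecell.knn_refine(features, flags, k=knn_k)
    thresholds = rarecell.compute_channel_thresholds(stack, labels)
    classified = rarecell.classify_cells(features, thresholds, rare_flags=refined)
    classified["sample_id"] = sample_id
    rois = rarecell.select_rois(classified, stack.shape, roi_px=roi_px)
    return classified, rois


def run_if_stage(
    cohort: CohortData,
    rare_cluster_max_fraction: float = 0.06,
    roi_px: int = 400,
    texture: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Detect, classify and enumerate across every sample's IF frames.

    Returns ``(classified cells, per-sample counts, per-condition stats)``.
    """
    all_cells = []
    for sample in cohort.samples:
        for stack, _ in sample.if_frames:
            classified, _ = detect_frame(
                stack,
                sample.sample_id,
                rare_cluster_max_fraction=rare_cluster_max_fraction,
                roi_px=roi_px,
                texture=texture,
            )
            all_cells.append(classified)
    classified = (
        pd.concat(all_cells, ignore_index=True) if all_cells else pd.DataFrame()
    )
    per_sample, per_condition = rarecell.enumerate_groups(
        classified, cohort.manifest
    )
    return classified, per_sample, per_condition


# ---------------------------------------------------------------------------
# IMC stage


def run_imc_stage(
    cohort: CohortData,
    seed: int = 0,
    k_mad: float = 5.0,
    upscale_factor: int = 2,
    classifier_channels: tuple[str, ...] = ("DNA1", "DNA2", "CD45", "CD138", "CD38"),
) -> pd.DataFrame:
    """Preprocess and quantify every ROI of the cohort.

    The pixel classifier is trained once, on the first ROI's truth-derived
    sparse labels, then applied to every ROI (batch processing). Returns the
    concatenated background-corrected, DNA-filtered per-cell table.
    """
    panel = default_panel()
    ch_idx = tuple(panel.index(c) for c in classifier_channels)
    first = next(
        (s for s in cohort.samples if s.imc_rois), None
    )
    if first is None:
        raise ValueError("cohort contains no ion-count ROIs")
    train_stack, train_truth = first.imc_rois[0]
    cleaned = imc_preprocess.remove_hot_pixels(train_stack, k_mad=k_mad)
    scaled = imc_preprocess.upscale(cleaned, factor=upscale_factor)
    train_labels = training_labels_from_truth(train_truth, factor=upscale_factor)
    clf = imc_preprocess.train_pixel_classifier(
        [scaled], [train_labels], seed=seed, channels=ch_idx
    )

    tables = []
    for sample in cohort.samples:
        for roi_id, (stack, _) in enumerate(sample.imc_rois):
            scaled, _, masks = imc_preprocess.preprocess_roi(
                stack, clf, k_mad=k_mad, factor=upscale_factor
            )
            raw = imc_quant.quantify(
                scaled, masks, sample_id=sample.sample_id, roi_id=roi_id
            )
            corrected, _ = imc_quant.subtract_background(raw, scaled, masks)
            tables.append(imc_quant.filter_cells(corrected))
    return pd.concat(tables, ignore_index=True)


# ---------------------------------------------------------------------------
# statistics stage


def run_comparison(
    table: pd.DataFrame,
    manifest: pd.DataFrame,
    markers: list[str] | None = None,
    target_markers: list[str] | None = None,
    alpha: float = 0.05,
    seed: int = 0,
    embed: bool = True,
) -> dict[str, object]:
    """Normalize, gate, type and compare a quantified per-cell table.

    Returns a dict with the normalized gated table, gate thresholds, the
    per-marker comparison, the marker correlation, the microenvironment
    profile and (optionally) clinical-marker embedding coordinates.
    """
    panel = default_panel()
    if markers is None:
        markers = [m for m in panel.markers if m in table.columns]
    if target_markers is None:
        target_markers = [m for m in TARGET_MARKERS if m in table.columns]
    normalized, norm_params = imc_quant.normalize(table, markers)
    # thresholds are found on the raw count scale (where a missing positive
    # population is detectable) and mapped onto the normalized scale
    thresholds = imc_quant.compute_positivity_thresholds(
        table, markers, norm_params=norm_params
    )
    gated, _ = imc_quant.gate_populations(normalized, markers, thresholds=thresholds)
    typed = imc_quant.assign_cell_types(gated, thresholds)
    comparison = stats.compare_markers(
        typed, manifest, target_markers, alpha=alpha
    )
    correlation = stats.marker_correlation(typed, target_markers)
    micro_sample, micro_condition = stats.microenvironment_profile(typed, manifest)
    out: dict[str, object] = {
        "table": typed,
        "norm_params": norm_params,
        "thresholds": thresholds,
        "comparison": comparison,
        "correlation": correlation,
        "micro_per_sample": micro_sample,
        "micro_per_condition": micro_condition,
    }
    if embed:
        pcs = typed[typed["gate"] == "PC"]
        clinical = [m for m in CLINICAL_MARKERS if m in typed.columns]
        if len(pcs) >= 5 and clinical:
            out["embedding"] = stats.embed_cells(pcs, clinical, seed=seed)
    return out


# ---------------------------------------------------------------------------
# full pipeline


@dataclass
class PipelineResult:
    """Everything the end-to-end run produces, ready to be written out."""

    manifest: pd.DataFrame
    classified: pd.DataFrame
    enumeration_per_sample: pd.DataFrame
    enumeration_per_condition: pd.DataFrame
    expression: pd.DataFrame
    comparison: pd.DataFrame
    correlation: pd.DataFrame
    micro_per_sample: pd.DataFrame
    micro_per_condition: pd.DataFrame
    extras: dict = field(default_factory=dict)


def run_full_pipeline(
    seed: int = 0,
    n_samples_per_condition: int = 2,
    if_cells: int = 150,
    if_frame_px: int = 512,
    imc_roi_px: int = 200,
    imc_cells_per_roi: int = 70,
    pc_fraction: float = 0.05,
) -> PipelineResult:
    """Simulate a small cohort and run every stage on it.

    The defaults are deliberately desk-scale (two samples per condition, one
    frame and one ROI each) so the whole chain runs in a couple of minutes;
    every stage uses the same code paths as at full scale.
    """
    from liquidimc.profiles import SampleConfig

    samples = []
    for i in range(n_samples_per_condition):
        samples.append(
            SampleConfig(f"PRE{i + 1}", "precursor", n_cells=if_cells, pc_fraction=pc_fraction)
        )
        samples.append(
            SampleConfig(f"DIS{i + 1}", "disease", n_cells=if_cells, pc_fraction=pc_fraction)
        )
    config = CohortConfig(samples=tuple(samples), seed=seed)
    cohort = generate_cohort(
        config,
        if_params=IFFrameParams(shape=(if_frame_px, if_frame_px)),
        roi_px=(imc_roi_px, imc_roi_px),
        imc_cells_per_roi=imc_cells_per_roi,
    )
    classified, per_sample, per_condition = run_if_stage(
        cohort, roi_px=min(400, if_frame_px)
    )
    expression = run_imc_stage(cohort, seed=seed)
    comparison = run_comparison(expression, cohort.manifest, seed=seed, embed=False)
    return PipelineResult(
        manifest=cohort.manifest,
        classified=classified,
        enumeration_per_sample=per_sample,
        enumeration_per_condition=per_condition,
        expression=comparison["table"],
        comparison=comparison["comparison"],
        correlation=comparison["correlation"].correlation.reset_index(names="marker"),
        micro_per_sample=comparison["micro_per_sample"],
        micro_per_condition=comparison["micro_per_condition"],
    )


def write_pipeline_outputs(result: PipelineResult, out_dir: str | Path) -> list[Path]:
    """Write every result table as CSV; returns the paths written."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    tables = {
        "manifest.csv": result.manifest,
        "classified_cells.csv": result.classified,
        "enumeration_per_sample.csv": result.enumeration_per_sample,
        "enumeration_per_condition.csv": result.enumeration_per_condition,
        "expression_table.csv": result.expression,
        "marker_comparison.csv": result.comparison,
        "marker_correlation.csv": result.correlation,
        "microenvironment_per_sample.csv": result.micro_per_sample,
        "microenvironment_per_condition.csv": result.micro_per_condition,
    }
    paths = []
    for name, df in tables.items():
        path = out_dir / name
        df.to_csv(path, index=False)
        paths.append(path)
    return paths


def _round_up_power(x: float) -> int:  # small helper used by analysis scripts
    return int(2 ** math.ceil(math.log2(max(x, 1))))
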