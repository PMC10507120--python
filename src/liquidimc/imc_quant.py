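"""Per-cell marker quantification, background correction, scaling and gates.

The quantification contract is deliberately simple: a cell's raw value for a
channel is the mean ion count over its segmented territory (sum / area). The
per-channel background is the mean count over the negative-mask space of the
same ROI and is subtracted from every cell (clamped at zero — negative ion
counts are non-physical). Marker scales are then harmonized cohort-wide to
[0, 1] by robust percentile min-max (0.5th / 99.5th percentile), and cells
are gated into plasma cells (CD138+CD38+), white-blood-cell controls
(CD45+CD138-CD38-) and microenvironment types by a priority-ordered rule
table.

Positivity thresholds: for markers on which the control WBC population is
expected negative (CD138, CD38 and the target markers), the threshold is the
95th percentile of the control-candidate distribution; for markers expressed
by control subsets themselves (CD45 and the lineage-typing markers), that
percentile would sit inside the positive population, so a deterministic
bimodal split (Otsu) over the cohort distribution is used instead. All
thresholds are logged so gates are reproducible from the log alone.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.filters import threshold_otsu

from liquidimc.datatypes import ImageStack
from liquidimc.imc_preprocess import CellMask

logger = logging.getLogger(__name__)

__all__ = [
    "quantify",
    "subtract_background",
    "filter_cells",
    "normalize",
    "GateRule",
    "gate_populations",
    "assign_cell_types",
    "DEFAULT_TYPE_RULES",
]

ID_COLUMNS = ("sample_id", "roi_id", "cell_id", "area")

#: Markers for which positivity is determined by a bimodal (Otsu) split
#: rather than the control-population percentile (controls express them).
OTSU_MARKERS = frozenset(
    {"CD45", "CD3", "CD20", "CD56", "HLA-DR", "CD31", "CD61", "CD4", "CD8a", "CD45RO"}
)


def quantify(
    stack: ImageStack,
    masks: CellMask,
    sample_id: str = "sample",
    roi_id: int = 0,
) -> pd.DataFrame:
    """Mean ion counts per cell territory for every channel.

    One row per cell label, value = sum of counts over the territory divided
    by the territory area in pixels. An empty mask yields an empty table.
    """
    if masks.cell_labels.shape != stack.shape:
        raise ValueError("stack and masks geometry differ")
    n = masks.n_cells
    ids = np.arange(1, n + 1)
    out = pd.DataFrame(
        {
            "sample_id": sample_id,
            "roi_id": roi_id,
            "cell_id": ids,
            "area": (
                ndimage.sum_labels(
                    np.ones(stack.shape), masks.cell_labels, index=ids
                ).astype(int)
                if n
                else np.array([], dtype=int)
            ),
        }
    )
    for name, plane in zip(stack.channels, stack.data):
        sums = (
            ndimage.sum_labels(plane.astype(np.float64), masks.cell_labels, index=ids)
            if n
            else np.array([])
        )
        out[name] = sums / out["area"].to_numpy() if n else sums
    return out


def subtract_background(
    raw: pd.DataFrame,
    stack: ImageStack,
    masks: CellMask,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Subtract the per-channel negative-mask background from every cell.

    Background = mean counts over the ROI's negative mask; corrected values
    are clamped at zero. An empty negative mask means background 0 (with a
    warning). Returns the corrected table and the background log.
    """
    neg = masks.negative_mask
    background: dict[str, float] = {}
    corrected = raw.copy()
    if not neg.any():
        logger.warning("negative mask is empty; background set to 0")
    for name, plane in zip(stack.channels, stack.data):
        b = float(plane[neg].mean()) if neg.any() else 0.0
        background[name] = b
        if name in corrected.columns:
            corrected[name] = np.maximum(corrected[name] - b, 0.0)
    return corrected, background


def filter_cells(
    table: pd.DataFrame,
    intercalators: tuple[str, ...] = ("DNA1", "DNA2"),
) -> pd.DataFrame:
    """Drop cells without DNA-intercalator signal; log the removal count."""
    missing = [c for c in intercalators if c not in table.columns]
    if missing:
        raise ValueError(f"intercalator channels absent from table: {missing}")
    dna = table[list(intercalators)].sum(axis=1)
    keep = dna > 0
    removed = int((~keep).sum())
    if removed:
        logger.info("filter_cells: removed %d cells without DNA signal", removed)
    return table[keep].reset_index(drop=True)


def normalize(
    table: pd.DataFrame,
    markers: list[str],
    lower_pct: float = 0.5,
    upper_pct: float = 99.5,
    control_mask: np.ndarray | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Scale each marker to [0, 1] by cohort-wide robust min-max.

    ``normalized = clip((x - p_low) / (p_high - p_low), 0, 1)`` with
    percentiles over all cells of the cohort. A degenerate marker
    (``p_high == p_low``) maps to all zeros with a warning. If
    *control_mask* selects control cells, their per-marker statistics are
    logged alongside for the distribution-vs-control assessment.

    Returns the table with marker columns replaced by normalized values and
    a per-marker parameter log.
    """
    out = table.copy()
    rows = []
    for m in markers:
        x = table[m].to_numpy(dtype=float)
        lo, hi = np.percentile(x, [lower_pct, upper_pct])
        if hi <= lo:
            logger.warning("marker %s is degenerate (p%.1f == p%.1f)", m, lower_pct, upper_pct)
            out[m] = 0.0
        else:
            out[m] = np.clip((x - lo) / (hi - lo), 0.0, 1.0)
        row = {"marker": m, "p_low": float(lo), "p_high": float(hi)}
        if control_mask is not None and control_mask.any():
            cx = x[control_mask]
            row["control_mean"] = float(cx.mean())
            row["control_q95"] = float(np.percentile(cx, 95))
        rows.append(row)
    return out, pd.DataFrame(rows)


@dataclass(frozen=True)
class GateRule:
    """One marker criterion of a population gate."""

    marker: str
    direction: str  # "+" or "-"

    def __post_init__(self) -> None:
        if self.direction not in ("+", "-"):
            raise ValueError("direction must be '+' or '-'")


PC_GATE = (GateRule("CD138", "+"), GateRule("CD38", "+"))
WBC_CONTROL_GATE = (GateRule("CD45", "+"), GateRule("CD138", "-"), GateRule("CD38", "-"))


def _otsu_threshold(x: np.ndarray) -> float:
    x = np.asarray(x, dtype=float)
    if np.ptp(x) <= 0:
        return float(x.max()) + 1.0  # nothing can be positive
    return float(threshold_otsu(x, nbins=256))


def compute_positivity_thresholds(
    table: pd.DataFrame,
    markers: list[str],
    control_quantile: float = 95.0,
    min_positive_counts: float = 1.0,
    norm_params: pd.DataFrame | None = None,
) -> dict[str, float]:
    """Per-marker positivity thresholds (see module docstring).

    *table* should hold raw background-corrected counts: the count scale is
    where "no positive population" is detectable, because 0-1 normalization
    stretches pure noise across the full range. A coarse Otsu split on
    CD45/CD138/CD38 first identifies control-candidate WBCs; markers outside
    :data:`OTSU_MARKERS` then take the ``control_quantile``-th percentile of
    the candidate distribution, the rest their cohort Otsu threshold. Every
    threshold is floored at ``min_positive_counts`` (counts/pixel) so a
    marker that nobody expresses yields no positives.

    If *norm_params* (the log from :func:`normalize`) is given, thresholds
    are mapped onto the normalized [0, 1] scale before being returned.
    """
    for required in ("CD45", "CD138", "CD38"):
        if required not in table.columns:
            raise ValueError(f"gating requires marker {required!r} in the table")
    o45 = _otsu_threshold(table["CD45"])
    o138 = _otsu_threshold(table["CD138"])
    o38 = _otsu_threshold(table["CD38"])
    candidates = (
        (table["CD45"] > o45) & (table["CD138"] <= o138) & (table["CD38"] <= o38)
    ).to_numpy()
    if candidates.sum() < 10:
        logger.warning(
            "only %d control candidates; falling back to cohort Otsu thresholds",
            int(candidates.sum()),
        )
    thresholds: dict[str, float] = {}
    for m in markers:
        x = table[m].to_numpy(dtype=float)
        if m in OTSU_MARKERS or candidates.sum() < 10:
            t = _otsu_threshold(x)
        else:
            t = float(np.percentile(x[candidates], control_quantile))
        thresholds[m] = max(t, min_positive_counts)
    if norm_params is not None:
        scale = {
            r["marker"]: (r["p_low"], r["p_high"]) for _, r in norm_params.iterrows()
        }
        for m in markers:
            lo, hi = scale[m]
            span = hi - lo
            thresholds[m] = (
                float(np.clip((thresholds[m] - lo) / span, 0.0, 1.0))
                if span > 0
                else 1.0
            )
    return thresholds


def gate_populations(
    table: pd.DataFrame,
    markers: list[str] | None = None,
    thresholds: dict[str, float] | None = None,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Assign the PC / WBC_control / other gates on normalized values.

    PC = CD138+ AND CD38+; WBC_control = CD45+ AND CD138- AND CD38-. The
    gates partition: a PC is never also a control. Rules referencing markers
    absent from the table raise a configuration error. Returns the gated
    table and the threshold log.
    """
    if markers is None:
        markers = [c for c in table.columns if c not in ID_COLUMNS and table[c].dtype.kind == "f"]
    missing = [
        r.marker
        for r in PC_GATE + WBC_CONTROL_GATE
        if r.marker not in table.columns
    ]
    if missing:
        raise ValueError(f"gate rules reference unknown markers: {sorted(set(missing))}")
    if thresholds is None:
        thresholds = compute_positivity_thresholds(table, markers)

    def satisfied(rules: tuple[GateRule, ...]) -> np.ndarray:
        mask = np.ones(len(table), dtype=bool)
        for r in rules:
            x = table[r.marker].to_numpy(dtype=float)
            t = thresholds[r.marker]
            mask &= (x > t) if r.direction == "+" else (x <= t)
        return mask

    out = table.copy()
    gate = np.full(len(table), "other", dtype=object)
    gate[satisfied(WBC_CONTROL_GATE)] = "WBC_control"
    gate[satisfied(PC_GATE)] = "PC"  # PC has priority; partition holds
    out["gate"] = gate
    return out, thresholds


#: Priority-ordered microenvironment typing rules: first match wins.
DEFAULT_TYPE_RULES: tuple[tuple[str, tuple[GateRule, ...]], ...] = (
    ("T_cell", (GateRule("CD3", "+"),)),
    ("B_cell", (GateRule("CD20", "+"), GateRule("CD3", "-"))),
    ("NK_cell", (GateRule("CD56", "+"), GateRule("CD3", "-"))),
    (
        "myeloid",
        (GateRule("HLA-DR", "+"), GateRule("CD3", "-"), GateRule("CD20", "-")),
    ),
    ("endothelial", (GateRule("CD31", "+"),)),
    ("megakaryocyte", (GateRule("CD61", "+"),)),
)


def assign_cell_types(
    table: pd.DataFrame,
    thresholds: dict[str, float],
    rules: tuple[tuple[str, tuple[GateRule, ...]], ...] = DEFAULT_TYPE_RULES,
) -> pd.DataFrame:
    """Assign exactly one microenvironment type per cell.

    Gated plasma cells keep type ``PC``; the remaining cells take the first
    matching rule of the priority-ordered *rules* table, else ``other``.
    Duplicate type names in the rule table are a configuration error.
    """
    if "gate" not in table.columns:
        raise ValueError("run gate_populations before assign_cell_types")
    names = [name for name, _ in rules]
    if len(set(names)) != len(names):
        raise ValueError("conflicting duplicate entries in type rules")
    unknown = sorted(
        {r.marker for _, rs in rules for r in rs} - set(table.columns)
    )
    if unknown:
        raise ValueError(f"type rules reference unknown markers: {unknown}")

    out = table.copy()
    cell_type = np.full(len(table), "other", dtype=object)
    unassigned = np.ones(len(table), dtype=bool)
    is_pc = (table["gate"] == "PC").to_numpy()
    cell_type[is_pc] = "PC"
    unassigned &= ~is_pc
    for name, rs in rules:
        mask = unassigned.copy()
        for r in rs:
            x = table[r.marker].to_numpy(dtype=float)
            t = thresholds[r.marker]
            mask &= (x > t) if r.direction == "+" else (x <= t)
        cell_type[mask] = name
        unassigned &= ~mask
    out["cell_type"] = cell_type
    return out
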