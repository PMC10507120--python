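"""Cohort statistics: enumeration, marker comparison, correlation, embedding.

Conventions fixed here and used everywhere:

* descriptive statistics use the population SD (divide by N, not N-1);
* the Kruskal-Wallis H test uses mid-ranks with tie correction and a
  chi-square null with (groups - 1) degrees of freedom; an all-tied input
  degenerates to H = 0, p = 1;
* p-values at or below alpha (default 0.05, closed boundary) are flagged
  significant, with **no multiple-testing correction** — comparisons are
  treated as planned, and every report carries that note;
* marker-marker relationships use Pearson correlation with average-linkage
  hierarchical clustering on distance 1 - r.

The default unit of analysis for marker comparison is the cell, pooling
cells across the samples of each condition; since cells within a sample are
not independent, a per-sample aggregation mode is also provided.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import squareform
from scipy.stats import kruskal as _scipy_kruskal
from sklearn.manifold import TSNE

logger = logging.getLogger(__name__)

__all__ = [
    "DescriptiveStats",
    "descriptive_stats",
    "kruskal_wallis",
    "compare_markers",
    "CorrelationResult",
    "marker_correlation",
    "microenvironment_profile",
    "embed_cells",
    "NO_CORRECTION_NOTE",
]

NO_CORRECTION_NOTE = (
    "No multiple-testing correction applied (planned comparisons); "
    "significance boundary closed at alpha."
)


@dataclass(frozen=True)
class DescriptiveStats:
    """n, arithmetic mean and population SD (divide-by-N) of a series."""

    n: int
    mean: float
    sd: float

    def __str__(self) -> str:
        return f"{self.mean:g} ± {self.sd:g} (n={self.n})"


def descriptive_stats(values) -> DescriptiveStats:
    """Mean and population standard deviation of *values*.

    The population convention divides the squared deviations by N; a single
    observation therefore has SD 0. An empty input is an error.
    """
    x = np.asarray(list(values), dtype=float)
    if x.size == 0:
        raise ValueError("descriptive_stats requires at least one value")
    return DescriptiveStats(n=int(x.size), mean=float(x.mean()), sd=float(x.std()))


def kruskal_wallis(*groups) -> tuple[float, float]:
    """Kruskal-Wallis H and p for two or more groups of numbers.

    Mid-ranks with tie correction; p from the chi-square approximation with
    (k - 1) degrees of freedom. If every observation is tied the statistic
    degenerates to H = 0, p = 1. Empty groups are an error.
    """
    if len(groups) < 2:
        raise ValueError("kruskal_wallis needs at least two groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    for i, a in enumerate(arrays):
        if a.size == 0:
            raise ValueError(f"group {i} is empty")
    pooled = np.concatenate(arrays)
    if pooled.size < 3:
        raise ValueError("kruskal_wallis needs a total of at least 3 observations")
    if np.ptp(pooled) == 0:
        return 0.0, 1.0
    h, p = _scipy_kruskal(*arrays)
    return float(h), float(p)


def compare_markers(
    table: pd.DataFrame,
    manifest: pd.DataFrame,
    markers: list[str],
    conditions: tuple[str, str] = ("precursor", "disease"),
    alpha: float = 0.05,
    unit: str = "cell",
) -> pd.DataFrame:
    """Per-marker precursor-vs-disease comparison of gated plasma cells.

    Pools PC-gated cells across the samples of each condition and runs the
    Kruskal-Wallis test per marker (``unit="cell"``, the default); with
    ``unit="sample"`` each sample contributes its PC mean instead, avoiding
    pseudo-replication at the cost of power. Significance is ``p <= alpha``
    with no multiplicity correction; the result is ranked by p-value
    (ties by marker order).
    """
    if unit not in ("cell", "sample"):
        raise ValueError("unit must be 'cell' or 'sample'")
    if "gate" not in table.columns:
        raise ValueError("table must be gated (run gate_populations)")
    cond_of = dict(zip(manifest["sample_id"], manifest["condition"]))
    pcs = table[table["gate"] == "PC"].copy()
    pcs["condition"] = pcs["sample_id"].map(cond_of)

    groups: dict[str, pd.DataFrame] = {}
    for cond in conditions:
        sub = pcs[pcs["condition"] == cond]
        if sub.empty:
            raise ValueError(f"no gated plasma cells for condition {cond!r}")
        groups[cond] = sub

    rows = []
    for m in markers:
        samples = []
        for cond in conditions:
            sub = groups[cond]
            if unit == "cell":
                samples.append(sub[m].to_numpy(dtype=float))
            else:
                samples.append(
                    sub.groupby("sample_id", sort=True)[m].mean().to_numpy()
                )
        h, p = kruskal_wallis(*samples)
        row = {"marker": m, "H": h, "p": p, "significant": p <= alpha}
        for cond, vals in zip(conditions, samples):
            row[f"n_{cond}"] = int(len(vals))
            row[f"mean_{cond}"] = float(np.mean(vals))
        rows.append(row)
    out = pd.DataFrame(rows)
    out = out.sort_values(["p", out.index.name or "marker"], kind="stable").reset_index(
        drop=True
    )
    out.attrs["note"] = NO_CORRECTION_NOTE
    out.attrs["unit"] = unit
    return out


@dataclass
class CorrelationResult:
    """Marker-marker Pearson matrix with its clustering."""

    correlation: pd.DataFrame
    linkage: np.ndarray
    leaf_order: list[str]


def marker_correlation(
    table: pd.DataFrame,
    markers: list[str],
    gate: str | None = "PC",
) -> CorrelationResult:
    """Pairwise Pearson correlation over (by default) gated plasma cells.

    Zero-variance markers get correlation 0 against everything (diagonal
    stays 1) with a warning. Clustering is average linkage on distance
    ``1 - r`` with scipy's deterministic leaf ordering.
    """
    if len(markers) < 2:
        raise ValueError("need at least two markers")
    sub = table if gate is None else table[table["gate"] == gate]
    if len(sub) < 3:
        raise ValueError("need at least three cells for correlation")
    x = sub[markers].to_numpy(dtype=float)
    sd = x.std(axis=0)
    degenerate = sd == 0
    if degenerate.any():
        logger.warning(
            "zero-variance markers in correlation: %s",
            [m for m, d in zip(markers, degenerate) if d],
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(x, rowvar=False)
    r = np.nan_to_num(r, nan=0.0)
    np.fill_diagonal(r, 1.0)
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    corr = pd.DataFrame(r, index=markers, columns=markers)
    dist = squareform(np.clip(1.0 - r, 0.0, None), checks=False)
    link = linkage(dist, method="average")
    order = [markers[i] for i in leaves_list(link)]
    return CorrelationResult(correlation=corr, linkage=link, leaf_order=order)


def microenvironment_profile(
    table: pd.DataFrame,
    manifest: pd.DataFrame,
    conditions: tuple[str, str] = ("precursor", "disease"),
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-sample cell-type percentages and a per-condition comparison.

    Percentages are 100 x type count / typed cells per sample (they sum to
    100). Samples with zero typed cells are excluded with a warning. The
    per-condition table reports mean +- population SD over sample
    percentages and a Kruskal-Wallis comparison across *conditions*.
    """
    if "cell_type" not in table.columns:
        raise ValueError("table must carry cell_type (run assign_cell_types)")
    cond_of = dict(zip(manifest["sample_id"], manifest["condition"]))
    rows = []
    for sid, sub in table.groupby("sample_id", sort=True):
        if len(sub) == 0:
            logger.warning("sample %s has zero typed cells; excluded", sid)
            continue
        counts = sub["cell_type"].value_counts()
        for t, c in counts.items():
            rows.append(
                {
                    "sample_id": sid,
                    "condition": cond_of.get(sid),
                    "cell_type": t,
                    "n_cells": int(c),
                    "percent": 100.0 * c / len(sub),
                }
            )
    per_sample = pd.DataFrame(rows)

    comp_rows = []
    for t in sorted(per_sample["cell_type"].unique()):
        sub = per_sample[per_sample["cell_type"] == t]
        by_cond = {}
        for cond in conditions:
            sids = [s for s, c in cond_of.items() if c == cond]
            vals = [
                float(sub.loc[sub["sample_id"] == s, "percent"].sum())
                for s in sids
                if s in set(per_sample["sample_id"])
            ]
            by_cond[cond] = np.asarray(vals)
        stats = {
            f"{cond}_{k}": v
            for cond, vals in by_cond.items()
            if len(vals)
            for k, v in (
                ("n", len(vals)),
                ("mean", float(vals.mean())),
                ("sd", float(vals.std())),
            )
        }
        row = {"cell_type": t, **stats}
        if all(len(v) for v in by_cond.values()):
            h, p = kruskal_wallis(*by_cond.values())
            row["H"] = h
            row["p"] = p
            row["significant"] = p <= alpha
        comp_rows.append(row)
    per_condition = pd.DataFrame(comp_rows)
    per_condition.attrs["note"] = NO_CORRECTION_NOTE
    return per_sample, per_condition


def embed_cells(
    table: pd.DataFrame,
    markers: list[str],
    seed: int = 0,
    perplexity: float | None = None,
) -> np.ndarray:
    """Seeded 2-D t-SNE embedding of cells over the named markers.

    Returns an (n, 2) coordinate array; identical input and seed give
    identical coordinates. Perplexity defaults to min(30, (n - 1) / 3).
    """
    if len(markers) < 1:
        raise ValueError("need at least one marker to embed")
    x = table[markers].to_numpy(dtype=float)
    n = len(x)
    if n < 2:
        raise ValueError("need at least two cells to embed")
    if perplexity is None:
        perplexity = min(30.0, max(1.0, (n - 1) / 3.0))
    tsne = TSNE(
        n_components=2,
        random_state=seed,
        perplexity=perplexity,
        init="pca",
        max_iter=500,
    )
    return tsne.fit_transform(x)
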