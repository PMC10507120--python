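"""Rare-cell detection on immunofluorescence frames.

The stage mirrors an outlier-clustering rare-cell workflow: segment nuclei on
the DAPI channel, extract a morphometric + intensity + texture feature
battery per cell, flag rare cells by PCA followed by hierarchical clustering
in component space (small clusters are rare), refine candidates with a
K-nearest-neighbor test, classify each DAPI+ cell by CD138/CD45 positivity,
enumerate the channel classes per sample and condition, and select
400 x 400 px regions of interest around plasma-cell-class cells for
downstream ion-count acquisition.

Everything here is deterministic: there is no unseeded randomness, ties are
broken by lowest index, and a fixed input frame yields an identical report
across runs.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.cluster.hierarchy import fcluster, linkage
from skimage.feature import graycomatrix, graycoprops, peak_local_max
from skimage.filters import gaussian, threshold_otsu
from skimage.measure import regionprops
from skimage.morphology import remove_small_objects
from skimage.segmentation import watershed
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

from liquidimc.datatypes import ImageStack

logger = logging.getLogger(__name__)

__all__ = [
    "FeatureMatrix",
    "segment_nuclei",
    "extract_features",
    "detect_rare",
    "knn_refine",
    "compute_channel_thresholds",
    "classify_cells",
    "enumerate_groups",
    "select_rois",
    "CHANNEL_CLASSES",
]

#: The four channel classes of DAPI+ cells.
CHANNEL_CLASSES = (
    "PC_CD45neg",  # DAPI+ CD138+ CD45-
    "PC_CD45pos",  # DAPI+ CD138+ CD45+
    "nonPC_hematopoietic",  # DAPI+ CD138- CD45+
    "DAPI_only",  # DAPI+ CD138- CD45-
)

PC_CLASSES = ("PC_CD45neg", "PC_CD45pos")


@dataclass
class FeatureMatrix:
    """Cells x features matrix with names and standardization parameters."""

    values: pd.DataFrame  # indexed by cell label
    feature_names: tuple[str, ...] = ()
    mean_: np.ndarray | None = None
    sd_: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not self.feature_names:
            self.feature_names = tuple(self.values.columns)
        if self.values.isna().any().any():
            raise ValueError("feature matrix contains missing values")

    @property
    def n_cells(self) -> int:
        return len(self.values)

    def standardized(self) -> np.ndarray:
        """Z-scored feature array; zero-variance features map to 0.

        The per-feature mean and SD used are stored on the instance.
        """
        x = self.values.to_numpy(dtype=float)
        self.mean_ = x.mean(axis=0)
        self.sd_ = x.std(axis=0)
        sd = np.where(self.sd_ > 0, self.sd_, 1.0)
        return (x - self.mean_) / sd


# ---------------------------------------------------------------------------
# segmentation


def segment_nuclei(
    dapi: np.ndarray,
    sigma: float = 1.5,
    min_area: int = 20,
    min_peak_distance: int = 5,
) -> np.ndarray:
    """Segment DAPI+ nuclei into a dense label mask.

    A Gaussian-smoothed Otsu threshold separates DAPI+ from DAPI- pixels;
    touching nuclei are split by a watershed on the distance transform
    seeded at its local maxima. Labels are dense from 1; a blank image
    yields zero labels.
    """
    dapi = np.asarray(dapi, dtype=float)
    if dapi.ndim != 2 or (dapi < 0).any():
        raise ValueError("dapi must be a 2-D non-negative image")
    smoothed = gaussian(dapi, sigma=sigma, preserve_range=True)
    if smoothed.max() <= 0 or np.allclose(smoothed, smoothed.flat[0]):
        return np.zeros(dapi.shape, dtype=np.int32)
    thr = threshold_otsu(smoothed)
    mask = smoothed > thr
    mask = remove_small_objects(mask, max_size=min_area - 1)
    if not mask.any():
        return np.zeros(dapi.shape, dtype=np.int32)
    distance = ndimage.distance_transform_edt(mask)
    peaks = peak_local_max(
        distance, min_distance=min_peak_distance, labels=mask, exclude_border=False
    )
    markers = np.zeros(dapi.shape, dtype=np.int32)
    for i, (y, x) in enumerate(peaks, start=1):
        markers[y, x] = i
    if markers.max() == 0:
        labels, _ = ndimage.label(mask)
        return labels.astype(np.int32)
    labels = watershed(-distance, markers, mask=mask)
    # merging/relabeling keeps ids dense from 1
    return _relabel_dense(labels)


def _relabel_dense(labels: np.ndarray) -> np.ndarray:
    ids = np.unique(labels)
    ids = ids[ids > 0]
    out = np.zeros_like(labels, dtype=np.int32)
    for new, old in enumerate(ids, start=1):
        out[labels == old] = new
    return out


# ---------------------------------------------------------------------------
# feature extraction

_SHAPE_FEATURES = (
    "area",
    "perimeter",
    "eccentricity",
    "solidity",
    "extent",
    "axis_major_length",
    "axis_minor_length",
)
_INTENSITY_STATS = ("mean", "total", "max", "sd", "q25", "median", "q75", "q90")
_GLCM_PROPS = ("contrast", "correlation", "energy", "homogeneity")
_GLCM_ANGLES = (0.0, np.pi / 4, np.pi / 2, 3 * np.pi / 4)


def extract_features(
    stack: ImageStack,
    labels: np.ndarray,
    texture: bool = True,
    glcm_levels: int = 16,
) -> FeatureMatrix:
    """Extract the per-cell morphometric / intensity / texture battery.

    Shape features (area, perimeter, eccentricity, solidity, extent, major
    and minor axis length) come from the label geometry; per channel, eight
    intensity statistics (mean, total, max, SD, quartiles and the 90th
    percentile) are computed over each cell's pixels; per channel, gray-level
    co-occurrence contrast/correlation/energy/homogeneity at four offsets
    describe texture. The battery size is configuration; the intent is to
    span the morphology + intensity space of much larger parameter sets.
    """
    if labels.shape != stack.shape:
        raise ValueError("labels and stack geometry differ")
    labels = np.asarray(labels)
    present = np.unique(labels)
    present = present[present > 0]
    rows: list[dict[str, float]] = []
    index: list[int] = []
    props = regionprops(labels)
    by_label = {p.label: p for p in props}
    for lab in present:
        p = by_label.get(int(lab))
        if p is None:
            raise ValueError(f"label {lab} absent from mask")
        row: dict[str, float] = {
            "area": float(p.area),
            "perimeter": float(p.perimeter),
            "eccentricity": float(p.eccentricity),
            "solidity": float(p.solidity),
            "extent": float(p.extent),
            "axis_major_length": float(p.axis_major_length),
            "axis_minor_length": float(p.axis_minor_length),
            "centroid_y": float(p.centroid[0]),
            "centroid_x": float(p.centroid[1]),
        }
        sl = p.slice
        region_mask = labels[sl] == lab
        for ch_name, plane in zip(stack.channels, stack.data):
            vals = np.asarray(plane[sl][region_mask], dtype=float)
            row[f"{ch_name}_mean"] = float(vals.mean())
            row[f"{ch_name}_total"] = float(vals.sum())
            row[f"{ch_name}_max"] = float(vals.max())
            row[f"{ch_name}_sd"] = float(vals.std())
            q25, med, q75, q90 = np.percentile(vals, [25, 50, 75, 90])
            row[f"{ch_name}_q25"] = float(q25)
            row[f"{ch_name}_median"] = float(med)
            row[f"{ch_name}_q75"] = float(q75)
            row[f"{ch_name}_q90"] = float(q90)
            if texture:
                row.update(_glcm_features(plane[sl], region_mask, ch_name, glcm_levels))
        rows.append(row)
        index.append(int(lab))
    df = pd.DataFrame(rows, index=pd.Index(index, name="label"))
    if df.empty:
        df = pd.DataFrame(columns=_empty_battery(stack.channels, texture))
    return FeatureMatrix(values=df)


def _glcm_features(
    patch: np.ndarray, region_mask: np.ndarray, ch_name: str, levels: int
) -> dict[str, float]:
    vals = np.asarray(patch, dtype=float)
    lo, hi = vals.min(), vals.max()
    if hi <= lo:
        quant = np.zeros(vals.shape, dtype=np.uint8)
    else:
        quant = ((vals - lo) / (hi - lo) * (levels - 1)).astype(np.uint8)
    quant = np.where(region_mask, quant + 1, 0).astype(np.uint8)  # 0 = outside
    glcm = graycomatrix(
        quant, distances=[1], angles=list(_GLCM_ANGLES), levels=levels + 1
    )
    glcm = glcm[1:, 1:]  # drop co-occurrences with outside-region pixels
    out: dict[str, float] = {}
    for prop in _GLCM_PROPS:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            vals4 = graycoprops(_renorm(glcm), prop)[0]
        for k, v in enumerate(vals4):
            out[f"{ch_name}_glcm_{prop}_{k}"] = float(np.nan_to_num(v))
    return out


def _renorm(glcm: np.ndarray) -> np.ndarray:
    glcm = glcm.astype(float)
    totals = glcm.sum(axis=(0, 1), keepdims=True)
    totals[totals == 0] = 1.0
    return glcm / totals


def _empty_battery(channels: tuple[str, ...], texture: bool) -> list[str]:
    cols = list(_SHAPE_FEATURES) + ["centroid_y", "centroid_x"]
    for ch in channels:
        cols += [f"{ch}_{s}" for s in _INTENSITY_STATS]
        if texture:
            cols += [
                f"{ch}_glcm_{p}_{k}" for p in _GLCM_PROPS for k in range(4)
            ]
    return cols


_NON_BATTERY = ("centroid_y", "centroid_x")


def _battery_array(features: FeatureMatrix) -> pd.DataFrame:
    """Feature columns that enter detection (centroids are bookkeeping)."""
    keep = [c for c in features.values.columns if c not in _NON_BATTERY]
    return features.values[keep]


# ---------------------------------------------------------------------------
# rare-cell detection


def detect_rare(
    features: FeatureMatrix,
    n_components: int = 350,
    rare_cluster_max_fraction: float = 0.01,
    n_clusters: int = 5,
) -> np.ndarray:
    """Flag rare cells by PCA + Ward hierarchical clustering.

    Features are standardized, projected onto the top ``n_components``
    principal components (capped at min(requested, n_features, n_cells)),
    and Ward-clustered; the tree is cut into ``n_clusters`` groups and any
    cluster of size <= ``rare_cluster_max_fraction * N`` is flagged rare.
    The procedure is deterministic: identical input yields identical flags.
    """
    n = features.n_cells
    if n < 2:
        raise ValueError("detect_rare requires at least 2 cells")
    battery = _battery_array(features)
    x = battery.to_numpy(dtype=float)
    sd = x.std(axis=0)
    if not (sd > 0).any():
        logger.warning("constant feature matrix: no rare cells can be flagged")
        return np.zeros(n, dtype=bool)
    mean = x.mean(axis=0)
    z = (x - mean) / np.where(sd > 0, sd, 1.0)
    features.mean_ = mean
    features.sd_ = sd

    k = min(n_components, z.shape[1], n)
    scores = PCA(n_components=k, svd_solver="full").fit_transform(z)
    link = linkage(scores, method="ward")
    assignments = fcluster(link, t=min(n_clusters, n), criterion="maxclust")
    sizes = np.bincount(assignments)
    rare_clusters = np.flatnonzero(sizes <= rare_cluster_max_fraction * n)
    flags = np.isin(assignments, rare_clusters)
    if flags.all():
        # every cluster small (tiny n): nothing is an outlier relative to the rest
        flags[:] = False
    return flags


def knn_refine(
    features: FeatureMatrix,
    candidates: np.ndarray,
    k: int = 5,
    distance_percentile: float = 99.0,
) -> np.ndarray:
    """Refine candidate rare flags by a K-nearest-neighbor test.

    A candidate is retained iff the majority of its *k* nearest neighbors
    (Euclidean distance in standardized feature space, self excluded) are
    also candidates, or its mean neighbor distance exceeds the given
    percentile of the non-candidate cells' mean neighbor distances. Ties in
    the majority vote break toward retention.
    """
    candidates = np.asarray(candidates, dtype=bool)
    n = features.n_cells
    if candidates.shape != (n,):
        raise ValueError("candidate flags must align with the feature matrix")
    if k < 1 or k >= n:
        raise ValueError(f"k must satisfy 1 <= k < n_cells (got k={k}, n={n})")
    if not candidates.any():
        return candidates.copy()
    z = features.standardized()
    nn = NearestNeighbors(n_neighbors=k + 1).fit(z)
    dist, idx = nn.kneighbors(z)
    dist, idx = dist[:, 1:], idx[:, 1:]  # drop self
    mean_dist = dist.mean(axis=1)
    inlier_mean = mean_dist[~candidates]
    cutoff = (
        np.percentile(inlier_mean, distance_percentile)
        if inlier_mean.size
        else -np.inf
    )
    refined = np.zeros(n, dtype=bool)
    for i in np.flatnonzero(candidates):
        votes = candidates[idx[i]].sum()
        if 2 * votes >= k or mean_dist[i] > cutoff:
            refined[i] = True
    return refined


# ---------------------------------------------------------------------------
# channel classification


def compute_channel_thresholds(
    stack: ImageStack,
    labels: np.ndarray,
    n_sd: float = 3.0,
) -> dict[str, float]:
    """Per-frame positivity thresholds: non-cell background mean + n_sd x SD.

    The SD is the population convention (divide by N) over non-cell pixels.
    """
    non_cell = labels == 0
    if not non_cell.any():
        raise ValueError("no non-cell pixels to estimate background from")
    out = {}
    for name, plane in zip(stack.channels, stack.data):
        bg = np.asarray(plane[non_cell], dtype=float)
        out[name] = float(bg.mean() + n_sd * bg.std())
    return out


def classify_cells(
    features: FeatureMatrix,
    thresholds: dict[str, float],
    dapi_channel: str = "DAPI",
    cd138_channel: str = "CD138",
    cd45_channel: str = "CD45",
    rare_flags: np.ndarray | None = None,
    distinct_percentile: float = 98.0,
) -> pd.DataFrame:
    """Assign each DAPI+ cell to exactly one of the four channel classes.

    Cells whose DAPI mean intensity is below threshold are excluded (not an
    error). ``morphologically_distinct`` marks cells whose area or
    eccentricity exceeds the given percentile of the surrounding
    CD45+CD138- white-blood-cell population.
    """
    df = features.values
    dapi_pos = df[f"{dapi_channel}_mean"] >= thresholds[dapi_channel]
    cd138_pos = df[f"{cd138_channel}_mean"] >= thresholds[cd138_channel]
    cd45_pos = df[f"{cd45_channel}_mean"] >= thresholds[cd45_channel]

    cls = np.where(
        cd138_pos,
        np.where(cd45_pos, "PC_CD45pos", "PC_CD45neg"),
        np.where(cd45_pos, "nonPC_hematopoietic", "DAPI_only"),
    )
    out = pd.DataFrame(
        {
            "label": df.index.to_numpy(),
            "centroid_y": df["centroid_y"].to_numpy(),
            "centroid_x": df["centroid_x"].to_numpy(),
            "area": df["area"].to_numpy(),
            "eccentricity": df["eccentricity"].to_numpy(),
            "channel_class": cls,
            "rare": (
                np.asarray(rare_flags, dtype=bool)
                if rare_flags is not None
                else np.zeros(len(df), dtype=bool)
            ),
        }
    )
    wbc = out[(out["channel_class"] == "nonPC_hematopoietic")]
    if len(wbc):
        area_cut = np.percentile(wbc["area"], distinct_percentile)
        ecc_cut = np.percentile(wbc["eccentricity"], distinct_percentile)
    else:
        area_cut = ecc_cut = np.inf
    out["morphologically_distinct"] = (out["area"] > area_cut) | (
        out["eccentricity"] > ecc_cut
    )
    return out[np.asarray(dapi_pos)].reset_index(drop=True)


# ---------------------------------------------------------------------------
# enumeration


def enumerate_groups(
    classified: pd.DataFrame,
    manifest: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-sample class counts and per-condition mean +- population SD.

    *classified* must carry a ``sample_id`` column plus ``channel_class`` and
    ``rare``; *manifest* maps every sample id to a condition. Returns
    ``(per_sample, per_condition)`` tables. A sample in *classified* that is
    missing from the manifest is a consistency error.
    """
    if "sample_id" not in classified.columns:
        raise ValueError("classified cells need a sample_id column")
    known = set(manifest["sample_id"])
    unknown = sorted(set(classified["sample_id"]) - known)
    if unknown:
        raise ValueError(f"samples missing from manifest: {unknown}")

    rows = []
    for _, m in manifest.iterrows():
        sub = classified[classified["sample_id"] == m["sample_id"]]
        row = {"sample_id": m["sample_id"], "condition": m["condition"]}
        for cls in CHANNEL_CLASSES:
            row[cls] = int((sub["channel_class"] == cls).sum())
        row["total_rare"] = int(sub["rare"].sum())
        row["total_cells"] = int(len(sub))
        rows.append(row)
    per_sample = pd.DataFrame(rows)

    cond_rows = []
    for cond, grp in per_sample.groupby("condition", sort=True):
        for cls in CHANNEL_CLASSES + ("total_rare",):
            vals = grp[cls].to_numpy(dtype=float)
            cond_rows.append(
                {
                    "condition": cond,
                    "group": cls,
                    "n_samples": len(vals),
                    "mean": float(vals.mean()),
                    "sd": float(vals.std()),  # population convention
                }
            )
    per_condition = pd.DataFrame(cond_rows)
    return per_sample, per_condition


# ---------------------------------------------------------------------------
# ROI selection


def select_rois(
    classified: pd.DataFrame,
    frame_shape: tuple[int, int],
    roi_px: int = 400,
    target_wbc: int = 300,
) -> pd.DataFrame:
    """Greedy ROI placement: one ROI per unassigned plasma-cell-class cell.

    Each box is centered on the seed cell then shifted within frame bounds to
    maximize the number of contained white blood cells up to ``target_wbc``
    (ties break toward the smallest shift, then lowest index order). ROIs are
    half-open boxes ``[x0, x1) x [y0, y1)``; no two ROIs share a
    plasma-cell-class cell, and every ROI contains at least one.
    """
    h, w = frame_shape
    is_pc = classified["channel_class"].isin(PC_CLASSES).to_numpy()
    is_wbc = (classified["channel_class"] == "nonPC_hematopoietic").to_numpy()
    ys = classified["centroid_y"].to_numpy()
    xs = classified["centroid_x"].to_numpy()
    assigned = np.zeros(len(classified), dtype=bool)
    rois = []
    roi_id = 0
    shifts = [0, -roi_px // 4, roi_px // 4, -roi_px // 2, roi_px // 2]
    for i in np.flatnonzero(is_pc):
        if assigned[i]:
            continue
        best = None
        for dy in shifts:
            for dx in shifts:
                y0 = int(np.clip(ys[i] - roi_px / 2 + dy, 0, max(h - roi_px, 0)))
                x0 = int(np.clip(xs[i] - roi_px / 2 + dx, 0, max(w - roi_px, 0)))
                y1, x1 = min(y0 + roi_px, h), min(x0 + roi_px, w)
                inside = (ys >= y0) & (ys < y1) & (xs >= x0) & (xs < x1)
                if not inside[i]:
                    continue
                n_wbc = min(int((inside & is_wbc).sum()), target_wbc)
                if best is None or n_wbc > best[0]:
                    best = (n_wbc, x0, y0, x1, y1, inside)
        if best is None:
            continue
        _, x0, y0, x1, y1, inside = best
        roi_id += 1
        members = inside & is_pc & ~assigned
        assigned |= members
        rois.append(
            {
                "roi_id": roi_id,
                "x0": x0,
                "y0": y0,
                "x1": x1,
                "y1": y1,
                "n_pc": int(members.sum()),
                "n_wbc": int((inside & is_wbc).sum()),
                "cell_labels": ";".join(
                    str(v) for v in classified.loc[members, "label"].tolist()
                ),
            }
        )
    return pd.DataFrame(
        rois,
        columns=["roi_id", "x0", "y0", "x1", "y1", "n_pc", "n_wbc", "cell_labels"],
    )
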