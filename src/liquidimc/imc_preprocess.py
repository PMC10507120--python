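"""Ion-count ROI preparation: hot pixels, upscaling, pixel classes, masks.

The fixed stage order is hot-pixel removal -> 2x upscaling -> pixel
classification -> cell-mask generation; :func:`preprocess_roi` runs and logs
it. The pixel classifier is a seeded, scriptable stand-in for an interactive
trainable classifier with the same contract: per-pixel features are the raw
channel values plus Gaussian-smoothed values and gradient magnitudes at two
scales, and the output is a calibrated per-pixel probability for each of
nuclei / membrane / background, normalized to sum to one.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.filters import gaussian
from skimage.measure import label as cc_label
from skimage.segmentation import watershed
from skimage.transform import resize
from sklearn.ensemble import RandomForestClassifier

from liquidimc.datatypes import ImageStack

logger = logging.getLogger(__name__)

__all__ = [
    "remove_hot_pixels",
    "upscale",
    "PixelClassifier",
    "train_pixel_classifier",
    "apply_pixel_classifier",
    "ProbabilityMasks",
    "CellMask",
    "make_cell_masks",
    "preprocess_roi",
]

PIXEL_CLASSES = ("nuclei", "membrane", "background")


# ---------------------------------------------------------------------------
# hot pixels


def remove_hot_pixels(stack: ImageStack, k_mad: float = 5.0) -> ImageStack:
    """Replace isolated extreme pixels by their 3x3 neighborhood median.

    A pixel is hot when it exceeds ``median3x3 + k_mad * scale`` *and* stands
    clear of its 8-neighborhood maximum by the same margin. The noise scale
    is the channel's scaled median absolute deviation (MAD x 1.4826), floored
    at the local Poisson scale ``sqrt(median3x3 + 1)``; the floor keeps the
    rule meaningful on sparse count images, where more than half the pixels
    are zero and the raw channel MAD degenerates to 0. The neighborhood-
    maximum condition distinguishes isolated detector artifacts from the
    bright edges of genuine single-pixel-wide structure, whose neighbors
    share the signal. All non-flagged pixels are returned unchanged; the
    operation is idempotent in practice because replacements sit at the
    local median.
    """
    data = stack.data.astype(np.float64, copy=True)
    ring = np.ones((3, 3), dtype=bool)
    ring[1, 1] = False
    for ch in range(data.shape[0]):
        plane = data[ch]
        # "mirror" keeps a border pixel out of its own neighborhood
        med = ndimage.median_filter(plane, size=3, mode="mirror")
        nbr_max = ndimage.maximum_filter(plane, footprint=ring, mode="mirror")
        channel_mad = 1.4826 * np.median(np.abs(plane - np.median(plane)))
        scale = np.maximum(channel_mad, np.sqrt(med + 1.0))
        margin = k_mad * scale
        hot = (plane > med + margin) & (plane > nbr_max + margin)
        plane[hot] = med[hot]
    return ImageStack(data.astype(stack.data.dtype, copy=False), stack.channels)


# ---------------------------------------------------------------------------
# upscaling


def upscale(stack: ImageStack, factor: int = 2) -> ImageStack:
    """Bilinear upscaling that conserves per-channel total counts.

    Intensities are rescaled by ``1 / factor**2`` and renormalized so each
    channel's total is exactly conserved (a blank channel stays blank).
    """
    if int(factor) != factor or factor < 1:
        raise ValueError("factor must be an integer >= 1")
    factor = int(factor)
    if factor == 1:
        return stack.copy()
    h, w = stack.shape
    out = np.empty((stack.data.shape[0], h * factor, w * factor), dtype=np.float64)
    for ch in range(stack.data.shape[0]):
        plane = stack.data[ch].astype(np.float64)
        up = resize(
            plane,
            (h * factor, w * factor),
            order=1,
            anti_aliasing=False,
            preserve_range=True,
        ) / (factor**2)
        total = plane.sum()
        up_total = up.sum()
        if total > 0 and up_total > 0:
            up *= total / up_total
        out[ch] = up
    return ImageStack(out, stack.channels)


# ---------------------------------------------------------------------------
# pixel classification


@dataclass
class PixelClassifier:
    """Trained per-pixel classifier state with its feature configuration."""

    model: RandomForestClassifier
    channels: tuple[int, ...]
    sigmas: tuple[float, float] = (1.0, 2.0)
    seed: int = 0

    @property
    def metadata(self) -> dict:
        return {
            "channels": list(self.channels),
            "sigmas": list(self.sigmas),
            "seed": self.seed,
            "classes": list(PIXEL_CLASSES),
            "n_estimators": self.model.n_estimators,
        }


def _pixel_features(
    stack: ImageStack, channels: tuple[int, ...], sigmas: tuple[float, float]
) -> np.ndarray:
    """(H*W, n_features) per-pixel feature array.

    Per selected channel: raw value, Gaussian-smoothed value and gradient
    magnitude at each of two scales.
    """
    feats: list[np.ndarray] = []
    for ch in channels:
        plane = stack.data[ch].astype(np.float64)
        feats.append(plane)
        for s in sigmas:
            sm = gaussian(plane, sigma=s, preserve_range=True)
            feats.append(sm)
            gy, gx = np.gradient(sm)
            feats.append(np.hypot(gy, gx))
    return np.stack([f.ravel() for f in feats], axis=1)


def train_pixel_classifier(
    stacks: list[ImageStack],
    label_images: list[np.ndarray],
    seed: int = 0,
    channels: tuple[int, ...] | None = None,
    sigmas: tuple[float, float] = (1.0, 2.0),
    n_estimators: int = 50,
    max_train_pixels: int = 200_000,
) -> PixelClassifier:
    """Train the pixel classifier from sparse labels.

    *label_images* align with *stacks*; pixel labels are 0 (unlabeled),
    1 = nuclei, 2 = membrane, 3 = background. All three classes must be
    present. The classifier is a random forest with a fixed seed, so
    training and prediction are deterministic.
    """
    if len(stacks) != len(label_images):
        raise ValueError("stacks and label images must align")
    if not stacks:
        raise ValueError("at least one training stack is required")
    channels = (
        tuple(range(stacks[0].data.shape[0])) if channels is None else tuple(channels)
    )
    xs, ys = [], []
    for stack, lab in zip(stacks, label_images):
        lab = np.asarray(lab)
        if lab.shape != stack.shape:
            raise ValueError("label image geometry differs from stack")
        feats = _pixel_features(stack, channels, sigmas)
        sel = lab.ravel() > 0
        xs.append(feats[sel])
        ys.append(lab.ravel()[sel])
    x = np.concatenate(xs)
    y = np.concatenate(ys)
    for class_id, name in enumerate(PIXEL_CLASSES, start=1):
        if not (y == class_id).any():
            raise ValueError(f"training labels contain no {name!r} pixels")
    if len(y) > max_train_pixels:
        rng = np.random.default_rng(seed)
        keep = rng.choice(len(y), size=max_train_pixels, replace=False)
        keep.sort()
        x, y = x[keep], y[keep]
    model = RandomForestClassifier(
        n_estimators=n_estimators,
        random_state=seed,
        n_jobs=1,
        min_samples_leaf=2,
    )
    model.fit(x, y)
    return PixelClassifier(model=model, channels=channels, sigmas=sigmas, seed=seed)


@dataclass
class ProbabilityMasks:
    """Per-pixel class probabilities; the three planes sum to 1 everywhere."""

    nuclei: np.ndarray
    membrane: np.ndarray
    background: np.ndarray

    def __post_init__(self) -> None:
        total = self.nuclei + self.membrane + self.background
        if not np.allclose(total, 1.0, atol=1e-6):
            raise ValueError("class probabilities must sum to 1 at every pixel")


def apply_pixel_classifier(
    stack: ImageStack, clf: PixelClassifier
) -> ProbabilityMasks:
    """Predict nuclei/membrane/background probabilities for every pixel."""
    feats = _pixel_features(stack, clf.channels, clf.sigmas)
    proba = clf.model.predict_proba(feats)
    h, w = stack.shape
    planes = {name: np.zeros((h, w)) for name in PIXEL_CLASSES}
    for col, class_id in enumerate(clf.model.classes_):
        planes[PIXEL_CLASSES[int(class_id) - 1]] = proba[:, col].reshape(h, w)
    total = sum(planes.values())
    total[total == 0] = 1.0
    return ProbabilityMasks(
        nuclei=planes["nuclei"] / total,
        membrane=planes["membrane"] / total,
        background=planes["background"] / total,
    )


# ---------------------------------------------------------------------------
# cell masks


@dataclass
class CellMask:
    """Watershed cell territories with nuclear seeds and the negative mask."""

    cell_labels: np.ndarray
    nucleus_labels: np.ndarray
    negative_mask: np.ndarray

    @property
    def n_cells(self) -> int:
        return int(self.cell_labels.max())

    def validate(self) -> None:
        ids = np.unique(self.cell_labels)
        ids = ids[ids > 0]
        if len(ids) and not np.array_equal(ids, np.arange(1, len(ids) + 1)):
            raise ValueError("cell labels must be dense 1..N")
        if np.any(self.negative_mask & (self.cell_labels > 0)):
            raise ValueError("negative mask overlaps cell territories")


def make_cell_masks(
    probs: ProbabilityMasks,
    nuclear_threshold: float = 0.5,
    background_threshold: float = 0.5,
    min_nucleus_area: int = 9,
) -> CellMask:
    """Segment cell territories from probability masks.

    Nuclei are connected components of thresholded nuclear probability;
    territories grow by watershed over ``1 - P(background)`` seeded at the
    nuclei and stop where ``P(background) > background_threshold``; the
    negative mask is exactly that background region. Zero nuclei yield an
    empty (but valid) mask with a full negative mask.
    """
    nuc_mask = probs.nuclei > nuclear_threshold
    nucleus_labels = cc_label(nuc_mask).astype(np.int32)
    if min_nucleus_area > 1 and nucleus_labels.max():
        sizes = np.bincount(nucleus_labels.ravel())
        small = np.flatnonzero(sizes < min_nucleus_area)
        nucleus_labels[np.isin(nucleus_labels, small[small > 0])] = 0
        nucleus_labels = _dense(nucleus_labels)
    negative = probs.background > background_threshold
    if nucleus_labels.max() == 0:
        return CellMask(
            cell_labels=np.zeros_like(nucleus_labels),
            nucleus_labels=nucleus_labels,
            negative_mask=np.ones_like(negative, dtype=bool),
        )
    cells = watershed(
        -(1.0 - probs.background), nucleus_labels, mask=~negative
    ).astype(np.int32)
    cells = _dense(cells)
    mask = CellMask(
        cell_labels=cells,
        nucleus_labels=nucleus_labels,
        negative_mask=negative & (cells == 0),
    )
    mask.validate()
    return mask


def _dense(labels: np.ndarray) -> np.ndarray:
    ids = np.unique(labels)
    ids = ids[ids > 0]
    lut = np.zeros(labels.max() + 1 if labels.size else 1, dtype=np.int32)
    lut[ids] = np.arange(1, len(ids) + 1)
    return lut[labels]


# ---------------------------------------------------------------------------
# pipeline wrapper


def preprocess_roi(
    stack: ImageStack,
    clf: PixelClassifier,
    k_mad: float = 5.0,
    factor: int = 2,
) -> tuple[ImageStack, ProbabilityMasks, CellMask]:
    """Run the fixed stage order on one ROI and return every intermediate.

    Order: remove_hot_pixels -> upscale -> classify -> masks.
    """
    logger.info(
        "preprocess_roi: remove_hot_pixels(k_mad=%s) -> upscale(%dx) -> "
        "classify -> masks (watershed to background)",
        k_mad,
        factor,
    )
    cleaned = remove_hot_pixels(stack, k_mad=k_mad)
    scaled = upscale(cleaned, factor=factor)
    probs = apply_pixel_classifier(scaled, clf)
    masks = make_cell_masks(probs)
    return scaled, probs, masks
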