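"""Reading and writing pipeline artifacts.

Images travel as multi-page TIFF (one page per channel, channel name in the
page description); ground truth as a cell CSV plus a JSON sidecar holding hot
pixels, background levels and the seed; cohort manifests as CSV with columns
``sample_id``, ``condition`` and artifact paths.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from liquidimc.datatypes import ImageStack, SyntheticGroundTruth

__all__ = [
    "write_stack",
    "read_stack",
    "write_ground_truth",
    "read_ground_truth",
    "write_manifest",
    "read_manifest",
]


def write_stack(path: str | Path, stack: ImageStack) -> None:
    """Write *stack* as a multi-page TIFF, channel names in page metadata."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with tifffile.TiffWriter(path) as tif:
        for name, plane in zip(stack.channels, stack.data):
            tif.write(plane, description=name, contiguous=False)


def read_stack(path: str | Path) -> ImageStack:
    """Read a multi-page TIFF written by :func:`write_stack`."""
    planes: list[np.ndarray] = []
    names: list[str] = []
    with tifffile.TiffFile(path) as tif:
        for i, page in enumerate(tif.pages):
            planes.append(page.asarray())
            names.append(page.description or f"channel_{i}")
    return ImageStack(np.stack(planes), tuple(names))


def write_ground_truth(prefix: str | Path, truth: SyntheticGroundTruth) -> None:
    """Write cells as ``<prefix>.cells.csv`` and a ``<prefix>.meta.json`` sidecar."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    truth.cells.to_csv(prefix.with_suffix(".cells.csv"), index=False)
    meta = {
        "seed": int(truth.seed),
        "shape": list(truth.shape),
        "background": {k: float(v) for k, v in truth.background.items()},
        "hot_pixels": truth.hot_pixels.to_dict(orient="list"),
    }
    with open(prefix.with_suffix(".meta.json"), "w") as fh:
        json.dump(meta, fh, indent=1, sort_keys=True)


def read_ground_truth(prefix: str | Path) -> SyntheticGroundTruth:
    prefix = Path(prefix)
    cells = pd.read_csv(prefix.with_suffix(".cells.csv"))
    with open(prefix.with_suffix(".meta.json")) as fh:
        meta = json.load(fh)
    hot = pd.DataFrame(meta["hot_pixels"])
    if hot.empty:
        hot = pd.DataFrame(columns=["channel", "y", "x", "value"])
    return SyntheticGroundTruth(
        cells=cells,
        hot_pixels=hot,
        background=meta["background"],
        seed=meta["seed"],
        shape=tuple(meta["shape"]),
    )


def write_manifest(path: str | Path, manifest: pd.DataFrame) -> None:
    required = {"sample_id", "condition"}
    missing = required - set(manifest.columns)
    if missing:
        raise ValueError(f"manifest missing columns: {sorted(missing)}")
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    manifest.to_csv(path, index=False)


def read_manifest(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
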