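#!/usr/bin/env python
"""Preprocess and quantify the simulated ion-count ROIs.

Pipeline order (fixed): hot-pixel removal -> 2x count-conserving upscaling
-> seeded pixel classification (nuclei / membrane / background) -> watershed
cell masks -> per-cell mean ion counts -> negative-mask background
subtraction -> DNA-signal filter. The pixel classifier is trained once on
the first ROI's truth-derived sparse labels, then batch-applied.

    python analysis/03_segment_and_quantify.py --cohort results/cohort --out results/quantify
"""

from __future__ import annotations

import argparse
import json
from pathlib import Path

import pandas as pd

from liquidimc import imc_preprocess, imc_quant, io
from liquidimc.panel import default_panel
from liquidimc.pipeline import training_labels_from_truth


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--cohort", type=Path, default=Path("results/cohort"))
    parser.add_argument("--out", type=Path, default=Path("results/quantify"))
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--k-mad", type=float, default=5.0)
    parser.add_argument("--upscale", type=int, default=2)
    args = parser.parse_args()

    panel = default_panel()
    manifest = io.read_manifest(args.cohort / "manifest.csv")
    roi_paths = [
        (row["sample_id"], i, args.cohort / rel)
        for _, row in manifest.iterrows()
        for i, rel in enumerate(str(row["imc_rois"]).split(";"))
    ]

    # train the pixel classifier on the first ROI
    sid0, _, path0 = roi_paths[0]
    stack0 = io.read_stack(path0)
    truth0 = io.read_ground_truth(path0.with_suffix(""))
    cleaned0 = imc_preprocess.remove_hot_pixels(stack0, k_mad=args.k_mad)
    scaled0 = imc_preprocess.upscale(cleaned0, factor=args.upscale)
    labels0 = training_labels_from_truth(truth0, factor=args.upscale)
    channels = tuple(
        panel.index(m) for m in ("DNA1", "DNA2", "CD45", "CD138", "CD38")
    )
    clf = imc_preprocess.train_pixel_classifier(
        [scaled0], [labels0], seed=args.seed, channels=channels
    )
    print(f"trained pixel classifier on {sid0} ROI 0: {clf.metadata}")

    tables, backgrounds = [], {}
    for sid, roi_id, path in roi_paths:
        stack = io.read_stack(path)
        scaled, _, masks = imc_preprocess.preprocess_roi(
            stack, clf, k_mad=args.k_mad, factor=args.upscale
        )
        raw = imc_quant.quantify(scaled, masks, sample_id=sid, roi_id=roi_id)
        corrected, bg = imc_quant.subtract_background(raw, scaled, masks)
        backgrounds[f"{sid}/{roi_id}"] = bg
        tables.append(imc_quant.filter_cells(corrected))
        print(f"{sid} ROI {roi_id}: {masks.n_cells} cells segmented")

    expression = pd.concat(tables, ignore_index=True)
    args.out.mkdir(parents=True, exist_ok=True)
    expression.to_csv(args.out / "expression_raw.csv", index=False)
    with open(args.out / "background_log.json", "w") as fh:
        json.dump(backgrounds, fh, indent=1, sort_keys=True)
    print(f"\nquantified {len(expression)} cells -> {args.out / 'expression_raw.csv'}")


if __name__ == "__main__":
    main()
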