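#!/usr/bin/env python
"""Simulate a desk-scale myeloma-spectrum cohort with ground truth.

Writes, per sample, one 3-channel immunofluorescence frame and one
multi-channel ion-count ROI (multi-page TIFF), the ground-truth cell tables
with JSON sidecars, and a cohort manifest mapping samples to conditions.

    python analysis/01_simulate_cohort.py --out results/cohort --seed 1
"""

from __future__ import annotations

import argparse
from pathlib import Path

from liquidimc import io
from liquidimc.profiles import CohortConfig
from liquidimc.synthetic import IFFrameParams, generate_cohort


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--out", type=Path, default=Path("results/cohort"))
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--n-cells", type=int, default=400, help="cells per IF frame")
    parser.add_argument("--pc-fraction", type=float, default=0.05)
    parser.add_argument("--frame-px", type=int, default=700)
    parser.add_argument("--roi-px", type=int, default=200)
    parser.add_argument("--imc-cells", type=int, default=70, help="cells per ROI")
    args = parser.parse_args()

    config = CohortConfig.default(
        seed=args.seed, n_cells=args.n_cells, pc_fraction=args.pc_fraction
    )
    cohort = generate_cohort(
        config,
        if_params=IFFrameParams(shape=(args.frame_px, args.frame_px)),
        roi_px=(args.roi_px, args.roi_px),
        imc_cells_per_roi=args.imc_cells,
    )

    manifest = cohort.manifest.copy()
    if_paths, roi_paths = [], []
    for sample in cohort.samples:
        sdir = args.out / sample.sample_id
        fp, rp = [], []
        for i, (stack, truth) in enumerate(sample.if_frames):
            path = sdir / f"if_frame_{i}.tiff"
            io.write_stack(path, stack)
            io.write_ground_truth(sdir / f"if_frame_{i}", truth)
            fp.append(str(path.relative_to(args.out)))
        for i, (stack, truth) in enumerate(sample.imc_rois):
            path = sdir / f"imc_roi_{i}.tiff"
            io.write_stack(path, stack)
            io.write_ground_truth(sdir / f"imc_roi_{i}", truth)
            rp.append(str(path.relative_to(args.out)))
        if_paths.append(";".join(fp))
        roi_paths.append(";".join(rp))
    manifest["if_frames"] = if_paths
    manifest["imc_rois"] = roi_paths
    io.write_manifest(args.out / "manifest.csv", manifest)

    n_cells = sum(t.n_cells for s in cohort.samples for _, t in s.if_frames)
    n_rois = sum(len(s.imc_rois) for s in cohort.samples)
    print(
        f"simulated {len(cohort.samples)} samples: {n_cells} IF cells, "
        f"{n_rois} ion-count ROIs -> {args.out}"
    )
    print(manifest[["sample_id", "condition"]].to_string(index=False))


if __name__ == "__main__":
    main()
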