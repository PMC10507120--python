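#!/usr/bin/env python
"""Normalize, gate and statistically compare the quantified cohort.

Takes the per-cell table from 03_segment_and_quantify.py, scales every
marker to [0, 1] cohort-wide, gates plasma cells (CD138+CD38+) and control
WBCs (CD45+CD138-CD38-), assigns microenvironment cell types, and runs the
per-marker precursor-vs-disease Kruskal-Wallis comparison, the marker-marker
Pearson correlation with average-linkage clustering, the microenvironment
composition comparison, and a seeded 2-D embedding of plasma cells over the
clinical markers.

    python analysis/04_compare_markers.py --quantify results/quantify \
        --cohort results/cohort --out results/compare --seed 1
"""

from __future__ import annotations

import argparse
import json
from pathlib import Path

import pandas as pd

from liquidimc import io
from liquidimc.pipeline import run_comparison
from liquidimc.stats import NO_CORRECTION_NOTE


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--quantify", type=Path, default=Path("results/quantify"))
    parser.add_argument("--cohort", type=Path, default=Path("results/cohort"))
    parser.add_argument("--out", type=Path, default=Path("results/compare"))
    parser.add_argument("--alpha", type=float, default=0.05)
    parser.add_argument("--seed", type=int, default=1)
    args = parser.parse_args()

    table = pd.read_csv(args.quantify / "expression_raw.csv")
    manifest = io.read_manifest(args.cohort / "manifest.csv")
    res = run_comparison(
        table, manifest, alpha=args.alpha, seed=args.seed, embed=True
    )

    args.out.mkdir(parents=True, exist_ok=True)
    res["table"].to_csv(args.out / "expression_table.csv", index=False)
    res["comparison"].to_csv(args.out / "marker_comparison.csv", index=False)
    corr = res["correlation"]
    corr.correlation.to_csv(args.out / "marker_correlation.csv")
    with open(args.out / "marker_clustering.json", "w") as fh:
        json.dump(
            {
                "linkage": corr.linkage.tolist(),
                "leaf_order": corr.leaf_order,
                "method": "average linkage on 1 - Pearson r",
            },
            fh,
            indent=1,
        )
    res["micro_per_sample"].to_csv(
        args.out / "microenvironment_per_sample.csv", index=False
    )
    res["micro_per_condition"].to_csv(
        args.out / "microenvironment_per_condition.csv", index=False
    )
    with open(args.out / "gate_thresholds.json", "w") as fh:
        json.dump(res["thresholds"], fh, indent=1, sort_keys=True)
    if "embedding" in res:
        pd.DataFrame(res["embedding"], columns=["tsne_1", "tsne_2"]).to_csv(
            args.out / "pc_embedding.csv", index=False
        )

    comp = res["comparison"]
    print(f"# {NO_CORRECTION_NOTE}")
    print("\nper-marker precursor-vs-disease comparison (ranked by p):")
    print(
        comp[["marker", "H", "p", "significant", "mean_precursor", "mean_disease"]]
        .round(4)
        .to_string(index=False)
    )
    gates = res["table"]["gate"].value_counts().to_dict()
    print(f"\ngate counts: {gates}")
    print(f"outputs -> {args.out}")


if __name__ == "__main__":
    main()
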