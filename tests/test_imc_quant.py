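"""Quantification, background correction, normalization and gating."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from liquidimc import imc_quant as q
from liquidimc.datatypes import ImageStack
from liquidimc.imc_preprocess import CellMask
from liquidimc.panel import default_panel


def _mask_from_labels(labels):
    labels = np.asarray(labels, dtype=np.int32)
    return CellMask(
        cell_labels=labels,
        nucleus_labels=labels,
        negative_mask=labels == 0,
    )


def _random_fixture(rng, n_channels=3, n_cells=4, size=10):
    labels = np.zeros((size, size), dtype=np.int32)
    cells = rng.choice(size * size, size=n_cells * 8, replace=False)
    for i, flat in enumerate(cells):
        labels.flat[flat] = (i % n_cells) + 1
    data = rng.poisson(5, (n_channels, size, size)).astype(float)
    names = tuple(f"ch{i}" for i in range(n_channels))
    return ImageStack(data, names), _mask_from_labels(labels)


class TestQuantify:
    def test_uniform_channel_gives_constant_mean(self):
        labels = np.zeros((12, 12), dtype=np.int32)
        labels[2:5, 2:5] = 1
        labels[7:10, 7:10] = 2
        stack = ImageStack(np.full((1, 12, 12), 3.5), ("m",))
        out = q.quantify(stack, _mask_from_labels(labels))
        assert np.allclose(out["m"], 3.5)

    def test_matches_pixel_loop_oracle_exactly(self, rng):
        for _ in range(20):
            stack, masks = _random_fixture(rng)
            out = q.quantify(stack, masks)
            for _, row in out.iterrows():
                sel = masks.cell_labels == row["cell_id"]
                for ch in stack.channels:
                    expected = stack.channel(ch)[sel].sum() / sel.sum()
                    assert row[ch] == expected

    def test_empty_mask_empty_table(self):
        stack = ImageStack(np.zeros((2, 6, 6)), ("a", "b"))
        out = q.quantify(stack, _mask_from_labels(np.zeros((6, 6))))
        assert len(out) == 0

    def test_geometry_mismatch_error(self, rng):
        stack, _ = _random_fixture(rng)
        with pytest.raises(ValueError):
            q.quantify(stack, _mask_from_labels(np.zeros((3, 3))))


class TestSubtractBackground:
    def test_cell_equal_to_background_clamps_to_zero(self):
        labels = np.zeros((10, 10), dtype=np.int32)
        labels[4:6, 4:6] = 1
        stack = ImageStack(np.full((1, 10, 10), 2.0), ("m",))
        masks = _mask_from_labels(labels)
        raw = q.quantify(stack, masks)
        corrected, bg = q.subtract_background(raw, stack, masks)
        assert bg["m"] == pytest.approx(2.0)
        assert np.allclose(corrected["m"], 0.0)

    def test_zero_background_is_identity(self):
        labels = np.zeros((10, 10), dtype=np.int32)
        labels[4:6, 4:6] = 1
        data = np.zeros((1, 10, 10))
        data[0, 4:6, 4:6] = 7.0
        stack = ImageStack(data, ("m",))
        masks = _mask_from_labels(labels)
        raw = q.quantify(stack, masks)
        corrected, bg = q.subtract_background(raw, stack, masks)
        assert bg["m"] == 0.0
        assert np.allclose(corrected["m"], raw["m"])

    def test_background_recovered_within_standard_error(self, preprocessed_roi):
        scaled, truth, _, _, masks = preprocessed_roi
        raw = q.quantify(scaled, masks)
        _, bg = q.subtract_background(raw, scaled, masks)
        # the 2x-upscaled image spreads each count over 4 pixels
        b_true = truth.background["CD20"] / 4.0
        n = int(masks.negative_mask.sum())
        se = np.sqrt(b_true / n)
        assert abs(bg["CD20"] - b_true) < 5 * se


class TestFilterCells:
    def _table(self, dna):
        return pd.DataFrame(
            {
                "sample_id": "s",
                "cell_id": np.arange(1, len(dna) + 1),
                "DNA1": dna,
                "DNA2": dna,
            }
        )

    def test_all_positive_is_identity(self):
        t = self._table([1.0, 2.0, 3.0])
        assert len(q.filter_cells(t)) == 3

    def test_dna_free_cell_removed(self):
        t = self._table([1.0, 0.0, 3.0])
        out = q.filter_cells(t)
        assert list(out["cell_id"]) == [1, 3]

    def test_removed_count_matches_constructed_truth(self, rng):
        dna = rng.poisson(5, 50).astype(float)
        zero_idx = rng.choice(50, size=7, replace=False)
        dna[zero_idx] = 0.0
        out = q.filter_cells(self._table(dna))
        assert len(out) == 50 - (dna == 0).sum()

    def test_missing_channel_error(self):
        with pytest.raises(ValueError, match="DNA2"):
            q.filter_cells(pd.DataFrame({"DNA1": [1.0]}))


class TestNormalize:
    def test_endpoint_mapping(self, rng):
        x = rng.normal(10, 2, 2000)
        t = pd.DataFrame({"m": x})
        out, params = q.normalize(t, ["m"])
        assert out["m"].min() == 0.0
        assert out["m"].max() == 1.0
        lo, hi = params.iloc[0][["p_low", "p_high"]]
        assert lo == pytest.approx(np.percentile(x, 0.5))
        assert hi == pytest.approx(np.percentile(x, 99.5))

    def test_constant_marker_all_zero(self):
        out, _ = q.normalize(pd.DataFrame({"m": [3.0] * 10}), ["m"])
        assert (out["m"] == 0.0).all()

    @settings(max_examples=25, deadline=None)
    @given(st.lists(st.floats(0, 1e6), min_size=5, max_size=60))
    def test_monotone(self, values):
        t = pd.DataFrame({"m": values})
        out, _ = q.normalize(t, ["m"])
        order = np.argsort(values, kind="stable")
        normed = out["m"].to_numpy()[order]
        assert (np.diff(normed) >= -1e-12).all()
        assert ((out["m"] >= 0) & (out["m"] <= 1)).all()


class TestGating:
    def test_gate_definitions_on_constructed_cells(self):
        t = pd.DataFrame(
            {
                "CD138": [1.0, 0.0, 0.0],
                "CD38": [1.0, 0.0, 0.0],
                "CD45": [0.0, 1.0, 0.0],
            }
        )
        thr = {"CD138": 0.5, "CD38": 0.5, "CD45": 0.5}
        out, _ = q.gate_populations(t, ["CD138", "CD38", "CD45"], thresholds=thr)
        assert list(out["gate"]) == ["PC", "WBC_control", "other"]

    def test_gates_partition(self, analyzed_cohort):
        _, _, res = analyzed_cohort
        gated = res["table"]
        assert set(gated["gate"]) <= {"PC", "WBC_control", "other"}

    def test_pc_gate_recall_on_synthetic_cohort(self, analyzed_cohort):
        table, _, res = analyzed_cohort
        gated = res["table"]
        truth_pc = table["true_type"].str.startswith("PC").to_numpy()
        called_pc = (gated["gate"] == "PC").to_numpy()
        recall = (truth_pc & called_pc).sum() / truth_pc.sum()
        assert recall >= 0.9

    def test_unknown_gate_marker_error(self):
        with pytest.raises(ValueError):
            q.gate_populations(pd.DataFrame({"CD138": [1.0]}), ["CD138"])


class TestAssignCellTypes:
    def _typed(self, **markers):
        cols = {
            "CD3": 0.0, "CD20": 0.0, "CD56": 0.0, "HLA-DR": 0.0,
            "CD31": 0.0, "CD61": 0.0,
        }
        cols.update(markers)
        t = pd.DataFrame({k: [v] for k, v in cols.items()})
        t["gate"] = "other"
        thr = {m: 0.5 for m in cols}
        return q.assign_cell_types(t, thr)

    def test_cd3_positive_is_t_cell(self):
        assert self._typed(CD3=1.0)["cell_type"].iloc[0] == "T_cell"

    def test_all_negative_is_other(self):
        assert self._typed()["cell_type"].iloc[0] == "other"

    def test_priority_cd20_over_nk(self):
        out = self._typed(CD20=1.0, CD56=1.0)
        assert out["cell_type"].iloc[0] == "B_cell"

    def test_duplicate_rule_names_rejected(self):
        t = pd.DataFrame({"CD3": [1.0], "gate": ["other"]})
        rules = (("T_cell", (q.GateRule("CD3", "+"),)),) * 2
        with pytest.raises(ValueError, match="conflict"):
            q.assign_cell_types(t, {"CD3": 0.5}, rules=rules)

    def test_t_cell_fraction_recovered(self, analyzed_cohort):
        """Per-sample T-cell percentage tracks the generator's fraction."""
        table, _, res = analyzed_cohort
        typed = res["table"]
        for sid, grp in typed.groupby("sample_id"):
            truth = table[table["sample_id"] == sid]
            true_pct = 100.0 * (truth["true_type"] == "T_cell").mean()
            est_pct = 100.0 * (grp["cell_type"] == "T_cell").mean()
            assert abs(est_pct - true_pct) <= 2.0

    def test_no_positive_population_means_no_calls(self, analyzed_cohort):
        """Markers nobody expresses (CD31, CD61) produce no typed cells."""
        _, _, res = analyzed_cohort
        typed = res["table"]
        assert (typed["cell_type"] != "endothelial").all()
        assert (typed["cell_type"] != "megakaryocyte").all()
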