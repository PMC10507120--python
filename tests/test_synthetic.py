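"""Generator contracts: determinism, count conservation, noise law."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from liquidimc.datatypes import PlacementError
from liquidimc.panel import PanelDefinition, default_panel
from liquidimc.profiles import (
    CellTypeProfile,
    CohortConfig,
    SampleConfig,
    apply_fold_change,
    default_profiles,
)
from liquidimc.synthetic import (
    IFFrameParams,
    generate_cohort,
    generate_if_frame,
    generate_imc_roi,
    sample_expression_table,
)


class TestPanel:
    def test_default_panel_shape(self):
        panel = default_panel()
        assert len(panel) == 36
        assert len(panel.intercalators) == 2
        assert len(set(panel.markers)) == len(panel.markers)

    def test_duplicate_markers_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            PanelDefinition(markers=("A", "A"), roles={"A": "lineage"})

    def test_unknown_marker_lookup(self):
        with pytest.raises(KeyError, match="CDxx"):
            default_panel().index("CDxx")


class TestProfiles:
    def test_disease_differs_only_on_elevated_markers(self):
        profs = default_profiles(elevated_markers=("BCMA", "ICAM3"), fold_change=3.0)
        normal, disease = profs["PC_normal"], profs["PC_disease"]
        for m, v in normal.marker_means.items():
            expected = v * 3.0 if m in ("BCMA", "ICAM3") else v
            assert disease.marker_means[m] == pytest.approx(expected)

    def test_fold_change_one_is_identity(self):
        normal = default_profiles()["PC_normal"]
        same = apply_fold_change(normal, ("BCMA",), 1.0)
        assert same.marker_means == normal.marker_means

    def test_unknown_marker_in_profile_named_in_error(self):
        prof = CellTypeProfile(name="bad", marker_means={"NOT_A_MARKER": 1.0})
        with pytest.raises(ValueError, match="NOT_A_MARKER"):
            prof.validate_against(default_panel())


class TestIFFrame:
    def test_empty_frame_is_background_only(self):
        params = IFFrameParams(shape=(64, 64), noise_sd=0.0)
        stack, truth = generate_if_frame(0, 0.0, seed=1, params=params)
        assert truth.n_cells == 0
        for ch in stack.channels:
            assert np.all(stack.channel(ch) == params.background[ch])

    def test_rare_count_forced_by_fraction(self):
        _, truth = generate_if_frame(200, 0.05, seed=7)
        assert (truth.cells["cell_type"] == "PC").sum() == 10
        assert truth.n_cells == 200

    def test_same_seed_bit_identical(self):
        s1, t1 = generate_if_frame(80, 0.05, seed=42)
        s2, t2 = generate_if_frame(80, 0.05, seed=42)
        assert np.array_equal(s1.data, s2.data)
        pd.testing.assert_frame_equal(t1.cells, t2.cells)

    def test_rare_cells_carry_cd138_above_background(self, if_frame):
        stack, truth = if_frame
        cd138 = stack.channel("CD138")
        bg = truth.background["CD138"]
        for _, cell in truth.cells[truth.cells.cell_type == "PC"].iterrows():
            assert cd138[int(cell.y), int(cell.x)] > bg + 50

    def test_overcrowded_frame_raises_placement_error(self):
        with pytest.raises(PlacementError):
            generate_if_frame(500, 0.0, seed=0, params=IFFrameParams(shape=(64, 64)))


class TestIMCROI:
    def test_silent_cell_only_intercalators_positive(self):
        prof = CellTypeProfile(
            name="silent", marker_means={"DNA1": 20.0, "DNA2": 20.0}, abundance=1.0
        )
        stack, truth = generate_imc_roi(
            [prof], roi_px=(60, 60), n_cells=1, hot_pixel_rate=0.0, seed=1,
            background=0.0,
        )
        panel = default_panel()
        for m in panel.markers:
            plane = stack.channel(m)
            if m in ("DNA1", "DNA2"):
                cy, cx = truth.cells.iloc[0][["y", "x"]]
                assert plane[int(cy), int(cx)] > 0
            else:
                assert np.all(plane == 0)

    def test_background_mean_recovered(self):
        b = 4.0
        stack, _ = generate_imc_roi(
            [CellTypeProfile(name="none", abundance=1.0)],
            roi_px=(100, 100),
            n_cells=0,
            hot_pixel_rate=0.0,
            background=b,
            seed=9,
        )
        # Poisson moment oracle: SE of the mean of n pixels is sqrt(b/n)
        n = 100 * 100
        se = np.sqrt(b / n)
        assert abs(stack.data[0].mean() - b) < 4 * se

    def test_zero_hot_pixel_rate_empty_list(self):
        _, truth = generate_imc_roi(
            list(default_profiles().values()),
            roi_px=(80, 80),
            n_cells=5,
            hot_pixel_rate=0.0,
            seed=2,
        )
        assert len(truth.hot_pixels) == 0

    def test_hot_pixels_recorded_in_bounds(self, imc_roi):
        _, truth = imc_roi
        assert len(truth.hot_pixels) > 0
        truth.validate()

    def test_unknown_marker_raises_named_error(self):
        prof = CellTypeProfile(name="bad", marker_means={"XYZ": 1.0}, abundance=1.0)
        with pytest.raises(ValueError, match="XYZ"):
            generate_imc_roi([prof], roi_px=(50, 50), n_cells=1, seed=0)

    def test_poisson_law_background_region(self):
        """Pixel histogram over a constant-mean region passes a GOF check."""
        b = 2.0
        stack, _ = generate_imc_roi(
            [CellTypeProfile(name="none", abundance=1.0)],
            roi_px=(120, 120),
            n_cells=0,
            hot_pixel_rate=0.0,
            background=b,
            seed=11,
        )
        x = stack.data[0].ravel().astype(int)
        kmax = 8
        observed = np.bincount(np.minimum(x, kmax), minlength=kmax + 1)
        expected = sps.poisson.pmf(np.arange(kmax), b) * x.size
        expected = np.append(expected, x.size - expected.sum())
        chi2 = ((observed - expected) ** 2 / expected).sum()
        p = sps.chi2.sf(chi2, df=kmax)  # mean is known, not fitted
        assert p > 0.01

    def test_determinism(self):
        profs = list(default_profiles().values())
        a, _ = generate_imc_roi(profs, roi_px=(80, 80), n_cells=10, seed=4)
        b, _ = generate_imc_roi(profs, roi_px=(80, 80), n_cells=10, seed=4)
        assert np.array_equal(a.data, b.data)


class TestCohort:
    def test_empty_cohort(self):
        data = generate_cohort(CohortConfig(samples=(), seed=0))
        assert data.samples == []
        assert len(data.manifest) == 0

    def test_manifest_group_sizes(self):
        samples = tuple(
            SampleConfig(f"P{i}", "precursor", n_cells=5) for i in range(2)
        ) + tuple(SampleConfig(f"D{i}", "disease", n_cells=5) for i in range(3))
        cfg = CohortConfig(samples=samples, seed=1)
        data = generate_cohort(
            cfg,
            if_params=IFFrameParams(shape=(96, 96)),
            roi_px=(40, 40),
            imc_cells_per_roi=3,
        )
        counts = data.manifest["condition"].value_counts()
        assert counts["precursor"] == 2 and counts["disease"] == 3

    def test_duplicate_sample_ids_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            CohortConfig(
                samples=(
                    SampleConfig("A", "precursor"),
                    SampleConfig("A", "disease"),
                ),
                seed=0,
            )

    def test_cohort_determinism_byte_identical(self):
        cfg = CohortConfig(
            samples=(SampleConfig("A", "precursor", n_cells=20, pc_fraction=0.1),),
            seed=3,
        )
        kwargs = dict(
            if_params=IFFrameParams(shape=(128, 128)),
            roi_px=(60, 60),
            imc_cells_per_roi=8,
        )
        d1 = generate_cohort(cfg, **kwargs)
        d2 = generate_cohort(cfg, **kwargs)
        for s1, s2 in zip(d1.samples, d2.samples):
            for (a, ta), (b, tb) in zip(s1.if_frames, s2.if_frames):
                assert np.array_equal(a.data, b.data)
                assert a.data.tobytes() == b.data.tobytes()
                pd.testing.assert_frame_equal(ta.cells, tb.cells)
            for (a, ta), (b, tb) in zip(s1.imc_rois, s2.imc_rois):
                assert a.data.tobytes() == b.data.tobytes()
                pd.testing.assert_frame_equal(ta.hot_pixels, tb.hot_pixels)

    def test_disease_samples_use_elevated_profile(self):
        cfg = CohortConfig(
            samples=(
                SampleConfig("P", "precursor", n_cells=0),
                SampleConfig("D", "disease", n_cells=0),
            ),
            seed=5,
        )
        table, _ = sample_expression_table(cfg, pcs_per_sample=400, wbcs_per_sample=0)
        means = table.groupby("true_type")["BCMA"].mean()
        assert means["PC_disease"] > 2.0 * means["PC_normal"]

    def test_expression_table_columns_and_manifest(self):
        cfg = CohortConfig.default(seed=0)
        table, manifest = sample_expression_table(
            cfg, pcs_per_sample=5, wbcs_per_sample=10
        )
        assert set(manifest.columns) == {"sample_id", "condition"}
        assert len(manifest) == len(cfg.samples)
        assert len(table) == 15 * len(cfg.samples)
        for m in default_panel().markers:
            assert m in table.columns
            assert (table[m] >= 0).all()
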