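"""Rare-cell stage: segmentation, features, outlier detection, classes."""

import numpy as np
import pandas as pd
import pytest

from liquidimc import rarecell as rc
from liquidimc.datatypes import ImageStack


def _disk_mask(shape, cy, cx, r):
    yy, xx = np.mgrid[: shape[0], : shape[1]]
    return (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2


class TestSegmentNuclei:
    def test_blank_image_zero_labels(self):
        assert rc.segment_nuclei(np.zeros((64, 64))).max() == 0

    def test_two_separated_disks_two_labels(self):
        img = np.zeros((100, 100))
        img[_disk_mask(img.shape, 25, 25, 8)] = 100.0
        img[_disk_mask(img.shape, 75, 75, 8)] = 100.0
        labels = rc.segment_nuclei(img)
        assert labels.max() == 2

    def test_count_recovered_on_synthetic_frame(self, segmented):
        _, truth, labels = segmented
        n = truth.n_cells
        assert abs(labels.max() - n) <= 0.05 * n

    def test_labels_dense_from_one(self, segmented):
        _, _, labels = segmented
        ids = np.unique(labels)
        assert np.array_equal(ids[ids > 0], np.arange(1, labels.max() + 1))

    def test_negative_values_rejected(self):
        with pytest.raises(ValueError):
            rc.segment_nuclei(np.full((10, 10), -1.0))


class TestExtractFeatures:
    def test_uniform_disk_exact_area_mean_round(self):
        shape = (41, 41)
        mask = _disk_mask(shape, 20, 20, 10)
        labels = mask.astype(np.int32)
        stack = ImageStack(np.full((1,) + shape, 7.0), ("DAPI",))
        fm = rc.extract_features(stack, labels, texture=False)
        row = fm.values.iloc[0]
        assert row["area"] == mask.sum()
        assert row["DAPI_mean"] == pytest.approx(7.0)
        assert row["eccentricity"] < 0.1

    def test_rotation_invariant_features(self, if_frame):
        stack, _ = if_frame
        labels = rc.segment_nuclei(stack.channel("DAPI"))
        fm = rc.extract_features(stack, labels, texture=False)
        rot = ImageStack(
            np.stack([np.rot90(p) for p in stack.data]), stack.channels
        )
        labels_rot = np.rot90(labels)
        fm_rot = rc.extract_features(rot, labels_rot, texture=False)
        for col in ("area", "DAPI_mean", "eccentricity", "CD138_total"):
            np.testing.assert_allclose(
                fm.values[col].to_numpy(),
                fm_rot.values[col].to_numpy(),
                rtol=1e-9,
            )

    def test_pixel_loop_oracle_exact(self, segmented, rng):
        """Mean/total/max intensity equal a raw pixel loop for random cells."""
        stack, _, labels = segmented
        fm = rc.extract_features(stack, labels, texture=False)
        picks = rng.choice(fm.values.index.to_numpy(), size=10, replace=False)
        for lab in picks:
            mask = labels == lab
            for ch in stack.channels:
                pix = stack.channel(ch)[mask].astype(float)
                assert fm.values.loc[lab, f"{ch}_mean"] == pix.mean()
                assert fm.values.loc[lab, f"{ch}_total"] == pix.sum()
                assert fm.values.loc[lab, f"{ch}_max"] == pix.max()
            assert fm.values.loc[lab, "area"] == mask.sum()

    def test_missing_values_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            rc.FeatureMatrix(values=pd.DataFrame({"a": [1.0, np.nan]}))

    def test_geometry_mismatch_is_error(self, if_frame):
        stack, _ = if_frame
        with pytest.raises(ValueError):
            rc.extract_features(stack, np.zeros((5, 5), dtype=np.int32))


class TestDetectRare:
    def _gaussian_fixture(self, n_out=10, shift=10.0, seed=0):
        rng = np.random.default_rng(seed)
        inliers = rng.normal(0, 1, size=(990, 12))
        outliers = rng.normal(0, 1, size=(n_out, 12)) + shift
        x = np.vstack([inliers, outliers])
        df = pd.DataFrame(x, columns=[f"f{i}" for i in range(12)])
        df["centroid_y"] = 0.0
        df["centroid_x"] = 0.0
        return rc.FeatureMatrix(values=df)

    def test_identical_rows_no_flags(self):
        fm = rc.FeatureMatrix(
            values=pd.DataFrame(np.ones((50, 4)), columns=list("abcd"))
        )
        assert rc.detect_rare(fm).sum() == 0

    def test_shifted_outliers_found(self):
        fm = self._gaussian_fixture()
        flags = rc.detect_rare(fm, rare_cluster_max_fraction=0.02)
        # brute-force oracle: the 10 shifted rows are the 10 farthest from
        # the coordinate-wise median
        x = fm.values[[f"f{i}" for i in range(12)]].to_numpy()
        d = np.linalg.norm(x - np.median(x, axis=0), axis=1)
        oracle = np.zeros(len(x), dtype=bool)
        oracle[np.argsort(d)[-10:]] = True
        assert oracle[-10:].all()
        assert flags[-10:].sum() >= 9
        assert flags[:-10].sum() == 0

    def test_deterministic(self):
        fm = self._gaussian_fixture(seed=3)
        f1 = rc.detect_rare(fm, rare_cluster_max_fraction=0.02)
        f2 = rc.detect_rare(fm, rare_cluster_max_fraction=0.02)
        assert np.array_equal(f1, f2)

    def test_component_cap(self):
        fm = self._gaussian_fixture()
        flags = rc.detect_rare(fm, n_components=10_000, rare_cluster_max_fraction=0.02)
        assert flags[-10:].sum() >= 9

    def test_too_few_cells(self):
        fm = rc.FeatureMatrix(values=pd.DataFrame({"a": [1.0]}))
        with pytest.raises(ValueError):
            rc.detect_rare(fm)


class TestKnnRefine:
    def _fixture(self, seed=0):
        rng = np.random.default_rng(seed)
        x = rng.normal(0, 1, size=(100, 5))
        x[0] = 50.0  # isolated
        df = pd.DataFrame(x, columns=list("abcde"))
        return rc.FeatureMatrix(values=df)

    def test_isolated_candidate_retained(self):
        fm = self._fixture()
        cand = np.zeros(100, dtype=bool)
        cand[0] = True
        assert rc.knn_refine(fm, cand, k=5)[0]

    def test_embedded_candidate_dropped(self):
        """A lone candidate inside the inlier cloud fails both criteria."""
        fm = self._fixture()
        cand = np.zeros(100, dtype=bool)
        cand[10] = True  # ordinary inlier
        refined = rc.knn_refine(fm, cand, k=5)
        # explicit neighbor-list oracle: none of its 5 nearest neighbors
        # (Euclidean, standardized) are candidates
        z = fm.standardized()
        d = np.linalg.norm(z - z[10], axis=1)
        nn = np.argsort(d)[1:6]
        assert not cand[nn].any()
        assert not refined[10]

    def test_no_candidates_no_flags(self):
        fm = self._fixture()
        assert rc.knn_refine(fm, np.zeros(100, dtype=bool), k=5).sum() == 0

    def test_k_too_large_is_error(self):
        fm = self._fixture()
        with pytest.raises(ValueError):
            rc.knn_refine(fm, np.zeros(100, dtype=bool), k=100)


class TestClassifyCells:
    def _features(self, rows):
        return rc.FeatureMatrix(values=pd.DataFrame(rows))

    THRESH = {"DAPI": 10.0, "CD138": 10.0, "CD45": 10.0}

    def _classify(self, dapi, cd138, cd45):
        fm = self._features(
            [
                {
                    "DAPI_mean": dapi,
                    "CD138_mean": cd138,
                    "CD45_mean": cd45,
                    "centroid_y": 0.0,
                    "centroid_x": 0.0,
                    "area": 100.0,
                    "eccentricity": 0.2,
                }
            ]
        )
        return rc.classify_cells(fm, self.THRESH)

    @pytest.mark.parametrize(
        "cd138,cd45,expected",
        [
            (100.0, 0.0, "PC_CD45neg"),
            (100.0, 100.0, "PC_CD45pos"),
            (0.0, 100.0, "nonPC_hematopoietic"),
            (0.0, 0.0, "DAPI_only"),
        ],
    )
    def test_gate_definitions(self, cd138, cd45, expected):
        out = self._classify(100.0, cd138, cd45)
        assert list(out["channel_class"]) == [expected]

    def test_dapi_negative_excluded(self):
        out = self._classify(1.0, 100.0, 100.0)
        assert len(out) == 0

    def test_known_pc_count_on_synthetic_frame(self, segmented):
        stack, truth, labels = segmented
        fm = rc.extract_features(stack, labels, texture=False)
        thr = rc.compute_channel_thresholds(stack, labels)
        out = rc.classify_cells(fm, thr)
        n_pc = out["channel_class"].isin(rc.PC_CLASSES).sum()
        assert n_pc == (truth.cells["cell_type"] == "PC").sum()

    def test_class_partition(self, segmented):
        stack, _, labels = segmented
        fm = rc.extract_features(stack, labels, texture=False)
        thr = rc.compute_channel_thresholds(stack, labels)
        out = rc.classify_cells(fm, thr)
        assert out["channel_class"].isin(rc.CHANNEL_CLASSES).all()


class TestEnumerateGroups:
    def _tables(self, counts_by_sample, condition="precursor"):
        rows = []
        for sid, n in counts_by_sample.items():
            for i in range(n):
                rows.append(
                    {
                        "sample_id": sid,
                        "channel_class": "PC_CD45neg",
                        "rare": False,
                    }
                )
        classified = pd.DataFrame(
            rows, columns=["sample_id", "channel_class", "rare"]
        )
        manifest = pd.DataFrame(
            {
                "sample_id": list(counts_by_sample),
                "condition": condition,
            }
        )
        return classified, manifest

    def test_printed_precursor_counts(self):
        """Counts 180/1022/517 give mean 573 and population SD 346.0."""
        classified, manifest = self._tables({"MGUS1": 180, "MGUS2": 1022, "SMM": 517})
        _, per_condition = rc.enumerate_groups(classified, manifest)
        row = per_condition[per_condition["group"] == "PC_CD45neg"].iloc[0]
        assert row["mean"] == pytest.approx(573.0)
        assert round(row["sd"], 1) == 346.0

    def test_single_sample_sd_zero(self):
        classified, manifest = self._tables({"A": 7})
        _, per_condition = rc.enumerate_groups(classified, manifest)
        assert (per_condition["sd"] == 0).all()

    def test_empty_sample_zero_counts(self):
        classified, manifest = self._tables({"A": 3})
        manifest = pd.concat(
            [manifest, pd.DataFrame([{"sample_id": "B", "condition": "precursor"}])],
            ignore_index=True,
        )
        per_sample, _ = rc.enumerate_groups(classified, manifest)
        row = per_sample[per_sample["sample_id"] == "B"].iloc[0]
        assert row["total_cells"] == 0

    def test_unknown_sample_is_error(self):
        classified, _ = self._tables({"A": 3})
        manifest = pd.DataFrame({"sample_id": ["B"], "condition": ["disease"]})
        with pytest.raises(ValueError, match="A"):
            rc.enumerate_groups(classified, manifest)

    def test_counts_sum_to_total(self, segmented):
        stack, _, labels = segmented
        fm = rc.extract_features(stack, labels, texture=False)
        thr = rc.compute_channel_thresholds(stack, labels)
        out = rc.classify_cells(fm, thr).assign(sample_id="S")
        manifest = pd.DataFrame({"sample_id": ["S"], "condition": ["disease"]})
        per_sample, _ = rc.enumerate_groups(out, manifest)
        row = per_sample.iloc[0]
        assert sum(row[c] for c in rc.CHANNEL_CLASSES) == row["total_cells"]


class TestSelectROIs:
    def _classified(self, pcs, wbcs):
        rows = [
            {"label": i + 1, "centroid_y": y, "centroid_x": x,
             "channel_class": "PC_CD45neg"}
            for i, (y, x) in enumerate(pcs)
        ] + [
            {"label": 1000 + i, "centroid_y": y, "centroid_x": x,
             "channel_class": "nonPC_hematopoietic"}
            for i, (y, x) in enumerate(wbcs)
        ]
        return pd.DataFrame(rows)

    def test_no_pcs_empty(self):
        out = rc.select_rois(self._classified([], [(10, 10)]), (500, 500))
        assert len(out) == 0

    def test_single_pc_single_roi(self):
        out = rc.select_rois(self._classified([(250, 250)], []), (500, 500))
        assert len(out) == 1
        r = out.iloc[0]
        assert r.x0 <= 250 < r.x1 and r.y0 <= 250 < r.y1

    def test_every_roi_contains_a_pc(self, rng):
        """Exhaustive post-check over 20 random synthetic layouts."""
        for _ in range(20):
            n_pc = int(rng.integers(0, 6))
            pcs = [(rng.uniform(0, 900), rng.uniform(0, 900)) for _ in range(n_pc)]
            wbcs = [
                (rng.uniform(0, 900), rng.uniform(0, 900)) for _ in range(200)
            ]
            cls = self._classified(pcs, wbcs)
            out = rc.select_rois(cls, (900, 900))
            assert (out["n_pc"] >= 1).all()
            # no two ROIs share a PC cell
            seen = set()
            for labs in out["cell_labels"]:
                for lab in labs.split(";"):
                    assert lab not in seen
                    seen.add(lab)
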