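"""Shared fixtures: all test data is generated, none is stored."""

from __future__ import annotations

import numpy as np
import pytest

from liquidimc.pipeline import run_comparison, training_labels_from_truth
from liquidimc.profiles import CohortConfig, default_profiles
from liquidimc.synthetic import (
    generate_if_frame,
    generate_imc_roi,
    sample_expression_table,
)
from liquidimc import imc_preprocess, rarecell


@pytest.fixture(scope="session")
def if_frame():
    """A 200-cell IF frame with 5% rare plasma-cell-like events (seed 7)."""
    return generate_if_frame(200, rare_fraction=0.05, seed=7)


@pytest.fixture(scope="session")
def segmented(if_frame):
    stack, truth = if_frame
    labels = rarecell.segment_nuclei(stack.channel("DAPI"))
    return stack, truth, labels


@pytest.fixture(scope="session")
def features(segmented):
    stack, truth, labels = segmented
    return rarecell.extract_features(stack, labels, texture=False)


@pytest.fixture(scope="session")
def imc_roi():
    """A compact 160x160 px ion-count ROI with ~40 cells and hot pixels."""
    profiles = list(default_profiles().values())
    return generate_imc_roi(
        profiles, roi_px=(160, 160), n_cells=40, hot_pixel_rate=1e-4, seed=3
    )


@pytest.fixture(scope="session")
def preprocessed_roi(imc_roi):
    """Cleaned, upscaled, classified and masked version of the small ROI."""
    stack, truth = imc_roi
    cleaned = imc_preprocess.remove_hot_pixels(stack)
    scaled = imc_preprocess.upscale(cleaned, factor=2)
    labels = training_labels_from_truth(truth, factor=2)
    clf = imc_preprocess.train_pixel_classifier(
        [scaled], [labels], seed=5, channels=(34, 35, 30, 13, 1)
    )
    probs = imc_preprocess.apply_pixel_classifier(scaled, clf)
    masks = imc_preprocess.make_cell_masks(probs)
    return scaled, truth, clf, probs, masks


@pytest.fixture(scope="session")
def cohort_table():
    """Table-level synthetic cohort (default disease-vs-precursor effect)."""
    config = CohortConfig.default(seed=2)
    table, manifest = sample_expression_table(
        config, pcs_per_sample=100, wbcs_per_sample=200
    )
    return table, manifest


@pytest.fixture(scope="session")
def analyzed_cohort(cohort_table):
    table, manifest = cohort_table
    out = run_comparison(table, manifest, embed=False)
    return table, manifest, out


@pytest.fixture
def rng():
    return np.random.default_rng(0)
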