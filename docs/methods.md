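# Methods

This note records the models, conventions and numerical choices behind
`liquidimc`, in the order the pipeline runs them. Nothing here states an
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Synthetic-slide generator

The generator is first-class code: it defines the study conditions under
which every downstream guarantee is measured.

**Immunofluorescence frames.** A frame is a 3-channel (DAPI, CD138, CD45)
float image. Nuclei are rendered as anisotropic super-Gaussian ellipses
(`A·exp(−m⁴)`, where `m` is the normalized elliptical radius), which gives a
flat top and a steep edge so threshold segmentation recovers stable areas.
White blood cells have nuclear radius 6 ± 0.8 px and eccentricity
0.25 ± 0.08; rare plasma-cell-like events have radius 12 ± 1.2 px and
eccentricity 0.55 ± 0.08 — a >10-SD shift in area against the WBC
population — and carry CD138 signal over a 1.3×-scaled cell body. About 30%
of rare cells are also CD45+, mirroring the two plasma-cell channel
classes. Channels share a diffuse background (default 8) with Gaussian read
noise (SD 3), clipped at zero. Placement is rejection sampling with a
per-cell exclusion halo; rare cells get a 2.2× halo so their membrane
signal cannot bleed into a neighbouring nucleus and manufacture spurious
outliers. Exhausting the retry budget raises a placement error — cell
counts are never silently truncated.

**Ion-count ROIs.** A ROI is a 36-channel stack (34 antibody targets — the
two BCMA clones share one metal tag and hence one channel — plus two DNA
intercalators) of per-pixel Poisson counts with mean = diffuse background
(default 0.3 counts/px) + the summed contribution of overlapping cells.
Intercalators and nuclear-localized markers render over the nucleus;
membrane markers over an elliptical annulus out to 1.6× the nuclear
ellipse. Expression profiles (counts/px) are per cell type; positive
markers sit at 2–30 counts/px, the regime of antibody staining read out at
1 µm² resolution. The disease plasma-cell profile equals the normal one
except on a declared elevated-marker subset (default BCMA, ICAM3, CD221 at
fold 3.0). Hot pixels are injected per channel at a configurable rate
(default 10⁻⁴) as isolated single-pixel values ≥ 10× the channel's 99.9th
percentile and ≥ 10× the local true mean + 50, at recorded coordinates,
never closer than 2 px to each other.

**Cohorts.** The default cohort mirrors a small myeloma-spectrum study:
2 MGUS + 1 SMM (precursor), 2 NDMM + 1 RRMM + 1 PCL (disease), 1 normal
donor. Per-sample seeds are spawned deterministically from the cohort seed;
identical configuration yields byte-identical images and truths.

**Table-level fast path.** For cohort-scale statistical studies
(calibration at 200 replicates), `sample_expression_table` draws each
cell's per-marker value directly from the count model the image path
induces — the mean of `area` Poisson(profile mean + background) pixels,
background-corrected, with membrane markers diluted by the annulus/territory
area ratio (0.6) — instead of rendering and re-segmenting images. The
per-cell sampling distribution matches what the quantification stage
measures on rendered ROIs; the image path remains the one used for all
segmentation and preprocessing guarantees.

**What the generator does not emulate** — and hence what passing tests do
not show about real slides: optical point-spread functions and
autofluorescence, isotope spillover and impurity, staining-batch and
storage-time effects, cell debris and overlapping/touching nuclei beyond
watershed-separable contact, morphological diversity beyond two-parameter
ellipses, and spatial organisation (cells are placed uniformly at random).

## Rare-cell detection

The feature battery is a documented, configurable set (~130 features for 3
channels): shape (area, perimeter, eccentricity, solidity, extent,
major/minor axis), per-channel intensity (mean, total, max, SD, quartiles,
90th percentile) and per-channel gray-level co-occurrence texture
(contrast/correlation/energy/homogeneity at 4 offsets, 16 gray levels).
The published parameter sets of slide scanners are an order of magnitude
larger but unpublished in detail; this battery spans the same
morphology + intensity space, and the battery size is configuration, not
contract.

Detection standardizes the battery (zero-variance features map to 0),
projects onto the top `n_components` principal components (default 350,
capped at min(features, cells); a full-rank SVD keeps this deterministic),
and Ward-clusters the scores. The tree is cut into `n_clusters` groups
(default 5) and every cluster of size ≤ `rare_cluster_max_fraction`·N is
flagged. A small cut count is deliberate: with few clusters, the inlier
population cannot shatter into accidentally-small clusters, so only
genuinely separated minorities are flagged; the benchmark fixtures use
`rare_cluster_max_fraction = 0.06` because their rare fraction runs up to
5%. KNN refinement (k = 5) keeps a candidate iff the majority of its k
nearest standardized-space neighbours are candidates or its mean neighbour
distance exceeds the 99th percentile of the non-candidates'; ties break
toward retention. There is no unseeded randomness anywhere in this module.

Channel positivity thresholds are per frame: non-cell background mean +
3 population SD, per channel. "Morphologically distinct" is relative to the
surrounding CD45+CD138− population (area or eccentricity above its 98th
percentile). ROI selection is greedy: one 400 × 400 px box per unassigned
PC-class cell, shifted within bounds to maximize contained WBCs up to ~300,
ties toward the smallest shift; no two boxes share a PC. Boxes are half-open
`[x0, x1) × [y0, y1)`, 0-based, origin top-left — stated once, used
everywhere.

## IMC preprocessing

The stage order is fixed and logged: hot-pixel removal → upscale →
pixel classification → masks.

**Hot pixels.** A pixel is replaced by its 3×3 neighbourhood median when it
exceeds `median3×3 + k·scale` (default k = 5) *and* exceeds the
8-neighbourhood maximum by the same margin. The scale is the channel's
scaled MAD (×1.4826) floored at the local Poisson scale `sqrt(median + 1)`:
on sparse count channels more than half the pixels are zero and the raw MAD
degenerates to 0, which would turn a plain median+MAD rule into a filter
that rewrites every pixel above its local median. The neighbourhood-maximum
condition distinguishes isolated artifacts from the bright rim of genuine
single-pixel-wide structure, whose neighbours share the signal; without it,
annulus edges get clipped and the filter is not idempotent. Border handling
mirrors without repeating the edge pixel, so a border pixel is never its
own neighbour.

**Upscaling** (default 2×) is bilinear with intensities rescaled by 1/f²
and renormalized so each channel's total counts are conserved exactly.

**Pixel classification.** The interactive trainable classifier of
slide-processing practice is replaced by a seeded, scriptable one with the
same contract: per-pixel features are the raw channel values plus
Gaussian-smoothed values and gradient magnitudes at two scales (σ = 1, 2),
and the output is a per-pixel probability for nuclei / membrane /
background normalized to sum to 1. The default model is a random forest
(50 trees, fixed seed, single-threaded — deterministic); training labels in
the pipeline are sparse strokes derived from generator truth (nucleus
cores, membrane annuli, far-background grid points). The pipeline trains on
the first ROI and batch-applies to the rest. The channel subset fed to the
classifier is configurable; the drivers use the two intercalators plus
CD45/CD138/CD38, which carry the geometry.

**Masks.** Nuclei are connected components of P(nuclei) > 0.5 (components
under 9 px discarded as noise); territories grow by watershed over
1 − P(background) seeded at nuclei and stopped where P(background) > 0.5;
the negative mask is that background region minus any territory. Cell
labels are dense 1..N; territories partition non-background space.

## Quantification and gating

Per cell and channel, the raw value is total counts over the territory
divided by territory area — nothing more; this is checked exactly against a
brute-force pixel loop. Background is estimated per ROI (the negative mask
is a per-ablation concept) and subtraction clamps at zero since negative
ion counts are non-physical. Cells with zero corrected intercalator signal
are dropped and the count logged.

Normalization is cohort-wide robust min-max per marker:
`clip((x − p0.5)/(p99.5 − p0.5), 0, 1)`. Percentile endpoints resist
residual hot pixels; cohort-wide (not per-sample) scaling is required for
cross-sample comparisons and heatmaps, and the percentiles are logged so
the scaling is reproducible. A degenerate marker maps to all zeros with a
warning.

Positivity thresholds are found on the **raw count scale** and then mapped
through the logged normalization parameters, because 0–1 normalization
stretches pure noise across the full range — on the normalized scale, "no
positive population" and "0.5% positive" are indistinguishable by
construction. For markers the control WBCs are negative for (CD138, CD38,
the target markers), the threshold is the 95th percentile of the
control-candidate distribution; for markers expressed by control subsets
themselves (CD45 and the lineage-typing markers CD3, CD20, CD56, HLA-DR,
CD31, CD61, ...), that percentile would sit inside the positive population,
so a deterministic bimodal split (Otsu, 256 bins) is used instead. All
thresholds are floored at 1 count/px — above background noise, below any
real signal — and logged. Control candidates are found by a coarse Otsu
pass on CD45/CD138/CD38.

Gates: PC = CD138+ ∧ CD38+ (priority), WBC control = CD45+ ∧ CD138− ∧
CD38−; the gates partition. Microenvironment types come from a
priority-ordered rule table (T cell = CD3+; B cell = CD20+CD3−;
NK = CD56+CD3−; myeloid = HLA-DR+CD3−CD20−; endothelial = CD31+;
megakaryocyte = CD61+; else other), first match wins, exactly one type per
cell.

## Statistics

* Descriptive statistics use the population SD (divide by N). This
  convention exactly reproduces the published worked summaries of
  per-sample enumeration counts (180, 1022, 517 → 573 ± 346.0) and T-cell
  percentages (16.87, 14.62, 17.0 → 16.16 ± 1.09), which is how the
  convention was identified.
* Kruskal–Wallis uses mid-ranks with tie correction and a χ² null with
  (groups − 1) df; an all-tied input returns H = 0, p = 1 rather than an
  error. The implementation is checked against an independent hand
  rank-sum oracle.
* Significance is p ≤ α (closed boundary, default α = 0.05) with no
  multiple-testing correction — the comparisons are planned — and every
  report carries that note.
* The default unit of analysis is the **cell**, pooling cells across each
  condition's samples. Cells within a sample are not independent, so this
  pseudo-replicates; it is nevertheless the default because it is what the
  cohort-scale comparison this package models does. A `unit="sample"` mode
  aggregates each sample to its PC mean first (with 3 vs 3 samples the
  smallest attainable exact p is ≈ 0.05, so expect no significance at that
  size).
* Marker correlation is Pearson over gated PCs; zero-variance markers get
  0 against everything with a warning; clustering is average linkage on
  1 − r with scipy's deterministic leaf ordering.
* Embeddings are seeded t-SNE (PCA init, perplexity min(30, (n−1)/3)) over
  the six clinical markers; only shape and determinism are contractual.

## Problem sizes and benchmarks

The shipped benchmarks (shared by the test suite and
`scripts/acceptance.py`) use: 20 random 10×10 fixtures for the
quantification oracle; three 400 × 400 × 36 ROIs for hot-pixel sensitivity
and specificity; ten 1000-cell frames at rare fractions 1–5% for rare-cell
recall/precision; 200 table-level cohort replicates (40 PCs/sample) for
type-I calibration and 20 replicates (70 PCs/sample, > 200 pooled
PCs/condition) for power; and a 2-samples-per-condition image cohort
(512 px frames, 150 cells; 200 px ROIs, 70 cells) run twice for byte-level
determinism. These sizes are the package's chosen desk-scale study
conditions; every stage uses the same code path at any scale.

## Known limitations

* The feature battery and cluster-cut rule are this package's documented
  choices; published slide-processing pipelines do not specify theirs at
  this level, so exact numeric parity with any external tool is out of
  scope.
* The pixel classifier is as good as its training strokes; on real data an
  interactive tool with human-curated labels would be retrained per batch.
* Patient-scale findings (per-patient marker heatmaps, specific correlation
  coefficients, microenvironment p-values at n = 3 samples/condition)
  depend on the deposited patient images and are not reproduced at desk
  scale; the benchmarks above are property-based substitutes.
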