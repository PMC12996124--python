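# Methods

This note records the models, conventions and numerical choices behind
`synmap`, and what the synthetic tests do and do not establish about real
microscope data.

## Data model and conventions

A dataset is a parent directory whose immediate subdirectories are
experimental conditions; each condition holds multi-plane TIFF files, one
per field of view, channels as planes. All coordinates are (row, col),
0-based, with pixel centers at integers. Label masks use 0 for background
and the gap-free set {1..n}; every label is one 4-connected component.

Channel names and pixel size travel as a small JSON document in the TIFF
ImageDescription tag; TIFFs without it fall back to C0, C1, … Replicates
are parsed from an optional `repN` filename token; otherwise each file is
its own replicate. Vendor formats, OME-XML fidelity and 3D/time series are
out of scope.

The run configuration is a versioned JSON schema (pydantic). Unknown keys
are errors, not warnings: a silently ignored misspelled parameter is the
worst reproducibility failure mode. Together with deterministic dataset
ordering (lexicographic by subfolder, then filename) and lossless CSV float
formatting (see below), this makes every non-timestamp output byte a pure
function of (dataset, config).

## Background subtraction

Background is a per-channel scalar: the median of pixels outside all masks,
or — before any mask exists — the median of the lowest-intensity 25% of
pixels, which is correct as long as cells cover less than ~75% of the
field. SLB images have flat background, so a scalar is adequate and, unlike
rolling-ball variants, parameter-free and deterministic. The pipeline uses
the mask-free fallback to feed segmentation, then re-estimates with the
mask for feature extraction; both estimates are recorded in the manifest.
Subtracted images are clipped at 0.

Two deliberate exceptions use unclipped data:

- **Recruitment fold change** divides mean raw intensity under the mask by
  the mean raw intensity of the free bilayer (pixels outside all masks
  after dilating them by a 5 px guard band, so edge blur stays out of the
  denominator). Subtracting background first would drive the denominator
  toward zero and make the ratio meaningless. A zero denominator reports
  the ratio as missing, with a warning.
- **PCC** is computed on subtracted-but-unclipped intensities. Pearson's
  coefficient is invariant to the scalar shift, whereas clipping censors
  the sub-background half of a weakly enriched channel's distribution and
  attenuates the coefficient (we measured ≈0.52 recovered at a generated
  ρ = 0.6 with clipping, 0.60 without). A `pcc_on_raw` flag skips the
  subtraction entirely; by translation invariance it gives the same values.

## Segmentation

The built-in segmenter is a fully pinned function of the expected synapse
diameter *d* (default 100 px): Gaussian smoothing with σ = d/20; Otsu
threshold; hole filling; removal of objects with area < π(d/4)²/4;
watershed on the negated Euclidean distance transform, seeded at distance
maxima at least d/2 apart, to split touching cells; relabeling to {1..n} in
raster order. Blank images give zero cells and empty downstream outputs
rather than errors. Border-touching cells are kept by default (filtering is
morphological, not positional); a config flag excludes them.

The resize-for-inference contract: images are resized by the pre-inference
scale (bilinear, dimensions rounded), the diameter is multiplied by the
same scale so the same physical size is targeted, and the resulting label
grid is resized back by nearest-neighbor so labels stay integral. External
segmenters (e.g. a Cellpose installation) plug in through
`register_backend(name, fn)` where `fn(image_2d, diameter) -> label grid`;
the built-in backend is the default and the only one the test suite needs.

## Morphology and filtering

Perimeter uses the chain-code weighted boundary estimator
(`skimage.measure.regionprops().perimeter`), pinned so circularity values
are reproducible across versions. Circularity 4πA/P² can slightly exceed 1
on rasterized near-circles; reported values are clamped at 1.0. The size
slider is the equivalent-circle diameter 2√(A/π) in pixels, matching the
segmentation diameter parameterization. Both filter ranges are inclusive.
Filtering only annotates records (`included` + reason string); aggregates
use included cells and are recomputed whenever ranges change, either by a
fresh run or by `refilter` on the stored per-cell tables.

## Radial averaging

Center = the cell's binary-mask centroid rounded to the nearest pixel
(robust to channel-specific enrichment; intensity weighting would drag the
center toward whichever channel is brightest). Radius bins are Euclidean
distances rounded to nearest (symmetric bins). Means are taken over all
bounding-box pixels, matching the bounding-box construction of the output
image; a mask-only mode exists for sensitivity analysis. Because rings
partition the bounding box, ring means are conserved exactly, and 90°
rotation about the center permutes pixels within rings, so profiles are
exactly invariant — both properties are tested against an independent
brute-force oracle at 1e-9.

Scaled profiles are linearly interpolated onto a common target length
(default 100 bins, matching the default diameter's radius scale); endpoints
and monotonicity are preserved. Unscaled profiles keep their native length
and are padded with missing values during aggregation, so per-bin n shrinks
with radius. Ensemble SEM uses the sample (n−1) standard deviation divided
by √n per bin. Normalization divides the group mean profile (not each
cell's profile) by its maximum; the SEM is scaled by the same factor.

Note that a bounding-box profile extends to the box corners (≈√2 × the mask
radius), so a structure at radius fraction *f* of the cell radius appears
near bin f/√2 × L of a scaled profile, not f × L. The generator therefore
records, per synapse and channel, the argmax of the noise-free profile; the
geometry-recovery tests compare noisy measurements against that
construction-derived expectation.

Group outputs per condition and channel: all radial-averaged cells are
zero-padded and centered to the largest bounding box, then written as a
montage (⌈√n⌉ × ⌈n/⌈√n⌉⌉ grid), a stack (one plane per included cell, in
cell order) and the per-pixel mean of the stack, named
`<Channel>_radMontage.tif` / `_radStack.tif` / `_radTotAv.tif`.

## Colocalization

Standard Pearson product-moment coefficient of the two intensity vectors
under one cell's label (mask pixels only — the quantity of interest is
colocalization across the synaptic interface, not the bilayer). Cells with
fewer than two pixels or a zero-variance channel report a missing value
with a reason instead of failing. Summaries per condition × channel pair:
per-cell values, per-replicate medians, overall median and IQR. No
Manders/Costes variants; a pixel-shuffle null is available as a diagnostic.

## Synthetic data generator

Each synthetic synapse is a disk with three concentric domains — central
(radius fraction f_c = 0.3), intermediate annulus [f_c, f_p = 0.8] and
distal annulus [f_p, 1] — mirroring cSMAC/pSMAC/dSMAC organization. A
channel is background + amplitude × (weighted, σ = 2 px edge-smoothed
domain indicator) + Gaussian noise, clipped at 0. Defaults chosen as the
study conditions: 512×512 fields, radii uniform in [40, 55] px (matching
the 100 px default diameter), background 100, per-channel noise SD 10–20
(segmentation-channel SNR ≥ 5), 3 replicates assigned round-robin over
fields, rejection-sampled non-overlapping placement with a 10 px minimum
edge gap.

Two calibrations make ground truth exact rather than approximate:

- **Enrichment** is parameterized as the realized mask-mean fold: the
  amplitude is solved per synapse so the noise-free mean under the mask
  equals fold × background exactly, despite edge smoothing (which would
  otherwise depress the realized fold by ~5% at r = 30).
- **Correlated channels** (the flat ligand pair) carry standardized shared
  noise B = ρZ_A + √(1−ρ²)Z_B and no domain structure, so the expected
  within-mask PCC equals ρ exactly. Domain-structured channels shared
  between a pair would add deterministic common signal and bias the
  coefficient away from ρ.

What the generator does *not* emulate: TIRF point-spread functions, Poisson
photon statistics (Gaussian noise is used; a realistic camera adds
shot-noise scaling), microclusters and their dynamics, uneven illumination,
spectral crosstalk, or irregular cell outlines. Passing tests therefore
establish the correctness of the operators and the pipeline plumbing under
idealized, radially organized inputs — not segmentation robustness on
difficult real images, which is what the external deep-learning backend
seam is for.

## Numerical and formatting choices

- CSVs are written with pandas' shortest round-trip float repr and read
  back with round-trip parsing. This keeps per-cell storage lossless, which
  is what makes `refilter` byte-identical to a fresh run with the same
  ranges (a truncating fixed-precision format would break medians in the
  last digit; the default pandas float parser is off by 1 ulp often enough
  to matter).
- Rounding of centroids and radii uses IEEE round-half-to-even
  (`np.rint`), applied consistently in the operators and the test oracles.
- Degenerate inputs are non-fatal wherever the data, not the caller, is at
  fault: empty folders, blank fields, constant channels and zero
  denominators produce warnings and missing values; contract violations
  (shape mismatches, unknown config keys, unavailable backends) are fatal.

## Problem sizes in the test suite

The bundled tests and the acceptance script run on generated data sized for
desk-scale verification: 32×32 oracle images; 160×160 fields with 12–16 px
cells for end-to-end determinism checks; and the full-scale study
conditions (512×512 fields, 40–55 px radii) for correlation recovery
(4 conditions × 52 cells), fold-change recovery (20 cells) and segmentation
count fidelity (50 fields). These sizes reproduce the statistical behavior
of the estimators (sampling error of a per-cell PCC at n ≈ 7000 mask pixels
is ≈0.01) while keeping the whole suite under a minute.
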