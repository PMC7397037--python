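# Methods

## Measurement model

### Zonal partition and I_cgd

The ooplasm mask is partitioned by the Euclidean distance transform:
`central = {pixels with distance to the mask boundary >= d*}`, with `d*`
chosen among the distinct distance values to minimize the deviation of the
central area fraction from the target (default 0.8), ties broken toward
the larger central region. This is a uniform-width peripheral band; on a
disc of radius R it coincides with the radial construction (central
radius √0.8·R, band width (1−√0.8)·R ≈ 0.106·R). The band construction
was preferred over radial scaling from a centroid because it extends
naturally to non-circular masks and needs no centre estimate. The
achieved fraction and `d*` are always reported so downstream statistics
can audit partition error; the achieved fraction must sit within a
tolerance (default 0.02) of the target or the partition is refused
(masks under 500 px cannot meet it and are rejected outright).

Discretization note: on pixel grids the selected `d*`/R ratio deviates
from the continuum value (1−√0.8) by up to ~0.3 px/R (distance values are
measured between pixel centres), i.e. the ratio is accurate to ±0.01 for
R ≥ 100 px and improves with radius.

I_cgd is the ratio of arithmetic means of **raw** intensities over the
two zones — no background subtraction, flat-field correction or
normalization — matching the definition of the index as a ratio of
average signal intensities. Consequences worth knowing: the index is
invariant to global intensity scaling but *not* to additive background
(background pushes it toward 1), and spot tails that blur across the
mask boundary bias the peripheral mean slightly downward (with uniform
granule placement the expected index is ≈ 0.9, not 1.0, at the packaged
study geometry — the generative-model oracle in the test suite computes
this expectation exactly and the estimator is required to match it).

### Segmentation

Pipeline: Gaussian smoothing (default σ = 4 µm — large enough that the
granule texture, not individual spots, thresholds as one region), Otsu
threshold, morphological closing, hole filling, largest component, then
an edge-profile calibration: for a boundary blurred with σ, a threshold
sitting at fraction α of the near-edge foreground level places the
contour σ·Φ⁻¹(α) away from the half-level point, so the mask is eroded or
dilated by that predicted offset. The foreground level is estimated from
a ring just inside the edge (1σ–3σ deep) so that cortically-biased
granule patterns — bright rim, dim centre — calibrate against the level
that actually forms the edge. Residual bias is a few percent outward in
area; the mean Jaccard overlap with the generative disc exceeds 0.9
across the simulator's operating range (SNR ≥ 5).

The zona pellucida is dark in the granule channel and is therefore
excluded by construction; the DNA channel is ignored. Images whose
exterior is exactly zero are recognized as pre-masked and returned
unchanged (`apply_mask` establishes the convention: exterior exactly 0,
ooplasm strictly positive), which makes segmentation idempotent under
exterior masking.

### Spot detection and density

Multi-scale Laplacian of Gaussian: scale-normalized responses
`-σ²∇²G_σ * I` at each scale (an isolated Gaussian spot of amplitude A
peaks at ≈ A/2 at its own scale), 3D local maxima above a response
threshold, then greedy non-maximum suppression at radius √2·scale
(strongest first, deterministic tie-break on position). Scales default to
the granule diameter range 0.2–0.6 µm converted via σ = diameter/2.355
and floored at one pixel; scales below one pixel are refused as
unresolvable.

Density follows the three-window protocol: three disjoint axis-aligned
windows placed with a seeded RNG fully inside the sampling region
(anchor validity via an integral image; placement refused if three
disjoint windows cannot fit), spot centres counted per window with
half-open bounds (a centre on a shared edge lands in exactly one
window, making counts additive), per-oocyte density = unweighted mean of
the three window densities in CGs per 100 µm². With equal-size windows
the unweighted mean coincides with pooled count/pooled area.

### Group comparison

Pooled-variance Student's t (df = n₁+n₂−2) by default — the classical
"independent samples t-test" of desktop statistics packages — with Welch
available by flag; two-sided p-values; significance flagged at a
configurable α (default 0.05); SD reported with the n−1 denominator. No
multiple-testing correction: one contrast per measurement. Zero variance
in both groups with equal means raises an error rather than returning an
undefined statistic.

### Transcript summary

Direction calls use inclusive fold bounds (≥ 2 up, ≤ 0.5 down; the
packaged table's boundary-nearest value, 0.4887, must count as down) and
a strict p cut (< 0.05). Fold change is the after/before expression
ratio, so downregulation is encoded as values below 1. p-values are used
as printed (they are already corrected upstream); no re-correction. The
GO Z-score is (n_up − n_down)/√count over the term members present in
the DE table; absent members are dropped and logged, and |z| ≤ √count
always. The occurrence matrix is binary gene-by-term incidence with rows
sorted by |log₂ fold change| descending.

The packaged `go_membership_synthetic.csv` is **synthetic and
illustrative**: real term membership depends on the annotation release,
so quantitative GO analyses must supply their own membership CSV. The
packaged file is constrained only by the qualitative structure of the
study it emulates (all six upregulated genes in "cellular component
morphogenesis"; the matrix-metalloproteinase gene in the two branching
terms).

## Synthetic data

### What the generator emulates

Equatorial sections: a disc-shaped ooplasm (radius default 60 µm —
a ~120 µm porcine-scale oocyte) on a dark background, with `n` Gaussian
granule spots. A fraction `p` (the peripheral bias) is placed uniformly
in the outer annulus holding 20% of the disc area (inner radius √0.8·R);
the rest uniformly over the whole disc, so `p = 0` is fully homogeneous
and `p = 1` fully cortical, and the placement model is geometrically
conjugate to the 80/20 measurement partition. Surface fields: a
homogeneous Poisson process at a target density per 100 µm². Spot
centres are continuous (sub-pixel); rendering evaluates the Gaussian at
pixel centres (σ < 1 px is refused as aliasing); granules may overlap —
no excluded-volume rule. Noise models: none, additive Gaussian, or
Poisson; images are clipped at zero. Cohorts jitter each oocyte's radius
±10% and granule count (or density) ±20%.

Defaults are realistic confocal scale: 0.2 µm pixels, granule σ 0.25 µm
(the upper end of the 0.2–0.6 µm diameter range), spot amplitude 60 over
background 5 with Gaussian noise SD 2. Background and noise levels are
config values, not literature estimates — no published characterization
of the real acquisitions exists.

### What it does not emulate

No optics-grade PSF (single isotropic Gaussian only), no z-dependence or
photobleaching, no zona pellucida or cumulus-cell rendering, no
nucleus/germinal-vesicle structure, no spatially varying background.
Passing tests therefore demonstrate correctness of the *estimators under
the stated generative model*, not robustness to every real-microscopy
artifact; in particular real images with bright zona rims or uneven
illumination may need supplied masks.

### Boundary-blur bias

Spot tails leaking across the disc edge depress the peripheral mean; the
bias is part of the measurement model and is *captured by the oracle*
(closed-form expected image via the Rice CDF) rather than corrected.

## Study problem sizes and numerical choices

Replicate studies run on scaled-down geometry so that hundreds of
replicates complete in minutes while exercising the identical estimators:

* Bias ordering and power: 110 px sections, 0.5 µm pixels, R = 23 µm,
  250 granules, σ = 0.6 µm, SNR ≈ 27; 30 oocytes/group, 100 replicates.
* Type-I error: 80 px sections, R = 16.5 µm, 150 granules; 1000
  equal-config replicates (binomial 95% band at α = 0.05 is ±0.014).
* Density recovery: 100×100 µm fields at 0.1 µm pixels, granule
  σ = 0.10 µm (small end of the size range, so individual granules stay
  resolvable at the 20–100 per 100 µm² densities the protocol reports),
  amplitude 60, noise SD 8 (SNR 7.5), detection scales {0.10, 0.12,
  0.15} µm, response threshold 11 (≈ 5× the LoG-filtered noise SD),
  three 30×30 µm windows; 50 fields. The residual undercount at the top
  of the density range (~10–15%) is resolution-limited pair merging, a
  physical property of spot counting at that density, not a detector
  defect.
* Zonal studies measure on the generative truth masks so they
  characterize the statistic itself; segmentation accuracy has its own
  suite.

Seeding: one global seed; each stage/replicate derives a child seed by
hashing (seed, stage name) with BLAKE2s, so stages are independent and
reproducible in any execution order. Identical config + seed reproduces
images bit-exactly.

The demonstration configs (peripheral biases 0.2021 and 0.4475 at the
full-scale default geometry) were solved once from the closed-form
expected-image model so the cohort-mean I_cgd lands near 1.5 and 2.2 —
the regime separating low from high meiotic competence. They are an
illustration of the pipeline's operating point, not a reproduction of
any real dataset: no raw images underlie them.

## Known limitations

* The Otsu-based segmenter retains a small outward area bias (the demo
  driver reports truth-mask and segmented measurements side by side so
  the induced I_cgd shift is visible); irregular or low-SNR real images
  should use supplied masks.
* I_cgd is background-sensitive by definition (raw intensities); the
  index is comparable only across images acquired with identical
  settings.
* Spot counting saturates at densities where inter-granule spacing
  approaches 2σ of the spot profile.
* Whether the real "central 80%" was constructed radially or by uniform
  band width is unknowable from the assay description (identical on
  discs); the band-width construction is implemented. Whether the zona
  pellucida or the germinal vesicle were excluded from the original
  measurements is likewise unstated; mask provenance is recorded so both
  conventions can be compared.
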