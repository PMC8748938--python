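# Methods

## Scope and data model

The package implements the quantitative core of a tumor-microenvironment
mIF analysis: cell identification from co-registered binary channel masks,
boolean phenotyping, fixed-radius proximity statistics, nonparametric
cohort comparisons, and RLE-CPM-based transcriptome stratification. The
central exchange object is the **cell table**: one row per cell with planar
coordinates in µm, one boolean column per marker channel (PanCK, PGRN,
MHCI, CD8, GzmB — DAPI marks nuclei and is never a marker flag), and
boolean phenotype columns added by classification. Masks carry their pixel
size so every downstream statistic is in µm.

Coordinate convention, used everywhere: x runs along image columns, y along
rows (growing downward), pixel indices are 0-based, and pixel centers sit
at (index + 0.5) · pixel_size. Distances are Euclidean,
centroid-to-centroid; the pairing radius is a closed threshold (a pair at
exactly the radius counts — a measure-zero event for continuous
coordinates, so the convention is documented rather than consequential).

## The tissue simulator

Patient mIF images for this kind of study are typically not deposited, so
all imaging-side stages are exercised on synthetic tissue whose statistical
structure matches what the analysis assumes:

* **Tumor nests** follow a Thomas cluster process: nest centers are a
  homogeneous Poisson process of intensity κ (`nest_parent_intensity`,
  default 2·10⁻⁵ /µm² — ~20 nests per mm²); each nest draws
  Poisson(µ = `nest_mean_cells`, default 150) cells scattered isotropically
  with Gaussian σ (`nest_sigma_um`, default 40 µm). Offspring falling
  outside the window are discarded (no edge correction anywhere; border
  neighborhoods are simply truncated).
* **PGRN status** is assigned per nest (probability `p_nest_pgrn`, default
  0.5, that a nest is PGRN-high), then per cell within high nests
  (`p_pgrn_within`, default 0.9). Cells of PGRN-low nests are PGRN−. This
  two-level scheme emulates the intratumoral heterogeneity of high- and
  low-PGRN tumor regions within one section; setting `p_nest_pgrn = 1`
  degenerates to a purely per-cell assignment.
* **MHCI** is drawn per tumor cell conditional on PGRN:
  `p_mhc_given_pgrn_pos` = 0.2, `p_mhc_given_pgrn_neg` = 0.7 by default,
  i.e. MHCI positivity depleted on PGRN+ tumor cells.
* **Stroma** is a homogeneous Poisson background (`lambda_stroma`,
  default 8·10⁻⁴ /µm²) with all markers negative.
* **CD8 exclusion.** CD8 candidates are homogeneous Poisson
  (`lambda_cd8`, default 6·10⁻⁴ /µm², i.e. 600 per default 1 mm² window)
  and are independently thinned with retention probability
  ρ(d) = ρ_min + (1 − ρ_min) · min(1, d / R), where d is the distance to
  the nearest PGRN+ tumor cell, R = `excl_radius_um` (default 50 µm) and
  ρ_min = `excl_floor` (default 0.2). R = 0, or the absence of any PGRN+
  tumor cell, disables thinning entirely. The linear ramp is a choice of
  analytic convenience; any monotone ramp produces the qualitative
  exclusion, and the defaults are illustrative rather than fitted — no
  published estimate of the exclusion strength exists to fit against.
  Retained CD8 cells are GzmB+ with probability `p_gzmb_given_cd8` (0.4).

Each cell class draws from its own counter-based substream
(`numpy.random.SeedSequence(seed, spawn_key=(k,))`), so enabling or
disabling one class (e.g. CD8) never perturbs the realization of another —
this is what makes ablation comparisons (exclusion on vs off) exact.

Rendering rasterizes disks: a pixel is true iff its center lies within the
disk radius of a cell. Nucleus radius defaults to 3 µm, marker disks to
5 µm at 1 µm/px. Rendering is deliberately idealized — no grayscale
intensities, PSF, noise, nucleus-shape realism or 3D structure — so passing
round-trip tests demonstrate the correctness of the detection/assignment
logic, not robustness to real staining artifacts.

### What the generator does not emulate

Real tissue has irregular nucleus shapes, touching and overlapping nuclei,
intensity gradients, autofluorescence, and tissue-level anatomy (ducts,
vessels). Consequences: the detector does not split touching nuclei (no
watershed — declared limitation), and recovery guarantees are stated for
isolated nuclei only (see round trip below).

## Image-to-cell-table stage

* **Thresholding**: pixel true iff intensity ≥ t; `"otsu"` maximizes
  between-class variance and is refused on constant images. Because the
  histogram-based Otsu value follows a strict `>` convention, the returned
  cut is shifted to the smallest observed value above it so the package-wide
  closed (≥) convention holds.
* **Detection**: one cell per connected component of the DAPI mask,
  8-connectivity by default (4 available), centroid at the mean pixel
  center, ids in raster-scan discovery order, components under
  `min_area_px` (default 4) discarded as debris.
* **Marker assignment**: a cell's captured region is its nucleus component
  dilated by `dilation_um` (default 3 µm, Euclidean via distance
  transform); a marker is positive when the overlap with the captured
  region reaches `min_overlap_fraction` (default: any overlapping pixel).
  When only centroids exist (cells loaded from CSV), a disk of radius
  `dilation_um` stands in for the footprint. Whether the original
  quantification required nuclear or expanded-region overlap is not
  determinable from published descriptions; both are supported.
* **Positive fraction**: positives over all nuclei-detected cells; an empty
  table is an error rather than NaN.

**Round trip.** With marker disks equal to the nucleus disk and no
dilation, two disks at center distance > 2r share no pixel, so cells whose
nearest neighbor exceeds 2r are recovered with exact marker flags. On a
raster, two disjoint disks can still touch diagonally when the gap is below
one pixel diagonal, so the isolation condition used in the round-trip
benchmarks carries a 2√2·pixel margin beyond 2r. Under this condition the
benchmark recovers 100% of isolated cells with fully correct flags.

## Spatial statistics

Pairing uses a KD-tree (`scipy.spatial.cKDTree`) and is property-tested to
agree exactly with an O(n²) all-pairs oracle. A cell appearing in both the
anchor and partner group (same id) never pairs with itself. The per-anchor
unique-neighbor count is over distinct partner ids; anchors with no pairs
report 0 and stay in the denominator of group means. Phenotype-conditional
marker fractions are computed **per image** and compared **across images**
(matching a per-patient design with n = 8 images); pooling across images is
possible by relabeling but is not the default.

Calibration of the whole per-image-then-across-images procedure is measured
by simulation: with equal MHCI probabilities in both tumor phenotypes, the
two-tailed Mann–Whitney comparison of per-image fractions rejects at
α = 0.05 in ≈3.5% of 400 simulated 8-image cohorts (the mild conservatism
comes from the continuity-corrected normal approximation at n = 8 vs 8);
with probabilities 0.1 vs 0.8 it rejects in 100%.

## Cohort statistics

* **Median dichotomization**: cutoff = sample median (mean of middle order
  statistics for even n); strictly-above → high; ties at the median → low.
  The tie rule is a documented convention — published cohort splits report
  exact halves without stating one — and is configurable in effect by
  transforming values upstream.
* **Mann–Whitney**: U from midranks; reported U is the smaller one-sided U.
  Exact enumeration when n_x + n_y ≤ 12 with no ties, otherwise normal
  approximation with tie-corrected variance and continuity correction
  (delegated to `scipy.stats.mannwhitneyu`; verified against a hand-written
  exhaustive-permutation oracle over all 1272 tie-free rank patterns with
  n_x = n_y ≤ 6, max |Δp| at machine precision). No multiple-testing
  correction is applied inside the module.

## Transcriptome stratification

* **RLE-CPM**: reference = per-gene geometric mean of count proportions
  over genes positive in every sample; raw factor = per-sample median ratio
  to the reference; factors rescaled to geometric mean 1;
  CPM = count / (library size × factor) × 10⁶. Genes containing zeros are
  excluded from the reference only, never from the output. Verified
  algebraically and numerically (rtol 10⁻⁶) against edgeR's
  `calcNormFactors(method="RLE")`, which computes the same factors up to a
  constant that cancels in the rescaling.
* **Median split by gene** restricts one gene's CPM row to a sample subset
  (e.g. stroma-only) and delegates to the median dichotomizer.
* **Paired Spearman** correlates log2(CPM + 1) between compartments of the
  same subject; midranks for ties; two-tailed p via the t-approximation
  t = ρ√((n−2)/(1−ρ²)). The pseudocount is irrelevant to the result (rank
  invariance) and kept only so plotted log values are finite.
* **Ranking statistic**: −ln(p)·sign(log2FC), natural log (any base is
  rank-equivalent; the base affects printed magnitudes only), sorted
  descending with lexicographic gene-id tie-breaks; p = 0 is rejected —
  callers must floor p. The differential-expression fit itself is consumed
  as a (gene, log2FC, p) table; count-model fitting is out of scope.

### Synthetic paired cohort

`simulate_counts` emulates a laser-capture cohort of 64 subjects with one
epithelium and one stroma sample each: negative-binomial counts with
log-normal gene means (base mean 50), log-normal library-size factors
(σ = 0.3), and a designated stratification gene ("GRN") that is bimodal in
stroma — half the subjects at 4× the low-component mean (300). The
designated gene's epithelial component is drawn independently of its
stromal one, so the compartments are uncorrelated by construction. The
residual within-component dispersion is 0.06 (biological CV ≈ 25%): the
bimodal component carries the between-group biological variation, and this
residual level makes the 4-fold-separated components recoverable by the
median split for ≥ 95% of samples — a designed property of the generator,
verified across seeds. The 64-subject layout yields the 32/32 split used in
the stratification benchmark.

## Problem sizes

Benchmarks run at desk scale: 50 random pairing instances up to 1000 cells
per side; one 600×600 µm round-trip field; 20 seeds of the default 1 mm²
tissue for the exclusion effect; 400 cohorts of 8 images (400×400 µm
tumor-only fields, ~700 tumor cells each) for calibration and power; the
64-subject synthetic cohort for stratification. The full benchmark suite
completes in well under a minute.

## Estimator interfaces

Transform-shaped stages double as scikit-learn estimators:
`RLECPMNormalizer` (samples × genes orientation, fitted `size_factors_`),
`MedianDichotomizer` (fitted `cutoff_`, applies a learnt split to new
subjects), `PhenotypeClassifier` and `CellDetector`. The generator and the
spatial/test statistics have no fit/transform semantics and remain
functions.

## Known limitations

No instance segmentation of touching nuclei; no edge-corrected spatial
estimators (Ripley's K etc. are out of scope); no spectral unmixing or
intensity modelling; exclusion-ramp shape and strength are illustrative;
the Mann–Whitney normal approximation is mildly conservative at very small
per-group image counts; differential-expression fitting and enrichment
scoring are consumed from, and emitted to, external tools rather than
re-implemented.
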