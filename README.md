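# proximif

Spatial proximity statistics for multiplexed immunofluorescence (mIF) of the
tumor microenvironment, with a synthetic tissue generator, and bulk-RNA-seq
cohort stratification.

## The problem

In pancreatic cancer, progranulin (PGRN)-expressing tumor cells are associated
with low MHC class I (MHCI) expression and poor infiltration of cytotoxic
CD8+/GzmB+ T cells: tumor regions rich in PGRN+ tumor cells tend to exclude
CD8 cells, while PGRN− tumor regions of the same section are MHCI+ and
infiltrated. Quantifying this requires (a) turning channel masks of a
multiplexed stain (DAPI, PanCK, PGRN, MHCI, CD8, GzmB) into a table of cells
with marker flags, (b) classifying cells into compound phenotypes
(e.g. PGRN+PanCK+ tumor; CD8+GzmB+ effector T cell), (c) counting, for each
anchor cell, the distinct partner cells within a fixed radius — 50 µm
by convention — and (d) comparing per-image statistics between groups with a
two-tailed Mann–Whitney test. On the transcriptome side, bulk cohorts are
RLE-normalized to CPM, split into gene-high/low halves at the median, and
differential-expression results are ordered by the signed statistic
−log(p)·sign(log2FC) for preranked gene-set enrichment.

Patient images for such studies are rarely deposited, so the package ships a
marked point-process **tissue simulator** that reproduces the statistical
structure the analysis assumes — clustered tumor nests (a Thomas process)
with nest-coherent PGRN status, PGRN-conditional MHCI positivity, and CD8
cells thinned near PGRN+ tumor cells with a distance ramp
ρ(d) = ρ_min + (1 − ρ_min)·min(1, d/R) — making every downstream stage
testable end to end.

## The statistics at the core

* **Fixed-radius pairing.** For anchor set A and partner set P, the pair set
  is {(a, p) : ‖x_a − x_p‖ ≤ r}, centroid-to-centroid, closed threshold,
  r = 50 µm by default. Per anchor we report the number of *unique* partners
  within r (anchors with none count 0) and, over all pairs, the mean pair
  distance. Verified exactly against an O(n²) all-pairs oracle.
* **Phenotype-conditional fractions.** Per image, the fraction of MHCI+
  cells within PGRN+PanCK+ and within PGRN−PanCK+ tumor cells; the per-image
  fractions are compared across images by a two-tailed Mann–Whitney U test
  (exact for small tie-free samples, tie-corrected normal approximation with
  continuity correction otherwise).
* **Median dichotomization.** Cutoff = sample median; value > cutoff → high,
  ties at the median → low, so 64 distinct values split 32/32.
* **RLE-CPM.** Median-of-ratios size factors on count proportions over genes
  positive in every sample, rescaled to geometric mean 1;
  CPM_ij = count_ij / (L_j·f_j) × 10⁶. Cross-checked against edgeR's
  `calcNormFactors(method="RLE")`.
* **Ranking statistic.** −ln(p)·sign(log2FC) per gene, sorted descending,
  written as a standard 2-column `.rnk` file.

## Worked example

```python
import proximif as px

cfg = px.SimConfig(seed=11)                  # 1 mm x 1 mm synthetic tissue
cells = px.classify_cells(px.generate_tissue(cfg))

for name in ("tumor_pgrn_pos", "tumor_pgrn_neg"):
    anchors = cells[cells[name]]
    cd8 = cells[cells["cd8"]]
    ps = px.pairs_within_radius(anchors, cd8, radius_um=50.0)
    s = px.neighbor_summary(ps, anchors["id"], cd8["id"])
    print(f"{name}: {s.n_anchors} anchors, "
          f"mean unique CD8 neighbors {s.mean_unique_partners:.2f}")

res = px.conditional_marker_fraction(
    cells.assign(image=0), "tumor_pgrn_pos", "tumor_pgrn_neg", "MHCI")
print(f"MHCI+ fraction: PGRN+ tumor {res.fraction_a:.3f}, "
      f"PGRN- tumor {res.fraction_b:.3f}")
```

prints

```
tumor_pgrn_pos: 1784 anchors, mean unique CD8 neighbors 1.32
tumor_pgrn_neg: 1865 anchors, mean unique CD8 neighbors 2.92
MHCI+ fraction: PGRN+ tumor 0.203, PGRN- tumor 0.706
```

PGRN+ tumor cells see fewer than half as many distinct CD8 neighbors within
50 µm as PGRN− tumor cells (the configured exclusion at work), and MHCI
positivity is strongly depleted among PGRN+ tumor cells — both under the
generator's default conditional probabilities (0.2 vs 0.7).

On the transcriptome side:

```python
counts, annot, truth = px.simulate_counts(seed=11)   # 64 paired subjects
cpm = px.rle_cpm(counts)
stroma = annot.loc[annot["compartment"] == "stroma", "sample"].tolist()
split = px.median_split_by_gene(cpm, "GRN", stroma)
print(f"GRN split (stroma): {split.n_high} high / {split.n_low} low")
# GRN split (stroma): 32 high / 32 low
```

A command-line interface mirrors the library
(`proximif simulate | render | detect | phenotype-markers | spatial |
dichotomize | compare | stratify | rank | paired-correlation`); see
`proximif --help`.

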