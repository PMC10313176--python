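# Methods

This note documents the models behind `pnatlas`, the parameters that
matter, the design choices made where the design was genuinely open, and
what the synthetic studies do and do not demonstrate.

## Synthetic study design

### Count model

Counts are gamma-Poisson (negative binomial). Each gene *g* carries a
base weight *w_g* ~ LogNormal(0, 1); a cell of group *k* (cell state
and/or terminal subtype) multiplies the weights of *k*'s marker genes by
`2**marker_log2fc` (default 2, i.e. fourfold). The cell's expected
expression is `μ_cg = L_c · w_cg / Σ_g w_cg` with library size
*L_c* ~ LogNormal(log 6000, 0.25); the realized count is
Poisson(Gamma(1/φ, μ φ)) with a single shared dispersion φ
(`nb_dispersion`, default 0.1). Defaults were chosen to give realistic
QC behavior — median ~1500 detected genes of 2000 per cell, so healthy
cells pass the ≥ 1000-gene filter.

Groups: five embryonic cell states and six terminal subtypes, ten marker
genes each, all marker sets disjoint. E14.5-style datasets carry true
states only, P5-style true subtypes only, and E18.5-style both (subtypes
assigned to differentiated cells), which supplies the cross-stage
matching fixture. Cells are allocated to groups by one multinomial draw
per replicate whose probabilities carry logistic-normal jitter
(`replicate_logit_sd`, default 0.1) — real between-animal variability of
composition is not reported anywhere we could anchor it, so this is a
free parameter with a deliberately modest default; the composition
power analyses use 0.05 ("low jitter").

Default compositions: the control E14.5 state vector is
(0.093, 0.150, 0.300, 0.293, 0.164) and the mutant
(0.310, 0.150, 0.243, 0.197, 0.100), reproducing the observed
progenitor increase (9.3% → 31%) and migrating-2 decrease
(29.3% → 19.7%) with the intermediate-progenitor share held fixed;
the unstated remainder was split plausibly between migrating-1 and
differentiated cells. Subtype shares at P5 are
(0.24, 0.21, 0.18, 0.17, 0.11, 0.09), making PN5 and PN6 the smallest
populations. Mitochondrial genes (2% of the panel) are scaled to a 0.4%
expected share of each library, far below the 1% QC cutoff; an optional
spiked fraction of cells is raised to 3% to exercise the filter.

The nine-transcript panel is named after the field's subtype markers
(Sst, Ntng1, Prox1, Ephb1, Cdkn1c, Hoxb5, Slc17a6, Etv1, Cdh8) purely as
labels. Eight are subtype-selective (PN1 and PN2 carry two each), Cdh8
is pan-PN. Panel genes get elevated base weights (6× the median gene,
8× for Cdh8) so that, like real selective markers, they are
well-detected.

### Seeds

All outputs are pure functions of `SyntheticConfig.seed`. Child
generators are derived with `numpy.random.SeedSequence(seed, spawn_key)`
using fixed stream keys: genes (0), cells per (genotype, replicate) (1),
images per section (2), binding annotation (3). Gene-level randomness
never depends on genotype, so all datasets from one configuration share
a genome.

### ISH image model

Each (section, transcript) stack is 10 z-slices 0.9 μm apart at 2 μm
pixels over a 700 μm × 1000 μm field. The six subtype territories are
rectangles in a 2 × 3 grid occupying ~45% of the field (the synthetic
pons); spots fall in each territory at Poisson rate
`spot_density_per_um2 × signature` where the signature mirrors the count
model (fourfold for a subtype's own marker, 1.5 for Cdh8). Spots are
Gaussian kernels (σ 3 μm, continuous intensities — no camera model,
since only relative intensity matters downstream), and clipped Gaussian
background noise (SD 1.0) is added. A TdTom reporter channel covers the
union of territories. Territories are constant across sections; the
rostro-caudal drift of real sections is not modeled.

## Pipeline choices

- **Normalization** is global log-normalization,
  log(1 + 10⁴·count/library). The reference pipeline's variance-
  stabilizing regression and cross-replicate integration are
  deliberately omitted: the generator has no batch structure, so
  integration would only add machinery. This is a documented divergence.
- **PCA** centers and unit-scales genes (values clipped at ±10 SD), keeps
  the top 30 components, and fixes each component's sign so its
  largest-magnitude loading is positive (bitwise deterministic).
- **Clustering** builds a k = 20 shared-nearest-neighbor graph with
  Jaccard edge weights (pruned below 1/15) and runs Leiden modularity
  optimization at resolution 0.8 with a fixed seed. Communities smaller
  than `min_cluster_size` (10) — isolated outliers whose SNN edges were
  pruned — are dissolved into the nearest retained cluster centroid,
  mirroring the singleton grouping of the standard pipeline. Resolution
  is exposed because the appropriate value depends on dataset
  complexity.
- **Markers** are one-vs-rest Wilcoxon rank-sum tests; genes at
  BH-adjusted p < 0.05 are ranked by log₂ fold change and the top 10
  reported. Clusters with fewer than 3 cells are untestable and return
  nothing.
- **Pseudotime** is the projection of each cell onto the piecewise-linear
  path through the state centroids in PC space, rescaled to [0, 1] —
  a transparent stand-in for principal-curve trajectory fitting. Only
  the two-sample Kolmogorov–Smirnov comparison between genotypes is
  treated as the contract.
- **Composition testing** transforms replicate proportions with
  arcsin-square-root (logit available via `transform=`), chosen for
  stability at small proportions, and uses a pooled two-sample *t*-test —
  the moderated-*t* spirit at n = 3 replicates without empirical-Bayes
  machinery. Genotypes are ordered alphabetically, so the reported
  difference has a deterministic sign. Tests are two-sided. FDR is
  computed across the groups tested in one call. Note that proportions
  are compositional: planting a shift in one state necessarily moves the
  others, so "unshifted" power analyses are only meaningful for a state
  whose planted share is identical between genotypes.
- **Differential expression** uses the Wilcoxon rank-sum test on
  log-normalized values instead of a hurdle regression model; the
  contract preserved is the ≥ 10%-detection filter (in either genotype),
  BH FDR, and the strict DEG thresholds |log₂FC| > 0.25, FDR < 0.05.
  log₂FC compares de-logged group means with a 10⁻⁹ pseudocount.
- **Enrichment** crosses DEG status with binding-peak status over the
  background of *tested* genes (all detected genes available via the
  caller's choice of background set). Fisher's exact test is two-sided;
  the odds ratio is the conditional MLE with the exact 95% CI from
  inverting the noncentral hypergeometric test, because that is the
  estimator displayed alongside exact tests; Bonferroni uses the number
  of states tested in the run.
- **Friedman–Rafsky test**: the MST is built by Kruskal's algorithm with
  lexicographic (weight, i, j) tie-breaking so the tree — and hence R —
  is unique even with duplicate points. The null permutes sample labels
  on the *fixed* pooled tree; p = (1 + #{R_perm ≤ R_obs})/(n_perm + 1),
  one-sided (small R = separated), with resolution 1/(n_perm+1). The
  classical asymptotic z-score is reported as a diagnostic only. Cluster
  matching projects both datasets onto the union of their per-cluster
  top-10 markers, subsamples to 200 cells per side (seeded), and calls a
  pair matched when the test fails to separate it at α = 0.05; α, the
  feature space, and the cap are exposed because no canonical values
  exist.
- **Tiling** reads "34 μm × 31 μm" as width × height; tile size in
  pixels is rounded per axis. Ragged right/bottom remainder tiles are
  kept, flagged `partial`, and excluded from the per-transcript maximum
  used for normalization (a sliver's mean is noisy). The per-transcript
  maximum is taken over tiles, not raw pixels. Threshold comparisons
  (mean thresholding, Manders) are strict (>). Gaussian smoothing uses
  reflect padding; components are 8-connected, the boundary test
  4-connected with the image border counting as background. Midline
  cropping is a user-supplied crop, not automated.
- **KNN transfer** unit-normalizes each nine-component vector (a min-max
  scheme is available behind the same switch; whichever is chosen is
  applied identically to cells and tiles). Cross-validation is
  stratified sixfold with rows canonically sorted first, so accuracy
  does not depend on training-set assembly order. Vote ties break by
  smallest summed neighbor distance, then smallest label. A tile is
  in-boundary when its center pixel is inside the mask; all-zero tiles
  are `unassigned`. The RtTg/BPN anatomical partition is user-supplied
  metadata, never computed.

## Numerical and degenerate-input behavior

Strict inequalities follow the stated thresholds exactly (a cell at
exactly 1% mitochondrial UMIs is removed; a gene at log₂FC = 0.25 is not
a DEG). Zero-variance composition comparisons return p = 1 when means
are equal; states absent from every replicate are excluded with a
warning. A zero peak margin makes the odds ratio undefined (NaN, p = 1).
All-zero transcripts normalize to zero rather than dividing by zero.
Constant images are an explicit error in boundary detection (no pixel
exceeds the mean).

## Problem sizes

The test suite and the acceptance script run the study at the sizes the
generator defaults define: composition analyses at 2000 cells ×
3 replicates per genotype, cluster-number recovery at 3000 cells over
five seeds, the classifier benchmark at ~7000 cells per seed over five
seeds, FR calibration over 1000 null draws of 60 + 60 points in 10
dimensions, and one five-section image study per run.

## Limitations

The generator's groups are exchangeable blobs with disjoint marker
blocks — no doublets, batch effects, ambient RNA, continuous
trajectories between subtypes, or spatial gradients within territories.
Passing tests therefore demonstrate that the implementations are correct
and well-calibrated under the stated statistical structure, not that the
pipeline is robust to every artifact of real tissue data. The FR match
decision accepts the null ("cannot separate"), so its diagonal retention
rate is bounded by the test's own type-I error; matched calls should be
read as "no evidence of difference", as in any equivalence-by-failure
procedure.
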