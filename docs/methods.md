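# Methods

This note documents the models, conventions and defaults behind `stclust`,
and what the synthetic benchmark does and does not establish.

## Preprocessing

Raw counts pass through three stages before feature selection.

**Outlier filtering.** Per-gene and per-cell mean expression are screened
with inclusive Tukey fences: keep `Q1 − 1.5·IQR ≤ mean ≤ Q3 + 1.5·IQR`.
Genes are screened first; cell means are then recomputed on the retained
genes.  The inclusive bounds make the zero-IQR case behave sensibly: on a
constant matrix the fence collapses to `[Q1, Q3]` and nothing is removed,
while a gene whose mean sits far outside an otherwise tight distribution is
still dropped.  Tukey fences were chosen as a robust, parameter-light
concretization of "remove statistical outliers"; the multiplier (1.5) is
exposed.

**Small cell-type filtering.** Cells of truth classes holding strictly less
than 5% of the population are removed.  Frequencies are evaluated once on the
input, not iteratively, and a class at exactly the threshold is retained.

**Normalization.** Two paths, chosen per dataset:

* `lognorm` — counts are rescaled (default ×1000, for small-panel imaging
  data whose raw intensities are fractional), each cell is scaled to the
  median cell total, then `log1p`.  The median was chosen as the scaling
  target because it is robust and keeps the transform monotone per cell.
* `pearson` — analytic negative-binomial Pearson residuals under the offset
  model `μ_ij = (row_i total · col_j total) / grand total`, with
  `r_ij = (x_ij − μ_ij) / sqrt(μ_ij + μ_ij²/θ)`, fixed `θ = 100`, clipped to
  `±sqrt(n_cells)`.  These are the canonical defaults of the analytic
  residual normalization; entries with `μ_ij = 0` get residual 0.

## Gene selection

**HV, LOESS path** (used with `lognorm`-style data): per gene, the
coefficient of variation (sd/mean on the rescaled expression scale) is
regressed on log mean expression with LOESS (span 0.3, locally linear, no
robustness iterations — genes above the trend are the signal the statistic
must expose, so they must not be down-weighted as outliers).  The statistic
is observed CV minus fitted CV; candidates have statistic > 0.  Genes with
zero mean get a −∞ sentinel and are never candidates.

**HV, residual-variance path** (used with `pearson`): the statistic is the
per-gene variance of the residuals; candidates have variance > 1 (strict).

**HV levels**: low/medium/high keep candidates at or above the 50th/70th/90th
percentile (linear interpolation, ties included) of the *candidate*
statistics.  Taking percentiles over candidates rather than all genes keeps
the candidacy rule meaningful when many genes sit below the trend.

**SV selection**: low keeps genes with p < 0.05.  Medium and high nest
sequentially — medium keeps low's genes with p at or below the 25th
percentile of low's p-values; high keeps medium's genes at or below the 50th
percentile of medium's.  Sequential nesting guarantees high ⊆ medium ⊆ low
and therefore the monotone shrinkage that stringency levels are meant to
express.  P-values normally come from an external SV detector's output file;
the built-in fallback is a Moran's-I permutation test on the symmetrized
binary kNN spatial graph (k = 6), one-sided for positive autocorrelation,
with the add-one correction `p = (1 + #{I_perm ≥ I_obs}) / (1 + n_perm)` and
permutations shared across genes.  Constant genes get p = 1 by convention.

**Concatenation**: set union of the HV and SV selections, HV order first,
duplicates removed.  The "all genes" baseline is every gene surviving
preprocessing.

## Clustering

PCA (up to 50 components, capped by matrix rank; deterministic sign
convention: the largest-magnitude loading of each component is positive) is
followed by either:

* **sNN–Leiden** — kNN (k = 15, euclidean in PC space, ties broken by cell
  index) defines per-cell neighbor sets; edge weights are Jaccard overlaps of
  those sets, zero-weight edges pruned.  Leiden optimizes modularity with a
  resolution parameter over a grid (0.1–2.0, step 0.1), 10 runs per
  resolution with seeds 0–9.  The resolution whose runs most often produce
  exactly the ground-truth cluster count wins (ties to the smaller
  resolution); among its qualifying runs the medoid partition (highest mean
  pairwise adjusted Rand agreement) is returned, a deterministic reading of
  "pick the majority set".  If no resolution hits the target count, the grid
  expands geometrically up to three times before erroring.
* **kmeans** — k set to the truth class count, best of 10 restarts.
  Correlation distances are realized by row transformation (center + unit
  norm for Pearson; rank transform first for Spearman) followed by euclidean
  kmeans, which optimizes the correlation objective up to scale with a single
  well-tested optimizer.

**Label matching.** Predicted clusters are mapped onto truth classes by
correlating mean expression profiles, computed in the experiment's
union-level gene space for every gene set so that all gene sets are matched
in a common space and weighted F1 stays comparable across them.  Equal
cluster/class counts use the maximum-total-correlation one-to-one assignment
(Hungarian); otherwise each cluster maps to its best-correlated class.
Zero-variance profiles fall back to smallest euclidean distance, with a
warning.

## Metrics

AMI uses arithmetic-mean normalization (the dominant modern convention).
Pearson Gamma is computed over all O(n²) pairs up to n = 2000 and on a seeded
uniform subsample of 2000 cells beyond that; for Leiden-derived clusterings
it uses euclidean distance on the PC embedding, for kmeans the
method-appropriate distance.  A single predicted cluster leaves the
indicator constant and returns NaN with a warning.

Spatial neighborhoods are self-inclusive kNN sets with `k_spatial = 15` by
default (mirroring the sNN k), ties broken by cell index.  Including the
focal cell makes one-cell tissues degrade gracefully.  Entropy uses the
natural log; SC is invariant to the log base since a base change rescales all
`e_i` by a constant that cancels in the normalization.  When every
neighborhood is label-pure (Σe = 0) the weights fall back to uniform 1/n, so
SC reduces to plain per-cell accuracy.  Mean Spatial AMI uses the same
normalized weights as SC for consistency between the two spatial metrics,
with explicit small-sample conventions — identical restricted partitions
(including the all-one-label case) score 1, a zero normalizer scores 0 — and
the weighted sum is clipped to [0, 1] because AMI itself can be slightly
negative.

## Hypothesis testing

Gene-set comparisons use two-sided paired permutation tests on the mean
paired difference, pairing strictly by dataset (and method).  The null is
generated by independent sign flips of the differences: exact enumeration of
all 2ⁿ patterns for n ≤ 12 (p without the add-one correction), Monte-Carlo
sampling with the add-one correction otherwise (10,000 flips by default, so
p is never 0).  Significance categories for reports: `****` p < 1e-3,
`***` 1e-3 ≤ p < 1e-2, `**` 1e-2 ≤ p < 5e-2, `*` 5e-2 ≤ p < 0.1, `ns`
otherwise.  No multiple-testing correction is applied across the test
matrix; the bins annotate unadjusted p-values.

## The synthetic tissue generator

The generator produces the data regime in which HV and SV selections are
genuinely complementary:

* Cells are placed in the unit square (uniformly, or on a jittered lattice
  for the `grid` layout) and assigned to spatial domains — equal-width
  vertical stripes or Voronoi regions of random seed points.
* Each domain hosts a *localized* cell type; a configurable fraction of
  cells, sampled uniformly over the tissue, is reassigned to *dispersed*
  types independent of location.
* Three gene classes: *SV-pattern* genes modulate a base mean by a spatial
  surface (Gaussian hotspot, linear gradient, or sinusoid) independent of
  cell type; *HV marker* genes multiply the base mean by `exp(log-FC)` in one
  assigned cell type independent of position; *noise* genes keep the flat
  base mean.  Markers cycle over the dispersed types, because those are by
  construction the types carrying no spatial signal — separating them is the
  information HV selection contributes that SV selection cannot.  (With no
  dispersed cells configured, markers fall back to the localized types.)
* Counts are negative binomial with variance `μ + μ²/θ`, drawn as a
  gamma–Poisson mixture, with per-cell lognormal library-size factors applied
  to the means so the NB family stays closed.  Mean surfaces are stored on
  the dataset object for white-box tests.

Defaults (one tissue ≈ one imaging-platform field of view): 500 cells,
4 stripe domains, 4 localized + 3 dispersed types, dispersed fraction 0.3,
40 SV + 40 HV + 80 noise genes, base mean 2 counts, marker log-FC ln 3
(a 3-fold marker — the modest end of real marker effect sizes),
spatial amplitude 1.0 (≈ e-fold modulation across the tissue, spatially
coherent without dominating marginal variance), θ = 100 (so noise genes sit
at the analytic Pearson-residual null), library-size σ = 0.15.  All
randomness derives from a single seed through keyed substreams, so every
output is a pure function of the configuration.

**What the generator does not emulate**: segmentation errors, doublets,
platform-specific probe panels, batch effects, irregular tissue geometry,
cell-type-dependent library sizes, and gene–gene correlation beyond what the
type/domain structure induces.  Passing the synthetic benchmark therefore
shows that the pipeline ranks gene sets correctly *when the complementarity
regime holds*, not that any particular real platform exhibits that regime.

## Benchmark problem sizes

The self-contained benchmark (`run_synthetic_benchmark`, also used by
`scripts/acceptance.py`) runs ten default tissues with the Moran scorer at
499 permutations and the full Leiden recipe; the acceptance script adds a
2000-gene null calibration of the Moran scorer at 999 permutations.  These
sizes give stable medians and p-value resolution of ~0.002 for the
ten-dataset paired test while keeping a full run in the minutes range on a
single CPU.

## Known limitations

* The Moran fallback scorer shares permutations across genes; marginal
  p-values are exact, but gene–gene dependence of the p-values is not
  modeled (immaterial for thresholding, relevant if the p-values were fed
  into dependence-sensitive FDR machinery).
* Leiden tuning targets the ground-truth cluster count; on data where no
  resolution yields that count the run errors after grid expansion rather
  than returning a nearest-count partition.
* `filter_outliers` densifies sparse matrices; the pipeline is designed for
  desk-scale datasets (up to a few tens of thousands of cells), not atlases.
* Pearson Gamma is subsampled above 2000 cells; values on larger datasets
  carry Monte-Carlo noise (seeded, hence reproducible).
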