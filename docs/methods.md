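# Methods

This note documents the models and procedures implemented in `ctsvg`, the
parameter choices that matter, what the synthetic-data generator does and
does not emulate, and the numerical decisions taken where the design was
genuinely open.

## Coordinate conventions

All geometry lives in continuous full-resolution pixel coordinates with the
image convention (origin top-left, y downward). A 2 µm square with center
(cx, cy) and side s occupies the half-open region
[cx − s/2, cx + s/2) × [cy − s/2, cy + s/2), so the lattice tiles the plane
without double-counting boundary points. The square side in pixels is
derived from the Space Ranger scale-factor record as
2 µm / microns_per_pixel. No reader rescales coordinates; nucleus polygons
must be supplied in the same full-resolution frame.

## Square-to-cell assignment

1. **Nucleus size filter.** Segmentation artifacts (merged nuclei) are
   removed by discarding nuclei whose natural-log area exceeds
   mean + 2 sd of log areas (sample sd, n−1). A 1e-9 tolerance on the
   cutoff keeps equal-area nuclei intact when the sd is zero up to float
   jitter. A single nucleus is retained with a warning.
2. **Overlap approximation.** Exact polygon clipping per square/nucleus pair
   would dominate runtime; instead each square is divided into a 10 × 10
   subsquare lattice and the overlap area is estimated as
   (subsquare centroids inside the polygon) × area/100. "Inside" includes
   the boundary (even-odd with on-edge → inside), applied consistently. For
   convex nuclei of realistic size the absolute error is far below the
   4 × perimeter × subsquare-width bound we verify, and argmax assignment
   agrees with exact clipping on ≥ 95% of random configurations.
3. **Assignment and expansion.** Squares go to the argmax-overlap nucleus
   (ties to the smallest nucleus id — deterministic and arbitrary, since
   ties are measure-zero). Each nucleus is then scaled about its centroid by
   the linear factor √r, which makes the expanded area exactly r× the
   original; r defaults to 2, the empirical whole-cell/nucleus area ratio in
   multimodal segmentation data. A compatibility flag
   (`literal_ratio_scaling`) scales linearly by r instead, for
   interoperability with implementations that read the contour formula
   literally; that variant squares the area ratio and is not the default
   because it contradicts the stated area relationship. The second pass
   only touches squares left unassigned by the first, so nucleus-pass
   assignments are never overwritten.
4. **Abnormal cells.** A cell is dropped when it has no squares, when its
   assigned square area is below half its *expanded* cell area (the expanded
   polygon approximates the whole cell; configurable to the nucleus area),
   or when its squares are not a single 4-connected lattice component.
   4-neighbourhood is the conservative reading of "disconnected".

## Preprocessing and clustering

Cells detecting < 300 genes are removed, then genes positive in < 1% of
retained cells (count ≥ 0.01·n, no rounding) — cells first, then genes.
Counts are log-normalized: ln(1 + count/total × 10⁴) (10² in Xenium-style
evaluation, where panels are small). Dispersion-based highly variable genes
(2000; all genes when the panel is smaller), per-gene scaling clipped at 10,
PCA (top 10 PCs, full SVD — deterministic), a kNN graph (k = 20), and
Louvain community detection at resolution 1.2 follow the standard
single-cell workflow. Community detection is igraph's multilevel algorithm
seeded through Python's `random` module; clustering is a pure function of
(matrix, parameters, seed), which the testing stage exploits. Labels are
relabelled by decreasing cluster size for stable output.

## Spatial model and F statistic

Within a cluster, each gene's log-normalized expression is regressed on a
tensor-product cubic B-spline surface of the cell coordinates: an
intercept, K + 3 main-effect basis functions per dimension (K equidistant
internal knots spanning the cluster's observed coordinate range), and all
(K+3)² pairwise products, p = 1 + 2(K+3) + (K+3)² columns in total. The
per-dimension basis is the clamped K + 4 cubic B-spline basis with its
first function dropped; the dropped function is absorbed by the intercept,
keeping the design full rank (the full clamped basis, not the retained
columns, carries the partition of unity). Default K = 2 (p = 36): small
enough that clusters of a few hundred cells satisfy n > p with a healthy
residual margin, large enough for non-trivial surfaces; K is exposed
everywhere.

All genes share the design, so a single pivoted QR factorization serves the
whole expression matrix; rank-deficient designs (degenerate geometry) drop
dependent columns with a logged warning and reduce the effective p. The
statistic is the overall-regression F with p−1 and n−p degrees of freedom;
constant genes get F = 0 by convention, exact fits F = ∞. Clusters with
fewer than p + 10 cells after spatial filtering are skipped: with a residual
degree of freedom near zero the F statistic is numerically meaningless.

**Spatial isolation filter.** Before fitting, cells far from their cluster
mates are removed: the isolation score is the mean Euclidean distance to the
k nearest within-cluster cells, k = round(0.01·n) clamped to [10, 50]
(round-half-up; capped at n−1), and cells above mean + 6 sd are dropped.
The filter uses coordinates only. Genes positive in ≥ 1% of the remaining
cells are tested.

## Permutation test with clustering uncertainty

Clusters are estimated from expression, so treating them as fixed
understates the null variance of the F statistic. Community detection is
re-run under seeds 1..n_seeds (full-scale default 1000); each original
cluster is matched per seed to the reassigned cluster with the highest
Jaccard index (ties to the smaller label), and the `keep` (default 100)
highest-Jaccard matches across seeds are retained (ties to the smaller
seed). For each retained reassigned cluster the isolation filter is
re-applied, the coordinate *pairs* are permuted uniformly at random among
its cells, the design is rebuilt and the original cluster's retained gene
list refitted — yielding `keep` null F values per gene. Only community
detection is re-seeded; the PCA embedding and graph are deterministic and
reused.

A Gamma distribution is fitted per gene to its null values (maximum
likelihood, location fixed at zero, method-of-moments initialization; zero
nulls replaced by the smallest positive null × 10⁻³), and the p-value is the
fitted upper tail at the observed F — a smooth extrapolation beyond the
1/(keep+1) resolution of the empirical permutation p, which is the fallback
when the fit fails. The Gamma family is exact in the many-cell limit
(F(p−1, n−p) → Gamma(½(p−1), 2/(p−1)) as n → ∞) and per-gene fitting
respects each gene's own null scale. BH adjustment is applied within each
cluster; FDR ≤ 0.05 flags significance, and genes are ranked by p, ties by
descending F. At least 30 usable null statistics are required per cluster
(relaxed to `keep` when a reduced desk-scale `keep < 30` is requested
explicitly). The parametric baseline — the F(p−1, n−p) upper tail, which
ignores clustering uncertainty and distributional misfit — is retained for
comparison.

## Downstream analysis

Significant SVGs are standardized per gene (fitted surface to mean 0,
sample sd 1; constant surfaces to zero) and grouped by k-means
(25 restarts, fixed seed) for k = 1..15; the module count is the elbow of
the within-SS/total-SS curve by maximum perpendicular distance to the chord
from k = 1 to k_max. A module's metagene is the per-cell mean of its
members' standardized fits. Marker genes use a Wilcoxon rank-sum test
(normal approximation with tie correction) of each cluster against the
rest, after seeded downsampling to 5000 cells per cluster; the top 50 by
p-value per cluster (ties by descending |log fold change|) are pooled into
a union. Gene-set enrichment is a one-sided hypergeometric test against
user-supplied GMT sets, BH-adjusted, reported at FDR ≤ 0.05 in decreasing
fold change (observed/expected overlap) — a deliberate simplification with
no ontology-graph handling.

## Evaluation against gold-standard segmentation

Xenium-style inputs (transcript coordinates with point-in-whole-cell gold
assignments, nucleus and whole-cell polygons) are rasterized into a 2 µm
lattice and run through the assignment pipeline; the baseline maps every
whole cell to its argmax-overlap 8 µm square (same subsquare
approximation). Metrics: transcript mapping accuracy (matching cell or
both unassigned; for the 8 µm baseline, squares claimed by several cells are
first given to one at random, seeded), median per-cell Pearson correlation
of scaled log-normalized expression against the gold matrix (cells with
≥ 10 reads, scale factor 100; zero-variance cells excluded), and the
adjusted Rand index between clusterings of the method and gold matrices.
The lattice frame can be fixed explicitly — the platform defines it in
reality — which the nested-lattice ideal-tissue property requires.
The 8 µm expression matrix double-counts transcripts of shared squares,
mirroring how binned analyses treat them outside the accuracy metric.

## Synthetic data: what it emulates, and what it does not

The tissue generator places elliptical nuclei (16-point contours,
log-normal areas around 60 µm², pixel = µm) by rejection sampling until the
*whole-cell* polygons (nuclei scaled by √2) are pairwise disjoint, samples
per-gene transcript counts per cell as Poisson with per-type rates
(optionally modulated by a smooth spatial field — linear or radial —
evaluated at the cell centroid), places transcripts uniformly inside the
whole cell, and bins them on the 2 µm lattice. The ideal-tissue variant
builds whole cells as axis-aligned squares of whole 2 µm squares with the
nucleus at 1/√2 scale, so expansion reproduces the cell exactly and
assignment should be perfect — a positive control for the geometry.

The labeled-cell generator (used for null calibration) draws
negative-binomial counts (gamma-Poisson, dispersion 0.5) with a log-normal
gene-abundance spectrum (log-sd 1.5 around 0.2 mean counts): real UMI data
is overdispersed and most genes sit near the detection floor, and it is
precisely the sparse-gene regime in which Gaussian-F tail probabilities are
unreliable — the regime the permutation null is designed to survive. The
continuous-expression generator plants SVG genes as
effect × standardized field + N(0, noise²) alongside pure-noise genes, so
effect/noise is the planted signal-to-noise ratio.

Not emulated: subcellular transcript structure, segmentation errors and
doublets, cell-shape irregularity beyond ellipses, spatial correlation of
noise, and batch effects. Passing tests therefore demonstrate correctness
of the algorithms under the stated generative assumptions, not robustness
to segmentation failure modes in real H&E images.

## Problem sizes and calibration checks

The benchmark harnesses run at desk scale by choice: geometry oracles use
500 random square/ellipse pairs; the batch-fit oracle 20 genes × 300 cells;
the null-law check 2000 i.i.d. Gaussian genes at n = 300, K = 2; null
calibration 10 replicates of 600 cells × 500 genes with a reduced
reassignment budget (n_seeds = 100, keep = 20); planted-SVG recovery 4000
cells in two type-scale clusters with 100 nulls per gene (the full-scale
null count), averaged over 5 replicates — BH controls the FDR in
expectation, so the calibration statement concerns the replicate mean, and
single runs with a handful of false calls fluctuate around it. The recovery
study is run in the many-cells-per-cluster regime the method targets (real
Visium HD clusters hold thousands of cells), where the Gamma family matches
the F null closely; in small clusters the Gamma tail is lighter than the
polynomial F tail and p-values near the significance boundary become
slightly anti-conservative — a known property of parametric tail smoothing
on permutation nulls.

## Known limitations

- Hard assignment only: squares are never split fractionally across cells,
  so transcripts of genuinely overlapping cells are attributed to one cell.
- The expansion is a similarity transform; irregular cell shapes (processes,
  protrusions) are not captured.
- Gamma tail extrapolation below the permutation resolution inherits
  estimation noise from the 100 null values; p-values far in the tail are
  smooth estimates, not exact permutation probabilities.
- The Louvain re-seeding explores the variability of community detection at
  fixed data; it does not model uncertainty from the embedding itself.
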