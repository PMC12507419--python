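# Methods

## Model and assumptions

`statesig` treats state classification as a supervised feature-selection
problem on log-scale expression. The working assumptions are:

- categories differ in the *mean* expression of some genes (linear,
  additive shifts on the log2 scale); genes whose expression separates
  categories have large between-category variance relative to
  within-category variance, which the one-way ANOVA F-ratio measures
  directly;
- replicates within a dataset share a category and a batch; batch effects
  are additive on the log scale and not aliased with category;
- the relative ordering of expression values, not their absolute scale,
  carries the classification signal — hence Spearman correlation for
  query assignment, which is invariant to any strictly monotone
  per-sample transform and therefore robust to residual normalization
  differences between query and reference.

## The selection statistic and the elbow cut

For gene *g* with expression grouped by category, `F_g = MS_between /
MS_within` with the usual degrees of freedom. Genes constant within every
category but differing between categories receive `F = +inf` and rank
first (ties broken by gene id); genes constant everywhere receive `F = 0`
and rank last. Whether a gene counts as "constant" uses a scale-aware
tolerance (`SS <= 1e-12 * (mean square + 1)`).

The ranked F curve is cut at its elbow: both axes are min-max scaled to
[0, 1] (rank to x, F to y) and the elbow is the point with maximum
perpendicular distance from the chord joining the first and last points.
The scaling makes the cut invariant to the absolute F scale, which would
otherwise change the geometry arbitrarily. Infinite sentinels are clamped
just above the finite maximum (`max_finite * (1 + 1e-6)`) so the geometry
is defined while rank order is preserved. Ties in distance resolve to the
smallest rank; an exactly linear curve (all distances zero) resolves to
rank 1 with a logged warning. The selected set contains the genes with F
strictly greater than the elbow gene's; when that set is empty the elbow
gene and its F-ties are included instead, so selection is never empty.

ANOVA runs at dataset level by default (replicate columns averaged per
dataset first): merged public references are dominated by between-dataset
variation, and dataset-level units are what cross-validation holds out.
Sample-level mode is a switch.

## Normalization chain

The transform is `log2(count / size_factor + 1)` on median-of-ratios size
factors (the median over genes expressed in all samples of the count
divided by the gene's geometric mean). This shifted log stands in for a
dispersion-trend variance-stabilizing transform by design: every
downstream statistic is either rank-based (Spearman), variance-ratio
based (F), or distance-based on standardized values, so the exact
stabilizer has little leverage, and the shifted log is monotone,
deterministic and dependency-free. The median of ratios is taken on the
natural scale (for an odd number of reference genes this equals the
exp-of-median-log variant).

Upper-quartile normalization (each sample scaled so its 75th percentile
over nonzero genes matches the across-sample mean) is available as a
per-dataset rescue for library-construction artifacts; which samples
receive it is a caller decision recorded in the run manifest.

Batch correction regresses each gene on batch indicators plus category
indicators and subtracts only the fitted batch component, the linear-model
residualization familiar from expression workflows. Category is retained
in the design by default so that unbalanced designs do not leak category
signal into the batch estimate; a flag drops it. A design where batch is
aliased with category raises a hard error rather than silently removing
the biology. Correction operates on transformed expression, never raw
counts, and single-batch input passes through unchanged.

## Classification and placement

A query is compared to every reference column by Spearman correlation
over the selected genes, pairwise-complete (positions missing in either
profile are dropped; at least 3 complete pairs, at least 50% gene overlap
required). Per category the mean correlation and `SEM = SD/sqrt(n)` are
reported; the argmax is assigned. Categories within 0.01 of the top mean
are flagged as tied — an arbitrary but logged margin chosen because
differences at SEM scale should not silently decide an assignment. Query
placement recomputes the classical-MDS embedding jointly over reference
plus query columns; this is deliberate (simple and exact) rather than
out-of-sample interpolation, and the reference geometry may shift
slightly, which the run manifest records.

Classical MDS double-centers the squared distance matrix
(`B = -1/2 J D^2 J`) and uses the top eigenpairs of `B`. Negative
eigenvalues (non-Euclidean residual) are truncated to zero with a warning
and their mass reported as a diagnostic. Axes are deterministically
oriented (largest-magnitude loading positive). The clustering score is
the mean silhouette of the samples under their category labels computed
on the 2-D embedding — it grades the map actually shown to the user;
singleton categories contribute 0.

## Cross-validation protocol

Leave-one-out holds out one unit (dataset by default), reruns gene
selection on the remaining units only — selection never sees the held-out
unit, so there is no selection leakage — and classifies the held-out unit
over the fold's own gene set. Folds whose removal would empty a category
are skipped with a warning and excluded from the denominator. On
degenerate folds where the elbow selects fewer than 3 genes (a rank
correlation is undefined below 3 pairs), the fold classifies on the top 3
ranked genes.

Subsampling robustness draws, for each proportion and repeat, a
stratified subsample of reference units (round-half-up per category,
minimum one unit) and runs full LOOCV on it. The "10-fold" label of this
protocol is read as 10 random subsample repeats per proportion, since the
sampling is with-replacement-free random drawing rather than
partitioning; the repeat count is configurable. Proportion 1.0 reproduces
plain LOOCV exactly.

## Shadow-feature baseline

Each iteration appends a column-permuted shadow copy of every gene, fits
an `ExtraTreesClassifier`, and scores a hit for every real gene whose
importance exceeds the maximum shadow importance. Genes whose hit counts
beat a Binomial(n_iter, 1/2) upper tail at level alpha are Confirmed.
The tree backend and its hyperparameters are recorded in the result's
params; a fixed seed makes runs identical.

## Synthetic data generator

The generator emulates a merged multi-lab bulk RNA-seq reference: per
gene, a baseline log2 mean drawn uniformly from [3, 10] (mean counts
8–1024, the post-filter regime); negative-binomial counts with a shared
dispersion of 0.05 (variance `mu + 0.05 mu^2`, typical of bulk RNA-seq
after filtering); per-sample library factors log-uniform over
[2^-0.5, 2^0.5]; additive per-gene batch offsets `N(0, 0.5)` on the log2
scale, shared within batch, with datasets assigned to batches cyclically
so batch never aliases category. Informative genes (disjoint sets per
category) are shifted up or down by `effect_size` multiples of the
delta-method within-group SD of log2 expression,
`sqrt(1/mu + dispersion)/ln 2`, so "effect 2" means category means two
within-replicate SDs apart.

The default scenario is 3 categories × 9 datasets × 3 replicates, 5000
genes, 100 informative genes per category at effect 2, three batches —
the shape of a ~27-dataset merged reference. The scaled "small" scenario
used for repeat-heavy protocols is 3 × 9 × 2 with 2000 genes and effect
1: deliberately noisy so subsampling degradation is visible, while nine
datasets per category keep two units per category even at a 20%
subsample. These problem sizes are the package's own choices for
desk-scale reproducibility.

What the generator does **not** emulate: per-gene dispersion trends,
gene–gene correlation, compositional effects, tissue mixtures, or
dataset-specific protocols. Passing tests therefore demonstrate internal
correctness and qualitative behavior (signal recovery, robustness
degradation, null calibration), not performance on any particular real
dataset.

## Numerical choices and degenerate inputs

- Prefilter boundary inclusive ("at least 80%"), compared in integer
  space with a 1e-9 slack against float rounding.
- Z-scoring uses the sample SD (ddof = 1); constant rows become all-zero
  with a warning.
- Hierarchical clustering defaults to average linkage on Euclidean
  distances of Z-scored values (configurable: complete, ward); the tree
  is cut with `maxclust` to k clusters and labels are renumbered in order
  of first appearance so output is input-order stable.
- Spearman with zero rank variance in either vector is undefined and
  returned as missing with a warning, then dropped from category means.
- LOOCV under permuted labels is slightly pessimistic (the held-out
  unit's category is under-represented by one unit); chance-level checks
  use ≥ 9 units per category where the bias is small.

## Known limitations

- The elbow cut has no optimality guarantee; on curves where planted
  signal merges smoothly into the null tail it selects a margin of
  borderline null genes (precision on the default scenario is ~0.8–0.9 at
  perfect recall).
- Joint re-embedding means a query far outside the reference manifold
  can distort the 2-D map; the per-category correlations, not the map,
  are the assignment.
- Batch correction models additive offsets only; multiplicative or
  rank-distorting batch artifacts are out of scope (rank-based
  classification softens but does not remove them).
- The dispersion-trend VST of count-model packages is intentionally not
  re-derived; see the normalization section.
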