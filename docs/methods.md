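# Methods

## The scan statistic

Tiled arrays cover each protein with fixed-length peptides at a fixed
stride, so an antibody binding a contiguous epitope elevates a run of
adjacent probes. For a cut-off intensity `I0` and a sample's empirical
exceedance probability `P = P(I > I0)` (the fraction of the sample's
peptides above `I0`), a run of `N` consecutive exceedances would occur
with probability `P^N` if exceedances were independent. The statistic

    R = P_joint(N) / P^N

uses for `P_joint(N)` the fraction of all windows of `N` tiling-adjacent
peptides (pooled across proteins, never spanning a protein boundary) that
lie entirely above `I0`. Both probabilities come from the same sample, so
R is self-calibrating against per-sample intensity scale.

The scan walks an increasing cut-off grid — the per-sample intensity
quantiles {0.90, 0.95, 0.99, 0.995, 0.999, 0.9995, 0.9999}. At each
cut-off, every maximal run of >= 2 adjacent above-threshold peptides
receives the R computed for its length, overwriting earlier assignments
("latest value kept"); peptides never in a qualifying run keep R = 0. The
grid stops early at any point with zero exceedance (the marginal
probability would vanish). Quantiles rather than absolute intensities make
the grid portable across scanners; both the grid and the hit threshold
(default R > 1e6) are configuration fields.

Hit selection requires R above the threshold in at least one case sample
(`min_case_hits`, configurable) and — control subtraction — a comparably
high ratio in **no** control. "Comparable" defaults to the same strict
threshold; a slack factor is available because borderline control
reactivity is common in practice. Hits are then filtered for sequence
complexity: Shannon entropy of the residue composition >= 3.17 bits
(log base 2; a 16-mer caps at 4 bits) and no single-residue run longer
than 5. Low-complexity stretches bind sera promiscuously and dominate
false positives.

Two consequences of the empirical construction are worth knowing:

* **Short runs saturate.** With `n` peptides per sample, a single
  observed window gives `P_joint >= 1/n`, while the marginal cannot fall
  below `m/n` for `m` exceeding peptides. A run of length 2 therefore
  cannot exceed `R = n / m^2`, which stays below 1e6 even at several
  million peptides. Under the default threshold, detectable epitopes span
  >= 3 adjacent peptides; the synthetic generator consequently plants runs
  of 3-6 peptides.
* **At small array sizes** (hundreds of peptides) the top grid quantiles
  interpolate among the planted peptides' own values, so a qualifying run
  can shrink near the top of the grid and its latest-kept R can drop.
  This is inherent to "latest value kept" and disappears at realistic
  array sizes.

## Synthetic data

The generator emulates exactly the structure the analysis assumes, with
the discovery-design cohort (10 cases, 4 healthy controls) as default:

* **Background**: i.i.d. log-normal fluorescence per peptide x sample,
  `meanlog = ln 1000`, `sdlog = 0.6` — positive, right-skewed signal with
  roughly two-fold typical scatter, a plausible regime for scanner data.
* **Epitopes**: each planted epitope multiplies a run of 3-6
  tiling-adjacent peptides by an effect (default 100) in a subset of case
  samples (carrier fraction 0.7 — patient antibody repertoires differ, and
  hit calling is per-sample before aggregation).
* **Modules**: peptides of a module share a latent Gaussian factor on the
  log scale, with per-peptide loadings drawn uniformly from (0.6, 0.95) so
  modules have hubs and peripheral members, as real co-expression networks
  do (and as the scale-free criterion presupposes). A continuous
  pseudo-proteinuria trait equals `rho * f + sqrt(1 - rho^2) * noise` for
  module 1's factor `f`, giving correlation `rho` (default 0.8) by
  construction.
* **Serology**: log-normal titers around stated group medians.

What the generator does **not** emulate: batch and spatial array
artifacts, probe-synthesis failures, heavy-tailed or correlated background
noise, shared epitopes between partially overlapping patient subgroups,
and any relation between sequence content and binding. Passing tests
demonstrate correctness of the computations and calibration under this
idealised model, not performance on real arrays.

## Co-expression stage

Unsigned network, Pearson correlation on log2-transformed intensities:
`a_ij = |cor|^beta`. The soft threshold is the smallest power in 1..20
whose scale-free fit R^2 (regression of log10 bin frequency on log10 mean
binned connectivity, 10 equal-width bins) reaches 0.9, falling back to the
best power with a warning. On latent-factor data the R^2 curve is flat
near its maximum, so the selected power can wander by several units
between seeds; module detection is run at the conventional moderate powers
(the bundled pipeline default is the chosen beta, tests use 6) because
very high powers shrink within-module overlap below what a static cut can
recover.

Topological overlap follows the standard formula
`TOM_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij)`; it is validated
against a naive triple-loop implementation to 1e-12. Modules come from
average-linkage clustering of `1 - TOM` with a **static** cut at 0.99 of
the merge-height range — deterministic and fully specified, unlike the
dynamic tree-cut heuristic — and a minimum module size of 30; smaller
clusters are left unassigned (label 0). On pure-noise input the near-top
cut fragments the tree into sub-threshold clusters, so no modules are
reported.

Module eigengenes are the leading left-singular vector of the per-peptide
z-scored module submatrix (unit norm over samples), sign-oriented to
correlate positively with the module's mean profile — the PCA sign is
otherwise arbitrary. Module-trait association uses Spearman correlation
with pairwise deletion of missing trait values and Benjamini-Hochberg
adjustment across the whole module x trait table; constant or
nearly-empty traits are reported as NA with a reason rather than dropped
silently.

The case-elevated prefilter retains peptides whose case-group median
(configurable to mean; the two disagree on outlier-skewed peptides)
exceeds the control median.

## Validation-array statistics

* **MDS**: classical (Torgerson) scaling of `1 - Spearman` sample
  dissimilarity, eigendecomposition-based and deterministic; axis signs
  are canonicalised (largest-magnitude loading positive).
* **Differential testing**: two-sided Welch t-tests on `log2(I + 1)`
  (unequal variances are the norm for array data), BH adjustment, hit =
  adjusted p <= 0.05 and |log2 FC| >= 1. Zero-variance peptides get p = 1
  by convention. The volcano boundary `y = c / (x - x0)` with `x0 = 1` and
  `c` anchored so the curve passes through `(2, -log10 0.05)` is cosmetic;
  calling uses the thresholds.
* **SVM ranking**: exhausting all case/control partitions is
  combinatorially infeasible, so 200 seed-controlled stratified 65/35
  splits are used. Per split, peptides are ranked by ANOVA F on the
  learning part; a linear SVM on the top 50 is scored by stratified 4-fold
  CV within the learning split and on the holdout. Mean rank positions
  are converted to integer ranks 0 (best) .. n-1.
* **PLS-DA VIP**: standard VIP over the fitted components; the identity
  `sum_j VIP_j^2 = n_peptides` is asserted in tests.
* **Combination and rollup**: hit sets are combined by union with
  inclusion-exclusion accounting; protein profiles are means over member
  hit peptides, z-scored per row, with average-linkage row/column orders
  for heatmap display.

## Serology

Mann-Whitney for two groups; Kruskal-Wallis plus Dunn's pairwise z-tests
(mid-ranks, tie correction) for more, with Bonferroni adjustment — the
common reading of "Dunn's correction"; the adjustment method is exposed.
ROC curves are fully empirical; AUC by the trapezoid rule equals the
Mann-Whitney U statistic divided by `n1 * n2` (asserted to 1e-9), the
reported cutoff maximises Youden's J with ties broken toward the lowest
cutoff, and LR+ = sens / (1 - spec) (infinite under perfect specificity).
The 2x2 odds ratio uses the Woolf log-normal 95% CI (closed-form and
testable; the CI method used for published estimates is typically
unstated) and a two-sided Fisher exact p; the Haldane-Anscombe 0.5
correction is applied, and flagged, only when a cell is zero.

## Problem sizes and determinism

Simulation-backed checks run at: ~1.06e5 peptides x 14 samples x 50
replicates for scan operating characteristics (sensitivity and null
selection); 140 peptides x 50 samples x 50 seeds for module-trait
recovery; 200 null and 25 power replicates for differential calibration;
100 random matrices up to 50 nodes for TOM oracle agreement. These sizes
give stable estimates while keeping the suite quick on a laptop. Every
stochastic step takes an explicit integer seed; `scripts/acceptance.py`
derives all of its seeds from `--seed`.

## Known limitations

* Probability estimation is per-sample; information is pooled across
  samples only at hit selection, not in R itself.
* The static tree cut cannot split nested or touching modules the way
  dynamic tree cutting can, and module merging by eigengene similarity is
  not implemented.
* The scan's run-length-2 ceiling (above) means dipeptide-scale epitopes
  are invisible at the default threshold by construction.
* Validation-array peptide lists and co-expression module counts from any
  particular study depend on unpublished parameters (threshold grids, cut
  heights, network sign) and raw data; this package exposes those
  parameters rather than hard-coding one study's values.
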