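# Methods

This note documents the models and procedures `bepanel` implements, the
parameters that matter, the numerical conventions, and what the
synthetic-data tests do and do not demonstrate about real cohorts.

## Metric suite

All performance reporting goes through one confusion matrix
(TP, FP, TN, FN) and nine derived metrics:

- accuracy = (TP+TN)/N, precision = TP/(TP+FP), recall = TP/(TP+FN),
  specificity = TN/(TN+FP), NPV = TN/(TN+FN), FPR = FP/(FP+TN),
  F1 = 2TP/(2TP+FP+FN);
- MCC = (TP·TN − FP·FN) / √((TP+FP)(TP+FN)(TN+FP)(TN+FN));
- Cohen's kappa = (p_o − p_e)/(1 − p_e) with p_o = accuracy and
  p_e = [(TP+FP)(TP+FN) + (FN+TN)(FP+TN)]/N².

Counts are real-valued so that mean confusion matrices over repeated
runs are valid inputs (every metric is a ratio of count sums, invariant
under positive scaling). A zero denominator yields `nan`, never a
silent 0 — except the MCC, which is set to 0 and flagged
(`mcc_degenerate`) when its denominator vanishes, the usual convention.
Computing metrics *of* mean counts and averaging per-run metrics agree
to 3 decimals in practice except for NPV on small negative classes,
where the mean-of-ratios can differ in the third decimal; the package
computes metrics of mean counts and documents rather than hides the
discrepancy. Reports round half-even to 3 decimals; internal values
are never rounded. The positive class is always the disease /
progression class, so recall tracks detection of dysplasia or
progressors.

## Per-gene thresholding

F1 as a function of the cutpoint is piecewise constant between observed
expression values, so the candidate grid of midpoints between
consecutive distinct sorted values loses nothing; two sentinel points —
half the smallest adjacent gap below the minimum and above the maximum
(±1 when all values tie) — make the all-positive and all-negative
classifiers representable, which guarantees the optimal F1 is at least
the trivial-predictor baseline 2·prevalence/(1+prevalence). Both
orientations (positive-if-high, positive-if-low) are searched because
real candidate lists contain up- and down-regulated genes. Ties in F1
break toward higher specificity (fewer false positives), then the
cutpoint closest to the median, then positive-if-high with the smaller
cutpoint — fully deterministic. Gene ranking sorts by F1, then AUC,
then gene ID. The single-gene AUC is the rank-based (Mann–Whitney)
AUC of the raw values, reported unfolded (< 0.5 = down-regulated);
for one feature every monotone score gives the same ROC, so no model
fit is needed.

## Candidate filters

The direction-consistency filters operate on DE summary tables and use
the thresholds as quoted conventions: path A requires |logFC| ≥ 1 and
FDR < 0.05 in the primary contrast plus same-sign change with
FDR < 0.05 in the secondary; path B requires |logFC| ≥ 2 and FDR < 0.05
in the secondary-type contrast plus same-sign p < 0.05 in the primary;
the two-dataset path requires |logFC| > 1 and FDR < 0.05 in both
per-dataset tables with matching sign, also matching the reference
contrast. Genes absent from a required table are excluded with a
logged warning (conservative, no imputation). The expression floor
("log2-CPM above 1") is applied to the across-sample mean with a strict
inequality; the mean was chosen over median/min for robustness to
single-sample dropouts. Candidate assembly is a deduplicated union
(paths in order, each internally lexicographic) plus forced genes.

## Feature selection

Four selectors run on standardized features: L1-penalized logistic
regression (liblinear, C = 1.0; keeps nonzero weights),
mutual-information ranking (top k), recursive feature elimination over
a liblinear logistic regression (step 1, k survivors), and univariate
F-score (top k). The consensus keeps genes selected by at least two of
the four methods — the only coherent reading of "appearing at least
twice", since one method selects a gene at most once. k defaults to
twice the panel-size budget. Correlation pruning is greedy in
descending single-gene F1: a gene is kept iff its |Pearson r| with
every kept gene is ≤ 0.9, so the individually stronger member of a
redundant pair survives; constant genes (undefined r) are treated as
uncorrelated and logged. The final panel is the top-n genes of the F1
ranking restricted to the pruned consensus and an F1 floor
(diagnostic configuration: floor 0.7, n = 16; prognostic: 0.67, 13),
with forced genes appended without duplication. The F1 floor is
applied before pruning-independent truncation; whether filtering
preceded pruning was an open choice — filter-then-prune was fixed.

## LOOCV engine

One model = (family, gene subset). For each held-out sample the
training fold is balanced by minority oversampling, optionally
standardized, fitted, and used to predict the held-out sample once; the
n single predictions form one confusion matrix.

- **Oversampling (SMOTE interpolation):** each synthetic point is
  x + u·(x′−x), u ~ U(0,1), x a minority training point and x′ one of
  its 5 nearest minority neighbours (Euclidean, on raw unstandardized
  features); the neighbour count drops to m−1 when the minority has
  m ≤ 5 members and degenerates to duplication at m = 1. Oversampling
  precedes standardization (the ordering was an open choice; fixed).
- **Standardization:** per-feature centring/scaling fitted on the
  augmented training fold only — the held-out sample never influences
  the scaler (asserted by an instrumentation hook in the tests).
  Naive Bayes is exempt: its per-feature variances absorb scale.
- **Hyperparameters (fixed, not tuned):** logistic regression — L2,
  C = 1.0, intercept, 1000 iterations; Gaussian naive Bayes — variance
  floor 10⁻⁹ × largest feature variance; KNN — k = 5, Euclidean,
  uniform votes (with k = 5 and two classes a vote tie cannot occur);
  linear SVM — C = 1.0; RBF SVM — C = 1.0, γ = 1/(d·Var(features)).
- **Seeding:** a single integer seed drives a counter-based substream
  per fold (`default_rng([seed, fold])`), so serial and parallel fold
  execution agree bit-for-bit and repeated runs that vary only the seed
  isolate the oversampling randomness.

The exhaustive search enumerates subsets from size 2 to the panel size,
families in declared order, subsets in size-then-lexicographic order.
Panels above 12 genes require explicit confirmation (the error reports
the implied combination count); 18 is a hard cap. Leaderboard queries
(`best_by_metric`) return the metric maximum, all attaining entries and
per-family tallies. The frequency consensus restricts to entries with
F1 above a cutoff (default 0.96) and selects genes present in at least
50% of the qualifying subsets. Repeated runs report per-metric mean
and sample SD (ddof = 1, the mean ± SD table convention) plus mean
counts. Ablation evaluates all subsets per size k (full panel down
to 2), or a seeded uniform sample of 200 per size when the count
exceeds the cap, reporting median and SD per metric.

Note the consensus is a panel-shrinking step by construction: with
redundant informative genes, removing any one of them barely moves F1,
so individual frequencies hover near the base rate and the consensus
retains a *sufficient* discriminative subset rather than every
informative gene. Fidelity of the consensus is therefore measured by
its precision (share of selected genes that are truly informative),
while recovery of the full informative set is a property of the
assembled panel.

## Synthetic cohorts

Generative model on the log2 scale:
x[g,s] = μ_g + δ_g·m(s) + b(batch(s)) + ε, ε ~ N(0, σ²), with μ_g ~
U(2, 8) (a typical log-CPM range for expressed genes), δ_g = ±effect
for the planted genes (signs alternating so both up- and down-regulated
markers exist, 0 otherwise), m(s) = 0/1/1.5 for negative/positive/
third-group samples (the 1.5 multiplier makes the optional high-grade
group a monotone extension, guaranteeing direction consistency for the
filter tests), and b a per-dataset additive offset (round-robin batch
assignment unless given explicitly). Default cohort shapes mirror the
study designs this pipeline targets: 21 vs 40 (+ optional 27) for
diagnosis, 135 vs 65 for prognosis. DE summary tables are derived from
the generated matrix: empirical group-mean logFC, Welch two-sample
t-test p-values, Benjamini–Hochberg FDR across genes; per-batch tables
are emitted for every batch containing both classes.

This is deliberately *not* a count-level simulator: every in-scope
stage consumes normalized log-scale values, so library sizes,
dispersion, probe effects and dropout are not modelled. Passing tests
therefore demonstrate correctness of the selection/search machinery on
Gaussian log-scale data with additive batch structure — not robustness
to count noise, normalization artifacts, or confounded batches.

## qPCR normalization

ΔCq = target Cq − geometric mean of the reference genes' Cq, computed
per sample after arithmetic averaging of technical replicates per
(sample, gene); replicate averaging before normalization was an open
choice, fixed here. Lower ΔCq means higher expression; downstream
"expression level" axes must negate. Nonpositive Cq values are
rejected. Amplification-efficiency correction is out of scope.

## Problem sizes used in tests and the acceptance script

The full diagnostic search (16 + 2 genes, ≈ 2.6×10⁵ subsets × 5
families) is a cluster-scale computation by design. The test suite and
acceptance script exercise the identical code paths at desk scale, a
deliberate package choice: recovery runs use 200-gene cohorts
(10 planted at 1.5 log2 units, σ = 1, 30 vs 30) with the search stage
enumerating all 247 subsets of the panel's top 8 genes under the linear
SVM; stability uses 25 repeated runs (100 in release-scale runs); null
calibration uses 10 permutation replicates per family; ablation caps at
a few dozen subsets per size. Scaling down the enumeration breadth
changes nothing about the per-model evaluation, which is what the
correctness claims concern.

## Known limitations

- Gaussian log-scale cohorts only (see above); no confounding between
  batch and class in the default generator.
- The LOOCV + oversampling scheme evaluates models; it does not produce
  an unbiased estimate of generalization to external cohorts (model
  selection over ~10⁵ subsets optimistically biases the maximum).
  The repeated-run SD quantifies oversampling randomness only.
- DE tables are consumed, not produced: upstream normalization, batch
  correction and count-model fitting are out of scope.
- The enumeration is exhaustive by design; no heuristic subset search
  is provided.
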