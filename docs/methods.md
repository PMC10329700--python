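# Methods

This document records the statistical model, the algorithmic choices and
their defaults, the synthetic data generator, and known caveats of the
estimators, so results produced with `evohdtree` can be interpreted and
reproduced without reading the source.

## 1. Data model and preprocessing

Input is a samples × metabolites concentration matrix (µM) with a diagnostic
group and an acquisition batch per sample, plus a per-(metabolite, batch)
limit of detection (LOD). Missing cells denote concentrations below the LOD.

Two preprocessing rules are applied, in this order:

1. **Presence filter** — keep metabolites quantified in at least
   `min_presence` (default 0.80) of *all* samples. The boundary is
   inclusive (8 of 10 survives at 0.80) and the retained set is monotone in
   the threshold. Presence is computed jointly, not per group or batch.
2. **Half-LOD imputation** — replace every remaining missing value by half
   the LOD of its metabolite in the sample's batch. The operation is
   idempotent and leaves observed cells untouched.

A binary comparison dataset is then sliced from the imputed matrix
(`make_comparison`): `y = 1` is the patient/positive class, all metabolites
carry over with no feature pre-selection.

## 2. The heterogeneous tree classifier

Trees are strictly binary. Node tests:

* univariate `x[f] <= t` (boundary routes left); candidate thresholds are
  the midpoints between consecutive distinct sorted values of the feature,
  so every candidate realizes a distinct split;
* bivariate `x[a] > x[b]` (equality routes right). Because it depends only
  on the order of two features, the test is invariant under any common
  strictly increasing transform, the defining property of relative
  expression analysis / top-scoring-pair classifiers.

Leaves are labelled by training majority; ties label positive; a leaf that
receives no training samples inherits its parent's majority.
`predict_score` returns the Laplace-smoothed positive fraction of the
reached leaf, `(n₊ + 1) / (n₊ + n₋ + 2)`, so scores are always in (0, 1)
and an empty leaf scores 0.5.

### Fitness

```
fitness(T) = F1_train(T) − alpha · |internal nodes|
```

F1 is the positive-class harmonic mean of precision and recall, defined as
0 when there are no true positives. `alpha` (default **0.01**) prices one
internal node at one F1 percentage point: two trees must differ by a full
point of training F1 before the larger one is preferred. This keeps panels
small without forbidding depth where the data genuinely support it.

### Evolutionary search (defaults)

Generational GA with tournament selection (size 3), elitism 1, crossover
probability 0.8, mutation probability 0.4, population 100, 200 generations,
stagnation stop after 50 improvement-free generations, maximum depth 5,
ramped initialization over depths 1–3. One seeded generator drives every
stochastic choice; run *r* of a repeated experiment uses seed `base + r`.

The variation catalogue has sixteen operators: fourteen unary (threshold
shift on the candidate-rank scale, threshold re-draw, univariate feature
replacement, bivariate partner replacement, bivariate pair re-draw,
test-kind swap, memetic threshold hill-climb, memetic node-test
re-optimization, memetic lookahead split, prune-to-leaf, leaf expansion,
child swap, subtree replacement, leaf label flip) and two crossovers
(subtree exchange, test exchange). Mutation draws uniformly among the unary
variants; inapplicable draws degrade to a no-op.

The two stronger memetic moves exist because the fitness landscape over
tree space is deceptive: a split that is useless on its own can be the root
of the optimal depth-2 tree. *Lookahead split* plants a random test at a
node and then coordinate-ascends both child tests (each child may remain a
leaf); *node-test re-optimization* replaces one node's test by the best of
a random candidate sample. Without them the search reliably plateaus below
the exhaustive depth-2 optimum; with them it attains it (verified against
`exhaustive_best_tree` in the test suite). The memetic scan budget scales
as `max(6, 1600 / n)` candidates per move, bounding per-move cost on large
cohorts; this constant was fixed from the oracle-equivalence experiments on
small instances, before any validation-level measurements.

### Exhaustive oracle

`exhaustive_best_tree` enumerates every topology of depth ≤ 2 over the full
test vocabulary and returns the global fitness optimum, with deterministic
tie-breaking (fewer nodes, then lexicographically smallest serialization).
It exists purely as an independent correctness check of the stochastic
search and refuses instances whose enumeration would exceed a size guard.

## 3. Validation

Out-of-fold predictions within one run are pooled into a single confusion
matrix (micro pooling) before computing ACC/F1; AUC is the tie-corrected
Mann–Whitney concordance of pooled out-of-fold scores. Stochastic learners
are re-run `n_runs` times and metrics reported as mean ± SD across runs.
Stratified k-fold reduces k to the minority class size when necessary
(logged and noted in the report). LOOCV is n folds of one held-out sample.
The learner is refit — including any feature selection — inside every
training fold.

Cross-algorithm comparison uses the Friedman rank test over a methods ×
comparisons score table (χ²_F with k−1 df, average ranks for ties) with
Dunn's pairwise z-tests and Bonferroni adjustment as post-hoc.

### Known caveat: pooled LOOCV AUC is pessimistically biased under a fixed class balance

With a fixed n₊/n₋ label vector (e.g. permuted labels on a 30/30 cohort),
LOOCV has a structural anti-correlation: holding out a positive leaves a
29/30 training set, holding out a negative a 30/29 one, so the training
class balance is informative about the held-out label with the *opposite*
sign. A learner that maximizes training F1 by searching tens of thousands
of candidate tests amplifies this one-sample tilt, and pooling raw scores
across folds converts it into AUC < 0.5 on data with no signal (measured
here: means of 0.44–0.47 across simulated cohorts, 100 label-permuted runs
each at n=60, p≈160, versus ≈ 0.48 for a weaker pre-memetic search). This is the stratification/pooling bias
described by Parker et al. (2007) and Airola et al. (2011); it is a
property of the estimator, not a defect of the implementation, and the
trivial class-prior learner exhibits it in the extreme (pooled LOOCV AUC
of 0 on balanced data — see the unit test
`test_loocv_majority_learner_anticorrelates`). Consequences: LOOCV AUC
values reported by this package are conservative, and a no-signal control
lands slightly *below* 0.5 rather than on it. Repeated stratified k-fold
CV with per-run pooling is less affected and is the recommended scheme
when the cohort allows it.

## 4. Conventional comparator

Per metabolite, Shapiro–Wilk normality in each class (at 0.05) gates the
two-sample test: Welch's t when both classes pass, otherwise the two-sided
Wilcoxon rank-sum test. Metabolites with p < alpha (default 0.05, optional
Benjamini–Hochberg correction) form the panel for a linear-kernel SVM
(standardized inputs). Screening is re-run inside every training fold; an
empty selection degrades to a class-prior chance model, flagged in the
report. The type-I error of the screening is calibrated (≈ 5% on null
features, verified in the test suite).

## 5. Synthetic cohort generator

`simulate` produces a study-shaped cohort: six diagnostic groups (default
3/15/10/66/70/71 = 235 samples), 188 metabolites named after p180 compound
classes (21 amino acids, 21 biogenic amines, 40 acylcarnitines, 14
lysoPCs, 76 PCs, 15 sphingolipids, 1 hexose), three batches. Mechanism:

* baseline log-concentrations uniform on (−1, 4) (natural log of µM),
  lognormal noise with log-scale SD 0.5;
* within-compound-class correlation 0.3 via one shared latent factor per
  class and sample;
* additive per-batch log-offsets, SD 0.1;
* planted **univariate effects**: group-specific mean shifts in units of
  the log SD; planted **bivariate effects**: the two metabolites' latent
  means are swapped inside the target group, flipping their typical
  ordering while keeping the marginals similar;
* LOD censoring: per (metabolite, batch), the LOD is the empirical batch
  quantile (default 0.05) and values below it are blanked; a disjoint 15%
  of metabolites is "poorly detected" (censored at the batch median) so the
  80% presence filter genuinely removes features. Planted markers are
  excluded from the poorly-detected set so ground truth survives
  preprocessing.

The generator is a structural emulation, not a calibrated reproduction of
any real cohort: absolute concentration scales, correlation structure and
effect sizes are plausible defaults chosen to exercise the workflow, and
conclusions about real plasma metabolomes should not be read off it.

`make_threshold_dataset` / `make_rank_pair_dataset` are small noise-free
constructions (a planted threshold rule, a planted rank reversal with
overlapping marginals) used for parameter-recovery checks.

## 6. Scaled configurations in tests and the acceptance script

Full-size searches (population 100 × 200 generations) on 160-feature
cohorts are unnecessary for verifying behaviour, so study-shaped
experiments in the test suite and `scripts/acceptance.py` run a scaled
budget — population 24, 15 generations, stagnation 8, depth 3, init depths
1–2 — chosen once for runtime. Small planted-rule experiments use
population 40 × 30 generations. Oracle-equivalence checks use the full
population 100 × 300 generations with 5 restarts, since there the point is
search capability.

## 7. Numerical and reproducibility notes

* All derived seeds stay below 2³¹; repeated-run seeds advance as
  `base + r` and per-fold fit seeds as `(seed + 7919·i) mod (2³¹ − 1)`.
* Tree serialization sorts JSON keys, so identical fits are byte-identical.
* Fitness ties in the oracle are broken at 10⁻¹² tolerance toward fewer
  nodes, then lexicographic serialization, making it deterministic.
* `f1_score` returns 0 when tp = 0; `roc_auc` requires both classes.
* Thresholds are midpoints of observed values; a univariate test can
  therefore always be re-fitted after a monotone transform to reproduce the
  same partition, while bivariate tests need no re-fitting at all.
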