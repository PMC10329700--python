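# evohdtree

Evolutionary induction of **heterogeneous decision trees** for targeted
metabolomics biomarker panels, together with the full evaluation workflow
around the classifier: preprocessing of p180-style concentration matrices,
repeated cross-validation and LOOCV, a conventional univariate-selection +
SVM comparator, cross-algorithm rank statistics, panel overlap analysis, and
a synthetic cohort generator with planted ground truth.

## The model

A heterogeneous tree is a binary decision tree whose internal nodes carry
one of two test kinds:

* **univariate**: `metabolite <= threshold` (route left on or below the
  boundary), or
* **bivariate rank pair**: `metabolite_a > metabolite_b` (equality routes
  right) — the relative-expression / top-scoring-pair construction, which is
  invariant under any common strictly increasing transform of the two
  features and therefore robust to monotone normalisation choices.

Trees are evolved by a generational genetic algorithm (tournament selection,
elitism, a catalogue of sixteen specialized variation operators including
memetic local-search moves) against the size-regularized fitness

```
fitness(T) = F1_train(T) − alpha · |internal nodes of T|
```

so at equal training F1 the smaller, more interpretable tree always wins.
The metabolites referenced by a fitted tree's nodes form the proposed
diagnostic **panel** for that group comparison.

An exhaustive depth-≤2 oracle (`exhaustive_best_tree`) provides a brute-force
global optimum on small instances; the test suite verifies that the
stochastic search attains it.

## Worked example

```python
from evohdtree import EvoHDTree, EAConfig
from evohdtree.io import filter_by_presence, impute_half_lod, make_comparison
from evohdtree.simulate import SimConfig, simulate

matrix, truth = simulate(SimConfig(seed=1))                   # 235 x 188 cohort
matrix = impute_half_lod(filter_by_presence(matrix, 0.80))    # preprocessing
data = make_comparison(matrix, ["GIV"], ["Con"])              # binary slice

model = EvoHDTree.from_dataset(data)
results = model.fit(EAConfig(population_size=50, generations=40, seed=1))
print(results.summary())
```

Output:

```
Evolutionary Heterogeneous Decision Tree Results
========================================================
Comparison:          GIV vs Con
No. observations:    137 (pos=66, neg=71)
No. metabolites:     160
Generations run:     40
Regularization a:    0.01
Internal nodes:      2
Tree depth:          2
--------------------------------------------------------
Fitness (F1 - a*nodes): 0.9497
Training F1:            0.9697
Training accuracy:      0.9708
Training AUC:           0.9752
Panel:                  Glutamine, Glycine
--------------------------------------------------------
if Glycine <= 22.0864:
  leaf -> class 0 (pos=2, neg=48)
else:
  if Glutamine <= 33.888:
    leaf -> class 1 (pos=64, neg=2)
  else:
    leaf -> class 0 (pos=0, neg=21)
```

The two metabolites in the fitted panel are exactly the rank-reversal pair
planted in the simulated GIV group (`truth.bivariate_pairs`). Honest
out-of-sample estimates come from refitting inside every fold:

```python
report = model.loocv(EAConfig(population_size=50, generations=40), seed=1)
print(report.f1, report.auc)      # micro-pooled out-of-fold metrics
```

## Command line

```bash
evohdtree simulate --seed 1 --out matrix.csv --lod-out lod.csv
evohdtree preprocess matrix.csv lod.csv --out preprocessed.csv
evohdtree train matrix.csv lod.csv --positive GIV --negative Con --seed 1
evohdtree run pipeline.yaml          # full configured workflow + manifest
```

`evohdtree run` executes simulate/load → preprocess → (methods ×
comparisons) validation → panels/overlap and writes a benchmark table, ROC
curves, fitted trees, panel CSV/JSON and a reproducibility manifest; see
`evohdtree.cli.run_pipeline` for the config schema.

## Package layout

| module | contents |
| --- | --- |
| `evohdtree.io` | matrix/LOD I/O, presence filter, half-LOD imputation, comparison slicing |
| `evohdtree.node_tests` | univariate and bivariate node tests, threshold candidates |
| `evohdtree.tree` | tree structure, routing, leaf refitting, JSON serialization |
| `evohdtree.core` | EA engine, operator catalogue, fitness, exhaustive oracle |
| `evohdtree.evaluation` | metrics, repeated CV/LOOCV, ROC/AUC, Friedman + Dunn |
| `evohdtree.learners` | common learner interface incl. sklearn baselines |
| `evohdtree.conventional` | Shapiro-gated Welch-t/Wilcoxon screening + linear SVM |
| `evohdtree.panels` | panel extraction, Venn regions, bipartite edge lists |
| `evohdtree.simulate` | p180-style synthetic cohorts with planted ground truth |
| `evohdtree.model` | `EvoHDTree` / `EvoHDTreeResults` model-results facade |
| `evohdtree.cli` | click CLI |

## Reproduction

All stochastic components run from a single seeded generator; identical
seeds reproduce byte-identical simulated CSVs, trees and reports. The
headline quantities on a synthetic study-shaped cohort are recomputed by

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

Methodological details, parameter defaults and known estimator caveats
(including the pessimistic bias of pooled LOOCV AUC under label
permutation) are documented in [docs/methods.md](docs/methods.md).
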