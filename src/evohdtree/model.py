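"""Model/Results interface for evolutionary heterogeneous tree induction.

``EvoHDTree`` is constructed from data (arrays, a DataFrame, or a
:class:`~evohdtree.io.LabeledDataset`); ``fit()`` runs the evolutionary
search and returns an :class:`EvoHDTreeResults` carrying the fitted tree,
its fitness trajectory, training metrics, the extracted metabolite panel and
a ``summary()`` table. Cross-validated uncertainty (repeated CV or LOOCV)
hangs off the model, since it refits the tree per fold.

Example
-------
>>> from evohdtree import EvoHDTree, EAConfig
>>> from evohdtree.simulate import make_rank_pair_dataset
>>> d = make_rank_pair_dataset(seed=7)
>>> res = EvoHDTree.from_dataset(d).fit(EAConfig(seed=7))
>>> res.fitness >= 0.9  # one bivariate node separates the classes
True
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .core import EAConfig, EvolutionLog, evolve, fitness as tree_fitness, training_f1
from .evaluation import (
    EvaluationReport,
    confusion,
    accuracy,
    cross_validate,
    f1_score,
    loocv,
    roc_auc,
)
from .io import LabeledDataset
from .learners import EvoHDTreeLearner
from .panels import Panel, extract_panel
from .tree import HeterogeneousTree


class EvoHDTree:
    """Evolutionary heterogeneous decision-tree model for a binary comparison.

    Parameters
    ----------
    endog : array-like
        Binary labels, 1 = positive (patient) class.
    exog : array-like
        Concentration matrix, samples x metabolites.
    metabolite_names : sequence of str, optional
        Feature names; defaults to ``M1..Mp``.
    """

    def __init__(self, endog, exog, metabolite_names=None,
                 positive_group: str = "pos", negative_group: str = "neg"):
        exog = np.asarray(exog, dtype=float)
        if metabolite_names is None:
            metabolite_names = [f"M{j + 1}" for j in range(exog.shape[1])]
        self.data = LabeledDataset(
            values=exog,
            y=np.asarray(endog),
            metabolite_names=list(metabolite_names),
            positive_group=positive_group,
            negative_group=negative_group,
        )

    @classmethod
    def from_dataset(cls, d: LabeledDataset) -> "EvoHDTree":
        obj = cls.__new__(cls)
        obj.data = d
        return obj

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, label_col: str, positive_label=1, **kwargs
    ) -> "EvoHDTree":
        y = (df[label_col] == positive_label).astype(int).to_numpy()
        X = df.drop(columns=[label_col])
        return cls(y, X.to_numpy(dtype=float), metabolite_names=list(X.columns), **kwargs)

    # ------------------------------------------------------------------

    def fit(self, config: EAConfig | None = None, seed: int | None = None) -> "EvoHDTreeResults":
        """Evolve a tree on the full data; deterministic given the seed."""
        cfg = config or EAConfig()
        if seed is not None:
            cfg = replace(cfg, seed=seed)
        tree, log = evolve(self.data, cfg, return_log=True)
        return EvoHDTreeResults(model=self, tree=tree, config=cfg, log=log)

    def cross_validate(
        self, config: EAConfig | None = None, k: int = 10, n_runs: int = 1, seed: int = 0
    ) -> EvaluationReport:
        """Repeated stratified k-fold CV, refitting the tree in every fold."""
        report = cross_validate(
            self.data, EvoHDTreeLearner(config), k=k, n_runs=n_runs, seed=seed
        )
        report.method = "evohdtree"
        return report

    def loocv(
        self, config: EAConfig | None = None, n_runs: int = 1, seed: int = 0
    ) -> EvaluationReport:
        """Leave-one-out CV, refitting the tree for every held-out sample."""
        report = loocv(self.data, EvoHDTreeLearner(config), n_runs=n_runs, seed=seed)
        report.method = "evohdtree"
        return report


@dataclass
class EvoHDTreeResults:
    """Fitted tree plus training diagnostics."""

    model: EvoHDTree
    tree: HeterogeneousTree
    config: EAConfig
    log: EvolutionLog

    # -- point estimates ----------------------------------------------------

    @property
    def fitness(self) -> float:
        """Regularized training fitness of the selected tree."""
        return tree_fitness(self.tree, self.model.data, self.config.alpha)

    @property
    def train_f1(self) -> float:
        return training_f1(self.tree)

    @property
    def train_accuracy(self) -> float:
        d = self.model.data
        return accuracy(confusion(d.y, self.tree.predict(d.values)))

    @property
    def train_auc(self) -> float:
        d = self.model.data
        auc, _ = roc_auc(d.y, self.tree.predict_score(d.values))
        return auc

    def predict(self, X) -> np.ndarray:
        return self.tree.predict(X)

    def predict_score(self, X) -> np.ndarray:
        return self.tree.predict_score(X)

    def panel(self) -> Panel:
        """Metabolites referenced by the fitted tree's internal nodes."""
        return extract_panel(self.tree, self.model.data.name)

    # -- presentation ---------------------------------------------------------

    def summary(self) -> str:
        d = self.model.data
        lines = [
            "Evolutionary Heterogeneous Decision Tree Results",
            "=" * 56,
            f"Comparison:          {d.name}",
            f"No. observations:    {d.n_samples} "
            f"(pos={int(d.y.sum())}, neg={int(len(d.y) - d.y.sum())})",
            f"No. metabolites:     {d.n_features}",
            f"Generations run:     {self.log.generations_run}"
            + (" (stopped on stagnation)" if self.log.stopped_early else ""),
            f"Regularization a:    {self.config.alpha}",
            f"Internal nodes:      {self.tree.n_internal_nodes()}",
            f"Tree depth:          {self.tree.depth()}",
            "-" * 56,
            f"Fitness (F1 - a*nodes): {self.fitness:.4f}",
            f"Training F1:            {self.train_f1:.4f}",
            f"Training accuracy:      {self.train_accuracy:.4f}",
            f"Training AUC:           {self.train_auc:.4f}",
            f"Panel:                  {', '.join(sorted(self.panel().metabolites)) or '(empty)'}",
            "-" * 56,
            self.tree.pretty(),
        ]
        return "\n".join(lines)

    def plot_fitness(self, ax=None):
        """Best/mean fitness per generation (requires matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.log.best_fitness, label="best")
        ax.plot(self.log.mean_fitness, label="population mean")
        ax.set_xlabel("generation")
        ax.set_ylabel("fitness")
        ax.legend()
        return ax

    def plot_roc(self, ax=None):
        """Training ROC curve of the fitted tree (requires matplotlib)."""
        import matplotlib.pyplot as plt

        d = self.model.data
        auc, pts = roc_auc(d.y, self.tree.predict_score(d.values))
        if ax is None:
            _, ax = plt.subplots()
        fpr, tpr = zip(*pts)
        ax.plot(fpr, tpr, label=f"AUC = {auc:.3f}")
        ax.plot([0, 1], [0, 1], "k--", lw=0.5)
        ax.set_xlabel("false positive rate")
        ax.set_ylabel("true positive rate")
        ax.legend()
        return ax
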