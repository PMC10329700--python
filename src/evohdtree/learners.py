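"""Learner adapters: the evolutionary tree plus standard baseline classifiers.

Everything exposes the same minimal interface used by the validation code:
``learner.fit(X, y, metabolite_names, seed) -> fitted`` where the fitted
object has ``predict`` and ``predict_score``. Baselines delegate to
scikit-learn estimators, optionally with a small per-fit grid search
mirroring an automatic parameter sweep; their internals are deliberately
not re-implemented here.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .core import EAConfig, evolve
from .io import LabeledDataset


@dataclass
class _FittedTree:
    tree: object

    def predict(self, X):
        return self.tree.predict(np.asarray(X, dtype=float))

    def predict_score(self, X):
        return self.tree.predict_score(np.asarray(X, dtype=float))


@dataclass
class EvoHDTreeLearner:
    """Evolutionary heterogeneous tree behind the common learner interface."""

    config: EAConfig | None = None

    def fit(self, X, y, metabolite_names, seed: int = 0):
        cfg = replace(self.config or EAConfig(), seed=seed)
        d = LabeledDataset(
            values=np.asarray(X, dtype=float),
            y=np.asarray(y),
            metabolite_names=list(metabolite_names),
        )
        return _FittedTree(evolve(d, cfg))


class _FittedSklearn:
    def __init__(self, est):
        self.est = est

    def predict(self, X):
        return np.asarray(self.est.predict(X), dtype=int)

    def predict_score(self, X):
        if hasattr(self.est, "predict_proba"):
            return self.est.predict_proba(X)[:, 1]
        return self.est.decision_function(X)


@dataclass
class SklearnLearner:
    """Wrap any sklearn-style estimator factory ``build(seed) -> estimator``."""

    build: callable
    name: str = ""

    def fit(self, X, y, metabolite_names, seed: int = 0):
        est = self.build(seed)
        est.fit(X, y)
        return _FittedSklearn(est)


@dataclass
class MajorityLearner:
    """Predicts the training majority class; a deterministic sanity baseline."""

    def fit(self, X, y, metabolite_names, seed: int = 0):
        y = np.asarray(y)
        label = 1 if y.sum() * 2 >= len(y) else 0
        frac = float(y.mean())

        class _Fitted:
            def predict(self, X):
                return np.full(len(X), label, dtype=int)

            def predict_score(self, X):
                return np.full(len(X), frac)

        return _Fitted()


def baseline_learners(grid_search: bool = False) -> dict[str, SklearnLearner]:
    """The conventional-ML comparison set behind one interface.

    Names: naive_bayes, glm (L2 logistic), logistic_regression, fast_large_margin
    (linear SVM), decision_tree, random_forest, gradient_boosted_trees, svm
    (RBF), mlp. With ``grid_search=True`` each fit runs a small 3-fold
    parameter sweep.
    """
    from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
    from sklearn.linear_model import LogisticRegression
    from sklearn.naive_bayes import GaussianNB
    from sklearn.neural_network import MLPClassifier
    from sklearn.pipeline import make_pipeline
    from sklearn.preprocessing import StandardScaler
    from sklearn.svm import SVC, LinearSVC
    from sklearn.tree import DecisionTreeClassifier

    def builders():
        yield "naive_bayes", lambda s: GaussianNB(), {}
        yield "glm", lambda s: make_pipeline(
            StandardScaler(), LogisticRegression(max_iter=2000, C=1.0)
        ), {}
        yield "logistic_regression", lambda s: make_pipeline(
            StandardScaler(), LogisticRegression(max_iter=2000, C=1e6)
        ), {}
        yield "fast_large_margin", lambda s: make_pipeline(
            StandardScaler(), LinearSVC(random_state=s)
        ), {}
        yield "decision_tree", lambda s: DecisionTreeClassifier(
            random_state=s
        ), {"max_depth": [2, 4, 8], "min_impurity_decrease": [0.0, 0.01]}
        yield "random_forest", lambda s: RandomForestClassifier(
            n_estimators=100, random_state=s
        ), {"max_depth": [4, 8, None]}
        yield "gradient_boosted_trees", lambda s: GradientBoostingClassifier(
            random_state=s
        ), {"n_estimators": [50, 100], "max_depth": [2, 3]}
        yield "svm", lambda s: make_pipeline(
            StandardScaler(), SVC(random_state=s)
        ), {"svc__C": [0.1, 1, 10], "svc__gamma": ["scale", 0.01]}
        yield "mlp", lambda s: make_pipeline(
            StandardScaler(),
            MLPClassifier(max_iter=800, random_state=s, learning_rate="adaptive"),
        ), {}

    out = {}
    for name, build, grid in builders():
        if grid_search and grid:
            from sklearn.model_selection import GridSearchCV

            def wrapped(s, build=build, grid=grid):
                return GridSearchCV(build(s), grid, cv=3, scoring="f1", n_jobs=1,
                                    error_score=0.0)

            out[name] = SklearnLearner(build=wrapped, name=name)
        else:
            out[name] = SklearnLearner(build=build, name=name)
    return out
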