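"""Conventional comparator: univariate selection followed by a linear SVM.

Each metabolite is screened with a distribution-adaptive two-sample test —
Shapiro-Wilk normality in each class decides between Welch's t-test (both
classes normal at the 5% level) and the two-sided Wilcoxon rank-sum test.
Metabolites significant at ``alpha`` form the panel on which a linear
support-vector classifier is evaluated by cross-validation.

To avoid selection leakage, the screening is re-run inside every training
fold; the held-out samples never inform which metabolites enter the model.
Concentrations are used as-is (no scaling or transformation) for the
selection step; the SVM standardizes internally for numerical stability.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .evaluation import EvaluationReport, cross_validate, loocv
from .io import LabeledDataset

logger = logging.getLogger(__name__)


def univariate_select(
    d: LabeledDataset,
    alpha: float = 0.05,
    correction: str | None = None,
) -> pd.DataFrame:
    """Distribution-adaptive univariate screening.

    Returns the metabolites with p < ``alpha`` sorted ascending by p-value,
    as a frame with columns ``metabolite, p_value, test``. Constant
    metabolites are excluded (logged, never an error).
    ``correction="bh"`` applies a Benjamini-Hochberg adjustment first
    (off by default).
    """
    pos = d.values[d.y == 1]
    neg = d.values[d.y == 0]
    if len(pos) < 3 or len(neg) < 3:
        raise ValueError("univariate selection needs >=3 samples per class")
    rows = []
    for j, name in enumerate(d.metabolite_names):
        a, b = pos[:, j], neg[:, j]
        if np.ptp(a) == 0 and np.ptp(b) == 0:
            logger.info("metabolite %s constant in both classes; excluded", name)
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            normal = (
                np.ptp(a) > 0
                and np.ptp(b) > 0
                and stats.shapiro(a).pvalue > 0.05
                and stats.shapiro(b).pvalue > 0.05
            )
            if normal:
                p = stats.ttest_ind(a, b, equal_var=False).pvalue
                used = "welch_t"
            else:
                p = stats.mannwhitneyu(a, b, alternative="two-sided").pvalue
                used = "wilcoxon"
        rows.append({"metabolite": name, "p_value": float(p), "test": used})
    table = pd.DataFrame(rows, columns=["metabolite", "p_value", "test"])
    if correction == "bh" and len(table):
        m = len(table)
        order = np.argsort(table["p_value"].to_numpy())
        adj = np.empty(m)
        prev = 1.0
        for rank, idx in enumerate(order[::-1]):
            i = m - rank
            prev = min(prev, table["p_value"].iloc[idx] * m / i)
            adj[idx] = prev
        table["p_value"] = adj
    table = table[table["p_value"] < alpha].sort_values("p_value", kind="stable")
    return table.reset_index(drop=True)


@dataclass
class ConventionalLearner:
    """Per-fold univariate selection + linear-kernel SVM."""

    alpha: float = 0.05
    correction: str | None = None

    def fit(self, X, y, metabolite_names, seed: int = 0):
        from sklearn.pipeline import make_pipeline
        from sklearn.preprocessing import StandardScaler
        from sklearn.svm import SVC

        d = LabeledDataset(values=np.asarray(X, dtype=float), y=np.asarray(y),
                           metabolite_names=list(metabolite_names))
        selected = univariate_select(d, alpha=self.alpha, correction=self.correction)
        cols = [metabolite_names.index(m) for m in selected["metabolite"]]
        if not cols:
            label = 1 if d.y.sum() * 2 >= len(d.y) else 0
            frac = float(d.y.mean())

            class _Chance:
                empty_selection = True

                def predict(self, X):
                    return np.full(len(X), label, dtype=int)

                def predict_score(self, X):
                    return np.full(len(X), frac)

            return _Chance()

        est = make_pipeline(StandardScaler(), SVC(kernel="linear", random_state=seed))
        est.fit(np.asarray(X, dtype=float)[:, cols], y)

        class _Fitted:
            empty_selection = False
            columns = cols

            def predict(self, Xn):
                return np.asarray(est.predict(np.asarray(Xn, dtype=float)[:, cols]), dtype=int)

            def predict_score(self, Xn):
                return est.decision_function(np.asarray(Xn, dtype=float)[:, cols])

        return _Fitted()


def conventional_panel_model(
    d: LabeledDataset,
    selected: list[str] | None = None,
    k: int = 10,
    n_runs: int = 1,
    seed: int = 0,
    scheme: str = "cv",
    alpha: float = 0.05,
) -> EvaluationReport:
    """Evaluate the conventional pipeline by cross-validation.

    ``selected`` is the full-data panel reported alongside (computed here if
    None); the validation itself always re-selects inside each training fold
    so the held-out samples never leak into the screening. An empty full-data
    selection yields a chance-level report, flagged in ``notes``.
    """
    if selected is None:
        selected = list(univariate_select(d, alpha=alpha)["metabolite"])
    learner = ConventionalLearner(alpha=alpha)
    if scheme == "loocv":
        report = loocv(d, learner, n_runs=n_runs, seed=seed)
    else:
        report = cross_validate(d, learner, k=k, n_runs=n_runs, seed=seed)
    report.method = "conventional"
    report.per_run["selected_full_data"] = list(selected)
    if not selected:
        report.notes.append("empty full-data selection: metrics reflect chance")
    return report
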