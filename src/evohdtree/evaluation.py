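"""Classification metrics, repeated CV / LOOCV, ROC curves and rank tests.

Metrics follow the positive-class convention: ``y == 1`` is the patient
group. F1 returns 0 when there are no true positives (the degenerate case
where a classifier never predicts the minority class). Out-of-fold
predictions are pooled into a single confusion matrix per run (micro
pooling), and metrics are averaged over repeated runs for stochastic
learners, reported as mean with standard deviation.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Protocol

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_curve
from sklearn.model_selection import StratifiedKFold

from .io import LabeledDataset

logger = logging.getLogger(__name__)

_SEED_MOD = 2**31 - 1


@dataclass
class ConfusionMatrix:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def confusion(y_true, y_pred) -> ConfusionMatrix:
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred length mismatch")
    return ConfusionMatrix(
        tp=int(np.sum((y_true == 1) & (y_pred == 1))),
        fp=int(np.sum((y_true == 0) & (y_pred == 1))),
        fn=int(np.sum((y_true == 1) & (y_pred == 0))),
        tn=int(np.sum((y_true == 0) & (y_pred == 0))),
    )


def f1_score(cm: ConfusionMatrix) -> float:
    """Harmonic mean of precision and recall; 0 by convention when tp == 0."""
    if cm.tp == 0:
        return 0.0
    return 2.0 * cm.tp / (2.0 * cm.tp + cm.fp + cm.fn)


def accuracy(cm: ConfusionMatrix) -> float:
    if cm.n == 0:
        raise ValueError("empty confusion matrix")
    return (cm.tp + cm.tn) / cm.n


def roc_auc(y_true, scores) -> tuple[float, list[tuple[float, float]]]:
    """AUC (tie-corrected pairwise concordance) plus ROC points.

    The AUC equals P(s+ > s-) + 0.5 P(s+ = s-) over all positive-negative
    pairs — the Mann-Whitney statistic scaled to [0, 1]. ROC points come
    from a sweep over the distinct score thresholds.
    """
    y_true = np.asarray(y_true, dtype=int)
    scores = np.asarray(scores, dtype=float)
    n_pos = int((y_true == 1).sum())
    n_neg = int((y_true == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("roc_auc needs both classes present")
    # rank-based concordance handles ties exactly
    ranks = stats.rankdata(scores)
    auc = (ranks[y_true == 1].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)
    fpr, tpr, _ = roc_curve(y_true, scores)
    return float(auc), list(zip(fpr.tolist(), tpr.tolist()))


# ---------------------------------------------------------------------------
# Learner protocol and cross-validation


class FittedModel(Protocol):
    def predict(self, X) -> np.ndarray: ...
    def predict_score(self, X) -> np.ndarray: ...


class Learner(Protocol):
    """Anything that can be fit on (X, y) with a seed and then predict."""

    def fit(self, X, y, metabolite_names, seed: int) -> FittedModel: ...


@dataclass
class EvaluationReport:
    """Mean metrics over repeated validation runs, with dispersion."""

    acc: float
    f1: float
    auc: float
    roc_points: list[tuple[float, float]]
    acc_sd: float
    f1_sd: float
    auc_sd: float
    n_runs: int
    scheme: str = ""
    comparison: str = ""
    method: str = ""
    notes: list[str] = field(default_factory=list)
    per_run: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "comparison": self.comparison,
            "scheme": self.scheme,
            "acc": self.acc,
            "acc_sd": self.acc_sd,
            "f1": self.f1,
            "f1_sd": self.f1_sd,
            "auc": self.auc,
            "auc_sd": self.auc_sd,
            "n_runs": self.n_runs,
            "notes": self.notes,
        }

    def to_json(self, **kwargs) -> str:
        kwargs.setdefault("sort_keys", True)
        return json.dumps(self.to_dict(), **kwargs)

    def summary_row(self) -> dict:
        """One row of a benchmark table (method x comparison x metrics)."""
        return self.to_dict()


def _run_folds(d: LabeledDataset, learner: Learner, splits, seed: int):
    """Fit per training fold, predict held-out samples; returns pooled vectors."""
    n = d.n_samples
    pred = np.empty(n, dtype=int)
    score = np.empty(n, dtype=float)
    for i, (train_idx, test_idx) in enumerate(splits):
        fit_seed = (seed + 7919 * i) % _SEED_MOD
        model = learner.fit(
            d.values[train_idx], d.y[train_idx], d.metabolite_names, seed=fit_seed
        )
        pred[test_idx] = model.predict(d.values[test_idx])
        score[test_idx] = model.predict_score(d.values[test_idx])
    return pred, score


def _aggregate(d, runs, scheme, notes) -> EvaluationReport:
    accs, f1s, aucs = [], [], []
    all_scores, all_y = [], []
    for pred, score in runs:
        cm = confusion(d.y, pred)
        accs.append(accuracy(cm))
        f1s.append(f1_score(cm))
        auc, _ = roc_auc(d.y, score)
        aucs.append(auc)
        all_scores.append(score)
        all_y.append(d.y)
    _, roc_pts = roc_auc(np.concatenate(all_y), np.concatenate(all_scores))
    sd = lambda v: float(np.std(v, ddof=0)) if len(v) > 1 else 0.0
    return EvaluationReport(
        acc=float(np.mean(accs)),
        f1=float(np.mean(f1s)),
        auc=float(np.mean(aucs)),
        roc_points=roc_pts,
        acc_sd=sd(accs),
        f1_sd=sd(f1s),
        auc_sd=sd(aucs),
        n_runs=len(runs),
        scheme=scheme,
        comparison=d.name,
        notes=notes,
    )


def cross_validate(
    d: LabeledDataset,
    learner: Learner,
    k: int = 10,
    n_runs: int = 1,
    seed: int = 0,
) -> EvaluationReport:
    """Repeated stratified k-fold CV with micro-pooled out-of-fold metrics."""
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > d.n_samples:
        raise ValueError(f"k={k} exceeds n={d.n_samples}")
    notes: list[str] = []
    n_min = int(min(d.y.sum(), len(d.y) - d.y.sum()))
    k_eff = k
    if n_min < k:
        k_eff = max(2, n_min)
        notes.append(f"minority class smaller than k; folds reduced to {k_eff}")
        logger.warning("stratification degraded: k reduced from %d to %d", k, k_eff)
    runs = []
    for r in range(n_runs):
        run_seed = (seed + r) % _SEED_MOD
        skf = StratifiedKFold(n_splits=k_eff, shuffle=True, random_state=run_seed)
        splits = list(skf.split(d.values, d.y))
        runs.append(_run_folds(d, learner, splits, run_seed))
    return _aggregate(d, runs, scheme=f"{k_eff}-fold CV x{n_runs}", notes=notes)


def loocv(
    d: LabeledDataset,
    learner: Learner,
    n_runs: int = 1,
    seed: int = 0,
) -> EvaluationReport:
    """Leave-one-out CV: n folds of one held-out sample each, pooled."""
    n = d.n_samples
    if n < 2:
        raise ValueError("LOOCV needs at least 2 samples")
    runs = []
    all_idx = np.arange(n)
    for r in range(n_runs):
        run_seed = (seed + r) % _SEED_MOD
        splits = [(np.delete(all_idx, i), np.array([i])) for i in range(n)]
        runs.append(_run_folds(d, learner, splits, run_seed))
    return _aggregate(d, runs, scheme=f"LOOCV x{n_runs}", notes=[])


# ---------------------------------------------------------------------------
# Cross-algorithm comparison


@dataclass
class FriedmanResult:
    statistic: float
    pvalue: float
    mean_ranks: pd.Series  # rank 1 = best (highest score)
    dunn: pd.DataFrame  # pairwise z / raw p / Bonferroni-adjusted p

    def significant(self, level: float = 0.05) -> bool:
        return self.pvalue < level


def friedman_compare(score_table: pd.DataFrame) -> FriedmanResult:
    """Friedman rank test across algorithms (rows) over comparisons (columns).

    Uses average ranks for ties; the statistic is
    ``12N/(k(k+1)) * (sum R_bar_j^2 - k(k+1)^2/4)`` with N comparisons and k
    algorithms, referred to chi-square with k-1 df. Dunn's pairwise z-tests
    (Bonferroni-adjusted) are returned as the post-hoc companion.
    """
    if score_table.shape[0] < 2 or score_table.shape[1] < 2:
        raise ValueError("need >=2 algorithms and >=2 comparisons")
    k, N = score_table.shape
    # rank within each comparison; rank 1 = best score
    ranks = pd.DataFrame(
        np.column_stack([stats.rankdata(-score_table[c].to_numpy()) for c in score_table]),
        index=score_table.index,
        columns=score_table.columns,
    )
    mean_ranks = ranks.mean(axis=1)
    statistic = 12.0 * N / (k * (k + 1)) * (
        float((mean_ranks**2).sum()) - k * (k + 1) ** 2 / 4.0
    )
    pvalue = float(stats.chi2.sf(statistic, df=k - 1))

    se = np.sqrt(k * (k + 1) / (6.0 * N))
    rows = []
    algos = list(score_table.index)
    n_pairs = k * (k - 1) // 2
    for i in range(k):
        for j in range(i + 1, k):
            z = (mean_ranks.iloc[i] - mean_ranks.iloc[j]) / se
            p = 2.0 * stats.norm.sf(abs(z))
            rows.append(
                {
                    "algorithm_1": algos[i],
                    "algorithm_2": algos[j],
                    "z": float(z),
                    "pvalue": float(p),
                    "pvalue_adjusted": float(min(1.0, p * n_pairs)),
                }
            )
    return FriedmanResult(
        statistic=float(statistic),
        pvalue=pvalue,
        mean_ranks=mean_ranks,
        dunn=pd.DataFrame(rows),
    )


def reports_to_table(reports: list[EvaluationReport]) -> pd.DataFrame:
    """Flatten reports into a benchmark table (method x comparison x metrics)."""
    return pd.DataFrame([r.summary_row() for r in reports])
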