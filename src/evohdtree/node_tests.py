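"""Heterogeneous node tests: univariate thresholds and bivariate rank pairs.

A univariate test compares one metabolite against a concentration threshold;
a bivariate test compares the relative order of two metabolites, in the
spirit of relative expression analysis (top-scoring-pair classifiers). The
bivariate form carries no threshold, so it is invariant to any strictly
increasing transform applied to both participating features — the property
that makes rank-pair tests robust to monotone normalisation choices.

Conventions (fixed so that trees are reproducible):

* univariate: route **left** iff ``x[feature] <= threshold`` (boundary left);
* bivariate: route **left** iff ``x[a] > x[b]`` (equality routes right).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Union

import numpy as np


@dataclass(frozen=True)
class UnivariateTest:
    feature: int
    threshold: float

    def describe(self, names) -> str:
        return f"{names[self.feature]} <= {self.threshold:g}"


@dataclass(frozen=True)
class BivariateTest:
    feature_a: int
    feature_b: int

    def __post_init__(self) -> None:
        if self.feature_a == self.feature_b:
            raise ValueError("bivariate test needs two distinct features")

    def describe(self, names) -> str:
        return f"{names[self.feature_a]} > {names[self.feature_b]}"


NodeTest = Union[UnivariateTest, BivariateTest]


def evaluate_test(test: NodeTest, x: np.ndarray) -> str:
    """Route one fully observed sample; returns ``"left"`` or ``"right"``."""
    x = np.asarray(x)
    if isinstance(test, UnivariateTest):
        return "left" if x[test.feature] <= test.threshold else "right"
    return "left" if x[test.feature_a] > x[test.feature_b] else "right"


def branch_mask(test: NodeTest, X: np.ndarray) -> np.ndarray:
    """Vectorised routing: boolean array, ``True`` where a row goes left."""
    if isinstance(test, UnivariateTest):
        return X[:, test.feature] <= test.threshold
    return X[:, test.feature_a] > X[:, test.feature_b]


def branch_mask_idx(test: NodeTest, X: np.ndarray, idx: np.ndarray) -> np.ndarray:
    """Like :func:`branch_mask` restricted to rows ``idx``, touching only the
    columns the test reads (avoids materialising full row slices)."""
    if isinstance(test, UnivariateTest):
        return X[idx, test.feature] <= test.threshold
    return X[idx, test.feature_a] > X[idx, test.feature_b]


def candidate_thresholds(values) -> np.ndarray:
    """Midpoints between consecutive distinct sorted values.

    A constant feature yields no candidates (and hence no univariate tests).
    """
    u = np.unique(np.asarray(values, dtype=float))
    if u.size < 2:
        return np.empty(0)
    return (u[:-1] + u[1:]) / 2.0


def enumerate_tests(d, include_bivariate: bool = True) -> list[NodeTest]:
    """Every univariate test over candidate thresholds, plus all ordered pairs.

    This is the full search space the exhaustive oracle ranges over; the
    evolutionary engine samples from the same vocabulary.
    """
    tests: list[NodeTest] = []
    p = d.values.shape[1]
    for j in range(p):
        for thr in candidate_thresholds(d.values[:, j]):
            tests.append(UnivariateTest(j, float(thr)))
    if include_bivariate:
        for a in range(p):
            for b in range(p):
                if a != b:
                    tests.append(BivariateTest(a, b))
    return tests


# ---------------------------------------------------------------------------
# JSON schema: {"kind":"uni","feature":name,"threshold":t} /
#              {"kind":"bi","a":name,"b":name}


def test_to_json(test: NodeTest, names) -> dict:
    if isinstance(test, UnivariateTest):
        return {"kind": "uni", "feature": names[test.feature], "threshold": test.threshold}
    return {"kind": "bi", "a": names[test.feature_a], "b": names[test.feature_b]}


def test_from_json(obj: dict, names) -> NodeTest:
    index = {n: i for i, n in enumerate(names)}
    if obj["kind"] == "uni":
        return UnivariateTest(index[obj["feature"]], float(obj["threshold"]))
    if obj["kind"] == "bi":
        return BivariateTest(index[obj["a"]], index[obj["b"]])
    raise ValueError(f"unknown test kind {obj['kind']!r}")
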