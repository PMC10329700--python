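"""Binary decision trees with heterogeneous node tests.

A tree is strictly binary: every internal node carries one univariate or
bivariate test and two children; every leaf carries a class label together
with the training class counts ``(n_pos, n_neg)`` of the samples routed to
it. Leaves are labelled by training majority; ties and empty leaves default
to the positive class (empty leaves inherit the parent's majority first).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .node_tests import (
    BivariateTest,
    NodeTest,
    UnivariateTest,
    branch_mask,
    branch_mask_idx,
    test_from_json,
    test_to_json,
)


@dataclass
class TreeNode:
    test: NodeTest | None = None
    left: "TreeNode | None" = None
    right: "TreeNode | None" = None
    label: int = 1
    class_counts: tuple[int, int] = (0, 0)  # (n_pos, n_neg) routed here

    @property
    def is_leaf(self) -> bool:
        return self.test is None

    def copy(self) -> "TreeNode":
        if self.is_leaf:
            return TreeNode(label=self.label, class_counts=self.class_counts)
        return TreeNode(
            test=self.test,
            left=self.left.copy(),
            right=self.right.copy(),
            label=self.label,
            class_counts=self.class_counts,
        )


def leaf(label: int = 1, class_counts: tuple[int, int] = (0, 0)) -> TreeNode:
    return TreeNode(label=label, class_counts=class_counts)


def internal(test: NodeTest, left: TreeNode, right: TreeNode) -> TreeNode:
    return TreeNode(test=test, left=left, right=right)


@dataclass
class HeterogeneousTree:
    root: TreeNode
    metabolite_names: list[str]
    fitted_on: str = ""

    # -- structure ---------------------------------------------------------

    def n_internal_nodes(self) -> int:
        def count(n: TreeNode) -> int:
            return 0 if n.is_leaf else 1 + count(n.left) + count(n.right)

        return count(self.root)

    def depth(self) -> int:
        def d(n: TreeNode) -> int:
            return 0 if n.is_leaf else 1 + max(d(n.left), d(n.right))

        return d(self.root)

    def nodes(self) -> list[TreeNode]:
        """All nodes in pre-order."""
        out: list[TreeNode] = []

        def walk(n: TreeNode) -> None:
            out.append(n)
            if not n.is_leaf:
                walk(n.left)
                walk(n.right)

        walk(self.root)
        return out

    def internal_nodes(self) -> list[TreeNode]:
        return [n for n in self.nodes() if not n.is_leaf]

    def leaves(self) -> list[TreeNode]:
        return [n for n in self.nodes() if n.is_leaf]

    def copy(self) -> "HeterogeneousTree":
        return HeterogeneousTree(self.root.copy(), self.metabolite_names, self.fitted_on)

    # -- prediction --------------------------------------------------------

    def _align(self, X) -> np.ndarray:
        """Accept an ndarray (assumed aligned) or a DataFrame (aligned by name)."""
        if hasattr(X, "columns"):  # DataFrame
            missing = [n for n in self.metabolite_names if n not in X.columns]
            if missing:
                raise KeyError(f"features absent from input: {missing[:5]}")
            X = X[self.metabolite_names].to_numpy(dtype=float)
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != len(self.metabolite_names):
            raise ValueError(
                f"expected {len(self.metabolite_names)} features, got shape {X.shape}"
            )
        return X

    def _route_leaves(self, X: np.ndarray) -> list[TreeNode]:
        n = X.shape[0]
        out: list[TreeNode | None] = [None] * n

        def walk(node: TreeNode, idx: np.ndarray) -> None:
            if idx.size == 0:
                return
            if node.is_leaf:
                for i in idx:
                    out[i] = node
                return
            go_left = branch_mask_idx(node.test, X, idx)
            walk(node.left, idx[go_left])
            walk(node.right, idx[~go_left])

        walk(self.root, np.arange(n))
        return out  # type: ignore[return-value]

    def predict(self, X) -> np.ndarray:
        """Class label (0/1) of the leaf each row is routed to."""
        X = self._align(X)
        return np.array([lf.label for lf in self._route_leaves(X)], dtype=np.int64)

    def predict_score(self, X) -> np.ndarray:
        """Laplace-smoothed positive fraction of the reached leaf.

        ``score = (n_pos + 1) / (n_pos + n_neg + 2)``, always in (0, 1); an
        empty leaf scores 0.5.
        """
        X = self._align(X)
        return np.array(
            [
                (lf.class_counts[0] + 1.0) / (lf.class_counts[0] + lf.class_counts[1] + 2.0)
                for lf in self._route_leaves(X)
            ]
        )

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        def node_dict(n: TreeNode) -> dict:
            if n.is_leaf:
                return {"leaf": True, "label": int(n.label),
                        "counts": [int(n.class_counts[0]), int(n.class_counts[1])]}
            return {
                "leaf": False,
                "test": test_to_json(n.test, self.metabolite_names),
                "left": node_dict(n.left),
                "right": node_dict(n.right),
            }

        return {
            "metabolites": list(self.metabolite_names),
            "fitted_on": self.fitted_on,
            "root": node_dict(self.root),
        }

    def to_json(self, **kwargs) -> str:
        kwargs.setdefault("sort_keys", True)
        return json.dumps(self.to_dict(), **kwargs)

    @classmethod
    def from_dict(cls, obj: dict) -> "HeterogeneousTree":
        names = obj["metabolites"]

        def build(nd: dict) -> TreeNode:
            if nd["leaf"]:
                return leaf(int(nd["label"]), (int(nd["counts"][0]), int(nd["counts"][1])))
            return internal(test_from_json(nd["test"], names), build(nd["left"]), build(nd["right"]))

        return cls(build(obj["root"]), list(names), obj.get("fitted_on", ""))

    @classmethod
    def from_json(cls, s: str) -> "HeterogeneousTree":
        return cls.from_dict(json.loads(s))

    def pretty(self) -> str:
        """Human-readable rendering of the fitted rule."""
        lines: list[str] = []

        def walk(n: TreeNode, indent: int, tag: str) -> None:
            pad = "  " * indent
            if n.is_leaf:
                lines.append(
                    f"{pad}{tag}leaf -> class {n.label} "
                    f"(pos={n.class_counts[0]}, neg={n.class_counts[1]})"
                )
            else:
                lines.append(f"{pad}{tag}if {n.test.describe(self.metabolite_names)}:")
                walk(n.left, indent + 1, "")
                lines.append(f"{pad}else:")
                walk(n.right, indent + 1, "")

        walk(self.root, 0, "")
        return "\n".join(lines)


def refit_leaves(tree: HeterogeneousTree, d) -> HeterogeneousTree:
    """Recompute leaf class counts and majority labels on a dataset, in place.

    Majority labelling with ties to the positive class; a leaf that receives
    no training samples takes its parent's majority label.
    """
    X = np.asarray(d.values, dtype=float)
    y = np.asarray(d.y)
    n_pos_total = int(y.sum())
    n_neg_total = len(y) - n_pos_total
    root_major = 1 if n_pos_total >= n_neg_total else 0

    def walk(node: TreeNode, idx: np.ndarray, parent_major: int) -> None:
        pos = int(y[idx].sum())
        neg = idx.size - pos
        if pos > neg:
            major = 1
        elif neg > pos:
            major = 0
        else:  # tie or empty
            major = parent_major if idx.size == 0 else 1
        if node.is_leaf:
            node.class_counts = (pos, neg)
            node.label = major
            return
        node.class_counts = (pos, neg)
        if idx.size:
            go_left = branch_mask_idx(node.test, X, idx)
            left_idx, right_idx = idx[go_left], idx[~go_left]
        else:
            left_idx = right_idx = idx
        walk(node.left, left_idx, major)
        walk(node.right, right_idx, major)

    walk(tree.root, np.arange(len(y)), root_major)
    tree.fitted_on = d.fingerprint()
    return tree
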