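"""Evolutionary induction of heterogeneous decision trees.

A population of binary trees over univariate-threshold and bivariate
rank-pair node tests is evolved by tournament selection with elitism.
Fitness is the training F1-score of the tree minus a complexity penalty
proportional to the number of internal nodes:

    fitness(T) = F1_train(T) - alpha * |internal nodes of T|

so ``alpha`` trades predictive power against tree size; at equal F1 the
smaller tree always wins. Variation draws uniformly from a catalogue of
specialized operators (threshold perturbation and re-optimisation, feature
and pair replacement, test-kind swaps, pruning, expansion, subtree
replacement, label flips, and two crossover forms).

``exhaustive_best_tree`` provides a brute-force optimum over all trees of
depth <= 2 for small instances, used as an independent check that the
stochastic search actually finds global optima.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .io import LabeledDataset
from .node_tests import (
    BivariateTest,
    NodeTest,
    UnivariateTest,
    branch_mask,
    candidate_thresholds,
    enumerate_tests,
    test_to_json,
)
from .tree import HeterogeneousTree, TreeNode, internal, leaf, refit_leaves

logger = logging.getLogger(__name__)


@dataclass
class EAConfig:
    """All knobs of the evolutionary search.

    ``alpha`` is the size-regularization weight in the fitness function
    (penalty per internal node). The remaining parameters are the usual
    generational-GA controls; a single seeded generator drives every
    stochastic choice, so runs are reproducible.
    """

    population_size: int = 100
    generations: int = 200
    tournament_size: int = 3
    elitism: int = 1
    crossover_prob: float = 0.8
    mutation_prob: float = 0.4
    alpha: float = 0.01
    max_depth: int = 5
    init_depth_range: tuple[int, int] = (1, 3)
    stagnation_limit: int = 50
    seed: int = 0
    include_bivariate: bool = True

    def __post_init__(self) -> None:
        # keep the default init range usable with shallow max_depth settings
        lo, hi = self.init_depth_range
        self.init_depth_range = (min(lo, self.max_depth), min(hi, self.max_depth))

    def validate(self) -> None:
        if self.population_size < 2:
            raise ValueError("population_size must be >= 2")
        for name in ("crossover_prob", "mutation_prob"):
            p = getattr(self, name)
            if not 0 <= p <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")
        if self.max_depth < 1:
            raise ValueError("max_depth must be >= 1")
        lo, hi = self.init_depth_range
        if not (0 <= lo <= hi <= self.max_depth):
            raise ValueError("init_depth_range must satisfy 0 <= lo <= hi <= max_depth")
        if self.elitism < 0 or self.elitism >= self.population_size:
            raise ValueError("elitism must be in [0, population_size)")


# ---------------------------------------------------------------------------
# Fitness


def _tree_confusion(t: HeterogeneousTree) -> tuple[int, int, int]:
    """(tp, fp, fn) of a refit tree on its training data, from leaf counts."""
    tp = fp = fn = 0
    for lf in t.leaves():
        pos, neg = lf.class_counts
        if lf.label == 1:
            tp += pos
            fp += neg
        else:
            fn += pos
    return tp, fp, fn


def training_f1(t: HeterogeneousTree) -> float:
    """Training F1 of a tree whose leaves were refit; 0 when tp == 0."""
    tp, fp, fn = _tree_confusion(t)
    if tp == 0:
        return 0.0
    return 2.0 * tp / (2.0 * tp + fp + fn)


def fitness(t: HeterogeneousTree, d: LabeledDataset, alpha: float) -> float:
    """Size-regularized training fitness: F1 minus ``alpha`` per internal node.

    The tree's leaves must already be labelled on ``d`` (see
    :func:`~evohdtree.tree.refit_leaves`).
    """
    return training_f1(t) - alpha * t.n_internal_nodes()


# ---------------------------------------------------------------------------
# Evolution context: dataset + cached per-feature threshold candidates


class _Ctx:
    def __init__(self, d: LabeledDataset, cfg: EAConfig):
        self.d = d
        self.cfg = cfg
        self.X = np.asarray(d.values, dtype=float)
        self.p = self.X.shape[1]
        self._thresholds: dict[int, np.ndarray] = {}
        # features with at least two distinct values (usable for univariate tests)
        self.splittable = [j for j in range(self.p) if len(self.thresholds(j)) > 0]

    def thresholds(self, j: int) -> np.ndarray:
        if j not in self._thresholds:
            self._thresholds[j] = candidate_thresholds(self.X[:, j])
        return self._thresholds[j]

    def random_test(self, rng: np.random.Generator) -> NodeTest | None:
        want_bi = (
            self.cfg.include_bivariate and self.p >= 2 and rng.random() < 0.5
        )
        if not want_bi and self.splittable:
            j = self.splittable[rng.integers(len(self.splittable))]
            thr = self.thresholds(j)
            return UnivariateTest(j, float(thr[rng.integers(len(thr))]))
        if self.cfg.include_bivariate and self.p >= 2:
            a = int(rng.integers(self.p))
            b = int(rng.integers(self.p - 1))
            if b >= a:
                b += 1
            return BivariateTest(a, b)
        return None

    def random_subtree(self, depth: int, rng: np.random.Generator) -> TreeNode:
        if depth <= 0:
            return leaf()
        t = self.random_test(rng)
        if t is None:
            return leaf()
        grow = lambda: (
            self.random_subtree(depth - 1, rng) if rng.random() < 0.6 else leaf()
        )
        return internal(t, grow(), grow())


def _node_depths(t: HeterogeneousTree) -> list[tuple[TreeNode, TreeNode | None, int]]:
    """(node, parent, depth) triples in pre-order."""
    out: list[tuple[TreeNode, TreeNode | None, int]] = []

    def walk(n: TreeNode, parent: TreeNode | None, depth: int) -> None:
        out.append((n, parent, depth))
        if not n.is_leaf:
            walk(n.left, n, depth + 1)
            walk(n.right, n, depth + 1)

    walk(t.root, None, 0)
    return out


def _truncate_to_depth(node: TreeNode, remaining: int) -> TreeNode:
    """Replace any subtree deeper than allowed by a leaf."""
    if node.is_leaf:
        return node
    if remaining <= 0:
        return leaf(label=node.label, class_counts=node.class_counts)
    node.left = _truncate_to_depth(node.left, remaining - 1)
    node.right = _truncate_to_depth(node.right, remaining - 1)
    return node


# ---------------------------------------------------------------------------
# Variation operator catalogue


def _uni_nodes(t):
    return [n for n in t.internal_nodes() if isinstance(n.test, UnivariateTest)]


def _bi_nodes(t):
    return [n for n in t.internal_nodes() if isinstance(n.test, BivariateTest)]


def _pick(items, rng):
    return items[rng.integers(len(items))] if items else None


def _op_threshold_shift(t, ctx, rng) -> bool:
    """Gaussian step of a univariate threshold on the candidate-rank scale."""
    node = _pick(_uni_nodes(t), rng)
    if node is None:
        return False
    thr = ctx.thresholds(node.test.feature)
    if len(thr) == 0:
        return False
    i = int(np.searchsorted(thr, node.test.threshold))
    step = int(round(rng.normal(0, max(1.0, 0.1 * len(thr)))))
    if step == 0:
        step = 1 if rng.random() < 0.5 else -1
    j = int(np.clip(i + step, 0, len(thr) - 1))
    node.test = UnivariateTest(node.test.feature, float(thr[j]))
    return True


def _op_threshold_redraw(t, ctx, rng) -> bool:
    node = _pick(_uni_nodes(t), rng)
    if node is None:
        return False
    thr = ctx.thresholds(node.test.feature)
    if len(thr) == 0:
        return False
    node.test = UnivariateTest(node.test.feature, float(thr[rng.integers(len(thr))]))
    return True


def _op_uni_feature_replace(t, ctx, rng) -> bool:
    node = _pick(_uni_nodes(t), rng)
    if node is None or not ctx.splittable:
        return False
    j = ctx.splittable[rng.integers(len(ctx.splittable))]
    thr = ctx.thresholds(j)
    node.test = UnivariateTest(j, float(thr[rng.integers(len(thr))]))
    return True


def _op_bi_partner_replace(t, ctx, rng) -> bool:
    node = _pick(_bi_nodes(t), rng)
    if node is None or ctx.p < 2:
        return False
    a, b = node.test.feature_a, node.test.feature_b
    keep_a = rng.random() < 0.5
    fixed = a if keep_a else b
    new = int(rng.integers(ctx.p - 1))
    if new >= fixed:
        new += 1
    node.test = BivariateTest(a, new) if keep_a else BivariateTest(new, b)
    return True


def _op_bi_pair_redraw(t, ctx, rng) -> bool:
    node = _pick(_bi_nodes(t), rng)
    if node is None or ctx.p < 2:
        return False
    a = int(rng.integers(ctx.p))
    b = int(rng.integers(ctx.p - 1))
    if b >= a:
        b += 1
    node.test = BivariateTest(a, b)
    return True


def _op_test_kind_swap(t, ctx, rng) -> bool:
    """Swap a node's test kind: univariate <-> bivariate, children preserved."""
    node = _pick(t.internal_nodes(), rng)
    if node is None:
        return False
    if isinstance(node.test, UnivariateTest):
        if not ctx.cfg.include_bivariate or ctx.p < 2:
            return False
        a = node.test.feature
        b = int(rng.integers(ctx.p - 1))
        if b >= a:
            b += 1
        node.test = BivariateTest(a, b)
    else:
        a = node.test.feature_a
        thr = ctx.thresholds(a)
        if len(thr) == 0:
            if not ctx.splittable:
                return False
            a = ctx.splittable[rng.integers(len(ctx.splittable))]
            thr = ctx.thresholds(a)
        node.test = UnivariateTest(a, float(thr[rng.integers(len(thr))]))
    return True


_HILLCLIMB_CAP = 32  # candidates scanned per memetic re-optimisation


def _op_threshold_hillclimb(t, ctx, rng) -> bool:
    """Memetic move: set one univariate threshold to the best candidate."""
    node = _pick(_uni_nodes(t), rng)
    if node is None:
        return False
    thr = ctx.thresholds(node.test.feature)
    if len(thr) == 0:
        return False
    if len(thr) > _HILLCLIMB_CAP:
        thr = thr[rng.choice(len(thr), _HILLCLIMB_CAP, replace=False)]
    best_thr, best_fit = node.test.threshold, -np.inf
    feature = node.test.feature
    for c in thr:
        node.test = UnivariateTest(feature, float(c))
        refit_leaves(t, ctx.d)
        f = fitness(t, ctx.d, ctx.cfg.alpha)
        if f > best_fit:
            best_fit, best_thr = f, float(c)
    node.test = UnivariateTest(feature, best_thr)
    return True


def _scan_cap(ctx) -> int:
    # memetic scans get cheaper as the dataset grows, bounding per-move cost
    return max(6, 1600 // max(1, ctx.d.n_samples))


def _sample_tests(ctx, rng, cap: int) -> list[NodeTest]:
    out = []
    for _ in range(cap):
        c = ctx.random_test(rng)
        if c is not None:
            out.append(c)
    return out


def _best_test_for_node(t, node, candidates, ctx, keep_leaf: bool = False):
    """Coordinate step: set ``node`` to its best candidate by full-tree fitness."""
    saved = (node.test, node.left, node.right)
    best_fit, best_state = -np.inf, saved
    options = list(candidates)
    for c in options:
        node.test = c
        if node.left is None:
            node.left, node.right = leaf(), leaf()
        refit_leaves(t, ctx.d)
        f = fitness(t, ctx.d, ctx.cfg.alpha)
        if f > best_fit:
            best_fit, best_state = f, (c, node.left, node.right)
    if keep_leaf:
        node.test, node.left, node.right = None, None, None
        refit_leaves(t, ctx.d)
        f = fitness(t, ctx.d, ctx.cfg.alpha)
        if f > best_fit:
            best_fit, best_state = f, (None, None, None)
    node.test, node.left, node.right = best_state
    return best_fit


def _op_node_test_reoptimize(t, ctx, rng) -> bool:
    """Memetic move: replace one node's test by the best of a random sample."""
    node = _pick(t.internal_nodes(), rng)
    if node is None:
        return False
    candidates = [node.test] + _sample_tests(ctx, rng, _scan_cap(ctx))
    _best_test_for_node(t, node, candidates, ctx)
    return True


def _op_lookahead_split(t, ctx, rng) -> bool:
    """Memetic move countering deceptive splits: plant one random test at a
    node, then optimise both child tests by coordinate ascent on the full-tree
    fitness (each child may stay a leaf)."""
    eligible = [
        (n, depth) for n, _, depth in _node_depths(t) if depth < ctx.cfg.max_depth
    ]
    picked = _pick(eligible, rng)
    if picked is None:
        return False
    node, _ = picked
    test = ctx.random_test(rng)
    if test is None:
        return False
    node.test = test
    node.left, node.right = leaf(), leaf()
    cap = _scan_cap(ctx)
    for child_name in ("left", "right"):
        child = getattr(node, child_name)
        _best_test_for_node(t, child, _sample_tests(ctx, rng, cap), ctx, keep_leaf=True)
    return True


def _op_prune_to_leaf(t, ctx, rng) -> bool:
    node = _pick(t.internal_nodes(), rng)
    if node is None:
        return False
    node.test = None
    node.left = None
    node.right = None
    return True


def _op_expand_leaf(t, ctx, rng) -> bool:
    eligible = [
        (n, depth) for n, _, depth in _node_depths(t)
        if n.is_leaf and depth < ctx.cfg.max_depth
    ]
    picked = _pick(eligible, rng)
    if picked is None:
        return False
    node, _ = picked
    test = ctx.random_test(rng)
    if test is None:
        return False
    node.test = test
    node.left = leaf()
    node.right = leaf()
    return True


def _op_swap_children(t, ctx, rng) -> bool:
    node = _pick(t.internal_nodes(), rng)
    if node is None:
        return False
    node.left, node.right = node.right, node.left
    return True


def _op_replace_subtree(t, ctx, rng) -> bool:
    candidates = _node_depths(t)
    node, _, depth = candidates[rng.integers(len(candidates))]
    new = ctx.random_subtree(min(2, ctx.cfg.max_depth - depth), rng)
    node.test, node.left, node.right = new.test, new.left, new.right
    node.label, node.class_counts = new.label, new.class_counts
    return True


def _op_leaf_label_flip(t, ctx, rng) -> bool:
    node = _pick(t.leaves(), rng)
    if node is None:
        return False
    node.label = 1 - node.label
    return True


#: unary variation catalogue; together with the two crossover forms below this
#: is the full operator set (>= 13 specialized variants).
MUTATION_OPERATORS = {
    "threshold_shift": _op_threshold_shift,
    "threshold_redraw": _op_threshold_redraw,
    "uni_feature_replace": _op_uni_feature_replace,
    "bi_partner_replace": _op_bi_partner_replace,
    "bi_pair_redraw": _op_bi_pair_redraw,
    "test_kind_swap": _op_test_kind_swap,
    "threshold_hillclimb": _op_threshold_hillclimb,
    "node_test_reoptimize": _op_node_test_reoptimize,
    "lookahead_split": _op_lookahead_split,
    "prune_to_leaf": _op_prune_to_leaf,
    "expand_leaf": _op_expand_leaf,
    "swap_children": _op_swap_children,
    "replace_subtree": _op_replace_subtree,
    "leaf_label_flip": _op_leaf_label_flip,
}

CROSSOVER_OPERATORS = ("subtree_exchange", "test_exchange")

#: every named variation operator in the catalogue
OPERATOR_CATALOGUE = tuple(MUTATION_OPERATORS) + CROSSOVER_OPERATORS

_MUTATION_NAMES = tuple(MUTATION_OPERATORS)


def mutate(
    t: HeterogeneousTree,
    d: LabeledDataset,
    rng: np.random.Generator,
    cfg: EAConfig | None = None,
    ctx: "_Ctx | None" = None,
) -> HeterogeneousTree:
    """Apply one uniformly chosen variation operator; returns a new tree.

    Inapplicable draws degrade to a no-op copy. Leaves are relabelled on the
    training data afterwards (except for the deliberate label-flip variant,
    which perturbs one leaf label after the recount).
    """
    if ctx is None:
        ctx = _Ctx(d, cfg or EAConfig())
    out = t.copy()
    name = _MUTATION_NAMES[rng.integers(len(_MUTATION_NAMES))]
    flip = name == "leaf_label_flip"
    applied = MUTATION_OPERATORS[name](out, ctx, rng) if not flip else False
    _truncate_to_depth(out.root, ctx.cfg.max_depth)
    refit_leaves(out, ctx.d)
    if flip:
        MUTATION_OPERATORS[name](out, ctx, rng)
    return out


def crossover(
    a: HeterogeneousTree,
    b: HeterogeneousTree,
    d: LabeledDataset,
    rng: np.random.Generator,
    max_depth: int = 5,
) -> tuple[HeterogeneousTree, HeterogeneousTree]:
    """Subtree-exchange or test-exchange recombination.

    Offspring exceeding ``max_depth`` are truncated to leaves; both offspring
    are relabelled on ``d``.
    """
    ca, cb = a.copy(), b.copy()
    kind = CROSSOVER_OPERATORS[rng.integers(len(CROSSOVER_OPERATORS))]
    if kind == "test_exchange":
        na = _pick(ca.internal_nodes(), rng)
        nb = _pick(cb.internal_nodes(), rng)
        if na is not None and nb is not None:
            na.test, nb.test = nb.test, na.test
    else:
        nodes_a = _node_depths(ca)
        nodes_b = _node_depths(cb)
        na, pa, _ = nodes_a[rng.integers(len(nodes_a))]
        nb, pb, _ = nodes_b[rng.integers(len(nodes_b))]
        na.test, nb.test = nb.test, na.test
        na.left, nb.left = nb.left, na.left
        na.right, nb.right = nb.right, na.right
        na.label, nb.label = nb.label, na.label
    _truncate_to_depth(ca.root, max_depth)
    _truncate_to_depth(cb.root, max_depth)
    refit_leaves(ca, d)
    refit_leaves(cb, d)
    return ca, cb


# ---------------------------------------------------------------------------
# Population management


def initialize_population(
    d: LabeledDataset, cfg: EAConfig, rng: np.random.Generator
) -> list[HeterogeneousTree]:
    """Ramped random initialization: target depths cycle over the init range."""
    cfg.validate()
    ctx = _Ctx(d, cfg)
    lo, hi = cfg.init_depth_range
    pop: list[HeterogeneousTree] = []
    for i in range(cfg.population_size):
        depth = lo + (i % (hi - lo + 1))
        root_test = ctx.random_test(rng) if depth >= 1 else None
        root = internal(root_test, leaf(), leaf()) if root_test is not None else leaf()
        node_frontier = [(root, 1)]
        while node_frontier:
            node, dpt = node_frontier.pop()
            if node.is_leaf or dpt >= depth:
                continue
            for child_name in ("left", "right"):
                if rng.random() < 0.5:
                    test = ctx.random_test(rng)
                    if test is not None:
                        child = internal(test, leaf(), leaf())
                        setattr(node, child_name, child)
                        node_frontier.append((child, dpt + 1))
        t = HeterogeneousTree(root, list(d.metabolite_names))
        refit_leaves(t, d)
        pop.append(t)
    return pop


def _tournament(
    pop: list[HeterogeneousTree],
    fits: np.ndarray,
    k: int,
    rng: np.random.Generator,
) -> HeterogeneousTree:
    idx = rng.integers(len(pop), size=k)
    return pop[idx[np.argmax(fits[idx])]]


@dataclass
class EvolutionLog:
    """Per-generation trace of the search."""

    best_fitness: list[float] = field(default_factory=list)
    mean_fitness: list[float] = field(default_factory=list)
    generations_run: int = 0
    stopped_early: bool = False

    def to_tsv(self) -> str:
        lines = ["generation\tbest_fitness\tmean_fitness"]
        for g, (b, m) in enumerate(zip(self.best_fitness, self.mean_fitness)):
            lines.append(f"{g}\t{b:.6f}\t{m:.6f}")
        return "\n".join(lines) + "\n"


def evolve(
    d: LabeledDataset,
    cfg: EAConfig | None = None,
    return_log: bool = False,
):
    """Run the evolutionary search and return the best tree ever seen.

    Deterministic given ``cfg.seed``. With ``return_log=True`` also returns
    an :class:`EvolutionLog` with the per-generation fitness trajectory.
    """
    cfg = cfg or EAConfig()
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    ctx = _Ctx(d, cfg)

    pop = initialize_population(d, cfg, rng)
    fits = np.array([fitness(t, d, cfg.alpha) for t in pop])
    best_i = int(np.argmax(fits))
    best_tree, best_fit = pop[best_i].copy(), float(fits[best_i])

    log = EvolutionLog()
    since_improvement = 0
    for gen in range(cfg.generations):
        order = np.argsort(-fits, kind="stable")
        new_pop = [pop[i].copy() for i in order[: cfg.elitism]]
        while len(new_pop) < cfg.population_size:
            p1 = _tournament(pop, fits, cfg.tournament_size, rng)
            if rng.random() < cfg.crossover_prob:
                p2 = _tournament(pop, fits, cfg.tournament_size, rng)
                c1, c2 = crossover(p1, p2, d, rng, cfg.max_depth)
            else:
                c1, c2 = p1.copy(), None
            for c in (c1, c2):
                if c is None or len(new_pop) >= cfg.population_size:
                    continue
                if rng.random() < cfg.mutation_prob:
                    c = mutate(c, d, rng, ctx=ctx)
                new_pop.append(c)
        pop = new_pop
        fits = np.array([fitness(t, d, cfg.alpha) for t in pop])
        gen_best = int(np.argmax(fits))
        if fits[gen_best] > best_fit:
            best_tree, best_fit = pop[gen_best].copy(), float(fits[gen_best])
            since_improvement = 0
        else:
            since_improvement += 1
        log.best_fitness.append(best_fit)
        log.mean_fitness.append(float(fits.mean()))
        log.generations_run = gen + 1
        if since_improvement >= cfg.stagnation_limit:
            log.stopped_early = True
            break

    refit_leaves(best_tree, d)
    if return_log:
        return best_tree, log
    return best_tree


# ---------------------------------------------------------------------------
# Exhaustive small-instance oracle


def _tree_key(root_test, left_test, right_test, names) -> str:
    """Canonical serialization used only for deterministic tie-breaking."""
    def ser(t):
        return json.dumps(test_to_json(t, names), sort_keys=True) if t is not None else ""

    return "|".join([ser(root_test), ser(left_test), ser(right_test)])


def exhaustive_best_tree(
    d: LabeledDataset,
    max_depth: int = 2,
    alpha: float = 0.01,
    max_enumeration: int = 20_000_000,
) -> HeterogeneousTree:
    """Globally fitness-optimal tree of depth <= ``max_depth`` (0, 1 or 2).

    Brute-force enumeration over every topology and every test from
    :func:`~evohdtree.node_tests.enumerate_tests`, with majority leaf
    labelling. Ties break toward fewer internal nodes, then the
    lexicographically smallest test serialization. Intended as an
    independent correctness oracle on small instances only.
    """
    if max_depth not in (0, 1, 2):
        raise ValueError("oracle supports max_depth in {0, 1, 2}")
    tests = enumerate_tests(d)
    T = len(tests)
    if max_depth >= 1 and T == 0:
        max_depth = 0
    cost = T ** (2 ** max_depth - 1) if max_depth else 1
    if cost > max_enumeration:
        raise ValueError(
            f"instance too large for exhaustive search ({cost} trees > {max_enumeration})"
        )

    X = np.asarray(d.values, dtype=float)
    y = np.asarray(d.y, dtype=bool)
    n = len(y)
    P = int(y.sum())
    names = list(d.metabolite_names)

    B = (
        np.stack([branch_mask(t, X) for t in tests])
        if T
        else np.empty((0, n), dtype=bool)
    )

    def f1_from(tp, fp):
        tp = np.asarray(tp, dtype=float)
        fp = np.asarray(fp, dtype=float)
        denom = 2 * tp + fp + (P - tp)
        with np.errstate(invalid="ignore", divide="ignore"):
            out = np.where(tp > 0, 2 * tp / denom, 0.0)
        return out

    # contribution of a subtree rooted at subset S:
    #   option -1 = leaf; option t = depth-1 test with two majority leaves
    def subtree_options(S: np.ndarray):
        pS = int((S & y).sum())
        nS = int(S.sum()) - pS
        parent_major = 1 if pS >= nS else 0
        # leaf option
        if pS + nS == 0:
            lab = parent_major
        else:
            lab = 1 if pS >= nS else 0
        leaf_tp = pS if lab == 1 else 0
        leaf_fp = nS if lab == 1 else 0
        if T == 0:
            return (
                np.array([leaf_tp]),
                np.array([leaf_fp]),
                np.array([0]),
            )
        SL = B & S
        pL = (SL & y).sum(axis=1)
        nL = SL.sum(axis=1) - pL
        pR = pS - pL
        nR = nS - nL
        labL = np.where(pL + nL > 0, pL >= nL, parent_major).astype(bool)
        labR = np.where(pR + nR > 0, pR >= nR, parent_major).astype(bool)
        tp = labL * pL + labR * pR
        fp = labL * nL + labR * nR
        return (
            np.concatenate([[leaf_tp], tp]),
            np.concatenate([[leaf_fp], fp]),
            np.concatenate([[0], np.ones(T, dtype=int)]),
        )

    best = {"fit": -np.inf, "nodes": None, "key": None, "build": None}

    def consider(fit, nodes, build_fn, key_fn):
        if fit > best["fit"] + 1e-12:
            best.update(fit=fit, nodes=nodes, key=key_fn(), build=build_fn)
        elif abs(fit - best["fit"]) <= 1e-12:
            key = key_fn()
            if nodes < best["nodes"] or (nodes == best["nodes"] and key < best["key"]):
                best.update(fit=fit, nodes=nodes, key=key, build=build_fn)

    # depth 0: single leaf
    full = np.ones(n, dtype=bool)
    tp0, fp0, _ = subtree_options(np.zeros(n, dtype=bool) | full)
    consider(
        float(f1_from(tp0[0], fp0[0])),
        0,
        lambda: leaf(),
        lambda: _tree_key(None, None, None, names),
    )

    if max_depth >= 1:
        # depth-1 trees: every test at the root, majority leaves
        tp1 = tp0[1:]
        fp1 = fp0[1:]
        f1 = f1_from(tp1, fp1) - alpha
        for r in range(T):
            consider(
                float(f1[r]),
                1,
                lambda r=r: internal(tests[r], leaf(), leaf()),
                lambda r=r: _tree_key(tests[r], None, None, names),
            )

    if max_depth == 2 and T:
        for r in range(T):
            S = B[r]
            tpL, fpL, ndL = subtree_options(S)
            tpR, fpR, ndR = subtree_options(~S)
            TP = tpL[:, None] + tpR[None, :]
            FP = fpL[:, None] + fpR[None, :]
            NODES = 1 + ndL[:, None] + ndR[None, :]
            FIT = f1_from(TP, FP) - alpha * NODES
            thr = max(best["fit"], float(FIT.max())) - 1e-12
            cand = np.argwhere(FIT >= thr)
            for li, ri in cand:
                lt = None if li == 0 else tests[li - 1]
                rt = None if ri == 0 else tests[ri - 1]

                def build(r=r, lt=lt, rt=rt):
                    lchild = leaf() if lt is None else internal(lt, leaf(), leaf())
                    rchild = leaf() if rt is None else internal(rt, leaf(), leaf())
                    return internal(tests[r], lchild, rchild)

                consider(
                    float(FIT[li, ri]),
                    int(NODES[li, ri]),
                    build,
                    lambda r=r, lt=lt, rt=rt: _tree_key(tests[r], lt, rt, names),
                )

    out = HeterogeneousTree(best["build"](), names)
    refit_leaves(out, d)
    return out
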