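"""Diagnostic panels: metabolite sets extracted from fitted trees.

A panel is the union of all metabolites referenced by a tree's internal
nodes (a bivariate node contributes both partners). Overlap structure across
comparisons is summarized as Venn regions — for every non-empty subset of
panels, the number of metabolites belonging to exactly that subset — plus
pairwise intersections and a bipartite comparison-metabolite edge list.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from itertools import combinations

import pandas as pd

from .node_tests import BivariateTest, UnivariateTest
from .tree import HeterogeneousTree


@dataclass
class Panel:
    comparison: str
    metabolites: set[str] = field(default_factory=set)

    @property
    def size(self) -> int:
        return len(self.metabolites)


def extract_panel(t: HeterogeneousTree, comparison: str) -> Panel:
    """Metabolites used by any internal node of a fitted tree, deduplicated."""
    names = t.metabolite_names
    mets: set[str] = set()
    for node in t.internal_nodes():
        if isinstance(node.test, UnivariateTest):
            mets.add(names[node.test.feature])
        elif isinstance(node.test, BivariateTest):
            mets.add(names[node.test.feature_a])
            mets.add(names[node.test.feature_b])
    return Panel(comparison=comparison, metabolites=mets)


@dataclass
class OverlapTable:
    """Venn regions over a family of panels.

    ``regions`` maps the sorted tuple of comparison names to the count of
    metabolites lying in exactly those panels; counts partition the union.
    """

    regions: dict[tuple[str, ...], int]
    pairwise: dict[tuple[str, str], set[str]]
    union_size: int

    def to_json(self, **kwargs) -> str:
        obj = {
            "regions": {" & ".join(k): v for k, v in self.regions.items()},
            "pairwise_intersections": {
                " & ".join(k): sorted(v) for k, v in self.pairwise.items()
            },
            "union_size": self.union_size,
        }
        kwargs.setdefault("sort_keys", True)
        return json.dumps(obj, **kwargs)


def overlap_table(panels: list[Panel]) -> OverlapTable:
    """Exact-membership Venn region counts plus pairwise intersections."""
    if len(panels) < 2:
        raise ValueError("overlap analysis needs at least two panels")
    union: set[str] = set().union(*(p.metabolites for p in panels))
    regions: dict[tuple[str, ...], int] = {}
    for met in union:
        key = tuple(sorted(p.comparison for p in panels if met in p.metabolites))
        regions[key] = regions.get(key, 0) + 1
    pairwise = {
        (a.comparison, b.comparison): a.metabolites & b.metabolites
        for a, b in combinations(panels, 2)
    }
    return OverlapTable(regions=regions, pairwise=pairwise, union_size=len(union))


def bipartite_edges(panels: list[Panel]) -> pd.DataFrame:
    """One (comparison, metabolite) edge per panel membership."""
    if not panels:
        raise ValueError("need at least one panel")
    rows = [
        {"comparison": p.comparison, "metabolite": m}
        for p in panels
        for m in sorted(p.metabolites)
    ]
    return pd.DataFrame(rows, columns=["comparison", "metabolite"])


def panels_to_csv(panels: list[Panel]) -> pd.DataFrame:
    return bipartite_edges(panels)
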