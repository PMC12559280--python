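"""Dated intra-organismal pedigrees and stem growth quantities.

A tree's branching architecture can be read as a phylogeny of somatic cell
lineages: branch points are dated by ring counting, leaves are the sampled
lineage end-points, and the divergence time separating two samples is the
total lineage time back to their most recent common branch point.  This
module builds that dated pedigree, computes pairwise divergence times, and
computes the dendrochronological growth quantities (basal area increments,
stem growth rate) used to characterise how fast each stem grew.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "LineageTree",
    "TreeStructureError",
    "divergence_times",
    "basal_area_increment",
    "stem_growth_rate",
    "growth_cellcount_correlation",
]


class TreeStructureError(ValueError):
    """Raised when an edge set does not describe a single rooted tree."""


@dataclass
class _Node:
    name: str
    parent: str | None = None
    length: float = 0.0  # years on the edge to the parent
    children: list[str] = field(default_factory=list)


class LineageTree:
    """Rooted, dated tree whose edge lengths are durations in years.

    Node ages are measured forward in time from the root (age 0); each leaf's
    age is the total time from the earliest branch point to sampling.
    """

    def __init__(self) -> None:
        self._nodes: dict[str, _Node] = {}
        self.root: str | None = None

    # -- construction -----------------------------------------------------
    @classmethod
    def from_edges(cls, edges: list[tuple[str, str, float]]) -> "LineageTree":
        """Build from (parent, child, branch_length_years) triples."""
        tree = cls()
        for parent, child, length in edges:
            if length < 0:
                raise TreeStructureError(
                    f"negative branch length {length} on edge {parent}->{child}"
                )
            if parent not in tree._nodes:
                tree._nodes[parent] = _Node(parent)
            if child in tree._nodes:
                node = tree._nodes[child]
                if node.parent is not None:
                    raise TreeStructureError(f"node {child!r} has multiple parents")
                node.parent, node.length = parent, float(length)
            else:
                tree._nodes[child] = _Node(child, parent, float(length))
            tree._nodes[parent].children.append(child)
        roots = [n.name for n in tree._nodes.values() if n.parent is None]
        if len(roots) != 1:
            raise TreeStructureError(f"expected exactly one root, found {roots}")
        tree.root = roots[0]
        tree._check_acyclic()
        if len(tree.leaf_labels()) != len(set(tree.leaf_labels())):
            raise TreeStructureError("duplicate leaf labels")
        return tree

    @classmethod
    def from_newick(cls, newick: str) -> "LineageTree":
        import dendropy

        try:
            dtree = dendropy.Tree.get(
                data=newick, schema="newick", suppress_internal_node_taxa=False
            )
        except Exception as exc:
            raise TreeStructureError(f"malformed Newick: {exc}") from exc
        edges: list[tuple[str, str, float]] = []
        counter = itertools.count()

        def label(node) -> str:
            if node.taxon is not None and node.taxon.label:
                return node.taxon.label
            if node.label:
                return node.label
            node.label = f"_internal{next(counter)}"
            return node.label

        seen_leaves: list[str] = []
        for node in dtree.preorder_node_iter():
            if node.parent_node is None:
                label(node)
                continue
            edges.append(
                (label(node.parent_node), label(node), float(node.edge.length or 0.0))
            )
            if node.is_leaf():
                lbl = label(node)
                if lbl in seen_leaves:
                    raise TreeStructureError(f"duplicate leaf label {lbl!r}")
                seen_leaves.append(lbl)
        return cls.from_edges(edges)

    def _check_acyclic(self) -> None:
        for leaf in self._nodes:
            seen = set()
            node = leaf
            while node is not None:
                if node in seen:
                    raise TreeStructureError(f"cycle detected at node {node!r}")
                seen.add(node)
                node = self._nodes[node].parent

    # -- queries ----------------------------------------------------------
    def leaf_labels(self) -> list[str]:
        return sorted(n.name for n in self._nodes.values() if not n.children)

    def node_names(self) -> list[str]:
        return sorted(self._nodes)

    def children(self, name: str) -> list[str]:
        return list(self._nodes[name].children)

    def parent(self, name: str) -> str | None:
        return self._nodes[name].parent

    def edge_length(self, name: str) -> float:
        return self._nodes[name].length

    def age(self, name: str) -> float:
        """Years from the root to ``name`` (root age is 0)."""
        total = 0.0
        node = self._nodes[name]
        while node.parent is not None:
            total += node.length
            node = self._nodes[node.parent]
        return total

    def path_to_root(self, name: str) -> list[str]:
        path = [name]
        while self._nodes[path[-1]].parent is not None:
            path.append(self._nodes[path[-1]].parent)
        return path

    def mrca(self, a: str, b: str) -> str:
        if a not in self._nodes or b not in self._nodes:
            missing = a if a not in self._nodes else b
            raise KeyError(f"leaf {missing!r} not in tree")
        ancestors_a = set(self.path_to_root(a))
        for node in self.path_to_root(b):
            if node in ancestors_a:
                return node
        raise TreeStructureError("disconnected nodes")  # pragma: no cover

    def preorder(self) -> list[str]:
        order, stack = [], [self.root]
        while stack:
            node = stack.pop()
            order.append(node)
            stack.extend(reversed(self._nodes[node].children))
        return order

    def to_newick(self) -> str:
        def fmt(name: str) -> str:
            node = self._nodes[name]
            if not node.children:
                return f"{name}:{node.length:g}"
            inner = ",".join(fmt(c) for c in node.children)
            if node.parent is None:
                return f"({inner}){name}"
            return f"({inner}){name}:{node.length:g}"

        return fmt(self.root) + ";"

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, LineageTree):
            return NotImplemented
        if self.leaf_labels() != other.leaf_labels():
            return False
        # topology equality via the multiset of dated leaf bipartitions
        def signature(tree: "LineageTree") -> set:
            sig = set()
            for name in tree.node_names():
                if tree.children(name):
                    below = frozenset(
                        leaf for leaf in tree.leaf_labels()
                        if name in tree.path_to_root(leaf)
                    )
                    sig.add((below, round(tree.age(name), 9)))
            return sig

        return signature(self) == signature(other)


def divergence_times(tree: LineageTree, include_self: bool = False) -> pd.DataFrame:
    """Divergence times for all unordered leaf pairs.

    For a pair (i, j), tau_i and tau_j are the years from their most recent
    common branch point to each tip and ``delta_t = tau_i + tau_j``.  Pairs
    whose most recent common branch point is the root cannot be dated past
    the earliest branch point and carry ``root_censored=True``.
    """
    leaves = tree.leaf_labels()
    ages = {name: tree.age(name) for name in tree.node_names()}
    rows = []
    pairs = itertools.combinations_with_replacement(leaves, 2) if include_self \
        else itertools.combinations(leaves, 2)
    for a, b in pairs:
        anc = tree.mrca(a, b)
        tau_a = ages[a] - ages[anc]
        tau_b = ages[b] - ages[anc]
        rows.append(
            {
                "leaf_i": a,
                "leaf_j": b,
                "tau_i": tau_a,
                "tau_j": tau_b,
                "delta_t": tau_a + tau_b,
                "root_censored": anc == tree.root,
            }
        )
    return pd.DataFrame(rows, columns=["leaf_i", "leaf_j", "tau_i", "tau_j",
                                       "delta_t", "root_censored"])


def basal_area_increment(rings: pd.DataFrame, per_direction: bool = True) -> pd.DataFrame:
    """Basal area increments from annual ring widths.

    ``rings`` has columns ``year``, ``width_mm`` and optionally ``direction``
    (N/E/S/W).  Widths accumulate from the pith outward into a radius series
    r_t (cm) and bai_t = pi * (r_t^2 - r_{t-1}^2) (cm^2).  With
    ``per_direction`` (default) each cardinal series is transformed separately,
    matching the convention of averaging the four per-series increments;
    otherwise the four widths are averaged into one radius series first.
    """
    df = rings.copy()
    if "direction" not in df.columns:
        df["direction"] = "ALL"
    if (df["width_mm"] < 0).any():
        raise ValueError("ring widths must be non-negative")
    out = []
    for direction, grp in df.groupby("direction"):
        grp = grp.sort_values("year")
        years = grp["year"].to_numpy()
        if len(years) > 1 and not np.all(np.diff(years) == 1):
            raise ValueError(f"ring years not contiguous for direction {direction!r}")
        radius_cm = np.cumsum(grp["width_mm"].to_numpy()) / 10.0
        prev = np.concatenate([[0.0], radius_cm[:-1]])
        bai = math.pi * (radius_cm**2 - prev**2)
        out.append(
            pd.DataFrame(
                {"direction": direction, "year": years,
                 "radius_cm": radius_cm, "bai_cm2": bai}
            )
        )
    result = pd.concat(out, ignore_index=True)
    if not per_direction and result["direction"].nunique() > 1:
        mean_radius = result.groupby("year")["radius_cm"].mean()
        prev = mean_radius.shift(1, fill_value=0.0)
        bai = math.pi * (mean_radius**2 - prev**2)
        result = pd.DataFrame(
            {"direction": "MEAN", "year": mean_radius.index,
             "radius_cm": mean_radius.to_numpy(), "bai_cm2": bai.to_numpy()}
        )
    return result


def stem_growth_rate(growth: pd.DataFrame) -> float:
    """Mean annual basal area increment (cm^2/yr) over all series of a disk."""
    return float(growth.groupby("direction")["bai_cm2"].mean().mean())


def growth_cellcount_correlation(
    cumulative_bai: np.ndarray, cumulative_cells: np.ndarray
) -> float:
    """Pearson correlation between cumulative growth and cumulative cell count."""
    bai = np.asarray(cumulative_bai, dtype=float)
    cells = np.asarray(cumulative_cells, dtype=float)
    if bai.shape != cells.shape:
        raise ValueError("series lengths differ")
    return float(stats.pearsonr(bai, cells).statistic)
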