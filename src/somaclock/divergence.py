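"""Pairwise methylation divergence, effect sizes and divergence clustering.

The genome-wide divergence between two samples is the mean per-site absolute
difference of their methylation states, D = (1/n) * sum_i |M(A,i) - M(B,i)|,
computed over sites where both samples are called confidently.  States are
encoded u=0, i=0.5, m=1 by default; a binary mode instead counts any state
difference as 1 (differentially methylated positions as a divergence proxy).
Group contrasts are summarised by Cohen's d with the pooled standard
deviation, and the treatment effect on stem divergence is expressed as a
fold change after subtracting the same-side replicate baseline.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

__all__ = [
    "LEVEL_ENCODING",
    "DivergencePair",
    "EffectSize",
    "FoldChange",
    "pairwise_divergence",
    "divergence_from_states",
    "divergence_table",
    "cohens_d",
    "normalized_fold_change",
    "ClusterResult",
    "cluster_samples",
    "robinson_foulds",
    "compare_divergence_groups",
]

LEVEL_ENCODING = {"u": 0.0, "i": 0.5, "m": 1.0}


@dataclass
class DivergencePair:
    sample_i: str
    sample_j: str
    D: float
    n: int
    context: str | None = None
    delta_t: float | None = None


@dataclass
class EffectSize:
    mean_1: float
    mean_2: float
    n_1: int
    n_2: int
    sd_1: float
    sd_2: float
    pooled_sd: float
    d: float
    band: str
    infinite: bool = False


@dataclass
class FoldChange:
    value: float
    defined: bool


def pairwise_divergence(
    calls_a: pd.DataFrame,
    calls_b: pd.DataFrame,
    min_posterior: float = 0.99,
    encoding: str = "level",
    sample_i: str = "A",
    sample_j: str = "B",
) -> DivergencePair:
    """Genome-wide divergence between two samples from their state calls.

    Only sites with posteriorMax >= ``min_posterior`` in *both* samples enter
    the denominator (pairwise-complete universe).  ``encoding='level'`` uses
    u=0, i=0.5, m=1; ``encoding='binary'`` scores any state difference as 1.
    """
    if len(calls_a) != len(calls_b):
        raise ValueError("samples are called on different unit universes")
    passing = (
        (calls_a["posterior_max"].to_numpy() >= min_posterior)
        & (calls_b["posterior_max"].to_numpy() >= min_posterior)
    )
    n = int(passing.sum())
    if n == 0:
        raise ValueError("no sites pass the posterior filter in both samples")
    sa = calls_a["state"].to_numpy()[passing]
    sb = calls_b["state"].to_numpy()[passing]
    if encoding == "level":
        enc = np.vectorize(LEVEL_ENCODING.get)
        d = float(np.abs(enc(sa) - enc(sb)).mean())
    elif encoding == "binary":
        d = float((sa != sb).mean())
    else:
        raise ValueError(f"unknown encoding {encoding!r}")
    context = None
    if "context" in calls_a.columns and calls_a["context"].nunique() == 1:
        context = calls_a["context"].iloc[0]
    return DivergencePair(sample_i, sample_j, d, n, context=context)


def divergence_from_states(
    states_a: np.ndarray, states_b: np.ndarray, encoding: str = "level"
) -> float:
    """Divergence between two true-state vectors on the 0/1/2 (u/i/m) coding."""
    a = np.asarray(states_a, dtype=float)
    b = np.asarray(states_b, dtype=float)
    if encoding == "level":
        return float(np.abs(a - b).mean() / 2.0)
    if encoding == "binary":
        return float((a != b).mean())
    raise ValueError(f"unknown encoding {encoding!r}")


def divergence_table(
    calls_by_sample: dict[str, pd.DataFrame],
    min_posterior: float = 0.99,
    encoding: str = "level",
) -> pd.DataFrame:
    """All unordered pairwise divergences among a set of called samples."""
    rows = []
    for a, b in itertools.combinations(sorted(calls_by_sample), 2):
        pair = pairwise_divergence(
            calls_by_sample[a], calls_by_sample[b],
            min_posterior=min_posterior, encoding=encoding,
            sample_i=a, sample_j=b,
        )
        rows.append({"sample_i": a, "sample_j": b, "context": pair.context,
                     "D": pair.D, "n": pair.n})
    return pd.DataFrame(rows)


_BANDS = ((0.8, "large"), (0.5, "medium"), (0.2, "small"))


def cohens_d(group_1, group_2) -> EffectSize:
    """Cohen's d with the pooled standard deviation.

    d = (mean_1 - mean_2) / s,  s^2 = [(n1-1)s1^2 + (n2-1)s2^2] / (n1+n2-2).
    Bands: |d| > 0.8 large, > 0.5 medium, > 0.2 small.  A zero pooled SD with
    unequal means yields an infinite-effect flag.
    """
    g1 = np.asarray(group_1, dtype=float)
    g2 = np.asarray(group_2, dtype=float)
    n1, n2 = len(g1), len(g2)
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs at least two observations")
    s1, s2 = g1.std(ddof=1), g2.std(ddof=1)
    pooled = np.sqrt(((n1 - 1) * s1**2 + (n2 - 1) * s2**2) / (n1 + n2 - 2))
    diff = g1.mean() - g2.mean()
    if pooled == 0:
        d = 0.0 if diff == 0 else np.inf * np.sign(diff)
        infinite = diff != 0
    else:
        d, infinite = diff / pooled, False
    band = "negligible"
    for cut, name in _BANDS:
        if abs(d) > cut:
            band = name
            break
    return EffectSize(float(g1.mean()), float(g2.mean()), n1, n2,
                      float(s1), float(s2), float(pooled), float(d), band, infinite)


def normalized_fold_change(
    mean_rr: float, mean_moderate: float, mean_heavy: float
) -> FoldChange:
    """Treatment fold change after subtracting the replicate baseline.

    The same-side replicate divergence measures variation not attributable to
    lineage depth; subtracting it from each opposite-side mean isolates the
    divergence accrued across the stem, and the ratio
    (heavy - RR) / (moderate - RR) compares treatments on that scale.
    Undefined (flagged) when the moderate mean does not exceed the baseline.
    """
    denom = mean_moderate - mean_rr
    if denom <= 0:
        return FoldChange(np.nan, defined=False)
    return FoldChange((mean_heavy - mean_rr) / denom, defined=True)


@dataclass
class ClusterResult:
    linkage: np.ndarray
    labels: list[str]
    leaf_order: list[str]
    newick: str


def cluster_samples(distance: pd.DataFrame) -> ClusterResult:
    """Average-linkage (UPGMA) hierarchical clustering of a divergence matrix.

    The matrix must be symmetric with a zero diagonal; rows/columns are
    sample labels.  The dendrogram is also exported as Newick so it can be
    compared against a reference pedigree by Robinson-Foulds distance.
    """
    mat = distance.to_numpy(dtype=float)
    if mat.shape[0] != mat.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(mat, mat.T, atol=1e-12):
        raise ValueError("distance matrix must be symmetric")
    if not np.allclose(np.diag(mat), 0.0):
        raise ValueError("distance matrix must have a zero diagonal")
    labels = [str(c) for c in distance.columns]
    order = np.argsort(labels, kind="stable")  # label-canonical input order
    mat = mat[np.ix_(order, order)]
    labels = [labels[i] for i in order]
    if len(labels) < 2:
        raise ValueError("need at least two samples")
    Z = hierarchy.average(squareform(mat, checks=False))
    leaf_order = [labels[i] for i in hierarchy.leaves_list(Z)]
    tree = hierarchy.to_tree(Z)

    def to_newick(node, parent_height: float) -> str:
        length = max(parent_height - node.dist, 0.0)
        if node.is_leaf():
            return f"{labels[node.id]}:{length:g}"
        inner = ",".join(to_newick(c, node.dist) for c in (node.left, node.right))
        return f"({inner}):{length:g}"

    newick = to_newick(tree, tree.dist) + ";"
    return ClusterResult(Z, labels, leaf_order, newick)


def robinson_foulds(newick_a: str, newick_b: str) -> int:
    """Unrooted Robinson-Foulds (symmetric difference) distance between two
    trees given as Newick strings over the same leaf set."""
    import dendropy

    tns = dendropy.TaxonNamespace()
    t1 = dendropy.Tree.get(data=newick_a, schema="newick", taxon_namespace=tns)
    t2 = dendropy.Tree.get(data=newick_b, schema="newick", taxon_namespace=tns)
    t1.encode_bipartitions()
    t2.encode_bipartitions()
    return int(dendropy.calculate.treecompare.symmetric_difference(t1, t2))


def label_pair_groups(design: pd.DataFrame, pairs: pd.DataFrame) -> pd.DataFrame:
    """Attach a comparison group to each divergence pair using the stem
    sampling design (columns sample/tree/treatment/role).

    Same-tree R1-R2 pairs are the replicate baseline ('RR'); same-tree
    replicate-vs-opposite pairs are '<treatment>_opposite'; anything else
    (cross-tree) is left unlabelled and dropped.
    """
    meta = design.set_index("sample")
    rows = []
    for row in pairs.itertuples():
        a, b = row.sample_i, row.sample_j
        if a not in meta.index or b not in meta.index:
            continue
        if meta.loc[a, "tree"] != meta.loc[b, "tree"]:
            continue
        roles = {meta.loc[a, "role"], meta.loc[b, "role"]}
        if roles == {"R1", "R2"}:
            group = "RR"
        elif "S" in roles and roles & {"R1", "R2"}:
            group = f"{meta.loc[a, 'treatment']}_opposite"
        else:
            continue
        rows.append({"sample_i": a, "sample_j": b, "group": group, "D": row.D})
    return pd.DataFrame(rows)


def compare_divergence_groups(
    design: pd.DataFrame, pairs: pd.DataFrame
) -> pd.DataFrame:
    """One-sided Wilcoxon rank-sum comparisons between divergence groups.

    For each ordered contrast (heavy_opposite > moderate_opposite, each
    opposite group > RR) reports the rank-sum statistic W, the one-sided
    p-value (alternative: first group greater) and Cohen's d.
    """
    labelled = label_pair_groups(design, pairs)
    groups = {g: sub["D"].to_numpy() for g, sub in labelled.groupby("group")}
    contrasts = [
        ("heavy_opposite", "moderate_opposite"),
        ("heavy_opposite", "RR"),
        ("moderate_opposite", "RR"),
    ]
    rows = []
    for g1, g2 in contrasts:
        if g1 not in groups or g2 not in groups:
            continue
        x, y = groups[g1], groups[g2]
        if len(x) < 2 or len(y) < 2:
            raise ValueError(f"group {g1 if len(x) < 2 else g2} has < 2 observations")
        res = stats.mannwhitneyu(x, y, alternative="greater", method="exact")
        eff = cohens_d(x, y)
        rows.append(
            {"group_1": g1, "group_2": g2, "n_1": len(x), "n_2": len(y),
             "W": float(res.statistic), "p_value": float(res.pvalue),
             "cohens_d": eff.d, "band": eff.band}
        )
    return pd.DataFrame(rows)
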