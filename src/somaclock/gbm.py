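"""Gene-body-methylation (gbM) classification.

gbM genes are an evolutionarily conserved class with high exonic CG
methylation and essentially no CHG/CHH methylation; their CG sites are
maintained exclusively by the replication-coupled maintenance pathway,
which makes them the cleanest substrate for division-coupled epimutation
analysis.  A gene is called gbM when the proportion of methylated exonic
CG positions is significantly above the exonic background (one-sided
binomial test, BH-adjusted across genes) while its exonic CHG and CHH
proportions are not significantly different from theirs (two-sided,
unadjusted: adjusting a test whose desired outcome is non-significance
would be anti-conservative).  Per-sample calls are unioned into a liberal
candidate set, which is then filtered on intronic non-CG methylation:
only candidates strictly below the median of the candidate distribution
are retained.

Tests operate on counts of methylated cytosine *positions* (site status
calls), not methylated reads; this is recorded in the output.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_formats import GeneModel

__all__ = [
    "site_status",
    "exonic_background",
    "classify_gbm",
    "union_and_intron_filter",
]

CONTEXTS = ("CG", "CHG", "CHH")


def site_status(methylome: pd.DataFrame, min_total: int = 1) -> pd.DataFrame:
    """Binary methylated/unmethylated status per covered cytosine position.

    A position counts as methylated when at least half its reads are
    methylated; positions with fewer than ``min_total`` reads are dropped.
    """
    df = methylome[methylome["count_total"] >= min_total].copy()
    df["methylated"] = df["count_methylated"] * 2 >= df["count_total"]
    return df


def _sites_in(df: pd.DataFrame, chrom: str, intervals: list[tuple[int, int]]) -> pd.DataFrame:
    sub = df[df["chrom"] == chrom]
    if sub.empty or not intervals:
        return sub.iloc[0:0]
    pos = sub["pos"].to_numpy()
    mask = np.zeros(len(sub), dtype=bool)
    for start, end in intervals:
        mask |= (pos >= start) & (pos <= end)
    return sub[mask]


def exonic_background(
    status: pd.DataFrame, genes: list[GeneModel]
) -> dict[str, tuple[int, int, float]]:
    """Per-context methylated fraction over all exonic cytosines genome-wide.

    Returns {context: (methylated_positions, total_positions, proportion)}.
    """
    counts = {ctx: [0, 0] for ctx in CONTEXTS}
    for gene in genes:
        sub = _sites_in(status, gene.chrom, gene.exons)
        for ctx in CONTEXTS:
            ctx_sub = sub[sub["context"] == ctx]
            counts[ctx][0] += int(ctx_sub["methylated"].sum())
            counts[ctx][1] += len(ctx_sub)
    if all(total == 0 for _, total in counts.values()):
        raise ValueError("no exonic cytosines intersect the annotation")
    return {
        ctx: (meth, total, meth / total if total else np.nan)
        for ctx, (meth, total) in counts.items()
    }


def classify_gbm(
    status: pd.DataFrame,
    genes: list[GeneModel],
    background: dict[str, tuple[int, int, float]] | None = None,
    alpha_up: float = 0.05,
    alpha_diff: float = 0.05,
) -> pd.DataFrame:
    """Per-gene gbM calls for one sample.

    CG: one-sided binomial test (greater) of exonic methylated positions
    against the background proportion, BH-FDR adjusted across genes at
    ``alpha_up``.  CHG/CHH: two-sided binomial tests at ``alpha_diff``
    (unadjusted); a context with zero exonic cytosines is skipped and the
    corresponding p-value left missing (it cannot veto the call).
    """
    if background is None:
        background = exonic_background(status, genes)
    rows = []
    for gene in genes:
        sub = _sites_in(status, gene.chrom, gene.exons)
        rec: dict = {"gene_id": gene.gene_id}
        for ctx in CONTEXTS:
            ctx_sub = sub[sub["context"] == ctx]
            k, n = int(ctx_sub["methylated"].sum()), len(ctx_sub)
            rec[f"{ctx}_methylated"], rec[f"{ctx}_total"] = k, n
            p_bg = background[ctx][2]
            if n == 0 or not np.isfinite(p_bg):
                rec[f"p_{ctx}"] = np.nan
                continue
            alternative = "greater" if ctx == "CG" else "two-sided"
            rec[f"p_{ctx}"] = stats.binomtest(
                k, n, np.clip(p_bg, 1e-12, 1 - 1e-12), alternative=alternative
            ).pvalue
        rows.append(rec)
    calls = pd.DataFrame(rows)
    have_cg = calls["p_CG"].notna()
    q = np.full(len(calls), np.nan)
    if have_cg.any():
        q[have_cg.to_numpy()] = multipletests(
            calls.loc[have_cg, "p_CG"], method="fdr_bh"
        )[1]
    calls["q_CG"] = q
    non_cg_ok = ~(
        (calls["p_CHG"] <= alpha_diff).fillna(False)
        | (calls["p_CHH"] <= alpha_diff).fillna(False)
    )
    calls["gbm"] = (calls["q_CG"] < alpha_up).fillna(False) & non_cg_ok
    calls.attrs["tested_unit"] = "methylated cytosine positions"
    return calls


def _intronic_non_cg_level(
    methylomes: dict[str, pd.DataFrame], gene: GeneModel
) -> tuple[float, int]:
    """Pooled read-level non-CG methylation over the gene's introns,
    aggregated across samples.  Returns (level, n_positions)."""
    meth = total = n_pos = 0
    for methylome in methylomes.values():
        sub = _sites_in(methylome, gene.chrom, gene.introns)
        sub = sub[sub["context"].isin(("CHG", "CHH"))]
        meth += int(sub["count_methylated"].sum())
        total += int(sub["count_total"].sum())
        n_pos = max(n_pos, len(sub))
    return (meth / total if total else np.nan), n_pos


def union_and_intron_filter(
    calls_by_sample: dict[str, pd.DataFrame],
    methylomes: dict[str, pd.DataFrame],
    genes: list[GeneModel],
    min_intronic_sites: int = 5,
) -> pd.DataFrame:
    """Union the per-sample gbM sets and filter on intronic non-CG level.

    The union is the liberal candidate set; per candidate the pooled
    intronic CHG+CHH methylation level is computed and only candidates
    *strictly below* the median of the candidate distribution are retained.
    A candidate without introns (or without intronic non-CG data) is
    retained with a missing-intron flag, and candidates with fewer than
    ``min_intronic_sites`` informative positions are flagged low-information.
    """
    if not calls_by_sample:
        raise ValueError("need at least one sample")
    union: set[str] = set()
    for calls in calls_by_sample.values():
        union |= set(calls.loc[calls["gbm"], "gene_id"])
    by_id = {g.gene_id: g for g in genes}
    rows = []
    for gene_id in sorted(union):
        level, n_pos = _intronic_non_cg_level(methylomes, by_id[gene_id])
        rows.append(
            {"gene_id": gene_id, "intronic_non_cg_level": level,
             "n_intronic_sites": n_pos,
             "missing_introns": not np.isfinite(level),
             "low_information": np.isfinite(level) and n_pos < min_intronic_sites}
        )
    result = pd.DataFrame(
        rows, columns=["gene_id", "intronic_non_cg_level", "n_intronic_sites",
                       "missing_introns", "low_information"]
    )
    if result.empty:
        result["retained"] = pd.Series(dtype=bool)
        return result
    levels = result.loc[~result["missing_introns"], "intronic_non_cg_level"]
    median = float(levels.median()) if len(levels) else np.nan
    result["median_level"] = median
    result["retained"] = result["missing_introns"] | (
        result["intronic_non_cg_level"] < median
    )
    return result
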