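"""Synthetic lineage trees, methylomes and WGBS counts.

The generator produces data with the statistical structure the downstream
analysis assumes: cytosine methylation states evolve independently along a
dated branching topology as a two-state (unmethylated/methylated) Markov
chain with per-year gain rate ``alpha`` and loss rate ``beta``; an optional
epiheterozygote mode evolves two independent alleles so sites can show the
intermediate state; read counts are emitted with negative-binomial coverage
(mean ~20x) and binomial methylated counts.  Rates can alternatively be
specified per cell division together with a divisions-per-year factor
``kappa``, which is how the generator couples epimutation accrual to the
cell-division rate: the effective per-year rate is 1 - (1 - eps)**kappa.

Because the per-year chain is time-homogeneous, a branch of d years is
simulated exactly in one step from the d-step transition probabilities
(no per-year loop): with pi = alpha/(alpha+beta) and gamma = 1-alpha-beta,
P(m at t+d | m) = pi + (1-pi)*gamma**d and P(m at t+d | u) = pi*(1-gamma**d).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import METHYLOME_COLUMNS, GeneModel
from .pedigree_growth import LineageTree

__all__ = [
    "EvolutionParams",
    "make_topology",
    "evolve_methylomes",
    "emit_wgbs_counts",
    "simulate_stem_design",
    "make_annotation",
]

STATE_U, STATE_I, STATE_M = 0, 1, 2  # three-state coding used throughout


@dataclass
class EvolutionParams:
    """Neutral gain/loss process parameters.

    alpha, beta   per-site per-year gain (u->m) and loss (m->u) probabilities
    mode          'two_state' (haploid site states u/m) or 'three_state'
                  (two independent alleles; site state u/i/m by allele count)
    p0            ancestor methylated proportion; None means the equilibrium
                  alpha/(alpha+beta)
    kappa         cell divisions per year; when given, alpha/beta are derived
                  from the per-division rates eps_gain/eps_loss and must not
                  also be supplied directly
    """

    alpha: float | None = None
    beta: float | None = None
    mode: str = "two_state"
    p0: float | None = None
    kappa: float | None = None
    eps_gain: float | None = None
    eps_loss: float | None = None

    def __post_init__(self) -> None:
        if self.kappa is not None:
            if self.alpha is not None or self.beta is not None:
                raise ValueError("give either per-year rates or (kappa, eps_*), not both")
            if self.kappa <= 0 or self.eps_gain is None or self.eps_loss is None:
                raise ValueError("kappa mode needs kappa > 0, eps_gain and eps_loss")
            self.alpha = 1.0 - (1.0 - self.eps_gain) ** self.kappa
            self.beta = 1.0 - (1.0 - self.eps_loss) ** self.kappa
        if self.alpha is None or self.beta is None:
            raise ValueError("alpha and beta are required")
        if not (0.0 <= self.alpha <= 1.0 and 0.0 <= self.beta <= 1.0):
            raise ValueError("rates must lie in [0, 1]")
        if self.mode not in ("two_state", "three_state"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.p0 is None:
            if self.alpha + self.beta == 0:
                raise ValueError("p0 required when alpha = beta = 0")
            self.p0 = self.alpha / (self.alpha + self.beta)
        if not 0.0 <= self.p0 <= 1.0:
            raise ValueError("p0 must lie in [0, 1]")

    @property
    def pi(self) -> float:
        return self.alpha / (self.alpha + self.beta) if self.alpha + self.beta else np.nan

    @property
    def gamma(self) -> float:
        return 1.0 - self.alpha - self.beta


def make_topology(
    n_leaves: int,
    age_years: float,
    branch_times: list[float] | None = None,
    seed: int | None = None,
) -> LineageTree:
    """Random dated binary topology with all tips at ``age_years``.

    ``branch_times`` are years since germination of the n_leaves - 1 branch
    points; if omitted they are drawn uniformly on [0.2*age, 0.95*age].  The
    returned tree is rooted at the earliest branch point (divergence times
    depend only on path lengths, not on where germination sits).
    """
    if n_leaves < 2:
        raise ValueError("need at least two leaves")
    if age_years < 1:
        raise ValueError("tree age must be >= 1 year")
    rng = np.random.default_rng(seed)
    if branch_times is None:
        branch_times = np.sort(rng.uniform(0.2 * age_years, 0.95 * age_years,
                                           size=n_leaves - 1))
    else:
        branch_times = np.sort(np.asarray(branch_times, dtype=float))
        if len(branch_times) != n_leaves - 1:
            raise ValueError("need exactly n_leaves - 1 branch times")
        if branch_times[0] < 0 or branch_times[-1] > age_years:
            raise ValueError("branch times must lie within [0, age_years]")

    edges: list[tuple[str, str, float]] = []
    # active lineages: (pending parent node, time that node was created)
    root = "N1"
    active = [(root, branch_times[0]), (root, branch_times[0])]
    for k, t in enumerate(branch_times[1:], start=2):
        idx = int(rng.integers(len(active)))
        parent, t0 = active.pop(idx)
        name = f"N{k}"
        edges.append((parent, name, t - t0))
        active.append((name, t))
        active.append((name, t))
    order = rng.permutation(len(active))
    for leaf_idx, lineage_idx in enumerate(order, start=1):
        parent, t0 = active[lineage_idx]
        edges.append((parent, f"L{leaf_idx}", age_years - t0))
    return LineageTree.from_edges(edges)


def _step(states: np.ndarray, alpha: float, beta: float, years: float,
          rng: np.random.Generator) -> np.ndarray:
    """Advance haploid 0/1 states by ``years`` using the exact d-step chain."""
    lam = alpha + beta
    if lam == 0 or years == 0:
        return states.copy()
    pi = alpha / lam
    g = (1.0 - lam) ** years
    p_m = np.where(states == 1, pi + (1 - pi) * g, pi * (1 - g))
    return (rng.random(states.shape) < p_m).astype(np.int8)


def evolve_methylomes(
    tree: LineageTree,
    params: EvolutionParams,
    n_sites: int,
    seed: int | None = None,
    return_internal: bool = False,
) -> dict[str, np.ndarray]:
    """Evolve site states along every branch of a dated tree.

    Returns an array per leaf (and per internal node when requested).  In
    ``two_state`` mode values are 0 (u) and 2 (m); in ``three_state`` mode
    two independent alleles are evolved and values are 0/1/2 (u/i/m) by
    methylated-allele count.
    """
    if n_sites < 1:
        raise ValueError("n_sites must be >= 1")
    rng = np.random.default_rng(seed)
    n_alleles = 2 if params.mode == "three_state" else 1
    root_alleles = (rng.random((n_alleles, n_sites)) < params.p0).astype(np.int8)
    alleles: dict[str, np.ndarray] = {tree.root: root_alleles}
    for node in tree.preorder():
        if node == tree.root:
            continue
        parent_states = alleles[tree.parent(node)]
        alleles[node] = np.stack([
            _step(parent_states[a], params.alpha, params.beta,
                  tree.edge_length(node), rng)
            for a in range(n_alleles)
        ])
    leaves = set(tree.leaf_labels())
    out = {}
    for node, arr in alleles.items():
        if node in leaves or return_internal:
            out[node] = arr.sum(axis=0).astype(np.int8) * (2 // n_alleles)
    return out


def emit_wgbs_counts(
    states: np.ndarray,
    depth: float = 20.0,
    err_false_methylated: float = 0.0,
    err_false_unmethylated: float = 0.0,
    dispersion: float = 10.0,
    site_spacing: int = 10,
    chrom: str = "chr1",
    context: str = "CG",
    seed: int | None = None,
) -> pd.DataFrame:
    """Emit a per-cytosine count table from true site states.

    Coverage per site is negative-binomial with the given mean and dispersion
    (size) parameter; the methylated count is binomial with success
    probability err_fm, 0.5 or 1 - err_fu for u/i/m sites respectively.
    """
    if depth <= 0:
        raise ValueError("depth must be positive")
    rng = np.random.default_rng(seed)
    states = np.asarray(states)
    n = len(states)
    totals = rng.negative_binomial(dispersion, dispersion / (dispersion + depth), size=n)
    p = np.select(
        [states == STATE_U, states == STATE_I],
        [err_false_methylated, 0.5],
        default=1.0 - err_false_unmethylated,
    )
    meth = rng.binomial(totals, p)
    return pd.DataFrame(
        {
            "chrom": chrom,
            "pos": np.arange(1, n + 1) * site_spacing,
            "strand": "+",
            "context": context,
            "count_methylated": meth,
            "count_total": totals,
        }
    )[METHYLOME_COLUMNS]


def simulate_stem_design(
    kappa_by_treatment: dict[str, float] | None = None,
    eps_gain: float = 1.2e-6,
    eps_loss: float = 1.6e-6,
    age_years: float = 200.0,
    n_sites: int = 100_000,
    n_trees: dict[str, int] | None = None,
    terminal_fraction: float = 0.02,
    p0: float | None = None,
    depth: float | None = 20.0,
    seed: int | None = None,
) -> tuple[dict[str, np.ndarray | pd.DataFrame], pd.DataFrame]:
    """Cambium sampling design: per stem, two same-side replicates (R1, R2)
    plus one sample from the polar opposite side (S).

    Cambium cells terminate lineages rooted in a few ancestor cells at the
    stem core.  S diverges from the R side at the core; R1 and R2 share all
    but a small terminal fraction of their divisions.  Lineage depth is
    kappa * age divisions, so treatments with faster division rates
    accumulate proportionally more epimutations per year.

    Returns (samples, design): ``samples`` maps sample id to a count table
    (or to the true state vector when ``depth`` is None), ``design`` lists
    tree, treatment and role per sample.
    """
    kappa_by_treatment = kappa_by_treatment or {"moderate": 10.0, "heavy": 18.0}
    n_trees = n_trees or {"moderate": 4, "heavy": 3}
    rng = np.random.default_rng(seed)
    if p0 is None:
        p0 = eps_gain / (eps_gain + eps_loss)
    samples: dict[str, np.ndarray | pd.DataFrame] = {}
    design_rows = []
    tree_no = 0
    for treatment, kappa in kappa_by_treatment.items():
        n_div = int(round(kappa * age_years))
        n_term = max(1, int(round(terminal_fraction * n_div)))
        for _ in range(n_trees.get(treatment, 0)):
            tree_no += 1
            core = (rng.random(n_sites) < p0).astype(np.int8)
            s_state = _step(core, eps_gain, eps_loss, n_div, rng)
            r_shared = _step(core, eps_gain, eps_loss, n_div - n_term, rng)
            r1 = _step(r_shared, eps_gain, eps_loss, n_term, rng)
            r2 = _step(r_shared, eps_gain, eps_loss, n_term, rng)
            for role, state in (("R1", r1), ("R2", r2), ("S", s_state)):
                sample_id = f"tree{tree_no}_{role}"
                truth = state * 2  # u/m coding on the 0/1/2 scale
                if depth is None:
                    samples[sample_id] = truth
                else:
                    samples[sample_id] = emit_wgbs_counts(
                        truth, depth=depth, seed=int(rng.integers(2**31))
                    )
                design_rows.append(
                    {"sample": sample_id, "tree": f"tree{tree_no}",
                     "treatment": treatment, "role": role}
                )
    return samples, pd.DataFrame(design_rows)


_CLASS_LEVELS = {
    # per-context per-site methylation probabilities by gene class
    "gbM": {"CG": 0.92, "CHG": 0.002, "CHH": 0.002},
    "teM": {"CG": 0.85, "CHG": 0.70, "CHH": 0.60},
    "unmethylated": {"CG": 0.05, "CHG": 0.002, "CHH": 0.002},
}


def make_annotation(
    n_genes: int = 60,
    fractions: tuple[float, float, float] = (0.3, 0.1, 0.6),
    n_background_genes: int | None = None,
    n_exons: int = 3,
    exon_len: int = 150,
    intron_len: int = 100,
    depth: float = 20.0,
    seed: int | None = None,
) -> tuple[list[GeneModel], pd.DataFrame, pd.Series]:
    """Gene annotation plus a class-consistent methylome for testing the gbM
    classifier.

    ``fractions`` = (gbM, teM-like, unmethylated) proportions of the
    ``n_genes`` evaluated genes.  In addition, ``n_background_genes``
    (default: equal to ``n_genes``) unmethylated housekeeping-like genes are
    always emitted, labelled ``background``: real exonic backgrounds are
    dominated by the unmethylated majority of the genome, and without them a
    fixture made purely of gbM genes would have no contrast to its own
    background.  Returns (genes, methylome, labels) with true labels indexed
    by gene id.
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("class fractions must sum to 1")
    rng = np.random.default_rng(seed)
    if n_background_genes is None:
        n_background_genes = n_genes
    counts = np.floor(np.asarray(fractions) * n_genes).astype(int)
    while counts.sum() < n_genes:
        counts[int(np.argmax(np.asarray(fractions) * n_genes - counts))] += 1
    classes = (["gbM"] * counts[0] + ["teM"] * counts[1]
               + ["unmethylated"] * counts[2] + ["background"] * n_background_genes)

    genes: list[GeneModel] = []
    labels = {}
    meth_rows = []
    cursor = 1000
    for gi, cls in enumerate(classes, start=1):
        gene_id = f"gene{gi:04d}"
        labels[gene_id] = cls
        levels = _CLASS_LEVELS["unmethylated" if cls == "background" else cls]
        exons = []
        pos = cursor
        for e in range(n_exons):
            exons.append((pos, pos + exon_len - 1))
            pos += exon_len + intron_len
        genes.append(GeneModel(gene_id, "chr1", "+", exons))
        gene_end = exons[-1][1]
        # cytosines on a fixed grid; contexts interleaved
        for p in range(cursor, gene_end + 1, 5):
            context = ("CG", "CHG", "CHH")[(p // 5) % 3]
            state = rng.random() < levels[context]
            total = rng.negative_binomial(10, 10 / (10 + depth))
            meth = rng.binomial(total, 0.99 if state else 0.01)
            meth_rows.append(("chr1", p, "+", context, meth, total))
        cursor = gene_end + 200
    methylome = pd.DataFrame(meth_rows, columns=METHYLOME_COLUMNS)
    return genes, methylome, pd.Series(labels, name="class")
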