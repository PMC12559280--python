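import numpy as np
import pandas as pd
import pytest

from somaclock import divergence as dv
from somaclock import pedigree_growth as pg
from somaclock import simulate


@pytest.fixture
def small_methylome() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": ["chr1"] * 4,
            "pos": [10, 50, 120, 130],
            "strand": ["+", "+", "+", "-"],
            "context": ["CG", "CG", "CG", "CHG"],
            "count_methylated": [5, 0, 18, 2],
            "count_total": [20, 19, 20, 10],
        }
    )


@pytest.fixture
def three_leaf_tree() -> pg.LineageTree:
    # two leaves splitting 50 years before sampling, outgroup at 200
    return pg.LineageTree.from_newick("((A:50,B:50):150,C:200);")


def simulated_pair_table(alpha, beta, seed, n_sites=500_000, n_leaves=10,
                         age=200, branch_times=None):
    """Simulate true-state methylomes on a dated topology and return the
    (pairs-with-D, tree, p0) triple used by the rate-recovery protocols."""
    tree = simulate.make_topology(n_leaves, age, branch_times=branch_times, seed=seed)
    pairs = pg.divergence_times(tree)
    params = simulate.EvolutionParams(alpha=alpha, beta=beta)
    truth = simulate.evolve_methylomes(tree, params, n_sites, seed=seed + 10_000)
    pairs["D"] = [
        dv.divergence_from_states(truth[r.leaf_i], truth[r.leaf_j])
        for r in pairs.itertuples()
    ]
    p0 = float(np.mean([(truth[l] == 2).mean() for l in tree.leaf_labels()]))
    return pairs, tree, p0, truth
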