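import itertools

import numpy as np
import pandas as pd
import pytest

from somaclock import divergence as dv
from somaclock import pedigree_growth as pg
from somaclock import simulate


def _calls(states, posterior=0.999):
    return pd.DataFrame(
        {"chrom": "chr1", "pos": np.arange(1, len(states) + 1) * 10,
         "context": "CG", "state": list(states),
         "posterior_max": posterior}
    )


def test_hand_computed_divergence():
    pair = dv.pairwise_divergence(_calls("mmui"), _calls("muui"))
    assert pair.D == pytest.approx(0.25)  # (0 + 1 + 0 + 0) / 4
    assert pair.n == 4


def test_self_divergence_zero_and_posterior_filter():
    a = _calls("mmui")
    assert dv.pairwise_divergence(a, a).D == 0.0
    b = _calls("uuuu")
    a2 = a.copy()
    a2.loc[0, "posterior_max"] = 0.5  # site excluded from the denominator
    pair = dv.pairwise_divergence(a2, b)
    assert pair.n == 3
    with pytest.raises(ValueError, match="pass the posterior filter"):
        dv.pairwise_divergence(_calls("m", posterior=0.5), _calls("u"))


def test_divergence_matches_brute_force_site_loop():
    rng = np.random.default_rng(0)
    sa = rng.choice(["u", "i", "m"], 300)
    sb = rng.choice(["u", "i", "m"], 300)
    pa, pb = rng.uniform(0.95, 1.0, 300), rng.uniform(0.95, 1.0, 300)
    a, b = _calls(sa), _calls(sb)
    a["posterior_max"], b["posterior_max"] = pa, pb
    enc = {"u": 0.0, "i": 0.5, "m": 1.0}
    keep = (pa >= 0.99) & (pb >= 0.99)
    expected = np.mean([abs(enc[x] - enc[y])
                        for x, y, k in zip(sa, sb, keep) if k])
    assert dv.pairwise_divergence(a, b).D == pytest.approx(expected)
    expected_bin = np.mean([x != y for x, y, k in zip(sa, sb, keep) if k])
    assert dv.pairwise_divergence(a, b, encoding="binary").D == pytest.approx(expected_bin)


def test_divergence_is_a_pseudometric_on_level_encoding():
    rng = np.random.default_rng(1)
    samples = {k: _calls(rng.choice(["u", "i", "m"], 200)) for k in "abcd"}
    D = {}
    for x, y in itertools.combinations(samples, 2):
        d = dv.pairwise_divergence(samples[x], samples[y]).D
        D[(x, y)] = D[(y, x)] = d
    for x in samples:
        D[(x, x)] = 0.0
    for x, y, z in itertools.permutations(samples, 3):
        assert D[(x, y)] <= D[(x, z)] + D[(z, y)] + 1e-12


def test_cohens_d_examples():
    eff = dv.cohens_d([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
    assert eff.d == 0.0 and not eff.infinite
    flagged = dv.cohens_d([2.0, 2.0, 2.0, 2.0], [0.0, 0.0, 0.0, 0.0])
    assert flagged.infinite
    # means 3 vs 1, pooled sd 1 -> d = 2, large band
    g1, g2 = [2.0, 3.0, 4.0], [0.0, 1.0, 2.0]
    eff2 = dv.cohens_d(g1, g2)
    assert eff2.d == pytest.approx(2.0)
    assert eff2.band == "large"
    with pytest.raises(ValueError):
        dv.cohens_d([1.0], [1.0, 2.0])


def test_normalized_fold_change_reference_point():
    fc = dv.normalized_fold_change(0.005221033, 0.005485005, 0.005919238)
    assert fc.defined
    assert round(fc.value, 2) == 2.64


def test_normalized_fold_change_limits_and_flags():
    assert dv.normalized_fold_change(0.1, 0.2, 0.2).value == pytest.approx(1.0)
    assert dv.normalized_fold_change(0.1, 0.2, 0.1).value == pytest.approx(0.0)
    assert not dv.normalized_fold_change(0.2, 0.2, 0.3).defined


def test_normalized_fold_change_affine_invariance():
    rng = np.random.default_rng(2)
    rr, mod, heavy = 0.004, 0.006, 0.009
    base = dv.normalized_fold_change(rr, mod, heavy).value
    for _ in range(5):
        a, b = rng.uniform(0.5, 3.0), rng.uniform(-0.01, 0.01)
        scaled = dv.normalized_fold_change(a * rr + b, a * mod + b, a * heavy + b)
        assert scaled.value == pytest.approx(base)


def test_cluster_requires_valid_distance_matrix():
    bad = pd.DataFrame([[0.0, 1.0], [0.5, 0.0]], index=list("ab"), columns=list("ab"))
    with pytest.raises(ValueError, match="symmetric"):
        dv.cluster_samples(bad)


def test_two_sample_clustering_single_join():
    mat = pd.DataFrame([[0.0, 0.3], [0.3, 0.0]], index=list("ab"), columns=list("ab"))
    res = dv.cluster_samples(mat)
    assert res.linkage.shape == (1, 4)
    assert sorted(res.leaf_order) == ["a", "b"]


def test_clustering_invariant_to_input_order():
    rng = np.random.default_rng(3)
    labels = [f"s{i}" for i in range(6)]
    mat = rng.uniform(0.1, 1.0, (6, 6))
    mat = (mat + mat.T) / 2
    np.fill_diagonal(mat, 0.0)
    df = pd.DataFrame(mat, index=labels, columns=labels)
    perm = rng.permutation(6)
    shuffled = df.iloc[perm, perm]
    assert dv.cluster_samples(df).newick == dv.cluster_samples(shuffled).newick


def test_clean_simulation_recovers_topology():
    tree = simulate.make_topology(6, 200, branch_times=[50, 80, 110, 140, 170],
                                  seed=0)
    params = simulate.EvolutionParams(alpha=1e-4, beta=2e-4)
    truth = simulate.evolve_methylomes(tree, params, 100_000, seed=1)
    leaves = tree.leaf_labels()
    mat = pd.DataFrame(0.0, index=leaves, columns=leaves)
    for a, b in itertools.combinations(leaves, 2):
        d = dv.divergence_from_states(truth[a], truth[b], encoding="binary")
        mat.loc[a, b] = mat.loc[b, a] = d
    res = dv.cluster_samples(mat)
    assert dv.robinson_foulds(res.newick, tree.to_newick()) == 0


def _design_and_pairs(values_by_group):
    design_rows, pair_rows = [], []
    tree_no = 0
    for group, values in values_by_group.items():
        for v in values:
            tree_no += 1
            tree_id = f"t{tree_no}"
            treatment = group.replace("_opposite", "") if group != "RR" else "moderate"
            for role in ("R1", "R2", "S"):
                design_rows.append({"sample": f"{tree_id}_{role}", "tree": tree_id,
                                    "treatment": treatment, "role": role})
            if group == "RR":
                pair_rows.append({"sample_i": f"{tree_id}_R1",
                                  "sample_j": f"{tree_id}_R2", "D": v})
            else:
                pair_rows.append({"sample_i": f"{tree_id}_R1",
                                  "sample_j": f"{tree_id}_S", "D": v})
    return pd.DataFrame(design_rows), pd.DataFrame(pair_rows)


def test_group_comparison_identical_groups():
    design, pairs = _design_and_pairs(
        {"moderate_opposite": [0.1, 0.2, 0.3], "heavy_opposite": [0.1, 0.2, 0.3]}
    )
    report = dv.compare_divergence_groups(design, pairs)
    row = report[(report["group_1"] == "heavy_opposite")
                 & (report["group_2"] == "moderate_opposite")].iloc[0]
    assert row["p_value"] > 0.5
    assert row["cohens_d"] == pytest.approx(0.0)


def test_group_comparison_fully_separated_gives_max_rank_sum():
    design, pairs = _design_and_pairs(
        {"moderate_opposite": [0.1, 0.2, 0.3], "heavy_opposite": [0.4, 0.5, 0.6]}
    )
    report = dv.compare_divergence_groups(design, pairs)
    row = report[(report["group_1"] == "heavy_opposite")
                 & (report["group_2"] == "moderate_opposite")].iloc[0]
    assert row["W"] == 9.0  # every heavy value beats every moderate value
    # exact one-sided p for complete separation at 3 vs 3: 1 / C(6,3)
    assert row["p_value"] == pytest.approx(1 / 20)


def test_simulated_division_rate_ratio_orders_groups():
    samples, design = simulate.simulate_stem_design(
        kappa_by_treatment={"moderate": 8.0, "heavy": 16.0},
        n_sites=60_000, depth=None, seed=4,
    )
    pair_rows = []
    for tree_id, sub in design.groupby("tree"):
        for ri in ("R1", "R2"):
            pair_rows.append({
                "sample_i": f"{tree_id}_{ri}", "sample_j": f"{tree_id}_S",
                "D": dv.divergence_from_states(samples[f"{tree_id}_{ri}"],
                                               samples[f"{tree_id}_S"]),
            })
        pair_rows.append({
            "sample_i": f"{tree_id}_R1", "sample_j": f"{tree_id}_R2",
            "D": dv.divergence_from_states(samples[f"{tree_id}_R1"],
                                           samples[f"{tree_id}_R2"]),
        })
    report = dv.compare_divergence_groups(design, pd.DataFrame(pair_rows))
    hv = report[(report["group_1"] == "heavy_opposite")
                & (report["group_2"] == "moderate_opposite")].iloc[0]
    assert hv["cohens_d"] > 0.8
    assert hv["p_value"] < 0.05
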