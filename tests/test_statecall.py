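import numpy as np
import pandas as pd
import pytest

from somaclock import simulate, statecall


def make_mixture_counts(n_per_state=400, depth=20, p=(0.01, 0.5, 0.95), seed=0):
    """Counts drawn from the three-component generative model itself."""
    rng = np.random.default_rng(seed)
    rows = []
    pos = 0
    for comp in range(3):
        for _ in range(n_per_state):
            pos += 10
            total = depth
            rows.append(("chr1", pos, "CG", comp,
                         rng.binomial(total, p[comp]), total))
    df = pd.DataFrame(rows, columns=["chrom", "pos", "context", "truth",
                                     "count_methylated", "count_total"])
    return df.sample(frac=1.0, random_state=1).reset_index(drop=True)


def exact_posterior(k, n, p=(0.01, 0.5, 0.95)):
    """Independent Bayes oracle under fixed emissions and equal priors."""
    lik = np.array([pc**k * (1 - pc) ** (n - k) for pc in p])
    return lik / lik.sum()


def test_extreme_counts_called_confidently():
    counts = make_mixture_counts()
    res = statecall.call_states(counts)
    assert res.converged
    calls = res.calls.set_index("pos")
    full = counts[counts["count_methylated"] == counts["count_total"]]
    empty = counts[counts["count_methylated"] == 0]
    oracle_m = exact_posterior(20, 20)[2]
    oracle_u = exact_posterior(0, 20)[0]
    assert oracle_m > 0.99 and oracle_u > 0.99  # sanity of the oracle itself
    for pos in full["pos"].head(20):
        row = calls.loc[pos]
        assert row["state"] == "m" and row["posterior_max"] >= 0.99
    for pos in empty["pos"].head(20):
        row = calls.loc[pos]
        assert row["state"] == "u" and row["posterior_max"] >= 0.99


def test_posteriors_sum_to_one():
    res = statecall.call_states(make_mixture_counts(seed=3))
    total = (res.calls[["posterior_u", "posterior_i", "posterior_m"]]
             .sum(axis=1).to_numpy())
    assert np.allclose(total, 1.0, atol=1e-9)
    state_of_max = res.calls[["posterior_u", "posterior_i", "posterior_m"]].idxmax(axis=1)
    assert (res.calls["posterior_max"].to_numpy()
            == res.calls[["posterior_u", "posterior_i", "posterior_m"]].max(axis=1).to_numpy()).all()
    assert (state_of_max.str[-1] == res.calls["state"]).all()


def test_emission_parameters_recovered_near_truth():
    res = statecall.call_states(make_mixture_counts(n_per_state=1500, seed=4))
    p_u, p_i, p_m = res.emission_p
    assert p_u < p_i < p_m
    assert p_u == pytest.approx(0.01, abs=0.01)
    assert p_m == pytest.approx(0.95, abs=0.05)


def test_degenerate_identical_counts_do_not_crash():
    counts = pd.DataFrame(
        {"chrom": "chr1", "pos": np.arange(1, 31) * 10, "context": "CG",
         "count_methylated": 10, "count_total": 10}
    )
    res = statecall.call_states(counts)
    assert res.calls["state"].nunique() == 1


def test_chain_and_independent_modes_agree_on_extreme_units():
    counts = make_mixture_counts(n_per_state=120, seed=5)
    indep = statecall.call_states(counts, mode="independent").calls
    chain = statecall.call_states(counts, mode="chain").calls
    extreme = (
        (counts["count_total"] >= 20)
        & ((counts["count_methylated"] == 0)
           | (counts["count_methylated"] == counts["count_total"]))
    ).to_numpy()
    assert (indep.loc[extreme, "state"].to_numpy()
            == chain.loc[extreme, "state"].to_numpy()).all()


def test_bin_to_windows_grid_and_brute_force():
    calls = pd.DataFrame(
        {"chrom": "chr1", "pos": [10, 50, 120], "context": "CG",
         "state": ["m", "u", "m"]}
    )
    wc = statecall.bin_to_windows(calls)
    assert wc[["start", "end", "count_methylated", "count_total"]].values.tolist() == [
        [1, 100, 1, 2], [101, 200, 1, 1]
    ]
    assert statecall.bin_to_windows(calls.iloc[0:0]).empty

    rng = np.random.default_rng(0)
    pos = np.sort(rng.choice(np.arange(1, 5000), size=300, replace=False))
    states = rng.choice(["u", "i", "m"], size=300)
    calls = pd.DataFrame({"chrom": "chr1", "pos": pos, "context": "CG",
                          "state": states})
    wc = statecall.bin_to_windows(calls).set_index("start")
    for start in wc.index:
        inside = (pos >= start) & (pos <= start + 99)
        weight = pd.Series(states[inside]).map({"u": 0, "i": 0.5, "m": 1}).sum()
        assert wc.loc[start, "count_total"] == inside.sum()
        assert wc.loc[start, "count_methylated"] == int(np.floor(weight + 0.5))


def _calls(states, posteriors, unit="pos"):
    df = pd.DataFrame({"chrom": "chr1", "state": list(states),
                       "posterior_max": posteriors})
    if unit == "pos":
        df["pos"] = np.arange(1, len(df) + 1) * 10
        return df[["chrom", "pos", "state", "posterior_max"]]
    df["start"] = np.arange(0, len(df)) * 100 + 1
    df["end"] = df["start"] + 99
    return df[["chrom", "start", "end", "state", "posterior_max"]]


def test_smp_emitted_only_when_both_confident_and_states_differ():
    a = _calls("mmu", [0.999, 0.95, 0.999])
    b = _calls("uuu", [0.999, 0.999, 0.999])
    smps = statecall.call_smps(a, b)
    assert len(smps) == 1 and smps.iloc[0]["pos"] == 10
    assert smps.attrs["n_passing"] == 2  # the 0.95 site is excluded entirely


def test_disjoint_site_universes_error():
    a = _calls("mu", [0.999, 0.999])
    b = _calls("mu", [0.999, 0.999])
    b["pos"] += 5
    with pytest.raises(ValueError, match="unit universes"):
        statecall.call_smps(a, b)


def test_smps_match_brute_force_on_random_fixture():
    rng = np.random.default_rng(2)
    n = 500
    sa = rng.choice(["u", "i", "m"], size=n)
    sb = rng.choice(["u", "i", "m"], size=n)
    pa = rng.uniform(0.9, 1.0, size=n)
    pb = rng.uniform(0.9, 1.0, size=n)
    a, b = _calls(sa, pa), _calls(sb, pb)
    smps = statecall.call_smps(a, b, min_posterior=0.99)
    expected = {
        int(a["pos"][i])
        for i in range(n)
        if pa[i] >= 0.99 and pb[i] >= 0.99 and sa[i] != sb[i]
    }
    assert set(smps["pos"]) == expected


def test_raising_min_posterior_is_monotone():
    rng = np.random.default_rng(3)
    n = 400
    a = _calls(rng.choice(["u", "m"], n), rng.uniform(0.9, 1.0, n))
    b = _calls(rng.choice(["u", "m"], n), rng.uniform(0.9, 1.0, n))
    counts = [len(statecall.call_smps(a, b, min_posterior=q))
              for q in (0.9, 0.95, 0.99, 0.999)]
    assert counts == sorted(counts, reverse=True)


def test_dmrs_are_window_state_switches():
    a = _calls("ui", [0.999, 0.999], unit="window")
    b = _calls("mi", [0.999, 0.999], unit="window")
    dmrs = statecall.call_dmrs(a, b)
    assert len(dmrs) == 1
    assert dmrs.iloc[0][["state_a", "state_b"]].tolist() == ["u", "m"]


def test_dmr_recovery_of_shifted_blocks():
    """Windows whose true state differs between samples are recovered from
    window counts under the generative emission model."""
    rng = np.random.default_rng(4)
    n_win = 300
    truth_a = rng.choice(["u", "m"], size=n_win, p=[0.6, 0.4])
    truth_b = truth_a.copy()
    flip = rng.choice(n_win, size=30, replace=False)
    truth_b[flip] = np.where(truth_b[flip] == "u", "m", "u")
    p_state = {"u": 0.01, "m": 0.95}

    def windows(truth, seed):
        r = np.random.default_rng(seed)
        total = r.poisson(12, size=n_win) + 4
        meth = r.binomial(total, [p_state[s] for s in truth])
        return pd.DataFrame(
            {"chrom": "chr1", "start": np.arange(n_win) * 100 + 1,
             "end": np.arange(n_win) * 100 + 100, "context": "CG",
             "count_methylated": meth, "count_total": total}
        )

    calls_a = statecall.call_states(windows(truth_a, 10)).calls
    calls_b = statecall.call_states(windows(truth_b, 11)).calls
    dmrs = statecall.call_dmrs(calls_a, calls_b, min_posterior=0.99)
    recovered = set(dmrs["start"])
    true_starts = set(np.asarray(flip) * 100 + 1)
    assert len(recovered & true_starts) / len(true_starts) >= 0.9
    assert len(recovered - true_starts) <= 0.01 * n_win


def test_state_calls_match_simulated_truth_at_depth():
    tree = simulate.make_topology(2, 60, branch_times=[30], seed=0)
    params = simulate.EvolutionParams(alpha=0.004, beta=0.005, mode="three_state")
    truth = simulate.evolve_methylomes(tree, params, 20_000, seed=1)["L1"]
    counts = simulate.emit_wgbs_counts(truth, depth=50, seed=2)
    calls = statecall.call_states(counts).calls
    truth_labels = pd.Series(truth).map({0: "u", 1: "i", 2: "m"}).to_numpy()
    assert (calls["state"].to_numpy() == truth_labels).mean() >= 0.999
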