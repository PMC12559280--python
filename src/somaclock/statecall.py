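"""Methylation state calling from count data.

Each unit (a cytosine site or a 100-bp window) carries a methylated count k
out of n observations.  Units are classified as unmethylated (u),
intermediate (i) or methylated (m) under a three-component model with
binomial emission densities at success probabilities p_u < p_i < p_m,
estimated by expectation-maximization.  The intermediate component captures
somatic epiheterozygotes, which surface in bulk bisulfite data as ~50%
methylation.  Two modes are provided: ``independent`` treats units as a
mixture; ``chain`` couples consecutive units along genome order through a
first-order transition matrix (posteriors by forward-backward).

State switches between two samples at the same units define SMPs (single
sites) and DMRs (100-bp windows).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp

__all__ = [
    "STATES",
    "CallResult",
    "bin_to_windows",
    "call_states",
    "call_smps",
    "call_dmrs",
]

STATES = np.array(["u", "i", "m"])

# emission parameter box keeping the three components identifiable
P_U_BOUNDS = (0.001, 0.15)
P_M_BOUNDS = (0.6, 0.999)
DEFAULT_INIT = (0.01, 0.5, 0.95)


@dataclass
class CallResult:
    """State calls plus fitted model and convergence diagnostics."""

    calls: pd.DataFrame  # state, posterior_u/i/m, posterior_max per unit
    emission_p: tuple[float, float, float]
    weights: np.ndarray
    transition: np.ndarray | None
    converged: bool
    n_iterations: int
    log_likelihood: float
    mode: str
    notes: list[str] = field(default_factory=list)


def bin_to_windows(site_calls: pd.DataFrame, window_size: int = 100) -> pd.DataFrame:
    """Aggregate per-site state calls into fixed windows on a 1-based grid.

    ``site_calls`` needs chrom, pos, context and state columns.  Within each
    window the methylated-cytosine count is #m plus 0.5 per intermediate
    site, rounded half-up; the total is the number of called cytosines.
    Windows containing no cytosine of a context are simply absent.
    """
    if site_calls.empty:
        return pd.DataFrame(
            columns=["chrom", "start", "end", "context", "count_methylated", "count_total"]
        )
    df = site_calls.copy()
    df["start"] = ((df["pos"] - 1) // window_size) * window_size + 1
    meth_weight = df["state"].map({"u": 0.0, "i": 0.5, "m": 1.0})
    grouped = (
        df.assign(_mw=meth_weight)
        .groupby(["chrom", "start", "context"], as_index=False)
        .agg(count_methylated=("_mw", "sum"), count_total=("state", "size"))
    )
    grouped["end"] = grouped["start"] + window_size - 1
    grouped["count_methylated"] = np.floor(grouped["count_methylated"] + 0.5).astype(int)
    return grouped[
        ["chrom", "start", "end", "context", "count_methylated", "count_total"]
    ].sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)


def _log_emissions(k: np.ndarray, n: np.ndarray, p: np.ndarray) -> np.ndarray:
    """Per-unit per-component binomial log densities (combinatorial term
    dropped: it is constant across components)."""
    p = np.clip(p, 1e-12, 1 - 1e-12)
    return (k[:, None] * np.log(p[None, :])
            + (n - k)[:, None] * np.log1p(-p[None, :]))


def _m_step_p(resp: np.ndarray, k: np.ndarray, n: np.ndarray) -> np.ndarray:
    num = resp.T @ k
    den = resp.T @ n
    with np.errstate(invalid="ignore"):
        p = np.where(den > 0, num / np.maximum(den, 1e-300), DEFAULT_INIT)
    p_u = float(np.clip(p[0], *P_U_BOUNDS))
    p_m = float(np.clip(p[2], *P_M_BOUNDS))
    # p_i pinned midway between the outer components for identifiability
    return np.array([p_u, (p_u + p_m) / 2.0, p_m])


def call_states(
    counts: pd.DataFrame,
    mode: str = "independent",
    init: tuple[float, float, float] = DEFAULT_INIT,
    max_iter: int = 200,
    tol: float = 1e-6,
) -> CallResult:
    """Call u/i/m states for every unit of a count table.

    ``counts`` needs count_methylated and count_total columns (plus genome
    order already established by row order for ``chain`` mode).  Emission
    probabilities are estimated by EM from the data, starting at
    (0.01, 0.5, 0.95) and constrained to p_u < p_i < p_m.  Posterior vectors
    sum to one; the state is the posterior argmax with ties broken toward i.
    """
    if mode not in ("independent", "chain"):
        raise ValueError(f"unknown mode {mode!r}")
    k = counts["count_methylated"].to_numpy(dtype=float)
    n = counts["count_total"].to_numpy(dtype=float)
    if np.any(k > n) or np.any(k < 0):
        raise ValueError("invalid counts: need 0 <= count_methylated <= count_total")
    if len(k) < 10:
        raise ValueError("need at least 10 units to estimate emission parameters")
    notes: list[str] = []
    p = np.asarray(init, dtype=float)
    if mode == "independent":
        p, weights, post, loglik, n_it, converged = _em_mixture(k, n, p, max_iter, tol)
        transition = None
    else:
        p, weights, transition, post, loglik, n_it, converged = _baum_welch(
            k, n, p, max_iter, tol
        )
    if not converged:
        notes.append(f"EM did not converge within {max_iter} iterations")

    state_idx = post.argmax(axis=1)
    # ties toward the intermediate component (conservative)
    tie_with_i = np.isclose(post.max(axis=1), post[:, 1], rtol=0, atol=1e-12)
    state_idx = np.where(tie_with_i, 1, state_idx)
    calls = counts.copy()
    calls["posterior_u"] = post[:, 0]
    calls["posterior_i"] = post[:, 1]
    calls["posterior_m"] = post[:, 2]
    calls["state"] = STATES[state_idx]
    calls["posterior_max"] = post[np.arange(len(post)), state_idx]
    return CallResult(
        calls=calls, emission_p=tuple(p), weights=weights, transition=transition,
        converged=converged, n_iterations=n_it, log_likelihood=loglik, mode=mode,
        notes=notes,
    )


def _em_mixture(k, n, p, max_iter, tol):
    weights = np.full(3, 1 / 3)
    prev_ll = -np.inf
    converged = False
    post = np.full((len(k), 3), 1 / 3)
    for it in range(1, max_iter + 1):
        log_em = _log_emissions(k, n, p) + np.log(weights)[None, :]
        norm = logsumexp(log_em, axis=1)
        post = np.exp(log_em - norm[:, None])
        loglik = float(norm.sum())
        p = _m_step_p(post, k, n)
        weights = np.clip(post.mean(axis=0), 1e-12, None)
        weights = weights / weights.sum()
        if abs(loglik - prev_ll) < tol:
            converged = True
            break
        prev_ll = loglik
    return p, weights, post, loglik, it, converged


def _baum_welch(k, n, p, max_iter, tol):
    T = len(k)
    A = np.full((3, 3), 0.1) + np.eye(3) * 0.7  # sticky start
    start = np.full(3, 1 / 3)
    prev_ll = -np.inf
    converged = False
    for it in range(1, max_iter + 1):
        log_b = _log_emissions(k, n, p)
        b = np.exp(log_b - log_b.max(axis=1, keepdims=True))
        # scaled forward-backward
        alpha = np.empty((T, 3))
        scale = np.empty(T)
        alpha[0] = start * b[0]
        scale[0] = alpha[0].sum()
        alpha[0] /= scale[0]
        for t in range(1, T):
            alpha[t] = (alpha[t - 1] @ A) * b[t]
            scale[t] = alpha[t].sum()
            alpha[t] /= scale[t]
        beta_v = np.empty((T, 3))
        beta_v[-1] = 1.0
        for t in range(T - 2, -1, -1):
            beta_v[t] = (A @ (b[t + 1] * beta_v[t + 1])) / scale[t + 1]
        post = alpha * beta_v
        post /= post.sum(axis=1, keepdims=True)
        loglik = float(np.log(scale).sum() + log_b.max(axis=1).sum())
        # transition expected counts
        xi = np.zeros((3, 3))
        for t in range(T - 1):
            num = (alpha[t][:, None] * A) * (b[t + 1] * beta_v[t + 1])[None, :]
            xi += num / max(num.sum(), 1e-300)
        A = xi / np.maximum(xi.sum(axis=1, keepdims=True), 1e-300)
        start = post[0]
        p = _m_step_p(post, k, n)
        if abs(loglik - prev_ll) < tol:
            converged = True
            break
        prev_ll = loglik
    return p, post.mean(axis=0), A, post, loglik, it, converged


def _switches(
    calls_a: pd.DataFrame,
    calls_b: pd.DataFrame,
    unit_cols: list[str],
    min_posterior: float,
) -> pd.DataFrame:
    for col in unit_cols:
        if not calls_a[col].reset_index(drop=True).equals(
            calls_b[col].reset_index(drop=True)
        ):
            raise ValueError(
                "samples are called on different unit universes "
                f"(column {col!r} differs); align them first"
            )
    a = calls_a.reset_index(drop=True)
    b = calls_b.reset_index(drop=True)
    passing = (a["posterior_max"] >= min_posterior) & (b["posterior_max"] >= min_posterior)
    differ = passing & (a["state"].to_numpy() != b["state"].to_numpy())
    out = a.loc[differ, unit_cols].copy()
    out["state_a"] = a.loc[differ, "state"].to_numpy()
    out["state_b"] = b.loc[differ, "state"].to_numpy()
    out = out.reset_index(drop=True)
    out.attrs["n_passing"] = int(passing.sum())
    return out


def call_smps(
    calls_a: pd.DataFrame, calls_b: pd.DataFrame, min_posterior: float = 0.99
) -> pd.DataFrame:
    """Single methylation polymorphisms: sites where both samples are called
    confidently (posteriorMax >= threshold) and the states differ.  Sites
    failing the filter in either sample are excluded from the denominator
    (``.attrs['n_passing']``)."""
    return _switches(calls_a, calls_b, ["chrom", "pos"], min_posterior)


def call_dmrs(
    calls_a: pd.DataFrame, calls_b: pd.DataFrame, min_posterior: float = 0.99
) -> pd.DataFrame:
    """Differentially methylated regions: confident state switches between
    samples within fixed windows."""
    return _switches(calls_a, calls_b, ["chrom", "start", "end"], min_posterior)
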