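"""Neutral epimutation gain/loss rate estimation from divergence-time data.

Methylation divergence between two lineages accrues under a two-state
Markov chain in which an unmethylated site gains methylation at rate
``alpha`` per year and a methylated site loses it at rate ``beta``.
Writing pi = alpha/(alpha+beta) (the steady-state methylated fraction) and
gamma = 1 - alpha - beta (the per-year retention factor), the probability a
site is methylated tau years after its ancestor is

    a(tau) = pi + (1 - pi) * gamma**tau     (ancestor methylated)
    b(tau) = pi * (1 - gamma**tau)          (ancestor unmethylated)

and the expected divergence of two tips tau_i and tau_j years past their
common ancestor, whose sites were methylated with probability p0, is

    D = c + p0 * [a_i(1-a_j) + a_j(1-a_i)] + (1-p0) * [b_i(1-b_j) + b_j(1-b_i)]

with ``c`` absorbing divergence that predates the earliest datable branch
point.  At p0 = pi this collapses to c + 2*pi*(1-pi)*(1 - gamma**(tau_i+tau_j)).
Rates are estimated by bounded nonlinear least squares of observed pair
divergences against this curve; p0 is fixed to the observed mean methylated
fraction rather than fitted (with genome-wide mean divergences per pair the
four-parameter problem is weakly identified).

Near equilibrium the curve constrains alpha and beta essentially only
through their sum: the (alpha - beta) direction is a flat ridge with
second-order curvature far below sampling noise at realistic rates.  The
fit therefore also solves the equilibrium-constrained problem (steady
state pinned to the observed level, alpha = p0 * lambda,
beta = (1 - p0) * lambda with lambda = alpha + beta free) and adopts that
solution unless the unconstrained model fits significantly better by an
F-test — i.e. the gain/loss split is resolved by the observed methylation
level whenever the divergence curve itself cannot resolve it, and by the
curve when it can.  Standard errors come from the Jacobian-based
asymptotic covariance of whichever model was adopted (for the constrained
model, propagated through alpha = p0 * lambda).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "NeutralModelParams",
    "NeutralModelFit",
    "FitSummary",
    "model_divergence",
    "fit_neutral_model",
    "steady_state",
    "compare_fits",
    "bootstrap_se",
]

DEFAULT_BOUNDS = {"alpha": (1e-12, 1e-2), "beta": (1e-12, 1e-2), "c": (0.0, 0.4)}
_TIE_RTOL = 1e-3  # starts whose RSS agree within this are treated as equivalent


@dataclass
class NeutralModelParams:
    """Point parameters of the neutral gain/loss divergence model."""

    alpha: float
    beta: float
    c: float = 0.0
    p0: float = 0.5

    def __post_init__(self) -> None:
        if self.alpha < 0 or self.beta < 0:
            raise ValueError("rates must be non-negative")
        if self.alpha + self.beta > 1:
            raise ValueError("alpha + beta must not exceed 1")
        if not 0.0 <= self.c < 0.5:
            raise ValueError("intercept c must lie in [0, 0.5)")
        if not 0.0 <= self.p0 <= 1.0:
            raise ValueError("p0 must lie in [0, 1]")

    @property
    def gamma(self) -> float:
        return 1.0 - self.alpha - self.beta

    @property
    def pi(self) -> float:
        total = self.alpha + self.beta
        return self.alpha / total if total > 0 else np.nan


@dataclass
class NeutralModelFit:
    params: NeutralModelParams
    se_alpha: float
    se_beta: float
    se_c: float
    rss: float
    n_pairs: int
    converged: bool
    n_iterations: int
    se_reliable: bool
    notes: list[str] = field(default_factory=list)

    @property
    def alpha(self) -> float:
        return self.params.alpha

    @property
    def beta(self) -> float:
        return self.params.beta


@dataclass
class FitSummary:
    """Minimal (estimate, SE) container, e.g. for published rate estimates."""

    alpha: float
    se_alpha: float
    beta: float
    se_beta: float
    converged: bool = True


def _tip_probs(alpha: float, beta: float, tau: np.ndarray):
    lam = alpha + beta
    if lam == 0:
        a = np.ones_like(tau, dtype=float)
        b = np.zeros_like(tau, dtype=float)
        return a, b
    pi = alpha / lam
    g = (1.0 - lam) ** tau
    return pi + (1 - pi) * g, pi * (1 - g)


def model_divergence(
    params: NeutralModelParams,
    tau_i: np.ndarray | float,
    tau_j: np.ndarray | float,
) -> np.ndarray | float:
    """Expected divergence for tips tau_i and tau_j years past their MRCA."""
    ti = np.asarray(tau_i, dtype=float)
    tj = np.asarray(tau_j, dtype=float)
    if np.any(ti < 0) or np.any(tj < 0):
        raise ValueError("tip times must be non-negative")
    ai, bi = _tip_probs(params.alpha, params.beta, ti)
    aj, bj = _tip_probs(params.alpha, params.beta, tj)
    d = (params.c
         + params.p0 * (ai + aj - 2 * ai * aj)
         + (1 - params.p0) * (bi + bj - 2 * bi * bj))
    return float(d) if np.isscalar(tau_i) and np.isscalar(tau_j) else d


def _model_and_jac(theta: np.ndarray, p0: float, ti: np.ndarray, tj: np.ndarray):
    """Model values and analytic Jacobian wrt (alpha, beta, c)."""
    alpha, beta, c = theta
    lam = alpha + beta
    pi = alpha / lam
    gamma = 1.0 - lam
    gi, gj = gamma**ti, gamma**tj
    ai, bi = pi + (1 - pi) * gi, pi * (1 - gi)
    aj, bj = pi + (1 - pi) * gj, pi * (1 - gj)
    d = c + p0 * (ai + aj - 2 * ai * aj) + (1 - p0) * (bi + bj - 2 * bi * bj)

    dD_dai, dD_daj = p0 * (1 - 2 * aj), p0 * (1 - 2 * ai)
    dD_dbi, dD_dbj = (1 - p0) * (1 - 2 * bj), (1 - p0) * (1 - 2 * bi)
    # sensitivities of tip probabilities to (pi, gamma)
    dai_dpi, daj_dpi = 1 - gi, 1 - gj
    dbi_dpi, dbj_dpi = 1 - gi, 1 - gj
    with np.errstate(divide="ignore", invalid="ignore"):
        dgi = np.where(ti > 0, ti * gamma ** (ti - 1), 0.0)
        dgj = np.where(tj > 0, tj * gamma ** (tj - 1), 0.0)
    dai_dg, daj_dg = (1 - pi) * dgi, (1 - pi) * dgj
    dbi_dg, dbj_dg = -pi * dgi, -pi * dgj

    dD_dpi = (dD_dai * dai_dpi + dD_daj * daj_dpi
              + dD_dbi * dbi_dpi + dD_dbj * dbj_dpi)
    dD_dg = (dD_dai * dai_dg + dD_daj * daj_dg
             + dD_dbi * dbi_dg + dD_dbj * dbj_dg)
    dpi_da, dpi_db = beta / lam**2, -alpha / lam**2
    dD_da = dD_dpi * dpi_da - dD_dg
    dD_db = dD_dpi * dpi_db - dD_dg
    return d, np.column_stack([dD_da, dD_db, np.ones_like(d)])


def _prepare_pairs(pairs: pd.DataFrame, exclude_root_censored: bool):
    df = pairs.copy()
    if exclude_root_censored and "root_censored" in df.columns:
        df = df[~df["root_censored"].astype(bool)]
    if "tau_i" in df.columns and "tau_j" in df.columns:
        ti = df["tau_i"].to_numpy(dtype=float)
        tj = df["tau_j"].to_numpy(dtype=float)
    elif "delta_t" in df.columns:
        ti = tj = df["delta_t"].to_numpy(dtype=float) / 2.0
    else:
        raise ValueError("pairs need tau_i/tau_j or delta_t columns")
    groups = None
    for ci, cj in (("leaf_i", "leaf_j"), ("sample_i", "sample_j")):
        if ci in df.columns and cj in df.columns:
            groups = df[[ci, cj]].to_numpy(dtype=object)
            break
    return df["D"].to_numpy(dtype=float), ti, tj, groups


def fit_neutral_model(
    pairs: pd.DataFrame,
    p0: float,
    bounds: dict | None = None,
    exclude_root_censored: bool = True,
    extra_starts: list[tuple[float, float, float]] | None = None,
    se_method: str = "auto",
    tree=None,
    n_sites: int | None = None,
) -> NeutralModelFit:
    """Estimate (alpha, beta, c) by bounded nonlinear least squares.

    ``pairs`` needs columns ``D`` plus either ``tau_i``/``tau_j`` or
    ``delta_t`` (then tau_i = tau_j = delta_t / 2), optionally
    ``root_censored``.  ``p0`` is the observed mean methylated fraction
    across samples and is held fixed.  Optimisation runs in log10 rate
    space from a multi-start grid plus a slope-informed start; see the
    module docstring for how ridge-tied starts are resolved.

    Standard errors (``se_method``):

    - ``'asymptotic'`` — Jacobian-based covariance, which treats pair
      divergences as independent.  Pairs sharing a lineage are positively
      correlated, so this is anti-conservative.
    - ``'jackknife'`` — delete-one-leaf jackknife (needs leaf/sample label
      columns in ``pairs``); accounts for leaf-level dependence.
    - ``'model'`` — sandwich covariance using the exact model-implied
      covariance of pair divergences, computed from joint four-leaf
      discordance probabilities on the pedigree (needs ``tree``, a
      :class:`~somaclock.pedigree_growth.LineageTree`, and ``n_sites``);
      this also captures the variance contributed by epimutations on deep
      shared branches, which no within-dataset resampling can see.
    - ``'auto'`` — ``'model'`` when ``tree`` and ``n_sites`` are given,
      else ``'jackknife'`` when labels for >= 5 leaves are present, else
      ``'asymptotic'``.
    """
    bnds = dict(DEFAULT_BOUNDS, **(bounds or {}))
    D, ti, tj, groups = _prepare_pairs(pairs, exclude_root_censored)
    if len(D) < 4 or len(np.unique(ti + tj)) < 2:
        raise ValueError("need >= 4 pairs spanning >= 2 distinct divergence times")

    lo = np.array([np.log10(bnds["alpha"][0]), np.log10(bnds["beta"][0]), bnds["c"][0]])
    hi = np.array([np.log10(bnds["alpha"][1]), np.log10(bnds["beta"][1]), bnds["c"][1]])

    def residuals(x):
        d, _ = _model_and_jac(np.array([10 ** x[0], 10 ** x[1], x[2]]), p0, ti, tj)
        return d - D

    def jac(x):
        theta = np.array([10 ** x[0], 10 ** x[1], x[2]])
        _, J = _model_and_jac(theta, p0, ti, tj)
        J = J.copy()
        J[:, 0] *= theta[0] * np.log(10)
        J[:, 1] *= theta[1] * np.log(10)
        return J

    starts = []
    # slope-informed start at the p0-consistent rate split
    delta = ti + tj
    slope = max(np.polyfit(delta, D, 1)[0], 1e-15)
    lam0 = slope / max(2 * p0 * (1 - p0), 1e-6)
    for scale in (1.0, 0.3, 3.0):
        lam = np.clip(lam0 * scale, 2 * bnds["alpha"][0], bnds["alpha"][1])
        starts.append((max(p0 * lam, bnds["alpha"][0]),
                       max((1 - p0) * lam, bnds["beta"][0]),
                       max(float(D.min()), 0.0)))
    for la, lb in itertools.product((-7.0, -5.0, -3.0), repeat=2):
        for c0 in (0.0, max(float(D.min()), 0.0)):
            starts.append((10**la, 10**lb, c0))
    starts.extend(extra_starts or [])

    results = []
    for a0, b0, c0 in starts:
        x0 = np.clip(
            np.array([np.log10(a0), np.log10(b0), c0]),
            lo + 1e-9, hi - 1e-9,
        )
        try:
            res = optimize.least_squares(
                residuals, x0, jac=jac, bounds=(lo, hi),
                xtol=1e-15, ftol=1e-15, gtol=1e-15, max_nfev=2000,
            )
        except Exception:  # keep other starts alive
            continue
        results.append(res)
    if not results:
        raise RuntimeError("nonlinear least squares failed from every start")

    best_cost = min(r.cost for r in results)
    tied = [r for r in results if r.cost <= best_cost * (1 + _TIE_RTOL) + 1e-300]

    def pi_mismatch(res):
        a, b = 10 ** res.x[0], 10 ** res.x[1]
        return abs(a / (a + b) - p0)

    best = min(tied, key=pi_mismatch)
    alpha, beta, c = 10 ** best.x[0], 10 ** best.x[1], best.x[2]
    rss_free = float(2 * best.cost)
    notes = []

    # equilibrium-constrained alternative: alpha = p0*lam, beta = (1-p0)*lam
    con = _fit_constrained(D, ti, tj, p0, bnds)
    dof = max(len(D) - 3, 1)
    use_constrained = False
    if con is not None and 0 < p0 < 1:
        rss_con = float(2 * con.cost)
        excess = max(rss_con - rss_free, 0.0)
        if excess <= 1e-28:
            use_constrained = True
        elif rss_free > 0:
            f_stat = excess / (rss_free / dof)
            use_constrained = f_stat < stats.f.ppf(0.95, 1, dof)

    if use_constrained:
        lam, c = 10 ** con.x[0], con.x[1]
        alpha, beta = p0 * lam, (1 - p0) * lam
        rss = float(2 * con.cost)
        notes.append(
            "gain/loss split not resolved by the divergence curve; "
            "equilibrium-constrained estimates (steady state = p0) reported"
        )
        # covariance of (lam, c), propagated to (alpha, beta, c)
        _, J3 = _model_and_jac(np.array([alpha, beta, c]), p0, ti, tj)
        Jc = np.column_stack([J3[:, 0] * p0 + J3[:, 1] * (1 - p0), J3[:, 2]])
        s2 = rss / max(len(D) - 2, 1)
        cov2 = s2 * np.linalg.pinv(Jc.T @ Jc, rcond=1e-15)
        se_lam, se_c = np.sqrt(np.clip(np.diag(cov2), 0.0, None))
        ses = np.array([p0 * se_lam, (1 - p0) * se_lam, se_c])
        se_reliable = True
        converged = bool(con.status > 0)
        n_iter = int(con.nfev)
    else:
        rss = rss_free
        # asymptotic covariance from the Jacobian in natural parameters
        _, J = _model_and_jac(np.array([alpha, beta, c]), p0, ti, tj)
        s2 = rss / dof
        JtJ = J.T @ J
        cond = np.linalg.cond(JtJ)
        cov = s2 * np.linalg.pinv(JtJ, rcond=1e-15)
        ses = np.sqrt(np.clip(np.diag(cov), 0.0, None))
        se_reliable = bool(cond < 1e12)
        if not se_reliable:
            notes.append(
                "alpha-beta ridge: standard errors are ill-conditioned "
                f"(cond={cond:.2e}); consider bootstrap_se"
            )
        converged = bool(best.status > 0)
        n_iter = int(best.nfev)

    leaves = np.unique(groups) if groups is not None else np.array([])
    if se_method not in ("auto", "asymptotic", "jackknife", "model"):
        raise ValueError(f"unknown se_method {se_method!r}")
    do_model = se_method == "model" or (
        se_method == "auto" and tree is not None and n_sites is not None
    )
    do_jackknife = not do_model and (
        se_method == "jackknife" or (se_method == "auto" and len(leaves) >= 5)
    )
    if do_model:
        if tree is None or n_sites is None or groups is None:
            raise ValueError("model-based SEs need tree, n_sites and leaf labels")
        sigma = _pair_divergence_covariance(
            tree, alpha, beta, p0, groups, int(n_sites)
        )
        _, J3 = _model_and_jac(np.array([alpha, beta, c]), p0, ti, tj)
        if use_constrained:
            Jm = np.column_stack([J3[:, 0] * p0 + J3[:, 1] * (1 - p0), J3[:, 2]])
        else:
            Jm = J3
        A = np.linalg.pinv(Jm.T @ Jm, rcond=1e-15)
        cov = A @ (Jm.T @ sigma @ Jm) @ A
        d = np.sqrt(np.clip(np.diag(cov), 0.0, None))
        if use_constrained:
            ses = np.array([p0 * d[0], (1 - p0) * d[0], d[1]])
        else:
            ses = d
        se_reliable = True
        notes.append("standard errors: model-based sandwich covariance "
                     "(joint discordance probabilities on the pedigree)")
    if do_jackknife:
        if groups is None:
            raise ValueError("jackknife SEs need leaf/sample label columns")
        thetas = []
        for leaf in leaves:
            keep = ~np.any(groups == leaf, axis=1)
            if keep.sum() < 4 or len(np.unique(ti[keep] + tj[keep])) < 2:
                continue
            theta = _refit_quick(
                D[keep], ti[keep], tj[keep], p0, bnds,
                (alpha, beta, c), use_constrained,
            )
            if theta is not None:
                thetas.append(theta)
        if len(thetas) >= 3:
            thetas = np.asarray(thetas)
            g = len(thetas)
            ses = np.sqrt((g - 1) / g * ((thetas - thetas.mean(0)) ** 2).sum(0))
            se_reliable = True
            notes.append(f"standard errors: delete-one-leaf jackknife over {g} leaves")
        else:
            notes.append("jackknife SEs unavailable (too few leaves); "
                         "asymptotic SEs reported")

    params = NeutralModelParams(alpha, beta, c, p0)
    return NeutralModelFit(
        params=params, se_alpha=float(ses[0]), se_beta=float(ses[1]),
        se_c=float(ses[2]), rss=rss, n_pairs=len(D),
        converged=converged, n_iterations=n_iter,
        se_reliable=se_reliable, notes=notes,
    )


def _refit_quick(D, ti, tj, p0, bnds, start, use_constrained):
    """Single-start refit used by the jackknife: same model as the full fit."""
    alpha0, beta0, c0 = start
    try:
        if use_constrained:
            res = _fit_constrained(D, ti, tj, p0, bnds,
                                   starts=[(alpha0 + beta0, c0)])
            if res is None:
                return None
            lam = 10 ** res.x[0]
            return p0 * lam, (1 - p0) * lam, res.x[1]
        lo = np.array([np.log10(bnds["alpha"][0]), np.log10(bnds["beta"][0]),
                       bnds["c"][0]])
        hi = np.array([np.log10(bnds["alpha"][1]), np.log10(bnds["beta"][1]),
                       bnds["c"][1]])

        def residuals(x):
            d, _ = _model_and_jac(np.array([10 ** x[0], 10 ** x[1], x[2]]), p0, ti, tj)
            return d - D

        def jac(x):
            theta = np.array([10 ** x[0], 10 ** x[1], x[2]])
            _, J = _model_and_jac(theta, p0, ti, tj)
            J = J.copy()
            J[:, 0] *= theta[0] * np.log(10)
            J[:, 1] *= theta[1] * np.log(10)
            return J

        x0 = np.clip(np.array([np.log10(alpha0), np.log10(beta0), c0]),
                     lo + 1e-9, hi - 1e-9)
        res = optimize.least_squares(residuals, x0, jac=jac, bounds=(lo, hi),
                                     xtol=1e-15, ftol=1e-15, gtol=1e-15,
                                     max_nfev=2000)
        return 10 ** res.x[0], 10 ** res.x[1], res.x[2]
    except Exception:
        return None


def _joint_probability(tree, trans, prior, assignment: dict[str, int]) -> float:
    """P(leaf states = assignment) for <= 4 leaves by pruning on the tree.

    ``trans[node]`` is the 2x2 transition matrix on the edge above ``node``
    (rows: parent state, columns: child state); subtrees containing none of
    the constrained leaves contribute a factor of one and are skipped.
    """
    relevant: set[str] = set()
    for leaf in assignment:
        relevant.update(tree.path_to_root(leaf))

    def message(node: str) -> np.ndarray:
        if node in assignment:
            out = np.zeros(2)
            out[assignment[node]] = 1.0
            return out
        msg = np.ones(2)
        for child in tree.children(node):
            if child in relevant:
                msg = msg * (trans[child] @ message(child))
        return msg

    return float(prior @ message(tree.root))


def _pair_divergence_covariance(tree, alpha, beta, p0, groups, n_sites):
    """Model-implied covariance matrix of the observed pair divergences.

    Sites are independent, so Cov(D_ij, D_kl) = Cov(Y_ij, Y_kl) / n_sites
    with Y the per-site discordance indicator; the joint discordance
    probability P(X_i != X_j and X_k != X_l) follows from the four-leaf
    joint law on the pedigree under the fitted two-state chain.
    """
    lam = alpha + beta
    pi = alpha / lam if lam > 0 else 0.0
    trans = {}
    for node in tree.node_names():
        if node == tree.root:
            continue
        t = tree.edge_length(node)
        g = (1.0 - lam) ** t if lam > 0 else 1.0
        p_m_from_u = pi * (1 - g)
        p_m_from_m = pi + (1 - pi) * g
        trans[node] = np.array([[1 - p_m_from_u, p_m_from_u],
                                [1 - p_m_from_m, p_m_from_m]])
    prior = np.array([1 - p0, p0])

    n_pairs = len(groups)
    disc = np.empty(n_pairs)
    for a, (i, j) in enumerate(groups):
        disc[a] = sum(
            _joint_probability(tree, trans, prior, {i: x, j: 1 - x})
            for x in (0, 1)
        )
    sigma = np.empty((n_pairs, n_pairs))
    for a in range(n_pairs):
        i, j = groups[a]
        for b in range(a, n_pairs):
            k, l = groups[b]
            if a == b:
                joint = disc[a]
            else:
                joint = 0.0
                for x in (0, 1):
                    for y in (0, 1):
                        assignment = {i: x, j: 1 - x}
                        ok = True
                        for leaf, val in ((k, y), (l, 1 - y)):
                            if leaf in assignment:
                                if assignment[leaf] != val:
                                    ok = False
                            else:
                                assignment[leaf] = val
                        if ok:
                            joint += _joint_probability(tree, trans, prior, assignment)
            cov = (joint - disc[a] * disc[b]) / n_sites
            sigma[a, b] = sigma[b, a] = cov
    return sigma


def _fit_constrained(D, ti, tj, p0, bnds, starts=None):
    """Least squares over (log10 lambda, c) with the steady state pinned to p0."""
    if not 0 < p0 < 1:
        return None
    lam_lo = bnds["alpha"][0] + bnds["beta"][0]
    lam_hi = min(bnds["alpha"][1] / p0, bnds["beta"][1] / (1 - p0), 1.0)
    lo = np.array([np.log10(lam_lo), bnds["c"][0]])
    hi = np.array([np.log10(lam_hi), bnds["c"][1]])

    def split(x):
        lam = 10 ** x[0]
        return np.array([p0 * lam, (1 - p0) * lam, x[1]])

    def residuals(x):
        d, _ = _model_and_jac(split(x), p0, ti, tj)
        return d - D

    def jac(x):
        theta = split(x)
        _, J3 = _model_and_jac(theta, p0, ti, tj)
        lam = 10 ** x[0]
        d_dlam = J3[:, 0] * p0 + J3[:, 1] * (1 - p0)
        return np.column_stack([d_dlam * lam * np.log(10), J3[:, 2]])

    if starts is None:
        delta = ti + tj
        slope = max(np.polyfit(delta, D, 1)[0], 1e-15)
        lam0 = slope / max(2 * p0 * (1 - p0), 1e-6)
        starts = [(lam, c0) for lam in (lam0, 1e-6, 1e-4, 1e-2)
                  for c0 in (0.0, max(float(D.min()), 0.0))]
    best = None
    for lam_start, c0 in starts:
        x0 = np.clip(np.array([np.log10(max(lam_start, lam_lo)), c0]),
                     lo + 1e-9, hi - 1e-9)
        try:
            res = optimize.least_squares(
                residuals, x0, jac=jac, bounds=(lo, hi),
                xtol=1e-15, ftol=1e-15, gtol=1e-15, max_nfev=2000,
            )
        except Exception:
            continue
        if best is None or res.cost < best.cost:
            best = res
    return best


def steady_state(params: NeutralModelParams) -> float:
    """Equilibrium methylated fraction pi = alpha / (alpha + beta)."""
    if params.alpha + params.beta == 0:
        raise ValueError("steady state undefined when alpha = beta = 0")
    return params.alpha / (params.alpha + params.beta)


def _welch_one_sided(e1: float, se1: float, e2: float, se2: float) -> tuple[float, float]:
    if se1 == 0 and se2 == 0:
        raise ValueError("zero standard errors in both fits")
    t = (e1 - e2) / np.sqrt(se1**2 + se2**2)
    # estimate+SE summaries carry no replicate counts; normal reference
    return float(t), float(stats.norm.sf(t))


def compare_fits(fit_a, fit_b) -> pd.DataFrame:
    """Rate-ratio report between two fits (A relative to B).

    Accepts :class:`NeutralModelFit` or :class:`FitSummary`.  Per parameter:
    the A:B ratio and a one-sided Welch test (alternative: A greater) from
    the estimates and their standard errors.  The summary row carries the
    average of the gain- and loss-rate ratios.
    """
    for fit in (fit_a, fit_b):
        if not fit.converged:
            raise ValueError("both fits must have converged")
    rows = []
    for name in ("alpha", "beta"):
        e1, s1 = getattr(fit_a, name), getattr(fit_a, f"se_{name}")
        e2, s2 = getattr(fit_b, name), getattr(fit_b, f"se_{name}")
        t, p = _welch_one_sided(e1, s1, e2, s2)
        rows.append({"parameter": name, "estimate_a": e1, "estimate_b": e2,
                     "ratio": e1 / e2, "welch_t": t, "p_one_sided": p})
    report = pd.DataFrame(rows)
    avg = float(report["ratio"].mean())
    report.attrs["average_ratio"] = avg
    return report


@dataclass
class BootstrapResult:
    se_alpha: float
    se_beta: float
    se_c: float
    ci_alpha: tuple[float, float]
    ci_beta: tuple[float, float]
    n_boot: int
    n_failures: int
    unreliable: bool


def bootstrap_se(
    pairs: pd.DataFrame,
    p0: float,
    n_boot: int = 200,
    seed: int | None = None,
    **fit_kwargs,
) -> BootstrapResult:
    """Pair-resampling bootstrap standard errors and percentile intervals."""
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    rng = np.random.default_rng(seed)
    df = pairs.reset_index(drop=True)
    estimates = []
    failures = 0
    for _ in range(n_boot):
        sample = df.iloc[rng.integers(len(df), size=len(df))]
        try:
            fit = fit_neutral_model(sample, p0, **fit_kwargs)
        except (ValueError, RuntimeError):
            failures += 1
            continue
        estimates.append((fit.params.alpha, fit.params.beta, fit.params.c))
    est = np.asarray(estimates)
    if len(est) == 0:
        raise RuntimeError("all bootstrap refits failed")
    ses = est.std(axis=0, ddof=1)
    ci_a = tuple(np.percentile(est[:, 0], [2.5, 97.5]))
    ci_b = tuple(np.percentile(est[:, 1], [2.5, 97.5]))
    return BootstrapResult(
        float(ses[0]), float(ses[1]), float(ses[2]), ci_a, ci_b,
        n_boot, failures, unreliable=failures > 0.2 * n_boot,
    )
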