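"""EM marginal-maximum-likelihood estimation of the MNRM.

The latent traits are integrated out over a fixed rectangular quadrature
grid (Bock-Aitkin).  Each EM cycle:

* E-step: for every person, the posterior weight of each grid node is
  proportional to W(x) times the likelihood of their response pattern at x;
  posterior weights are accumulated into expected person counts per node and
  expected category-selection counts r_jk(x) per item.
* M-step: each item's expected complete-data multinomial log-likelihood is
  maximized over its slopes and intercepts by Newton-Raphson with analytic
  gradient and Hessian (step-halving on any decrease).  The latent
  correlation matrix is updated by directly maximizing the expected prior
  log-weight over the off-diagonal entries, which keeps the marginal
  log-likelihood nondecreasing.

Scale indeterminacy is resolved by fixing latent means to 0 and variances
to 1; rotational indeterminacy does not arise because scoring functions are
fixed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import minimize, minimize_scalar
from scipy.special import logsumexp
from scipy.stats import chi2

from .errors import ValidationError
from .grid import LatentGrid, build_grid
from .model import (
    ItemParameters,
    MNRMModel,
    ResponseMatrix,
    ScoringFunctionSet,
)

__all__ = [
    "FitSummary",
    "EMState",
    "marginal_loglik",
    "fit_em",
    "fit_indices",
    "likelihood_ratio_test",
]

log = logging.getLogger("mnrm")


@dataclass(frozen=True)
class FitSummary:
    """Deviance-based fit summary of one estimated model."""

    minus2LL: float
    n_params: int
    AIC: float
    BIC: float
    N: int
    n_iter: int
    converged: bool

    def to_dict(self) -> dict:
        return {
            "minus2LL": self.minus2LL,
            "n_params": self.n_params,
            "AIC": self.AIC,
            "BIC": self.BIC,
            "N": self.N,
            "n_iter": self.n_iter,
            "converged": self.converged,
        }


@dataclass
class EMState:
    """Intermediate EM quantities, exposed for inspection and testing."""

    model: MNRMModel
    grid: LatentGrid
    node_counts: np.ndarray  # expected persons per node, sums to N
    category_counts: list[np.ndarray]  # per item: (Q x K) expected counts
    loglik_trace: list[float] = field(default_factory=list)


# ---------------------------------------------------------------------------
# likelihood machinery


def _item_logT(item: ItemParameters, s_j: np.ndarray, nodes: np.ndarray) -> np.ndarray:
    """(Q x K) log category probabilities of one item at all grid nodes."""
    z = nodes @ (item.a * s_j).T + item.c  # (Q, K)
    z = z - z.max(axis=1, keepdims=True)
    return z - np.log(np.exp(z).sum(axis=1, keepdims=True))


def _pattern_logL(
    items: Sequence[ItemParameters],
    s: ScoringFunctionSet,
    grid: LatentGrid,
    responses: ResponseMatrix,
) -> np.ndarray:
    """(N x Q) log-likelihood of each person's pattern at each node.

    Missing responses contribute nothing (their factor is 1).
    """
    N, Q = responses.n_persons, grid.n_nodes
    out = np.zeros((N, Q))
    for j, item in enumerate(items):
        logT = _item_logT(item, s.for_item(j), grid.nodes)  # (Q, K)
        col = responses.data[:, j]
        obs = ~np.isnan(col)
        if obs.any():
            out[obs] += logT[:, col[obs].astype(int)].T
    return out


def marginal_loglik(
    model: MNRMModel, grid: LatentGrid, responses: ResponseMatrix
) -> float:
    """Marginal log-likelihood sum_i log sum_x W(x) prod_j T_j(y_ij | x)."""
    if responses.n_persons == 0:
        raise ValidationError("empty response matrix")
    ll = _pattern_logL(model.items, model.scoring, grid, responses)
    return float(logsumexp(ll + np.log(grid.weights), axis=1).sum())


# ---------------------------------------------------------------------------
# M-step: expected complete-data multinomial log-likelihood per item


def _design(s_j: np.ndarray, nodes: np.ndarray) -> np.ndarray:
    """(Q x K x P) logit gradient; P = D slopes then K-1 free intercepts."""
    Q, D = nodes.shape
    K = s_j.shape[0]
    G = np.empty((Q, K, D + K - 1))
    G[:, :, :D] = s_j[None, :, :] * nodes[:, None, :]
    G[:, :, D:] = np.eye(K)[:, 1:][None, :, :]
    return G


def _expected_ll(theta: np.ndarray, s_j: np.ndarray, nodes: np.ndarray, r: np.ndarray) -> float:
    D = nodes.shape[1]
    item = ItemParameters(a=theta[:D], c=np.concatenate([[0.0], theta[D:]]))
    return float((r * _item_logT(item, s_j, nodes)).sum())


def _grad_hess(
    theta: np.ndarray, s_j: np.ndarray, nodes: np.ndarray, r: np.ndarray
) -> tuple[float, np.ndarray, np.ndarray]:
    """Value, gradient and Hessian of the expected multinomial log-likelihood."""
    D = nodes.shape[1]
    item = ItemParameters(a=theta[:D], c=np.concatenate([[0.0], theta[D:]]))
    logT = _item_logT(item, s_j, nodes)
    T = np.exp(logT)  # (Q, K)
    n_x = r.sum(axis=1)  # (Q,)
    G = _design(s_j, nodes)  # (Q, K, P)
    resid = r - n_x[:, None] * T
    grad = np.einsum("qk,qkp->p", resid, G)
    GT = np.einsum("qk,qkp->qp", T, G)  # (Q, P): E[g|x]
    H = -(
        np.einsum("q,qk,qkp,qkr->pr", n_x, T, G, G)
        - np.einsum("q,qp,qr->pr", n_x, GT, GT)
    )
    return float((r * logT).sum()), grad, H


def _newton_item(
    theta: np.ndarray, s_j: np.ndarray, nodes: np.ndarray, r: np.ndarray,
    max_iter: int = 30, gtol: float = 1e-9,
) -> tuple[np.ndarray, bool]:
    """Maximize one item's expected log-likelihood; step-halving on decrease."""
    f, g, H = _grad_hess(theta, s_j, nodes, r)
    ok = True
    for _ in range(max_iter):
        if np.max(np.abs(g)) < gtol:
            break
        try:
            step = np.linalg.solve(H - 1e-10 * np.eye(H.shape[0]), g)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(H, g, rcond=None)[0]
        alpha, improved = 1.0, False
        for _ in range(30):
            cand = theta - alpha * step
            fc = _expected_ll(cand, s_j, nodes, r)
            if fc >= f - 1e-12:
                theta, f, improved = cand, fc, True
                break
            alpha *= 0.5
        if not improved:
            ok = False
            break
        f, g, H = _grad_hess(theta, s_j, nodes, r)
    return theta, ok


def _newton_shared_slopes(
    items: list[ItemParameters],
    s: ScoringFunctionSet,
    nodes: np.ndarray,
    counts: list[np.ndarray],
    max_iter: int = 30,
) -> tuple[list[ItemParameters], bool]:
    """Joint Newton update with one slope vector shared by all items."""
    D = nodes.shape[1]
    Ks = [it.K for it in items]
    offs = np.cumsum([D] + [K - 1 for K in Ks])  # global parameter offsets
    P = int(offs[-1])
    theta = np.concatenate([items[0].a] + [it.c[1:] for it in items])

    def split(th: np.ndarray) -> list[np.ndarray]:
        return [
            np.concatenate([th[:D], th[offs[j]: offs[j + 1]]])
            for j in range(len(items))
        ]

    def value(th: np.ndarray) -> float:
        return sum(
            _expected_ll(tj, s.for_item(j), nodes, counts[j])
            for j, tj in enumerate(split(th))
        )

    f = value(theta)
    ok = True
    for _ in range(max_iter):
        g = np.zeros(P)
        H = np.zeros((P, P))
        for j, tj in enumerate(split(theta)):
            _, gj, Hj = _grad_hess(tj, s.for_item(j), nodes, counts[j])
            idx = np.concatenate([np.arange(D), np.arange(offs[j], offs[j + 1])])
            g[idx] += gj
            H[np.ix_(idx, idx)] += Hj
        if np.max(np.abs(g)) < 1e-9:
            break
        try:
            step = np.linalg.solve(H - 1e-10 * np.eye(P), g)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(H, g, rcond=None)[0]
        alpha, improved = 1.0, False
        for _ in range(30):
            cand = theta - alpha * step
            fc = value(cand)
            if fc >= f - 1e-12:
                theta, f, improved = cand, fc, True
                break
            alpha *= 0.5
        if not improved:
            ok = False
            break
    new_items = [
        ItemParameters(a=tj[:D], c=np.concatenate([[0.0], tj[D:]]))
        for tj in split(theta)
    ]
    return new_items, ok


# ---------------------------------------------------------------------------
# latent correlation update


def _update_R(grid: LatentGrid, node_counts: np.ndarray, R: np.ndarray) -> np.ndarray:
    """Maximize the expected prior log-weight over the correlation entries.

    g(R) = sum_x nbar(x) log W_R(x) with nodes fixed; the current R is kept
    unless a candidate strictly improves g, so the EM ascent property is
    preserved.
    """
    D = R.shape[0]
    if D < 2:
        return R

    def neg_g(off: np.ndarray) -> float:
        cand = np.eye(D)
        cand[np.triu_indices(D, 1)] = off
        cand = cand + cand.T - np.eye(D)
        if np.linalg.eigvalsh(cand)[0] < 1e-6:
            return 1e12
        g = build_grid(nodes=list(grid.axes), R=cand)
        return -float(node_counts @ np.log(g.weights))

    cur = R[np.triu_indices(D, 1)]
    if D == 2:
        res = minimize_scalar(
            lambda r: neg_g(np.array([r])), bounds=(-0.98, 0.98), method="bounded",
            options={"xatol": 1e-6},
        )
        best = np.array([res.x])
    else:
        res = minimize(neg_g, cur, method="Nelder-Mead",
                       options={"xatol": 1e-5, "fatol": 1e-9, "maxiter": 400})
        best = res.x
    if neg_g(best) < neg_g(cur) - 1e-12:
        out = np.eye(D)
        out[np.triu_indices(D, 1)] = best
        return out + out.T - np.eye(D)
    return R


# ---------------------------------------------------------------------------
# EM driver


def _start_values(
    responses: ResponseMatrix, s: ScoringFunctionSet
) -> list[ItemParameters]:
    """Default starts: slope 1.0 on dimension 0, 0.5 on the remaining
    (style) dimensions; intercepts from smoothed log observed proportions."""
    items = []
    D = s.D
    a0 = np.full(D, 0.5)
    a0[0] = 1.0
    for j in range(s.n_items):
        K = s.K(j)
        col = responses.data[:, j]
        obs = col[~np.isnan(col)].astype(int)
        freq = np.bincount(obs, minlength=K).astype(float) + 0.5
        c = np.log(freq) - np.log(freq[0])
        items.append(ItemParameters(a=a0.copy(), c=c))
    return items


def fit_em(
    responses: ResponseMatrix,
    s: ScoringFunctionSet,
    *,
    nodes_per_dim: int | None = None,
    grid_range: tuple[float, float] = (-5.0, 5.0),
    max_iter: int = 500,
    tol: float = 1e-5,
    estimate_R: bool | None = None,
    equal_slopes: bool = False,
    start: MNRMModel | None = None,
) -> tuple[MNRMModel, FitSummary]:
    """Fit the MNRM by Bock-Aitkin EM-MML.

    Parameters
    ----------
    responses, s : data and fixed scoring functions.
    nodes_per_dim : quadrature nodes per dimension (default 21 for D <= 2,
        15 otherwise, on ``grid_range``).
    tol : stop when successive marginal log-likelihoods change by less.
    estimate_R : estimate latent correlations (default: True when D > 1).
    equal_slopes : constrain slopes equal across items (each dimension's
        slope shared), the sum-score-equivalent partial-credit constraint.
    start : optional starting model.

    Returns the fitted model and a :class:`FitSummary`; non-convergence is
    flagged on the summary, never raised.
    """
    s.check_identification()
    D = s.D
    for j in range(s.n_items):
        col = responses.data[:, j]
        if np.unique(col[~np.isnan(col)]).size < 2:
            raise ValidationError(
                f"item {responses.item_ids[j]!r}: fewer than 2 observed "
                "categories; cannot be estimated"
            )
    if estimate_R is None:
        estimate_R = D > 1
    if nodes_per_dim is None:
        nodes_per_dim = 21 if D <= 2 else 15
    lo, hi = grid_range

    if start is not None:
        items = [ItemParameters(a=it.a.copy(), c=it.c.copy()) for it in start.items]
        R = start.R.copy()
    else:
        items = _start_values(responses, s)
        R = np.eye(D)
    start_sign = np.sign([it.a.copy() for it in items])

    grid = build_grid(nodes_per_dim, lo, hi, R=R)
    N = responses.n_persons
    trace: list[float] = []
    converged = False
    mstep_ok = True
    it_count = 0
    node_counts = np.full(grid.n_nodes, np.nan)
    counts: list[np.ndarray] = []

    for it_count in range(1, max_iter + 1):
        # E-step
        ll_nodes = _pattern_logL(items, s, grid, responses)  # (N, Q)
        joint = ll_nodes + np.log(grid.weights)
        person_ll = logsumexp(joint, axis=1)
        ll = float(person_ll.sum())
        post = np.exp(joint - person_ll[:, None])  # (N, Q)
        node_counts = post.sum(axis=0)
        counts = []
        for j in range(s.n_items):
            K = s.K(j)
            r = np.zeros((grid.n_nodes, K))
            col = responses.data[:, j]
            for k in range(K):
                sel = col == k
                if sel.any():
                    r[:, k] = post[sel].sum(axis=0)
            counts.append(r)
        trace.append(ll)
        log.info("EM iter %d: logL = %.6f", it_count, ll)
        if len(trace) > 1 and abs(trace[-1] - trace[-2]) < tol:
            converged = True
            break

        # M-step
        if equal_slopes:
            items, ok = _newton_shared_slopes(items, s, grid.nodes, counts)
            mstep_ok &= ok
        else:
            new_items = []
            for j, item in enumerate(items):
                theta = np.concatenate([item.a, item.c[1:]])
                theta, ok = _newton_item(theta, s.for_item(j), grid.nodes, counts[j])
                mstep_ok &= ok
                new_items.append(
                    ItemParameters(a=theta[:D], c=np.concatenate([[0.0], theta[D:]]))
                )
            items = new_items
        if estimate_R and D > 1:
            R = _update_R(grid, node_counts, R)
            grid = build_grid(nodes=list(grid.axes), R=R)

    flip = np.sign([it.a for it in items]) * start_sign
    if np.any(flip < 0):
        log.warning(
            "slope sign flips relative to starting values detected "
            "(possible factor reflection)"
        )

    model = MNRMModel(items=items, scoring=s, R=R)
    if equal_slopes:
        n_free = D + sum(it.K - 1 for it in items)
    else:
        n_free = sum(D + it.K - 1 for it in items)
    if estimate_R and D > 1:
        n_free += D * (D - 1) // 2
    m2ll = -2.0 * trace[-1]
    aic, bic = fit_indices(m2ll, n_free, N)
    summary = FitSummary(
        minus2LL=m2ll,
        n_params=n_free,
        AIC=aic,
        BIC=bic,
        N=N,
        n_iter=it_count,
        converged=converged and mstep_ok,
    )
    model.em_state = EMState(  # attached for inspection; not part of identity
        model=model,
        grid=grid,
        node_counts=node_counts,
        category_counts=counts,
        loglik_trace=trace,
    )
    return model, summary


def fit_indices(minus2LL: float, n_params: int, N: int) -> tuple[float, float]:
    """AIC = -2LL + 2*np and BIC = -2LL + np*ln(N)."""
    if N <= 0:
        raise ValidationError("N must be positive")
    return minus2LL + 2.0 * n_params, minus2LL + n_params * float(np.log(N))


def likelihood_ratio_test(
    fit_full: FitSummary, fit_reduced: FitSummary
) -> tuple[float, int, float]:
    """Likelihood-ratio test of a reduced model nested in a full model.

    Nesting cannot be verified mechanically and is the caller's assertion.
    Returns (chi2, df, p) with chi2 the deviance difference; a negative
    chi2 (non-nesting or non-convergence) is returned with a warning.
    """
    if fit_reduced.n_params > fit_full.n_params:
        raise ValidationError("reduced model has more parameters than full")
    stat = fit_reduced.minus2LL - fit_full.minus2LL
    df = fit_full.n_params - fit_reduced.n_params
    if stat < 0:
        log.warning(
            "negative LR statistic (%.3f): models may not be nested or "
            "estimation did not converge", stat,
        )
    p = float(chi2.sf(stat, df)) if df > 0 else (1.0 if stat <= 0 else 0.0)
    return float(stat), int(df), p
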