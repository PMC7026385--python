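"""Marginal maximum likelihood (MML) estimation of 2PL item parameters.

MML integrates the latent trait out of the likelihood of the observed
response patterns and maximizes the resulting marginal likelihood.  It is
consistent and asymptotically efficient, which makes it the efficient member
of the Hausman estimator pair.  Its asymptotic covariance is the inverse of
the *expected* Fisher information — using the observed information instead
can break the positive-definiteness of the Hausman difference covariance.

The optimizer is EM in the Bock–Aitkin style (posterior trait weights on a
fixed quadrature grid in the E-step, per-item weighted logistic regressions
in the M-step), followed by a quasi-Newton polish of the full marginal
likelihood so the first-order condition holds sharply.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit, logit

from .exceptions import ConfigurationError, ConvergenceError, DataError
from .model_core import (
    PROB_CLIP,
    ItemParameters,
    QuadratureGrid,
    ResponseMatrix,
    make_quadrature,
)

__all__ = [
    "EstimateWithCovariance",
    "marginal_loglik",
    "fit_mml",
    "pattern_score_vector",
    "expected_information",
]

#: exact pattern enumeration is used for the expected information whenever
#: 2**G does not exceed this cap; beyond it a seeded Monte-Carlo estimate is used
ENUMERATION_CAP = 2**20


@dataclass
class EstimateWithCovariance:
    """Point estimates plus asymptotic covariance for one estimator.

    The covariance is 2G×2G over the stacked parameter vector
    (beta0_1, beta1_1, ..., beta0_G, beta1_G); the ordering is identical for
    both estimator tags so difference vectors can be formed coordinate-wise.
    """

    estimator_tag: str  # "MML" or "LI"
    params: ItemParameters
    covariance: np.ndarray
    n_subjects: int
    converged: bool
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self):
        cov = np.asarray(self.covariance, dtype=float)
        g2 = 2 * self.params.n_items
        if cov.shape != (g2, g2):
            raise ValueError("covariance must be 2G x 2G")
        if np.abs(cov - cov.T).max() > 1e-10:
            raise ValueError("covariance must be symmetric")
        self.covariance = cov


# ---------------------------------------------------------------------------
# pattern bookkeeping


def collapse_patterns(data: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Collapse response rows to unique patterns with counts.

    Estimation cost then scales with the number of distinct patterns rather
    than the number of subjects.
    """
    data = np.ascontiguousarray(np.asarray(data, dtype=np.uint8))
    n, g = data.shape
    # pack each row into an integer key for fast uniqueness
    if g <= 63:
        keys = data @ (1 << np.arange(g, dtype=np.uint64))
        _, idx, counts = np.unique(keys, return_index=True, return_counts=True)
        return data[idx].astype(np.float64), counts.astype(np.float64)
    uniq, counts = np.unique(data, axis=0, return_counts=True)
    return uniq.astype(np.float64), counts.astype(np.float64)


def _clip(p: np.ndarray, eps: float = PROB_CLIP) -> np.ndarray:
    return np.clip(p, eps, 1.0 - eps)


def _pattern_log_marginals(
    beta0: np.ndarray,
    beta1: np.ndarray,
    patterns: np.ndarray,
    grid: QuadratureGrid,
):
    """Return (log m_p, posterior weights A of shape P×Q, P_gq matrix)."""
    pmat = _clip(expit(beta0[:, None] + beta1[:, None] * grid.nodes[None, :]))
    logp, log1mp = np.log(pmat), np.log1p(-pmat)
    logl = patterns @ logp + (1.0 - patterns) @ log1mp  # P×Q
    shift = logl.max(axis=1, keepdims=True)
    lw = np.exp(logl - shift) * grid.weights[None, :]
    m_shifted = lw.sum(axis=1)
    log_m = np.log(m_shifted) + shift[:, 0]
    a_post = lw / m_shifted[:, None]
    return log_m, a_post, pmat


def marginal_loglik(
    params: ItemParameters, data: ResponseMatrix, grid: QuadratureGrid | None = None
) -> float:
    """Log marginal likelihood sum_i log ∫ Π_g P_g^x (1-P_g)^(1-x) dΦ(θ)."""
    if tuple(data.item_ids) != tuple(params.item_ids):
        raise ValueError("data columns do not match parameter item order")
    grid = grid or make_quadrature()
    patterns, counts = collapse_patterns(data.data)
    log_m, _, _ = _pattern_log_marginals(params.beta0, params.beta1, patterns, grid)
    return float(counts @ log_m)


def _neg_loglik_and_grad(x, patterns, counts, grid):
    beta0, beta1 = x[0::2], x[1::2]
    log_m, a_post, pmat = _pattern_log_marginals(beta0, beta1, patterns, grid)
    ll = counts @ log_m
    # posterior-expected probabilities per pattern/item
    b = a_post @ pmat.T  # P×G
    t = a_post @ grid.nodes  # P
    c = a_post @ (pmat * grid.nodes[None, :]).T  # P×G
    g0 = counts @ (patterns - b)
    g1 = counts @ (patterns * t[:, None] - c)
    grad = np.empty_like(x)
    grad[0::2], grad[1::2] = g0, g1
    return -ll, -grad


def pattern_score_vector(
    params: ItemParameters, pattern, grid: QuadratureGrid | None = None
) -> np.ndarray:
    """Gradient of the log marginal probability of one response pattern.

    Stacked order (beta0_1, beta1_1, ..., beta0_G, beta1_G).
    """
    grid = grid or make_quadrature()
    pattern = np.asarray(pattern, dtype=float).reshape(1, -1)
    if pattern.shape[1] != params.n_items:
        raise ValueError("pattern length must equal the number of items")
    if not np.isin(pattern, (0.0, 1.0)).all():
        raise ValueError("pattern entries must be 0/1")
    scores, _ = _pattern_scores(params.beta0, params.beta1, pattern, grid)
    return scores[0]


def _pattern_scores(beta0, beta1, patterns, grid):
    """(P×2G score matrix, log marginal probabilities) per pattern."""
    log_m, a_post, pmat = _pattern_log_marginals(beta0, beta1, patterns, grid)
    b = a_post @ pmat.T
    t = a_post @ grid.nodes
    c = a_post @ (pmat * grid.nodes[None, :]).T
    scores = np.empty((patterns.shape[0], 2 * beta0.size))
    scores[:, 0::2] = patterns - b
    scores[:, 1::2] = patterns * t[:, None] - c
    return scores, log_m


# ---------------------------------------------------------------------------
# EM + polish


def _em_iterate(beta0, beta1, patterns, counts, grid, max_iter, tol):
    """Bock–Aitkin EM on collapsed patterns; returns params, loglik, n_iter."""
    xc = (patterns * counts[:, None]).T  # G×P, expected-count helper
    nodes, theta2 = grid.nodes, grid.nodes**2
    last_ll = -np.inf
    for it in range(1, max_iter + 1):
        log_m, a_post, _ = _pattern_log_marginals(beta0, beta1, patterns, grid)
        ll = counts @ log_m
        if abs(ll - last_ll) < tol:
            return beta0, beta1, ll, it
        last_ll = ll
        nq = a_post.T @ counts  # expected subjects per node
        r = xc @ a_post  # expected positives per item/node
        # M-step: few Newton steps of weighted logistic regression, all items
        for _ in range(5):
            p = _clip(expit(beta0[:, None] + beta1[:, None] * nodes[None, :]))
            resid = r - nq[None, :] * p
            g0 = resid.sum(axis=1)
            g1 = resid @ nodes
            w = nq[None, :] * p * (1.0 - p)
            h00 = w.sum(axis=1)
            h01 = w @ nodes
            h11 = w @ theta2
            det = h00 * h11 - h01**2
            det = np.where(det <= 0, np.inf, det)
            beta0 = beta0 + (h11 * g0 - h01 * g1) / det
            beta1 = beta1 + (h00 * g1 - h01 * g0) / det
    return beta0, beta1, last_ll, max_iter


def fit_mml(
    data: ResponseMatrix,
    grid: QuadratureGrid | None = None,
    start: ItemParameters | None = None,
    max_em_iter: int = 500,
    em_tol: float = 1e-6,
    polish: bool = True,
    info_strategy: str = "auto",
    info_draws: int = 1_000_000,
    info_seed: int = 0,
    min_subjects: int = 100,
    strict: bool = False,
    compute_covariance: bool = True,
) -> EstimateWithCovariance:
    """Fit the 2PL by marginal maximum likelihood.

    Parameters
    ----------
    data:
        Binary response matrix; every item must show both response categories.
    start:
        Optional warm start.  Default: intercepts from the inverse-logistic of
        the item means, discriminations 1.
    info_strategy:
        ``"enumerate"``, ``"monte_carlo"`` or ``"auto"`` (enumerate whenever
        ``2**G`` is at most :data:`ENUMERATION_CAP`).
    strict:
        If True, raise on non-convergence instead of flagging the result.
    compute_covariance:
        Skip the expected-information covariance when False (useful inside
        bootstrap loops where only point estimates are needed); the stored
        covariance is then a zero matrix and ``diagnostics['covariance']``
        says ``"skipped"``.
    """
    grid = grid or make_quadrature()
    if data.n_subjects < min_subjects:
        raise DataError(
            f"need at least {min_subjects} subjects, got {data.n_subjects}"
        )
    means = data.data.mean(axis=0)
    bad = [i for i, m in enumerate(means) if m <= 0.0 or m >= 1.0]
    if bad:
        names = ", ".join(str(data.item_ids[i]) for i in bad)
        raise DataError(f"items with a single response category: {names}")

    patterns, counts = collapse_patterns(data.data)
    if start is not None:
        beta0, beta1 = start.beta0.copy(), start.beta1.copy()
    else:
        beta0 = logit(means)
        beta1 = np.ones(data.n_items)

    beta0, beta1, ll, n_iter = _em_iterate(
        beta0, beta1, patterns, counts, grid, max_em_iter, em_tol
    )
    converged = n_iter < max_em_iter
    if polish:
        x0 = np.empty(2 * data.n_items)
        x0[0::2], x0[1::2] = beta0, beta1
        res = minimize(
            _neg_loglik_and_grad,
            x0,
            args=(patterns, counts, grid),
            jac=True,
            method="L-BFGS-B",
            options={"gtol": 1e-7, "maxiter": 300},
        )
        if res.fun <= -ll:  # accept polish only if it did not degrade
            beta0, beta1, ll = res.x[0::2], res.x[1::2], -res.fun
            converged = converged or res.success
    if not converged and strict:
        raise ConvergenceError("MML estimation did not converge")

    est = ItemParameters(data.item_ids, beta0, beta1)
    diagnostics = {"n_iter_em": n_iter, "loglik": float(ll)}
    if compute_covariance:
        info = expected_information(
            est,
            data.n_subjects,
            grid,
            strategy=info_strategy,
            n_draws=info_draws,
            seed=info_seed,
        )
        cov = np.linalg.inv(info)
        cov = 0.5 * (cov + cov.T)
        diagnostics["covariance"] = info_strategy
    else:
        cov = np.zeros((2 * data.n_items, 2 * data.n_items))
        diagnostics["covariance"] = "skipped"
    return EstimateWithCovariance(
        estimator_tag="MML",
        params=est,
        covariance=cov,
        n_subjects=data.n_subjects,
        converged=bool(converged),
        diagnostics=diagnostics,
    )


# ---------------------------------------------------------------------------
# expected information


def _all_patterns(g: int, chunk: int = 1 << 16):
    total = 1 << g
    cols = np.arange(g, dtype=np.uint32)
    for lo in range(0, total, chunk):
        idx = np.arange(lo, min(lo + chunk, total), dtype=np.uint32)
        yield ((idx[:, None] >> cols[None, :]) & 1).astype(np.float64)


def expected_information(
    params: ItemParameters,
    n_subjects: int,
    grid: QuadratureGrid | None = None,
    strategy: str = "auto",
    n_draws: int = 1_000_000,
    seed: int = 0,
) -> np.ndarray:
    """Expected (Fisher) information of the marginal likelihood, 2G×2G.

    ``enumerate`` computes I = n · Σ_patterns P(pattern) s sᵀ exactly over all
    2^G patterns; ``monte_carlo`` replaces the pattern distribution by a
    seeded model simulation of ``n_draws`` patterns.  Patterns are processed
    in chunks so memory stays flat in G.
    """
    grid = grid or make_quadrature()
    g = params.n_items
    if strategy == "auto":
        strategy = "enumerate" if 2**g <= ENUMERATION_CAP else "monte_carlo"
    if strategy not in ("enumerate", "monte_carlo"):
        raise ConfigurationError(f"unknown information strategy: {strategy}")
    if strategy == "enumerate" and 2**g > ENUMERATION_CAP:
        raise ConfigurationError(
            f"2^{g} patterns exceed the enumeration cap; use strategy='monte_carlo'"
        )

    info = np.zeros((2 * g, 2 * g))
    if strategy == "enumerate":
        for patterns in _all_patterns(g):
            s, log_m = _pattern_scores(params.beta0, params.beta1, patterns, grid)
            info += (s * np.exp(log_m)[:, None]).T @ s
    else:
        rng = np.random.default_rng(seed)
        remaining = n_draws
        chunk = 200_000
        while remaining > 0:
            m = min(chunk, remaining)
            remaining -= m
            thetas = rng.standard_normal(m)
            probs = expit(
                params.beta0[None, :] + thetas[:, None] * params.beta1[None, :]
            )
            draws = (rng.random((m, g)) < probs).astype(np.uint8)
            patterns, counts = collapse_patterns(draws)
            s, _ = _pattern_scores(params.beta0, params.beta1, patterns, grid)
            info += (s * counts[:, None]).T @ s
        info /= n_draws
    info *= n_subjects
    return 0.5 * (info + info.T)
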