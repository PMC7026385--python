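"""Limited-information (pairwise-margin) estimation of 2PL item parameters.

The limited-information estimator fits the item parameters to low-order
margins of the response table instead of the full pattern frequencies: the
observed first-order proportions p_g and pairwise joint positive proportions
p_gh are stacked into a vector ``o``, their model-implied counterparts into
``e``, and the unweighted least-squares (ULS) estimator minimizes
``(o − e)'(o − e)``.  It is consistent but not efficient, which makes it the
inefficient member of the Hausman estimator pair.  Its asymptotic covariance
follows from the multinomial sampling covariance of the margins and the
delta method, giving the sandwich
``(Δ'Δ)⁻¹ Δ' Ξ Δ (Δ'Δ)⁻¹`` with Δ the margin Jacobian and Ξ the margin
sampling covariance.

By default ``o`` contains both univariate and pairwise margins
(``margins="pairs+uni"``); a strictly pairwise vector is available with
``margins="pairs"``.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy.optimize import least_squares

from .exceptions import ConvergenceError, DataError, HausmanIRTError
from .mml import EstimateWithCovariance
from .model_core import (
    ItemParameters,
    QuadratureGrid,
    ResponseMatrix,
    item_probabilities,
    make_quadrature,
)

__all__ = [
    "MarginVector",
    "observed_margins",
    "expected_margins",
    "fit_uls",
    "margin_jacobian",
    "margin_sampling_covariance",
    "uls_covariance",
]


@dataclass(frozen=True)
class MarginVector:
    """First- and second-order positive-response proportions.

    ``index_map`` maps each margin's item-index tuple — ``(g,)`` or
    ``(g, h)`` with g < h — to its position in the stacked vector.
    """

    first_order: np.ndarray
    second_order: np.ndarray
    index_map: dict

    def __post_init__(self):
        p1 = np.asarray(self.first_order, dtype=float)
        p2 = np.asarray(self.second_order, dtype=float)
        object.__setattr__(self, "first_order", p1)
        object.__setattr__(self, "second_order", p2)
        g = p1.size
        if p2.size != g * (g - 1) // 2:
            raise ValueError("second_order must have G(G-1)/2 entries")
        if ((p1 < 0) | (p1 > 1)).any() or ((p2 < 0) | (p2 > 1)).any():
            raise ValueError("margins must lie in [0, 1]")
        for idx, (gi, hi) in enumerate(combinations(range(g), 2)):
            if p2[idx] > min(p1[gi], p1[hi]) + 1e-12:
                raise ValueError("pairwise margin exceeds a univariate margin")

    @property
    def n_items(self) -> int:
        return self.first_order.size

    def stacked(self, margins: str = "pairs+uni") -> np.ndarray:
        if margins == "pairs+uni":
            return np.concatenate([self.first_order, self.second_order])
        if margins == "pairs":
            return self.second_order.copy()
        raise ValueError(f"unknown margins mode: {margins}")


def margin_index(g: int, margins: str = "pairs+uni") -> list[tuple]:
    """Ordered list of item-index tuples defining the stacked margin vector."""
    pairs = [(a, b) for a, b in combinations(range(g), 2)]
    if margins == "pairs+uni":
        return [(a,) for a in range(g)] + pairs
    if margins == "pairs":
        return pairs
    raise ValueError(f"unknown margins mode: {margins}")


def _index_map(g: int) -> dict:
    sets = [(a,) for a in range(g)] + list(combinations(range(g), 2))
    return {s: k for k, s in enumerate(sets)}


def observed_margins(data: ResponseMatrix) -> MarginVector:
    """Sample first-order and pairwise positive-response proportions."""
    x = data.data.astype(np.float64)
    n, g = x.shape
    p1 = x.mean(axis=0)
    cross = (x.T @ x) / n
    iu = np.triu_indices(g, k=1)
    return MarginVector(p1, cross[iu], _index_map(g))


def expected_margins(
    params: ItemParameters, grid: QuadratureGrid | None = None
) -> MarginVector:
    """Model-implied margins by quadrature over the trait distribution."""
    grid = grid or make_quadrature()
    pmat = item_probabilities(params, grid.nodes)  # G×Q
    w = grid.weights
    e1 = pmat @ w
    gi, hi = np.triu_indices(params.n_items, k=1)
    e2 = (pmat[gi] * pmat[hi]) @ w
    return MarginVector(e1, e2, _index_map(params.n_items))


def margin_jacobian(
    params: ItemParameters,
    grid: QuadratureGrid | None = None,
    margins: str = "pairs+uni",
) -> np.ndarray:
    """Jacobian Δ = ∂e/∂(beta0_1, beta1_1, ...) of the expected margins.

    A margin depends only on the parameters of its own items, so each row has
    at most four non-zero entries.
    """
    grid = grid or make_quadrature()
    g = params.n_items
    pmat = item_probabilities(params, grid.nodes)
    w = grid.weights
    nodes = grid.nodes
    dp = pmat * (1.0 - pmat)  # dP/dbeta0 per node; dP/dbeta1 adds a theta factor

    gi, hi = np.triu_indices(g, k=1)
    n_pairs = gi.size
    rows_uni = np.zeros((g, 2 * g))
    rows_uni[np.arange(g), 2 * np.arange(g)] = dp @ w
    rows_uni[np.arange(g), 2 * np.arange(g) + 1] = dp @ (w * nodes)

    rows_pair = np.zeros((n_pairs, 2 * g))
    dg = dp[gi] * pmat[hi]
    dh = pmat[gi] * dp[hi]
    rows_pair[np.arange(n_pairs), 2 * gi] = dg @ w
    rows_pair[np.arange(n_pairs), 2 * gi + 1] = dg @ (w * nodes)
    rows_pair[np.arange(n_pairs), 2 * hi] = dh @ w
    rows_pair[np.arange(n_pairs), 2 * hi + 1] = dh @ (w * nodes)

    if margins == "pairs+uni":
        return np.vstack([rows_uni, rows_pair])
    if margins == "pairs":
        return rows_pair
    raise ValueError(f"unknown margins mode: {margins}")


def margin_sampling_covariance(
    params: ItemParameters,
    n_subjects: int,
    grid: QuadratureGrid | None = None,
    margins: str = "pairs+uni",
) -> np.ndarray:
    """Asymptotic covariance Ξ of the observed margin vector.

    Margins are means of product indicators, so
    ``Cov(p̂_u, p̂_v) = (π_{u∪v} − π_u π_v)/n`` with π the model-implied joint
    positive probability of the union index set (size ≤ 4).
    """
    grid = grid or make_quadrature()
    g = params.n_items
    sets = margin_index(g, margins)
    pmat = item_probabilities(params, grid.nodes)
    w = grid.weights

    # per-margin node-wise product curves, then pairwise integrals
    r = np.stack([pmat[list(s)].prod(axis=0) for s in sets])
    pi = r @ w
    u = (r * w[None, :]) @ r.T  # correct for disjoint index sets

    # overlapping index sets need the union product, not the plain product;
    # find them via item-membership bitmasks, then fix only those entries
    masks = np.array([sum(1 << s for s in st) for st in sets], dtype=np.uint64)
    overlap = (masks[:, None] & masks[None, :]) != 0
    ii, jj = np.where(np.triu(overlap))
    for i, j in zip(ii, jj):
        union = sorted(set(sets[i]) | set(sets[j]))
        val = float(pmat[union].prod(axis=0) @ w)
        u[i, j] = u[j, i] = val
    xi = (u - np.outer(pi, pi)) / n_subjects
    return 0.5 * (xi + xi.T)


def uls_covariance(
    params: ItemParameters,
    n_subjects: int,
    grid: QuadratureGrid | None = None,
    margins: str = "pairs+uni",
) -> np.ndarray:
    """Delta-method sandwich covariance of the ULS estimator, 2G×2G."""
    grid = grid or make_quadrature()
    delta = margin_jacobian(params, grid, margins)
    sv = np.linalg.svd(delta, compute_uv=False)
    if sv[-1] < 1e-10 * sv[0]:
        raise HausmanIRTError(
            f"margin Jacobian is rank deficient (smallest singular value {sv[-1]:.3e})"
        )
    xi = margin_sampling_covariance(params, n_subjects, grid, margins)
    bread = np.linalg.inv(delta.T @ delta)
    cov = bread @ delta.T @ xi @ delta @ bread
    return 0.5 * (cov + cov.T)


def fit_uls(
    data: ResponseMatrix,
    init: ItemParameters,
    grid: QuadratureGrid | None = None,
    margins: str = "pairs+uni",
    cov_eval: str = "init",
    compute_covariance: bool = True,
    strict: bool = False,
    observed: MarginVector | None = None,
) -> EstimateWithCovariance:
    """Fit the 2PL by unweighted least squares on low-order margins.

    ``init`` is the warm start — conventionally the MML estimates, which
    keeps both estimators of the Hausman pair on the same orientation and
    mode.  ``cov_eval`` selects where the sandwich covariance is evaluated:
    ``"init"`` (the recommended common evaluation point, typically the MML
    estimates) or ``"estimate"`` (at the ULS solution itself).  ``observed``
    substitutes a margin vector for the one computed from ``data`` (e.g. to
    fit analytic margins directly).
    """
    grid = grid or make_quadrature()
    if tuple(data.item_ids) != tuple(init.item_ids):
        raise ValueError("data columns do not match init item order")
    obs = observed if observed is not None else observed_margins(data)
    p1 = obs.first_order
    if ((p1 <= 0.0) | (p1 >= 1.0)).any():
        bad = [str(data.item_ids[i]) for i in np.where((p1 <= 0) | (p1 >= 1))[0]]
        raise DataError(f"degenerate margins for items: {', '.join(bad)}")
    o = obs.stacked(margins)

    def resid(x):
        e = expected_margins(ItemParameters.from_stacked(data.item_ids, x), grid)
        return e.stacked(margins) - o

    def jac(x):
        return margin_jacobian(
            ItemParameters.from_stacked(data.item_ids, x), grid, margins
        )

    res = least_squares(
        resid,
        init.stacked(),
        jac=jac,
        method="lm",
        gtol=1e-12,
        xtol=1e-12,
        ftol=1e-12,
        max_nfev=500,
    )
    converged = bool(res.status > 0)
    if not converged and strict:
        raise ConvergenceError("ULS estimation did not converge")
    est = ItemParameters.from_stacked(data.item_ids, res.x)

    if compute_covariance:
        at = init if cov_eval == "init" else est
        cov = uls_covariance(at, data.n_subjects, grid, margins)
        cov_note = cov_eval
    else:
        cov = np.zeros((2 * data.n_items, 2 * data.n_items))
        cov_note = "skipped"
    return EstimateWithCovariance(
        estimator_tag="LI",
        params=est,
        covariance=cov,
        n_subjects=data.n_subjects,
        converged=converged,
        diagnostics={
            "objective": float(2.0 * res.cost),
            "n_evals": int(res.nfev),
            "covariance_eval": cov_note,
            "margins": margins,
        },
    )
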