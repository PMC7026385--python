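"""Two-parameter logistic (2PL) model core.

The 2PL item response model relates a binary response :math:`x_g` on item
``g`` to a latent trait :math:`\\theta` through

.. math:: P(x_g = 1 \\mid \\theta) = \\mathrm{logistic}(\\beta_{0g} + \\beta_{1g}\\theta),

with intercept :math:`\\beta_{0g}` and discrimination :math:`\\beta_{1g}`.
The trait is standard normal, the identification convention of marginal
maximum likelihood estimation.  This module provides the parameter and
response containers, Gauss–Hermite quadrature over the trait, model-implied
joint positive-response probabilities, and the baseline response simulator.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.special import expit

__all__ = [
    "ItemParameters",
    "ResponseMatrix",
    "QuadratureGrid",
    "icc_2pl",
    "make_quadrature",
    "item_probabilities",
    "joint_positive_probability",
    "simulate_2pl",
]

#: clipping bound applied to probabilities inside likelihood code, to keep
#: log(p) and log(1-p) finite; configurable by callers that need tighter control
PROB_CLIP = 1e-12


@dataclass(frozen=True)
class ItemParameters:
    """Item parameters of a 2PL test form, in slope–intercept parametrization.

    ``beta0`` is the intercept (logit of the response probability at the mean
    trait), ``beta1`` the discrimination (logit change per trait unit).
    """

    item_ids: tuple
    beta0: np.ndarray
    beta1: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "item_ids", tuple(self.item_ids))
        object.__setattr__(self, "beta0", np.asarray(self.beta0, dtype=float))
        object.__setattr__(self, "beta1", np.asarray(self.beta1, dtype=float))
        if not (len(self.item_ids) == self.beta0.size == self.beta1.size):
            raise ValueError("item_ids, beta0 and beta1 must have equal length")
        if len(set(self.item_ids)) != len(self.item_ids):
            raise ValueError("item_ids must be unique")
        if not (np.isfinite(self.beta0).all() and np.isfinite(self.beta1).all()):
            raise ValueError("item parameters must be finite")

    @property
    def n_items(self) -> int:
        return len(self.item_ids)

    def stacked(self) -> np.ndarray:
        """Parameters stacked item-wise: (b0_1, b1_1, b0_2, b1_2, ...)."""
        out = np.empty(2 * self.n_items)
        out[0::2] = self.beta0
        out[1::2] = self.beta1
        return out

    @classmethod
    def from_stacked(cls, item_ids: Sequence, stacked: np.ndarray) -> "ItemParameters":
        stacked = np.asarray(stacked, dtype=float)
        if stacked.size != 2 * len(item_ids):
            raise ValueError("stacked vector has wrong length")
        return cls(tuple(item_ids), stacked[0::2], stacked[1::2])

    def difficulty(self) -> np.ndarray:
        """Classical difficulty b = -beta0/beta1 (location of the 0.5 point)."""
        return -self.beta0 / self.beta1

    def index_of(self, item_id) -> int:
        try:
            return self.item_ids.index(item_id)
        except ValueError:
            raise KeyError(f"unknown item id: {item_id!r}") from None


@dataclass(frozen=True)
class ResponseMatrix:
    """N×G binary response matrix with optional simulation provenance.

    ``thetas`` stores the latent traits used to generate the data; it is
    carried for simulation audits only and never consumed by estimation.
    """

    data: np.ndarray
    item_ids: tuple
    thetas: np.ndarray | None = None

    def __post_init__(self):
        data = np.asarray(self.data)
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "item_ids", tuple(self.item_ids))
        if data.ndim != 2:
            raise ValueError("response data must be two-dimensional")
        if data.shape[1] != len(self.item_ids):
            raise ValueError("column count must match item_ids")
        if data.shape[0] < 1 or data.shape[1] < 2:
            raise ValueError("need at least 1 subject and 2 items")
        if not np.isin(data, (0, 1)).all():
            raise ValueError("responses must be coded 0/1")
        if self.thetas is not None:
            th = np.asarray(self.thetas, dtype=float)
            if th.shape != (data.shape[0],):
                raise ValueError("thetas must have one value per subject")
            object.__setattr__(self, "thetas", th)

    @property
    def n_subjects(self) -> int:
        return self.data.shape[0]

    @property
    def n_items(self) -> int:
        return self.data.shape[1]


@dataclass(frozen=True)
class QuadratureGrid:
    """Discretization of the standard-normal trait distribution."""

    nodes: np.ndarray
    weights: np.ndarray

    def __post_init__(self):
        nodes = np.asarray(self.nodes, dtype=float)
        weights = np.asarray(self.weights, dtype=float)
        object.__setattr__(self, "nodes", nodes)
        object.__setattr__(self, "weights", weights)
        if nodes.shape != weights.shape or nodes.ndim != 1:
            raise ValueError("nodes and weights must be 1-d and of equal length")
        if np.any(np.diff(nodes) <= 0):
            raise ValueError("nodes must be strictly increasing")
        if abs(weights.sum() - 1.0) > 1e-10:
            raise ValueError("weights must sum to 1")

    @property
    def n_nodes(self) -> int:
        return self.nodes.size

    def integrate(self, values: np.ndarray) -> np.ndarray:
        """Integrate node-wise values (last axis) against the trait measure."""
        return np.asarray(values) @ self.weights


def make_quadrature(n_nodes: int = 21) -> QuadratureGrid:
    """Gauss–Hermite grid rescaled to integrate against N(0,1).

    Exact for polynomial integrands up to degree ``2*n_nodes - 1``.
    """
    if n_nodes < 5:
        raise ValueError("n_nodes must be at least 5")
    x, w = np.polynomial.hermite.hermgauss(n_nodes)
    return QuadratureGrid(nodes=x * np.sqrt(2.0), weights=w / np.sqrt(np.pi))


def icc_2pl(params: ItemParameters, item_index: int, theta) -> np.ndarray:
    """Item characteristic curve P(x=1 | theta) of one 2PL item."""
    if not -params.n_items <= item_index < params.n_items:
        raise IndexError(f"item_index {item_index} out of range")
    theta = np.asarray(theta, dtype=float)
    if not np.isfinite(theta).all():
        raise ValueError("theta must be finite")
    return expit(params.beta0[item_index] + params.beta1[item_index] * theta)


def item_probabilities(params: ItemParameters, theta: np.ndarray) -> np.ndarray:
    """G×T matrix of response probabilities at the given trait values."""
    theta = np.asarray(theta, dtype=float)
    return expit(params.beta0[:, None] + params.beta1[:, None] * theta[None, :])


def joint_positive_probability(
    params: ItemParameters, item_subset: Iterable[int], grid: QuadratureGrid
) -> float:
    """Marginal probability that all items in the subset are answered positively.

    Under conditional independence the joint probability is the trait-integral
    of the product of the item curves,
    :math:`\\pi_S = \\int \\prod_{g \\in S} P_g(\\theta)\\, d\\Phi(\\theta)`.
    Subsets up to size 4 are supported — the orders needed for the sampling
    covariance of first- and second-order margins.
    """
    subset = list(item_subset)
    if not 1 <= len(subset) <= 4:
        raise ValueError("item_subset must contain 1 to 4 items")
    if len(set(subset)) != len(subset):
        raise ValueError("item_subset must not contain duplicates")
    probs = item_probabilities(params, grid.nodes)[subset, :]
    return float(grid.integrate(probs.prod(axis=0)))


def simulate_2pl(
    params: ItemParameters, n_subjects: int, seed: int | np.random.Generator
) -> ResponseMatrix:
    """Simulate responses of ``n_subjects`` standard-normal test takers.

    The same integer seed always yields the same matrix.  A Generator may be
    passed instead of an integer when the caller manages seeding itself.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be positive")
    rng = np.random.default_rng(seed)
    thetas = rng.standard_normal(n_subjects)
    probs = expit(params.beta0[None, :] + thetas[:, None] * params.beta1[None, :])
    data = (rng.random((n_subjects, params.n_items)) < probs).astype(np.int8)
    return ResponseMatrix(data=data, item_ids=params.item_ids, thetas=thetas)
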