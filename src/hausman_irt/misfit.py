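"""Generators of data that violate the 2PL, for power studies.

Two kinds of misspecification are emulated:

* **Misspecified item characteristic curves.**  Selected items swap the
  logistic ICC for a non-monotone curve (decreasing from a lower plateau
  before rising S-shaped to 1 — a seductive distractor for moderately able
  test takers) or a bounded curve with an upper asymptote below 1
  (careless-mistake behaviour, a 4PL-type generator).  Conditional
  independence still holds.
* **Local dependence.**  The ICCs stay exactly 2PL, but responses within
  chosen item pairs are coupled, given the trait, through a bivariate
  Gaussian copula.  Thresholding correlated normals against the conditional
  response probabilities preserves every univariate conditional margin while
  inducing within-pair association.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.special import expit, ndtr

from .model_core import ItemParameters, ResponseMatrix

__all__ = [
    "MisfitItemSpec",
    "CopulaSpec",
    "NONMONOTONE_DEFAULT",
    "BOUNDED_DEFAULT",
    "icc_nonmonotone",
    "icc_bounded",
    "simulate_with_misfit",
    "simulate_with_copula",
]

#: parameter values of the non-monotone alternative curve used in the power study
NONMONOTONE_DEFAULT = dict(a=4.25, b=1.00, c=0.25, l=1.50)
#: parameter values of the bounded (upper asymptote 0.70) alternative curve
BOUNDED_DEFAULT = dict(a=3.40, b=0.50, c=0.00, l=0.70)


@dataclass(frozen=True)
class MisfitItemSpec:
    """Alternative ICC for one item.

    ``family="nonmonotone"``: P(θ) = c·logistic(−a(θ−(b−l))) + logistic(a(θ−b)),
    falling from c to a dip and then rising to 1.  ``l`` shifts the falling
    branch left of the rising one.

    ``family="bounded"``: P(θ) = c + (1−c)·l·logistic(a(θ−b)), an S-shape
    between c and c + (1−c)·l.
    """

    item_id: object
    family: str
    a: float
    b: float
    c: float
    l: float

    def __post_init__(self):
        if self.family not in ("nonmonotone", "bounded"):
            raise ValueError(f"unknown misfit family: {self.family}")
        if self.a <= 0:
            raise ValueError("slope a must be positive")
        if not 0.0 <= self.c <= 1.0:
            raise ValueError("c must lie in [0, 1]")
        if self.family == "bounded" and self.c + (1 - self.c) * self.l > 1 + 1e-12:
            raise ValueError("upper asymptote c + (1-c)l must not exceed 1")

    def icc(self, theta) -> np.ndarray:
        if self.family == "nonmonotone":
            return icc_nonmonotone(self, theta)
        return icc_bounded(self, theta)


@dataclass(frozen=True)
class CopulaSpec:
    """Gaussian-copula local dependence in disjoint item pairs."""

    pairs: tuple
    rho: tuple

    def __init__(self, pairs: Sequence, rho):
        pairs = tuple(tuple(p) for p in pairs)
        flat = [i for p in pairs for i in p]
        if any(len(p) != 2 for p in pairs):
            raise ValueError("each entry of pairs must contain two item ids")
        if len(set(flat)) != len(flat):
            raise ValueError("copula pairs must be disjoint")
        rho_t = tuple(float(rho) for _ in pairs) if np.isscalar(rho) else tuple(
            float(r) for r in rho
        )
        if len(rho_t) != len(pairs):
            raise ValueError("need one rho per pair")
        if any(not -1.0 < r < 1.0 for r in rho_t):
            raise ValueError("rho must lie in (-1, 1)")
        object.__setattr__(self, "pairs", pairs)
        object.__setattr__(self, "rho", rho_t)


def icc_nonmonotone(spec: MisfitItemSpec, theta) -> np.ndarray:
    """Non-monotone alternative ICC (falling plateau, then S-shaped rise)."""
    if spec.family != "nonmonotone":
        raise ValueError("spec family must be 'nonmonotone'")
    theta = np.asarray(theta, dtype=float)
    falling = spec.c * expit(-spec.a * (theta - (spec.b - spec.l)))
    rising = expit(spec.a * (theta - spec.b))
    return falling + rising


def icc_bounded(spec: MisfitItemSpec, theta) -> np.ndarray:
    """Bounded alternative ICC between c and c + (1−c)·l."""
    if spec.family != "bounded":
        raise ValueError("spec family must be 'bounded'")
    theta = np.asarray(theta, dtype=float)
    return spec.c + (1.0 - spec.c) * spec.l * expit(spec.a * (theta - spec.b))


def _conditional_probabilities(
    params: ItemParameters, misfit: Sequence[MisfitItemSpec], thetas: np.ndarray
) -> np.ndarray:
    probs = expit(params.beta0[None, :] + thetas[:, None] * params.beta1[None, :])
    for spec in misfit:
        probs[:, params.index_of(spec.item_id)] = spec.icc(thetas)
    return probs


def simulate_with_misfit(
    params: ItemParameters,
    misfit: Sequence[MisfitItemSpec],
    n_subjects: int,
    seed: int | np.random.Generator,
) -> ResponseMatrix:
    """Simulate responses where listed items use their alternative ICC.

    Non-listed items follow the 2PL; conditional independence holds
    throughout.  With an empty misfit list the output is bit-for-bit the
    baseline simulation at the same seed.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be positive")
    rng = np.random.default_rng(seed)
    thetas = rng.standard_normal(n_subjects)
    probs = _conditional_probabilities(params, misfit, thetas)
    data = (rng.random((n_subjects, params.n_items)) < probs).astype(np.int8)
    return ResponseMatrix(data=data, item_ids=params.item_ids, thetas=thetas)


def simulate_with_copula(
    params: ItemParameters,
    copula: CopulaSpec,
    n_subjects: int,
    seed: int | np.random.Generator,
) -> ResponseMatrix:
    """Simulate 2PL responses with Gaussian-copula dependence in item pairs.

    Within each pair, given θ, latent normals (v_g, v_h) with correlation ρ
    are thresholded: x_g = 1 iff Φ(v_g) ≤ P_g(θ).  Since Φ(v_g) is uniform,
    each item's conditional margin is exactly its ICC; only the within-pair
    association changes.  Items outside the pairs are conditionally
    independent as usual.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be positive")
    pair_idx = [
        (params.index_of(g), params.index_of(h)) for g, h in copula.pairs
    ]
    rng = np.random.default_rng(seed)
    thetas = rng.standard_normal(n_subjects)
    probs = expit(params.beta0[None, :] + thetas[:, None] * params.beta1[None, :])
    data = (rng.random((n_subjects, params.n_items)) < probs).astype(np.int8)
    for (gi, hi), rho in zip(pair_idx, copula.rho):
        z = rng.standard_normal((n_subjects, 2))
        v1 = z[:, 0]
        v2 = rho * z[:, 0] + np.sqrt(1.0 - rho**2) * z[:, 1]
        data[:, gi] = (ndtr(v1) <= probs[:, gi]).astype(np.int8)
        data[:, hi] = (ndtr(v2) <= probs[:, hi]).astype(np.int8)
    return ResponseMatrix(data=data, item_ids=params.item_ids, thetas=thetas)
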