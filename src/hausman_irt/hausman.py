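"""Hausman specification tests of item and global fit for the 2PL.

The test compares the efficient MML estimates β̂ with the inefficient
limited-information estimates α̂.  Under a correctly specified model the
difference d = α̂ − β̂ is asymptotically normal with mean zero and covariance
Σ_d = Σ_α̂ − Σ_β̂ (efficiency makes the cross term vanish).  The statistics

* H_g = d_g' d_g over one item's (intercept, discrimination) pair, and
* H_T = d_T' d_T over all discrimination parameters

are squared norms, not Wald forms: inverting Σ_d, which is often nearly
singular, is deliberately avoided.  A squared norm of a Gaussian vector is a
mixture Σ λ_i z_i² of independent χ²₁ variates weighted by the eigenvalues
of Σ_d, approximated Satterthwaite-style by a·χ²_b with

    a = Σλ² / Σλ,    b = (Σλ)² / Σλ²,

which matches the first two moments.  Both sums are trace identities
(Σλ = tr Σ_d, Σλ² = tr Σ_d²), so no eigendecomposition is required either.
Σ_d comes from the analytic covariances or from a parametric bootstrap.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import chi2

from .exceptions import BootstrapUnstableError, DataError, InfeasibleTestError
from .limited_info import fit_uls
from .mml import EstimateWithCovariance, fit_mml
from .model_core import ItemParameters, QuadratureGrid, make_quadrature, simulate_2pl

__all__ = [
    "HausmanResult",
    "BootstrapCovariances",
    "item_selector",
    "global_selector",
    "difference_vector",
    "difference_covariance",
    "satterthwaite_coefficients",
    "hausman_item_test",
    "hausman_global_test",
    "hausman_report",
    "bootstrap_difference_covariance",
    "m2_degrees_of_freedom",
]

GLOBAL_SCOPE = "GLOBAL"


@dataclass
class HausmanResult:
    """One Hausman test: scope, difference vector, covariance and p-value."""

    scope: str
    d: np.ndarray
    sigma_d: np.ndarray
    H: float
    eigenvalues: np.ndarray
    a: float
    b: float
    p_value: float
    version: str
    warnings: list = field(default_factory=list)

    @property
    def has_negative_eigenvalues(self) -> bool:
        return bool((self.eigenvalues < 0).any())


def item_selector(params: ItemParameters, item_id) -> np.ndarray:
    """Stacked-vector indices of one item's (beta0, beta1) pair."""
    g = params.index_of(item_id)
    return np.array([2 * g, 2 * g + 1])


def global_selector(params: ItemParameters) -> np.ndarray:
    """Stacked-vector indices of all discrimination parameters."""
    return 2 * np.arange(params.n_items) + 1


def _check_pair(li: EstimateWithCovariance, mml: EstimateWithCovariance):
    if tuple(li.params.item_ids) != tuple(mml.params.item_ids):
        raise ValueError("estimator pair has mismatched item ordering")
    if li.n_subjects != mml.n_subjects:
        raise ValueError("estimator pair comes from different sample sizes")


def difference_vector(
    li: EstimateWithCovariance, mml: EstimateWithCovariance, selector: np.ndarray
) -> np.ndarray:
    """Misspecification indicator d = α̂ − β̂ on the selected coordinates."""
    _check_pair(li, mml)
    return (li.params.stacked() - mml.params.stacked())[selector]


def difference_covariance(
    li_cov: np.ndarray, mml_cov: np.ndarray, selector: np.ndarray
) -> np.ndarray:
    """Σ_d on the selected coordinates; raises if its trace is not positive."""
    li_cov = np.asarray(li_cov, dtype=float)
    mml_cov = np.asarray(mml_cov, dtype=float)
    if li_cov.shape != mml_cov.shape:
        raise ValueError("covariance shapes differ")
    sigma = (li_cov - mml_cov)[np.ix_(selector, selector)]
    sigma = 0.5 * (sigma + sigma.T)
    if np.trace(sigma) <= 0:
        raise InfeasibleTestError(
            f"trace of the difference covariance is {np.trace(sigma):.3e} <= 0; "
            "the Hausman statistic has no reference distribution"
        )
    return sigma


def satterthwaite_coefficients(eigenvalues) -> tuple[float, float]:
    """Moment-matching scale a and degrees of freedom b for Σ λ_i z_i²."""
    lam = np.asarray(eigenvalues, dtype=float)
    s1 = lam.sum()
    s2 = (lam**2).sum()
    if s1 <= 0:
        raise InfeasibleTestError("eigenvalue sum must be positive")
    return float(s2 / s1), float(s1**2 / s2)


def _result(scope, d, sigma_d, version, warnings=None) -> HausmanResult:
    h = float(d @ d)
    # trace identities: no eigendecomposition needed for a and b, but the
    # eigenvalues are reported for diagnostics
    lam = np.linalg.eigvalsh(sigma_d)
    s1, s2 = float(np.trace(sigma_d)), float(np.trace(sigma_d @ sigma_d))
    if s1 <= 0:
        raise InfeasibleTestError("difference covariance has non-positive trace")
    a, b = s2 / s1, s1**2 / s2
    warnings = list(warnings or [])
    if (lam < 0).any():
        warnings.append(
            f"difference covariance has negative eigenvalues (min {lam.min():.3e})"
        )
    p = float(chi2.sf(h / a, b))
    return HausmanResult(
        scope=scope,
        d=d,
        sigma_d=sigma_d,
        H=h,
        eigenvalues=lam,
        a=float(a),
        b=float(b),
        p_value=p,
        version=version,
        warnings=warnings,
    )


def hausman_item_test(
    li: EstimateWithCovariance,
    mml: EstimateWithCovariance,
    item_id,
    version: str = "analytic",
    bootstrap: "BootstrapCovariances | None" = None,
) -> HausmanResult:
    """Item-fit test H_g on the item's (intercept, discrimination) pair."""
    sel = item_selector(mml.params, item_id)
    d = difference_vector(li, mml, sel)
    if version == "analytic":
        sigma = difference_covariance(li.covariance, mml.covariance, sel)
    elif version == "bootstrap":
        if bootstrap is None:
            raise ValueError("bootstrap covariances required for version='bootstrap'")
        g = mml.params.index_of(item_id)
        sigma = bootstrap.item_covs[g]
        if np.trace(sigma) <= 0:
            raise InfeasibleTestError("bootstrap difference covariance has trace <= 0")
    else:
        raise ValueError(f"unknown version: {version}")
    return _result(str(item_id), d, sigma, version)


def hausman_global_test(
    li: EstimateWithCovariance,
    mml: EstimateWithCovariance,
    version: str = "analytic",
    bootstrap: "BootstrapCovariances | None" = None,
) -> HausmanResult:
    """Global-fit test H_T on the discrimination parameters only.

    Intercepts are excluded: including them makes Σ_d rank deficient and the
    test numerically unstable.
    """
    sel = global_selector(mml.params)
    d = difference_vector(li, mml, sel)
    if version == "analytic":
        sigma = difference_covariance(li.covariance, mml.covariance, sel)
    elif version == "bootstrap":
        if bootstrap is None:
            raise ValueError("bootstrap covariances required for version='bootstrap'")
        sigma = bootstrap.global_cov
        if np.trace(sigma) <= 0:
            raise InfeasibleTestError("bootstrap difference covariance has trace <= 0")
    else:
        raise ValueError(f"unknown version: {version}")
    return _result(GLOBAL_SCOPE, d, sigma, version)


def hausman_report(
    li: EstimateWithCovariance,
    mml: EstimateWithCovariance,
    version: str = "analytic",
    bootstrap: "BootstrapCovariances | None" = None,
) -> list[HausmanResult]:
    """All item-level tests plus the global test, in item order."""
    out = []
    for item_id in mml.params.item_ids:
        out.append(hausman_item_test(li, mml, item_id, version, bootstrap))
    out.append(hausman_global_test(li, mml, version, bootstrap))
    return out


def benjamini_hochberg(p_values) -> np.ndarray:
    """BH-adjusted p-values for multiplicity-aware reporting across items.

    Rejection-rate summaries use the raw p-values; this is a reporting aid
    only.
    """
    p = np.asarray(p_values, dtype=float)
    n = p.size
    order = np.argsort(p)
    ranked = p[order] * n / np.arange(1, n + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(adjusted, 1.0)
    return out


# ---------------------------------------------------------------------------
# parametric bootstrap covariance


@dataclass
class BootstrapCovariances:
    """Sample covariances of bootstrap difference vectors.

    ``item_covs[g]`` is the 2×2 covariance of item g's difference pair;
    ``global_cov`` the G×G covariance of the discrimination differences.
    """

    item_covs: np.ndarray
    global_cov: np.ndarray
    n_success: int
    n_failed: int


def bootstrap_difference_covariance(
    mml: EstimateWithCovariance,
    B: int = 200,
    seed: int = 0,
    grid: QuadratureGrid | None = None,
    margins: str = "pairs+uni",
    max_failure_fraction: float = 0.2,
) -> BootstrapCovariances:
    """Parametric-bootstrap proxy for the difference covariance.

    Resimulates ``B`` samples from the fitted 2PL at the MML estimates, refits
    both estimators in each, and returns the sample covariance of the
    difference vectors (item-level 2-vectors and the global discrimination
    vector in one pass).  Failed refits are redrawn with a fresh child seed up
    to ``3 * B`` total attempts and counted; more than
    ``max_failure_fraction * B`` failures raise :class:`BootstrapUnstableError`.
    """
    if B < 50:
        raise ValueError("B must be at least 50")
    grid = grid or make_quadrature()
    children = np.random.SeedSequence(seed).spawn(3 * B)
    g = mml.params.n_items
    diffs = np.empty((B, 2 * g))
    done = failed = attempt = 0
    while done < B and attempt < len(children):
        rng = np.random.default_rng(children[attempt])
        attempt += 1
        try:
            sample = simulate_2pl(mml.params, mml.n_subjects, rng)
            bfit = fit_mml(
                sample,
                grid=grid,
                start=mml.params,
                compute_covariance=False,
                min_subjects=1,
            )
            lfit = fit_uls(
                sample, init=bfit.params, grid=grid, margins=margins,
                compute_covariance=False,
            )
            if not (bfit.converged and lfit.converged):
                raise DataError("bootstrap refit did not converge")
        except (DataError, np.linalg.LinAlgError):
            failed += 1
            if failed > max_failure_fraction * B:
                raise BootstrapUnstableError(
                    f"{failed} of {attempt} bootstrap fits failed"
                )
            continue
        diffs[done] = lfit.params.stacked() - bfit.params.stacked()
        done += 1
    if done < B:
        raise BootstrapUnstableError("exhausted bootstrap retry budget")
    centered = diffs - diffs.mean(axis=0)
    full = (centered.T @ centered) / (B - 1)
    item_covs = np.stack(
        [full[np.ix_([2 * i, 2 * i + 1], [2 * i, 2 * i + 1])] for i in range(g)]
    )
    disc = 2 * np.arange(g) + 1
    return BootstrapCovariances(
        item_covs=item_covs,
        global_cov=full[np.ix_(disc, disc)],
        n_success=done,
        n_failed=failed,
    )


def m2_degrees_of_freedom(n_items: int) -> int:
    """Degrees of freedom of the limited-information M2 test for the 2PL.

    Counts margins minus free parameters: (G + G(G−1)/2) − 2G = G(G−1)/2 − G.
    """
    if n_items < 3:
        raise ValueError("the 2PL needs at least 3 items to be testable")
    return n_items * (n_items - 1) // 2 - n_items
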