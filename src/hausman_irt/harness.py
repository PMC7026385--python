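"""Monte-Carlo harness: scenario presets, replication loop, rejection tables.

The presets bundle the simulation designs of the size and power studies:

* ``size-scenario-1`` — 20 items from fully crossing intercepts
  (−1.5, −0.75, 0, 0.75, 1.5) with discriminations (0.6, 1.0, 1.4, 1.8),
  N = 1000, correctly specified 2PL.
* ``size-scenario-2`` — test lengths G ∈ {10, 20, 40} and sample sizes
  N ∈ {250, 1000, 10000}; discriminations 0.8/1.2 combined with ten equally
  spaced intercepts in [−1.5, 1.5]; correctly specified 2PL.
* ``power-icc1`` / ``power-icc2`` — the G=20 design with the alternative
  (non-monotone / bounded) ICC substituted in four items.
* ``power-copula`` — the G=20 design with Gaussian-copula dependence
  (ρ = 0.5) in eight disjoint item pairs.

Every replication simulates a dataset, fits MML and ULS, runs the requested
Hausman variants, and the p-values are aggregated into empirical rejection
rates per nominal level.  Replications carry pre-assigned child seeds, so
results are reproducible and invariant to execution order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import (
    ConfigurationError,
    DataError,
    HausmanIRTError,
    InfeasibleTestError,
    ScenarioUnstableError,
)
from .hausman import (
    GLOBAL_SCOPE,
    bootstrap_difference_covariance,
    hausman_global_test,
    hausman_item_test,
)
from .limited_info import fit_uls
from .misfit import (
    BOUNDED_DEFAULT,
    NONMONOTONE_DEFAULT,
    CopulaSpec,
    MisfitItemSpec,
    simulate_with_copula,
    simulate_with_misfit,
)
from .mml import fit_mml
from .model_core import ItemParameters, ResponseMatrix, make_quadrature

logger = logging.getLogger(__name__)

__all__ = [
    "ScenarioConfig",
    "RejectionTable",
    "crossed_design",
    "two_level_design",
    "rejection_rate",
    "run_scenario",
    "preset",
    "PRESET_NAMES",
]


def crossed_design(
    intercepts: Sequence[float], discriminations: Sequence[float]
) -> ItemParameters:
    """Fully cross intercept and discrimination levels into a test form."""
    beta0, beta1 = [], []
    for b1 in discriminations:
        for b0 in intercepts:
            beta0.append(b0)
            beta1.append(b1)
    ids = tuple(range(1, len(beta0) + 1))
    return ItemParameters(ids, np.array(beta0), np.array(beta1))


def two_level_design(n_items: int) -> ItemParameters:
    """Discriminations 0.8/1.2 with ten equally spaced intercepts in [−1.5, 1.5].

    G=20 fully crosses the levels.  G=10 alternates the two discriminations
    over the ten intercepts; G=40 duplicates the crossed design.  Rejection
    rates are item-averaged, so the assignment for G≠20 is immaterial.
    """
    intercepts = np.linspace(-1.5, 1.5, 10)
    if n_items == 20:
        return crossed_design(intercepts, (0.8, 1.2))
    if n_items == 10:
        beta1 = np.where(np.arange(10) % 2 == 0, 0.8, 1.2)
        return ItemParameters(tuple(range(1, 11)), intercepts, beta1)
    if n_items == 40:
        base = crossed_design(intercepts, (0.8, 1.2))
        return ItemParameters(
            tuple(range(1, 41)),
            np.concatenate([base.beta0, base.beta0]),
            np.concatenate([base.beta1, base.beta1]),
        )
    raise ConfigurationError("two_level_design supports G in {10, 20, 40}")


@dataclass
class ScenarioConfig:
    """Full description of one simulation scenario."""

    name: str
    params: ItemParameters
    n_subjects: int
    n_replications: int = 250
    misfit: tuple = ()
    copula: CopulaSpec | None = None
    versions: tuple = ("analytic",)
    alpha_levels: tuple = (0.10, 0.05, 0.01)
    bootstrap_B: int = 200
    quad_nodes: int = 21
    info_strategy: str = "auto"
    info_draws: int = 100_000
    margins: str = "pairs+uni"
    max_failed_fraction: float = 0.1

    def __post_init__(self):
        if self.n_replications < 1:
            raise ConfigurationError("n_replications must be >= 1")
        if any(not 0.0 < a < 1.0 for a in self.alpha_levels):
            raise ConfigurationError("alpha levels must lie in (0, 1)")
        if any(v not in ("analytic", "bootstrap") for v in self.versions):
            raise ConfigurationError("versions must be 'analytic' or 'bootstrap'")

    def to_dict(self) -> dict:
        """Plain-data form for YAML/JSON serialization."""
        out = {
            "name": self.name,
            "items": [
                {"item": i, "beta0": float(b0), "beta1": float(b1)}
                for i, b0, b1 in zip(
                    self.params.item_ids, self.params.beta0, self.params.beta1
                )
            ],
            "n_subjects": self.n_subjects,
            "n_replications": self.n_replications,
            "versions": list(self.versions),
            "alpha_levels": [float(a) for a in self.alpha_levels],
            "bootstrap_B": self.bootstrap_B,
            "quad_nodes": self.quad_nodes,
            "info_strategy": self.info_strategy,
            "info_draws": self.info_draws,
            "margins": self.margins,
            "max_failed_fraction": self.max_failed_fraction,
        }
        if self.misfit:
            out["misfit"] = [
                {
                    "item": s.item_id,
                    "family": s.family,
                    "a": s.a,
                    "b": s.b,
                    "c": s.c,
                    "l": s.l,
                }
                for s in self.misfit
            ]
        if self.copula is not None:
            out["copula"] = {
                "pairs": [list(p) for p in self.copula.pairs],
                "rho": list(self.copula.rho),
            }
        return out

    @classmethod
    def from_dict(cls, doc: dict) -> "ScenarioConfig":
        def maybe_int(x):
            try:
                return int(x)
            except (TypeError, ValueError):
                return x

        items = doc["items"]
        params = ItemParameters(
            tuple(maybe_int(e["item"]) for e in items),
            np.array([e["beta0"] for e in items]),
            np.array([e["beta1"] for e in items]),
        )
        misfit = tuple(
            MisfitItemSpec(
                item_id=maybe_int(e["item"]),
                family=e["family"],
                a=e["a"],
                b=e["b"],
                c=e["c"],
                l=e["l"],
            )
            for e in doc.get("misfit", [])
        )
        cop = doc.get("copula")
        copula = (
            CopulaSpec(
                [tuple(maybe_int(i) for i in p) for p in cop["pairs"]], cop["rho"]
            )
            if cop
            else None
        )
        kwargs = {
            k: doc[k]
            for k in (
                "n_subjects",
                "n_replications",
                "bootstrap_B",
                "quad_nodes",
                "info_strategy",
                "info_draws",
                "margins",
                "max_failed_fraction",
            )
            if k in doc
        }
        return cls(
            name=doc.get("name", "custom"),
            params=params,
            misfit=misfit,
            copula=copula,
            versions=tuple(doc.get("versions", ("analytic",))),
            alpha_levels=tuple(doc.get("alpha_levels", (0.10, 0.05, 0.01))),
            **kwargs,
        )


@dataclass
class RejectionTable:
    """Replication-level p-values and the aggregated rejection rates.

    ``p_item[(version)]`` is reps×G (NaN where a test was infeasible);
    ``p_global[(version)]`` has length reps.  ``table`` reports one row per
    (variant, version, scope, alpha) with the empirical rate, its binomial
    Monte-Carlo standard error, and counts.
    """

    item_ids: tuple
    p_item: dict
    p_global: dict
    alpha_levels: tuple
    n_replications: int
    n_failed: int
    n_infeasible: int
    table: pd.DataFrame = field(default=None)

    def __post_init__(self):
        if self.table is None:
            self.table = self._build_table()

    @staticmethod
    def _rate_row(p, alpha):
        p = p[~np.isnan(p)]
        n = p.size
        r = float((p < alpha).mean()) if n else np.nan
        se = float(np.sqrt(r * (1 - r) / n)) if n else np.nan
        return r, se, n

    def _build_table(self) -> pd.DataFrame:
        rows = []
        for version, mat in self.p_item.items():
            for alpha in self.alpha_levels:
                for j, item in enumerate(self.item_ids):
                    r, se, n = self._rate_row(mat[:, j], alpha)
                    rows.append(("Hg", version, str(item), alpha, r, se, n))
                r, se, n = self._rate_row(mat.ravel(), alpha)
                rows.append(("Hg", version, "ITEM_AVG", alpha, r, se, n))
        for version, vec in self.p_global.items():
            for alpha in self.alpha_levels:
                r, se, n = self._rate_row(vec, alpha)
                rows.append(("HT", version, GLOBAL_SCOPE, alpha, r, se, n))
        return pd.DataFrame(
            rows,
            columns=["variant", "version", "scope", "alpha", "rate", "mc_se", "n_used"],
        )

    def rate(self, variant: str, version: str, scope: str, alpha: float) -> float:
        t = self.table
        sel = t[
            (t.variant == variant)
            & (t.version == version)
            & (t.scope == scope)
            & (np.isclose(t.alpha, alpha))
        ]
        if sel.empty:
            raise KeyError((variant, version, scope, alpha))
        return float(sel.rate.iloc[0])

    def item_rate(self, version: str, items: Sequence, alpha: float) -> float:
        """Rejection rate pooled over the given items (power-study grouping)."""
        mat = self.p_item[version]
        cols = [self.item_ids.index(i) for i in items]
        p = mat[:, cols].ravel()
        p = p[~np.isnan(p)]
        return float((p < alpha).mean())


def rejection_rate(p_values, alpha: float) -> float:
    """Fraction of p-values strictly below the nominal level."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("p_values must be non-empty")
    if np.isnan(p).any() or ((p < 0) | (p > 1)).any():
        raise ValueError("p_values must lie in [0, 1]")
    return float((p < alpha).mean())


def _simulate(config: ScenarioConfig, rng) -> ResponseMatrix:
    if config.copula is not None:
        return simulate_with_copula(
            config.params, config.copula, config.n_subjects, rng
        )
    return simulate_with_misfit(
        config.params, config.misfit, config.n_subjects, rng
    )


def _one_replication(config: ScenarioConfig, child_seed) -> dict:
    grid = make_quadrature(config.quad_nodes)
    data_ss, boot_ss, info_ss = child_seed.spawn(3)
    data = _simulate(config, np.random.default_rng(data_ss))
    info_seed = int(info_ss.generate_state(1)[0] % (2**31))
    need_analytic = "analytic" in config.versions
    mml = fit_mml(
        data,
        grid=grid,
        info_strategy=config.info_strategy,
        info_draws=config.info_draws,
        info_seed=info_seed,
        compute_covariance=need_analytic,
    )
    li = fit_uls(
        data, init=mml.params, grid=grid, margins=config.margins,
        compute_covariance=need_analytic,
    )
    if not (mml.converged and li.converged):
        raise DataError("replication fit did not converge")
    g = config.params.n_items
    out = {"p_item": {}, "p_global": {}, "infeasible": 0}
    bootstrap = None
    if "bootstrap" in config.versions:
        boot_seed = int(boot_ss.generate_state(1)[0] % (2**31))
        bootstrap = bootstrap_difference_covariance(
            mml, B=config.bootstrap_B, seed=boot_seed, grid=grid,
            margins=config.margins,
        )
    for version in config.versions:
        p_items = np.full(g, np.nan)
        for j, item in enumerate(config.params.item_ids):
            try:
                res = hausman_item_test(li, mml, item, version, bootstrap)
                p_items[j] = res.p_value
            except InfeasibleTestError:
                out["infeasible"] += 1
        try:
            p_glob = hausman_global_test(li, mml, version, bootstrap).p_value
        except InfeasibleTestError:
            out["infeasible"] += 1
            p_glob = np.nan
        out["p_item"][version] = p_items
        out["p_global"][version] = p_glob
    return out


def run_scenario(
    config: ScenarioConfig,
    master_seed: int,
    n_replications: int | None = None,
    n_jobs: int = 1,
) -> RejectionTable:
    """Run the simulate → fit → test loop and aggregate rejection rates.

    ``n_replications`` overrides the configured count (for smoke-scale runs).
    Replications that fail to fit are excluded and counted; more than
    ``config.max_failed_fraction`` failures raise
    :class:`ScenarioUnstableError`.  With ``n_jobs > 1`` replications run as
    independent joblib tasks; pre-assigned child seeds keep the result
    identical for any worker count.
    """
    reps = n_replications or config.n_replications
    children = np.random.SeedSequence(master_seed).spawn(reps)

    def task(child):
        try:
            return _one_replication(config, child)
        except (DataError, HausmanIRTError, np.linalg.LinAlgError) as exc:
            logger.debug("replication failed: %s", exc)
            return None

    if n_jobs != 1:
        from joblib import Parallel, delayed

        results = Parallel(n_jobs=n_jobs)(delayed(task)(c) for c in children)
    else:
        results = [task(c) for c in children]

    ok = [r for r in results if r is not None]
    n_failed = reps - len(ok)
    if n_failed > config.max_failed_fraction * reps:
        raise ScenarioUnstableError(
            f"{n_failed} of {reps} replications failed to fit"
        )
    if not ok:
        raise ScenarioUnstableError("no replication succeeded")

    g = config.params.n_items
    p_item = {
        v: np.vstack([r["p_item"][v] for r in ok]) for v in config.versions
    }
    p_global = {
        v: np.array([r["p_global"][v] for r in ok]) for v in config.versions
    }
    n_infeasible = sum(r["infeasible"] for r in ok)
    if n_infeasible:
        logger.warning(
            "%d tests were infeasible (non-positive trace of the difference "
            "covariance)", n_infeasible,
        )
    return RejectionTable(
        item_ids=tuple(config.params.item_ids),
        p_item=p_item,
        p_global=p_global,
        alpha_levels=config.alpha_levels,
        n_replications=len(ok),
        n_failed=n_failed,
        n_infeasible=n_infeasible,
    )


# ---------------------------------------------------------------------------
# presets

MISFIT_ITEMS = (3, 8, 13, 18)  # spread across the difficulty range
COPULA_PAIRS = ((1, 2), (4, 5), (6, 7), (9, 10), (11, 12), (14, 15), (16, 17), (19, 20))

PRESET_NAMES = (
    "size-scenario-1",
    "size-scenario-2",
    "power-icc1",
    "power-icc2",
    "power-copula",
)


def preset(name: str, g: int | None = None, n: int | None = None) -> ScenarioConfig:
    """Named scenario configurations for the benchmark simulation designs.

    ``g`` and ``n`` select the test length / sample size axis where the
    design has one (size-scenario-2 and the power presets); the master seed
    is supplied at run time.
    """
    if name == "size-scenario-1":
        params = crossed_design((-1.5, -0.75, 0.0, 0.75, 1.5), (0.6, 1.0, 1.4, 1.8))
        return ScenarioConfig(
            name=name,
            params=params,
            n_subjects=n or 1000,
            n_replications=250,
            versions=("analytic", "bootstrap"),
        )
    if name == "size-scenario-2":
        g = g or 10
        n = n or 10000
        params = two_level_design(g)
        return ScenarioConfig(
            name=f"{name}-g{g}-n{n}",
            params=params,
            n_subjects=n,
            n_replications=250,
            versions=("analytic", "bootstrap"),
        )
    if name in ("power-icc1", "power-icc2"):
        params = two_level_design(20)
        family, defaults = (
            ("nonmonotone", NONMONOTONE_DEFAULT)
            if name == "power-icc1"
            else ("bounded", BOUNDED_DEFAULT)
        )
        misfit = tuple(
            MisfitItemSpec(item_id=i, family=family, **defaults)
            for i in MISFIT_ITEMS
        )
        return ScenarioConfig(
            name=name,
            params=params,
            n_subjects=n or 1000,
            n_replications=250,
            misfit=misfit,
            versions=("analytic", "bootstrap"),
            info_strategy="monte_carlo",
        )
    if name == "power-copula":
        params = two_level_design(20)
        return ScenarioConfig(
            name=name,
            params=params,
            n_subjects=n or 1000,
            n_replications=250,
            copula=CopulaSpec(COPULA_PAIRS, 0.5),
            versions=("analytic", "bootstrap"),
            info_strategy="monte_carlo",
        )
    raise ConfigurationError(
        f"unknown preset {name!r}; available: {', '.join(PRESET_NAMES)}"
    )
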