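import numpy as np
import pytest

from hausman_irt import (
    ItemParameters,
    fit_mml,
    fit_uls,
    make_quadrature,
    simulate_2pl,
    two_level_design,
)


@pytest.fixture(scope="session")
def grid():
    return make_quadrature(21)


@pytest.fixture(scope="session")
def params3():
    """Small three-item form with spread parameters."""
    return ItemParameters(("a", "b", "c"), [-1.0, 0.0, 0.8], [0.7, 1.0, 1.5])


@pytest.fixture(scope="session")
def params10():
    return two_level_design(10)


@pytest.fixture(scope="session")
def big_null_fit(params10, grid):
    """One large correctly specified dataset with both estimators fitted.

    Session-scoped: several recovery, efficiency and consistency checks share
    it (G=10, N=10000).
    """
    data = simulate_2pl(params10, 10000, seed=20260921)
    mml = fit_mml(data, grid=grid)
    li = fit_uls(data, init=mml.params, grid=grid)
    return params10, data, mml, li


def fine_grid_integral(fn, lo=-8.0, hi=8.0, n=10_000):
    """Trapezoid-rule oracle for ∫ fn(θ) dΦ(θ), independent of the quadrature."""
    theta = np.linspace(lo, hi, n)
    dens = np.exp(-0.5 * theta**2) / np.sqrt(2 * np.pi)
    return np.trapezoid(fn(theta) * dens, theta)
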