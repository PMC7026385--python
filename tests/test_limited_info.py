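import numpy as np
import pytest
from scipy.special import expit

from hausman_irt import (
    DataError,
    ItemParameters,
    ResponseMatrix,
    expected_margins,
    fit_uls,
    margin_jacobian,
    margin_sampling_covariance,
    observed_margins,
    simulate_2pl,
    uls_covariance,
)
from hausman_irt.limited_info import margin_index


class TestObservedMargins:
    def test_direct_counts(self):
        data = ResponseMatrix(np.array([[1, 1], [1, 0], [0, 1], [0, 0]]), ("a", "b"))
        m = observed_margins(data)
        assert np.allclose(m.first_order, [0.5, 0.5])
        assert np.allclose(m.second_order, [0.25])

    def test_all_ones(self):
        data = ResponseMatrix(np.ones((5, 3), dtype=int), ("a", "b", "c"))
        m = observed_margins(data)
        assert np.allclose(m.stacked(), 1.0)

    def test_duplication_invariance(self, params10):
        data = simulate_2pl(params10, 200, seed=4)
        doubled = ResponseMatrix(
            np.vstack([data.data, data.data]), params10.item_ids
        )
        assert np.allclose(
            observed_margins(data).stacked(), observed_margins(doubled).stacked()
        )


class TestExpectedMargins:
    def test_flat_items_factorize(self, grid):
        p = ItemParameters(("a", "b"), [0.0, 0.6], [0.0, 0.0])
        m = expected_margins(p, grid)
        assert m.first_order[0] == pytest.approx(0.5)
        assert m.second_order[0] == pytest.approx(0.5 * expit(0.6))

    def test_symmetric_item_centered(self, grid):
        p = ItemParameters(("a", "b"), [0.0, 0.0], [1.0, 1.0])
        m = expected_margins(p, grid)
        assert m.first_order[0] == pytest.approx(0.5, abs=1e-10)


class TestMarginJacobian:
    def test_sparsity_pattern(self, params3, grid):
        jac = margin_jacobian(params3, grid)
        sets = margin_index(3)
        for row, s in enumerate(sets):
            for g in range(3):
                if g not in s:
                    assert jac[row, 2 * g] == 0.0
                    assert jac[row, 2 * g + 1] == 0.0

    def test_matches_central_differences(self, params3, grid):
        jac = margin_jacobian(params3, grid)
        x0 = params3.stacked()
        eps = 1e-6
        for k in range(6):
            xp, xm = x0.copy(), x0.copy()
            xp[k] += eps
            xm[k] -= eps
            ep = expected_margins(
                ItemParameters.from_stacked(params3.item_ids, xp), grid
            ).stacked()
            em = expected_margins(
                ItemParameters.from_stacked(params3.item_ids, xm), grid
            ).stacked()
            fd = (ep - em) / (2 * eps)
            assert np.abs(jac[:, k] - fd).max() < 1e-5


class TestMarginSamplingCovariance:
    def test_indicator_identities(self, params3, grid):
        n = 400
        xi = margin_sampling_covariance(params3, n, grid)
        m = expected_margins(params3, grid)
        sets = margin_index(3)
        pos = {s: k for k, s in enumerate(sets)}
        # Var(p_g) = pi_g (1 - pi_g) / n
        for g in range(3):
            pi = m.first_order[g]
            assert xi[pos[(g,)], pos[(g,)]] == pytest.approx(pi * (1 - pi) / n)
        # Cov(p_g, p_gh) = pi_gh (1 - pi_g) / n since I_g * I_g I_h = I_g I_h
        pi_01 = m.second_order[0]
        assert xi[pos[(0,)], pos[(0, 1)]] == pytest.approx(
            pi_01 * (1 - m.first_order[0]) / n
        )

    def test_psd_and_symmetric(self, params10, grid):
        xi = margin_sampling_covariance(params10, 1000, grid)
        assert np.abs(xi - xi.T).max() < 1e-12
        assert np.linalg.eigvalsh(xi).min() > -1e-10

    def test_matches_empirical_margin_covariance(self, params3, grid):
        # 50k simulated datasets of N=40, fully vectorized
        n, reps = 40, 50_000
        rng = np.random.default_rng(21)
        th = rng.standard_normal((reps, n))
        probs = expit(
            params3.beta0[None, None, :] + th[:, :, None] * params3.beta1[None, None, :]
        )
        x = (rng.random(probs.shape) < probs).astype(np.float64)
        margins = np.concatenate(
            [
                x.mean(axis=1),
                np.stack(
                    [
                        (x[:, :, g] * x[:, :, h]).mean(axis=1)
                        for g, h in ((0, 1), (0, 2), (1, 2))
                    ],
                    axis=1,
                ),
            ],
            axis=1,
        )
        emp = np.cov(margins.T)
        ana = margin_sampling_covariance(params3, n, grid)
        # entrywise tolerance ~ 3 MC SEs of a covariance estimate
        tol = 3 * (np.abs(ana) + np.sqrt(np.outer(np.diag(ana), np.diag(ana)))) / np.sqrt(reps)
        assert (np.abs(emp - ana) <= tol + 1e-12).all()


class TestFitUls:
    def test_zero_residual_fixed_point(self, params10, grid):
        # feed analytic margins: the minimizer must return the generator
        target = expected_margins(params10, grid)
        start = ItemParameters(
            params10.item_ids, params10.beta0 + 0.2, params10.beta1 * 0.8
        )
        dummy = simulate_2pl(params10, 150, seed=1)
        fit = fit_uls(
            dummy, init=start, grid=grid, observed=target, compute_covariance=False
        )
        assert fit.diagnostics["objective"] < 1e-14
        assert np.abs(fit.params.stacked() - params10.stacked()).max() < 1e-5

    def test_recovery_within_standard_errors(self, big_null_fit):
        params10, _, _, li = big_null_fit
        se = np.sqrt(np.diag(li.covariance))
        err = np.abs(li.params.stacked() - params10.stacked())
        assert (err < 3 * se).mean() >= 0.95

    def test_deterministic(self, params10, grid):
        data = simulate_2pl(params10, 800, seed=17)
        init = params10
        a = fit_uls(data, init=init, grid=grid, compute_covariance=False)
        b = fit_uls(data, init=init, grid=grid, compute_covariance=False)
        assert np.array_equal(a.params.stacked(), b.params.stacked())

    def test_degenerate_margins_raise(self, params10):
        data = simulate_2pl(params10, 200, seed=2)
        bad = data.data.copy()
        bad[:, 0] = 0
        with pytest.raises(DataError):
            fit_uls(ResponseMatrix(bad, params10.item_ids), init=params10)

    def test_objective_beats_mml_estimates(self, big_null_fit, grid):
        params10, data, mml, li = big_null_fit
        o = observed_margins(data).stacked()
        e_mml = expected_margins(mml.params, grid).stacked()
        e_li = expected_margins(li.params, grid).stacked()
        assert ((o - e_li) ** 2).sum() <= ((o - e_mml) ** 2).sum() + 1e-12


class TestUlsCovariance:
    def test_scaling_in_n(self, params3, grid):
        c1 = uls_covariance(params3, 500, grid)
        c2 = uls_covariance(params3, 1000, grid)
        assert np.allclose(c1, 2 * c2)
        assert (np.diag(c1) > 0).all()

    def test_matches_empirical_variance(self, grid):
        # 800 replications, G=5, N=2000; diagonal within 15%
        p = ItemParameters(
            tuple(range(5)), [-1.0, -0.5, 0.0, 0.5, 1.0], [0.8, 1.2, 1.0, 0.8, 1.2]
        )
        reps = 800
        est = np.empty((reps, 10))
        for r in range(reps):
            d = simulate_2pl(p, 2000, seed=3000 + r)
            est[r] = fit_uls(
                d, init=p, grid=grid, compute_covariance=False
            ).params.stacked()
        emp = est.var(axis=0, ddof=1)
        ana = np.diag(uls_covariance(p, 2000, grid))
        assert (np.abs(emp - ana) / ana).max() < 0.15

    def test_efficiency_ordering(self, big_null_fit):
        _, _, mml, li = big_null_fit
        assert (np.diag(li.covariance) >= np.diag(mml.covariance) - 1e-8).all()
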