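import numpy as np
import pytest
from scipy.stats import chi2, kstest

from hausman_irt import (
    InfeasibleTestError,
    bootstrap_difference_covariance,
    difference_covariance,
    difference_vector,
    fit_mml,
    fit_uls,
    global_selector,
    hausman_global_test,
    hausman_item_test,
    hausman_report,
    item_selector,
    m2_degrees_of_freedom,
    satterthwaite_coefficients,
    simulate_2pl,
    two_level_design,
)


class TestSatterthwaite:
    @pytest.mark.parametrize(
        "lam,a,b",
        [
            ((1.0, 1.0), 1.0, 2.0),  # plain chi-square with 2 df
            ((2.0, 0.0), 2.0, 1.0),
            ((3.0, 1.0), 2.5, 1.6),
        ],
    )
    def test_coefficients(self, lam, a, b):
        got_a, got_b = satterthwaite_coefficients(lam)
        assert got_a == pytest.approx(a)
        assert got_b == pytest.approx(b)

    def test_moment_matching_identities(self):
        rng = np.random.default_rng(5)
        lam = rng.uniform(0.1, 3.0, size=7)
        a, b = satterthwaite_coefficients(lam)
        assert a * b == pytest.approx(lam.sum())  # mean of a*chi2_b
        assert a**2 * 2 * b == pytest.approx(2 * (lam**2).sum())  # variance

    def test_nonpositive_sum_infeasible(self):
        with pytest.raises(InfeasibleTestError):
            satterthwaite_coefficients([-1.0, 0.5])

    def test_trace_identities_match_eigendecomposition(self):
        rng = np.random.default_rng(11)
        m = rng.standard_normal((6, 6))
        sigma = m @ m.T
        lam = np.linalg.eigvalsh(sigma)
        a_eig, b_eig = satterthwaite_coefficients(lam)
        s1, s2 = np.trace(sigma), np.trace(sigma @ sigma)
        assert s2 / s1 == pytest.approx(a_eig, abs=1e-10)
        assert s1**2 / s2 == pytest.approx(b_eig, abs=1e-10)


class TestMixtureApproximation:
    @pytest.mark.parametrize("dim,seed", [(2, 1), (2, 2), (20, 3), (20, 4)])
    def test_tail_matches_monte_carlo(self, dim, seed):
        # For fixed Sigma_d, the a*chi2_b tail of H must match the exact
        # mixture sum(lambda_i z_i^2) within 0.01 at the usual alpha levels.
        rng = np.random.default_rng(seed)
        m = rng.standard_normal((dim, dim)) / np.sqrt(dim)
        sigma = m @ m.T
        lam = np.linalg.eigvalsh(sigma)
        a, b = satterthwaite_coefficients(lam)
        draws = 1_000_000
        total = np.zeros(draws)
        for l in lam:  # chunked by eigenvalue to bound memory
            total += l * rng.standard_normal(draws) ** 2
        for alpha in (0.10, 0.05, 0.01):
            # critical value from the approximation; exact tail by MC
            crit = a * chi2.ppf(1 - alpha, b)
            mc_tail = (total > crit).mean()
            assert abs(mc_tail - alpha) < 0.01


class TestDifferenceConstruction:
    def test_identical_estimates_give_zero(self, big_null_fit):
        _, _, mml, li = big_null_fit
        sel = global_selector(mml.params)
        d = difference_vector(mml, mml, sel)
        assert np.allclose(d, 0.0)

    def test_selector_shapes(self, big_null_fit):
        _, _, mml, li = big_null_fit
        assert item_selector(mml.params, mml.params.item_ids[0]).shape == (2,)
        assert global_selector(mml.params).shape == (10,)
        d = difference_vector(li, mml, global_selector(mml.params))
        # discrimination coordinates only
        assert np.allclose(
            d, li.params.beta1 - mml.params.beta1
        )

    def test_simple_difference_covariance(self):
        sel = np.array([0, 1])
        got = difference_covariance(np.diag([2.0, 2.0]), np.diag([1.0, 1.0]), sel)
        assert np.allclose(got, np.eye(2))

    def test_equal_covariances_infeasible(self):
        sel = np.array([0, 1])
        with pytest.raises(InfeasibleTestError):
            difference_covariance(np.eye(2), np.eye(2), sel)

    def test_item_submatrix_extraction(self, big_null_fit):
        _, _, mml, li = big_null_fit
        item = mml.params.item_ids[3]
        sel = item_selector(mml.params, item)
        sigma = difference_covariance(li.covariance, mml.covariance, sel)
        full = li.covariance - mml.covariance
        assert np.allclose(sigma, full[np.ix_(sel, sel)])


class TestItemAndGlobalTests:
    def test_zero_difference_gives_p_one(self, big_null_fit):
        import dataclasses

        _, _, mml, li = big_null_fit
        # identical point estimates with a valid difference covariance
        li_same = dataclasses.replace(li, params=mml.params)
        res = hausman_global_test(li_same, mml)
        assert res.H == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_chi2_tail_oracle(self):
        # H = 5.991 with identity Sigma (a=1, b=2) sits at the 5% point
        a, b = satterthwaite_coefficients([1.0, 1.0])
        p = chi2.sf(5.991 / a, b)
        assert p == pytest.approx(0.05, abs=1e-3)

    def test_report_contains_all_items_and_global(self, big_null_fit):
        _, _, mml, li = big_null_fit
        report = hausman_report(li, mml)
        assert len(report) == 11
        assert report[-1].scope == "GLOBAL"
        for r in report:
            assert r.H >= 0
            assert 0.0 <= r.p_value <= 1.0
            assert r.a > 0 and r.b > 0

    def test_item_pvalues_approximately_uniform_under_null(self, grid):
        # 250 replications of the G=10, N=10000 null: the pooled item-level
        # p-values should be close to U(0,1)
        params = two_level_design(10)
        pvals = []
        for r in range(250):
            data = simulate_2pl(params, 10000, seed=50_000 + r)
            mml = fit_mml(data, grid=grid)
            li = fit_uls(data, init=mml.params, grid=grid)
            for item in params.item_ids:
                pvals.append(hausman_item_test(li, mml, item).p_value)
        stat = kstest(pvals, "uniform").statistic
        assert stat <= 0.08


class TestBootstrapCovariance:
    def test_seeded_determinism(self, big_null_fit):
        mml = big_null_fit[2]
        a = bootstrap_difference_covariance(mml, B=50, seed=3)
        b = bootstrap_difference_covariance(mml, B=50, seed=3)
        assert np.array_equal(a.global_cov, b.global_cov)
        assert np.array_equal(a.item_covs, b.item_covs)

    def test_traces_agree_with_analytic(self, big_null_fit):
        # well-behaved instance: G=10, N=10000; compare Sigma_d traces
        _, _, mml, li = big_null_fit
        boot = bootstrap_difference_covariance(mml, B=200, seed=7)
        sel = global_selector(mml.params)
        ana = difference_covariance(li.covariance, mml.covariance, sel)
        t_boot, t_ana = np.trace(boot.global_cov), np.trace(ana)
        assert abs(t_boot - t_ana) / t_ana < 0.25

    def test_minimum_replicates_enforced(self, big_null_fit):
        with pytest.raises(ValueError):
            bootstrap_difference_covariance(big_null_fit[2], B=10, seed=1)


class TestM2DegreesOfFreedom:
    @pytest.mark.parametrize("g,df", [(18, 135), (3, 0), (5, 5)])
    def test_values(self, g, df):
        assert m2_degrees_of_freedom(g) == df

    def test_too_few_items(self):
        with pytest.raises(ValueError):
            m2_degrees_of_freedom(2)


class TestBenjaminiHochberg:
    def test_monotone_and_bounded(self):
        from hausman_irt import benjamini_hochberg

        p = np.array([0.001, 0.008, 0.039, 0.041, 0.27, 0.6, 0.74, 0.9])
        adj = benjamini_hochberg(p)
        # classic stepped-up values: p_(i) * n / i with running minimum
        assert adj[0] == pytest.approx(0.008)
        assert adj[1] == pytest.approx(0.032)
        assert (adj <= 1.0).all()
        assert (np.diff(adj[np.argsort(p)]) >= -1e-12).all()
        assert (adj >= p - 1e-12).all()
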