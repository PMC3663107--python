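"""EM core: likelihood, E-step, M-step, pseudocounts, full fits.

The independent oracles here are deliberate: the Poisson pmf from
scipy.stats for the likelihood, refined grid search for the E-step, and
an SLSQP simplex-constrained optimizer for the M-step.
"""

import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.stats import poisson

from emsig.em_core import (
    estep,
    fit,
    mstep,
    poisson_loglik,
    pseudocounts,
    total_loglik,
)


def grid_argmin(objective, bounds, step):
    """Coarse-to-fine 2-D grid minimiser (brute-force oracle)."""
    lo = np.array([b[0] for b in bounds], float)
    hi = np.array([b[1] for b in bounds], float)
    cur = step * 100
    best = None
    while cur >= step / 2:
        g0 = np.arange(lo[0], hi[0] + cur, cur)
        g1 = np.arange(lo[1], hi[1] + cur, cur)
        vals = np.array([[objective(np.array([a, b])) for b in g1] for a in g0])
        i, j = np.unravel_index(np.argmin(vals), vals.shape)
        best = np.array([g0[i], g1[j]])
        lo = np.maximum(best - 2 * cur, 0.0)
        hi = best + 2 * cur
        cur /= 10
    return best


class TestPoissonLoglik:
    def test_matches_scipy_pmf(self):
        X = np.array([3.0])
        val = poisson_loglik(X, np.array([3.0]), np.ones(1), np.array([[1.0]]))
        assert val == pytest.approx(poisson.logpmf(3, 3.0))

    def test_empty_counts_zero_activity(self):
        val = poisson_loglik(np.zeros(4), np.zeros(2), np.ones(4),
                             np.full((2, 4), 0.25))
        assert val == 0.0  # Pois(0 | 0) = 1

    def test_lambda_invariance(self, random_signatures):
        mu = random_signatures(2)
        X = np.arange(96, dtype=float)
        om = np.linspace(0.5, 2.0, 96)
        x = np.array([10.0, 20.0])
        a = poisson_loglik(X, x, om, mu)
        b = poisson_loglik(X, 0.5 * x, 2.0 * om, mu)
        assert a == pytest.approx(b, rel=1e-12)

    def test_zero_opportunity_with_counts_rejected(self):
        with pytest.raises(ValueError, match="zero opportunity"):
            poisson_loglik(np.array([1.0, 0.0]), np.array([1.0]),
                           np.array([0.0, 1.0]), np.array([[0.5, 0.5]]))


class TestEstep:
    def test_single_process_closed_form(self):
        x = estep(np.array([3.0, 5.0]), np.ones(2), np.array([[0.5, 0.5]]))
        assert x[0] == pytest.approx(8.0, rel=1e-8)

    def test_disjoint_support_decouples(self):
        mu = np.array([[1.0, 0.0], [0.0, 1.0]])
        x = estep(np.array([4.0, 6.0]), np.ones(2), mu)
        np.testing.assert_allclose(x, [4.0, 6.0], rtol=1e-8)

    def test_overlapping_support_matches_grid_oracle(self):
        mu = np.array([[0.7, 0.3], [0.2, 0.8]])
        X = np.array([9.0, 7.0])
        om = np.array([1.0, 1.0])

        def obj(x):
            lam = x @ (mu * om)
            lam = np.maximum(lam, 1e-300)
            return float((lam - X * np.log(lam)).sum())

        oracle = grid_argmin(obj, [(0, 20), (0, 20)], 0.001)
        x = estep(X, om, mu)
        np.testing.assert_allclose(x, oracle, atol=2e-3)

    def test_kkt_conditions(self, rng, random_signatures):
        mu = random_signatures(3)
        om = rng.lognormal(0, 0.5, 96)
        X = rng.poisson(40.0 * (mu[0] * om) + 10.0 * (mu[2] * om)).astype(float)
        x = estep(X, om, mu)
        G = mu * om[None, :]
        lam = np.maximum(x @ G, 1e-300)
        g = G.sum(axis=1) - G @ (X / lam)
        scale = G.sum(axis=1).max()
        active = x > 1e-8 * max(x.sum(), 1e-300)
        assert (np.abs(g[active]) < 1e-6 * scale).all()
        assert (g[~active] > -1e-6 * scale).all()

    def test_pseudocounts_shift_estimate(self, random_signatures):
        mu = random_signatures(2)
        om = np.ones(96)
        pt = pseudocounts(mu, om)
        # zero data: the penalized optimum carries exactly the pseudocounts
        x = estep(np.zeros(96), om, mu, pseudocounts=pt)
        lam_tot = (x @ (mu * om)).sum()
        assert lam_tot == pytest.approx(pt.sum(), rel=1e-6)


class TestMstep:
    def test_flat_omega_proportions(self):
        mu = mstep(np.array([[3.0, 5.0]]), np.array([[8.0]]), np.ones((1, 2)))
        np.testing.assert_allclose(mu, [[0.375, 0.625]], rtol=1e-10)

    def test_pooled_counts_two_samples(self):
        X = np.array([[3.0, 1.0], [1.0, 3.0]])
        x_hat = np.array([[4.0], [4.0]])
        mu = mstep(X, x_hat, np.ones((2, 2)))
        np.testing.assert_allclose(mu, [[0.5, 0.5]], rtol=1e-10)

    @pytest.mark.parametrize("omega", [[1.0, 2.0], [0.5, 3.0]])
    def test_matches_slsqp_oracle(self, omega):
        X = np.array([[4.0, 4.0]])
        x_hat = np.array([[8.0]])
        om = np.array([omega])
        mu = mstep(X, x_hat, om)

        def neg_ll(m):
            lam = np.maximum(x_hat[0, 0] * m * om[0], 1e-300)
            return float((lam - X[0] * np.log(lam)).sum())

        res = minimize(
            neg_ll, [0.5, 0.5], method="SLSQP", bounds=[(1e-9, 1), (1e-9, 1)],
            constraints=[{"type": "eq", "fun": lambda m: m.sum() - 1}],
            options={"ftol": 1e-14, "maxiter": 500},
        )
        np.testing.assert_allclose(mu[0], res.x, atol=1e-5)

    def test_fixed_point_is_opportunity_normalized_spectrum(self):
        # at the joint EM fixed point mu_j is proportional to X_j / omega_j
        X = np.array([[4.0, 4.0]])
        om = np.array([[1.0, 2.0]])
        mu = np.array([[2.0 / 3.0, 1.0 / 3.0]])
        x_hat = np.array([estep(X[0], om[0], mu)])
        mu_new = mstep(X, x_hat, om, mu_init=mu)
        np.testing.assert_allclose(mu_new, mu, atol=1e-9)

    def test_dead_process_reset_uniform(self):
        X = np.array([[3.0, 5.0]])
        x_hat = np.array([[8.0, 0.0]])
        with pytest.warns(RuntimeWarning, match="zero total activity"):
            mu = mstep(X, x_hat, np.ones((1, 2)))
        np.testing.assert_allclose(mu[1], [0.5, 0.5])


class TestPseudocounts:
    def test_uniform_symmetric_case(self):
        mu = np.full((2, 96), 1.0 / 96)
        pt = pseudocounts(mu, np.ones(96))
        np.testing.assert_allclose(pt, np.full((2, 96), 1.0 / 96), rtol=1e-12)

    def test_total_is_n(self, random_signatures, rng):
        for n in (1, 3, 5):
            mu = random_signatures(n)
            om = rng.lognormal(0, 1, 96)
            assert pseudocounts(mu, om).sum() == pytest.approx(n, abs=1e-9)

    def test_informed_prior_zero_weight(self, random_signatures):
        mu = random_signatures(2)
        pt = pseudocounts(mu, np.ones(96), prior_activities=np.array([1.0, 0.0]))
        assert (pt[1] == 0).all()
        assert pt.sum() == pytest.approx(2.0)

    def test_uniform_prior_is_special_case(self, random_signatures, rng):
        mu = random_signatures(3)
        om = rng.lognormal(0, 0.5, 96)
        np.testing.assert_allclose(
            pseudocounts(mu, om),
            pseudocounts(mu, om, prior_activities=np.ones(3)),
            rtol=1e-12,
        )


class TestFit:
    def test_single_process_recovery_flat_omega(self, rng):
        mu_true = rng.dirichlet(np.full(96, 0.2))
        X = rng.poisson(5000 * mu_true, size=(3, 96)).astype(float)
        om = np.ones((3, 96))
        res = fit(X, om, 1, restarts=2, seed=0)
        pooled = X.sum(axis=0) / X.sum()
        np.testing.assert_allclose(res.mu[0], pooled, atol=1e-6)

    def test_opportunity_absorption_one_process(self, rng):
        # data generated with opportunity; fitting with the true omega
        # recovers mu, fitting flat recovers the omega-tilted spectrum
        mu_true = rng.dirichlet(np.full(96, 0.5))
        om = rng.lognormal(0, 1, 96)
        lam = 3000 * mu_true * om / (mu_true * om).sum()
        X = rng.poisson(np.tile(lam, (4, 1))).astype(float)
        res_om = fit(X, np.tile(om, (4, 1)), 1, restarts=2, seed=0, tol=1e-12)
        res_flat = fit(X, np.ones((4, 96)), 1, restarts=2, seed=0, tol=1e-12)
        pooled = X.sum(axis=0)
        np.testing.assert_allclose(
            res_om.mu[0], (pooled / om) / (pooled / om).sum(), atol=1e-5
        )
        np.testing.assert_allclose(res_flat.mu[0], pooled / pooled.sum(), atol=1e-5)

    def test_monotone_loglik_trace(self, rng, random_signatures):
        mu = random_signatures(3)
        x = rng.lognormal(6, 0.5, size=(6, 3))
        X = rng.poisson(x @ mu).astype(float)
        res = fit(X, np.ones((6, 96)), 3, restarts=3, seed=1)
        assert np.diff(res.loglik_trace).min() > -1e-8

    def test_seeded_determinism_bitwise(self, rng, random_signatures):
        mu = random_signatures(2)
        X = rng.poisson(1000 * mu.sum(axis=0) / 2, size=(4, 96)).astype(float)
        om = np.ones((4, 96))
        r1 = fit(X, om, 2, restarts=3, seed=42)
        r2 = fit(X, om, 2, restarts=3, seed=42)
        assert (r1.mu == r2.mu).all()
        assert (r1.x == r2.x).all()
        assert r1.loglik == r2.loglik

    def test_permutation_equivariance(self, rng, random_signatures):
        mu = random_signatures(2)
        x = rng.lognormal(6, 0.3, size=(5, 2))
        X = rng.poisson(x @ mu).astype(float)
        om = np.ones((5, 96))
        perm = rng.permutation(96)
        r1 = fit(X, om, 2, restarts=2, seed=7, tol=1e-11)
        r2 = fit(X[:, perm], om[:, perm], 2, restarts=2, seed=7, tol=1e-11)
        # process labels are arbitrary: compare after optimal matching
        from emsig.simulate import match_and_score

        m = match_and_score(r1.mu[:, perm], r2.mu)
        order = [j for _, j in sorted(m.pairs)]
        np.testing.assert_allclose(r2.mu[order], r1.mu[:, perm], atol=1e-4)
        scale = r1.x.max()
        np.testing.assert_allclose(r2.x[:, order], r1.x, rtol=1e-3,
                                   atol=1e-4 * scale)

    def test_constant_term_only_shifts_loglik(self, rng, random_signatures):
        mu = random_signatures(2)
        x = rng.lognormal(5, 0.3, size=(3, 2))
        X = rng.poisson(x @ mu).astype(float)
        om = np.ones((3, 96))
        from scipy.special import gammaln

        r_with = fit(X, om, 2, restarts=2, seed=3, include_constant=True)
        r_without = fit(X, om, 2, restarts=2, seed=3, include_constant=False)
        shift = float(gammaln(X + 1).sum())
        assert r_with.loglik == pytest.approx(r_without.loglik - shift, abs=1e-6)
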