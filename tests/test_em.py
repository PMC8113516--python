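import itertools

import numpy as np
import pytest

from cfdecon import em, simulate
from cfdecon.core import CfdnaSamples, ReferencePanel, Site
from cfdecon.em import (
    add_unknowns,
    compute_responsibilities,
    observed_loglik,
    run_em,
    update_alpha,
    update_beta,
)


def _sites(M):
    return [Site("chr1", 1000 * m, 1000 * m + 2) for m in range(M)]


def _panel(Y, D_Y):
    Y = np.asarray(Y)
    return ReferencePanel([f"ct{t}" for t in range(Y.shape[0])], _sites(Y.shape[1]), Y, np.asarray(D_Y))


def _samples(X, D_X):
    X = np.asarray(X)
    return CfdnaSamples([f"s{n}" for n in range(X.shape[0])], _sites(X.shape[1]), X, np.asarray(D_X))


class TestResponsibilities:
    def test_equal_beta_reduces_to_alpha(self):
        # when no cell type is distinguishable at a site, a read's origin
        # posterior is just the prior mixing proportion
        alpha = np.array([[0.2, 0.3, 0.5]])
        beta = np.full((3, 2), 0.4)
        p = compute_responsibilities(alpha, beta).p
        for j in (0, 1):
            np.testing.assert_allclose(p[0, :, 0, j], alpha[0])

    def test_degenerate_beta_assigns_methylated_read_fully(self):
        eps = 1e-12
        alpha = np.array([[0.5, 0.5]])
        beta = np.array([[1 - eps], [eps]])
        p = compute_responsibilities(alpha, beta).p
        np.testing.assert_allclose(p[0, :, 0, 1], [1.0, 0.0], atol=1e-9)

    def test_two_type_arithmetic(self):
        # 0.7*0.8 / (0.7*0.8 + 0.3*0.2) = 0.56/0.62
        alpha = np.array([[0.7, 0.3]])
        beta = np.array([[0.8], [0.2]])
        p = compute_responsibilities(alpha, beta).p
        np.testing.assert_allclose(p[0, :, 0, 1], [0.56 / 0.62, 0.06 / 0.62])
        np.testing.assert_allclose(p[0, :, 0, 0], [0.14 / 0.38, 0.24 / 0.38])

    def test_closure_over_cell_types(self):
        rng = np.random.default_rng(0)
        alpha = rng.dirichlet(np.ones(4), size=3)
        beta = rng.uniform(0.01, 0.99, size=(4, 5))
        p = compute_responsibilities(alpha, beta).p
        np.testing.assert_allclose(p.sum(axis=1), 1.0)
        assert np.all(p >= 0) and np.all(p <= 1)

    def test_nan_rejected(self):
        with pytest.raises(FloatingPointError):
            compute_responsibilities(np.array([[np.nan, 1.0]]), np.full((2, 1), 0.5))


class TestAlphaUpdate:
    def test_one_hot_responsibilities_give_one_hot_alpha(self):
        p = np.zeros((1, 3, 2, 2))
        p[:, 1, :, :] = 1.0
        s = _samples([[3, 1]], [[4, 2]])
        alpha = update_alpha(em.Responsibilities(p), s)
        np.testing.assert_allclose(alpha, [[0.0, 1.0, 0.0]])

    def test_uniform_responsibilities_give_uniform_alpha(self):
        p = np.full((1, 4, 2, 2), 0.25)
        s = _samples([[3, 1]], [[4, 2]])
        np.testing.assert_allclose(update_alpha(em.Responsibilities(p), s), 0.25)

    def test_brute_force_expected_read_counts(self):
        # 2 types, 2 sites: alpha_t proportional to the four expected-count terms
        X = np.array([[3, 1]])
        D = np.array([[4, 2]])
        p = np.zeros((1, 2, 2, 2))
        p[0, 0, :, 1] = [0.9, 0.6]   # methylated-read responsibility, type 0
        p[0, 0, :, 0] = [0.2, 0.5]
        p[0, 1] = 1.0 - p[0, 0]
        expected_t0 = 3 * 0.9 + 1 * 0.2 + 1 * 0.6 + 1 * 0.5
        expected_t1 = 3 * 0.1 + 1 * 0.8 + 1 * 0.4 + 1 * 0.5
        alpha = update_alpha(em.Responsibilities(p), _samples(X, D))
        np.testing.assert_allclose(
            alpha[0], np.array([expected_t0, expected_t1]) / (expected_t0 + expected_t1)
        )

    def test_zero_read_sample_becomes_uniform(self):
        p = np.full((1, 2, 1, 2), 0.5)
        s = _samples([[0]], [[0]])
        with pytest.warns(UserWarning, match="zero total reads"):
            alpha = update_alpha(em.Responsibilities(p), s)
        np.testing.assert_allclose(alpha, 0.5)


class TestBetaUpdate:
    def test_no_cfdna_gives_reference_fraction(self):
        p = np.full((1, 2, 2, 2), 0.5)
        panel = _panel([[2, 3], [1, 4]], [[4, 6], [2, 8]])
        beta = update_beta(em.Responsibilities(p), _samples([[0, 0]], [[0, 0]]), panel)
        np.testing.assert_allclose(beta, panel.Y / panel.D_Y)

    def test_unknown_row_with_full_responsibility_gets_cfdna_fraction(self):
        p = np.zeros((2, 1, 2, 2))
        p[:, 0, :, :] = 1.0
        panel = _panel([[0, 0]], [[0, 0]])
        s = _samples([[2, 1], [4, 3]], [[4, 2], [8, 4]])
        beta = update_beta(em.Responsibilities(p), s, panel)
        np.testing.assert_allclose(beta[0], [(2 + 4) / (4 + 8), (1 + 3) / (2 + 4)])

    def test_term_by_term_single_sample(self):
        p1, p0 = 0.7, 0.4
        X, D = 5, 8
        Y, DY = 3, 10
        p = np.zeros((1, 2, 1, 2))
        p[0, 0, 0] = [p0, p1]
        p[0, 1, 0] = [1 - p0, 1 - p1]
        beta = update_beta(
            em.Responsibilities(p), _samples([[X]], [[D]]), _panel([[Y], [Y]], [[DY], [DY]])
        )
        expect = (p1 * X + Y) / (p0 * (D - X) + DY - Y + p1 * X + Y)
        np.testing.assert_allclose(beta[0, 0], expect)


def _enumeration_loglik(alpha, beta, X, D, Y, DY):
    """Exhaustive sum over every ordered read-origin assignment."""
    T, M = beta.shape
    total = 0.0
    for m in range(M):
        # each of D[m] ordered reads: first X[m] methylated, rest not
        for read in range(D[m]):
            methylated = read < X[m]
            prob = sum(
                alpha[t] * (beta[t, m] if methylated else 1 - beta[t, m])
                for t in range(T)
            )
            total += np.log(prob)
        for t in range(T):
            total += Y[t, m] * np.log(beta[t, m]) + (DY[t, m] - Y[t, m]) * np.log(
                1 - beta[t, m]
            )
    return total


class TestObservedLoglik:
    def test_all_zero_counts_is_zero(self):
        ll = observed_loglik(
            np.array([[0.5, 0.5]]), np.full((2, 2), 0.3),
            _samples([[0, 0]], [[0, 0]]), _panel([[0, 0], [0, 0]], [[0, 0], [0, 0]]),
        )
        assert ll == 0.0

    def test_single_type_collapses_to_binomial_kernel(self):
        beta = np.array([[0.3]])
        ll = observed_loglik(
            np.array([[1.0]]), beta, _samples([[2]], [[5]]), _panel([[4]], [[9]])
        )
        expect = 2 * np.log(0.3) + 3 * np.log(0.7) + 4 * np.log(0.3) + 5 * np.log(0.7)
        np.testing.assert_allclose(ll, expect)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_exhaustive_read_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        T, M = 2, 3
        alpha = rng.dirichlet(np.ones(T))
        beta = rng.uniform(0.1, 0.9, size=(T, M))
        D = rng.integers(0, 5, size=M)
        X = rng.binomial(D, 0.5)
        DY = rng.integers(1, 5, size=(T, M))
        Y = rng.binomial(DY, beta)
        ll = observed_loglik(alpha[None, :], beta, _samples(X[None, :], D[None, :]), _panel(Y, DY))
        np.testing.assert_allclose(ll, _enumeration_loglik(alpha, beta, X, D, Y, DY))


class TestAddUnknowns:
    def test_zero_is_identity(self):
        p = _panel([[1, 2]], [[2, 4]])
        assert add_unknowns(p, 0) is p

    def test_appends_zero_rows_with_labels(self):
        p = add_unknowns(_panel([[1, 2]], [[2, 4]]), 2)
        assert p.cell_types[-2:] == ["unknown_1", "unknown_2"]
        assert p.Y.shape == (3, 2)
        assert p.Y[1:].sum() == 0 and p.D_Y[1:].sum() == 0

    def test_more_unknowns_than_people_warns_but_runs(self):
        with pytest.warns(UserWarning, match="not identified"):
            add_unknowns(_panel([[1, 2]], [[2, 4]]), 3, n_samples=2)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            add_unknowns(_panel([[1]], [[2]]), -1)


class TestRunEm:
    def test_recovers_pure_cell_type_at_high_depth(self):
        rng = np.random.default_rng(5)
        beta = rng.uniform(size=(3, 800))
        alpha = np.array([[1.0, 0.0, 0.0]])
        sites = simulate.make_sites(800)
        panel = simulate.simulate_reference(beta, 1000, seed=1, sites=sites)
        samp = simulate.simulate_mixture(beta, alpha, 1000, seed=2, sites=sites)
        res = run_em(panel, samp, restarts=3, seed=3)
        assert res.alpha[0, 0] > 0.98

    def test_bit_identical_under_fixed_seed(self):
        rng = np.random.default_rng(6)
        beta = rng.uniform(size=(3, 50))
        alpha = np.array([[0.2, 0.3, 0.5]])
        sites = simulate.make_sites(50)
        panel = simulate.simulate_reference(beta, 10, seed=1, sites=sites)
        samp = simulate.simulate_mixture(beta, alpha, 10, seed=2, sites=sites)
        r1 = run_em(panel, samp, restarts=3, seed=9, max_iter=200)
        r2 = run_em(panel, samp, restarts=3, seed=9, max_iter=200)
        np.testing.assert_array_equal(r1.alpha, r2.alpha)
        np.testing.assert_array_equal(r1.beta, r2.beta)
        assert r1.restart_logliks == r2.restart_logliks

    def test_loglik_monotone_within_restart(self):
        # the check_monotone flag raises if the EM ascent property is violated
        rng = np.random.default_rng(7)
        beta = rng.uniform(size=(4, 100))
        alpha = rng.dirichlet(np.ones(4), size=2)
        sites = simulate.make_sites(100)
        panel = simulate.simulate_reference(beta, 8, seed=1, sites=sites)
        samp = simulate.simulate_mixture(beta, alpha, 8, seed=2, sites=sites)
        res = run_em(panel, samp, restarts=4, seed=3, max_iter=300, check_monotone=True)
        assert np.isfinite(res.loglik)

    def test_alpha_rows_on_simplex_and_beta_interior(self):
        rng = np.random.default_rng(8)
        beta = rng.uniform(size=(3, 60))
        alpha = rng.dirichlet(np.ones(3), size=2)
        sites = simulate.make_sites(60)
        panel = simulate.simulate_reference(beta, 5, seed=1, sites=sites)
        samp = simulate.simulate_mixture(beta, alpha, 5, seed=2, sites=sites)
        res = run_em(panel, samp, k_unknowns=1, restarts=2, seed=3, max_iter=200)
        np.testing.assert_allclose(res.alpha.sum(axis=1), 1.0, atol=1e-8)
        assert np.all(res.alpha >= 0)
        assert np.all(res.beta > 0) and np.all(res.beta < 1)

    def test_truth_is_near_fixed_point_at_extreme_depth(self):
        # at ~10^4x the pseudocounted M-step barely moves the true parameters
        rng = np.random.default_rng(9)
        T, M, N = 4, 300, 3
        beta = rng.uniform(0.05, 0.95, size=(T, M))
        alpha = rng.dirichlet(np.ones(T), size=N)
        sites = simulate.make_sites(M)
        panel = simulate.simulate_reference(beta, 1e4, seed=1, sites=sites)
        samp = simulate.simulate_mixture(beta, alpha, 1e4, seed=2, sites=sites)
        pc = 1.0
        work_p = ReferencePanel(panel.cell_types, panel.sites, panel.Y + pc, panel.D_Y + 2 * pc)
        work_s = CfdnaSamples(samp.samples, samp.sites, samp.X + pc, samp.D_X + 2 * pc)
        resp = compute_responsibilities(alpha, beta)
        a1 = update_alpha(resp, work_s)
        b1 = update_beta(resp, work_s, work_p)
        assert np.max(np.abs(a1 - alpha)) < 1e-3
        assert np.max(np.abs(b1 - beta)) < 5e-2  # per-site, noisier than alpha
        # one more step from the updated point moves even less
        resp2 = compute_responsibilities(a1, b1)
        a2 = update_alpha(resp2, work_s)
        assert np.max(np.abs(a2 - a1)) < 1e-3

    def test_beta_recovery_at_high_depth(self):
        # estimated methylation tracks the truth closely at 100x
        from cfdecon.evaluate import pearson_r2

        rng = np.random.default_rng(10)
        beta = rng.uniform(size=(5, 1000))
        alpha = rng.dirichlet(np.ones(5), size=2)
        sites = simulate.make_sites(1000)
        panel = simulate.simulate_reference(beta, 100, seed=1, sites=sites)
        samp = simulate.simulate_mixture(beta, alpha, 100, seed=2, sites=sites)
        res = run_em(panel, samp, restarts=2, seed=3, max_iter=500, ll_interval=5)
        assert pearson_r2(res.beta.ravel(), beta.ravel()) >= 0.95
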