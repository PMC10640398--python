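import math

import numpy as np
import pytest
import scipy.stats

from spanmrf import nb_mixture as nbm
from spanmrf._kernels import HAVE_NUMBA
from spanmrf.nb_mixture import (
    CountMatrix,
    HyperParams,
    MarkerMatrix,
    MixtureParams,
    compute_dispersion,
    compute_log_mean,
    compute_size_factors,
    e_step,
    fit_mixture,
    m_step,
    nb_logpmf,
    q_objective,
)

from conftest import random_mixture_instance


def make_params(delta, beta0, a, b, centers, pi, beta=None):
    """Build MixtureParams from natural-scale values."""
    delta = np.asarray(delta, dtype=float)
    G, K = delta.shape
    return MixtureParams(
        delta_raw=np.log(delta),
        beta0=np.asarray(beta0, dtype=float),
        beta=np.zeros((G, 0)) if beta is None else np.asarray(beta, dtype=float),
        a_raw=nbm._softplus_inv(a),
        b_raw=nbm._softplus_inv(np.maximum(b, 1e-12)),
        pi_raw=np.log(np.asarray(pi, dtype=float)),
        centers=np.asarray(centers, dtype=float),
    )


class TestSizeFactors:
    def test_median_normalization(self):
        Y = np.zeros((3, 2), dtype=int)
        Y[:, 0] = [100, 200, 300]
        assert np.allclose(compute_size_factors(Y), [0.5, 1.0, 1.5])

    def test_equal_totals_give_ones(self):
        Y = np.full((4, 3), 5)
        assert np.allclose(compute_size_factors(Y), 1.0)

    def test_single_spot(self):
        assert np.allclose(compute_size_factors(np.array([[7, 3]])), 1.0)

    def test_zero_spot_raises_with_id(self):
        Y = CountMatrix(np.array([[1, 2], [0, 0]]), spot_ids=["a", "b"])
        with pytest.raises(ValueError, match="b"):
            compute_size_factors(Y)


class TestLogMean:
    def test_all_terms_vanish(self):
        p = make_params([[1.0]], [0.0], [1.0], [0.0], [0.0], [1.0])
        mu = np.exp(compute_log_mean(p, np.ones(2), None, np.zeros((1, 1))))
        assert np.allclose(mu, 1.0)

    def test_marker_boost_product(self):
        # s=2, beta0=ln3, delta=ln5 with rho=1 -> mu = 2*5*3 = 30
        p = make_params([[math.log(5.0)]], [math.log(3.0)], [1.0], [0.0], [0.0],
                        [1.0])
        mu = np.exp(compute_log_mean(p, np.array([2.0]), None, np.ones((1, 1))))
        assert np.allclose(mu, 30.0)

    def test_covariate_multiplies(self):
        p = make_params([[math.log(5.0)]], [math.log(3.0)], [1.0], [0.0], [0.0],
                        [1.0], beta=[[1.0]])
        mu = np.exp(compute_log_mean(p, np.array([2.0]), np.array([[0.5]]),
                                     np.ones((1, 1))))
        assert np.allclose(mu, 30.0 * math.exp(0.5))

    def test_nonpositive_size_factor_rejected(self):
        p = make_params([[1.0]], [0.0], [1.0], [0.0], [0.0], [1.0])
        with pytest.raises(ValueError):
            compute_log_mean(p, np.array([0.0]), None, np.ones((1, 1)))

    def test_marker_monotonicity(self):
        """Flipping rho 0 -> 1 multiplies the mean by exp(delta)."""
        p = make_params([[2.5]], [0.3], [1.0], [0.0], [0.0], [1.0])
        s = np.array([1.3])
        mu0 = np.exp(compute_log_mean(p, s, None, np.zeros((1, 1))))
        mu1 = np.exp(compute_log_mean(p, s, None, np.ones((1, 1))))
        assert np.allclose(mu1 / mu0, math.exp(2.5))
        assert (mu1 > mu0).all()


class TestDispersion:
    def test_flat_rbf(self):
        assert np.allclose(compute_dispersion(np.array([0.5, 9.0]), [2.0], [0.0], [0.0]), 2.0)

    def test_zero_distance_center(self):
        assert np.allclose(compute_dispersion(np.array([3.0]), [1.0], [1.0], [3.0]), 1.0)

    def test_two_center_sum(self):
        # a=(1,1), b=(1,1), centers (0,2), mu=1 -> 2*exp(-1)
        phi = compute_dispersion(np.array([1.0]), [1.0, 1.0], [1.0, 1.0], [0.0, 2.0])
        assert np.allclose(phi, 2.0 * math.exp(-1.0))

    def test_floor_applies(self):
        phi = compute_dispersion(np.array([100.0]), [1.0], [50.0], [0.0])
        assert phi[0] == pytest.approx(nbm.PHI_FLOOR)


class TestNbLogpmf:
    def test_zero_count_closed_form(self):
        assert nb_logpmf(0, 1.0, 1.0) == pytest.approx(math.log(0.5), abs=1e-12)
        mu, phi = 3.7, 2.2
        assert nb_logpmf(0, mu, phi) == pytest.approx(phi * math.log(phi / (phi + mu)))

    def test_matches_scipy_nbinom(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            y = rng.integers(0, 30)
            mu = rng.gamma(3.0)
            phi = rng.gamma(2.0) + 0.05
            ref = scipy.stats.nbinom.logpmf(y, phi, phi / (phi + mu))
            assert nb_logpmf(y, mu, phi) == pytest.approx(ref, rel=1e-10)

    def test_poisson_limit(self):
        ref = scipy.stats.poisson.logpmf(3, 2.0)
        assert abs(nb_logpmf(3, 2.0, 1e6) - ref) < 1e-4

    def test_normalization(self):
        y = np.arange(10001)
        total = np.exp(nb_logpmf(y, 5.0, 2.0)).sum()
        assert total == pytest.approx(1.0, abs=1e-8)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            nb_logpmf(1, -1.0, 1.0)
        with pytest.raises(ValueError):
            nb_logpmf(1, 1.0, 0.0)


def bayes_oracle(Y, params, s, X, rho):
    """Direct Bayes-rule responsibilities via scipy nbinom, no log tricks."""
    mu = np.exp(compute_log_mean(params, s, X, rho))
    phi = compute_dispersion(mu, params.a, params.b, params.centers)
    like = scipy.stats.nbinom.pmf(Y[:, :, None], phi, phi / (phi + mu)).prod(axis=1)
    joint = params.pi[None, :] * like
    return joint / joint.sum(axis=1, keepdims=True)


class TestEStep:
    def test_single_component(self):
        p = make_params([[1.5]], [0.0], [1.0], [0.1], [1.0], [1.0])
        gamma = e_step(np.array([[3], [0]]), p, np.ones(2), None, np.ones((1, 1)))
        assert np.allclose(gamma, 1.0)

    def test_identical_components_split_evenly(self):
        p = make_params([[2.0, 2.0]], [0.1], [1.0], [0.1], [1.0], [0.5, 0.5])
        gamma = e_step(np.array([[3], [1]]), p, np.ones(2), None, np.ones((1, 2)))
        assert np.allclose(gamma, 0.5)

    def test_hand_bayes_two_by_two(self):
        p = make_params([[3.0, 1.2]], [math.log(2.0)], [2.0], [0.0], [0.0],
                        [0.3, 0.7])
        Y = np.array([[8], [0]])
        s = np.array([1.0, 2.0])
        rho = np.ones((1, 2))
        gamma = e_step(Y, p, s, None, rho)
        assert np.allclose(gamma, bayes_oracle(Y, p, s, None, rho), atol=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_oracle_equivalence_random_small(self, seed):
        rng = np.random.default_rng(seed)
        N, G, K = rng.integers(2, 5, size=3)
        Y, rho, X, s, params, hyper = random_mixture_instance(rng, N, G, K)
        gamma = e_step(Y, params, s, X, rho)
        assert np.allclose(gamma, bayes_oracle(Y, params, s, X, rho), atol=1e-12)
        assert np.allclose(gamma.sum(axis=1), 1.0, atol=1e-8)


def q_oracle(Y, gamma, params, s, X, rho, hyper):
    """Term-by-term Q recomputation with explicit loops."""
    mu = np.exp(compute_log_mean(params, s, X, rho))
    phi = compute_dispersion(mu, params.a, params.b, params.centers)
    N, G = Y.shape
    K = gamma.shape[1]
    total = 0.0
    for i in range(N):
        for k in range(K):
            term = math.log(params.pi[k])
            for g in range(G):
                term += float(nb_logpmf(Y[i, g], mu[i, g, k], phi[i, g, k]))
            total += gamma[i, k] * term
    for g in range(G):
        for k in range(K):
            if rho[g, k] == 1:
                d = params.delta_raw[g, k]
                total += (-d - (d - hyper.delta_bar) ** 2 / (2 * hyper.sigma2)
                          - 0.5 * math.log(2 * math.pi * hyper.sigma2))
    total += (math.lgamma(K * hyper.alpha) - K * math.lgamma(hyper.alpha)
              + (hyper.alpha - 1.0) * np.log(params.pi).sum())
    return total


class TestQObjective:
    def test_single_component_equals_loglik_plus_priors(self):
        rng = np.random.default_rng(2)
        Y, rho, X, s, params, hyper = random_mixture_instance(rng, 3, 2, 1)
        gamma = np.ones((3, 1))
        q = q_objective(Y, gamma, params, s, X, rho, hyper)
        ll = nbm.loglik_matrix(Y, params, s, X, rho).sum()
        prior = nbm._delta_log_prior(params.delta_raw, rho, hyper)
        # K=1: pi = 1 so both pi terms vanish
        assert q == pytest.approx(ll + prior, rel=1e-12)

    def test_tiny_instance_term_by_term(self):
        rng = np.random.default_rng(3)
        Y, rho, X, s, params, hyper = random_mixture_instance(rng, 2, 1, 2)
        gamma = e_step(Y, params, s, X, rho)
        q = q_objective(Y, gamma, params, s, X, rho, hyper)
        assert q == pytest.approx(q_oracle(Y, gamma, params, s, X, rho, hyper),
                                  rel=1e-12)

    def test_spot_permutation_invariance(self):
        rng = np.random.default_rng(4)
        Y, rho, X, s, params, hyper = random_mixture_instance(rng, 5, 3, 2)
        gamma = e_step(Y, params, s, X, rho)
        q1 = q_objective(Y, gamma, params, s, X, rho, hyper)
        perm = rng.permutation(5)
        q2 = q_objective(Y[perm], gamma[perm], params, s[perm], X, rho, hyper)
        assert q1 == pytest.approx(q2, rel=1e-12)
        assert q_objective(2 * Y, gamma, params, s, X, rho, hyper) != pytest.approx(q1)


def central_difference(closure, raw, h=1e-5):
    grads = {}
    for key, arr in raw.items():
        g = np.zeros_like(arr)
        flat = arr.ravel()
        for idx in range(flat.size):
            for sign in (+1, -1):
                pert = {k: v.copy() for k, v in raw.items()}
                pert[key].ravel()[idx] += sign * h
                val, _ = closure(pert)
                g.ravel()[idx] += sign * val / (2 * h)
        grads[key] = g
    return grads


def assert_grads_close(analytic, fd, rel=1e-4):
    for key in fd:
        scale = np.maximum(np.abs(fd[key]), 1.0)
        assert np.max(np.abs(analytic[key] - fd[key]) / scale) < rel, key


class TestGradients:
    @pytest.mark.parametrize("P", [0, 2])
    def test_q_gradient_matches_finite_differences(self, P):
        rng = np.random.default_rng(5)
        Y, rho, X, s, params, hyper = random_mixture_instance(rng, 3, 2, 2, P=P)
        gamma = e_step(Y, params, s, X, rho)

        def closure(raw):
            return nbm._q_value_and_grad(raw, Y, gamma, s, X, rho, hyper, params)

        raw = params.free_dict()
        _, analytic = closure(raw)
        assert_grads_close(analytic, central_difference(closure, raw))

    def test_hard_label_gradient_matches_finite_differences(self):
        rng = np.random.default_rng(6)
        Y, rho, X, s, params, hyper = random_mixture_instance(rng, 4, 3, 2)
        z = rng.integers(2, size=4)

        def closure(raw):
            return nbm._l2_value_and_grad(raw, Y, z, s, X, rho, hyper, params)

        raw = params.free_dict(include_pi=False)
        _, analytic = closure(raw)
        assert_grads_close(analytic, central_difference(closure, raw))

    @pytest.mark.skipif(not HAVE_NUMBA, reason="numba unavailable")
    @pytest.mark.parametrize("P", [0, 1])
    def test_fused_kernel_matches_numpy_reference(self, P):
        rng = np.random.default_rng(7)
        Y, rho, X, s, params, hyper = random_mixture_instance(rng, 6, 4, 3, P=P)
        gamma = e_step(Y, params, s, X, rho)
        raw = params.free_dict()
        v1, g1 = nbm._q_value_and_grad(raw, Y, gamma, s, X, rho, hyper, params)
        v2, g2 = nbm._value_and_grad_fused(raw, Y, gamma, s, X, rho, hyper, params)
        assert v2 == pytest.approx(v1, rel=1e-10)
        for key in g1:
            assert np.allclose(g1[key], g2[key], rtol=1e-8, atol=1e-8), key


class TestMStep:
    def test_zero_steps_identity(self):
        rng = np.random.default_rng(8)
        Y, rho, X, s, params, hyper = random_mixture_instance(rng, 3, 2, 2)
        gamma = e_step(Y, params, s, X, rho)
        out, _ = m_step(Y, gamma, params, s, X, rho, hyper, n_grad_steps=0)
        for f in params.__dataclass_fields__:
            assert np.array_equal(getattr(out, f), getattr(params, f))

    def test_q_never_decreases(self):
        rng = np.random.default_rng(9)
        Y, rho, X, s, params, hyper = random_mixture_instance(rng, 6, 3, 2)
        for _ in range(4):
            gamma = e_step(Y, params, s, X, rho)
            q_before = q_objective(Y, gamma, params, s, X, rho, hyper)
            params, q_after = m_step(Y, gamma, params, s, X, rho, hyper,
                                     n_grad_steps=15)
            assert q_after >= q_before - 1e-6

    def test_mean_matching_stationarity(self):
        """With a single component and flat dispersion, gradient ascent on Q
        drives the fitted mean to the sample mean of the counts."""
        rng = np.random.default_rng(10)
        y = rng.poisson(6.0, size=(300, 1))
        rho = np.ones((1, 1))
        hyper = HyperParams(sigma2=100.0, B=1)
        params = make_params([[1.0]], [math.log(y.mean())], [2.0], [1e-9], [0.0],
                             [1.0])
        s = np.ones(300)
        gamma = np.ones((300, 1))
        for _ in range(20):
            params, _ = m_step(y, gamma, params, s, None, rho, hyper,
                               n_grad_steps=30)
        mu_hat = float(np.exp(compute_log_mean(params, s, None, rho))[0, 0, 0])
        assert mu_hat == pytest.approx(y.mean(), rel=1e-2)


class TestFitMixture:
    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(11)
        Y = rng.poisson(4.0, size=(20, 5))
        rho = np.zeros((5, 2))
        rho[:3, 0] = 1
        rho[2:, 1] = 1
        r1 = fit_mixture(Y, rho, seed=3, max_em_iters=4)
        r2 = fit_mixture(Y, rho, seed=3, max_em_iters=4)
        assert np.array_equal(r1[1], r2[1])
        for f in r1[0].__dataclass_fields__:
            assert np.array_equal(getattr(r1[0], f), getattr(r2[0], f))

    def test_single_component_trivial(self):
        rng = np.random.default_rng(12)
        Y = rng.poisson(4.0, size=(10, 3))
        params, gamma, hist = fit_mixture(Y, np.ones((3, 1)), max_em_iters=3)
        assert np.allclose(gamma, 1.0)

    def test_marginal_loglik_monotone(self):
        rng = np.random.default_rng(13)
        Y = rng.poisson(4.0, size=(30, 6))
        rho = np.zeros((6, 2))
        rho[:3, 0] = 1
        rho[3:, 1] = 1
        _, _, hist = fit_mixture(Y, rho, max_em_iters=8, tol=1e-12)
        ll = np.array(hist["loglik"])
        assert (np.diff(ll) >= -1e-6).all()

    def test_strong_signal_recovery(self, strong_signal_dataset):
        from spanmrf.evaluate import score_assignment

        ds, Y, rho = strong_signal_dataset
        _, gamma, _ = fit_mixture(Y, rho, seed=11)
        acc, _, _ = score_assignment(ds.z_true, gamma.argmax(axis=1))
        assert acc >= 0.9
        assert np.allclose(gamma.sum(axis=1), 1.0, atol=1e-8)


class TestMarkerMatrix:
    def test_gene_without_type_rejected(self):
        with pytest.raises(ValueError):
            MarkerMatrix(rho=np.array([[1.0, 0.0], [0.0, 0.0]]))

    def test_non_binary_rejected(self):
        with pytest.raises(ValueError):
            MarkerMatrix(rho=np.array([[0.5, 1.0]]))
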