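"""Unit tests of the configuration-scoring machinery, including the
numeric-integration oracle that arbitrates the closed-form marginal."""

import math

import numpy as np
import pytest
from scipy import integrate
from scipy.stats import invgamma, norm

from bvsa import (
    EdgeConfiguration,
    Hyperparameters,
    SubnetworkProblem,
    log_marginal_posterior,
    log_prior_configuration,
    prior_precision_kernel,
    residual_term_b1,
)
from bvsa.core import SubproblemScorer, all_configurations

from conftest import make_random_subproblem


def make_subproblem(R_i, R_pr):
    R_pr = np.atleast_2d(np.asarray(R_pr, float))
    return SubnetworkProblem(
        node="i",
        candidates=[f"c{j}" for j in range(R_pr.shape[0])],
        R_i=np.asarray(R_i, float),
        R_pr=R_pr,
        experiment_ids=[f"e{k}" for k in range(R_pr.shape[1])],
    )


class TestConfigurationPrior:
    def test_beta_bernoulli_examples(self, hyper):
        # B(1,4)/B(1,2) = 1/2 for the empty set, B(2,3)/B(1,2) = 1/6 per edge
        assert log_prior_configuration(0, 3, hyper) == pytest.approx(np.log(0.5))
        assert log_prior_configuration(1, 3, hyper) == pytest.approx(np.log(1 / 6))

    @pytest.mark.parametrize("n", range(3, 11))
    def test_normalization(self, n, hyper):
        m = n - 1
        total = sum(
            math.comb(m, k) * np.exp(log_prior_configuration(k, n, hyper))
            for k in range(m + 1)
        )
        assert total == pytest.approx(1.0, abs=1e-12)

    def test_out_of_range(self, hyper):
        with pytest.raises(ValueError):
            log_prior_configuration(3, 3, hyper)


class TestPriorPrecisionKernel:
    def test_single_regulator_value(self):
        hyper = Hyperparameters(c=10.0)
        K_inv = prior_precision_kernel(np.array([[2.0, 0.0, 0.0]]), hyper)
        assert K_inv == pytest.approx(np.array([[0.41]]))

    def test_ridge_keeps_rank_deficient_pd(self, hyper):
        row = np.array([1.0, -2.0, 0.5])
        K_inv = prior_precision_kernel(np.vstack([row, row]), hyper)
        eig = np.linalg.eigvalsh(K_inv)
        assert eig.min() >= hyper.lam / hyper.effective_c(3) - 1e-12

    def test_small_ridge_approaches_g_prior(self):
        rng = np.random.default_rng(3)
        R = rng.standard_normal((2, 5))
        hyper = Hyperparameters(c=5.0, lam=1e-9)
        assert np.allclose(
            prior_precision_kernel(R, hyper), (R @ R.T) / 5.0, atol=1e-9
        )


class TestResidualTerm:
    def test_zero_data(self, hyper):
        sub = make_subproblem(np.zeros(4), np.random.default_rng(0).standard_normal((2, 4)))
        for key in all_configurations(2):
            b1 = residual_term_b1(sub, EdgeConfiguration(np.array(key)), hyper)
            assert b1 == pytest.approx(hyper.beta)

    def test_empty_configuration(self, hyper):
        R_i = np.array([1.0, 1.0, 2.0])  # R_i R_i^T = 6
        sub = make_subproblem(R_i, np.ones((1, 3)))
        b1 = residual_term_b1(sub, EdgeConfiguration([0]), hyper)
        assert b1 == pytest.approx(4.0)

    def test_projection_never_increases_b1(self, hyper):
        rng = np.random.default_rng(4)
        for _ in range(20):
            sub = make_random_subproblem(rng)
            empty = residual_term_b1(
                sub, EdgeConfiguration(np.zeros(sub.n_candidates, int)), hyper
            )
            one = np.zeros(sub.n_candidates, int)
            one[0] = 1
            assert residual_term_b1(sub, EdgeConfiguration(one), hyper) <= empty + 1e-12


def _numeric_log_evidence(sub, key, hyper, rho_lim=12.0, n_rho=320, n_u=240):
    """Brute-force marginal likelihood: integrate the Normal likelihood
    against the Normal slab and inverse-gamma noise priors numerically.

    Tensor-product Gauss-Legendre quadrature over the connection
    strengths (finite box) and over u = log(sigma^2) (substitution that
    smooths the inverse-gamma peak); fully independent of the analytic
    marginalization it checks.
    """
    y = sub.R_i
    sel = [j for j, b in enumerate(key) if b]
    c = hyper.effective_c(sub.n_pi)

    u_nodes, u_w = np.polynomial.legendre.leggauss(n_u)
    u_lo, u_hi = -10.0, 6.0
    u = 0.5 * (u_hi - u_lo) * u_nodes + 0.5 * (u_hi + u_lo)
    u_w = u_w * 0.5 * (u_hi - u_lo)
    s2 = np.exp(u)
    ig = invgamma.pdf(s2, hyper.alpha, scale=hyper.beta) * s2  # du Jacobian

    if not sel:
        lik = np.prod(norm.pdf(y[:, None], 0.0, np.sqrt(s2)[None, :]), axis=0)
        return np.log(np.sum(lik * ig * u_w))

    X = sub.R_pr[sel]
    k = len(sel)
    cov_kernel = c * np.linalg.inv(X @ X.T + hyper.lam * np.eye(k))
    kern_inv = np.linalg.inv(cov_kernel)
    det_kern = np.linalg.det(cov_kernel)

    r_nodes, r_w = np.polynomial.legendre.leggauss(n_rho)
    r = rho_lim * r_nodes
    r_w = r_w * rho_lim
    if k == 1:
        rho = r[:, None, None]  # (n_rho, 1, 1)
        resid = y[None, :, None] - rho * X[0][None, :, None]
        ss = np.sum(resid**2, axis=1)  # (n_rho, n_u) after broadcast
        lik = (2 * np.pi * s2[None, :]) ** (-sub.n_pi / 2) * np.exp(
            -0.5 * ss / s2[None, :]
        )
        slab = np.exp(-0.5 * kern_inv[0, 0] * r[:, None] ** 2 / s2[None, :]) / np.sqrt(
            2 * np.pi * s2[None, :] * det_kern
        )
        total = np.einsum("ru,r,u->", lik * slab, r_w, ig * u_w)
        return np.log(total)

    assert k == 2
    R1, R2 = np.meshgrid(r, r, indexing="ij")
    rho = np.stack([R1.ravel(), R2.ravel()], axis=1)  # (m, 2)
    resid = y[None, :] - rho @ X  # (m, n_pi)
    ss = np.sum(resid**2, axis=1)  # (m,)
    quad_form = np.einsum("mi,ij,mj->m", rho, kern_inv, rho)
    w2 = np.outer(r_w, r_w).ravel()
    lik = (2 * np.pi * s2[None, :]) ** (-sub.n_pi / 2) * np.exp(
        -0.5 * ss[:, None] / s2[None, :]
    )
    slab = np.exp(-0.5 * quad_form[:, None] / s2[None, :]) / (
        2 * np.pi * s2[None, :] * np.sqrt(det_kern)
    )
    total = np.einsum("mu,m,u->", lik * slab, w2, ig * u_w)
    return np.log(total)


class TestMarginalPosterior:
    def test_zero_data_empty_config_closed_form(self, hyper):
        sub = make_subproblem(np.zeros(5), np.random.default_rng(5).standard_normal((3, 5)))
        score = log_marginal_posterior(sub, EdgeConfiguration([0, 0, 0]), hyper)
        expected = log_prior_configuration(0, 4, hyper) - (
            hyper.alpha + sub.n_pi / 2
        ) * np.log(hyper.beta)
        assert score.log_score == pytest.approx(expected)
        assert score.b1 == pytest.approx(hyper.beta)

    def test_candidate_permutation_invariance(self, hyper):
        rng = np.random.default_rng(6)
        sub = make_random_subproblem(rng, n=5, n_pi=6)
        key = (1, 0, 1, 0)
        base = log_marginal_posterior(sub, EdgeConfiguration(key), hyper).log_score
        perm = rng.permutation(4)
        sub_p = make_subproblem(sub.R_i, sub.R_pr[perm])
        key_p = tuple(np.array(key)[perm])
        permuted = log_marginal_posterior(sub_p, EdgeConfiguration(key_p), hyper).log_score
        assert permuted == pytest.approx(base, rel=1e-12)

    def test_single_candidate_odds_match_quadrature(self, hyper):
        rng = np.random.default_rng(7)
        R_pr = rng.standard_normal((1, 3))
        sub = make_subproblem(0.8 * R_pr[0] + 0.5 * rng.standard_normal(3), R_pr)
        scorer = SubproblemScorer(sub, hyper)
        impl = scorer.log_score((1,)) - scorer.log_score((0,))
        oracle = (
            _numeric_log_evidence(sub, (1,), hyper)
            + log_prior_configuration(1, 2, hyper)
            - _numeric_log_evidence(sub, (0,), hyper)
            - log_prior_configuration(0, 2, hyper)
        )
        assert np.exp(impl) == pytest.approx(np.exp(oracle), rel=5e-3)

    def test_two_candidate_odds_match_quadrature(self, hyper):
        rng = np.random.default_rng(8)
        R_pr = rng.standard_normal((2, 4))
        sub = make_subproblem(
            0.9 * R_pr[0] - 0.6 * R_pr[1] + 0.4 * rng.standard_normal(4), R_pr
        )
        scorer = SubproblemScorer(sub, hyper)
        impl = scorer.log_score((1, 1)) - scorer.log_score((0, 0))
        oracle = (
            _numeric_log_evidence(sub, (1, 1), hyper)
            + log_prior_configuration(2, 3, hyper)
            - _numeric_log_evidence(sub, (0, 0), hyper)
            - log_prior_configuration(0, 3, hyper)
        )
        assert np.exp(impl) == pytest.approx(np.exp(oracle), rel=5e-3)

    def test_sparsity_prior_dominates_with_zero_data(self, hyper):
        # with no signal and a < b the empty configuration scores highest
        rng = np.random.default_rng(9)
        sub = make_subproblem(np.zeros(6), rng.standard_normal((4, 6)))
        scorer = SubproblemScorer(sub, hyper)
        scores = {k: scorer.log_score(k) for k in all_configurations(4)}
        assert max(scores, key=scores.get) == (0, 0, 0, 0)

    def test_common_scaling_preserves_ordering_after_standardization(self, hyper):
        from bvsa import GlobalResponseMatrix, standardize_rows

        rng = np.random.default_rng(10)
        for _ in range(10):
            R = rng.standard_normal((4, 6))
            orders = []
            for scale in (1.0, 37.5):
                resp = standardize_rows(
                    GlobalResponseMatrix(
                        scale * R, list("abcd"), [f"e{k}" for k in range(6)]
                    )
                )
                sub = make_subproblem(resp.R[0], resp.R[1:])
                scorer = SubproblemScorer(sub, hyper)
                scores = [scorer.log_score(k) for k in all_configurations(3)]
                orders.append(np.argsort(scores))
            assert np.array_equal(orders[0], orders[1])

    def test_length_mismatch_rejected(self, hyper):
        sub = make_subproblem(np.ones(3), np.ones((2, 3)))
        with pytest.raises(ValueError):
            log_marginal_posterior(sub, EdgeConfiguration([1]), hyper)


class TestHyperparameters:
    @pytest.mark.parametrize("kwargs", [{"a": 0}, {"beta": -1}, {"lam": 0}, {"lam": 1.0}, {"c": 0}])
    def test_invalid_rejected(self, kwargs):
        with pytest.raises(ValueError):
            Hyperparameters(**kwargs)

    def test_unit_information_default(self):
        assert Hyperparameters().effective_c(15) == 15.0
        assert Hyperparameters(c=3.0).effective_c(15) == 3.0
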