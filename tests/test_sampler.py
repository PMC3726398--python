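"""Gibbs sampler vs the exact enumeration oracle, plus chain mechanics."""

import numpy as np
import pytest

from bvsa import (
    ChainSettings,
    ChainTrace,
    EdgeConfiguration,
    convergence_report,
    exhaustive_posterior,
    gibbs_update_component,
    posterior_edge_probabilities,
    run_chain,
    run_chains,
)
from bvsa.core import SubproblemScorer, all_configurations, log_prior_configuration
from bvsa.sampler import bernoulli_probability

from conftest import make_random_subproblem
from test_core import make_subproblem


class TestBernoulliUpdate:
    def test_symmetric_scores_give_half(self):
        assert bernoulli_probability(-3.0, -3.0) == 0.5

    def test_extreme_odds_saturate_without_overflow(self):
        assert bernoulli_probability(0.0, -50.0) == pytest.approx(1.0)
        assert bernoulli_probability(-2000.0, 0.0) == pytest.approx(0.0)
        assert bernoulli_probability(0.0, -2000.0) == pytest.approx(1.0)

    def test_single_candidate_long_run_frequency(self, hyper):
        rng = np.random.default_rng(11)
        sub = make_random_subproblem(rng, n=2, n_pi=4)
        scorer = SubproblemScorer(sub, hyper)
        p_exact = bernoulli_probability(scorer.log_score((1,)), scorer.log_score((0,)))
        n_draws = 10_000
        cfg = EdgeConfiguration([0])
        hits = sum(
            int(gibbs_update_component(cfg, 0, scorer, rng=rng).bits[0])
            for _ in range(n_draws)
        )
        se = np.sqrt(p_exact * (1 - p_exact) / n_draws)
        assert abs(hits / n_draws - p_exact) < 3 * se


class TestRunChain:
    def test_single_sweep(self, hyper):
        sub = make_random_subproblem(np.random.default_rng(12))
        trace = run_chain(sub, hyper, ChainSettings(n_iterations=1, seed=0))
        assert trace.samples.shape == (1, sub.n_candidates)
        assert trace.log_scores.shape == (1,)

    def test_seed_determinism(self, hyper):
        sub = make_random_subproblem(np.random.default_rng(13))
        settings = ChainSettings(n_iterations=50, seed=42)
        t1 = run_chain(sub, hyper, settings)
        t2 = run_chain(sub, hyper, settings)
        assert np.array_equal(t1.samples, t2.samples)
        assert np.array_equal(t1.log_scores, t2.log_scores)

    def test_zero_iterations_rejected(self):
        with pytest.raises(ValueError):
            ChainSettings(n_iterations=0)

    def test_empirical_distribution_approaches_enumeration(self, hyper):
        # total-variation gap to the exact posterior shrinks with chain length
        rng = np.random.default_rng(14)
        sub = make_random_subproblem(rng, n=5, n_pi=6)
        _, exact_dist = exhaustive_posterior(sub, hyper)
        tv = {}
        for nts in (100, 10_000):
            trace = run_chain(sub, hyper, ChainSettings(n_iterations=nts, seed=3))
            keys, counts = np.unique(trace.samples, axis=0, return_counts=True)
            emp = {tuple(k): c / nts for k, c in zip(keys, counts)}
            tv[nts] = 0.5 * sum(
                abs(emp.get(k, 0.0) - p) for k, p in exact_dist.items()
            )
        assert tv[10_000] < tv[100]
        assert tv[10_000] < 0.05


class TestPosteriorEdgeProbabilities:
    def test_all_ones(self):
        settings = ChainSettings(n_iterations=10, burn_in_fraction=0.2)
        tr = ChainTrace(np.ones((10, 3), dtype=np.int8), np.zeros(10))
        assert posterior_edge_probabilities([tr], settings) == pytest.approx([1, 1, 1])

    def test_two_chain_average(self):
        # post-burn-in bit sums 30/80 and 50/80 pool to 80/160 = 0.5
        settings = ChainSettings(n_iterations=100, burn_in_fraction=0.2)
        def chain(n_on):
            bits = np.zeros((100, 1), dtype=np.int8)
            bits[:20] = 1  # burned-in samples must not matter
            bits[20 : 20 + n_on] = 1
            return ChainTrace(bits, np.zeros(100))
        p = posterior_edge_probabilities([chain(30), chain(50)], settings)
        assert p[0] == pytest.approx(0.5)

    def test_all_burned_rejected(self):
        settings = ChainSettings(n_iterations=10, burn_in_fraction=0.99)
        tr = ChainTrace(np.ones((5, 2), dtype=np.int8), np.zeros(5))
        with pytest.raises(ValueError):
            posterior_edge_probabilities([tr], settings)

    def test_six_candidate_agreement_with_enumeration(self, hyper):
        rng = np.random.default_rng(15)
        sub = make_random_subproblem(rng, n=7, n_pi=8)
        exact, _ = exhaustive_posterior(sub, hyper)
        settings = ChainSettings(n_chains=5, n_iterations=2000, seed=99)
        p = posterior_edge_probabilities(run_chains(sub, hyper, settings), settings)
        assert np.max(np.abs(p - exact)) <= 0.05


class TestExhaustivePosterior:
    def test_enumeration_size_and_normalization(self, hyper):
        sub = make_random_subproblem(np.random.default_rng(16), n=3, n_pi=4)
        marginals, dist = exhaustive_posterior(sub, hyper)
        assert len(dist) == 4  # 2^(n-1)
        assert sum(dist.values()) == pytest.approx(1.0, abs=1e-12)
        assert np.all((marginals >= 0) & (marginals <= 1))

    def test_cap(self, hyper):
        sub = make_random_subproblem(np.random.default_rng(17), n=6, n_pi=4)
        with pytest.raises(ValueError, match="Gibbs"):
            exhaustive_posterior(sub, hyper, cap=3)

    def test_no_data_reduces_to_prior_marginals(self, hyper):
        # with all responses zero the score is the prior alone
        sub = make_subproblem(np.zeros(4), np.zeros((3, 4)))
        marginals, dist = exhaustive_posterior(sub, hyper)
        logp = {
            k: log_prior_configuration(sum(k), 4, hyper)
            for k in all_configurations(3)
        }
        z = np.logaddexp.reduce(list(logp.values()))
        for k, p in dist.items():
            assert p == pytest.approx(np.exp(logp[k] - z), rel=1e-10)

    def test_stationary_distribution_of_gibbs_kernel(self, hyper):
        # eigen-analysis of the 4x4 sweep kernel for a 2-candidate problem
        rng = np.random.default_rng(18)
        sub = make_random_subproblem(rng, n=3, n_pi=5)
        scorer = SubproblemScorer(sub, hyper)
        states = all_configurations(2)
        T = np.zeros((4, 4))
        for a, start in enumerate(states):
            # one full sweep: update bit 0 then bit 1
            for b0 in (0, 1):
                p0 = bernoulli_probability(
                    scorer.log_score((1, start[1])), scorer.log_score((0, start[1]))
                )
                w0 = p0 if b0 == 1 else 1 - p0
                for b1 in (0, 1):
                    p1 = bernoulli_probability(
                        scorer.log_score((b0, 1)), scorer.log_score((b0, 0))
                    )
                    w1 = p1 if b1 == 1 else 1 - p1
                    T[a, states.index((b0, b1))] += w0 * w1
        evals, evecs = np.linalg.eig(T.T)
        i = np.argmin(np.abs(evals - 1.0))
        pi = np.real(evecs[:, i])
        pi /= pi.sum()
        _, exact_dist = exhaustive_posterior(sub, hyper)
        for k, p in exact_dist.items():
            assert pi[states.index(k)] == pytest.approx(p, abs=1e-10)


class TestConvergenceReport:
    def test_identical_traces_not_flagged(self):
        tr = ChainTrace(np.zeros((50, 2), dtype=np.int8), np.full(50, -3.0))
        rep = convergence_report([tr, tr], ChainSettings(n_iterations=50))
        assert rep.max_pairwise_gap == 0.0
        assert not rep.flagged
        assert all(len(t) == 50 for t in rep.log_score_traces)

    def test_divergent_chains_flagged(self):
        t1 = ChainTrace(np.zeros((50, 2), dtype=np.int8), np.full(50, -3.0))
        t2 = ChainTrace(np.zeros((50, 2), dtype=np.int8), np.full(50, -30.0))
        rep = convergence_report([t1, t2], ChainSettings(n_iterations=50))
        assert rep.flagged

    def test_needs_two_chains(self):
        tr = ChainTrace(np.zeros((5, 1), dtype=np.int8), np.zeros(5))
        with pytest.raises(ValueError):
            convergence_report([tr])

    def test_well_behaved_problem_not_flagged(self, hyper):
        sub = make_random_subproblem(np.random.default_rng(19), n=5, n_pi=8)
        settings = ChainSettings(n_chains=3, n_iterations=400, seed=5)
        rep = convergence_report(run_chains(sub, hyper, settings), settings)
        assert not rep.flagged


def test_longer_chains_shrink_oracle_gap_on_average(hyper):
    """Mean max-entry gap to enumeration over 20 seeded problems does not
    grow when the sweep budget increases tenfold."""
    rng = np.random.default_rng(20)
    gaps = {100: [], 1000: []}
    for _ in range(20):
        sub = make_random_subproblem(rng, n=4, n_pi=6)
        exact, _ = exhaustive_posterior(sub, hyper)
        for nts in gaps:
            settings = ChainSettings(
                n_chains=2, n_iterations=nts, seed=int(rng.integers(2**31))
            )
            p = posterior_edge_probabilities(
                run_chains(sub, hyper, settings), settings
            )
            gaps[nts].append(np.max(np.abs(p - exact)))
    assert np.mean(gaps[1000]) <= np.mean(gaps[100])
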