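"""Posterior approximation over edge configurations.

Two engines: componentwise Gibbs sampling with several independent
chains (the workhorse for networks of any size), and exhaustive
enumeration of all 2^(n-1) configurations (exact, feasible for small
candidate sets, and the oracle the sampler is validated against).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from .core import (
    EdgeConfiguration,
    Hyperparameters,
    SubproblemScorer,
    all_configurations,
)
from .data import SubnetworkProblem

EXHAUSTIVE_CAP = 20


@dataclass
class ChainSettings:
    """Gibbs-chain configuration.

    Defaults follow common practice for clean simulated data: 5 parallel
    chains of 500 sweeps each, with the first 20% discarded as burn-in.
    Noisy data may need more sweeps; real data more still (2000).
    """

    n_chains: int = 5
    n_iterations: int = 500
    burn_in_fraction: float = 0.20
    seed: int | None = None
    sweep_order: str = "ascending"  # or "random"

    def __post_init__(self) -> None:
        if self.n_chains < 1:
            raise ValueError("need at least one chain")
        if self.n_iterations < 1:
            raise ValueError("need at least one iteration")
        if not (0.0 <= self.burn_in_fraction < 1.0):
            raise ValueError("burn_in_fraction must lie in [0, 1)")
        if self.sweep_order not in ("ascending", "random"):
            raise ValueError("sweep_order must be 'ascending' or 'random'")

    @property
    def n_burn_in(self) -> int:
        return int(np.floor(self.burn_in_fraction * self.n_iterations))


@dataclass
class ChainTrace:
    """One chain's recorded samples: one configuration per full sweep."""

    samples: np.ndarray  # NTs x (n-1) binary
    log_scores: np.ndarray  # NTs
    seed: int | None = None

    @property
    def n_sweeps(self) -> int:
        return self.samples.shape[0]


def gibbs_update_component(
    current: EdgeConfiguration,
    j: int,
    subproblem: SubnetworkProblem | SubproblemScorer,
    hyper: Hyperparameters | None = None,
    rng: np.random.Generator | None = None,
) -> EdgeConfiguration:
    """Resample bit j from its full conditional, holding the others fixed.

    The full conditional is Bernoulli with success probability
    p1 / (p1 + p0), where p1 and p0 are the (unnormalized) posterior
    scores with bit j set and unset; evaluated via the logistic of the
    log-score difference so extreme odds cannot overflow.
    """
    if isinstance(subproblem, SubproblemScorer):
        scorer = subproblem
    else:
        if hyper is None:
            raise ValueError("hyper required when passing a raw subproblem")
        scorer = SubproblemScorer(subproblem, hyper)
    if rng is None:
        rng = np.random.default_rng()
    key = list(current.as_key())
    key[j] = 1
    lp1 = scorer.log_score(tuple(key))
    key[j] = 0
    lp0 = scorer.log_score(tuple(key))
    p_on = bernoulli_probability(lp1, lp0)
    return current.with_bit(j, int(rng.random() < p_on))


def bernoulli_probability(lp1: float, lp0: float) -> float:
    """p1/(p1+p0) from log scores, stabilized as 1/(1+exp(lp0-lp1))."""
    d = lp0 - lp1
    if d > 0:
        return float(np.exp(-d) / (1.0 + np.exp(-d)))
    return float(1.0 / (1.0 + np.exp(d)))


def run_chain(
    subproblem: SubnetworkProblem,
    hyper: Hyperparameters,
    settings: ChainSettings,
    init: EdgeConfiguration | None = None,
    rng: np.random.Generator | None = None,
    scorer: SubproblemScorer | None = None,
) -> ChainTrace:
    """Run one Gibbs chain for ``settings.n_iterations`` full sweeps.

    Each sweep resamples every candidate bit (ascending index order by
    default), then records the configuration and its log score.  The
    initial configuration is drawn with independent fair coin flips when
    not supplied, giving overdispersed starts across chains.
    """
    if rng is None:
        rng = np.random.default_rng(settings.seed)
    if scorer is None:
        scorer = SubproblemScorer(subproblem, hyper)
    m = subproblem.n_candidates
    if init is None:
        key = [int(b) for b in rng.integers(0, 2, size=m)]
    else:
        if init.bits.size != m:
            raise ValueError("init configuration length mismatch")
        key = list(init.as_key())
    nts = settings.n_iterations
    samples = np.empty((nts, m), dtype=np.int8)
    log_scores = np.empty(nts)
    for t in range(nts):
        if settings.sweep_order == "random":
            order = rng.permutation(m)
        else:
            order = range(m)
        u = rng.random(m)
        for idx, j in enumerate(order):
            key[j] = 1
            lp1 = scorer.log_score(tuple(key))
            key[j] = 0
            lp0 = scorer.log_score(tuple(key))
            key[j] = int(u[idx] < bernoulli_probability(lp1, lp0))
        samples[t] = key
        log_scores[t] = scorer.log_score(tuple(key))
    return ChainTrace(samples=samples, log_scores=log_scores, seed=settings.seed)


def run_chains(
    subproblem: SubnetworkProblem,
    hyper: Hyperparameters,
    settings: ChainSettings,
    rng: np.random.Generator | None = None,
) -> list[ChainTrace]:
    """Run ``settings.n_chains`` independent chains sharing one scorer cache."""
    if rng is None:
        rng = np.random.default_rng(settings.seed)
    scorer = SubproblemScorer(subproblem, hyper)
    return [
        run_chain(subproblem, hyper, settings, rng=rng, scorer=scorer)
        for _ in range(settings.n_chains)
    ]


def posterior_edge_probabilities(
    traces: list[ChainTrace], settings: ChainSettings
) -> np.ndarray:
    """Average each bit over all chains' post-burn-in samples.

    P_ij = (1 / (N_c (NTs - NTb))) sum_chains sum_{t > NTb} A_ij^(t).
    """
    if not traces:
        raise ValueError("need at least one trace")
    ntb = settings.n_burn_in
    kept = [tr.samples[ntb:] for tr in traces]
    if any(k.shape[0] == 0 for k in kept):
        raise ValueError("burn-in discarded every sample")
    stacked = np.concatenate(kept, axis=0)
    return stacked.mean(axis=0)


def exhaustive_posterior(
    subproblem: SubnetworkProblem,
    hyper: Hyperparameters,
    cap: int = EXHAUSTIVE_CAP,
) -> tuple[np.ndarray, dict[tuple, float]]:
    """Exact posterior by enumerating every configuration.

    Returns the exact marginal edge probabilities and the full normalized
    configuration distribution.  Raises for candidate sets beyond ``cap``
    (2^m configurations become prohibitive); use the Gibbs sampler there.
    """
    m = subproblem.n_candidates
    if m > cap:
        raise ValueError(
            f"{m} candidates exceed the enumeration cap ({cap}); "
            "use the Gibbs sampler instead"
        )
    scorer = SubproblemScorer(subproblem, hyper)
    keys = all_configurations(m)
    logs = np.array([scorer.log_score(k) for k in keys])
    probs = np.exp(logs - logsumexp(logs))
    probs /= probs.sum()
    marginals = np.zeros(m)
    for key, p in zip(keys, probs):
        for j, bit in enumerate(key):
            if bit:
                marginals[j] += p
    return marginals, dict(zip(keys, probs))


@dataclass
class ConvergenceReport:
    """Cross-chain agreement diagnostic on post-burn-in mean log scores."""

    log_score_traces: list[np.ndarray]
    mean_log_scores: np.ndarray
    max_pairwise_gap: float
    tolerance: float
    flagged: bool


def convergence_report(
    traces: list[ChainTrace],
    settings: ChainSettings | None = None,
    tolerance: float = 2.0,
) -> ConvergenceReport:
    """Compare chains' post-burn-in mean log scores; flag large gaps.

    The flag is advisory: chains exploring the same posterior should show
    broadly similar log-score levels, and a large gap suggests one chain
    is stuck.  No automatic remediation is attempted.
    """
    if len(traces) < 2:
        raise ValueError("need at least two chains to compare")
    ntb = settings.n_burn_in if settings is not None else 0
    means = np.array([tr.log_scores[ntb:].mean() for tr in traces])
    gap = float(means.max() - means.min())
    return ConvergenceReport(
        log_score_traces=[tr.log_scores.copy() for tr in traces],
        mean_log_scores=means,
        max_pairwise_gap=gap,
        tolerance=tolerance,
        flagged=gap > tolerance,
    )
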