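"""Marginal posterior score of an edge configuration for one subnetwork.

For node i with responses R_i over the n_pi admissible perturbations and
candidate-regulator block R_pr, an edge configuration A_i (one bit per
candidate) selects a submatrix R_sel of R_pr.  The model is

    R_i = rho . R_sel + eps,      eps_k ~ N(0, sigma^2) iid,
    rho | sigma^2 ~ N(0, V),      V = c sigma^2 (R_sel R_sel^T + lam I)^{-1},
    sigma^2 ~ InverseGamma(alpha, beta),
    A_ij ~ Bernoulli(theta),      theta ~ Beta(a, b),

a spike-and-slab formulation with a ridge-stabilized g-prior slab: the
ridge lam keeps the slab covariance positive definite even when fewer
perturbations than candidate regulators are available, which is what lets
the posterior exist for incomplete perturbation designs.

Both the connection strengths rho and the noise variance sigma^2
integrate out analytically.  Up to a constant shared by all
configurations of one subproblem,

    P(A_i | R)  propto  c^{-n_ki/2} * |G + lam I|^{1/2} / |K^{-1} + G|^{1/2}
                        * b1^{-(alpha + n_pi/2)}
                        * B(a + n_ki, b + (n-1) - n_ki) / B(a, b),

with G = R_sel R_sel^T, K^{-1} = (G + lam I)/c, n_ki = number of selected
regulators, and the residual term

    b1 = beta + 0.5 * (R_i R_i^T - R_i R_sel^T (K^{-1} + G)^{-1} R_sel R_i^T).

Everything is evaluated in log space via Cholesky factorizations.
"""

from __future__ import annotations

from dataclasses import dataclass
import numpy as np
from scipy.linalg import cho_factor, cho_solve
from scipy.special import betaln

from .data import SubnetworkProblem


@dataclass
class Hyperparameters:
    """Prior hyperparameters of the spike-and-slab model.

    a, b : Beta shapes of the sparsity prior on the edge indicators;
        a < b encodes the expectation that networks are sparse.
    alpha, beta : inverse-gamma shape/scale of the noise-variance prior;
        (1, 1) is flat enough to be weakly informative.
    c : g-prior scale; ``None`` means the unit-information choice
        c = n_pi, set per subproblem.
    lam : ridge parameter stabilizing the slab covariance; any value in
        (0, 1) works comparably well.
    """

    a: float = 1.0
    b: float = 2.0
    alpha: float = 1.0
    beta: float = 1.0
    c: float | None = None
    lam: float = 0.1

    def __post_init__(self) -> None:
        for name in ("a", "b", "alpha", "beta"):
            if getattr(self, name) <= 0:
                raise ValueError(f"hyperparameter {name} must be positive")
        if self.c is not None and self.c <= 0:
            raise ValueError("g-prior scale c must be positive")
        if not (0.0 < self.lam < 1.0):
            raise ValueError("ridge parameter lam must lie in (0, 1)")

    def effective_c(self, n_pi: int) -> float:
        return float(self.c) if self.c is not None else float(n_pi)

    def to_dict(self) -> dict:
        return {
            "a": self.a,
            "b": self.b,
            "alpha": self.alpha,
            "beta": self.beta,
            "c": self.c,
            "lambda": self.lam,
        }


@dataclass
class EdgeConfiguration:
    """Binary selection vector over a subproblem's candidate regulators."""

    bits: np.ndarray

    def __post_init__(self) -> None:
        self.bits = np.asarray(self.bits, dtype=np.int8)
        if self.bits.ndim != 1 or not np.isin(self.bits, (0, 1)).all():
            raise ValueError("bits must be a flat 0/1 vector")

    @property
    def n_ki(self) -> int:
        return int(self.bits.sum())

    def with_bit(self, j: int, value: int) -> "EdgeConfiguration":
        bits = self.bits.copy()
        bits[j] = value
        return EdgeConfiguration(bits)

    def as_key(self) -> tuple:
        return tuple(int(x) for x in self.bits)


@dataclass
class MarginalScore:
    """Unnormalized log posterior of one configuration, with diagnostics."""

    log_score: float
    b1: float
    n_ki: int
    n_pi: int


def log_prior_configuration(n_ki: int, n: int, hyper: Hyperparameters) -> float:
    """Log marginal prior of one specific configuration with n_ki edges.

    Integrating the Beta(a, b) sparsity parameter out of the Bernoulli
    indicators gives B(a + n_ki, b + (n-1) - n_ki) / B(a, b) for each
    individual configuration; summed over all 2^(n-1) configurations this
    is a proper distribution.
    """
    m = n - 1
    if not (0 <= n_ki <= m):
        raise ValueError(f"n_ki={n_ki} out of range for {m} candidates")
    return betaln(hyper.a + n_ki, hyper.b + m - n_ki) - betaln(hyper.a, hyper.b)


def prior_precision_kernel(
    R_pr_sel: np.ndarray, hyper: Hyperparameters, n_pi: int | None = None
) -> np.ndarray:
    """sigma^2-free precision kernel K^{-1} = (R_sel R_sel^T + lam I) / c.

    The slab covariance is V = c sigma^2 (R_sel R_sel^T + lam I)^{-1};
    factoring sigma^2 out leaves this kernel, positive definite for any
    lam > 0 even when R_sel is rank deficient.
    """
    R_pr_sel = np.atleast_2d(np.asarray(R_pr_sel, dtype=float))
    if not np.all(np.isfinite(R_pr_sel)):
        raise ValueError("selected regulator block contains non-finite entries")
    if n_pi is None:
        n_pi = R_pr_sel.shape[1]
    c = hyper.effective_c(n_pi)
    G = R_pr_sel @ R_pr_sel.T
    return (G + hyper.lam * np.eye(G.shape[0])) / c


class SubproblemScorer:
    """Memoizing evaluator of the log marginal posterior for one subproblem.

    Precomputes the full candidate Gram matrix once; scoring a
    configuration then only touches the selected submatrix.  Scores are
    cached by bit pattern, so Gibbs sweeps over small candidate sets cost
    at most 2^(n-1) distinct evaluations.
    """

    def __init__(self, subproblem: SubnetworkProblem, hyper: Hyperparameters):
        self.subproblem = subproblem
        self.hyper = hyper
        self.n_pi = subproblem.n_pi
        self.m = subproblem.n_candidates
        self.c = hyper.effective_c(self.n_pi)
        self._G = subproblem.R_pr @ subproblem.R_pr.T
        self._xy = subproblem.R_pr @ subproblem.R_i
        self._yy = float(subproblem.R_i @ subproblem.R_i)
        # log-prior depends on n_ki only; tabulate
        self._logprior = np.array(
            [log_prior_configuration(k, self.m + 1, hyper) for k in range(self.m + 1)]
        )
        self._cache: dict[tuple, tuple[float, float]] = {}

    def score_and_b1(self, key: tuple) -> tuple[float, float]:
        hit = self._cache.get(key)
        if hit is not None:
            return hit
        out = self._evaluate(key)
        self._cache[key] = out
        return out

    def log_score(self, key: tuple) -> float:
        return self.score_and_b1(key)[0]

    def _evaluate(self, key: tuple) -> tuple[float, float]:
        hyper = self.hyper
        k = sum(key)
        expo = hyper.alpha + 0.5 * self.n_pi
        if k == 0:
            b1 = hyper.beta + 0.5 * self._yy
            return float(self._logprior[0] - expo * np.log(b1)), b1
        sel = [j for j, bit in enumerate(key) if bit]
        G = self._G[np.ix_(sel, sel)]
        A = G + hyper.lam * np.eye(k)
        M = A / self.c + G  # K^{-1} + G
        try:
            cA = cho_factor(A, lower=True)
            cM = cho_factor(M, lower=True)
        except np.linalg.LinAlgError as err:  # pragma: no cover - ridge guards this
            cond = np.linalg.cond(M)
            raise np.linalg.LinAlgError(
                f"singular inner matrix despite ridge (cond={cond:.3e})"
            ) from err
        logdet_A = 2.0 * np.sum(np.log(np.diag(cA[0])))
        logdet_M = 2.0 * np.sum(np.log(np.diag(cM[0])))
        xy = self._xy[sel]
        quad = float(xy @ cho_solve(cM, xy))
        b1 = hyper.beta + 0.5 * (self._yy - quad)
        # numerical floor: the projected quadratic form cannot exceed yy
        if b1 < hyper.beta:
            b1 = hyper.beta
        log_score = (
            -0.5 * k * np.log(self.c)
            + 0.5 * logdet_A
            - 0.5 * logdet_M
            - expo * np.log(b1)
            + self._logprior[k]
        )
        return float(log_score), float(b1)


def residual_term_b1(
    subproblem: SubnetworkProblem,
    config: EdgeConfiguration,
    hyper: Hyperparameters,
) -> float:
    """Residual quadratic-form term b1 of the marginal posterior.

    b1 = beta + 0.5 [R_i R_i^T - R_i R_sel^T (K^{-1} + G)^{-1} R_sel R_i^T];
    the empty configuration reduces to beta + 0.5 R_i R_i^T.  Always
    >= beta because the subtracted term is a projection.
    """
    if config.bits.size != subproblem.n_candidates:
        raise ValueError("configuration length does not match candidate count")
    scorer = SubproblemScorer(subproblem, hyper)
    return scorer.score_and_b1(config.as_key())[1]


def log_marginal_posterior(
    subproblem: SubnetworkProblem,
    config: EdgeConfiguration,
    hyper: Hyperparameters,
) -> MarginalScore:
    """Log posterior score of one edge configuration, up to a shared constant.

    Terms independent of the configuration (powers of 2*pi, gamma-function
    factors of the noise prior) are dropped identically for every
    configuration of the same subproblem, so posterior odds and
    normalized posteriors are unaffected.
    """
    if config.bits.size != subproblem.n_candidates:
        raise ValueError("configuration length does not match candidate count")
    scorer = SubproblemScorer(subproblem, hyper)
    log_score, b1 = scorer.score_and_b1(config.as_key())
    return MarginalScore(
        log_score=log_score, b1=b1, n_ki=config.n_ki, n_pi=subproblem.n_pi
    )


def all_configurations(n_candidates: int) -> list[tuple]:
    """All 2^m bit patterns over m candidates, in binary counting order."""
    return [
        tuple((i >> j) & 1 for j in range(n_candidates))
        for i in range(1 << n_candidates)
    ]
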