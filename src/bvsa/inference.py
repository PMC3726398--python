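"""Whole-network inference: per-node posteriors assembled into an edge
probability matrix, and edge calling by thresholding.

Convention throughout: P[i, j] is the posterior probability that node j
directly influences node i (an edge j -> i).  Self-influence is not
modeled; diagonal entries are NaN ("undefined"), never 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import Hyperparameters
from .data import GlobalResponseMatrix, PerturbationDesign, build_subproblem
from .sampler import (
    ChainSettings,
    exhaustive_posterior,
    posterior_edge_probabilities,
    run_chains,
)


@dataclass
class PosteriorEdgeMatrix:
    """n x n matrix of posterior edge probabilities, diagonal undefined."""

    P: np.ndarray
    node_ids: list[str]

    def __post_init__(self) -> None:
        self.P = np.asarray(self.P, dtype=float)
        n = len(self.node_ids)
        if self.P.shape != (n, n):
            raise ValueError("probability matrix must be n x n")
        off = ~np.eye(n, dtype=bool)
        vals = self.P[off]
        if np.any((vals < 0) | (vals > 1)):
            raise ValueError("off-diagonal entries must lie in [0, 1]")

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)


@dataclass
class CalledNetwork:
    """Binary adjacency called from a probability matrix; A[i,j]=1 means j->i."""

    A: np.ndarray
    node_ids: list[str]
    threshold_used: float
    scheme: str


def infer_network(
    resp: GlobalResponseMatrix,
    design: PerturbationDesign,
    hyper: Hyperparameters | None = None,
    settings: ChainSettings | None = None,
    engine: str = "gibbs",
    rng: np.random.Generator | None = None,
) -> PosteriorEdgeMatrix:
    """Infer posterior edge probabilities for every node independently.

    Each node's subnetwork (the node plus its n-1 candidate regulators,
    over the perturbations not targeting it) is scored separately; the
    per-node marginals are assembled into the n x n matrix P.

    Parameters
    ----------
    engine
        ``"gibbs"`` approximates each node's posterior with parallel
        Gibbs chains; ``"exhaustive"`` enumerates all configurations
        (exact, small networks only).
    """
    if hyper is None:
        hyper = Hyperparameters()
    if settings is None:
        settings = ChainSettings()
    if engine not in ("gibbs", "exhaustive"):
        raise ValueError(f"unknown engine {engine!r}")
    if engine == "gibbs" and rng is None:
        rng = np.random.default_rng(settings.seed)
    n = resp.n_nodes
    P = np.full((n, n), np.nan)
    for i, node in enumerate(resp.node_ids):
        sub = build_subproblem(resp, design, node)
        if engine == "exhaustive":
            marginals, _ = exhaustive_posterior(sub, hyper)
        else:
            traces = run_chains(sub, hyper, settings, rng=rng)
            marginals = posterior_edge_probabilities(traces, settings)
        for cand, p in zip(sub.candidates, marginals):
            P[i, resp.node_ids.index(cand)] = p
    return PosteriorEdgeMatrix(P, list(resp.node_ids))


def threshold_probabilities(
    pem: PosteriorEdgeMatrix,
    scheme: str = "mean",
    value: float | None = None,
) -> CalledNetwork:
    """Call edges where P_ij >= p_th.

    Schemes: ``"mean"`` sets p_th to the average off-diagonal posterior
    probability (robust when multicollinearity depresses all
    probabilities below 0.5); ``"mpm"`` is the Median Probability Model,
    p_th = 0.5; ``"fixed"`` uses the supplied ``value``.  Ties at the
    threshold are called as present.
    """
    n = pem.n_nodes
    if n < 2:
        raise ValueError("need at least two nodes to call edges")
    off = ~np.eye(n, dtype=bool)
    if scheme == "mean":
        p_th = float(pem.P[off].mean())
    elif scheme == "mpm":
        p_th = 0.5
    elif scheme == "fixed":
        if value is None or not (0.0 <= value <= 1.0):
            raise ValueError("fixed scheme requires a threshold value in [0, 1]")
        p_th = float(value)
    else:
        raise ValueError(f"unknown thresholding scheme {scheme!r}")
    A = np.zeros((n, n), dtype=np.int8)
    A[off] = (pem.P[off] >= p_th).astype(np.int8)
    return CalledNetwork(A=A, node_ids=list(pem.node_ids), threshold_used=p_th, scheme=scheme)
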