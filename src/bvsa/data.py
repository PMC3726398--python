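"""Perturbation-response data structures and per-node subproblem construction.

Steady-state perturbation experiments are summarised as global response
coefficients: the fractional change of each node's steady-state activity
between the unperturbed baseline and each perturbed condition,

    R_ik = 2 (x_i^k - x_i^0) / (x_i^k + x_i^0),

which lies in (-2, 2].  Modular Response Analysis relates these *global*
responses to the *local* (direct) connection coefficients through linear
orthogonality constraints that, for node i, involve only the experiments
that do not directly target node i.  This module builds the response
matrix, row-standardizes it, and partitions it into the per-node
regression subproblems consumed by the scoring and sampling machinery.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np


class DataError(ValueError):
    """Raised for malformed or degenerate perturbation data."""


@dataclass
class SteadyStateTable:
    """Node x experiment matrix of steady-state activities (arbitrary units).

    Values must be non-negative; the baseline column must be strictly
    positive for response coefficients to be defined.
    """

    values: np.ndarray
    node_ids: list[str]
    experiment_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.node_ids), len(self.experiment_ids)):
            raise DataError(
                f"value matrix shape {self.values.shape} does not match "
                f"{len(self.node_ids)} nodes x {len(self.experiment_ids)} experiments"
            )
        if not np.all(np.isfinite(self.values)):
            raise DataError("steady-state table contains non-finite values")
        if np.any(self.values < 0):
            raise DataError("steady-state activities must be non-negative")


@dataclass
class PerturbationDesign:
    """Maps each perturbation experiment to the single node it directly targets.

    ``efficiency`` optionally records the knockdown efficiency in (0, 1]
    (0.8 means the target's expression is reduced to 20% of baseline);
    ``replicate`` optionally tags repeated perturbations of the same node.
    Multi-target experiments are not representable: each experiment id maps
    to exactly one node, matching the exclusion rule that defines which
    experiments are admissible for each node's subproblem.
    """

    target_of: dict[str, str]
    efficiency: dict[str, float] = field(default_factory=dict)
    replicate: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for exp, eff in self.efficiency.items():
            if not (0.0 < eff <= 1.0):
                raise DataError(
                    f"efficiency for experiment {exp!r} must be in (0, 1], got {eff}"
                )

    @property
    def experiment_ids(self) -> list[str]:
        return list(self.target_of)

    def validate_against(self, node_ids: Sequence[str]) -> None:
        known = set(node_ids)
        for exp, node in self.target_of.items():
            if node not in known:
                raise DataError(
                    f"experiment {exp!r} targets unknown node {node!r}"
                )

    def n_pi(self, node: str) -> int:
        """Number of experiments that do not directly target ``node``."""
        return sum(1 for t in self.target_of.values() if t != node)


@dataclass
class GlobalResponseMatrix:
    """Node x experiment matrix R of global response coefficients."""

    R: np.ndarray
    node_ids: list[str]
    experiment_ids: list[str]
    standardized: bool = False

    def __post_init__(self) -> None:
        self.R = np.asarray(self.R, dtype=float)
        if self.R.shape != (len(self.node_ids), len(self.experiment_ids)):
            raise DataError(
                f"response matrix shape {self.R.shape} does not match labels"
            )
        if not np.all(np.isfinite(self.R)):
            raise DataError("response matrix contains non-finite entries")

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)


@dataclass
class SubnetworkProblem:
    """Per-node inference problem: node i's responses vs its candidate regulators.

    ``R_i`` is the 1 x n_pi response row of the node over the admissible
    experiments (those not directly targeting it); ``R_pr`` stacks the
    (n-1) candidate regulators' responses over the same experiments, in
    the fixed ``candidates`` order.
    """

    node: str
    candidates: list[str]
    R_i: np.ndarray
    R_pr: np.ndarray
    experiment_ids: list[str]

    def __post_init__(self) -> None:
        self.R_i = np.asarray(self.R_i, dtype=float).ravel()
        self.R_pr = np.atleast_2d(np.asarray(self.R_pr, dtype=float))
        if self.R_pr.shape != (len(self.candidates), self.R_i.size):
            raise DataError("subproblem block shapes are inconsistent")
        if self.n_pi < 1:
            raise DataError(
                f"node {self.node!r} has no admissible perturbations (n_pi = 0); "
                "every experiment targets it directly"
            )

    @property
    def n_pi(self) -> int:
        return self.R_i.size

    @property
    def n_candidates(self) -> int:
        return len(self.candidates)


def compute_global_response(x0: float, xk: float) -> float:
    """Global response coefficient of one node to one perturbation.

    Parameters
    ----------
    x0
        Unperturbed steady-state activity (strictly positive).
    xk
        Perturbed steady-state activity (non-negative; 0 means a
        complete knockout of the measured signal).

    Returns
    -------
    float
        2 (xk - x0) / (xk + x0), in (-2, 2].
    """
    if not (np.isfinite(x0) and np.isfinite(xk)):
        raise DataError("non-finite steady-state values")
    if x0 <= 0 or xk < 0:
        raise DataError(f"require x0 > 0 and xk >= 0, got x0={x0}, xk={xk}")
    return 2.0 * (xk - x0) / (xk + x0)


def build_response_matrix(
    states: SteadyStateTable,
    baseline_id: str,
    design: PerturbationDesign,
) -> GlobalResponseMatrix:
    """Apply the response-coefficient formula columnwise against the baseline.

    Every non-baseline column of ``states`` must appear in ``design``.
    The baseline column itself is consumed, not returned.
    """
    if baseline_id not in states.experiment_ids:
        raise DataError(f"baseline column {baseline_id!r} not found in table")
    design.validate_against(states.node_ids)
    b = states.experiment_ids.index(baseline_id)
    x0 = states.values[:, b]
    zero = np.flatnonzero(x0 <= 0)
    if zero.size:
        names = [states.node_ids[i] for i in zero]
        raise DataError(f"baseline activity is zero for node(s) {names}")
    pert_ids = [e for e in states.experiment_ids if e != baseline_id]
    missing = [e for e in pert_ids if e not in design.target_of]
    if missing:
        raise DataError(f"experiments missing from design: {missing}")
    cols = [states.experiment_ids.index(e) for e in pert_ids]
    xk = states.values[:, cols]
    R = 2.0 * (xk - x0[:, None]) / (xk + x0[:, None])
    return GlobalResponseMatrix(R, list(states.node_ids), pert_ids)


def standardize_rows(resp: GlobalResponseMatrix, ddof: int = 0) -> GlobalResponseMatrix:
    """Divide each row by its standard deviation (population convention).

    Equalizes the variability of each node's responses before inference.
    Idempotent: standardizing an already-standardized matrix is a no-op
    up to floating error.  A constant row signals a node whose responses
    carry no information and is rejected.
    """
    sd = resp.R.std(axis=1, ddof=ddof)
    bad = np.flatnonzero(sd == 0)
    if bad.size:
        names = [resp.node_ids[i] for i in bad]
        raise DataError(
            f"row(s) for node(s) {names} are constant; cannot standardize "
            "(uninformative node)"
        )
    return GlobalResponseMatrix(
        resp.R / sd[:, None],
        list(resp.node_ids),
        list(resp.experiment_ids),
        standardized=True,
    )


def build_subproblem(
    resp: GlobalResponseMatrix,
    design: PerturbationDesign,
    node: str,
) -> SubnetworkProblem:
    """Restrict the response matrix to the experiments admissible for ``node``.

    Keeps exactly the columns whose designed target differs from ``node``
    (the orthogonality relations hold only for those), takes the node's
    own row as the regression target and stacks the other nodes' rows as
    the candidate-regulator block.
    """
    if node not in resp.node_ids:
        raise DataError(f"unknown node {node!r}")
    design.validate_against(resp.node_ids)
    keep = [
        j
        for j, e in enumerate(resp.experiment_ids)
        if design.target_of.get(e) != node
    ]
    if not keep:
        raise DataError(
            f"node {node!r} is unidentifiable: every experiment targets it"
        )
    i = resp.node_ids.index(node)
    others = [j for j in range(resp.n_nodes) if j != i]
    return SubnetworkProblem(
        node=node,
        candidates=[resp.node_ids[j] for j in others],
        R_i=resp.R[i, keep],
        R_pr=resp.R[np.ix_(others, keep)],
        experiment_ids=[resp.experiment_ids[j] for j in keep],
    )
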