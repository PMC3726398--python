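"""MRA baselines built on the same orthogonality relations.

Deterministic total-least-squares MRA recovers the connection
coefficients r_ij exactly from noise-free data (given enough independent
perturbations), and its Monte-Carlo "stochastic MRA" wrapper propagates
measurement uncertainty through repeated TLS solves followed by outlier
trimming, a Z-test per coefficient, and Benjamini-Hochberg correction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm
from statsmodels.stats.multitest import multipletests

from .data import DataError, GlobalResponseMatrix, PerturbationDesign

# relative singular-value cutoff used for the rank precondition
_RANK_RTOL = 1e-10


class RankDeficiencyError(DataError):
    """The admissible-perturbation system cannot pin down a node's regulators."""


@dataclass
class ConnectionCoefficientMatrix:
    """n x n local response coefficients; diagonal fixed at -1 by convention."""

    r: np.ndarray
    node_ids: list[str]

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        n = len(self.node_ids)
        if self.r.shape != (n, n):
            raise ValueError("coefficient matrix must be n x n")


@dataclass
class StochasticMraResult:
    """Per-coefficient Monte-Carlo summary and hypothesis-test calls."""

    node_ids: list[str]
    mean: np.ndarray
    sd: np.ndarray
    n_retained: np.ndarray
    p_value: np.ndarray
    p_adjusted: np.ndarray
    identifiable: np.ndarray
    sign: np.ndarray  # +1 activating, -1 inhibitory, 0 undecided
    called: np.ndarray
    n_failed_realizations: int = 0
    var_cutoff_used: float = float("nan")
    extras: dict = field(default_factory=dict)


def tlsr_connection_coefficients(
    resp: GlobalResponseMatrix, design: PerturbationDesign
) -> ConnectionCoefficientMatrix:
    """Solve the orthogonality relations per node by total least squares.

    For node i the relations say sum_{j != i} r_ij R_jk = R_ik over the
    admissible experiments k (those not targeting i).  The TLS solution
    comes from the smallest right singular vector of the stacked system
    [R_pr^T | R_i^T]: normalizing its last component to -1 yields the
    row r_i with the MRA convention r_ii = -1.  Requires the admissible
    response block to have rank >= n-1; rank deficiency is the stated
    failure mode of deterministic MRA on incomplete designs.
    """
    n = resp.n_nodes
    r = np.full((n, n), 0.0)
    np.fill_diagonal(r, -1.0)
    for i, node in enumerate(resp.node_ids):
        keep = [
            k
            for k, e in enumerate(resp.experiment_ids)
            if design.target_of.get(e) != node
        ]
        if len(keep) < n - 1:
            raise RankDeficiencyError(
                f"node {node!r}: only {len(keep)} admissible perturbations "
                f"for {n - 1} unknowns; system is rank deficient"
            )
        others = [j for j in range(n) if j != i]
        # stacked system rows over admissible k: [R_jk (j != i), R_ik]
        M = np.column_stack([resp.R[np.ix_(others, keep)].T, resp.R[i, keep]])
        # full SVD: when n_pi = n-1 the TLS direction is the null vector,
        # which the economy factorization does not return
        _, s, Vt = np.linalg.svd(M, full_matrices=True)
        if s[0] == 0 or np.sum(s / s[0] > _RANK_RTOL) < n - 1:
            raise RankDeficiencyError(
                f"node {node!r}: admissible system has rank "
                f"{int(np.sum(s / max(s[0], 1e-300) > _RANK_RTOL))} < {n - 1}"
            )
        v = Vt[-1]
        if abs(v[-1]) < 1e-12:
            raise RankDeficiencyError(
                f"node {node!r}: TLS solution is degenerate (no finite r row)"
            )
        row = -v[:-1] / v[-1]
        r[i, others] = row
    return ConnectionCoefficientMatrix(r=r, node_ids=list(resp.node_ids))


def stochastic_mra(
    R_mean: GlobalResponseMatrix,
    R_std: np.ndarray,
    design: PerturbationDesign,
    n_realizations: int = 10_000,
    outlier_frac: float = 0.01,
    var_cutoff: float | None = None,
    fdr: float = 0.05,
    seed: int | None = None,
) -> StochasticMraResult:
    """Monte-Carlo MRA with outlier trimming, Z-test, and BH correction.

    Draws ``n_realizations`` Gaussian response matrices (elementwise mean
    ``R_mean.R``, sd ``R_std``), solves each by TLS, trims
    ``outlier_frac`` extreme values per coefficient (half per tail),
    flags coefficients whose post-trim variance exceeds ``var_cutoff`` as
    unidentifiable (default cutoff: 25x the median post-trim variance),
    Z-tests the rest against zero and applies Benjamini-Hochberg at
    level ``fdr``.  Sign calls follow the majority of retained
    realizations.
    """
    R_std = np.asarray(R_std, dtype=float)
    if R_std.shape != R_mean.R.shape:
        raise ValueError("R_std shape must match the response matrix")
    if np.any(R_std < 0):
        raise ValueError("R_std must be elementwise non-negative")
    if n_realizations < 100:
        raise ValueError("need at least 100 realizations")
    rng = np.random.default_rng(seed)
    n = R_mean.n_nodes
    draws = np.full((n_realizations, n, n), np.nan)
    n_failed = 0
    for t in range(n_realizations):
        noisy = GlobalResponseMatrix(
            R_mean.R + rng.standard_normal(R_mean.R.shape) * R_std,
            list(R_mean.node_ids),
            list(R_mean.experiment_ids),
            standardized=R_mean.standardized,
        )
        try:
            draws[t] = tlsr_connection_coefficients(noisy, design).r
        except RankDeficiencyError:
            n_failed += 1
    if n_failed > 0.5 * n_realizations:
        raise RuntimeError(
            f"{n_failed}/{n_realizations} TLS realizations failed; aborting"
        )

    off = ~np.eye(n, dtype=bool)
    mean = np.zeros((n, n))
    sd = np.zeros((n, n))
    n_ret = np.zeros((n, n), dtype=int)
    variance = np.full((n, n), np.nan)
    sign = np.zeros((n, n), dtype=np.int8)
    per_tail = outlier_frac / 2.0
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            vals = draws[:, i, j]
            vals = np.sort(vals[np.isfinite(vals)])
            k_trim = int(round(per_tail * vals.size))
            kept = vals[k_trim : vals.size - k_trim] if k_trim else vals
            mean[i, j] = kept.mean()
            sd[i, j] = kept.std(ddof=1) if kept.size > 1 else 0.0
            n_ret[i, j] = kept.size
            variance[i, j] = sd[i, j] ** 2
            frac_neg = np.mean(kept < 0)
            sign[i, j] = -1 if frac_neg > 0.5 else 1
    if var_cutoff is None:
        # floor keeps a degenerate (noise-free) run from zeroing the cutoff
        var_cutoff = max(25.0 * float(np.median(variance[off])), 1e-12)
    identifiable = off & (variance <= var_cutoff)

    # Z-test on the Monte-Carlo distribution: is the mean far from 0
    # relative to the spread of the realizations?
    # sd at rounding level means a degenerate (noise-free) Monte Carlo
    sd_floor = 1e-12 * np.maximum(1.0, np.abs(mean))
    p = np.full((n, n), np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(
            sd > sd_floor,
            np.abs(mean) / sd,
            np.where(np.abs(mean) > 1e-9, np.inf, 0.0),
        )
    p[identifiable] = 2.0 * norm.sf(z[identifiable])

    p_adj = np.full((n, n), np.nan)
    called = np.zeros((n, n), dtype=bool)
    idx = np.flatnonzero(identifiable.ravel())
    if idx.size:
        rej, adj, _, _ = multipletests(p.ravel()[idx], alpha=fdr, method="fdr_bh")
        p_adj.ravel()[idx] = adj
        called.ravel()[idx] = rej
    return StochasticMraResult(
        node_ids=list(R_mean.node_ids),
        mean=mean,
        sd=sd,
        n_retained=n_ret,
        p_value=p,
        p_adjusted=p_adj,
        identifiable=identifiable,
        sign=sign,
        called=called,
        n_failed_realizations=n_failed,
        var_cutoff_used=float(var_cutoff),
    )
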