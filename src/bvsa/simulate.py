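"""Synthetic networks and perturbation-response datasets.

The generator emulates the statistical structure of steady-state
knockdown studies on signaling modules: a sparse directed signed
network with saturating activation kinetics, knockdowns that scale a
node's production capacity, optional intrinsic noise integrated with a
Milstein scheme, and a log-linear measurement-error model in which the
log-scale error variance is

    sigma_e^2 = alpha_b + beta_s * exp(-Y),

with Y the log signal intensity: a background floor alpha_b plus a
signal-dependent component beta_s that dominates for weak signals.

Node dynamics.  Each node i carries an activity x_i with production
capacity T_i (the expression level of the module's protein; knockdown
with efficiency e scales T_i to (1 - e) T_i) and evolves as

    dx_i/dt = T_i * v_i * drive_i(x) - d_i * x_i,

    drive_i(x) = (b_i + sum_act w_ij s(x_j)) / (1 + sum_inh w_ij s(x_j)),

with saturating occupancy s(x) = x / (K + x).  Production is
proportional to capacity and decay is linear, so an isolated
constitutive node's steady state scales exactly with its capacity:
an 80%-efficient knockdown leaves it at 20% of baseline.  These are
deliberately generic module-level kinetics, not any particular
published reaction scheme.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

from .data import DataError, PerturbationDesign, SteadyStateTable

_STEADY_TOL = 1e-9  # max |dx/dt| / max(|x|, floor) at the accepted point


class SimulationError(RuntimeError):
    """Raised when a simulated system fails to reach a usable steady state."""


@dataclass
class NoiseSpec:
    """Noise configuration: measurement error (alpha_b, beta_s) and
    intrinsic-noise intensity sde_scale (0 disables the SDE path)."""

    alpha_b: float = 0.0
    beta_s: float = 0.0
    sde_scale: float = 0.0

    def __post_init__(self) -> None:
        if self.alpha_b < 0 or self.beta_s < 0 or self.sde_scale < 0:
            raise ValueError("noise parameters must be non-negative")


@dataclass
class NetworkModel:
    """Signed directed network with saturating-kinetics dynamics.

    ``adjacency[i, j]`` is +1 / -1 / 0 for j activating / inhibiting /
    not directly affecting i; the diagonal is zero.  ``weights`` carries
    the corresponding positive edge strengths.
    """

    adjacency: np.ndarray
    weights: np.ndarray
    capacity: np.ndarray  # T_i, production capacity
    rate: np.ndarray  # v_i
    decay: np.ndarray  # d_i
    saturation: np.ndarray  # K_i, half-occupancy constant of s(x_j) terms
    basal: np.ndarray  # b_i, constitutive drive
    node_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.adjacency = np.asarray(self.adjacency, dtype=int)
        n = self.adjacency.shape[0]
        if self.adjacency.shape != (n, n):
            raise ValueError("adjacency must be square")
        if np.any(np.diag(self.adjacency) != 0):
            raise ValueError("self-edges are not modeled; diagonal must be 0")
        if not self.node_ids:
            self.node_ids = [f"n{i}" for i in range(n)]
        for arr in ("weights",):
            a = np.asarray(getattr(self, arr), dtype=float)
            setattr(self, arr, a)
        for arr in ("capacity", "rate", "decay", "saturation", "basal"):
            setattr(self, arr, np.asarray(getattr(self, arr), dtype=float))

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    def dxdt(self, x: np.ndarray, capacity: np.ndarray | None = None) -> np.ndarray:
        T = self.capacity if capacity is None else capacity
        s = x / (self.saturation + x)
        act = np.where(self.adjacency > 0, self.weights, 0.0) @ s
        inh = np.where(self.adjacency < 0, self.weights, 0.0) @ s
        drive = (self.basal + act) / (1.0 + inh)
        return T * self.rate * drive - self.decay * x

    def with_knockdown(self, node_index: int, efficiency: float) -> np.ndarray:
        """Capacity vector with one node's production scaled to (1-e)."""
        T = self.capacity.copy()
        T[node_index] *= 1.0 - efficiency
        return T


def steady_state(
    model: NetworkModel,
    capacity: np.ndarray | None = None,
    x0: np.ndarray | None = None,
    max_time: float = 5e4,
) -> np.ndarray:
    """Deterministic steady state by ODE relaxation.

    Integrates until max |dx/dt| / max(|x|, 1e-12) < 1e-9, in doubling
    time chunks; raises if the criterion is not met within ``max_time``.
    """
    n = model.n_nodes
    x = np.full(n, 1e-3) if x0 is None else np.asarray(x0, dtype=float).copy()
    t_chunk = 50.0
    elapsed = 0.0
    while elapsed < max_time:
        sol = solve_ivp(
            lambda t, y: model.dxdt(np.maximum(y, 0.0), capacity),
            (0.0, t_chunk),
            x,
            method="LSODA",
            rtol=1e-10,
            atol=1e-12,
        )
        if not sol.success:
            raise SimulationError(f"ODE integration failed: {sol.message}")
        x = np.maximum(sol.y[:, -1], 0.0)
        elapsed += t_chunk
        resid = np.abs(model.dxdt(x, capacity))
        scale = np.maximum(np.abs(x), 1e-12)
        if np.max(resid / scale) < _STEADY_TOL or np.max(resid) < 1e-14:
            return x
        t_chunk *= 2.0
    raise SimulationError("steady state not reached within the time budget")


def _is_stable(model: NetworkModel, x: np.ndarray, h: float = 1e-6) -> bool:
    """Numerical Jacobian at x; stable iff all eigenvalue real parts < 0."""
    n = model.n_nodes
    J = np.empty((n, n))
    f0 = model.dxdt(x)
    for j in range(n):
        xp = x.copy()
        step = h * max(abs(x[j]), 1.0)
        xp[j] += step
        J[:, j] = (model.dxdt(xp) - f0) / step
    return bool(np.all(np.linalg.eigvals(J).real < 0))


def generate_random_network(
    n: int,
    edge_density: float,
    seed: int | None = None,
    activating_fraction: float = 0.7,
    max_retries: int = 50,
) -> NetworkModel:
    """Random sparse signed network with a verified stable positive baseline.

    Edges appear independently with probability ``edge_density``; signs
    are activating with probability ``activating_fraction``.  Kinetic
    parameters are resampled until the baseline steady state exists and
    is linearly stable.
    """
    if n < 2:
        raise ValueError("need at least two nodes")
    if not (0.0 < edge_density < 1.0):
        raise ValueError("edge_density must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    for _ in range(max_retries):
        adj = np.zeros((n, n), dtype=int)
        off = ~np.eye(n, dtype=bool)
        present = rng.random((n, n)) < edge_density
        signs = np.where(rng.random((n, n)) < activating_fraction, 1, -1)
        adj[off & present] = signs[off & present]
        weights = np.where(adj != 0, rng.uniform(0.5, 2.0, (n, n)), 0.0)
        model = NetworkModel(
            adjacency=adj,
            weights=weights,
            capacity=np.ones(n),
            rate=rng.uniform(0.5, 1.5, n),
            decay=rng.uniform(0.5, 1.5, n),
            saturation=rng.uniform(0.3, 0.8, n),
            basal=rng.uniform(0.1, 0.5, n),
        )
        try:
            x = steady_state(model)
        except SimulationError:
            continue
        if np.all(x > 0) and _is_stable(model, x):
            return model
    raise SimulationError(
        f"no stable parameterization found in {max_retries} attempts"
    )


def mapk_fixture() -> NetworkModel:
    """Six-module MAPK cascade with three negative feedbacks.

    Modules: receptor -> adapter -> initiator -> MAP3K -> MAP2K -> MAPK
    (five activating cascade edges), plus inhibitory feedback from the
    terminal MAPK module onto the adapter, MAP3K, and MAP2K modules
    (ERK-type inactivation of SOS, of Raf activation, and activation of
    MEK phosphatases).  Parameters are fixed values chosen for a stable,
    strictly positive baseline in which the negative feedbacks are
    functionally strong: the terminal module's half-saturation constant
    keeps its feedback interactions in their sensitive range, so the
    feedback local-response coefficients (about -0.33) are comparable in
    magnitude to the cascade edges (0.19-0.32) — the defining property
    of this pathway rather than a decorative annotation.
    """
    names = ["receptor", "adapter", "initiator", "map3k", "map2k", "mapk"]
    n = 6
    adj = np.zeros((n, n), dtype=int)
    for child, parent in [(1, 0), (2, 1), (3, 2), (4, 3), (5, 4)]:
        adj[child, parent] = 1
    for target in (1, 3, 4):  # negative feedback from the MAPK module
        adj[target, 5] = -1
    weights = np.zeros((n, n))
    weights[adj == 1] = 2.0
    weights[adj == -1] = 3.0
    # concentration scale ~100 a.u.: typical of quantitative proteomic
    # intensities, so the signal-dependent part of the log-linear error
    # model matters for weak signals rather than dominating everywhere
    scale = 100.0
    return NetworkModel(
        adjacency=adj,
        weights=weights,
        capacity=np.full(n, scale),
        rate=np.array([1.0, 1.2, 1.2, 1.2, 1.2, 1.2]),
        decay=np.array([1.0, 0.8, 0.8, 0.8, 0.8, 0.8]),
        saturation=np.array([0.5, 0.5, 0.5, 0.5, 0.5, 4.0]) * scale,
        basal=np.array([1.0, 0.05, 0.05, 0.05, 0.05, 0.05]),
        node_ids=names,
    )


def add_measurement_error(
    values: np.ndarray, alpha_b: float, beta_s: float, rng: np.random.Generator
) -> np.ndarray:
    """Log-linear measurement error: Gaussian in log space with variance
    alpha_b + beta_s * exp(-Y), Y = log(value)."""
    values = np.asarray(values, dtype=float)
    if np.any(values <= 0):
        raise DataError("measurement error is defined for positive signals only")
    if alpha_b == 0 and beta_s == 0:
        return values.copy()
    Y = np.log(values)
    var = alpha_b + beta_s * np.exp(-Y)
    return np.exp(Y + rng.standard_normal(values.shape) * np.sqrt(var))


def milstein_steady_state(
    model: NetworkModel,
    sde_scale: float,
    capacity: np.ndarray | None = None,
    horizon: float = 200.0,
    dt: float = 0.01,
    seed: int | None = None,
    transient_fraction: float = 0.5,
    x0: np.ndarray | None = None,
) -> np.ndarray:
    """Stochastic steady state as the post-transient time average.

    Integrates dx = f(x) dt + g(x) dW with multiplicative noise
    g(x) = sde_scale * x per node, using the Milstein update
    x += f dt + g dW + 0.5 g g' (dW^2 - dt) with g'(x) = sde_scale.
    States are reflected at zero.  Returns the average over the final
    (1 - transient_fraction) of the horizon.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    rng = np.random.default_rng(seed)
    x = steady_state(model, capacity) if x0 is None else np.asarray(x0, float).copy()
    n_steps = int(np.ceil(horizon / dt))
    n_transient = int(transient_fraction * n_steps)
    acc = np.zeros(model.n_nodes)
    count = 0
    sqdt = np.sqrt(dt)
    for step in range(n_steps):
        dw = rng.standard_normal(model.n_nodes) * sqdt
        f = model.dxdt(x, capacity)
        g = sde_scale * x
        x = x + f * dt + g * dw + 0.5 * g * sde_scale * (dw * dw - dt)
        x = np.abs(x)  # reflecting boundary at 0
        if not np.all(np.isfinite(x)) or np.any(x > 1e9):
            raise SimulationError("SDE trajectory diverged")
        if step >= n_transient:
            acc += x
            count += 1
    return acc / count


def simulate_knockdown_responses(
    model: NetworkModel,
    efficiencies: tuple[float, ...] = (0.4, 0.6, 0.8),
    noise: NoiseSpec | None = None,
    seed: int | None = None,
    baseline_id: str = "baseline",
    sde_horizon: float = 200.0,
    sde_dt: float = 0.01,
    noisy_baseline: bool = False,
) -> tuple[SteadyStateTable, PerturbationDesign]:
    """Knock down every node at every efficiency and record steady states.

    Each perturbation scales the targeted node's production capacity to
    (1 - e) of baseline, re-solves the network to steady state (ODE, or
    Milstein time average when ``noise.sde_scale > 0``), and applies the
    log-linear measurement error to the perturbation measurements.  The
    returned table includes the unperturbed reference column; by default
    that column is the model's exact baseline (it still fluctuates when
    intrinsic SDE noise is enabled), since in a simulation study the
    unperturbed state is known rather than re-measured — set
    ``noisy_baseline=True`` to re-measure it with error like any other
    column.  The design maps each perturbation column to its target with
    its efficiency.
    """
    if noise is None:
        noise = NoiseSpec()
    for e in efficiencies:
        if not (0.0 < e <= 1.0):
            raise ValueError(f"efficiency {e} outside (0, 1]")
    rng = np.random.default_rng(seed)
    n = model.n_nodes
    columns: list[np.ndarray] = []
    exp_ids: list[str] = [baseline_id]
    target_of: dict[str, str] = {}
    efficiency: dict[str, float] = {}
    replicate: dict[str, int] = {}

    def _solve(capacity: np.ndarray | None, label: str) -> np.ndarray:
        try:
            if noise.sde_scale > 0:
                return milstein_steady_state(
                    model,
                    noise.sde_scale,
                    capacity,
                    horizon=sde_horizon,
                    dt=sde_dt,
                    seed=int(rng.integers(2**31)),
                )
            return steady_state(model, capacity)
        except SimulationError as err:
            raise SimulationError(f"perturbation {label!r}: {err}") from err

    columns.append(_solve(None, baseline_id))
    for i, node in enumerate(model.node_ids):
        for rep, e in enumerate(efficiencies, start=1):
            label = f"{node}_kd{int(round(100 * e))}"
            cap = model.with_knockdown(i, e)
            columns.append(_solve(cap, label))
            exp_ids.append(label)
            target_of[label] = node
            efficiency[label] = e
            replicate[label] = rep
    values = np.column_stack(columns)
    if noise.alpha_b > 0 or noise.beta_s > 0:
        lo = 0 if noisy_baseline else 1
        if np.any(values[:, lo:] <= 0):
            bad = exp_ids[lo + int(np.argwhere(values[:, lo:] <= 0)[0][1])]
            raise SimulationError(
                f"perturbation {bad!r} produced a zero signal; the log-scale "
                "measurement-error model needs strictly positive values"
            )
        values[:, lo:] = add_measurement_error(
            values[:, lo:], noise.alpha_b, noise.beta_s, rng
        )
    table = SteadyStateTable(values, list(model.node_ids), exp_ids)
    design = PerturbationDesign(target_of, efficiency, replicate)
    return table, design


def local_response_coefficients(
    model: NetworkModel, rel_step: float = 1e-6
) -> np.ndarray:
    """Finite-difference local response matrix at the baseline steady state.

    Relative (log-scale) sensitivities, matching the fractional global
    response definition: r_ij = (d ln x_i / d ln x_j) with all other
    nodes clamped, computed from the rate Jacobian as
    r_ij = -(J_ij x_j) / (J_ii x_i); diagonal -1 by convention.
    Nonzero exactly where a direct edge exists; used to validate that
    noise-free simulated responses satisfy the MRA relations.
    """
    x = steady_state(model)
    n = model.n_nodes
    J = np.empty((n, n))
    f0 = model.dxdt(x)
    for j in range(n):
        xp = x.copy()
        step = rel_step * max(abs(x[j]), 1.0)
        xp[j] += step
        J[:, j] = (model.dxdt(xp) - f0) / step
    r = -(J * x[None, :]) / (np.diag(J) * x)[:, None]
    np.fill_diagonal(r, -1.0)
    return r
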