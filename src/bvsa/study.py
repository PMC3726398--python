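"""Reproducible simulation-study protocols on the MAPK-cascade fixture.

These functions bundle the full pipelines used to characterize the
method: repeated inference on the noise-free 18-perturbation knockdown
design, measurement-noise sweeps over the (alpha_b, beta_s) grid, and
incomplete-perturbation designs where only a subset of modules can be
targeted.  Each returns plain summary statistics so callers (tests,
scripts, notebooks) can assert or report without re-plumbing the
pipeline.
"""

from __future__ import annotations

import numpy as np

from .core import Hyperparameters
from .data import (
    PerturbationDesign,
    SteadyStateTable,
    SubnetworkProblem,
    build_response_matrix,
    standardize_rows,
)
from .evaluate import repeated_run_summary, sweep_and_areas
from .inference import infer_network
from .sampler import ChainSettings
from .simulate import add_measurement_error, mapk_fixture, simulate_knockdown_responses


def random_subproblem(
    rng: np.random.Generator,
    n: int | None = None,
    n_pi: int | None = None,
    noise_sd: float = 0.4,
) -> SubnetworkProblem:
    """Random per-node inference problem with a genuinely sparse signal.

    Candidate responses are iid standard normal; the target row depends
    on a random subset of at most three candidates plus Gaussian noise.
    Used for sampler-vs-enumeration calibration, where only the internal
    consistency of the posterior matters, not biological provenance.
    """
    if n is None:
        n = int(rng.integers(3, 7))
    if n_pi is None:
        n_pi = int(rng.integers(2, 9))
    m = n - 1
    R_pr = rng.standard_normal((m, n_pi))
    k = int(rng.integers(0, min(3, m) + 1))
    coef = np.zeros(m)
    if k:
        sel = rng.choice(m, size=k, replace=False)
        coef[sel] = rng.uniform(0.5, 1.5, k) * rng.choice([-1.0, 1.0], k)
    R_i = coef @ R_pr + noise_sd * rng.standard_normal(n_pi)
    return SubnetworkProblem(
        node="target",
        candidates=[f"c{j}" for j in range(m)],
        R_i=R_i,
        R_pr=R_pr,
        experiment_ids=[f"e{j}" for j in range(n_pi)],
    )


def mapk_truth() -> np.ndarray:
    """Binary reference adjacency of the cascade fixture."""
    return (mapk_fixture().adjacency != 0).astype(int)


def mapk_clean_study(
    n_repetitions: int = 100,
    settings: ChainSettings | None = None,
    rng: np.random.Generator | None = None,
    hyper: Hyperparameters | None = None,
):
    """Repeat Gibbs-based inference on the noise-free knockdown design.

    The dataset (6 modules x 3 knockdown efficiencies, 18 perturbations)
    is fixed; repetitions differ only in the sampler's random numbers,
    so the spread of AUROC/AUPR measures robustness to Monte-Carlo
    approximation error.
    """
    if settings is None:
        settings = ChainSettings(n_chains=5, n_iterations=200)
    if rng is None:
        rng = np.random.default_rng(settings.seed)
    model = mapk_fixture()
    truth = (model.adjacency != 0).astype(int)
    table, design = simulate_knockdown_responses(model, (0.4, 0.6, 0.8))
    resp = standardize_rows(build_response_matrix(table, "baseline", design))
    results = []
    for _ in range(n_repetitions):
        pem = infer_network(resp, design, hyper, settings, engine="gibbs", rng=rng)
        results.append(sweep_and_areas(pem.P, truth))
    return repeated_run_summary(results)


def mapk_noise_study(
    alpha_b: float,
    beta_s: float,
    n_replicates: int = 50,
    settings: ChainSettings | None = None,
    rng: np.random.Generator | None = None,
    hyper: Hyperparameters | None = None,
):
    """Repeated inference under log-linear measurement error.

    The deterministic steady states are computed once; every replicate
    draws fresh measurement errors on the perturbation columns, rebuilds
    and re-standardizes the response matrix, and infers the network.
    """
    if settings is None:
        settings = ChainSettings(n_chains=5, n_iterations=500)
    if rng is None:
        rng = np.random.default_rng(settings.seed)
    model = mapk_fixture()
    truth = (model.adjacency != 0).astype(int)
    table, design = simulate_knockdown_responses(model, (0.4, 0.6, 0.8))
    results = []
    for _ in range(n_replicates):
        values = table.values.copy()
        values[:, 1:] = add_measurement_error(values[:, 1:], alpha_b, beta_s, rng)
        noisy = SteadyStateTable(values, table.node_ids, table.experiment_ids)
        resp = standardize_rows(build_response_matrix(noisy, "baseline", design))
        pem = infer_network(resp, design, hyper, settings, engine="gibbs", rng=rng)
        results.append(sweep_and_areas(pem.P, truth))
    return repeated_run_summary(results)


def mapk_incomplete_study(
    targets: tuple[str, ...] = ("map3k", "map2k", "mapk"),
    efficiency: float = 0.8,
    alpha_b: float = 0.01,
    beta_s: float = 0.1,
    n_replicates: int = 50,
    rng: np.random.Generator | None = None,
    hyper: Hyperparameters | None = None,
    engine: str = "exhaustive",
    settings: ChainSettings | None = None,
):
    """Inference when only a subset of modules can be perturbed.

    One knockdown per listed target, no replicate experiments; each
    replicate draws fresh measurement errors.  The exact enumeration
    engine is the default: at six modules the full posterior is cheap
    and removes sampler noise from an already information-poor design.
    """
    if rng is None:
        rng = np.random.default_rng()
    model = mapk_fixture()
    truth = (model.adjacency != 0).astype(int)
    table, design = simulate_knockdown_responses(model, (efficiency,))
    keep = ["baseline"] + [
        e for e in table.experiment_ids if design.target_of.get(e, "") in targets
    ]
    cols = [table.experiment_ids.index(e) for e in keep]
    sub_design = PerturbationDesign(
        {e: design.target_of[e] for e in keep if e != "baseline"},
        {e: design.efficiency[e] for e in keep if e != "baseline"},
    )
    base = table.values[:, cols]
    results = []
    for _ in range(n_replicates):
        values = base.copy()
        values[:, 1:] = add_measurement_error(values[:, 1:], alpha_b, beta_s, rng)
        noisy = SteadyStateTable(values, table.node_ids, keep)
        resp = standardize_rows(build_response_matrix(noisy, "baseline", sub_design))
        pem = infer_network(
            resp, sub_design, hyper, settings, engine=engine, rng=rng
        )
        results.append(sweep_and_areas(pem.P, truth))
    return repeated_run_summary(results)
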