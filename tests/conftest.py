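import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from bvsa import (
    Hyperparameters,
    SubnetworkProblem,
    build_response_matrix,
    mapk_fixture,
    simulate_knockdown_responses,
    standardize_rows,
)

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def hyper():
    return Hyperparameters()


def make_random_subproblem(rng, n=None, n_pi=None, signal=True):
    """Random per-node problem: candidate responses plus a target row that
    truly depends on a sparse subset of candidates."""
    if n is None:
        n = int(rng.integers(3, 7))
    if n_pi is None:
        n_pi = int(rng.integers(2, 9))
    m = n - 1
    R_pr = rng.standard_normal((m, n_pi))
    if signal:
        k = int(rng.integers(0, min(3, m) + 1))
        coef = np.zeros(m)
        if k:
            sel = rng.choice(m, size=k, replace=False)
            coef[sel] = rng.uniform(0.5, 1.5, k) * rng.choice([-1, 1], k)
        R_i = coef @ R_pr + 0.4 * rng.standard_normal(n_pi)
    else:
        R_i = rng.standard_normal(n_pi)
    return SubnetworkProblem(
        node="target",
        candidates=[f"c{j}" for j in range(m)],
        R_i=R_i,
        R_pr=R_pr,
        experiment_ids=[f"e{k}" for k in range(n_pi)],
    )


@pytest.fixture(scope="session")
def mapk_model():
    return mapk_fixture()


@pytest.fixture(scope="session")
def mapk_clean_dataset(mapk_model):
    """Noise-free 18-perturbation knockdown dataset of the MAPK cascade."""
    table, design = simulate_knockdown_responses(mapk_model, (0.4, 0.6, 0.8))
    return table, design


@pytest.fixture(scope="session")
def mapk_clean_responses(mapk_clean_dataset):
    table, design = mapk_clean_dataset
    resp = standardize_rows(build_response_matrix(table, "baseline", design))
    return resp, design
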