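"""Shared fixtures: random compositional datasets and cached benchmark runs."""

import numpy as np
import pytest

from cnode import CNODEModel, MicrobiomeDataset, TaxonSet
from cnode.benchmarks import run_glv_benchmark


def random_dataset(N: int, S: int, seed: int = 0) -> MicrobiomeDataset:
    """Random dataset with random supports and Dirichlet-like compositions."""
    rng = np.random.default_rng(seed)
    Z = np.zeros((S, N), dtype=np.int8)
    P = np.zeros((S, N))
    for k in range(S):
        z = (rng.random(N) < 0.6).astype(np.int8)
        if not z.any():
            z[rng.integers(N)] = 1
        w = rng.gamma(1.0, size=N) * z
        Z[k] = z
        P[k] = w / w.sum()
    return MicrobiomeDataset.from_matrices(TaxonSet.generic(N), P, Z=Z)


def random_assemblage(rng: np.random.Generator, N: int) -> np.ndarray:
    z = (rng.random(N) < 0.5).astype(np.int8)
    if not z.any():
        z[rng.integers(N)] = 1
    return z


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture
def small_dataset() -> MicrobiomeDataset:
    return random_dataset(6, 10, seed=3)


@pytest.fixture
def small_model() -> CNODEModel:
    return CNODEModel.initialize(6, seed=7)


@pytest.fixture(scope="session")
def capacity_runs():
    """Three seeded train/test runs of the scaled-down GLV learning task
    (N=10, C=0.5, sigma=0.1, S_train=2N): shared by the learning-capacity
    checks so the training cost is paid once."""
    return [run_glv_benchmark(seed) for seed in range(3)]
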