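import numpy as np
import pytest

from ssgrn import (
    ExpressionDataset,
    GAConfig,
    NoiseSpec,
    SSystemParams,
    add_noise,
    benchmark_5gene,
    benchmark_trajectory,
    simulate,
)


@pytest.fixture(scope="session")
def benchmark_params():
    return benchmark_5gene()


@pytest.fixture(scope="session")
def benchmark_traj():
    return benchmark_trajectory()


@pytest.fixture(scope="session")
def noise_free_dataset(benchmark_traj):
    """Single-replicate noise-free benchmark dataset."""
    return ExpressionDataset(
        time_grid=benchmark_traj.time_grid, replicates=benchmark_traj.values[None]
    )


@pytest.fixture(scope="session")
def noisy_dataset(benchmark_traj):
    """Three replicates at 5% multiplicative noise."""
    return add_noise(benchmark_traj, NoiseSpec(percent=0.05, n_replicates=3, seed=42))


@pytest.fixture(scope="session")
def two_gene_system():
    """A tiny ground-truth system (G1 represses G2) and its noise-free data."""
    params = SSystemParams(
        alpha=np.array([6.0, 8.0]),
        beta=np.array([9.0, 7.0]),
        G=np.array([[0.0, 0.0], [2.0, 0.0]]),
    )
    grid = np.linspace(0.0, 0.25, 8)
    traj = simulate(params, np.array([0.3, 0.8]), grid)
    data = ExpressionDataset(time_grid=grid, replicates=traj.values[None])
    return params, data


@pytest.fixture
def fast_config():
    """Small GA budget for smoke-level identification tests."""
    return GAConfig(
        tol=1e-5, population_size=12, generations=15, seed=11, n_restarts=2
    )
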