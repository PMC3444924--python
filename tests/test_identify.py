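"""Lower-level fitting, GA objective and bi-level search behaviour."""

import numpy as np
import pytest

from ssgrn import (
    ConnectivityMatrix,
    ExpressionDataset,
    GAConfig,
    SSystemParams,
    exhaustive_identify,
    fit_continuous,
    fitness,
    identify,
    simulate,
)


def test_fitness_penalty_identities():
    lam7 = ConnectivityMatrix.from_edges(5, [(i, (i + 1) % 5) for i in range(5)] + [(0, 2), (1, 3)])
    cfg = GAConfig(tol=0.1, penalty_weight=100.0)
    assert fitness(lam7, chi=0.1, config=cfg) == 7.0  # boundary of feasibility
    assert fitness(lam7, chi=0.2, config=cfg) == 107.0  # zeta = 1
    lam9 = ConnectivityMatrix.from_edges(5, [(i, j) for i in range(3) for j in range(3)])
    assert fitness(lam9, chi=0.05, config=cfg) == 9.0  # strictly feasible
    assert fitness(lam9, chi=np.inf, config=cfg) > 1e6  # diverged candidate


def test_default_penalty_outweighs_sparsity_gain():
    cfg = GAConfig(tol=0.1)
    assert cfg.effective_penalty(5) == 25.0


def test_all_zero_connectivity_rejected(noise_free_dataset, fast_config):
    with pytest.raises(ValueError, match="1 <= sum"):
        fit_continuous(ConnectivityMatrix(np.zeros((5, 5), int)), noise_free_dataset, fast_config)


def test_one_gene_rate_constants_recovered_from_closed_form_data():
    """Closed-form linear-ODE data: fit must recover (alpha, beta) within 1e-3."""
    alpha, beta, x0 = 7.0, 4.0, 0.25
    grid = np.linspace(0.0, 1.0, 12)
    exact = alpha / beta + (x0 - alpha / beta) * np.exp(-beta * grid)
    data = ExpressionDataset(time_grid=grid, replicates=exact[None, :, None])
    # the only admissible 1-gene pattern is the self-edge; with g_11 fitted
    # near 0 the dynamics reduce to the linear ODE
    lam = ConnectivityMatrix(np.array([[1]]))
    fit = fit_continuous(lam, data, GAConfig(tol=1e-5, seed=3))
    assert fit.chi < 1e-5
    assert fit.alpha[0] == pytest.approx(alpha, abs=1e-2)
    assert fit.beta[0] == pytest.approx(beta, abs=1e-2)
    assert abs(fit.rho[0, 0]) < 1e-2


def test_true_topology_fit_recovers_benchmark_parameters(
    benchmark_params, noise_free_dataset
):
    """Fitting the true 7-edge pattern on noise-free data recovers Tables-level accuracy."""
    lam = ConnectivityMatrix(benchmark_params.connectivity())
    fit = fit_continuous(lam, noise_free_dataset, GAConfig(tol=1e-5, seed=0))
    assert fit.converged
    assert fit.chi < 1e-5
    assert np.abs(fit.rho - benchmark_params.G).max() < 0.05
    assert np.abs(fit.alpha - benchmark_params.alpha).max() < 0.05
    assert np.abs(fit.beta - benchmark_params.beta).max() < 0.05
    # masked entries stay exactly zero in the assembled G
    assert np.all(fit.rho[benchmark_params.G == 0] == 0.0)


def test_fit_deterministic_given_seed(two_gene_system):
    params, data = two_gene_system
    lam = ConnectivityMatrix(params.connectivity())
    cfg = GAConfig(tol=1e-5, seed=21)
    a = fit_continuous(lam, data, cfg)
    b = fit_continuous(lam, data, cfg)
    assert a.chi == b.chi
    assert np.array_equal(a.rho, b.rho)


def test_exhaustive_identify_finds_single_true_connection(two_gene_system):
    params, data = two_gene_system
    cfg = GAConfig(tol=1e-5, seed=2, n_restarts=2)
    net = exhaustive_identify(data, cfg)
    assert net.feasible
    assert net.edges() == frozenset({(1, 0)})
    assert net.n_connections == 1


def test_exhaustive_identify_rejects_large_systems(noise_free_dataset, fast_config):
    with pytest.raises(ValueError, match="n <= 3"):
        exhaustive_identify(noise_free_dataset, fast_config)


def test_ga_matches_exhaustive_oracle_on_two_gene_system(two_gene_system):
    params, data = two_gene_system
    cfg = GAConfig(tol=1e-5, seed=4, population_size=10, generations=12, n_restarts=2)
    oracle = exhaustive_identify(data, cfg)
    net = identify(data, cfg)
    phi_net = fitness(net.lam, net.fit.chi, cfg)
    phi_oracle = fitness(oracle.lam, oracle.fit.chi, cfg)
    assert net.feasible
    assert phi_net == phi_oracle == oracle.n_connections


def test_identify_trace_non_increasing_and_deterministic(two_gene_system):
    params, data = two_gene_system
    cfg = GAConfig(tol=1e-5, seed=9, population_size=8, generations=10, n_restarts=2)
    a = identify(data, cfg)
    b = identify(data, cfg)
    assert a.per_generation_best == b.per_generation_best
    assert np.array_equal(a.lam.lam, b.lam.lam)
    trace = np.array(a.per_generation_best)
    assert np.all(np.diff(trace) <= 0)
    assert a.feasible == (a.fit.chi <= cfg.tol)


def test_identify_with_infinite_tolerance_returns_single_connection(two_gene_system):
    """With tol = inf every pattern is feasible, so the optimum is the sparsest."""
    params, data = two_gene_system
    cfg = GAConfig(tol=1e30, seed=6, population_size=10, generations=10, n_restarts=1)
    net = identify(data, cfg)
    assert net.n_connections == 1
    assert net.feasible


def test_infeasible_problem_flagged_not_crashed():
    """Data no sparse S-system can fit at tiny tol -> best-effort, feasible=False."""
    rng = np.random.default_rng(0)
    grid = np.linspace(0.0, 1.0, 6)
    values = rng.uniform(0.2, 1.0, size=(1, 6, 2))
    data = ExpressionDataset(time_grid=grid, replicates=values)
    cfg = GAConfig(tol=1e-9, seed=1, population_size=6, generations=4, n_restarts=1)
    net = identify(data, cfg)
    assert not net.feasible
    assert net.fit.chi > cfg.tol
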