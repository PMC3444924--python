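"""Bootstrap resampling, ensemble frequencies and robust-edge extraction."""

import numpy as np
import pytest
from scipy.stats import chisquare

from ssgrn import (
    ConnectivityMatrix,
    ExpressionDataset,
    GAConfig,
    NoiseSpec,
    add_noise,
    bootstrap_resample,
    ensemble_identify,
    frequency_convergence,
    robust_edges,
    sensitivity_sweep,
)
from ssgrn.identify import FitResult, IdentifiedNetwork
from ssgrn.robustness import NetworkEnsemble


def _fake_network(edges, n=3, feasible=True, g=1.5, chi=0.01):
    lam = ConnectivityMatrix.from_edges(n, edges)
    rho = np.zeros((n, n))
    for i, j in edges:
        rho[i, j] = g
    fit = FitResult(
        rho=rho, alpha=np.full(n, 2.0), beta=np.full(n, 3.0),
        chi=chi, converged=True,
    )
    return IdentifiedNetwork(
        lam=lam, fit=fit, per_generation_best=(1.0,), feasible=feasible, seed=0
    )


@pytest.fixture
def toy_ensemble():
    """10 networks: edge A in all, edge B in 6, edge C in 2."""
    nets = []
    for k in range(10):
        edges = {(0, 1)}
        if k < 6:
            edges.add((1, 2))
        if k < 2:
            edges.add((2, 0))
        nets.append(_fake_network(edges, g=1.0 + 0.1 * k))
    return NetworkEnsemble.from_networks(nets)


def test_single_replicate_bootstrap_copies_input(benchmark_traj):
    data = add_noise(benchmark_traj, NoiseSpec(percent=0.05, n_replicates=1, seed=0))
    with pytest.warns(UserWarning, match="single replicate"):
        samples = bootstrap_resample(data, 3, seed=1)
    for s in samples:
        assert np.array_equal(s.replicates, data.replicates)


def test_identical_replicates_give_identical_bootstrap(benchmark_traj):
    base = add_noise(benchmark_traj, NoiseSpec(percent=0.0, n_replicates=3, seed=0))
    samples = bootstrap_resample(base, 4, seed=7)
    for s in samples:
        assert np.array_equal(s.replicates, base.replicates)


def test_bootstrap_preserves_shape_and_draws_whole_gene_vectors(noisy_dataset):
    samples = bootstrap_resample(noisy_dataset, 5, seed=3)
    pool = {tuple(noisy_dataset.replicates[k, t]) for k in range(3) for t in range(10)}
    for s in samples:
        assert s.replicates.shape == noisy_dataset.replicates.shape
        for k in range(s.n_replicates):
            for t in range(s.n_times):
                assert tuple(s.replicates[k, t]) in pool


def test_bootstrap_index_distribution_is_multinomial(noisy_dataset):
    """Per-time-point replicate draws follow multinomial(r, uniform)."""
    samples = bootstrap_resample(noisy_dataset, 400, seed=5)
    r = noisy_dataset.n_replicates
    counts = np.zeros(r)
    t = 0
    for s in samples:
        for k in range(r):
            for orig in range(r):
                if np.array_equal(s.replicates[k, t], noisy_dataset.replicates[orig, t]):
                    counts[orig] += 1
                    break
    res = chisquare(counts)
    assert res.pvalue > 0.01


def test_bootstrap_rejects_bad_n_boot(noisy_dataset):
    with pytest.raises(ValueError):
        bootstrap_resample(noisy_dataset, 0, seed=1)


def test_frequency_matrix_matches_direct_recount(toy_ensemble):
    ens = toy_ensemble
    for (i, j), expect in {(0, 1): 1.0, (1, 2): 0.6, (2, 0): 0.2}.items():
        recount = sum(net.lam.lam[i, j] for net in ens.networks) / ens.n_boot
        assert ens.freq[i, j] == pytest.approx(expect)
        assert ens.freq[i, j] == pytest.approx(recount)
    # permutation invariance
    perm = NetworkEnsemble.from_networks(ens.networks[::-1])
    assert np.array_equal(perm.freq, ens.freq)


def test_threshold_shrinkage_is_monotone(toy_ensemble):
    sizes = [
        len(robust_edges(toy_ensemble, threshold=t).edges)
        for t in (0.05, 0.3, 0.45, 0.7, 1.0)
    ]
    assert sizes == sorted(sizes, reverse=True)
    assert robust_edges(toy_ensemble, threshold=1.0).edges == {(0, 1)}


def test_confidence_intervals_bracket_mean_and_widen(toy_ensemble):
    narrow = robust_edges(toy_ensemble, threshold=0.4, confidence_level=0.5)
    wide = robust_edges(toy_ensemble, threshold=0.4, confidence_level=0.95)
    for edge, (mean, lo, hi) in narrow.param_estimates.items():
        assert lo <= mean <= hi
        wlo, whi = wide.param_estimates[edge][1:]
        assert whi - wlo >= hi - lo
    for name in ("alpha", "beta"):
        for mean, lo, hi in narrow.rate_estimates[name].values():
            assert lo <= mean <= hi


def test_frequency_convergence_recount_and_degenerate_spread(toy_ensemble):
    block_freqs, spread = frequency_convergence(toy_ensemble, block_size=5)
    assert block_freqs.shape == (2, 3, 3)
    # independent recount of the first block
    manual = int(sum(net.lam.lam[1, 2] for net in toy_ensemble.networks[:5])) * 100 / 5
    assert block_freqs[0, 1, 2] == manual
    assert spread[0, 1] == 0.0  # unanimous edge has zero spread
    same = NetworkEnsemble.from_networks([_fake_network({(0, 1)})] * 8)
    _, spread0 = frequency_convergence(same, block_size=4)
    assert np.all(spread0 == 0.0)
    with pytest.raises(ValueError):
        frequency_convergence(toy_ensemble, block_size=6)


def test_sensitivity_sweep_limit_cases(toy_ensemble):
    truth = ConnectivityMatrix.from_edges(3, {(0, 1), (1, 2)})
    table = sensitivity_sweep(toy_ensemble, [0.05, 0.45, 0.95, 1.0], truth)
    assert table[0]["recall"] <= 1.0 and table[0]["n_edges"] == 3  # every seen edge kept
    assert table[0]["recall"] == 1.0
    assert table[-1]["n_edges"] == 1
    precisions = [r["precision"] for r in table if not np.isnan(r["precision"])]
    assert precisions == sorted(precisions)  # precision non-decreasing here


def test_ensemble_identify_deterministic_and_order_independent(two_gene_system):
    params, data = two_gene_system
    noisy = add_noise(
        __import__("ssgrn").simulate(params, np.array([0.3, 0.8]), data.time_grid),
        NoiseSpec(percent=0.03, n_replicates=3, seed=13),
    )
    cfg = GAConfig(tol=0.05, seed=17, population_size=8, generations=6, n_restarts=1)
    samples = bootstrap_resample(noisy, 4, seed=17)
    a = ensemble_identify(samples, cfg)
    b = ensemble_identify(samples, cfg)
    assert np.array_equal(a.freq, b.freq)
    assert all(
        np.array_equal(x.lam.lam, y.lam.lam) for x, y in zip(a.networks, b.networks)
    )
    assert a.n_boot == 4
    # frequency equals direct recount over members
    recount = sum(net.lam.lam for net in a.networks) / a.n_boot
    assert np.array_equal(a.freq, recount)


def test_ensemble_identify_rejects_empty_or_mismatched(two_gene_system, fast_config):
    _, data = two_gene_system
    with pytest.raises(ValueError):
        ensemble_identify([], fast_config)
    other = ExpressionDataset(
        time_grid=data.time_grid[:5], replicates=data.replicates[:, :5]
    )
    with pytest.raises(ValueError):
        ensemble_identify([data, other], fast_config)
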