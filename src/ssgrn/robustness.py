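"""Bootstrap robustness analysis of identified networks.

With only a handful of experimental replicates, a single identification run
is at the mercy of the particular noise realisation.  The robustness
pipeline resamples the replicates with replacement to build many artificial
datasets of the original size, identifies a network on each, and interprets
the frequency with which a connection recurs across the resulting ensemble
as its insensitivity to measurement noise.  Connections above a frequency
threshold (default 45%) form the robust network; their kinetic parameters
get bootstrap percentile confidence intervals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from joblib import Parallel, delayed

from .evaluation import Metrics, edges_of, precision_recall
from .identify import GAConfig, IdentifiedNetwork, identify
from .ssystem import ExpressionDataset

__all__ = [
    "NetworkEnsemble",
    "RobustNetwork",
    "bootstrap_resample",
    "ensemble_identify",
    "robust_edges",
    "frequency_convergence",
    "sensitivity_sweep",
]


@dataclass(frozen=True)
class NetworkEnsemble:
    """One identified network per bootstrap sample, plus the frequency matrix.

    ``freq[i, j]`` is the fraction of the ``n_boot`` ensemble members whose
    network contains the edge j -> i.  Members that never reached the fit
    tolerance are retained (their best-effort connectivity still counts);
    they are excluded only from parameter confidence intervals.
    """

    networks: tuple
    n_boot: int
    freq: np.ndarray

    @classmethod
    def from_networks(cls, networks) -> "NetworkEnsemble":
        networks = tuple(networks)
        if not networks:
            raise ValueError("empty network ensemble")
        n_boot = len(networks)
        freq = np.zeros(networks[0].lam.lam.shape, dtype=float)
        for net in networks:
            freq += net.lam.lam
        return cls(networks=networks, n_boot=n_boot, freq=freq / n_boot)


@dataclass(frozen=True)
class RobustNetwork:
    """Thresholded robust edge set with bootstrap confidence intervals.

    ``param_estimates[(i, j)] = (mean, lo, hi)`` of the kinetic order g_ij
    over the feasible ensemble members containing that edge;
    ``rate_estimates["alpha"|"beta"][i] = (mean, lo, hi)`` over all feasible
    members.
    """

    edges: frozenset
    threshold: float
    param_estimates: dict
    rate_estimates: dict
    confidence_level: float


def bootstrap_resample(
    data: ExpressionDataset, n_boot: int, seed: int
) -> list[ExpressionDataset]:
    """Generate artificial replicate datasets by resampling with replacement.

    Independently at every time point, r replicate indices are drawn with
    replacement and those replicates' full gene vectors are taken, so each
    artificial set has exactly the r x m x n size of the original and
    preserves cross-gene correlation within a measurement.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    r, m = data.n_replicates, data.n_times
    if r < 2:
        warnings.warn(
            "bootstrap with a single replicate degenerates to copies of the input",
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n_boot):
        idx = rng.integers(0, r, size=(r, m))  # idx[k, t]: replicate used for slot k at time t
        reps = data.replicates[idx, np.arange(m)[None, :], :]
        out.append(
            ExpressionDataset(
                time_grid=data.time_grid, replicates=reps, gene_names=data.gene_names
            )
        )
    return out


def _member_seeds(master_seed: int, n: int) -> list[int]:
    """Deterministic per-member seeds (independent of execution order)."""
    ss = np.random.SeedSequence(master_seed)
    return [int(s) for s in ss.generate_state(n) % (2**31)]


def ensemble_identify(
    datasets, config: GAConfig, *, n_jobs: int = 1, verbose: int = 0
) -> NetworkEnsemble:
    """Run the bi-level identification on every bootstrap dataset.

    Member seeds are derived deterministically from ``config.seed`` by
    member index, so any execution order (or parallel backend) gives
    identical results.
    """
    datasets = list(datasets)
    if not datasets:
        raise ValueError("empty dataset list")
    shapes = {d.replicates.shape for d in datasets}
    if len(shapes) != 1:
        raise ValueError(f"datasets must share one shape, got {sorted(shapes)}")
    seeds = _member_seeds(config.seed, len(datasets))
    runs = Parallel(n_jobs=n_jobs, verbose=verbose)(
        delayed(identify)(d, replace(config, seed=s)) for d, s in zip(datasets, seeds)
    )
    return NetworkEnsemble.from_networks(runs)


def robust_edges(
    ensemble: NetworkEnsemble,
    threshold: float = 0.45,
    confidence_level: float = 0.90,
) -> RobustNetwork:
    """Extract the robust network: edges at or above the frequency threshold.

    Parameter estimates are bootstrap percentile intervals at
    ``confidence_level`` — per edge over the feasible members containing it,
    per gene (alpha, beta) over all feasible members.
    """
    if not (0.0 < threshold <= 1.0):
        raise ValueError("threshold must be in (0, 1]")
    edges = frozenset(
        (int(i), int(j)) for i, j in np.argwhere(ensemble.freq >= threshold)
    )
    lo_q = 100 * (1 - confidence_level) / 2
    hi_q = 100 - lo_q
    feasible = [net for net in ensemble.networks if net.feasible]
    pool = feasible if feasible else list(ensemble.networks)

    param_estimates = {}
    for i, j in sorted(edges):
        vals = np.array(
            [net.fit.rho[i, j] for net in pool if net.lam.lam[i, j] == 1]
        )
        if vals.size:
            param_estimates[(i, j)] = (
                float(vals.mean()),
                float(np.percentile(vals, lo_q)),
                float(np.percentile(vals, hi_q)),
            )
    rate_estimates = {"alpha": {}, "beta": {}}
    if pool:
        n = pool[0].lam.n
        for name in ("alpha", "beta"):
            for i in range(n):
                vals = np.array(
                    [getattr(net.fit, name)[i] for net in pool if net.fit.converged]
                )
                if vals.size:
                    rate_estimates[name][i] = (
                        float(vals.mean()),
                        float(np.percentile(vals, lo_q)),
                        float(np.percentile(vals, hi_q)),
                    )
    return RobustNetwork(
        edges=edges,
        threshold=threshold,
        param_estimates=param_estimates,
        rate_estimates=rate_estimates,
        confidence_level=confidence_level,
    )


def frequency_convergence(ensemble: NetworkEnsemble, block_size: int = 200):
    """Per-edge occurrence percentages in consecutive sample blocks.

    Splits the ensemble into consecutive blocks of ``block_size`` members,
    computes each edge's occurrence percentage per block, and returns
    ``(block_freqs, spread)`` where ``block_freqs`` is (n_blocks, n, n) in
    percent and ``spread = max - min`` over blocks (percentage points).  A
    small spread indicates that the bootstrap frequencies have converged at
    this ensemble size.
    """
    if block_size < 1 or ensemble.n_boot < 2 * block_size:
        raise ValueError("need n_boot >= 2 * block_size")
    n_blocks = ensemble.n_boot // block_size
    shape = ensemble.networks[0].lam.lam.shape
    block_freqs = np.zeros((n_blocks,) + shape)
    for b in range(n_blocks):
        for net in ensemble.networks[b * block_size : (b + 1) * block_size]:
            block_freqs[b] += net.lam.lam
    block_freqs *= 100.0 / block_size
    spread = block_freqs.max(axis=0) - block_freqs.min(axis=0)
    return block_freqs, spread


def sensitivity_sweep(ensemble: NetworkEnsemble, thresholds, truth) -> list[dict]:
    """Precision/recall of the robust network across frequency thresholds.

    For in-silico studies with known truth.  Returns one record per
    threshold: ``{"threshold", "precision", "recall", "n_edges"}``
    (precision is NaN where nothing is predicted).
    """
    true_edges = edges_of(truth)
    out = []
    for th in thresholds:
        robust = robust_edges(ensemble, threshold=th)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            m: Metrics = precision_recall(robust.edges, true_edges)
        out.append(
            {
                "threshold": float(th),
                "precision": m.precision,
                "recall": m.recall,
                "n_edges": len(robust.edges),
            }
        )
    return out
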