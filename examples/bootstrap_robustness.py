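"""Extract noise-robust connections by bootstrapping experimental replicates.

Three noisy replicates of a 2-gene system are resampled with replacement
(per time point) into a small ensemble of artificial datasets; the bi-level
identification runs on each, and the fraction of ensemble networks
containing each connection measures that connection's robustness to
measurement noise.  Connections above the 45% threshold form the robust
network, with bootstrap percentile confidence intervals on their kinetic
orders.  (A full-scale analysis uses hundreds of bootstrap samples;
this example keeps the ensemble tiny so it runs in seconds.)
"""

import numpy as np

from ssgrn import (
    GAConfig,
    NoiseSpec,
    SSystemParams,
    add_noise,
    bootstrap_resample,
    ensemble_identify,
    robust_edges,
    simulate,
)

truth = SSystemParams(
    alpha=np.array([6.0, 8.0]),
    beta=np.array([9.0, 7.0]),
    G=np.array([[0.0, 0.0], [2.0, 0.0]]),
)
grid = np.linspace(0.0, 0.25, 8)
traj = simulate(truth, np.array([0.3, 0.8]), grid)
data = add_noise(traj, NoiseSpec(percent=0.05, n_replicates=3, seed=8))

samples = bootstrap_resample(data, n_boot=10, seed=8)
cfg = GAConfig(tol=0.05, population_size=10, generations=12, seed=8, n_restarts=2)
ensemble = ensemble_identify(samples, cfg)

print("bootstrap occurrence frequency per possible connection:")
for i in range(2):
    for j in range(2):
        if ensemble.freq[i, j] > 0:
            print(f"  G{j + 1} -> G{i + 1}: {ensemble.freq[i, j]:.0%}")

robust = robust_edges(ensemble, threshold=0.45, confidence_level=0.90)
print(f"\nrobust connections (>= 45% of {ensemble.n_boot} bootstrap networks):")
for (i, j) in sorted(robust.edges):
    mean, lo, hi = robust.param_estimates[(i, j)]
    print(f"  G{j + 1} -> G{i + 1}: g = {mean:.2f}  (90% CI [{lo:.2f}, {hi:.2f}])")
print("\na high frequency means the connection is insensitive to the particular")
print("noise realisation; the CI quantifies uncertainty in its strength.")
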