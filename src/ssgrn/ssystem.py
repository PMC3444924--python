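"""S-system dynamics: power-law ODE models of gene regulatory networks.

An S-system describes the expression level :math:`X_i` of each gene by a
difference of two power-law terms,

.. math::

    \\dot X_i = \\alpha_i \\prod_j X_j^{g_{ij}} - \\beta_i \\prod_j X_j^{h_{ij}},

where the kinetic orders :math:`g_{ij}` encode which genes regulate the
production of gene *i* (sign = activation/repression, magnitude = strength)
and :math:`\\alpha_i, \\beta_i > 0` are rate constants.  Throughout this
package degradation is assumed first order in the gene's own level
(:math:`h_{ij} = \\delta_{ij}`), which reduces the number of unknown
parameters from :math:`2n(n+1)` to :math:`n(n+2)`.

This module holds the parameter/trajectory/dataset containers, the numerical
integrator, and the scalar model-vs-data discrepancy ``fit_error`` used as
the objective of the identification problem.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

try:  # pragma: no cover - numba is a hard dependency, fallback is belt-and-braces
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(fn):
            return fn

        if len(args) == 1 and callable(args[0]):
            return args[0]
        return wrap


#: Default floor applied to expression values so that power laws with
#: negative kinetic orders stay defined.
EXPRESSION_FLOOR = 1e-6

#: Any state exceeding this during integration flags the candidate parameter
#: set as dynamically unstable (routine for candidate topologies during search).
DIVERGENCE_CEILING = 1e6


class UnstableDynamicsError(RuntimeError):
    """Integration diverged (non-finite state or state above the ceiling).

    Callers in the identification layer treat the offending candidate as
    infeasible rather than aborting the search.
    """


@dataclass(frozen=True)
class SSystemParams:
    """Rate constants and kinetic orders defining one network's dynamics.

    Parameters
    ----------
    alpha, beta
        Length-``n`` positive production / degradation rate constants
        (concentration/time and 1/time respectively).
    G
        ``n x n`` production kinetic orders; ``G[i, j]`` is the exponent of
        gene ``j`` in gene ``i``'s production term (the directed regulatory
        edge ``j -> i``).
    H
        Degradation kinetic orders; fixed to the identity matrix (first-order
        self-degradation).  The field exists for completeness only — no
        operation in this package estimates ``H``.
    """

    alpha: np.ndarray
    beta: np.ndarray
    G: np.ndarray
    H: np.ndarray | None = None

    def __post_init__(self):
        alpha = np.asarray(self.alpha, dtype=float)
        beta = np.asarray(self.beta, dtype=float)
        G = np.asarray(self.G, dtype=float)
        n = alpha.shape[0]
        if alpha.ndim != 1 or beta.shape != (n,) or G.shape != (n, n):
            raise ValueError("alpha, beta must be length-n; G must be n x n")
        if not (np.all(alpha > 0) and np.all(beta > 0)):
            raise ValueError("rate constants alpha, beta must be strictly positive")
        if not np.all(np.isfinite(G)):
            raise ValueError("kinetic orders must be finite")
        H = np.eye(n) if self.H is None else np.asarray(self.H, dtype=float)
        if H.shape != (n, n) or not np.array_equal(H, np.eye(n)):
            raise ValueError("H must be the identity (first-order degradation)")
        object.__setattr__(self, "alpha", alpha)
        object.__setattr__(self, "beta", beta)
        object.__setattr__(self, "G", G)
        object.__setattr__(self, "H", H)

    @property
    def n(self) -> int:
        """Number of genes."""
        return self.alpha.shape[0]

    def connectivity(self) -> np.ndarray:
        """Binary matrix of nonzero production kinetic orders."""
        return (self.G != 0).astype(np.int8)


@dataclass(frozen=True)
class Trajectory:
    """Deterministic expression time course on a fixed grid.

    ``values[t, i]`` is the level of gene ``i`` at ``time_grid[t]``.
    """

    time_grid: np.ndarray
    values: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.time_grid, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if t.ndim != 1 or v.ndim != 2 or v.shape[0] != t.shape[0]:
            raise ValueError("values must be (len(time_grid), n_genes)")
        if np.any(np.diff(t) <= 0):
            raise ValueError("time_grid must be strictly increasing")
        if not np.all(np.isfinite(v)) or np.any(v < 0):
            raise ValueError("expression values must be finite and non-negative")
        object.__setattr__(self, "time_grid", t)
        object.__setattr__(self, "values", v)

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    @property
    def n_times(self) -> int:
        return self.time_grid.shape[0]


@dataclass(frozen=True)
class ExpressionDataset:
    """Replicated expression measurements: an ``r x m x n`` tensor.

    ``replicates[k, t, i]`` is replicate ``k`` of gene ``i`` at
    ``time_grid[t]``.  The identification layer fits the per-time-point mean
    across replicates.
    """

    time_grid: np.ndarray
    replicates: np.ndarray
    gene_names: tuple[str, ...] = field(default=())

    def __post_init__(self):
        t = np.asarray(self.time_grid, dtype=float)
        reps = np.asarray(self.replicates, dtype=float)
        if reps.ndim != 3 or reps.shape[1] != t.shape[0]:
            raise ValueError("replicates must be (n_replicates, len(time_grid), n_genes)")
        if reps.shape[0] < 1:
            raise ValueError("need at least one replicate")
        if np.any(np.diff(t) <= 0):
            raise ValueError("time_grid must be strictly increasing")
        if not np.all(np.isfinite(reps)) or np.any(reps < 0):
            raise ValueError("expression values must be finite and non-negative")
        names = tuple(self.gene_names) or tuple(f"G{i + 1}" for i in range(reps.shape[2]))
        if len(names) != reps.shape[2]:
            raise ValueError("gene_names length must match the gene axis")
        object.__setattr__(self, "time_grid", t)
        object.__setattr__(self, "replicates", reps)
        object.__setattr__(self, "gene_names", names)

    @property
    def n_replicates(self) -> int:
        return self.replicates.shape[0]

    @property
    def n_times(self) -> int:
        return self.replicates.shape[1]

    @property
    def n_genes(self) -> int:
        return self.replicates.shape[2]

    def mean(self) -> np.ndarray:
        """Per-time-point mean across replicates (an ``m x n`` matrix)."""
        return self.replicates.mean(axis=0)


@njit(cache=True, inline="always")
def _rhs_into(alpha, beta, G, x, floor, lx, out):  # pragma: no cover - jitted
    n = x.shape[0]
    for j in range(n):
        xj = x[j]
        if xj < floor:
            xj = floor
        lx[j] = np.log(xj)
    for i in range(n):
        s = 0.0
        for j in range(n):
            gij = G[i, j]
            if gij != 0.0:
                s += gij * lx[j]
        xi = x[i]
        if xi < floor:
            xi = floor
        out[i] = alpha[i] * np.exp(s) - beta[i] * xi


@njit(cache=True)
def _rk4_kernel(alpha, beta, G, x0, time_grid, substeps, ceiling, floor):  # pragma: no cover - jitted
    m = time_grid.shape[0]
    n = x0.shape[0]
    out = np.zeros((m, n))
    x = np.empty(n)
    xt = np.empty(n)
    lx = np.empty(n)
    k1 = np.empty(n)
    k2 = np.empty(n)
    k3 = np.empty(n)
    k4 = np.empty(n)
    for i in range(n):
        x[i] = x0[i]
        out[0, i] = x0[i]
    for t in range(m - 1):
        h = (time_grid[t + 1] - time_grid[t]) / substeps
        for _ in range(substeps):
            _rhs_into(alpha, beta, G, x, floor, lx, k1)
            for i in range(n):
                xt[i] = x[i] + 0.5 * h * k1[i]
            _rhs_into(alpha, beta, G, xt, floor, lx, k2)
            for i in range(n):
                xt[i] = x[i] + 0.5 * h * k2[i]
            _rhs_into(alpha, beta, G, xt, floor, lx, k3)
            for i in range(n):
                xt[i] = x[i] + h * k3[i]
            _rhs_into(alpha, beta, G, xt, floor, lx, k4)
            for i in range(n):
                xi = x[i] + (h / 6.0) * (k1[i] + 2.0 * k2[i] + 2.0 * k3[i] + k4[i])
                if not np.isfinite(xi) or xi > ceiling:
                    return out, False
                if xi < floor:
                    xi = floor
                x[i] = xi
        for i in range(n):
            out[t + 1, i] = x[i]
    return out, True


def _rhs(params: SSystemParams, floor: float):
    alpha, beta, G = params.alpha, params.beta, params.G

    def f(_t, x):
        xc = np.maximum(x, floor)
        return alpha * np.exp(G @ np.log(xc)) - beta * xc

    return f


def simulate(
    params: SSystemParams,
    x0,
    time_grid,
    *,
    method: str = "rk4",
    substeps: int = 8,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    ceiling: float = DIVERGENCE_CEILING,
    floor: float = EXPRESSION_FLOOR,
) -> Trajectory:
    """Integrate the S-system ODEs on ``time_grid`` starting from ``x0``.

    The default integrator is a fixed-step classical Runge-Kutta scheme with
    ``substeps`` internal steps per output interval, compiled with numba; the
    identification layer calls it millions of times, and on the non-stiff
    benchmark dynamics it agrees with an adaptive solver to well below 1e-6.
    ``method="lsoda"`` switches to :func:`scipy.integrate.solve_ivp` with the
    stiff-capable LSODA solver at tolerances ``rtol``/``atol``.

    Raises
    ------
    UnstableDynamicsError
        If any state becomes non-finite or exceeds ``ceiling``.  Candidate
        topologies during search routinely blow up; callers treat this as
        "candidate infeasible".
    """
    x0 = np.asarray(x0, dtype=float)
    t = np.asarray(time_grid, dtype=float)
    if np.any(x0 <= 0):
        raise ValueError("x0 must be strictly positive (power laws undefined at 0)")
    if x0.shape != (params.n,):
        raise ValueError("x0 must have one entry per gene")

    if method == "rk4":
        values, ok = _rk4_kernel(
            params.alpha, params.beta, params.G, x0, t, substeps, ceiling, floor
        )
        if not ok:
            raise UnstableDynamicsError("state diverged during RK4 integration")
    elif method == "lsoda":
        sol = solve_ivp(
            _rhs(params, floor),
            (t[0], t[-1]),
            x0,
            t_eval=t,
            method="LSODA",
            rtol=rtol,
            atol=atol,
        )
        if not sol.success:
            raise UnstableDynamicsError(f"LSODA failed: {sol.message}")
        values = sol.y.T
        if not np.all(np.isfinite(values)) or np.any(values > ceiling):
            raise UnstableDynamicsError("state diverged during LSODA integration")
    else:
        raise ValueError(f"unknown integration method {method!r}")

    return Trajectory(time_grid=t, values=np.clip(values, 0.0, None))


def fit_error(predicted, observed) -> float:
    """Fit error chi: root of the total sum of squared deviations.

    .. math:: \\chi = \\sqrt{\\sum_t \\sum_i (x^{exp}_{t,i} - x^{pred}_{t,i})^2}

    i.e. the Frobenius norm of the residual matrix between the predicted
    trajectory and the observed (typically replicate-averaged) data.
    Symmetric in its arguments, zero iff they coincide.
    """
    p = predicted.values if isinstance(predicted, Trajectory) else np.asarray(predicted, float)
    o = observed.values if isinstance(observed, Trajectory) else np.asarray(observed, float)
    if p.shape != o.shape:
        raise ValueError(f"shape mismatch: predicted {p.shape} vs observed {o.shape}")
    return float(np.linalg.norm(p - o))


def steady_state(params: SSystemParams, x_guess, *, horizon: float = 50.0) -> np.ndarray:
    """Numerically relax the system to its steady state from ``x_guess``."""
    grid = np.linspace(0.0, horizon, 201)
    traj = simulate(params, x_guess, grid, method="lsoda", rtol=1e-10, atol=1e-12)
    return traj.values[-1]
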