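"""Integrator correctness and fit-error identities."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from ssgrn import (
    ExpressionDataset,
    SSystemParams,
    Trajectory,
    UnstableDynamicsError,
    benchmark_grid,
    benchmark_x0,
    fit_error,
    simulate,
)


def test_steady_state_initial_condition_stays_constant():
    """At a steady state the derivative is zero, so the trajectory is flat."""
    # alpha * x2^1 = beta * x1  and  alpha * x1 = beta * x2 at x = (1, 1)
    params = SSystemParams(
        alpha=np.array([4.0, 3.0]),
        beta=np.array([4.0, 3.0]),
        G=np.array([[0.0, 1.0], [1.0, 0.0]]),
    )
    x0 = np.array([1.0, 1.0])
    traj = simulate(params, x0, np.linspace(0, 2.0, 15))
    assert np.allclose(traj.values, 1.0, atol=1e-10)


@pytest.mark.parametrize("alpha,beta,x0", [(3.0, 5.0, 0.2), (10.0, 2.0, 1.5)])
def test_uncoupled_gene_matches_linear_ode_closed_form(alpha, beta, x0):
    """With all g = 0, dx/dt = alpha - beta*x has the exponential closed form."""
    params = SSystemParams(
        alpha=np.array([alpha]), beta=np.array([beta]), G=np.zeros((1, 1))
    )
    grid = np.linspace(0, 1.5, 25)
    traj = simulate(params, np.array([x0]), grid)
    exact = alpha / beta + (x0 - alpha / beta) * np.exp(-beta * grid)
    assert np.allclose(traj.values[:, 0], exact, rtol=1e-6, atol=1e-9)


def test_benchmark_integration_matches_adaptive_solver(benchmark_params, benchmark_traj):
    """Fixed-step RK4 agrees with high-accuracy LSODA on the benchmark transient."""
    p = benchmark_params

    def rhs(_t, x):
        return p.alpha * np.exp(p.G @ np.log(x)) - p.beta * x

    grid = benchmark_grid()
    sol = solve_ivp(rhs, (grid[0], grid[-1]), benchmark_x0(), t_eval=grid,
                    method="LSODA", rtol=1e-10, atol=1e-12)
    rel = np.abs(benchmark_traj.values - sol.y.T) / np.abs(sol.y.T)
    assert rel.max() < 1e-4


def test_divergent_dynamics_flagged_as_unstable():
    """Strong positive self-feedback blows up and must raise, not crash downstream."""
    params = SSystemParams(
        alpha=np.array([50.0]), beta=np.array([0.1]), G=np.array([[3.0]])
    )
    with pytest.raises(UnstableDynamicsError):
        simulate(params, np.array([5.0]), np.linspace(0, 50.0, 40))


def test_simulate_rejects_nonpositive_initial_condition(benchmark_params):
    with pytest.raises(ValueError):
        simulate(benchmark_params, np.zeros(5), benchmark_grid())


def test_fit_error_identities():
    rng = np.random.default_rng(0)
    a = rng.uniform(0.1, 2.0, size=(6, 4))
    assert fit_error(a, a) == 0.0
    b = a.copy()
    b[2, 1] += 0.37
    assert np.isclose(fit_error(b, a), 0.37)
    assert fit_error(a, b) == fit_error(b, a)
    ones = np.ones((4, 5))
    assert np.isclose(fit_error(ones, np.zeros((4, 5))), np.sqrt(20.0))


def test_fit_error_shape_mismatch_rejected():
    with pytest.raises(ValueError):
        fit_error(np.ones((3, 2)), np.ones((2, 3)))


def test_trajectory_and_dataset_validation():
    with pytest.raises(ValueError):
        Trajectory(time_grid=[0.0, 0.0, 1.0], values=np.ones((3, 2)))
    with pytest.raises(ValueError):
        Trajectory(time_grid=[0.0, 1.0], values=-np.ones((2, 2)))
    with pytest.raises(ValueError):
        ExpressionDataset(time_grid=[0.0, 1.0], replicates=np.ones((1, 3, 2)))
    data = ExpressionDataset(time_grid=[0.0, 1.0], replicates=np.arange(8.0).reshape(2, 2, 2))
    assert np.allclose(data.mean(), [[2.0, 3.0], [4.0, 5.0]])
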