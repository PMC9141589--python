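"""Lorenz-system ground truth for the deletion/reconstruction benchmark.

The Lorenz equations

    dx/dt = 10 (y - x),   dy/dt = 28 x - y - x z,   dz/dt = x y - (8/3) z

are integrated with the classical fourth-order Runge-Kutta scheme from the
on-attractor initial state ``(x, y, z) = (-8, 8, 27)``.  The step size and
series length are coupled to the interpolation-point count ``n_I`` of the
benchmark,

    dt = 0.1 / (n_I + 1),        L = 200 (n_I + 1),

so the total simulated time is always 20 and every subsampled (kept) grid
has spacing 0.1 in time.  The univariate benchmark signal is the
x-component of the ``L`` states *after* the initial condition, i.e. samples
at ``t = dt, 2 dt, ..., L dt`` — the initial state itself is not part of
the series.
"""

from __future__ import annotations

import numpy as np

from .series import TimeSeries

__all__ = ["lorenz_rhs", "rk4_integrate", "simulate_lorenz", "simulate_lorenz_x",
           "LORENZ_INITIAL_STATE"]

LORENZ_INITIAL_STATE = np.array([-8.0, 8.0, 27.0])


def lorenz_rhs(state) -> np.ndarray:
    """Time derivative ``(dx/dt, dy/dt, dz/dt)`` of the Lorenz system."""
    x, y, z = np.asarray(state, dtype=float)
    return np.array([10.0 * (-x + y), 28.0 * x - y - x * z, x * y - (8.0 / 3.0) * z])


def rk4_integrate(func, initial, dt: float, n_steps: int, include_initial: bool = True):
    """Classical fourth-order Runge-Kutta integration at fixed step size.

    Parameters
    ----------
    func
        Right-hand side ``f(state) -> d state / dt``; state may be scalar
        or a 1-d array.
    initial
        State at ``t = 0``.
    dt
        Step size, > 0.
    n_steps
        Number of RK4 steps to take.
    include_initial
        If true (default) the returned array has ``n_steps + 1`` rows
        starting with the initial state; if false, the ``n_steps`` states
        after it.

    Raises on the first non-finite state, naming the offending step.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    n_steps = int(n_steps)
    if n_steps < 0:
        raise ValueError("n_steps must be >= 0")
    state = np.atleast_1d(np.asarray(initial, dtype=float))
    scalar = np.isscalar(initial) or np.ndim(initial) == 0

    states = [state.copy()] if include_initial else []
    for k in range(n_steps):
        k1 = np.atleast_1d(func(state if not scalar else state[0]))
        k2 = np.atleast_1d(func(_adv(state, dt / 2.0, k1, scalar)))
        k3 = np.atleast_1d(func(_adv(state, dt / 2.0, k2, scalar)))
        k4 = np.atleast_1d(func(_adv(state, dt, k3, scalar)))
        state = state + (dt / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
        if not np.all(np.isfinite(state)):
            raise FloatingPointError(f"integration blew up at step {k + 1}")
        states.append(state.copy())
    out = np.array(states)
    return out[:, 0] if scalar else out


def _adv(state, h, k, scalar):
    s = state + h * k
    return s[0] if scalar else s


def sim_params(n_interp: int):
    """Step size and series length coupled to the interpolation count."""
    n_interp = int(n_interp)
    if n_interp < 1:
        raise ValueError("n_interp must be >= 1")
    return 0.1 / (n_interp + 1), 200 * (n_interp + 1)


def simulate_lorenz(n_interp: int) -> np.ndarray:
    """Full ``(L, 3)`` state series of the benchmark run for a given n_I."""
    dt, length = sim_params(n_interp)
    return rk4_integrate(lorenz_rhs, LORENZ_INITIAL_STATE, dt, length, include_initial=False)


def simulate_lorenz_x(n_interp: int) -> TimeSeries:
    """Benchmark x-series: samples at ``t = dt .. L dt`` for a given n_I."""
    dt, length = sim_params(n_interp)
    states = simulate_lorenz(n_interp)
    times = dt * np.arange(1, length + 1)
    return TimeSeries(times, states[:, 0])
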