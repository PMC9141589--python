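"""Fractional Brownian motion and multi-point fractional Brownian bridges.

Fractional Brownian motion (fBm) is the zero-mean Gaussian process with
covariance

    C(t, t') = 1/2 (t^{2H} + t'^{2H} - |t - t'|^{2H}),

where the Hurst exponent ``H`` in (0, 1) controls roughness: ``H = 1/2`` is
standard Brownian motion, larger ``H`` gives smoother, persistent paths.
The process is pinned to zero at ``t = 0``.

A *multi-point fractional Brownian bridge* is an fBm realization corrected
by Gaussian conditioning so that it passes exactly through an arbitrary set
of prescribed points ``(t_i, X_i)``:

    X_B(t) = X(t) - (X(t_i) - X_i) [sigma^{-1}]_{ij} C(t, t_j),

with ``sigma_ij = C(t_i, t_j)`` and summation over repeated indices.  The
correction is affine in the path, so the bridge remains Gaussian, with the
usual kriging (conditional-Gaussian) mean and covariance.

Sampling is exact: the full-grid covariance matrix is Cholesky-factorized.
This is cubic in the grid size and intended for desk-scale grids (a few
thousand points), trading speed for exactness.
"""

from __future__ import annotations

import numpy as np
from scipy.linalg import cho_factor, cho_solve, cholesky, solve

from .series import TimeSeries

__all__ = [
    "FbmNumericalError",
    "fbm_covariance",
    "fbm_covariance_matrix",
    "sample_fbm",
    "condition_on_points",
    "interpolate_gaps",
    "bridge_interpolate",
]

# Relative jitter added to the covariance diagonal on a failed factorization
# before giving up; large enough to absorb round-off, small enough not to
# perturb the law measurably at desk scales.
_JITTER_REL = 1e-12


class FbmNumericalError(RuntimeError):
    """Covariance factorization failed beyond the documented jitter."""


def _check_hurst(h: float) -> float:
    h = float(h)
    if not 0.0 < h < 1.0:
        raise ValueError(f"Hurst exponent must lie in (0, 1), got {h}")
    return h


def fbm_covariance(t, t_prime, h: float):
    """Covariance ``C(t, t')`` of fractional Brownian motion.

    Symmetric in ``t`` and ``t_prime``; accepts scalars or broadcastable
    arrays of non-negative times.  For ``h = 0.5`` the formula collapses to
    ``min(t, t')``.
    """
    h = _check_hurst(h)
    t = np.asarray(t, dtype=float)
    t_prime = np.asarray(t_prime, dtype=float)
    if np.any(t < 0) or np.any(t_prime < 0):
        raise ValueError("fBm covariance requires non-negative times")
    two_h = 2.0 * h
    out = 0.5 * (t**two_h + t_prime**two_h - np.abs(t - t_prime) ** two_h)
    return out if out.ndim else float(out)


def fbm_covariance_matrix(times, h: float) -> np.ndarray:
    """Dense covariance matrix of fBm over a set of times."""
    times = np.asarray(times, dtype=float)
    return fbm_covariance(times[:, None], times[None, :], h)


def _check_grid(times) -> np.ndarray:
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or times.size == 0:
        raise ValueError("time grid must be a non-empty 1-d sequence")
    if np.any(times < 0):
        raise ValueError("time grid must be non-negative")
    if np.any(np.diff(times) <= 0):
        raise ValueError("time grid must be strictly increasing")
    return times


def sample_fbm(grid, h: float, seed=None) -> np.ndarray:
    """Draw one exact fBm realization on a strictly increasing grid.

    The grid may contain ``t = 0``, where the path is exactly zero; that
    row/column is removed before Cholesky factorization so the covariance
    stays positive definite.  ``seed`` may be an int or a
    :class:`numpy.random.Generator`; the same ``(seed, grid, h)`` always
    yields the identical path.
    """
    grid = _check_grid(grid)
    h = _check_hurst(h)
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed

    pinned = grid == 0.0
    free = grid[~pinned]
    values = np.zeros(grid.size)
    if free.size:
        cov = fbm_covariance_matrix(free, h)
        factor = _cholesky_with_jitter(cov)
        values[~pinned] = factor @ rng.standard_normal(free.size)
    return values


def _cholesky_with_jitter(cov: np.ndarray) -> np.ndarray:
    try:
        return cholesky(cov, lower=True)
    except np.linalg.LinAlgError:
        pass
    jitter = _JITTER_REL * float(np.max(np.diag(cov)))
    try:
        return cholesky(cov + jitter * np.eye(cov.shape[0]), lower=True)
    except np.linalg.LinAlgError as exc:
        raise FbmNumericalError(
            f"fBm covariance matrix is not positive definite even after "
            f"jitter {jitter:.3e}; grid too fine or Hurst exponent too "
            f"extreme for double precision"
        ) from exc


def condition_on_points(grid, values, h: float, constraint_times, constraint_values) -> np.ndarray:
    """Condition a Gaussian path so it passes exactly through given points.

    Implements the multi-point bridge correction
    ``X_B(t) = X(t) - (X(t_i) - X_i) [sigma^{-1}]_{ij} C(t, t_j)``.
    The operation is affine in ``values``: applied to the zero path it
    returns the conditional (kriging) mean, and a path already satisfying
    the constraints is returned unchanged.

    All constraint times must be members of ``grid`` and strictly positive
    (the origin is pinned at zero by the fBm law itself and cannot carry a
    constraint).
    """
    grid = _check_grid(grid)
    values = np.asarray(values, dtype=float)
    if values.shape != grid.shape:
        raise ValueError("values must match the grid in length")
    h = _check_hurst(h)

    ct = np.asarray(constraint_times, dtype=float)
    cx = np.asarray(constraint_values, dtype=float)
    if ct.ndim != 1 or ct.size == 0 or ct.shape != cx.shape:
        raise ValueError("need at least one (time, value) constraint pair")
    order = np.argsort(ct)
    ct, cx = ct[order], cx[order]
    dup = np.flatnonzero(np.diff(ct) == 0)
    if dup.size:
        raise ValueError(f"duplicate constraint at t={ct[dup[0]]!r} makes sigma singular")
    if np.any(ct <= 0):
        bad = float(ct[ct <= 0][0])
        raise ValueError(
            f"constraint at t={bad!r} is not allowed: the process is pinned "
            f"to 0 at the origin, so sigma would be singular"
        )

    idx = np.searchsorted(grid, ct)
    ok = (idx < grid.size) & (grid[np.minimum(idx, grid.size - 1)] == ct)
    if not np.all(ok):
        bad = float(ct[~ok][0])
        raise ValueError(f"constraint time t={bad!r} is not a grid point")

    sigma = fbm_covariance_matrix(ct, h)
    cross = fbm_covariance(grid[:, None], ct[None, :], h)  # C(t, t_j), shape (n, m)
    resid = values[idx] - cx
    try:
        weights = solve(sigma, resid, assume_a="pos")
    except np.linalg.LinAlgError as exc:
        raise FbmNumericalError(
            f"constraint covariance sigma is singular for times {ct.tolist()}"
        ) from exc
    return values - cross @ weights


def bridge_interpolate(
    observed: TimeSeries,
    points_per_gap,
    h: float,
    seed=None,
    scale: float = 1.0,
) -> TimeSeries:
    """Refine an observed series with bridge samples inside every gap.

    ``points_per_gap`` may be a single positive int (the same number of new
    samples in every gap) or a sequence with one count per gap (>= 0), which
    the deletion/reconstruction benchmark uses when its final gap is shorter
    than the others.  New samples are placed uniformly in time inside each
    gap.

    Internally the bridge lives on the *index* grid of the refined series
    (consecutive refined samples one unit apart) regardless of the real time
    spacing; the first observed point is the pinned origin (its value is
    subtracted from all constraints and added back afterwards), the
    remaining observed points are bridge constraints.  ``scale`` multiplies
    the sampled fBm fluctuation before conditioning.
    """
    if len(observed) < 2:
        raise ValueError("need at least 2 observed points to interpolate")
    n_gaps = len(observed) - 1
    if np.isscalar(points_per_gap):
        k = int(points_per_gap)
        if k < 1:
            raise ValueError("points_per_gap must be >= 1")
        counts = np.full(n_gaps, k, dtype=int)
    else:
        counts = np.asarray(points_per_gap, dtype=int)
        if counts.shape != (n_gaps,) or np.any(counts < 0) or not np.any(counts):
            raise ValueError(
                "per-gap counts must give one non-negative entry per gap, "
                "with at least one new point overall"
            )
    if float(scale) <= 0:
        raise ValueError("scale must be positive")

    # Refined real-time grid: uniform placement inside each gap.
    t_out, anchor_idx = _refined_times(observed.t, counts)
    n = t_out.size

    index_grid = np.arange(n, dtype=float)
    offset = observed.x[0]
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    path = float(scale) * sample_fbm(index_grid, h, rng)
    bridged = condition_on_points(
        index_grid,
        path,
        h,
        index_grid[anchor_idx[1:]],
        observed.x[1:] - offset,
    )
    x_out = bridged + offset
    # Anchors are exact by construction; assign to remove float round-off.
    x_out[anchor_idx] = observed.x
    return TimeSeries(t_out, x_out)


def _refined_times(t_obs: np.ndarray, counts: np.ndarray):
    pieces = []
    anchor_idx = np.empty(t_obs.size, dtype=int)
    pos = 0
    for g in range(counts.size):
        anchor_idx[g] = pos
        seg = np.linspace(t_obs[g], t_obs[g + 1], counts[g] + 2)
        pieces.append(seg[:-1])
        pos += counts[g] + 1
    anchor_idx[-1] = pos
    pieces.append(t_obs[-1:])
    return np.concatenate(pieces), anchor_idx


def interpolate_gaps(
    observed: TimeSeries,
    points_per_gap: int,
    h: float,
    seed=None,
    scale: float = 1.0,
) -> TimeSeries:
    """Uniformly refine every gap of a series with one bridge realization.

    Thin wrapper over :func:`bridge_interpolate` with the same number of new
    samples in every gap; observed values appear unchanged in the output.
    """
    if not np.isscalar(points_per_gap):
        raise TypeError("points_per_gap must be a positive integer")
    return bridge_interpolate(observed, int(points_per_gap), h, seed=seed, scale=scale)
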