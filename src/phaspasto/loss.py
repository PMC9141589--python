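"""Smoothness score of a reconstructed phase-space trajectory.

The fitness of an interpolated series is judged in its delay-embedded phase
space: along the trajectory ``y_i = (x_i, x_{i+tau}, ..., x_{i+(d_E-1)tau})``
each component's discrete curvature is the second central difference

    u''_j(i) = x_{i+(j-1)tau+1} - 2 x_{i+(j-1)tau} + x_{i+(j-1)tau-1},

the per-point curvature magnitude combines the components, and the loss is
the population variance of those magnitudes over the trajectory.  A smooth
curve has similar curvature everywhere — low variance — whereas a mix of
straight stretches and sharp kinks scores high.  The idea is borrowed from
blur detection in image processing, where a low variance of second
derivatives marks a blurry (smooth) image.

Two readings of the per-point magnitude are exposed, because candidate
*rankings* can differ between them:

``"squared_norm"``
    ``u''(i) = sum_j u''_j(i)^2`` (sum of squared components).
``"norm"`` (default)
    the Euclidean magnitude ``sqrt(sum_j u''_j(i)^2)``.
"""

from __future__ import annotations

import numpy as np

from .embedding import delay_embed

__all__ = ["second_central_diff", "trajectory_loss", "loss_surface", "LOSS_MODES"]

LOSS_MODES = ("norm", "squared_norm")


def second_central_diff(component) -> np.ndarray:
    """Second central differences ``x_{k+1} - 2 x_k + x_{k-1}`` of a sequence.

    Defined at interior points only: output length is input length minus 2.
    """
    x = np.asarray(component, dtype=float)
    if x.ndim != 1 or x.size < 3:
        raise ValueError("need a 1-d sequence of length >= 3")
    return x[2:] - 2.0 * x[1:-1] + x[:-2]


def trajectory_loss(series, dimension: int = 3, delay: int = 1, mode: str = "norm") -> float:
    """Variance of curvature magnitudes along the delay-embedded trajectory.

    Lower is fitter.  Exactly zero for any series whose per-point curvature
    magnitude is constant — in particular for affine series, so the loss is
    invariant under adding a constant or a linear trend.
    """
    if mode not in LOSS_MODES:
        raise ValueError(f"mode must be one of {LOSS_MODES}, got {mode!r}")
    vectors = delay_embed(series, dimension, delay)
    if vectors.shape[0] < 3:
        raise ValueError(
            f"series too short: only {vectors.shape[0]} delay vectors, need >= 3"
        )
    curv = vectors[2:] - 2.0 * vectors[1:-1] + vectors[:-2]
    magnitude = np.einsum("ij,ij->i", curv, curv)
    if mode == "norm":
        magnitude = np.sqrt(magnitude)
    return float(np.var(magnitude))


def loss_surface(series, delays, dimensions, mode: str = "norm") -> np.ndarray:
    """Trajectory loss on the Cartesian grid ``delays x dimensions``.

    Cells whose ``(tau, d_E)`` pair violates the length precondition are
    returned as NaN.  Shape is ``(len(delays), len(dimensions))``.
    """
    if mode not in LOSS_MODES:
        raise ValueError(f"mode must be one of {LOSS_MODES}, got {mode!r}")
    delays = list(delays)
    dimensions = list(dimensions)
    if not delays or not dimensions:
        raise ValueError("delays and dimensions must be non-empty")
    out = np.full((len(delays), len(dimensions)), np.nan)
    for i, tau in enumerate(delays):
        for j, dim in enumerate(dimensions):
            try:
                out[i, j] = trajectory_loss(series, dim, tau, mode)
            except ValueError:
                continue
    return out
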