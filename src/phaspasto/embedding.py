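"""Takens delay embedding and standard estimators for its two parameters.

A scalar series ``x_1 .. x_n`` is unfolded into state vectors

    y_i = (x_i, x_{i+tau}, ..., x_{i+(d_E-1) tau}),

where ``d_E`` is the embedding dimension and ``tau`` the time delay in
samples.  The estimators implemented here are the field's standard advisory
tools — first zero crossing of the autocorrelation and first local minimum
of the average mutual information for ``tau``, the Kennel false-nearest-
neighbour criterion for ``d_E``.  The interpolation pipeline itself defaults
to ``d_E = 3, tau = 1``, which keeps the reconstructed trajectory
three-dimensional for every data set.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.spatial import cKDTree
from statsmodels.tsa.stattools import acf

__all__ = [
    "EmbeddingError",
    "delay_embed",
    "estimate_delay_autocorr",
    "estimate_delay_mutual_info",
    "estimate_dim_fnn",
]

FNN_MAX_DIM = 10


class EmbeddingError(ValueError):
    """No valid embedding could be constructed or estimated."""


def delay_embed(series, dimension: int, delay: int) -> np.ndarray:
    """All delay vectors of a series, as rows of an ``(m, d_E)`` array.

    Row ``i`` is ``(x_i, x_{i+tau}, ..., x_{i+(d_E-1) tau})``;
    ``m = n - (d_E - 1) tau``.  No padding is applied.
    """
    x = np.asarray(series, dtype=float)
    dimension = int(dimension)
    delay = int(delay)
    if dimension < 1 or delay < 1:
        raise ValueError("dimension and delay must be >= 1")
    if x.ndim != 1:
        raise ValueError("series must be one-dimensional")
    m = x.size - (dimension - 1) * delay
    if m < 1:
        raise EmbeddingError(
            f"series of length {x.size} too short for d_E={dimension}, tau={delay}"
        )
    return np.column_stack([x[j * delay : j * delay + m] for j in range(dimension)])


def estimate_delay_autocorr(series) -> int:
    """Smallest lag at which the autocorrelation first reaches zero.

    Uses the biased autocovariance estimator normalized by lag zero.  A lag
    counts as a zero crossing when its autocorrelation is no longer
    significantly positive, i.e. drops to or below the standard white-noise
    band ``1.96 / sqrt(n)`` — with a sharp cutoff at exactly zero, finite-
    sample truncation noise (e.g. a periodic signal whose true
    autocorrelation vanishes at the quarter period) would push the estimate
    past the intended lag.  If no lag qualifies, falls back to 1 with a
    warning.
    """
    x = np.asarray(series, dtype=float)
    if x.size < 10:
        raise ValueError("need at least 10 samples")
    if np.ptp(x) == 0:
        raise ValueError("autocorrelation is undefined for a constant series")
    rho = acf(x, nlags=x.size - 1, fft=True, adjusted=False)
    band = 1.96 / np.sqrt(x.size)
    crossed = np.flatnonzero(rho[1:] <= band)
    if crossed.size == 0:  # unreachable for the full-lag biased estimator
        warnings.warn(
            "autocorrelation never reaches zero; falling back to delay 1",
            stacklevel=2,
        )
        return 1
    return int(crossed[0]) + 1


def _mutual_info(x: np.ndarray, lag: int, bins: int) -> float:
    """Histogram estimate of I(x_k; x_{k+lag}) in nats."""
    a, b = x[:-lag], x[lag:]
    joint, _, _ = np.histogram2d(a, b, bins=bins)
    joint /= joint.sum()
    px = joint.sum(axis=1)
    py = joint.sum(axis=0)
    nz = joint > 0
    return float(np.sum(joint[nz] * np.log(joint[nz] / np.outer(px, py)[nz])))


def estimate_delay_mutual_info(series, bins: int = 16) -> int:
    """Smallest lag that is a local minimum of the average mutual information.

    The mutual information between the series and its lagged copy is
    estimated from a 2-d histogram with ``bins`` bins per axis for lags up
    to ``n / 4``.  If no local minimum exists in that range (e.g. i.i.d.
    noise, where the curve is flat near zero), falls back to 1 with a
    warning.
    """
    x = np.asarray(series, dtype=float)
    bins = int(bins)
    if bins < 2:
        raise ValueError("bins must be >= 2")
    if x.size < 10 * bins:
        raise ValueError(f"need at least {10 * bins} samples for {bins} bins")
    max_lag = x.size // 4
    mi = np.array([_mutual_info(x, lag, bins) for lag in range(1, max_lag + 1)])
    # Lag 1 counts as a minimum when the curve does not descend past it
    # (the mutual information at lag 0 is maximal by definition).
    if mi.size >= 2 and mi[0] <= mi[1]:
        return 1
    for k in range(1, mi.size - 1):
        if mi[k] < mi[k - 1] and mi[k] <= mi[k + 1]:
            return k + 1
    warnings.warn(
        "no local minimum of mutual information within n/4 lags; "
        "falling back to delay 1",
        stacklevel=2,
    )
    return 1


def estimate_dim_fnn(
    series,
    delay: int,
    r_tol: float = 10.0,
    a_tol: float = 2.0,
    threshold: float = 0.01,
) -> int:
    """Smallest embedding dimension by the false-nearest-neighbour test.

    For each trial dimension ``d`` the nearest neighbour of every delay
    vector is found; the pair is a *false* neighbour if adding the
    ``(d+1)``-th coordinate stretches it by more than ``r_tol`` relative to
    its ``d``-dimensional distance (ratio test), or moves it beyond
    ``a_tol`` attractor sizes (the second Kennel criterion).  Returns the
    first ``d`` whose false-neighbour fraction drops below ``threshold``,
    searching up to ``d = 10``.
    """
    x = np.asarray(series, dtype=float)
    if x.size < 50:
        raise ValueError("need at least 50 samples")
    if np.ptp(x) == 0:
        raise EmbeddingError("degenerate (constant) series")
    delay = int(delay)
    if delay < 1:
        raise ValueError("delay must be >= 1")
    attractor_size = float(np.std(x))

    for d in range(1, FNN_MAX_DIM + 1):
        frac = _fnn_fraction(x, d, delay, r_tol, a_tol, attractor_size)
        if frac is None:
            break
        if frac < threshold:
            return d
    raise EmbeddingError(
        f"no embedding found: false-neighbour fraction stayed >= {threshold} "
        f"up to dimension {FNN_MAX_DIM}"
    )


def _fnn_fraction(x, d, delay, r_tol, a_tol, attractor_size):
    m_next = x.size - d * delay  # vectors that still have a (d+1)-th coordinate
    if m_next < 2:
        return None
    vecs = delay_embed(x, d, delay)[:m_next]
    tree = cKDTree(vecs)
    dist, nn = tree.query(vecs, k=2)
    dist, nn = dist[:, 1], nn[:, 1]
    extra = np.abs(x[np.arange(m_next) + d * delay] - x[nn + d * delay])
    # (Near-)coincident vectors — exact repeats of periodic data — defeat
    # the distance-ratio test with round-off noise; such a pair is a false
    # neighbour only if the extra coordinate genuinely separates it.
    eps = 1e-10 * attractor_size
    coincident = dist < eps
    safe_dist = np.where(coincident, 1.0, dist)
    ratio_test = np.where(coincident, extra > eps, extra / safe_dist > r_tol)
    size_test = np.sqrt(dist**2 + extra**2) / attractor_size > a_tol
    return float(np.mean(ratio_test | size_test))
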