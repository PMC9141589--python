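"""CSV input/output and the synthetic fixture generator.

Series are exchanged as two-column CSV files with a ``t,value`` header,
decimal points and UTF-8 encoding.  Writing uses 17 significant digits so a
write/read round trip is lossless for doubles.  A single-column file
(values only) is accepted with auto-assigned times ``0 .. n-1`` and a
warning.

The fixture generator produces seasonal-plus-trend-plus-noise series

    x_k = trend_slope * k + amplitude * |sin(pi k / period)|^p + eps_k,

with Gaussian noise ``eps_k ~ N(0, noise_sd^2)``.  The peak-sharpening
exponent ``p`` turns the smooth seasonal bump into the sharp repetitive
peaks typical of epidemic-count series; ``p = 1`` resembles smooth seasonal
records such as monthly sales or temperature data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .series import TimeSeries

__all__ = ["read_series", "write_series", "FixtureSpec", "make_fixture"]


def read_series(path) -> TimeSeries:
    """Read a ``t,value`` CSV (or a single value column) into a series."""
    frame = pd.read_csv(path, float_precision="round_trip")
    if frame.shape[1] == 0 or frame.shape[0] == 0:
        raise ValueError(f"{path}: empty file")
    if frame.shape[1] == 1:
        warnings.warn(
            f"{path}: single-column CSV, assigning times 0..{len(frame) - 1}",
            stacklevel=2,
        )
        values = pd.to_numeric(frame.iloc[:, 0], errors="raise").to_numpy(float)
        return TimeSeries(np.arange(values.size, dtype=float), values)
    t = pd.to_numeric(frame.iloc[:, 0], errors="raise").to_numpy(float)
    x = pd.to_numeric(frame.iloc[:, 1], errors="raise").to_numpy(float)
    return TimeSeries(t, x)  # raises with the offending row on non-monotone t


def write_series(series: TimeSeries, path) -> None:
    """Write a series as ``t,value`` CSV, lossless at 17 significant digits."""
    pd.DataFrame({"t": series.t, "value": series.x}).to_csv(
        path, index=False, float_format="%.17g"
    )


@dataclass(frozen=True)
class FixtureSpec:
    """Shape parameters of a synthetic seasonal test series."""

    length: int = 200
    period: float = 12.0
    trend_slope: float = 0.0
    noise_sd: float = 0.05
    amplitude: float = 1.0
    peak_power: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.length < 2:
            raise ValueError("length must be >= 2")
        if self.period > 0 and self.length < 2 * self.period:
            raise ValueError("seasonal fixtures need length >= 2 * period")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def make_fixture(spec: FixtureSpec) -> TimeSeries:
    """Deterministic (seeded) synthetic series from a :class:`FixtureSpec`."""
    rng = np.random.default_rng(spec.seed)
    k = np.arange(spec.length, dtype=float)
    x = spec.trend_slope * k
    if spec.period > 0:
        x = x + spec.amplitude * np.abs(np.sin(np.pi * k / spec.period)) ** spec.peak_power
    if spec.noise_sd > 0:
        x = x + rng.normal(0.0, spec.noise_sd, spec.length)
    return TimeSeries(k, x)
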