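"""Deletion/reconstruction benchmark with linear and cubic-spline baselines.

The benchmark deletes samples from a known series, reconstructs them with
each method, and scores the reconstruction error.  For an interpolation
count ``n_I`` the kept samples follow the stride-``(n_I + 1)`` pattern
``x_1, x_{n_I+2}, x_{2 n_I+2}, ...`` (1-based), and the final sample is
always kept as the closing anchor — so every gap has both ends, and the
last gap may hold fewer than ``n_I`` deleted points when the series length
is not on the pattern.

Scoring: the squared reconstruction errors at the deleted samples are
summed and normalized by the *full* signal length (kept samples are
reproduced exactly by every method here and contribute zero), then rooted.
This follows the RMSE definition used to produce the published benchmark
numbers, whose ``n`` is the length of the signal.  The plain
:func:`rmse` helper is the ordinary root-mean-square error of two
equal-length sequences.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from scipy.interpolate import CubicSpline

from .ga import GAConfig, run_ga
from .series import TimeSeries

__all__ = [
    "ValidationSplit",
    "RmseValue",
    "ValidationReport",
    "PreprocessRecord",
    "subsample",
    "rmse",
    "linear_baseline",
    "spline_baseline",
    "preprocess",
    "invert_preprocess",
    "run_benchmark",
]


@dataclass(frozen=True)
class ValidationSplit:
    """Index sets (0-based) of kept and deleted samples of a series."""

    kept: np.ndarray
    missing: np.ndarray
    n_interp: int

    @property
    def n_total(self) -> int:
        return self.kept.size + self.missing.size

    def gap_counts(self) -> np.ndarray:
        """Number of deleted samples inside each kept-to-kept gap."""
        return np.diff(self.kept) - 1


class RmseValue(NamedTuple):
    value: float
    n_points: int


def subsample(series_length: int, n_interp: int) -> ValidationSplit:
    """Stride-``(n_I + 1)`` deletion pattern with the last sample kept.

    ``series_length`` may also be a :class:`TimeSeries`.
    """
    if isinstance(series_length, TimeSeries):
        series_length = len(series_length)
    n = int(series_length)
    n_interp = int(n_interp)
    if n_interp < 1:
        raise ValueError("n_interp must be >= 1")
    if n < n_interp + 2:
        raise ValueError(f"series of length {n} too short for n_interp={n_interp}")
    kept = np.arange(0, n, n_interp + 1)
    if kept[-1] != n - 1:
        kept = np.append(kept, n - 1)
    missing = np.setdiff1d(np.arange(n), kept)
    return ValidationSplit(kept, missing, n_interp)


def rmse(truth, estimate) -> RmseValue:
    """Root mean squared error of two equal-length sequences."""
    truth = np.asarray(truth, dtype=float)
    estimate = np.asarray(estimate, dtype=float)
    if truth.shape != estimate.shape or truth.ndim != 1:
        raise ValueError("truth and estimate must be 1-d and of equal length")
    if truth.size == 0:
        raise ValueError("empty input")
    return RmseValue(float(np.sqrt(np.mean((estimate - truth) ** 2))), truth.size)


def linear_baseline(split: ValidationSplit, series: TimeSeries) -> np.ndarray:
    """Full reconstruction by straight segments between kept points."""
    if split.kept.size < 2:
        raise ValueError("need at least 2 kept points for linear interpolation")
    recon = series.x.copy()
    recon[split.missing] = np.interp(
        series.t[split.missing], series.t[split.kept], series.x[split.kept]
    )
    return recon


def spline_baseline(split: ValidationSplit, series: TimeSeries) -> np.ndarray:
    """Full reconstruction by a C^2 not-a-knot cubic spline through kept points."""
    if split.kept.size < 4:
        raise ValueError("need at least 4 kept points for a cubic spline")
    recon = series.x.copy()
    spline = CubicSpline(series.t[split.kept], series.x[split.kept])  # not-a-knot
    recon[split.missing] = spline(series.t[split.missing])
    return recon


@dataclass(frozen=True)
class PreprocessRecord:
    """Parameters needed to undo detrending and unit-interval rescaling."""

    slope: float = 0.0
    intercept: float = 0.0
    offset: float = 0.0
    span: float = 1.0


def preprocess(series: TimeSeries, rescale: bool = True, detrend: bool = False):
    """Optional linear detrend, then min-max rescale to the unit interval.

    Returns the transformed series together with a :class:`PreprocessRecord`
    that :func:`invert_preprocess` uses to map reconstructions back to the
    original scale, so errors can be reported in raw units.
    """
    x = series.x.copy()
    slope = intercept = 0.0
    if detrend:
        slope, intercept = np.polyfit(series.t, x, 1)
        x = x - (slope * series.t + intercept)
    offset, span = 0.0, 1.0
    if rescale:
        offset = float(x.min())
        span = float(np.ptp(x))
        # detrending a perfect line leaves only round-off; treat that as
        # constant rather than blowing the residue up to the unit interval
        if span <= 1e-12 * max(1.0, float(np.max(np.abs(series.x)))):
            raise ValueError("cannot rescale a (numerically) constant series to the unit interval")
        x = (x - offset) / span
    record = PreprocessRecord(slope, intercept, offset, span)
    return TimeSeries(series.t, x), record


def invert_preprocess(series: TimeSeries, record: PreprocessRecord) -> TimeSeries:
    """Exact inverse of :func:`preprocess` on the same time grid."""
    x = series.x * record.span + record.offset
    x = x + record.slope * series.t + record.intercept
    return TimeSeries(series.t, x)


@dataclass
class ValidationReport:
    """Per-method benchmark errors, in the scoring convention above."""

    n_interp: int
    population_mean: RmseValue
    population_lowest: RmseValue
    linear: RmseValue
    spline: RmseValue
    ga_improved: RmseValue
    below_best_fraction: float
    generations_run: int
    seed: int

    def as_dict(self) -> dict:
        return {
            "n_interp": self.n_interp,
            "rmse_population_mean": self.population_mean.value,
            "rmse_lowest_in_population": self.population_lowest.value,
            "rmse_linear": self.linear.value,
            "rmse_spline": self.spline.value,
            "rmse_ga_improved": self.ga_improved.value,
            "below_best_percent": 100.0 * self.below_best_fraction,
            "scored_points": self.population_mean.n_points,
            "generations_run": self.generations_run,
            "seed": self.seed,
        }


def _score(recon: np.ndarray, truth: np.ndarray) -> RmseValue:
    # Kept samples are exact in every reconstruction, so the RMSE over the
    # full signal equals the deleted-point error mass normalized by the
    # signal length.
    return rmse(truth, recon)


def run_benchmark(
    series: TimeSeries,
    n_interp: int,
    ga_config: GAConfig,
    rescale: bool = False,
    detrend: bool = False,
) -> ValidationReport:
    """Delete, reconstruct by every method, and score against the truth.

    The bridge population and genetic algorithm see the (optionally
    preprocessed) kept points only; their reconstructions are mapped back
    to the original scale before scoring, as are the baselines' inputs.
    """
    split = subsample(len(series), n_interp)
    truth = series.x

    work, record = (
        preprocess(series, rescale=rescale, detrend=detrend)
        if (rescale or detrend)
        else (series, PreprocessRecord())
    )

    observed = TimeSeries(work.t[split.kept], work.x[split.kept])
    result = run_ga(observed, split.gap_counts(), ga_config, keep_initial=True)

    def to_raw(values: np.ndarray) -> np.ndarray:
        return invert_preprocess(TimeSeries(series.t, values), record).x

    candidate_values = np.array([to_raw(c.series.x) for c in result.initial_population])
    per_candidate = np.sqrt(np.mean((candidate_values - truth) ** 2, axis=1))
    mean_series = candidate_values.mean(axis=0)

    report = ValidationReport(
        n_interp=n_interp,
        population_mean=_score(mean_series, truth),
        population_lowest=RmseValue(float(per_candidate.min()), truth.size),
        linear=_score(linear_baseline(split, series), truth),
        spline=_score(spline_baseline(split, series), truth),
        ga_improved=_score(to_raw(result.best.series.x), truth),
        below_best_fraction=float(
            np.mean(per_candidate < np.sqrt(np.mean((to_raw(result.best.series.x) - truth) ** 2)))
        ),
        generations_run=result.generations_run,
        seed=ga_config.seed,
    )
    return report
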