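"""Univariate time-series container used throughout the package.

A :class:`TimeSeries` is an immutable pair of equal-length float arrays
``(t, x)`` with strictly increasing sample times.  It is deliberately thin:
every algorithm in this package operates on plain numpy arrays and uses the
container only at module boundaries (file I/O, simulation output,
interpolation results).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["TimeSeries"]


@dataclass(frozen=True)
class TimeSeries:
    """An ordered sequence of ``(time, value)`` pairs.

    Parameters
    ----------
    t
        Sample times, strictly increasing.  Arbitrary units; non-equidistant
        sampling is allowed.
    x
        Sample values, same length as ``t``.
    """

    t: np.ndarray
    x: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=float)
        x = np.asarray(self.x, dtype=float)
        if t.ndim != 1 or x.ndim != 1:
            raise ValueError("t and x must be one-dimensional")
        if t.shape != x.shape:
            raise ValueError(
                f"t and x must have equal length, got {t.size} and {x.size}"
            )
        if t.size == 0:
            raise ValueError("empty series")
        dt = np.diff(t)
        if np.any(dt <= 0):
            i = int(np.argmax(dt <= 0))
            raise ValueError(
                f"sample times must be strictly increasing; "
                f"row {i + 1} (t={t[i + 1]!r}) does not follow t={t[i]!r}"
            )
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "x", x)

    def __len__(self) -> int:
        return self.t.size

    def equals(self, other: "TimeSeries", *, atol: float = 0.0) -> bool:
        """Exact (or toleranced) element-wise equality of two series."""
        if len(self) != len(other):
            return False
        if atol == 0.0:
            return bool(np.array_equal(self.t, other.t) and np.array_equal(self.x, other.x))
        return bool(
            np.allclose(self.t, other.t, rtol=0.0, atol=atol)
            and np.allclose(self.x, other.x, rtol=0.0, atol=atol)
        )
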