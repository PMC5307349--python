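"""Core containers: sample paths, increment series, parameter spaces.

A trajectory is a one-dimensional process observed at strictly increasing
times in the unit interval.  Every estimator in the package consumes a
:class:`SamplePath`; by self-similarity of fractional Brownian motion an
arbitrary observation window can always be rescaled to the unit interval
first (:meth:`SamplePath.rescaled`).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ParameterSpace",
    "SamplePath",
    "IncrementSeries",
]


class ParameterSpace(enum.Enum):
    """Support of the Hurst index used by estimators and priors.

    ``SHORT`` is the anti-persistent (rough) regime ``(0, 1/2]``, ``LONG``
    the persistent regime ``(1/2, 1)`` and ``FULL`` the whole interval
    ``(0, 1)``.  The boundary ``H = 1/2`` (Brownian motion) belongs to
    ``SHORT``.
    """

    SHORT = "short"
    LONG = "long"
    FULL = "full"

    @property
    def bounds(self) -> tuple[float, float]:
        if self is ParameterSpace.SHORT:
            return (0.0, 0.5)
        if self is ParameterSpace.LONG:
            return (0.5, 1.0)
        return (0.0, 1.0)

    def contains(self, H: float) -> bool:
        lo, hi = self.bounds
        if self is ParameterSpace.SHORT:
            return lo < H <= hi
        if self is ParameterSpace.LONG:
            return lo < H < hi
        return lo < H < hi

    @staticmethod
    def of(H: float) -> "ParameterSpace":
        """Restricted space containing ``H``."""
        if not 0.0 < H < 1.0:
            raise ValueError(f"Hurst index must lie in (0, 1); got {H}")
        return ParameterSpace.SHORT if H <= 0.5 else ParameterSpace.LONG


@dataclass(frozen=True)
class IncrementSeries:
    """First differences of a sample path (length ``m - 1``)."""

    values: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))

    def __len__(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class SamplePath:
    """A regularly or irregularly sampled trajectory on the unit interval.

    The path value at time zero is fixed to zero and not stored.  For a
    regular path of ``m`` observations the grid is ``t_i = i / m`` for
    ``i = 1..m``.
    """

    times: np.ndarray
    values: np.ndarray
    regular: bool = field(default=False)

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if t.ndim != 1 or v.ndim != 1 or len(t) != len(v):
            raise ValueError("times and values must be 1-d arrays of equal length")
        if len(t) < 2:
            raise ValueError("a sample path needs at least two observations")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if t[0] <= 0 or t[-1] > 1.0 + 1e-12:
            raise ValueError("times must lie in (0, 1]")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)

    @property
    def m(self) -> int:
        return len(self.values)

    @property
    def spacing(self) -> float:
        """Grid spacing ``1/m`` of a regular path."""
        if not self.regular:
            raise ValueError("spacing is defined for regular paths only")
        return 1.0 / self.m

    @classmethod
    def from_values(cls, values) -> "SamplePath":
        """Regular path ``t_i = i/m`` from a value vector."""
        values = np.asarray(values, dtype=float)
        m = len(values)
        return cls(times=np.arange(1, m + 1) / m, values=values, regular=True)

    def increments(self) -> IncrementSeries:
        return IncrementSeries(np.diff(self.values))

    def rescaled(self) -> "SamplePath":
        """Map arbitrary observation times onto the regular unit grid.

        Uses the self-similarity of index-``H`` processes: stretching time
        and ignoring the (unidentifiable) global scale leaves the Hurst
        index unchanged, so a transect of ``m`` nodes may be re-indexed to
        ``t_i = i/m`` with values shifted to start from zero.
        """
        v = self.values - self.values[0]
        return SamplePath.from_values(v[:])

    # -- plain-text I/O ----------------------------------------------------
    def to_csv(self, path) -> None:
        pd.DataFrame({"time": self.times, "value": self.values}).to_csv(
            path, index=False
        )

    @classmethod
    def from_csv(cls, path) -> "SamplePath":
        df = pd.read_csv(path)
        if not {"time", "value"} <= set(df.columns):
            raise ValueError("path CSV must have 'time' and 'value' columns")
        t = df["time"].to_numpy(dtype=float)
        m = len(t)
        regular = bool(np.allclose(t, np.arange(1, m + 1) / m))
        return cls(times=t, values=df["value"].to_numpy(dtype=float), regular=regular)
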