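"""Uniformly sampled signal container.

Every waveform in the package -- simulated pulses, motion artifacts,
filtered bands, instant-parameter tracks -- is carried by
:class:`UniformSeries`: a real-valued array with a sampling rate and a
start time.  The container is deliberately minimal; all processing lives
in the functional modules.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["UniformSeries"]


@dataclass(frozen=True)
class UniformSeries:
    """A uniformly sampled real-valued signal.

    Parameters
    ----------
    values : ndarray
        Sample values, one-dimensional, finite.
    fs : float
        Sampling rate in Hz, > 0.
    t0 : float, optional
        Time of the first sample in seconds (default 0).
    """

    values: np.ndarray
    fs: float
    t0: float = 0.0

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        if vals.ndim != 1:
            raise ValueError(f"values must be 1-D, got shape {vals.shape}")
        if vals.size == 0:
            raise ValueError("empty series")
        if not np.isfinite(self.fs) or self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if not np.all(np.isfinite(vals)):
            raise ValueError("series contains non-finite values")
        object.__setattr__(self, "values", vals)

    def __len__(self) -> int:
        return self.values.size

    @property
    def dt(self) -> float:
        return 1.0 / self.fs

    @property
    def duration(self) -> float:
        """Record length in seconds (n samples / fs)."""
        return self.values.size / self.fs

    @property
    def t(self) -> np.ndarray:
        """Time axis in seconds."""
        return self.t0 + np.arange(self.values.size) / self.fs

    def with_values(self, values: np.ndarray) -> "UniformSeries":
        """Same grid, new samples."""
        return UniformSeries(np.asarray(values, dtype=float), self.fs, self.t0)

    def crop(self, start: float, end: float) -> "UniformSeries":
        """Return the sub-series with t in [start, end)."""
        i0 = int(np.ceil((start - self.t0) * self.fs - 1e-6))
        i1 = int(np.floor((end - self.t0) * self.fs + 1e-6))
        i0 = max(i0, 0)
        i1 = min(i1, len(self))
        if i1 <= i0:
            raise ValueError(f"empty segment [{start}, {end}) for record "
                             f"spanning [{self.t0}, {self.t0 + self.duration})")
        return UniformSeries(self.values[i0:i1], self.fs,
                             self.t0 + i0 / self.fs)

    def same_grid(self, other: "UniformSeries", rtol: float = 1e-9) -> bool:
        return (len(self) == len(other)
                and abs(self.fs - other.fs) <= rtol * self.fs
                and abs(self.t0 - other.t0) <= rtol / self.fs + 1e-12)

    def require_same_grid(self, other: "UniformSeries") -> None:
        if not self.same_grid(other):
            raise ValueError(
                f"series grids differ: ({len(self)}, fs={self.fs}, t0={self.t0})"
                f" vs ({len(other)}, fs={other.fs}, t0={other.t0})")


def as_series(values, fs: float, t0: float = 0.0) -> UniformSeries:
    """Convenience constructor accepting any array-like."""
    return UniformSeries(np.asarray(values, dtype=float), fs, t0)
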