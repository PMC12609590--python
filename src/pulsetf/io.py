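"""Record readers and writers.

The native interchange format is two-column CSV (time_s, value); a
single value column is accepted when the sampling rate is given
explicitly.  WFDB records (as distributed by the public pulse-waveform
datasets) are read through the optional ``wfdb`` package when it is
installed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .series import UniformSeries

__all__ = ["PulseRecord", "read_signal", "write_series_csv"]


@dataclass(frozen=True)
class PulseRecord:
    series: UniformSeries
    label: str = ""
    sensor_kind: str = "unknown"

    def __post_init__(self) -> None:
        if self.sensor_kind not in ("tactile", "ppg", "unknown"):
            raise ValueError(f"unknown sensor_kind {self.sensor_kind!r}")


def _read_csv(path: Path, fs: float | None) -> UniformSeries:
    df = pd.read_csv(path, comment="#")
    if df.shape[1] >= 2:
        t = df.iloc[:, 0].to_numpy(dtype=float)
        v = df.iloc[:, 1].to_numpy(dtype=float)
        steps = np.diff(t)
        med = float(np.median(steps))
        if med <= 0 or np.any(np.abs(steps - med) > 0.01 * med):
            raise ValueError(f"{path}: time stamps are not uniform within "
                             "1% of the median step")
        return UniformSeries(v, fs=1.0 / med, t0=float(t[0]))
    if fs is None:
        raise ValueError(f"{path}: single-column CSV requires an explicit "
                         "sampling rate (fs)")
    return UniformSeries(df.iloc[:, 0].to_numpy(dtype=float), fs=fs)


def _read_wfdb(path: Path, channel: str | None, fs: float | None) -> UniformSeries:
    try:
        import wfdb  # noqa: F401
    except ImportError as exc:  # pragma: no cover - wfdb is optional
        raise ImportError(
            "reading WFDB records requires the optional 'wfdb' package; "
            "install it or convert the record to CSV") from exc
    rec = wfdb.rdrecord(str(path.with_suffix("")))  # pragma: no cover
    names = list(rec.sig_name)  # pragma: no cover
    if channel is None:  # pragma: no cover
        idx = 0
    elif channel in names:  # pragma: no cover
        idx = names.index(channel)
    else:  # pragma: no cover
        raise ValueError(f"channel {channel!r} not in record (has {names})")
    return UniformSeries(rec.p_signal[:, idx], fs=float(rec.fs))  # pragma: no cover


def read_signal(path: str | Path, format: str = "csv",
                channel: str | None = None, fs: float | None = None,
                segment: tuple[float, float] | None = None,
                sensor_kind: str = "unknown") -> PulseRecord:
    """Load a uniformly sampled pulse record.

    ``segment`` is a (start, end) window in seconds applied at load.
    """
    path = Path(path)
    if format == "csv":
        if not path.exists():
            raise FileNotFoundError(path)
        series = _read_csv(path, fs)
    elif format == "wfdb":
        series = _read_wfdb(path, channel, fs)
    else:
        raise ValueError(f"unknown format {format!r}")
    if segment is not None:
        series = series.crop(*segment)
    return PulseRecord(series=series, label=path.stem,
                       sensor_kind=sensor_kind)


def write_series_csv(path: str | Path, series: UniformSeries,
                     value_name: str = "value") -> None:
    """Write a series as two-column CSV (time_s, value)."""
    pd.DataFrame({"time_s": series.t, value_name: series.values}).to_csv(
        path, index=False, float_format="%.12g")


def write_sidecar(path: str | Path, payload: dict) -> None:
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True,
                                     default=float) + "\n")
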