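"""Hilbert vibration decomposition (HVD) and instant-parameter tracks.

Each separated harmonic x_i(t) is written as

    x_i(t) = A_i(t) cos(2 pi int f_i dt + phi0_i(t))

where A_i is the instant amplitude, f_i the instant frequency, and
phi0_i the instant *initial* phase, defined against the constant-rate
reference ramp 2 pi i f_C t:

    phi0_i(t) = theta_i(t) - 2 pi i f_C t

with theta_i the unwrapped analytic phase.  This reference is the crux
of the method: respiration appears in f_i(t) as a frequency modulation
of amplitude R f_r and in phi0_i(t) as a phase modulation of amplitude
R, while drift-driven multiplicative distortion hits A_i(t) hard, f_i(t)
weakly, and phi0_i(t) hardly at all -- which is why phi0 is the
preferred carrier for respiration extraction.

The decomposition itself is classic iterative HVD: estimate the
instantaneous frequency of the dominant component by low-pass smoothing
the analytic-phase derivative, synchronously demodulate against the
integrated reference phase to refine envelope and residual phase,
reconstruct, subtract, repeat.  The smoothing cutoff (default 0.6 Hz)
passes the 0.1-0.5 Hz respiration band into the frequency track while
rejecting carrier-rate ripple.  Hilbert end effects are meaningless, so
every statistic excludes a trim window at each end.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from scipy.integrate import cumulative_trapezoid
from scipy.signal import hilbert

from .series import UniformSeries
from .spectral import lowpass_zero_phase

__all__ = [
    "HarmonicTrack",
    "HVDComponent",
    "analytic_tracks",
    "hvd_extract",
    "harmonic_instant_params",
    "default_trim",
]

FREQ_SMOOTH_CUTOFF = 0.6   # Hz; keeps respiration inside f_i(t)
N_ITERATIONS = 2


@dataclass(frozen=True)
class HarmonicTrack:
    """Instant parameters of one harmonic.

    ``phase`` is the full unwrapped analytic phase theta(t); ``phi0`` is
    theta(t) - 2 pi i f_C t.  ``valid`` is the sample slice that
    excludes the Hilbert end effects.
    """

    i: int
    A: UniformSeries
    f: UniformSeries
    phi0: UniformSeries
    phase: UniformSeries
    component: UniformSeries
    valid: slice
    f_C: float

    @property
    def t_valid(self) -> np.ndarray:
        return self.A.t[self.valid]

    def mean_valid(self, series: UniformSeries) -> float:
        return float(np.mean(series.values[self.valid]))


class HVDComponent(NamedTuple):
    component: UniformSeries
    amplitude: UniformSeries
    frequency: UniformSeries
    phase: UniformSeries      # unwrapped total phase of the component


def default_trim(f_C: float, floor: float = 2.0) -> float:
    """End-effect trim in seconds: max(3 carrier periods, 2 s)."""
    return max(3.0 / f_C, floor)


def analytic_tracks(series: UniformSeries) -> tuple[UniformSeries, UniformSeries]:
    """Envelope and continuous unwrapped phase of the analytic signal.

    The record is mirror-extended before the Hilbert transform so that
    the inevitable end effects fall mostly on the padding rather than on
    the record itself; the remaining edge distortion is handled by the
    callers' trim windows.
    """
    x = series.values
    if not np.any(x):
        raise ValueError("all-zero input has no analytic phase")
    pad = min(x.size - 1, int(round(10.0 * series.fs)))
    if pad > 0:
        xe = np.concatenate([x[pad:0:-1], x, x[-2:-pad - 2:-1]])
        z = hilbert(xe)[pad:pad + x.size]
    else:
        z = hilbert(x)
    amp = np.abs(z)
    phase = np.unwrap(np.angle(z))
    return series.with_values(amp), series.with_values(phase)


def _smooth(series: UniformSeries, cutoff: float) -> UniformSeries:
    if cutoff >= series.fs / 2:
        return series
    return lowpass_zero_phase(series, cutoff)


def _edge_held_if(phase: np.ndarray, fs: float) -> np.ndarray:
    """Raw instantaneous frequency with sanitized ends.

    The phase derivative is meaningless over roughly the first and last
    couple of carrier periods (Hilbert end effects); holding the nearest
    interior value there keeps the garbage from being smeared inward by
    the smoothing filter.
    """
    g = np.gradient(phase, 1.0 / fs) / (2.0 * np.pi)
    n = g.size
    carrier = float(np.median(g[n // 4: 3 * n // 4]))
    k = int(round(2.0 / max(abs(carrier), 0.2) * fs))
    k = min(max(k, 1), n // 4)
    g[:k] = g[k]
    g[n - k:] = g[n - k - 1]
    return g


def _extract_one(series: UniformSeries, freq_smooth_cutoff: float,
                 n_iterations: int) -> HVDComponent:
    """One HVD stage: dominant component of ``series``."""
    amp, phase = analytic_tracks(series)
    dt = series.dt
    finst = _smooth(series.with_values(_edge_held_if(phase.values, series.fs)),
                    freq_smooth_cutoff)
    x = series.values
    theta = phase.values
    A = amp.values
    mid = len(theta) // 2
    for _ in range(max(1, n_iterations)):
        cum = 2.0 * np.pi * cumulative_trapezoid(finst.values, dx=dt,
                                                 initial=0.0)
        # anchor the reference phase to the observed phase mid-record,
        # away from the Hilbert end effects
        ref = cum - cum[mid] + theta[mid]
        # synchronous demodulation against the smoothed reference phase
        i_arm = _smooth(series.with_values(2.0 * x * np.cos(ref)),
                        freq_smooth_cutoff).values
        q_arm = _smooth(series.with_values(-2.0 * x * np.sin(ref)),
                        freq_smooth_cutoff).values
        A = np.hypot(i_arm, q_arm)
        theta = ref + np.unwrap(np.arctan2(q_arm, i_arm))
        finst = _smooth(series.with_values(_edge_held_if(theta, series.fs)),
                        freq_smooth_cutoff)
    comp = A * np.cos(theta)
    return HVDComponent(series.with_values(comp), series.with_values(A),
                        finst, series.with_values(theta))


def hvd_extract(series: UniformSeries, n_components: int,
                freq_smooth_cutoff: float = FREQ_SMOOTH_CUTOFF,
                n_iterations: int = N_ITERATIONS) -> list[HVDComponent]:
    """Iterative largest-component extraction.

    Components are extracted greedily (largest energy first) and
    returned ordered by energy.  Extraction stops with a warning if
    subtracting a component fails to reduce the residual energy.
    """
    if n_components < 1:
        raise ValueError("n_components must be >= 1")
    residual = series
    out: list[HVDComponent] = []
    for _ in range(n_components):
        comp = _extract_one(residual, freq_smooth_cutoff, n_iterations)
        new_vals = residual.values - comp.component.values
        if out and np.sum(new_vals**2) > np.sum(residual.values**2):
            warnings.warn("HVD stopped early: residual energy increased",
                          RuntimeWarning, stacklevel=2)
            break
        out.append(comp)
        residual = residual.with_values(new_vals)
        if not np.any(residual.values):
            break
    out.sort(key=lambda c: -float(np.sum(c.component.values**2)))
    return out


def harmonic_instant_params(x_sd_i: UniformSeries, i: int, f_C: float,
                            trim_seconds: float | None = None,
                            freq_smooth_cutoff: float = FREQ_SMOOTH_CUTOFF,
                            n_iterations: int = N_ITERATIONS,
                            ) -> HarmonicTrack:
    """Instant amplitude / frequency / initial phase of one harmonic band."""
    if trim_seconds is None:
        trim_seconds = default_trim(f_C)
    if trim_seconds > x_sd_i.duration / 2.0:
        raise ValueError(
            f"trim of {trim_seconds:.1f} s per end exceeds half the "
            f"{x_sd_i.duration:.1f} s record")
    comp = _extract_one(x_sd_i, freq_smooth_cutoff, n_iterations)
    ramp = 2.0 * np.pi * i * f_C * x_sd_i.t
    phi0 = comp.phase.values - ramp
    k = int(round(trim_seconds * x_sd_i.fs))
    valid = slice(k, len(x_sd_i) - k)
    return HarmonicTrack(i=i, A=comp.amplitude, f=comp.frequency,
                         phi0=x_sd_i.with_values(phi0), phase=comp.phase,
                         component=comp.component, valid=valid, f_C=f_C)
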