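"""Synthetic pulse and motion-artifact generators.

An arterial pulse signal is modelled as a sum of harmonics of the heart
rate whose common phase is modulated by respiration (respiratory sinus
arrhythmia):

    y(t) = sum_i A_i cos(2 pi i f_C t + phi0 + psi(t)),
    psi(t) = R sin(2 pi f_r t + alpha0).

The frequency of the i-th harmonic is therefore
i f_C + R f_r cos(2 pi f_r t + alpha0): respiration rides on every
harmonic as a frequency modulation of amplitude R f_r and, equivalently,
as a phase modulation of amplitude R.  The respiration reference signal
embedded in a harmonic's frequency is r(t) = B cos(2 pi f_r t + alpha0)
with B = -R f_r (B is the respiration modulation, the strength of RSA).

Two motion-artifact families are provided:

* at rest -- band-limited (< 0.7 Hz) stochastic baseline drift; the
  measured drifts the model was developed against are not redistributable,
  so a seeded Gaussian surrogate with matched bandwidth and configurable
  RMS stands in;
* during activities -- a slowly decaying tone exp(-0.01 t) cos(2 pi f t)
  whose frequency falls inside the pulse band.

All generators are pure functions of their arguments (and seed) and
return the excitation together with its analytic time derivative, which
the SDOF solvers consume.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .series import UniformSeries

__all__ = [
    "PulseSpec",
    "RespReference",
    "synth_pulse",
    "resp_reference",
    "gen_ma_rest",
    "gen_ma_activity",
]


@dataclass(frozen=True)
class PulseSpec:
    """Configuration of the multi-harmonic synthetic pulse.

    Parameters
    ----------
    f_C : float
        Fundamental (constant-heart-rate) frequency in Hz; must exceed
        0.2 Hz so the downstream harmonic bandwidth rule BW = f_C - 0.2
        stays positive.
    harmonics : sequence of (A_i, phi0_i)
        Amplitude (a.u.) and initial phase (rad) per harmonic, order 1..N.
    R : float
        Respiration phase-modulation amplitude in rad (>= 0).
    f_r : float
        Respiration frequency in Hz; must lie below 0.7 Hz (the baseline
        drift band edge) when R > 0.
    alpha0 : float
        Respiration initial phase in rad.
    fs : float
        Sampling rate in Hz; must satisfy Nyquist for the highest
        harmonic with margin, fs > 2 (N + 1) f_C.
    duration : float
        Record length in seconds.
    """

    f_C: float
    harmonics: tuple = ((1.0, 0.0),)
    R: float = 0.0
    f_r: float = 0.2
    alpha0: float = 0.0
    fs: float = 100.0
    duration: float = 80.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "harmonics",
                           tuple((float(a), float(p)) for a, p in self.harmonics))
        if self.f_C <= 0.2:
            raise ValueError("f_C must exceed 0.2 Hz")
        if not self.harmonics:
            raise ValueError("at least one harmonic required")
        if self.R < 0:
            raise ValueError("R must be >= 0")
        if self.R > 0 and not (0.0 < self.f_r < 0.7):
            raise ValueError("respiration frequency must lie in (0, 0.7) Hz")
        n = len(self.harmonics)
        if self.fs <= 2.0 * (n * self.f_C + self.f_C):
            raise ValueError(
                f"fs={self.fs} Hz violates Nyquist margin for N={n} "
                f"harmonics at f_C={self.f_C} Hz (need fs > {2*(n+1)*self.f_C})")

    @property
    def n_harmonics(self) -> int:
        return len(self.harmonics)


@dataclass(frozen=True)
class RespReference:
    """Ground-truth respiration signal embedded in harmonic frequency.

    ``B`` is the signed respiration modulation in Hz, B = -R f_r.
    """

    series: UniformSeries
    B: float


@dataclass(frozen=True)
class BaseExcitation:
    """An excitation waveform and its time derivative.

    The derivative is analytic for synthetic inputs; callers building an
    excitation from measured data should use :func:`from_samples`, which
    differentiates numerically (central differences).
    """

    series: UniformSeries
    derivative: UniformSeries

    def __post_init__(self) -> None:
        self.series.require_same_grid(self.derivative)

    @staticmethod
    def from_samples(series: UniformSeries) -> "BaseExcitation":
        d = np.gradient(series.values, series.dt)
        return BaseExcitation(series, series.with_values(d))

    @staticmethod
    def zero(fs: float, duration: float, t0: float = 0.0) -> "BaseExcitation":
        n = int(round(duration * fs))
        z = UniformSeries(np.zeros(n), fs, t0)
        return BaseExcitation(z, z)


def _time(fs: float, duration: float) -> np.ndarray:
    return np.arange(int(round(duration * fs))) / fs


def synth_pulse(spec: PulseSpec) -> BaseExcitation:
    """Generate the multi-harmonic pulse y(t) with closed-form derivative."""
    t = _time(spec.fs, spec.duration)
    psi = spec.R * np.sin(2 * np.pi * spec.f_r * t + spec.alpha0)
    dpsi = 2 * np.pi * spec.f_r * spec.R * np.cos(2 * np.pi * spec.f_r * t
                                                  + spec.alpha0)
    y = np.zeros_like(t)
    dy = np.zeros_like(t)
    for i, (amp, phi0) in enumerate(spec.harmonics, start=1):
        arg = 2 * np.pi * i * spec.f_C * t + phi0 + psi
        y += amp * np.cos(arg)
        dy += -amp * (2 * np.pi * i * spec.f_C + dpsi) * np.sin(arg)
    return BaseExcitation(UniformSeries(y, spec.fs),
                          UniformSeries(dy, spec.fs))


def resp_reference(spec: PulseSpec) -> RespReference:
    """Respiration reference r(t) = B cos(2 pi f_r t + alpha0), B = -R f_r."""
    t = _time(spec.fs, spec.duration)
    B = -spec.R * spec.f_r
    r = B * np.cos(2 * np.pi * spec.f_r * t + spec.alpha0)
    return RespReference(UniformSeries(r, spec.fs), B)


def gen_ma_rest(fs: float, duration: float, cutoff: float = 0.7,
                rms_amplitude: float = 0.3, seed: int | None = 0) -> BaseExcitation:
    """Band-limited stochastic baseline drift: the motion artifact at rest.

    Zero-mean Gaussian noise low-pass filtered (zero phase) at ``cutoff``
    Hz and rescaled to ``rms_amplitude``.  Deterministic for a fixed seed.
    """
    n = int(round(duration * fs))
    if rms_amplitude == 0:
        z = UniformSeries(np.zeros(n), fs)
        return BaseExcitation(z, z)
    rng = np.random.default_rng(seed)
    white = rng.standard_normal(n)
    # shape the spectrum directly: flat below 0.85*cutoff, raised-cosine
    # taper to zero at the cutoff, nothing above it.  Time-domain IIR
    # filtering is numerically fragile at cutoffs this far below the
    # sampling rate, and a hard band limit matches the definition of
    # the artifact band.
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    lo = 0.85 * cutoff
    gain = np.ones_like(freqs)
    taper = (freqs > lo) & (freqs < cutoff)
    gain[taper] = 0.5 * (1.0 + np.cos(np.pi * (freqs[taper] - lo)
                                      / (cutoff - lo)))
    gain[freqs >= cutoff] = 0.0
    drift = np.fft.irfft(spec * gain, n)
    drift -= drift.mean()
    drift *= rms_amplitude / np.sqrt(np.mean(drift**2))
    series = UniformSeries(drift, fs)
    return BaseExcitation.from_samples(series)


def gen_ma_activity(f: float, fs: float, duration: float) -> BaseExcitation:
    """Decaying-cosine motion artifact during activities.

    x_b(t) = exp(-0.01 t) cos(2 pi f t); its frequency typically sits at
    or near a pulse harmonic, so it cannot be removed by filtering.
    """
    if f >= fs / 2:
        raise ValueError(f"artifact frequency {f} Hz violates Nyquist at fs={fs}")
    t = _time(fs, duration)
    env = np.exp(-0.01 * t)
    x = env * np.cos(2 * np.pi * f * t)
    dx = (-0.01 * env * np.cos(2 * np.pi * f * t)
          - 2 * np.pi * f * env * np.sin(2 * np.pi * f * t))
    return BaseExcitation(UniformSeries(x, fs), UniformSeries(dx, fs))
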