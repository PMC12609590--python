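"""Base-excited SDOF model of the tissue-contact-sensor (TCS) stack.

The transmission path between an artery and a skin-surface sensor is
modelled as a single-degree-of-freedom oscillator: equivalent mass m0,
damping c0 and stiffness k0 set by the tissue and the contact pressure,
plus, for a tactile sensor, the microstructure's own stiffness ks and
damping cs (a PPG sensor contributes mass only, so ks = cs = 0).

Two base excitations drive the stack:

* the true pulse y(t) (arterial wall displacement), which when the
  system is time-invariant produces the clean measured pulse
  x_C(t) = |G| y(t - phase/omega) with

      G(omega) = (k0 + j omega c0)
                 / (k0 + ks - m0 omega^2 + j omega (c0 + cs));

* the motion artifact, which (a) adds a baseline drift term and (b)
  modulates the stack's parameters themselves (time-varying system
  parameters, TVSP): m(t), c(t), k(t) proportional to the drift x_b(t)
  at the mass.  The TVSP response x_M(t) obeys

      (m0+m(t)) x_M'' + (c0+c(t)+cs) x_M' + (k0+k(t)+ks) x_M
          = (k0+k(t)) y + (c0+c(t)) y',

  and the multiplicative distortion is x_tvsp = x_M - x_C: sidebands
  riding on every pulse harmonic, which no band filter can remove.

Measured signals assemble as

    tactile:  x_meas = x_M + (x_b - z_b)        (drift measured relative
                                                 to the moving substrate)
    PPG:      x_meas = y + x_tvsp + x_b         (optical path length adds
                                                 the drift directly)

Integration is fixed-step classical Runge-Kutta on the sample grid with
the excitation interpolated by a cubic Hermite spline (using the
analytic derivative when the generator supplies one).  Initial
conditions are zero displacement and velocity: the static preload is
absorbed into the nominal parameters and excluded from the dynamics.
The first ``transient_seconds`` of every solution are flagged as
transient rather than deleted, so callers decide what to discard.
"""

from __future__ import annotations

import cmath
import math
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicHermiteSpline, CubicSpline

from .series import UniformSeries
from .synth import BaseExcitation

__all__ = [
    "SDOFParams",
    "TVSPCoupling",
    "MeasurementBundle",
    "frequency_response",
    "solve_forced_sdof",
    "solve_tvsp_sdof",
    "simulate_measurement",
]

#: seconds of every simulated response flagged as start-up transient
TRANSIENT_SECONDS = 5.0


@dataclass(frozen=True)
class SDOFParams:
    """Nominal oscillator constants of the TCS stack (arbitrary units)."""

    m0: float = 1.0
    c0: float = 2.0 * 0.3 * (2.0 * math.pi * 10.0)      # zeta=0.3, fn=10 Hz
    k0: float = (2.0 * math.pi * 10.0) ** 2
    ks: float = 0.0
    cs: float = 0.0

    def __post_init__(self) -> None:
        for name in ("m0", "c0", "k0", "ks", "cs"):
            v = getattr(self, name)
            if not (isinstance(v, (int, float)) and math.isfinite(v)):
                raise ValueError(f"{name} must be a finite number, got {v!r}")
        if self.m0 <= 0 or self.k0 <= 0:
            raise ValueError("m0 and k0 must be positive")
        if self.c0 < 0 or self.ks < 0 or self.cs < 0:
            raise ValueError("c0, ks, cs must be non-negative")

    @classmethod
    def from_modal(cls, m0: float = 1.0, f_natural: float = 10.0,
                   zeta: float = 0.3, ks_ratio: float = 0.2,
                   cs_ratio: float = 0.2) -> "SDOFParams":
        """Build from natural frequency (Hz) and damping ratio.

        The default 10 Hz natural frequency sits well above the <= 15 Hz
        pulse band, so the stack transmits the pulse with near-unity
        gain and distortion comes from TVSP rather than resonance.
        """
        k0 = (2.0 * math.pi * f_natural) ** 2 * m0
        c0 = 2.0 * zeta * math.sqrt(k0 * m0)
        return cls(m0=m0, c0=c0, k0=k0, ks=ks_ratio * k0, cs=cs_ratio * c0)

    @classmethod
    def ppg(cls, m0: float = 1.0, f_natural: float = 10.0,
            zeta: float = 0.3) -> "SDOFParams":
        """PPG variant: the sensor adds no stiffness or damping."""
        return cls.from_modal(m0=m0, f_natural=f_natural, zeta=zeta,
                              ks_ratio=0.0, cs_ratio=0.0)


@dataclass(frozen=True)
class TVSPCoupling:
    """Fractional modulation of the nominal parameters by baseline drift.

    m(t) = alpha_m m0 xhat_b(t) and likewise for c, k, where xhat_b is
    the drift normalized to unit peak.  alpha = 0 recovers the linear
    time-invariant stack.

    The defaults are deliberately unequal.  When all three fractions are
    identical and the sensor adds no stiffness or damping (ks = cs = 0),
    the common factor (1 + alpha xhat_b) cancels from both sides of the
    equation of motion and the modulation produces *no* distortion at
    all; drift that modulates contact pressure has no reason to scale
    inertia, damping and stiffness identically.  The magnitudes are set
    so the distortion sidebands are clearly noticeable in a spectrum
    while every instantaneous parameter stays strictly positive.
    """

    alpha_m: float = 0.9
    alpha_c: float = 0.5
    alpha_k: float = 0.1
    normalization: str = "unit-peak"

    def __post_init__(self) -> None:
        for name in ("alpha_m", "alpha_c", "alpha_k"):
            a = getattr(self, name)
            if not math.isfinite(a) or abs(a) >= 1.0:
                raise ValueError(
                    f"|{name}| must be < 1 to keep system parameters "
                    f"positive, got {a}")
        if self.normalization not in ("unit-peak", "none"):
            raise ValueError(f"unknown normalization {self.normalization!r}")

    @classmethod
    def zero(cls) -> "TVSPCoupling":
        return cls(0.0, 0.0, 0.0)

    def normalize(self, xb: np.ndarray) -> np.ndarray:
        if self.normalization == "none":
            return xb
        peak = np.max(np.abs(xb))
        return xb / peak if peak > 0 else xb


@dataclass(frozen=True)
class MeasurementBundle:
    """All series produced by one simulated measurement.

    ``measured`` is what the sensor records; ``x_C`` the artifact-free
    response; ``x_M`` the TVSP response; ``x_tvsp = x_M - x_C`` the
    multiplicative distortion; ``baseline`` the additive drift term
    (x_b - z_b for tactile, x_b for PPG).
    """

    measured: UniformSeries
    x_C: UniformSeries
    x_M: UniformSeries
    x_tvsp: UniformSeries
    baseline: UniformSeries
    sensor_kind: str
    transient_seconds: float = TRANSIENT_SECONDS

    def __post_init__(self) -> None:
        for s in (self.x_C, self.x_M, self.x_tvsp, self.baseline):
            self.measured.require_same_grid(s)
        if self.sensor_kind not in ("tactile", "ppg"):
            raise ValueError(f"unknown sensor_kind {self.sensor_kind!r}")
        if not np.allclose(self.x_tvsp.values,
                           self.x_M.values - self.x_C.values,
                           atol=1e-9 * max(1.0, float(np.max(np.abs(self.x_M.values))))):
            raise ValueError("bundle inconsistent: x_tvsp != x_M - x_C")


def frequency_response(params: SDOFParams, omega: float,
                       forcing_stiffness: float | None = None,
                       forcing_damping: float | None = None) -> complex:
    """Steady-state complex gain of the stack at angular frequency omega.

    With the default forcing (k0, c0), this is the transmission of the
    true pulse to the clean measurement:

        G = (k0 + j omega c0) / (k0 + ks - m0 omega^2 + j omega (c0+cs)).

    Returns the complex gain; use abs() and cmath.phase() for magnitude
    and phase.
    """
    if not (math.isfinite(omega) and omega >= 0):
        raise ValueError(f"omega must be finite and >= 0, got {omega}")
    a = params.k0 if forcing_stiffness is None else forcing_stiffness
    b = params.c0 if forcing_damping is None else forcing_damping
    num = a + 1j * omega * b
    den = (params.k0 + params.ks - params.m0 * omega**2
           + 1j * omega * (params.c0 + params.cs))
    return num / den


def _half_grid_eval(base: BaseExcitation, t: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Excitation and its derivative on the doubled (half-step) grid."""
    spline = CubicHermiteSpline(base.series.t, base.series.values,
                                base.derivative.values)
    return spline(t), spline.derivative()(t)


def _rk4(mh, ch, kh, fh, dt: float, n: int) -> np.ndarray:
    """Fixed-step RK4 for m(t) x'' + c(t) x' + k(t) x = F(t), zero ICs.

    Coefficient arrays are sampled on the half-step grid (length 2n-1).
    """
    mh = mh.tolist(); ch = ch.tolist(); kh = kh.tolist(); fh = fh.tolist()
    x = 0.0
    v = 0.0
    out = np.empty(n)
    out[0] = 0.0
    h = dt
    for j in range(n - 1):
        i0 = 2 * j
        i1 = i0 + 1
        i2 = i0 + 2
        k1x = v
        k1v = (fh[i0] - ch[i0] * v - kh[i0] * x) / mh[i0]
        x2 = x + 0.5 * h * k1x
        v2 = v + 0.5 * h * k1v
        k2v = (fh[i1] - ch[i1] * v2 - kh[i1] * x2) / mh[i1]
        x3 = x + 0.5 * h * v2
        v3 = v + 0.5 * h * k2v
        k3v = (fh[i1] - ch[i1] * v3 - kh[i1] * x3) / mh[i1]
        x4 = x + h * v3
        v4 = v + h * k3v
        k4v = (fh[i2] - ch[i2] * v4 - kh[i2] * x4) / mh[i2]
        # slope samples for x are the velocity samples: k2x = v2, k3x = v3, k4x = v4
        x = x + h / 6.0 * (k1x + 2.0 * v2 + 2.0 * v3 + v4)
        v = v + h / 6.0 * (k1v + 2.0 * k2v + 2.0 * k3v + k4v)
        if not (math.isfinite(x) and math.isfinite(v)):
            raise FloatingPointError(
                f"SDOF integration diverged at step {j + 1} (t = {(j + 1) * dt:.4f} s)")
        out[j + 1] = x
    return out


def solve_forced_sdof(params: SDOFParams, base: BaseExcitation,
                      forcing_stiffness: float, forcing_damping: float,
                      ) -> UniformSeries:
    """Linear time-invariant response to a base excitation.

    Solves m0 x'' + (c0+cs) x' + (k0+ks) x = a u + b u' on the
    excitation's own grid, starting from rest.
    """
    series = base.series
    n = len(series)
    dt = series.dt
    th = series.t0 + np.arange(2 * n - 1) * (dt / 2.0)
    u, du = _half_grid_eval(base, th)
    fh = forcing_stiffness * u + forcing_damping * du
    mh = np.full(th.shape, params.m0)
    ch = np.full(th.shape, params.c0 + params.cs)
    kh = np.full(th.shape, params.k0 + params.ks)
    x = _rk4(mh, ch, kh, fh, dt, n)
    return series.with_values(x)


def solve_tvsp_sdof(params: SDOFParams, coupling: TVSPCoupling,
                    xb: UniformSeries, y: BaseExcitation) -> UniformSeries:
    """Response of the stack with drift-modulated parameters.

    The drift ``xb`` (displacement at the mass) is normalized to unit
    peak and modulates each nominal parameter fractionally; the true
    pulse ``y`` forces through the instantaneous (k, c).
    """
    series = y.series
    xb.require_same_grid(series)
    n = len(series)
    dt = series.dt
    th = series.t0 + np.arange(2 * n - 1) * (dt / 2.0)
    yh, dyh = _half_grid_eval(y, th)
    xbh = CubicSpline(xb.t, coupling.normalize(xb.values))(th)

    mt = coupling.alpha_m * params.m0 * xbh
    ct = coupling.alpha_c * params.c0 * xbh
    kt = coupling.alpha_k * params.k0 * xbh
    mh = params.m0 + mt
    ch = params.c0 + ct + params.cs
    kh = params.k0 + kt + params.ks
    if np.min(mh) <= 0 or np.min(kh) <= 0 or np.min(ch) < 0:
        raise ValueError("TVSP coupling too large: an instantaneous system "
                         "parameter is non-positive")
    fh = (params.k0 + kt) * yh + (params.c0 + ct) * dyh
    x = _rk4(mh, ch, kh, fh, dt, n)
    return series.with_values(x)


def simulate_measurement(sensor_kind: str, params: SDOFParams,
                         coupling: TVSPCoupling, y: BaseExcitation,
                         ma: BaseExcitation) -> MeasurementBundle:
    """Full forward simulation of one artifact-corrupted measurement.

    ``ma`` is the substrate motion z_b for a tactile sensor (the drift
    x_b at the mass is then the stack's response to it through ks, cs)
    and the drift x_b itself for a PPG sensor (where ks = cs = 0 makes
    that transmission vanish).
    """
    if sensor_kind not in ("tactile", "ppg"):
        raise ValueError(f"sensor_kind must be 'tactile' or 'ppg', got {sensor_kind!r}")
    if sensor_kind == "ppg" and (params.ks != 0 or params.cs != 0):
        raise ValueError("PPG sensor requires ks = cs = 0")
    y.series.require_same_grid(ma.series)

    x_C = solve_forced_sdof(params, y, params.k0, params.c0)
    if sensor_kind == "tactile":
        xb = solve_forced_sdof(params, ma, params.ks, params.cs)
        baseline = xb.with_values(xb.values - ma.series.values)
    else:
        xb = ma.series
        baseline = xb
    x_M = solve_tvsp_sdof(params, coupling, xb, y)
    x_tvsp = x_M.with_values(x_M.values - x_C.values)
    if sensor_kind == "tactile":
        measured = x_M.with_values(x_M.values + baseline.values)
    else:
        measured = x_M.with_values(y.series.values + x_tvsp.values
                                   + baseline.values)
    return MeasurementBundle(measured=measured, x_C=x_C, x_M=x_M,
                             x_tvsp=x_tvsp, baseline=baseline,
                             sensor_kind=sensor_kind)
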