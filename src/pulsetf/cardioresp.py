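"""Heart rate, respiration and HRV-partition extraction.

From the instant parameters of harmonic i:

* heart rate           HR_i(t) = f_i(t) / i * 60                [bpm]
* respiration (freq)   r_fi(t) = f_i(t) - i f_C                 [Hz]
* respiration (phase)  the detrended instant initial phase      [rad]

Each respiration signal is reduced by a one-component HVD with
respiration-band settings to an instant modulation amplitude B(t), an
instant respiration frequency f_resp(t) (RR = mean f_resp * 60
breaths/min) and an instant initial phase.  Heart-rate tracks that
account for respiration only are formed as HR = (r_HVD + f_C) * 60.

Heart-rate variability is quantified as the RMS deviation of an HR
track about its own mean.  RMSE(HR_i) is the total HRV (respiration +
other physiological factors); RMSE(HR_phi_i) the respiration-driven
part, because the initial phase is nearly immune to motion artifacts
and carries only the time-harmonic respiration component; their
difference is attributed to other physiological factors:

    RMSE(HR_PF_i) = RMSE(HR_i) - RMSE(HR_phi_i)

reported as-is (it can legitimately go negative when artifacts depress
the frequency-track HRV below the respiration-driven part).

A note on units: the phase-sourced track adds a quantity in radians to
f_C in Hz before scaling by 60.  This is dimensionally loose but is the
field's working convention for these indices; an optional corrected
mode converts the phase modulation to an equivalent frequency
modulation (time derivative / 2 pi) before the sum.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.integrate import cumulative_trapezoid

from .hvd import HarmonicTrack, _extract_one
from .series import UniformSeries
from .spectral import bandpass_zero_phase

__all__ = [
    "RespirationTrack",
    "HRVReport",
    "hr_track",
    "resp_from_frequency",
    "resp_from_phase",
    "hr_with_resp",
    "hrv_report",
]

RESP_BAND = (0.05, 0.65)       # Hz; pre-filter band for respiration signals
RESP_SMOOTH_CUTOFF = 0.1       # Hz; HVD frequency-smoothing in that band
RESP_TRIM = 5.0                # s; extra end trim for slow-signal statistics


@dataclass(frozen=True)
class RespirationTrack:
    """One-component HVD of a respiration signal.

    ``B`` is in Hz when sourced from instant frequency and in rad when
    sourced from instant initial phase.
    """

    source: str                # "frequency" | "phase"
    B: UniformSeries
    f_resp: UniformSeries
    alpha: UniformSeries
    r: UniformSeries
    valid: slice

    def mean_B(self) -> float:
        return float(np.mean(self.B.values[self.valid]))

    def mean_f_resp(self) -> float:
        return float(np.mean(self.f_resp.values[self.valid]))

    def mean_rr(self) -> float:
        """Respiration rate in breaths per minute."""
        return self.mean_f_resp() * 60.0


def hr_track(track: HarmonicTrack) -> UniformSeries:
    """Instant heart rate in bpm from harmonic i: f_i(t)/i * 60."""
    return track.f.with_values(track.f.values / track.i * 60.0)


def _resp_valid(track: HarmonicTrack, fs: float, n: int,
                resp_trim: float) -> slice:
    trim_s = max(resp_trim,
                 (track.valid.start or 0) / fs)
    k = int(round(trim_s * fs))
    return slice(k, n - k)


def _hold_edges(values: np.ndarray, valid: slice) -> np.ndarray:
    """Replace the Hilbert end-effect regions by the edge value.

    The instant-parameter tracks are meaningless outside the valid
    window; left in place, their large excursions would bleed far into
    the record through the long impulse response of the respiration-band
    filters.
    """
    out = values.copy()
    start = valid.start or 0
    stop = valid.stop if valid.stop is not None else len(values)
    out[:start] = out[start]
    out[stop:] = out[stop - 1]
    return out


def _resp_hvd(values: np.ndarray, template: UniformSeries, source: str,
              track: HarmonicTrack, resp_band: tuple[float, float],
              smooth_cutoff: float, resp_trim: float,
              gain_fn=None) -> RespirationTrack:
    series = template.with_values(_hold_edges(values, track.valid))
    valid = _resp_valid(track, series.fs, len(series), resp_trim)
    rms = float(np.sqrt(np.mean(values[valid] ** 2)))
    scale = max(1.0, float(np.max(np.abs(values))))
    if rms < 1e-12 * scale or not np.any(values):
        warnings.warn(f"{source}-sourced respiration signal below noise "
                      "floor; returning a zero-amplitude track",
                      RuntimeWarning, stacklevel=3)
        zero = series.with_values(np.zeros_like(values))
        return RespirationTrack(source, zero, zero, zero, zero, valid)
    band = bandpass_zero_phase(series, *resp_band)
    comp = _extract_one(band, smooth_cutoff, n_iterations=2)
    alpha = comp.phase.values - 2.0 * np.pi * cumulative_trapezoid(
        comp.frequency.values, dx=series.dt, initial=0.0)
    B = comp.amplitude
    r = comp.component
    if gain_fn is not None:
        # undo the known attenuation of the analysis filters at the
        # recovered respiration frequency (clamped: a deeply suppressed
        # sideband cannot be restored reliably)
        g = float(np.clip(gain_fn(np.mean(comp.frequency.values[valid])),
                          0.2, 1.5))
        B = B.with_values(B.values / g)
        r = r.with_values(r.values / g)
    return RespirationTrack(source=source, B=B,
                            f_resp=comp.frequency,
                            alpha=series.with_values(alpha),
                            r=r, valid=valid)


def resp_from_frequency(track: HarmonicTrack, f_C: float,
                        resp_band: tuple[float, float] = RESP_BAND,
                        smooth_cutoff: float = RESP_SMOOTH_CUTOFF,
                        resp_trim: float = RESP_TRIM,
                        gain_fn=None) -> RespirationTrack:
    """Respiration extracted from the instant frequency: f_i(t) - i f_C.

    ``gain_fn`` (modulation frequency -> gain) optionally compensates
    the known sideband attenuation of the upstream analysis filters.
    """
    r_f = track.f.values - track.i * f_C
    return _resp_hvd(r_f, track.f, "frequency", track, resp_band,
                     smooth_cutoff, resp_trim, gain_fn)


def resp_from_phase(track: HarmonicTrack,
                    resp_band: tuple[float, float] = RESP_BAND,
                    smooth_cutoff: float = RESP_SMOOTH_CUTOFF,
                    resp_trim: float = RESP_TRIM,
                    gain_fn=None) -> RespirationTrack:
    """Respiration extracted from the instant initial phase.

    phi0(t) is linearly detrended over the valid window first: the slope
    of the initial phase out of the Hilbert transform is not well
    defined, and only the time-harmonic content is respiratory.
    """
    t = track.phi0.t
    tv = t[track.valid]
    pv = track.phi0.values[track.valid]
    coef = np.polyfit(tv, pv, 1)
    detrended = track.phi0.values - np.polyval(coef, t)
    return _resp_hvd(detrended, track.phi0, "phase", track, resp_band,
                     smooth_cutoff, resp_trim, gain_fn)


def hr_with_resp(resp: RespirationTrack, f_C: float,
                 pm_to_fm: bool = False) -> UniformSeries:
    """HR accounting for respiration only: (r_HVD(t) + f_C) * 60 bpm.

    With ``pm_to_fm`` a phase-sourced track is first converted to its
    equivalent frequency modulation (dr/dt / 2 pi).
    """
    r = resp.r.values
    if pm_to_fm and resp.source == "phase":
        r = np.gradient(r, resp.r.dt) / (2.0 * np.pi)
    return resp.r.with_values((r + f_C) * 60.0)


def _rmse_about_mean(values: np.ndarray) -> float:
    return float(np.sqrt(np.mean((values - values.mean()) ** 2)))


@dataclass(frozen=True)
class HRVReport:
    """Per-harmonic HR / respiration summary (one row per harmonic)."""

    frame: pd.DataFrame

    COLUMNS = ("n", "mean_HR", "rmse_HR", "mean_RR_f", "mean_B_f",
               "mean_HR_f", "mean_RR_phi", "mean_B_phi", "mean_HR_phi",
               "rmse_HR_phi", "rmse_HR_pf")

    def row(self, i: int) -> pd.Series:
        return self.frame.set_index("n").loc[i]


def hrv_report(tracks: list[HarmonicTrack],
               resp_f: list[RespirationTrack],
               resp_phi: list[RespirationTrack], f_C: float) -> HRVReport:
    """Assemble the per-harmonic HR / respiration / HRV-partition table.

    All statistics are taken over the respiration tracks' valid window
    (the wider trim), so every mean and RMSE shares one support.
    """
    rows = []
    for track, rf, rp in zip(tracks, resp_f, resp_phi):
        w = rf.valid
        hr = hr_track(track).values[w]
        hr_f = hr_with_resp(rf, f_C).values[w]
        hr_phi = hr_with_resp(rp, f_C).values[w]
        rmse_hr = _rmse_about_mean(hr)
        rmse_hr_phi = _rmse_about_mean(hr_phi)
        rows.append({
            "n": track.i,
            "mean_HR": float(np.mean(hr)),
            "rmse_HR": rmse_hr,
            "mean_RR_f": rf.mean_rr(),
            "mean_B_f": float(np.mean(rf.B.values[w])),
            "mean_HR_f": float(np.mean(hr_f)),
            "mean_RR_phi": rp.mean_rr(),
            "mean_B_phi": float(np.mean(rp.B.values[w])),
            "mean_HR_phi": float(np.mean(hr_phi)),
            "rmse_HR_phi": rmse_hr_phi,
            "rmse_HR_pf": rmse_hr - rmse_hr_phi,
        })
    return HRVReport(pd.DataFrame(rows, columns=list(HRVReport.COLUMNS)))
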