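"""End-to-end analysis of one pulse record.

Orchestrates the full chain: 15 Hz low-pass -> fundamental estimation ->
baseline removal -> per-harmonic band split -> instant-parameter tracks
-> amplitude-regression / mean-phase summaries -> artifact-free
reconstructions -> waveform and cardio-respiratory reports.  The run is
fully deterministic given the record and the configuration.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field

import numpy as np

from . import cardioresp, hvd, recon, spectral
from .cardioresp import HRVReport, RespirationTrack
from .hvd import HarmonicTrack
from .recon import APWSummary, HarmonicSummary
from .series import UniformSeries
from .spectral import PreprocessResult

log = logging.getLogger("pulsetf")

__all__ = ["AnalysisConfig", "AnalysisResult", "run_analysis"]


@dataclass(frozen=True)
class AnalysisConfig:
    """Knobs of the analysis chain (defaults are the recommended values).

    n_harmonics is capped automatically when the band rule
    i f_C +/- (f_C - bw_offset)/2 would exceed min(lpf_hf, fs/2).
    """

    n_harmonics: int = 5
    lpf_hf: float = 15.0
    baseline_offset: float = 0.4
    bw_offset: float = 0.2
    search_band: tuple[float, float] = (0.7, 3.0)
    freq_smooth_cutoff: float = 0.6
    n_iterations: int = 2
    trim_seconds: float | None = None
    resp_band: tuple[float, float] = (0.05, 0.65)
    resp_smooth_cutoff: float = 0.1
    resp_trim: float = 5.0
    f_C: float | None = None     # override the FFT estimate when set

    def hash(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True).encode()).hexdigest()[:12]


@dataclass(frozen=True)
class AnalysisResult:
    pre: PreprocessResult
    f_C: float
    tracks: list[HarmonicTrack]
    summaries: list[HarmonicSummary]
    x_hvd: UniformSeries
    x_tf: UniformSeries
    x_cf: UniformSeries
    x_tvsp: UniformSeries
    apw: APWSummary
    resp_f: list[RespirationTrack]
    resp_phi: list[RespirationTrack]
    hrv: HRVReport
    harmonic_snr_db: tuple
    config: AnalysisConfig


def _stage(name: str):
    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, _StageError):
                raise _StageError(f"stage '{name}': {exc}") from exc
            return False

    return _Ctx()


class _StageError(RuntimeError):
    pass


def _band_snr_db(x0: UniformSeries, f_C: float, i: int,
                 half_bw: float) -> float:
    """In-band tone energy over the off-band floor, in dB."""
    x = x0.values - x0.values.mean()
    mag2 = np.abs(np.fft.rfft(x)) ** 2
    freqs = np.fft.rfftfreq(x.size, x0.dt)
    sel = (freqs >= i * f_C - half_bw) & (freqs <= i * f_C + half_bw)
    guard = (freqs >= i * f_C - 2 * half_bw) & (freqs <= i * f_C + 2 * half_bw)
    noise = mag2[guard & ~sel]
    signal = mag2[sel]
    floor = np.median(noise) * signal.size if noise.size else 1e-300
    return float(10.0 * np.log10(max(signal.sum(), 1e-300) / max(floor, 1e-300)))


def run_analysis(series: UniformSeries,
                 config: AnalysisConfig = AnalysisConfig()) -> AnalysisResult:
    """Run the full time-frequency chain on one record (>= 40 s)."""
    if series.duration < 40.0:
        raise ValueError(
            f"record of {series.duration:.1f} s too short: need >= 40 s for "
            "stable respiration statistics")

    with _stage("preprocess"):
        pre = spectral.preprocess(series, lpf_hf=config.lpf_hf,
                                  baseline_offset=config.baseline_offset,
                                  search_band=config.search_band,
                                  f_C=config.f_C)
        f_C = pre.f_C
    log.info("f_C = %.3f Hz (removed_hf=%s)", f_C, pre.removed_hf)

    with _stage("harmonic split"):
        n_max = spectral.max_harmonics(f_C, series.fs, config.bw_offset,
                                       config.lpf_hf)
        n = min(config.n_harmonics, n_max)
        if n < config.n_harmonics:
            log.warning("n_harmonics capped from %d to %d at f_C=%.2f Hz",
                        config.n_harmonics, n, f_C)
        bands = spectral.split_harmonics(pre.x0, f_C, n,
                                         bw_offset=config.bw_offset,
                                         lpf_hf=config.lpf_hf)
        half_bw = (f_C - config.bw_offset) / 2.0
        snrs = tuple(_band_snr_db(pre.x0, f_C, i, half_bw)
                     for i in range(1, n + 1))
    log.info("analyzing %d harmonics; band SNR [dB]: %s", n,
             ["%.1f" % s for s in snrs])

    with _stage("instant parameters"):
        tracks = [hvd.harmonic_instant_params(
            band, i, f_C, trim_seconds=config.trim_seconds,
            freq_smooth_cutoff=config.freq_smooth_cutoff,
            n_iterations=config.n_iterations)
            for i, band in enumerate(bands, start=1)]

    with _stage("summaries"):
        summaries = [recon.summarize_track(t) for t in tracks]

    with _stage("reconstruction"):
        x_hvd = recon.hvd_sum(tracks)
        x_tf = recon.reconstruct(tracks, summaries, "tf", f_C)
        x_cf = recon.reconstruct(tracks, summaries, "cf", f_C)
        x_tvsp = recon.tvsp_estimate(x_hvd, x_tf)
        carrier_gain = [spectral.harmonic_carrier_gain(
            f_C, t.i, series.fs, bw_offset=config.bw_offset,
            baseline_offset=config.baseline_offset) for t in tracks]
        apw = recon.apw_summary(tracks, summaries, pre.x0, x_tf, x_cf, f_C,
                                bw_offset=config.bw_offset,
                                carrier_gain=carrier_gain)

    with _stage("cardio-respiratory"):
        gains = [spectral.modulation_response(
            f_C, t.i, series.fs, bw_offset=config.bw_offset,
            baseline_offset=config.baseline_offset,
            freq_smooth_cutoff=config.freq_smooth_cutoff,
            resp_band=config.resp_band) for t in tracks]
        resp_f = [cardioresp.resp_from_frequency(
            t, f_C, resp_band=config.resp_band,
            smooth_cutoff=config.resp_smooth_cutoff,
            resp_trim=config.resp_trim, gain_fn=g)
            for t, g in zip(tracks, gains)]
        resp_phi = [cardioresp.resp_from_phase(
            t, resp_band=config.resp_band,
            smooth_cutoff=config.resp_smooth_cutoff,
            resp_trim=config.resp_trim, gain_fn=g)
            for t, g in zip(tracks, gains)]
        hrv = cardioresp.hrv_report(tracks, resp_f, resp_phi, f_C)

    return AnalysisResult(pre=pre, f_C=f_C, tracks=tracks,
                          summaries=summaries, x_hvd=x_hvd, x_tf=x_tf,
                          x_cf=x_cf, x_tvsp=x_tvsp, apw=apw, resp_f=resp_f,
                          resp_phi=resp_phi, hrv=hrv, harmonic_snr_db=snrs,
                          config=config)
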