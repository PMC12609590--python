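"""Reconstruction and waveform summaries."""

import numpy as np
import pytest

from pulsetf import (AnalysisConfig, PulseSpec, SDOFParams, TVSPCoupling,
                     BaseExcitation, UniformSeries, amplitude_regression,
                     apw_summary, gen_ma_rest, hvd_sum, phase_mean,
                     reconstruct, run_analysis, simulate_measurement,
                     summarize_track, synth_pulse, tvsp_estimate)
from tests.conftest import sine_track


class TestAmplitudeRegression:
    def test_constant_amplitude(self, make_track):
        slope, intercept = amplitude_regression(make_track(A=2.0))
        assert slope == pytest.approx(0.0, abs=1e-9)
        assert intercept == pytest.approx(2.0)

    def test_exact_line(self, make_track, fs):
        import dataclasses
        tr = make_track(A=1.0)
        t = tr.A.t
        tr = dataclasses.replace(tr, A=tr.A.with_values(1 + 0.01 * t))
        slope, intercept = amplitude_regression(tr)
        assert slope == pytest.approx(0.01, abs=1e-6)
        assert intercept == pytest.approx(1.0, abs=1e-6)

    def test_sinusoidal_ripple_averages_out(self, make_track):
        import dataclasses
        tr = make_track(A=2.0)
        t = tr.A.t
        # integer periods of the ripple inside the 70 s valid window
        tr = dataclasses.replace(tr, A=tr.A.with_values(
            2 + 0.5 * np.sin(2 * np.pi * 0.1 * (t - 5.0))))
        slope, intercept = amplitude_regression(tr)
        line_mid = slope * 40.0 + intercept
        assert line_mid == pytest.approx(2.0, abs=0.01)

    def test_midpoint_equals_mean(self, make_track):
        summ = summarize_track(sine_track(A=1.5, f_dev=0.0))
        tr = sine_track(A=1.5)
        t_mid = tr.t_valid.mean()
        assert summ.amplitude_line(np.array([t_mid]))[0] == pytest.approx(
            summ.A_bar, rel=1e-9)


class TestPhaseMean:
    def test_constant_phase(self, make_track):
        tr = make_track(phi0=5.78)
        assert phase_mean(tr) == pytest.approx(5.78, abs=1e-6)

    def test_oscillation_averages_out(self, make_track):
        # 0.2 Hz oscillation -> integer periods inside the 70 s window
        tr = make_track(phi0=1.0, pm=0.3, f_mod=0.2)
        assert phase_mean(tr) == pytest.approx(1.0, abs=0.01)

    def test_agrees_with_unwrapped_signal_phase(self, fs):
        # a raw phase with a 2 pi wrap gives the same mean once unwrapped
        t = np.arange(8000) / fs
        phase = 2 * np.pi * 1.2 * t + 3.0
        wrapped = np.mod(phase, 2 * np.pi)
        assert np.allclose(np.unwrap(wrapped), phase)


class TestReconstruct:
    def test_constant_frequency_collapses_tf_to_cf(self, make_track):
        tracks = [sine_track(i=i, f_dev=0.0, phi0=0.3 * i) for i in (1, 2)]
        summaries = [summarize_track(t) for t in tracks]
        tf = reconstruct(tracks, summaries, "tf", 1.2)
        cf = reconstruct(tracks, summaries, "cf", 1.2)
        w = tracks[0].valid
        assert np.allclose(tf.values[w], cf.values[w], atol=1e-4)

    def test_clean_round_trip_through_pipeline(self, three_harmonic_spec):
        y = synth_pulse(three_harmonic_spec)
        res = run_analysis(y.series, AnalysisConfig(n_harmonics=3))
        w = res.tracks[0].valid
        ref = res.pre.x0.values[w]
        rel = (np.sqrt(np.mean((res.x_tf.values[w] - ref) ** 2))
               / np.sqrt(np.mean(ref**2)))
        assert rel < 0.05

    def test_unknown_mode_rejected(self, make_track):
        tr = make_track()
        with pytest.raises(ValueError):
            reconstruct([tr], [summarize_track(tr)], "xy", 1.2)


class TestTvspEstimate:
    def test_identical_inputs_give_zero(self, fs):
        s = UniformSeries(np.random.default_rng(0).standard_normal(1000), fs)
        assert not np.any(tvsp_estimate(s, s).values)

    def test_scales_linearly(self, fs):
        rng = np.random.default_rng(1)
        a = UniformSeries(rng.standard_normal(1000), fs)
        b = UniformSeries(rng.standard_normal(1000), fs)
        d1 = tvsp_estimate(a, b).values
        d2 = tvsp_estimate(a.with_values(3 * a.values),
                           b.with_values(3 * b.values)).values
        assert np.allclose(d2, 3 * d1)

    def test_length_mismatch_rejected(self, fs):
        a = UniformSeries(np.ones(100), fs)
        b = UniformSeries(np.ones(99), fs)
        with pytest.raises(ValueError):
            tvsp_estimate(a, b)

    def test_tracks_simulated_distortion(self, three_harmonic_spec, fs):
        # oracle: the simulator's own x_tvsp for a drift-modulated stack
        y = synth_pulse(three_harmonic_spec)
        t = y.series.t
        drift = BaseExcitation(
            UniformSeries(0.5 * np.cos(2 * np.pi * 0.3 * t), fs),
            UniformSeries(-0.5 * 2 * np.pi * 0.3
                          * np.sin(2 * np.pi * 0.3 * t), fs))
        b = simulate_measurement("ppg", SDOFParams.ppg(), TVSPCoupling(),
                                 y, drift)
        res = run_analysis(b.measured, AnalysisConfig(n_harmonics=3))
        w = res.tracks[0].valid
        r = np.corrcoef(res.x_tvsp.values[w], b.x_tvsp.values[w])[0, 1]
        assert r > 0.7


class TestAPWSummary:
    def test_single_harmonic(self, three_harmonic_spec):
        spec = PulseSpec(f_C=1.2, harmonics=((1.0, 0.0),), fs=100.0,
                         duration=80)
        res = run_analysis(synth_pulse(spec).series,
                           AnalysisConfig(n_harmonics=1))
        assert res.apw.a_bar_ratio == (1.0,)
        assert res.apw.phase_diff == (0.0,)

    def test_clean_ratios_match_generator(self, fs):
        spec = PulseSpec(f_C=1.2, harmonics=((1.0, 0.0), (0.5, 1.0),
                                             (0.25, 2.0)),
                         R=0.1, f_r=0.25, fs=fs, duration=80)
        res = run_analysis(synth_pulse(spec).series,
                           AnalysisConfig(n_harmonics=3))
        for col in (res.apw.a_bar_ratio, res.apw.a_x0_ratio,
                    res.apw.a_tf_ratio, res.apw.a_cf_ratio):
            assert np.allclose(col, (1.0, 0.5, 0.25), rtol=0.03)
        assert res.apw.phase_diff[1] == pytest.approx(1.0, abs=0.05)

    def test_cf_ratios_robust_to_artifact(self, fs):
        spec = PulseSpec(f_C=1.2, harmonics=((1.0, 0.0), (0.5, 1.0),
                                             (0.25, 2.0)),
                         R=0.1, f_r=0.25, fs=fs, duration=80)
        y = synth_pulse(spec)
        ma = gen_ma_rest(fs, 80, rms_amplitude=0.5, seed=4)
        b = simulate_measurement("ppg", SDOFParams.ppg(), TVSPCoupling(),
                                 y, ma)
        # broadband sensor noise corrupts the raw-spectrum route but not
        # the reconstructed one
        noise = 0.3 * np.random.default_rng(8).standard_normal(
            len(b.measured))
        measured = b.measured.with_values(b.measured.values + noise)
        res = run_analysis(measured, AnalysisConfig(n_harmonics=3))
        truth = np.array((1.0, 0.5, 0.25))
        err_cf = np.max(np.abs(np.array(res.apw.a_cf_ratio) - truth) / truth)
        assert err_cf < 0.05

    def test_mean_amplitude_and_cf_routes_agree(self, three_harmonic_spec):
        res = run_analysis(synth_pulse(three_harmonic_spec).series,
                           AnalysisConfig(n_harmonics=3))
        assert np.allclose(res.apw.a_bar_ratio, res.apw.a_cf_ratio, rtol=0.02)

    def test_reconstruction_energy_triangle(self, three_harmonic_spec):
        res = run_analysis(synth_pulse(three_harmonic_spec).series,
                           AnalysisConfig(n_harmonics=3))
        w = res.tracks[0].valid
        norm = lambda s: np.linalg.norm(s.values[w])
        assert norm(res.x_tf) <= norm(res.x_hvd) + norm(res.x_tvsp) + 1e-9

    def test_hvd_sum_matches_components(self, make_track):
        tracks = [sine_track(i=i, A=1.0 / i) for i in (1, 2)]
        total = hvd_sum(tracks)
        assert np.allclose(total.values,
                           tracks[0].component.values
                           + tracks[1].component.values)
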