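"""SDOF forward model: closed-form gain, forced/TVSP solves, bundles."""

import cmath

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import solve_ivp

from pulsetf import (BaseExcitation, SDOFParams, TVSPCoupling,
                     UniformSeries, frequency_response, simulate_measurement,
                     solve_forced_sdof, solve_tvsp_sdof)
from pulsetf.synth import PulseSpec, gen_ma_activity, gen_ma_rest, synth_pulse


def steady_amp_phase(x, freq, fs, settle=15.0):
    """Complex amplitude by projection over an integer number of periods."""
    k0 = int(round(settle * fs))
    n_per = int((len(x) - k0) * freq / fs)
    n = int(round(n_per * fs / freq))
    seg = x[k0:k0 + n]
    t = np.arange(k0, k0 + n) / fs
    return 2 * np.mean(seg * np.exp(-1j * 2 * np.pi * freq * t))


class TestFrequencyResponse:
    def test_static_gain_is_unity_without_sensor_stiffness(self):
        g = frequency_response(SDOFParams.ppg(), 0.0)
        assert g == pytest.approx(1.0)

    def test_inertial_rolloff(self):
        p = SDOFParams.ppg()
        w = 1e6 * np.sqrt(p.k0 / p.m0)
        assert abs(frequency_response(p, w)) < 1e-6

    def test_matches_integrated_oscillator(self, make_tone):
        # independent oracle: scipy ODE integration of the same system
        p = SDOFParams.ppg()
        fs, f = 500.0, 1.2
        w = 2 * np.pi * f

        def rhs(t, s):
            u = np.cos(w * t)
            du = -w * np.sin(w * t)
            return [s[1], (p.k0 * u + p.c0 * du - p.c0 * s[1]
                           - p.k0 * s[0]) / p.m0]

        sol = solve_ivp(rhs, (0, 30), [0, 0], rtol=1e-10, atol=1e-12,
                        dense_output=True)
        t = np.arange(int(15 * fs), int(30 * fs)) / fs
        c = 2 * np.mean(sol.sol(t)[0] * np.exp(-1j * w * t))
        g = frequency_response(p, w)
        assert abs(c) == pytest.approx(abs(g), rel=0.005)
        assert cmath.phase(c / g) == pytest.approx(0.0, abs=0.01)

    def test_rejects_bad_input(self):
        with pytest.raises(ValueError):
            frequency_response(SDOFParams.ppg(), -1.0)
        with pytest.raises(ValueError):
            SDOFParams(m0=float("nan"))

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(m0=st.floats(0.1, 10.0), fn=st.floats(1.0, 50.0),
           zeta=st.floats(0.05, 1.0), ks_ratio=st.floats(0.0, 1.0))
    def test_static_gain_is_stiffness_divider(self, m0, fn, zeta, ks_ratio):
        p = SDOFParams.from_modal(m0=m0, f_natural=fn, zeta=zeta,
                                  ks_ratio=ks_ratio, cs_ratio=0.1)
        g = frequency_response(p, 0.0)
        assert g.imag == 0.0
        assert g.real == pytest.approx(p.k0 / (p.k0 + p.ks), rel=1e-12)


class TestForcedSolve:
    def test_zero_input_zero_output(self, fs):
        base = BaseExcitation.zero(fs, 10)
        p = SDOFParams.from_modal()
        out = solve_forced_sdof(p, base, p.k0, p.c0)
        assert not np.any(out.values)

    @pytest.mark.parametrize("freq", [0.5, 1.2, 3.6, 8.0, 15.0])
    def test_steady_state_matches_closed_form(self, make_tone, freq):
        p = SDOFParams.ppg()
        base = make_tone(freq, fs=500.0, duration=30.0)
        x = solve_forced_sdof(p, base, p.k0, p.c0)
        c = steady_amp_phase(x.values, freq, 500.0)
        g = frequency_response(p, 2 * np.pi * freq)
        assert abs(c) == pytest.approx(abs(g), rel=0.01)
        assert cmath.phase(c / g) == pytest.approx(0.0, abs=2 * np.pi * 0.01)

    def test_quasi_static_drift_transmission(self, make_tone):
        # slow substrate drift passes with the static gain ks/(k0+ks)
        p = SDOFParams.from_modal()
        base = make_tone(0.1, fs=200.0, duration=60.0)
        x = solve_forced_sdof(p, base, p.ks, p.cs)
        c = steady_amp_phase(x.values, 0.1, 200.0, settle=20.0)
        assert abs(c) == pytest.approx(p.ks / (p.k0 + p.ks), rel=0.02)

    def test_divergence_reported_with_step(self, make_tone):
        # sampling far below the natural frequency destabilizes RK4
        p = SDOFParams.from_modal(f_natural=10.0)
        base = make_tone(0.5, fs=15.0, duration=40.0)
        with pytest.raises(FloatingPointError, match="step"):
            solve_forced_sdof(p, base, p.k0, p.c0)


class TestTVSPSolve:
    def test_zero_coupling_reduces_to_lti(self, make_tone, fs):
        p = SDOFParams.ppg()
        y = make_tone(3.6, duration=30.0)
        xb = UniformSeries(0.5 * np.cos(2 * np.pi * 0.2 * y.series.t), fs)
        xm = solve_tvsp_sdof(p, TVSPCoupling.zero(), xb, y)
        xc = solve_forced_sdof(p, y, p.k0, p.c0)
        assert np.allclose(xm.values, xc.values, atol=1e-12)

    def test_sidebands_dominate_distortion_spectrum(self, make_tone, fs):
        p = SDOFParams.ppg()
        y = make_tone(3.6, duration=60.0)
        xb = UniformSeries(np.cos(2 * np.pi * 0.2 * y.series.t), fs)
        xm = solve_tvsp_sdof(p, TVSPCoupling(), xb, y)
        xc = solve_forced_sdof(p, y, p.k0, p.c0)
        d = (xm.values - xc.values)[int(10 * fs):]
        mag2 = np.abs(np.fft.rfft(d)) ** 2
        freqs = np.fft.rfftfreq(d.size, 1 / fs)
        inband = mag2[(freqs >= 3.0) & (freqs <= 4.2)].sum()
        assert inband / mag2.sum() > 0.9

    def test_first_order_in_coupling(self, make_tone, fs):
        p = SDOFParams.ppg()
        y = make_tone(3.6, duration=40.0)
        xb = UniformSeries(np.cos(2 * np.pi * 0.2 * y.series.t), fs)
        xc = solve_forced_sdof(p, y, p.k0, p.c0)
        sl = slice(int(10 * fs), None)
        peaks = []
        for scale in (1.0, 0.5):
            cp = TVSPCoupling(0.3 * scale, 0.2 * scale, 0.1 * scale)
            xm = solve_tvsp_sdof(p, cp, xb, y)
            peaks.append(np.abs(xm.values[sl] - xc.values[sl]).max())
        assert peaks[0] / peaks[1] == pytest.approx(2.0, rel=0.1)

    def test_excessive_instantaneous_coupling_rejected(self, make_tone, fs):
        p = SDOFParams.ppg()
        y = make_tone(3.6, duration=10.0)
        xb = UniformSeries(5.0 * np.cos(2 * np.pi * 0.2 * y.series.t), fs)
        cp = TVSPCoupling(0.5, 0.2, 0.5, normalization="none")
        with pytest.raises(ValueError, match="too large"):
            solve_tvsp_sdof(p, cp, xb, y)

    def test_coupling_validation(self):
        with pytest.raises(ValueError):
            TVSPCoupling(alpha_m=1.0)


class TestSimulateMeasurement:
    def test_ppg_without_artifact_measures_the_pulse_exactly(self, make_tone):
        y = make_tone(1.2, duration=20.0)
        ma = BaseExcitation.zero(100.0, 20.0)
        b = simulate_measurement("ppg", SDOFParams.ppg(), TVSPCoupling.zero(),
                                 y, ma)
        assert np.allclose(b.measured.values, y.series.values, atol=1e-12)

    def test_tactile_without_artifact_measures_the_lti_response(self, make_tone):
        y = make_tone(1.2, duration=20.0)
        ma = BaseExcitation.zero(100.0, 20.0)
        b = simulate_measurement("tactile", SDOFParams.from_modal(),
                                 TVSPCoupling.zero(), y, ma)
        assert np.allclose(b.measured.values, b.x_C.values, atol=1e-12)

    def test_bundle_additivity(self, three_harmonic_spec, fs):
        y = synth_pulse(three_harmonic_spec)
        ma = gen_ma_rest(fs, three_harmonic_spec.duration,
                         rms_amplitude=0.3, seed=2)
        for kind, params in (("ppg", SDOFParams.ppg()),
                             ("tactile", SDOFParams.from_modal())):
            b = simulate_measurement(kind, params, TVSPCoupling(), y, ma)
            clean = b.x_C.values if kind == "tactile" else y.series.values
            resid = (b.measured.values - b.baseline.values
                     - b.x_tvsp.values - clean)
            assert np.max(np.abs(resid)) < 1e-9

    def test_linearity_in_the_pulse(self, fs):
        spec = PulseSpec(f_C=1.2, harmonics=((1.0, 0.0),), fs=fs, duration=30)
        ma = gen_ma_rest(fs, 30, rms_amplitude=0.3, seed=5)
        p = SDOFParams.ppg()
        outs = {}
        for s in (0.5, 1.0, 2.0):
            sp = PulseSpec(f_C=1.2, harmonics=((s, 0.0),), fs=fs, duration=30)
            b = simulate_measurement("ppg", p, TVSPCoupling(),
                                     synth_pulse(sp), ma)
            outs[s] = b
        sl = slice(int(10 * fs), None)
        for s in (0.5, 2.0):
            assert np.allclose(outs[s].x_C.values, s * outs[1.0].x_C.values,
                               atol=1e-9)
            ratio = (np.abs(outs[s].x_M.values[sl]).max()
                     / np.abs(outs[1.0].x_M.values[sl]).max())
            assert ratio == pytest.approx(s, rel=0.02)

    def test_activity_artifact_spawns_off_harmonic_components(self, fs):
        spec = PulseSpec(f_C=1.2, harmonics=((0, 0), (0, 0), (1.0, 0)),
                         fs=fs, duration=60)
        y = synth_pulse(spec)
        ma = gen_ma_activity(3.6, fs, 60)
        b = simulate_measurement("ppg", SDOFParams.ppg(), TVSPCoupling(),
                                 y, ma)
        d = b.x_tvsp.values[int(10 * fs):]
        mag2 = np.abs(np.fft.rfft(d)) ** 2
        freqs = np.fft.rfftfreq(d.size, 1 / fs)
        near = mag2[np.abs(freqs - 3.6) < 0.3].sum()
        far = mag2[np.abs(freqs - 3.6) >= 0.3].sum()
        assert near > 0          # a (small) component at the harmonic itself
        assert far > near        # and dominant components far off it

    def test_ppg_with_sensor_stiffness_rejected(self, make_tone):
        y = make_tone(1.2, duration=10.0)
        ma = BaseExcitation.zero(100.0, 10.0)
        with pytest.raises(ValueError, match="ks"):
            simulate_measurement("ppg", SDOFParams.from_modal(),
                                 TVSPCoupling.zero(), y, ma)
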