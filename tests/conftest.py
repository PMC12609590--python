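import numpy as np
import pytest

from pulsetf import BaseExcitation, PulseSpec, UniformSeries, synth_pulse

FS = 100.0


@pytest.fixture
def fs():
    return FS


@pytest.fixture
def make_tone():
    """Factory: sinusoidal base excitation with analytic derivative."""

    def _make(freq, fs=FS, duration=40.0, amplitude=1.0, phase=0.0):
        t = np.arange(int(round(duration * fs))) / fs
        w = 2 * np.pi * freq
        x = amplitude * np.cos(w * t + phase)
        dx = -amplitude * w * np.sin(w * t + phase)
        return BaseExcitation(UniformSeries(x, fs), UniformSeries(dx, fs))

    return _make


@pytest.fixture
def pm_tone():
    """The worked single-harmonic example: third harmonic of a 1.2 Hz
    pulse, phase-modulated by respiration 0.3 sin(2 pi 0.2 t), 80 s."""
    spec = PulseSpec(f_C=1.2, harmonics=((0, 0), (0, 0), (1.0, 0.0)),
                     R=0.3, f_r=0.2, fs=FS, duration=80.0)
    return synth_pulse(spec)


@pytest.fixture
def three_harmonic_spec():
    """A three-harmonic pulse with mild respiratory modulation."""
    return PulseSpec(f_C=1.2,
                     harmonics=((1.0, 0.0), (0.457, 5.781), (0.407, 5.420)),
                     R=0.1, f_r=0.25, fs=FS, duration=80.0)


def sine_track(i=1, f_C=1.2, fs=FS, duration=80.0, A=1.0, f_dev=0.0,
               f_mod=0.25, phi0=0.0, pm=0.0, trim=5.0):
    """Build a HarmonicTrack analytically (no signal processing)."""
    from pulsetf.hvd import HarmonicTrack

    t = np.arange(int(round(duration * fs))) / fs
    f = i * f_C + f_dev * np.cos(2 * np.pi * f_mod * t)
    phase = (2 * np.pi * i * f_C * t
             + f_dev / f_mod * np.sin(2 * np.pi * f_mod * t)
             + phi0 + pm * np.sin(2 * np.pi * f_mod * t))
    f = f + pm * f_mod * np.cos(2 * np.pi * f_mod * t)
    amp = np.full_like(t, A)
    comp = amp * np.cos(phase)
    k = int(round(trim * fs))
    mk = lambda v: UniformSeries(v, fs)
    return HarmonicTrack(i=i, A=mk(amp), f=mk(f),
                         phi0=mk(phase - 2 * np.pi * i * f_C * t),
                         phase=mk(phase), component=mk(comp),
                         valid=slice(k, t.size - k), f_C=f_C)


@pytest.fixture
def make_track():
    return sine_track
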