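# Methods

## The forward model

The tissue–contact–sensor (TCS) stack is a linear base-excited SDOF
oscillator.  Two excitations drive it: the arterial wall displacement
y(t) (the true pulse) and the motion of the sensor relative to the
artery.  For a tactile sensor the substrate motion z_b(t) forces the
stack through the sensor's stiffness and damping,

    m₀ x_b'' + (c₀+cₛ) x_b' + (k₀+kₛ) x_b = kₛ z_b + cₛ z_b',

and the measured baseline drift is x_b − z_b; for a PPG sensor
(kₛ = cₛ = 0) the drift x_b enters the optical path directly.  The
drift at the mass modulates the stack's parameters fractionally
(unit-peak-normalized drift x̂_b):

    m(t) = α_m m₀ x̂_b(t),  c(t) = α_c c₀ x̂_b(t),  k(t) = α_k k₀ x̂_b(t),

and the modulated equation of motion

    (m₀+m) x_M'' + (c₀+c+cₛ) x_M' + (k₀+k+kₛ) x_M
        = (k₀+k) y + (c₀+c) y'

produces the multiplicative distortion x_tvsp = x_M − x_C, where x_C is
the response of the time-invariant stack with gain

    G(ω) = (k₀ + jωc₀) / (k₀ + kₛ − m₀ω² + jω(c₀+cₛ)).

Measured signals: tactile x = x_M + (x_b − z_b); PPG x = y + x_tvsp + x_b.

### Parameter defaults and why

| parameter | default | rationale |
|---|---|---|
| m₀ | 1 (a.u.) | sets the scale only |
| natural frequency | 10 Hz | well above the ≤ 15 Hz pulse band: the stack transmits the pulse with near-unity gain, so distortion comes from parameter modulation, not resonance |
| damping ratio ζ | 0.3 | moderately damped soft tissue; no sharp resonance |
| kₛ/k₀, cₛ/c₀ (tactile) | 0.2 | a microstructure stiff enough to register but much softer than the preloaded tissue |
| α_m, α_c, α_k | 0.9, 0.5, 0.1 | see below |
| start-up transient | first 5 s flagged | ζω_n ≈ 19 s⁻¹ decays in well under a second; 5 s is conservative and also covers filter edges downstream |

**The coupling fractions must be unequal.**  If α_m = α_c = α_k and
kₛ = cₛ = 0, the factor (1 + α x̂_b) multiplies *both* sides of the
equation of motion and cancels exactly: equal fractional modulation of
a PPG stack produces no distortion whatsoever.  (This is an algebraic
identity, confirmed numerically to machine precision.)  Physically,
drift that modulates contact pressure has no reason to scale inertia,
damping and stiffness identically, so the defaults are strongly spread
(0.9, 0.5, 0.1) — large enough that the distortion sidebands are
clearly visible in a spectrum, while every instantaneous coefficient
stays strictly positive.  At pulse frequencies far below the stack's
natural frequency, the stiffness and damping modulations largely cancel
between the two sides of the equation, leaving the mass modulation
(≈ α_m (ω/ω_n)² per unit x̂_b) as the dominant distortion source; this
is why α_m carries the largest fraction.

### Integration

Fixed-step classical Runge–Kutta on the sample grid, with the
excitation evaluated at half-steps through a cubic Hermite spline built
from the excitation and its derivative (analytic for all generators,
central differences otherwise).  At 100 Hz sampling with a 10 Hz
natural frequency this reproduces the closed-form steady state to
≈ 10⁻⁴ relative; the acceptance sweep runs at 500 Hz where the error is
≈ 10⁻⁵.  Divergence (possible when the sampling rate approaches the
natural frequency) raises an error naming the failing step.  Initial
conditions are zero displacement and velocity; the static preload is
absorbed into the nominal parameters.

## The synthetic pulse and artifact generators

`synth_pulse` implements the harmonic sum with a *common* respiratory
phase modulation ψ(t) = R sin(2π f_r t + α₀): every harmonic carries
frequency modulation of amplitude R·f_r and phase modulation of
amplitude R.  The respiration reference is r(t) = B cos(2π f_r t + α₀)
with B = −R f_r.  (The sign of B follows this convention; the analysis
recovers |B| — a sign cannot be observed from a single harmonic track.)

`gen_ma_rest` emulates the baseline drift of a recording at rest:
Gaussian noise spectrally shaped to be flat below 0.85·cutoff with a
raised-cosine taper to exactly zero at the cutoff (default 0.7 Hz), then
scaled to the requested RMS (default 0.3 of the unit first-harmonic
amplitude — a visible but low-level artifact, as expected at rest).
The shaping is done in the frequency domain: time-domain IIR filtering
at 0.7 Hz on a 100 Hz grid is numerically fragile (high-order
forward–backward Butterworth runs produced seed-dependent edge
blow-ups), and a hard band edge matches the definition of the artifact
band.  Real resting drifts differ in two ways the generator does not
model: they are non-Gaussian (posture shifts, respiration-locked
components) and non-stationary.  Passing tests therefore demonstrate
correct behaviour for band-limited stochastic drift, not for every
field recording.

`gen_ma_activity` is the activity-band artifact
exp(−0.01 t)·cos(2π f t) with f inside the pulse band — demonstrably
unremovable by band filtering, included for simulator experiments.

The pulse model deliberately excludes aperiodic heart-rate variability
(the influence of physiological factors other than respiration) and
amplitude modulation by respiration.  Consequences: synthetic heart
rates are sinusoidally modulated only, and raw-spectrum harmonic ratios
(the `A_x0` column) are *not* degraded by carrier spreading the way
real recordings' are — a contrast the waveform table shows on real data
but which synthetic tests cannot exercise.

## The analysis chain

1. **High-frequency removal**: zero-phase Butterworth low-pass at 15 Hz,
   order 8 (deep stopband, ≥ 40 dB by 20 Hz).
2. **Fundamental**: largest FFT magnitude (Hann window) inside
   0.7–3.0 Hz (42–180 bpm), refined by quadratic interpolation of the
   log magnitude; a peak less than 3 dB above the band median is
   rejected as "no fundamental".
3. **Baseline**: low-pass at f_C − 0.4 Hz (order 4); x₀ is the
   difference, so x₀ + x_b reproduces the 15 Hz-filtered input exactly.
4. **Band split**: zero-phase band-pass at i f_C ± (f_C − 0.2)/2,
   order 4.  All filters are forward–backward (zero phase) because the
   harmonic amplitudes and phases are the end product; 10 s of
   reflection padding suppresses edge transients.
5. **Instant parameters**: per band, the analytic signal is computed on
   a mirror-extended record (end effects land mostly on the padding);
   the instantaneous frequency is the smoothed phase derivative
   (low-pass at 0.6 Hz — chosen to pass the 0.1–0.5 Hz respiration band
   into f(t) while rejecting carrier-rate ripple), refined by two
   rounds of synchronous demodulation against the integrated frequency
   reference.  φ₀(t) is the unwrapped phase minus the reference ramp
   2π i f_C t; this reference keeps respiration in *both* f(t) (as FM)
   and φ₀(t) (as PM), which is the property the respiration extraction
   relies on.  The raw phase derivative is meaningless over the first
   and last couple of carrier periods; those samples are replaced by
   the nearest interior value before smoothing so the garbage is not
   smeared inward, and all statistics exclude a trim window of
   max(3/f_C, 2 s) per end.
6. **Reconstruction**: x_tf = Σ Ãᵢ(t) cos(2π∫fᵢ dt + φ̄₀ᵢ) with Ãᵢ the
   least-squares line through Aᵢ(t) and the integration constant
   anchored at the valid-window midpoint to the observed phase (so the
   reconstruction is phase-aligned and x_HVD − x_tf is a meaningful
   distortion estimate); x_cf replaces the integral by the constant
   ramp.
7. **Respiration and HRV**: the respiration signal (fᵢ − i f_C, or
   linearly detrended φ₀ᵢ) is reduced by a one-component decomposition
   with respiration-band settings (pre-band-pass 0.05–0.65 Hz,
   frequency smoothing 0.1 Hz, 5 s trim).  HRV is the RMS deviation of
   an HR track about its own mean — this reference makes
   RMSE(HR_φ) ≈ mean(B_φ)/√2·60 an internal consistency identity.
   The partition RMSE(HR_PF) = RMSE(HR) − RMSE(HR_φ) is reported
   as-is, including negative values.

### Filter-response compensation

The printed filter rules collide with the signal once respiration is
fast: the baseline low-pass (cutoff f_C − 0.4) absorbs a substantial
part of the first harmonic's lower sideband at f_C − f_r (≈ 38 % at
f_C = 1.2, f_r = 0.35) and a few percent of the carrier itself, and the
band edges clip fast sidebands further.  All of these filters are known
exactly, so the pipeline divides out their combined gain: modulation
amplitudes B are divided by the mean sideband gain at the recovered
respiration frequency (clamped to [0.2, 1.5] — a deeply suppressed
sideband cannot be restored reliably), and the waveform table's
amplitude columns are divided by the carrier gain at i f_C.  This
standard instrument-response correction brings modulation-amplitude
recovery from ≈ 24 % error (worst grid point) to ≈ 5 %.  The same
uncompensated mechanism explains why frequency-sourced respiration
rates tend to be underestimated on real records.  Compensation is a
pipeline feature; the module-level functions leave it off unless a gain
function is supplied.

### Units of the HRV partition

The phase-sourced "heart rate" adds a quantity in radians to f_C in Hz
before scaling by 60.  This is dimensionally loose but is the working
convention for these indices and is implemented literally; with deep
phase modulation (R ≳ 0.1 rad) the phase-sourced HRV can therefore
exceed the total HRV and make the partition negative.  An optional
corrected mode (`hr_with_resp(..., pm_to_fm=True)`) converts the phase
modulation to its equivalent frequency modulation (time derivative /
2π) first; it is off by default to keep the reported tables on the
conventional scale.

## Numerical and design choices

* **Butterworth order 4, forward–backward** for all band filters:
  maximally flat passband preserves the harmonic amplitudes that become
  waveform indices.  The 15 Hz high-frequency filter alone uses order 8
  for stopband depth.
* **One global f_C per record**, as the band-edge rules require; with a
  strongly drifting heart rate the fixed band edges become suboptimal
  (a known limitation, visible post-exercise).
* **Harmonic count**: default 5, automatically capped so the highest
  band fits under min(15 Hz, Nyquist); the analyzer reports per-band
  spectral SNR so users can justify fewer (noisy PPG) or more (clean
  tactile) harmonics.
* **Trimmed statistics everywhere**: the mean amplitudes, mean phases,
  regressions and all HR/respiration statistics use the valid window
  only.
* **Phase differences** in the waveform table are wrapped into
  [0, 2π): mean unwrapped phases of different harmonics carry arbitrary
  2π offsets.
* **Determinism**: no stage consumes randomness; only the generators
  do, and they are seed-controlled.

## Problem sizes

Synthetic studies use 80 s records at 100 Hz (8000 samples) — long
enough for ≥ 12 respiration cycles at the slowest rate studied
(0.15 Hz) and matching the segment length used for real recordings.
The simulator-fidelity sweep runs 30 s at 500 Hz per frequency.  The
full test suite and the acceptance script each run in well under a
minute on one CPU.

## Known limitations

* With deep phase modulation (R ≈ 0.3) and a narrow first-harmonic
  band, asymmetric sideband filtering converts part of the PM into
  genuine amplitude modulation; the regression line then discards real
  signal structure and the time-varying reconstruction loses some of
  its advantage.  The artifact-removal figure of merit is therefore
  quoted in the mild-modulation regime where the linear amplitude model
  holds.
* The distortion estimate x_HVD − x_tf captures the amplitude-borne
  part of the multiplicative distortion; the part expressed as slow
  phase ripple survives into x_tf and is not attributed.  Correlation
  with the simulator's ground-truth distortion is high for
  mass-dominant coupling (mostly AM) and moderate otherwise.
* Respiration rates above ≈ 0.35 Hz approach the baseline-filter
  offset (0.4 Hz) and are increasingly absorbed before compensation;
  rates at or above 0.4 Hz are unrecoverable by construction of the
  printed filter rules.
* The WFDB reader requires the optional `wfdb` package; CSV is the
  supported interchange format.
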