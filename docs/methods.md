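# Methods

## The harmonic-structure model

`waveshape` analyses sums of sinusoids

    x(t) = sum_{n=1}^{N} a_n cos(omega_n t + phi_n),    omega_n increasing,

and asks when such a sum should be regarded as *one* non-sinusoidal
waveform rather than several co-existing oscillations.  The criteria are:

1. **Integer frequency ratios and constant phases** — `omega_n = n omega_1`
   with time-independent `phi_n`.  This makes the sum periodic with the
   base period, so the joint waveform repeats.
2. **Non-negative joint instantaneous frequency (IF)** — the derivative of
   the analytic-signal phase of the sum never goes negative.  Negative IF
   appears exactly where prominent secondary extrema appear, i.e. where
   the "harmonic" visibly rides on top of the base instead of reshaping
   it.

For two tones `cos t + a cos(w t + phi)` condition 2 reduces to the
closed-form criterion `a w <= 1` (for `a <= 1`; `joint_if`, `two_tone_if`
and `if_nonnegative` evaluate the general expressions exactly).  A second
threshold `a w^2 <= 1` excludes even *small* secondary extrema and grades
structures:

* **strong** (`gamma > 2` for power-law amplitude decay `a_n = 1/n^gamma`):
  no secondary extrema at any harmonic count; the constructive peak IF of
  the infinite sum converges to `zeta(gamma-1)/zeta(gamma)`;
* **weak** (`1 <= gamma <= 2`): IF is non-negative but small secondary
  extrema exist and the peak IF diverges with harmonic count.  The
  classic triangle/sawtooth/square waves all live here (`gamma` of 2, 1, 1
  with odd-only spectra for triangle/square).

The `gamma = 2` transition is checked by the midpoint-convexity sum
`sum (-1)^(n-1) n^{2-gamma}` (even `N` only; odd `N` has an odd number of
secondary extrema and the midpoint argument does not apply).  For three
harmonics the critical exponent for non-negative IF is the root of a
six-term exponential equation, 1.0177 — barely above the two-tone value
of 1, which justifies using the pairwise `a w <= 1` rule even when an
extracted component carries a couple of harmonics.

Sign/convention notes.  `two_tone_if` takes the phase offset with the
`cos t + a cos(wt + phi)` convention (flipping the sign only reverses
time).  The strong/weak phase-plane boundary
`a = (1/4)(1 + |cos phi|^{2/3})` is stated and tested for the pair
`sin t + a sin(2t + phi)`, where its endpoints (0.5 at `phi = 0`, 0.25 at
`phi = pi/2`) are the exact transition amplitudes obtained by factorising
the derivative; in between it is treated as an approximation (tested with
15% margins).

## Instantaneous frequency estimation

`analytic_track` builds the analytic signal with the FFT Hilbert
transform, unwraps the phase, optionally smooths it with a centred moving
average (the pipeline default is 5 samples; smoothing is applied after
unwrapping), and differentiates with central differences.  The series is
transformed *as given* — no demeaning — because a signal's offset is part
of its analytic geometry; callers that want a demeaned analysis remove
the mean first.  The first and last `max(window, 10)` samples are flagged
invalid, and zero-amplitude stretches get NaN IF plus an invalid flag so
that downstream statistics exclude rather than propagate them.
`if_range` additionally discards 1% of samples per edge before reporting
extremes, since the circular FFT boundary contaminates a neighbourhood,
not just a few samples.

## Simulators

* **FitzHugh–Nagumo** (`simulate_fhn`): classical fixed-step RK4 (default
  internal step = one output sample) of the two-variable neuron model.
  Model time is in milliseconds; with the default parameter set
  (I = 0.475, a = 0.7, b = 0.8, tau = 12.5, V0 = 0, W0 = −0.4) the limit
  cycle takes ≈ 40 ms, i.e. continuous 25 Hz spiking.  Fixed-step RK4 was
  chosen over adaptive integration for bit-level reproducibility; halving
  the step changes the waveform by < 1e-4 RMS.
* **Abreu wave** (`simulate_abreu`): pointwise evaluation of the
  asymmetric shallow-water-wave velocity formula with nonlinearity degree
  `r` and angle `phi`; `f = sqrt(1 - r^2)`.  The constant term keeps the
  long-run mean at zero, so the formula is evaluated unclamped — the
  signed velocity oscillates about zero (whether a printed positivity
  constraint on the source formula denotes a clamp or a parameter
  condition is treated as the latter).
* **`synthesize`**: renders any `SinusoidSum` with optional slow cosine
  amplitude modulation (warning if the AM rate reaches the base
  frequency, where Bedrosian's theorem stops protecting the analysis) and
  seeded white/pink noise.  Pink noise is spectrally shaped white noise
  (power ∝ 1/f, DC zeroed, unit variance before scaling).

## The synthetic LFP fixture

`synthetic_lfp` emulates the structure of a CA1 hippocampal recording
sampled at 625 Hz without using any recorded data: a unit-amplitude theta
base near 7.5 Hz carrying a second harmonic at twice its instantaneous
phase.  Defaults (chosen once, as study conditions):

| parameter | default | role |
| --- | --- | --- |
| `theta_f` | 7.5 Hz | theta base frequency |
| `harmonic_a` | 0.27 | relative harmonic amplitude (`a omega` = 0.54) |
| `harmonic_phi` | pi/2 | phase offset of the locked harmonic |
| `am_depth` | 0.5 | bursting envelope (low-passed noise < 0.5 Hz, clipped ≥ 0.1) |
| `freq_wander_sd` | 0.4 Hz | slow theta-frequency wander (< 0.01 Hz band) |
| `harmonic_mod` | 0.4 | slow waxing/waning of harmonic strength |
| `noise.pink_sd` | 0.15 | 1/f² background floor (0.1 Hz – Nyquist) |
| `noise.white_sd` | 1.2 | broadband noise high-passed above 25 Hz |

The two-part background mirrors real LFP band structure: a steep 1/f²
floor that leaves the theta–harmonic band at realistic signal-to-noise
(the 15 Hz peak stands clearly above the floor, as in CA1 spectra), and
broadband high-frequency power that sets the zero-crossing rate — and
hence the mask-frequency ladder — the way spiking/muscle wideband
activity does in recordings.  With these defaults the zero-crossing rate
is ≈ 130 Hz and the dyadic ladder lands at ≈ 130/65/32/16/8 Hz, which
places the harmonic solidly inside the 16 Hz level's band and the theta
base inside the 8 Hz level's — each component well clear of a dyadic
boundary.  The broadband level matters: at lower levels the ladder
shifts down until theta straddles a mask frequency and the sift smears
it across two components.  The decomposition then reproduces the
published situation: base in one IMF, harmonic in the next-faster IMF.  What the fixture does *not* emulate:
spike waveforms, non-stationary theta frequency jumps, volume-conducted
artifacts, or cross-frequency coupling beyond the single planted
harmonic — so passing tests demonstrate pipeline correctness on this
class of signal, not performance on arbitrary recordings.

With `phase_locked=False` the harmonic's offset performs a per-cycle
random walk (steps ~ N(0, (pi/2)^2), linearly interpolated): locking
dissolves within a few cycles while the waveform stays continuous and
narrow-band, making it the negative control for the phase-dependence
test.

## Masked EMD sift

`mask_sift` follows the standard recipe: first mask frequency from the
zero-crossing rate, each further level halving it; mask amplitude equal
to the standard deviation of the input signal (configurable to use the
per-level residual instead — the convention is ambiguous in the
literature); four mask phases per level, averaged.  Envelopes are natural
cubic splines through the strict extrema with two mirrored extrema per
end; the sift stops on the classic normalised-change criterion
(threshold 1e-8) or an iteration cap.

The cap is a real modelling choice, not a formality: on broadband data
the stopping metric plateaus around 1e-4, far above tight thresholds, so
the cap always binds.  Iterating far past the plateau over-sifts — each
component's band broadens until harmonically related components merge
back together and the dyadic separation is lost (at 50 iterations the
planted 15 Hz harmonic of the LFP fixture is expelled from its own IMF).
The default of 15 iterations sits near the plateau; it is exposed as
`max_iters` everywhere.

Cycle detection marks cycles between downward wrap-jumps of the phase;
quality control keeps cycles with strictly increasing phase and mean
amplitude above the 50th percentile.  Phase alignment interpolates each
good cycle's IF onto a 48-point uniform phase grid; the pointwise mean is
the average within-cycle shape profile.

## Segment-wise harmonic assessment

`assess_pairs` computes analytic tracks for every component (5-point
phase smoothing), picks the base as the component whose mean IF is
closest to the Welch spectral peak in the base band (default 4–8 Hz, 8 s
segments), and splits the recording into 20 equal segments.  Per-segment
mean IF and IA are computed **over quality-controlled cycles only** —
noise-dominated stretches carry the IF of the background band, not of
the component, and demonstrably bias the frequency-ratio statistics.  A
segment with under 10% of its samples in good cycles (the oscillation
was off-burst throughout) holds no usable estimate of the component's
frequency at all; such segments are dropped from the pair statistics
rather than imputed.

Per faster-than-base component:

* **Integer ratio** — one-sample t-test of per-segment IF ratios against
  the nearest integer.  The default (`nhst`) passes on failure to
  reject, mirroring common practice; because that logic is inverted (an
  exactly-integer ratio is still rejected in a fraction alpha of
  samples), an equivalence mode (`tost`, margin 0.05) is provided and is
  what the package's own acceptance tests use.
* **Phase dependence** — distance correlation between the wrapped
  instantaneous phases, subsampled to ≤ 2000 points (the V-statistic is
  O(n²)); significance from the bias-corrected t-test (Székely & Rizzo
  2013).  At this subsample size the effective sensitivity threshold is
  a dcor of roughly 0.04, which matches the borderline behaviour seen in
  published per-IMF tables.
* **a·omega** — one-sided t-test of per-segment products against 1
  (alternative: below), Bonferroni-corrected by the number of candidate
  pairs; exact boundary values count as a pass.  The mean of `a omega^2`
  supplies the pairwise strong/weak flag.

The decision tree: non-harmonic unless the integer, dependence and
`a omega` tests all pass; then strong if a multi-harmonic drop-off fit
gives `gamma > 2` (it aggregates all harmonics, so it takes precedence)
or, failing that, if `a omega^2 <= 1`; weak otherwise.  `alpha = 0.05`
throughout, configurable.

Known limitation: when the decomposition leaks base content into the
harmonic component (mode mixing — typically because a component sits
near a dyadic mask boundary), the phase-dependence test can remain
significant even for genuinely phase-diffused signals.  The dependence
it detects is real; it just originates in the leak rather than in
cross-frequency locking.  Inspect the component correlations or the
mask ladder when a surprising phase dependence appears, and prefer the
aggregate spectral-exponent route where pairwise phases are suspect.

## Spectral drop-off fitting

`power_spectrum` provides a boxcar periodogram (mean-removed; suited to
clean simulations) and Hann/50%-overlap Welch spectra.  `harmonic_peaks`
takes, per harmonic index, the local power maximum within ±0.25 `f0`,
requiring it to exceed 3× the window's median power and 1e-8 of the base
peak's amplitude (the double-precision FFT floor).  Amplitudes are square
roots of power so the fitted `gamma` lives on the amplitude scale where
the strong/weak boundary is `gamma = 2`.  `fit_dropoff` is ordinary least
squares of log amplitude on log frequency, optionally split at a knee
frequency.

Study configurations used by the acceptance script: the FitzHugh–Nagumo
study fits the first 27 harmonic peaks of the full 10 s trace (including
the onset transient, matching the initial conditions as part of the
study); the Abreu study fits harmonics 1–17 with the knee at 10 Hz
(1–9 Hz below, 10–17 Hz at/above).  IF ranges are reported with the 1%
edge trim.

## Numerical choices

* Non-negativity tolerance for the joint-IF minimum: −1e-9·(Σa)² —
  boundary structures (`a omega = 1`, e.g. sawtooth neighbours) touch
  zero exactly.
* Brute-force minima use 2^14 grid points per base period (≥ 64 per
  term).
* `zeta_peak_if` uses the library zeta function; the test suite checks it
  against independent partial sums with an integral tail estimate.
* The `(cos phi)^{2/3}` in the phase boundary is computed as
  `|cos phi|^{2/3}` (real and even in phi).
* Natural-spline envelopes (numba-accelerated, scipy fallback) agree with
  scipy's natural `CubicSpline` to ~4e-15.
* Integer-ratio and `a omega` tests degenerate to exact comparisons for
  zero-variance samples.

## Problem sizes

The acceptance script and tests run the studies at their native sizes —
FitzHugh–Nagumo 10 s @ 100 kHz, Abreu 100 s @ 10 kHz, LFP fixture
1000 s @ 625 Hz with 20 seeded pipeline repetitions plus one control —
about 10–15 minutes of compute in total, dominated by the sift
repetitions.
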