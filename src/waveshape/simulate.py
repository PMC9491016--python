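"""Forward models producing test signals with known harmonic content.

Four generators:

* ``simulate_fhn`` — a FitzHugh–Nagumo model neuron in its tonically
  spiking regime.  The default parameters produce a continuous 25 Hz
  spike train whose highly non-sinusoidal waveform is a strong harmonic
  structure (drop-off exponent just above 2).
* ``simulate_abreu`` — the Abreu asymmetric shallow-water wave, a closed
  form with sharp rising edges and rapidly decaying harmonics.
* ``synthesize`` — direct synthesis of a sinusoid-sum model with optional
  slow amplitude modulation and additive noise.
* ``synthetic_lfp`` — a hippocampal-LFP-like fixture: a ~7.5 Hz
  non-sinusoidal theta base with a phase-locked second harmonic, slow
  bursting, frequency wander and broadband background noise, built so the
  masked-EMD assessment pipeline can be exercised end to end without any
  recorded data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .analytic import UniformSeries
from .theory import SinusoidSum

__all__ = [
    "FHNParams",
    "AbreuParams",
    "NoiseSpec",
    "simulate_fhn",
    "simulate_abreu",
    "synthesize",
    "synthetic_lfp",
    "pink_noise",
]


@dataclass(frozen=True)
class FHNParams:
    """FitzHugh–Nagumo parameters.

    dV/dt = V - V^3/3 - W + I
    tau dW/dt = V + a - b W

    Model time is measured in milliseconds: with the default parameters
    the limit cycle takes ~40 ms, i.e. a 25 Hz oscillation.
    """

    I: float = 0.475
    a: float = 0.7
    b: float = 0.8
    tau: float = 12.5
    V0: float = 0.0
    W0: float = -0.4

    def __post_init__(self) -> None:
        if self.tau <= 0:
            raise ValueError("tau must be positive")


@dataclass(frozen=True)
class AbreuParams:
    """Abreu wave parameters: nonlinearity degree ``r`` in [0, 1),
    nonlinearity angle ``phi`` (rad) and base frequency in Hz."""

    r: float = 0.75
    phi: float = -np.pi / 4
    base_f: float = 1.0

    def __post_init__(self) -> None:
        if not 0 <= self.r < 1:
            raise ValueError("r must lie in [0, 1); the denominator can vanish otherwise")
        if self.base_f <= 0:
            raise ValueError("base_f must be positive")

    @property
    def f(self) -> float:
        """Derived amplitude factor ``sqrt(1 - r^2)``."""
        return float(np.sqrt(1.0 - self.r**2))


@dataclass(frozen=True)
class NoiseSpec:
    """Additive noise description: white and 1/f components plus RNG seed."""

    white_sd: float = 0.0
    pink_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.white_sd < 0 or self.pink_sd < 0:
            raise ValueError("noise standard deviations must be >= 0")


def simulate_fhn(
    p: FHNParams = FHNParams(),
    duration: float = 10.0,
    fs: float = 1e5,
    dt_internal: float | None = None,
) -> UniformSeries:
    """Integrate the FitzHugh–Nagumo equations; return the voltage trace.

    Classical fixed-step fourth-order Runge–Kutta from ``(V0, W0)``,
    integrated on the model's millisecond time base and decimated to the
    requested sampling rate.  ``dt_internal`` (seconds) defaults to
    ``1/fs``; it must divide the sampling interval.

    Raises
    ------
    RuntimeError
        If the trajectory diverges (|V| > 1e3).
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    dt_internal = dt_internal if dt_internal is not None else 1.0 / fs
    if dt_internal > 1.0 / fs + 1e-15:
        raise ValueError("dt_internal must not exceed the sampling interval")
    sub = int(round((1.0 / fs) / dt_internal))
    dt = 1000.0 / fs / sub  # model ms per internal step
    n_out = int(round(duration * fs))

    I, a, b, tau = p.I, p.a, p.b, p.tau
    v, w = p.V0, p.W0
    out = np.empty(n_out)
    third = 1.0 / 3.0
    for i in range(n_out):
        out[i] = v
        for _ in range(sub):
            k1v = v - v * v * v * third - w + I
            k1w = (v + a - b * w) / tau
            v2 = v + 0.5 * dt * k1v
            w2 = w + 0.5 * dt * k1w
            k2v = v2 - v2 * v2 * v2 * third - w2 + I
            k2w = (v2 + a - b * w2) / tau
            v3 = v + 0.5 * dt * k2v
            w3 = w + 0.5 * dt * k2w
            k3v = v3 - v3 * v3 * v3 * third - w3 + I
            k3w = (v3 + a - b * w3) / tau
            v4 = v + dt * k3v
            w4 = w + dt * k3w
            k4v = v4 - v4 * v4 * v4 * third - w4 + I
            k4w = (v4 + a - b * w4) / tau
            v += dt * (k1v + 2.0 * (k2v + k3v) + k4v) / 6.0
            w += dt * (k1w + 2.0 * (k2w + k3w) + k4w) / 6.0
        if abs(v) > 1e3:
            raise RuntimeError(f"FitzHugh–Nagumo trajectory diverged with {p}")
    return UniformSeries(out, fs)


def simulate_abreu(
    p: AbreuParams = AbreuParams(), duration: float = 100.0, fs: float = 1e4
) -> UniformSeries:
    """Abreu asymmetric wave velocity, evaluated pointwise:

        u(t) = f [sin(w t) + r sin(phi) / (1 + f)] / [1 - r cos(w t + phi)]

    with ``f = sqrt(1 - r^2)`` and ``w = 2 pi base_f``.  The offset term
    makes the long-run mean vanish, so the signed velocity oscillates
    about zero.
    """
    n = int(round(duration * fs))
    t = np.arange(n) / fs
    w = 2.0 * np.pi * p.base_f
    f = p.f
    u = f * (np.sin(w * t) + p.r * np.sin(p.phi) / (1.0 + f)) / (
        1.0 - p.r * np.cos(w * t + p.phi)
    )
    return UniformSeries(u, fs)


def pink_noise(n: int, fs: float, rng: np.random.Generator, slope: float = -1.0) -> np.ndarray:
    """Unit-variance noise with power spectral density ``f^slope``.

    Spectral shaping of seeded white noise; the DC bin is zeroed.
    ``slope=-1`` is classic pink noise, ``slope=-2`` Brownian-like.
    """
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    shape = np.zeros_like(freqs)
    shape[1:] = freqs[1:] ** (slope / 2.0)
    out = np.fft.irfft(spec * shape, n)
    return out / np.std(out)


def _band_noise(
    n: int,
    fs: float,
    lo: float,
    hi: float,
    rng: np.random.Generator,
    slope: float = 0.0,
) -> np.ndarray:
    """Unit-variance noise restricted to [lo, hi] Hz with PSD ``f^slope``."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    keep = (freqs >= lo) & (freqs <= hi)
    shape = np.zeros_like(freqs)
    shape[keep] = 1.0 if slope == 0.0 else freqs[keep] ** (slope / 2.0)
    out = np.fft.irfft(spec * shape, n)
    sd = np.std(out)
    return out / sd if sd > 0 else out


def synthesize(
    model: SinusoidSum,
    duration: float,
    fs: float,
    am_freq: float = 0.0,
    am_depth: float = 0.0,
    noise: NoiseSpec = NoiseSpec(),
) -> UniformSeries:
    """Render a sinusoid-sum model with optional slow AM and noise.

    The amplitude envelope is ``1 - d + d (1 + cos(2 pi f_am t)) / 2`` so
    the signal swings between full amplitude and ``1 - d`` of it.  A slow
    envelope (``am_freq`` below the base frequency) keeps the analysis of
    the underlying structure valid (Bedrosian's theorem: the envelope
    spectrum must not overlap the carrier's); a faster one is accepted but
    triggers a warning.
    """
    if not 0.0 <= am_depth <= 1.0:
        raise ValueError("am_depth must lie in [0, 1]")
    if am_depth > 0 and am_freq >= model.f_hz[0]:
        import warnings

        warnings.warn(
            "amplitude modulation at or above the base frequency violates "
            "the slow-AM (Bedrosian) condition; harmonic analysis of the "
            "result is not guaranteed to be meaningful",
            stacklevel=2,
        )
    n = int(round(duration * fs))
    t = np.arange(n) / fs
    x = model.evaluate(t)
    if am_depth > 0:
        env = 1.0 - am_depth + am_depth * (1.0 + np.cos(2.0 * np.pi * am_freq * t)) / 2.0
        x = x * env
    if noise.white_sd > 0 or noise.pink_sd > 0:
        rng = np.random.default_rng(noise.seed)
        if noise.pink_sd > 0:
            x = x + noise.pink_sd * pink_noise(n, fs, rng)
        if noise.white_sd > 0:
            x = x + noise.white_sd * rng.standard_normal(n)
    return UniformSeries(x, fs)


def _slow_noise(n: int, fs: float, fc: float, rng: np.random.Generator) -> np.ndarray:
    return _band_noise(n, fs, 1.0 / (n / fs), fc, rng)


def synthetic_lfp(
    theta_f: float = 7.5,
    harmonic_a: float = 0.27,
    harmonic_phi: float = np.pi / 2,
    duration: float = 1000.0,
    fs: float = 625.0,
    noise: NoiseSpec = NoiseSpec(white_sd=1.2, pink_sd=0.15, seed=0),
    am_depth: float = 0.5,
    freq_wander_sd: float = 0.4,
    harmonic_mod: float = 0.4,
    broadband_cutoff: float = 25.0,
    phase_locked: bool = True,
    return_parts: bool = False,
):
    """Hippocampal-LFP-like two-tone theta fixture (synthetic).

    A theta base of unit amplitude at ``theta_f`` carries a second
    harmonic of relative amplitude ``harmonic_a`` at twice its
    instantaneous phase plus ``harmonic_phi`` (so the pair satisfies the
    harmonic conditions by construction when ``phase_locked``).  Realism
    terms, all slow relative to theta: a bursting amplitude envelope
    (depth ``am_depth``), a random walk of the theta frequency
    (``freq_wander_sd`` Hz), and slow waxing/waning of the harmonic's
    relative strength (``harmonic_mod``).  Background noise has two parts
    mirroring the band structure of CA1 recordings: a steep ``1/f^2``
    low-frequency floor (``noise.pink_sd``) and broadband power above
    ``broadband_cutoff`` Hz (``noise.white_sd``) which sets the
    zero-crossing rate seen by the mask sift while leaving the
    theta–harmonic band at realistic signal-to-noise.

    With ``phase_locked=False`` the harmonic's phase offset performs a
    random walk with one step per base cycle (linearly interpolated so
    the waveform stays continuous and narrow-band): after a few cycles
    the offset has diffused across the circle, destroying the constant
    phase relationship while leaving the spectrum essentially in place —
    the negative control for the phase-dependence test.

    Returns the mixed series; with ``return_parts=True`` also a dict with
    the clean ``base`` and ``harmonic`` components.
    """
    if harmonic_a > 1:
        raise ValueError("harmonic_a must be <= 1 (decreasing-amplitude structure)")
    rng = np.random.default_rng(noise.seed)
    n = int(round(duration * fs))

    env = np.clip(1.0 + am_depth * _slow_noise(n, fs, 0.5, rng), 0.1, None)
    wander = freq_wander_sd * _slow_noise(n, fs, 0.01, rng)
    phase = 2.0 * np.pi * np.cumsum(theta_f + wander) / fs
    amod = np.clip(1.0 + harmonic_mod * _slow_noise(n, fs, 0.01, rng), 0.05, None)

    base = env * np.cos(phase)
    if phase_locked:
        offset: np.ndarray | float = harmonic_phi
    else:
        wrapped = np.angle(np.exp(1j * phase))
        starts = np.concatenate(
            [[0], np.flatnonzero(np.diff(wrapped) < -np.pi) + 1, [n - 1]]
        )
        # phase offset diffuses by ~pi/2 per cycle: locking is gone after a
        # few cycles, but the interpolated offset keeps the harmonic's
        # bandwidth narrow (its IF shifts by well under the base frequency)
        steps = np.cumsum(rng.normal(0.0, np.pi / 2, len(starts)))
        offset = harmonic_phi + np.interp(np.arange(n), starts, steps)
    harmonic = env * harmonic_a * amod * np.cos(2.0 * phase + offset)

    background = np.zeros(n)
    if noise.pink_sd > 0:
        # steep low-frequency floor; cut below 0.1 Hz so sub-theta drift does
        # not dominate the variance or shift the zero-crossing rate
        background += noise.pink_sd * _band_noise(n, fs, 0.1, fs / 2, rng, slope=-2.0)
    if noise.white_sd > 0:
        background += noise.white_sd * _band_noise(n, fs, broadband_cutoff, fs / 2, rng)

    series = UniformSeries(base + harmonic + background, fs)
    if return_parts:
        return series, {
            "base": UniformSeries(base, fs),
            "harmonic": UniformSeries(harmonic, fs) if harmonic_a > 0 else None,
        }
    return series
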