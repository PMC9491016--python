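"""Power spectra, harmonic-peak detection and amplitude drop-off fits.

The harmonic amplitude drop-off exponent ``gamma`` (``a_n ~ k / n^gamma``)
is estimated by locating spectral peaks at integer multiples of a base
frequency and regressing log peak *amplitude* on log frequency.  Amplitude
(square root of power) rather than power is fitted so the slope is directly
comparable with the theory's amplitude exponent, whose ``gamma = 2``
boundary separates strong from weak harmonic structures.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps
from scipy import stats

from .analytic import UniformSeries
from .theory import PowerLawFit

__all__ = [
    "Spectrum",
    "SpectralPeakSet",
    "power_spectrum",
    "find_base",
    "harmonic_peaks",
    "fit_dropoff",
]


@dataclass(frozen=True)
class Spectrum:
    """One-sided power spectrum with its frequency grid and method tag."""

    freqs: np.ndarray
    power: np.ndarray
    method: str
    resolution: float

    def __post_init__(self) -> None:
        if len(self.freqs) != len(self.power):
            raise ValueError("freqs and power must match in length")
        if np.any(np.diff(self.freqs) <= 0):
            raise ValueError("freqs must be strictly increasing")
        if np.any(self.power < 0):
            raise ValueError("power must be non-negative")


@dataclass(frozen=True)
class SpectralPeakSet:
    """Harmonic peaks: base frequency plus (index, frequency, amplitude) rows.

    Amplitudes are linear (square root of spectral power).
    """

    f0: float
    index: np.ndarray
    freq: np.ndarray
    amplitude: np.ndarray

    def __post_init__(self) -> None:
        if not (len(self.index) == len(self.freq) == len(self.amplitude)):
            raise ValueError("peak columns must match in length")
        if np.any(np.diff(self.index) <= 0):
            raise ValueError("harmonic indices must be strictly increasing")

    def __len__(self) -> int:
        return len(self.index)


def power_spectrum(
    x: UniformSeries, method: str = "periodogram", seg_len: float | None = None
) -> Spectrum:
    """One-sided power spectrum via a plain periodogram or Welch's method.

    The periodogram uses a boxcar window on the mean-removed signal
    (suited to clean simulations, where leakage control matters less than
    resolution).  Welch uses Hann-tapered segments of ``seg_len`` seconds
    with 50% overlap — the noise-robust choice for recordings.
    """
    if method == "periodogram":
        freqs, power = sps.periodogram(
            x.values, fs=x.fs, window="boxcar", detrend="constant"
        )
    elif method == "welch":
        if seg_len is None:
            raise ValueError("welch needs a segment length in seconds")
        nper = int(round(seg_len * x.fs))
        if nper > len(x):
            raise ValueError("seg_len exceeds the signal duration")
        freqs, power = sps.welch(
            x.values, fs=x.fs, nperseg=nper, noverlap=nper // 2, window="hann"
        )
    else:
        raise ValueError(f"unknown method {method!r}")
    return Spectrum(freqs=freqs, power=power, method=method, resolution=freqs[1] - freqs[0])


def find_base(spec: Spectrum, band: tuple[float, float]) -> float:
    """Frequency of maximal power inside ``band`` (inclusive)."""
    lo, hi = band
    mask = (spec.freqs >= lo) & (spec.freqs <= hi)
    if not np.any(mask):
        raise ValueError(f"band {band} contains no spectral bins")
    return float(spec.freqs[mask][np.argmax(spec.power[mask])])


def harmonic_peaks(
    spec: Spectrum,
    f0: float,
    n_max: int,
    rel_tol: float = 0.25,
    floor_factor: float = 3.0,
    min_rel_amplitude: float = 1e-8,
) -> SpectralPeakSet:
    """Spectral peaks at integer multiples of ``f0``.

    For each harmonic index ``n`` up to ``n_max`` the local power maximum
    within ``n f0 +- rel_tol f0`` is taken; a candidate is kept only if it
    exceeds ``floor_factor`` times the median power in its search window
    (a simple local noise floor) and ``min_rel_amplitude`` times the base
    peak's amplitude (the double-precision FFT floor sits around 1e-15).
    Amplitude is the square root of the peak power.
    """
    if f0 <= 0:
        raise ValueError("f0 must be positive")
    idx, freqs, amps = [], [], []
    for n in range(1, n_max + 1):
        lo, hi = (n - rel_tol) * f0, (n + rel_tol) * f0
        mask = (spec.freqs >= lo) & (spec.freqs <= hi)
        if not np.any(mask):
            continue
        win = spec.power[mask]
        k = int(np.argmax(win))
        floor = np.median(win)
        if floor > 0 and win[k] < floor_factor * floor:
            continue
        amp = np.sqrt(win[k])
        if amps and amp < min_rel_amplitude * amps[0]:
            continue
        idx.append(n)
        freqs.append(spec.freqs[mask][k])
        amps.append(amp)
    if not idx or idx[0] != 1:
        raise ValueError("no base peak found at f0; check f0 and the noise floor")
    return SpectralPeakSet(
        f0=f0, index=np.array(idx), freq=np.array(freqs), amplitude=np.array(amps)
    )


def _ols_loglog(freq: np.ndarray, amp: np.ndarray) -> PowerLawFit:
    res = stats.linregress(np.log(freq), np.log(amp))
    return PowerLawFit(
        k=float(np.exp(res.intercept)),
        gamma=float(-res.slope),
        pearson_r=float(res.rvalue),
        p_value=float(res.pvalue),
        n_points=len(freq),
    )


def fit_dropoff(
    peaks: SpectralPeakSet, knee: float | None = None
) -> PowerLawFit | tuple[PowerLawFit, PowerLawFit]:
    """Ordinary least squares of log amplitude on log frequency.

    ``gamma`` is the negated slope.  With a ``knee`` frequency, separate
    fits are returned for peaks below and at/above the knee (useful when
    the drop-off steepens, as for strongly nonlinear waves).
    """
    if knee is None:
        if len(peaks) < 2:
            raise ValueError("need at least 2 peaks to fit")
        return _ols_loglog(peaks.freq, peaks.amplitude)
    low = peaks.freq < knee
    high = ~low
    if low.sum() < 2 or high.sum() < 2:
        raise ValueError("need at least 2 peaks on each side of the knee")
    return (
        _ols_loglog(peaks.freq[low], peaks.amplitude[low]),
        _ols_loglog(peaks.freq[high], peaks.amplitude[high]),
    )
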