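"""Analytic-signal construction and instantaneous phase/frequency/amplitude.

The analytic signal of a real series ``u(t)`` is ``u + i v`` where ``v`` is
the Hilbert transform of ``u``.  Writing it in polar form ``A e^{i theta}``
gives the instantaneous amplitude ``A(t)`` and the unwrapped instantaneous
phase ``theta(t)``; the instantaneous frequency (IF) is the phase derivative
divided by ``2 pi``.  IF fully characterises the within-cycle shape of a
mono-component oscillation and goes negative exactly where prominent
secondary extrema appear — the property the harmonic conditions build on.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks, hilbert

__all__ = [
    "UniformSeries",
    "AnalyticTrack",
    "hilbert_quadrature",
    "analytic_track",
    "count_extrema",
    "if_range",
]


@dataclass(frozen=True)
class UniformSeries:
    """A uniformly sampled real-valued signal.

    Parameters
    ----------
    values:
        Sample vector, in signal units.
    fs:
        Sampling rate in Hz, strictly positive.
    t0:
        Time of the first sample in seconds (default 0).
    """

    values: np.ndarray
    fs: float
    t0: float = 0.0

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 1 or values.size < 2:
            raise ValueError("UniformSeries needs a 1-D vector of length >= 2")
        if not np.all(np.isfinite(values)):
            raise ValueError("UniformSeries values must all be finite")
        if not (np.isfinite(self.fs) and self.fs > 0):
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        object.__setattr__(self, "values", values)

    def __len__(self) -> int:
        return self.values.size

    @property
    def duration(self) -> float:
        """Total duration in seconds (n / fs)."""
        return len(self) / self.fs

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(len(self)) / self.fs


@dataclass(frozen=True)
class AnalyticTrack:
    """Instantaneous phase / frequency / amplitude of one component.

    ``phase`` is the unwrapped analytic-signal phase in radians, ``if_hz``
    its sample-wise derivative over ``2 pi``, and ``ia`` the analytic
    amplitude.  ``valid`` marks samples whose IF estimate is trustworthy:
    boundary samples and zero-amplitude stretches are flagged False, with
    ``if_hz`` set to NaN there so that downstream statistics exclude rather
    than propagate them.
    """

    phase: np.ndarray
    if_hz: np.ndarray
    ia: np.ndarray
    fs: float
    valid: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        n = len(self.phase)
        if not (len(self.if_hz) == len(self.ia) == n):
            raise ValueError("phase, if_hz and ia must have equal length")
        if self.valid is None:
            object.__setattr__(self, "valid", np.ones(n, dtype=bool))

    def __len__(self) -> int:
        return len(self.phase)

    @property
    def wrapped_phase(self) -> np.ndarray:
        """Phase wrapped to (-pi, pi]."""
        return np.angle(np.exp(1j * self.phase))


def hilbert_quadrature(x: UniformSeries) -> np.ndarray:
    """Quadrature component ``v`` of the analytic signal of ``x``.

    Uses the frequency-domain construction (zero out negative frequencies,
    double the positive ones), so that ``a cos(w t + phi)`` maps to
    ``a sin(w t + phi)`` away from the boundaries.
    """
    if len(x) < 4:
        raise ValueError("need at least 4 samples for the Hilbert transform")
    return np.imag(hilbert(x.values))


def analytic_track(x: UniformSeries, phase_smooth_window: int = 1) -> AnalyticTrack:
    """Instantaneous phase, frequency and amplitude via the Hilbert transform.

    Parameters
    ----------
    x:
        Input series.  The series is transformed as given (no demeaning);
        remove offsets beforehand if they are not part of the signal.
    phase_smooth_window:
        Odd moving-average window (in samples) applied to the unwrapped
        phase before differentiation; ``1`` disables smoothing.

    Returns
    -------
    AnalyticTrack
        IF by central differences (one-sided at the ends).  The first and
        last ``max(window, 10)`` samples are flagged invalid as
        boundary-contaminated, as are zero-amplitude stretches.
    """
    if phase_smooth_window < 1 or phase_smooth_window % 2 == 0:
        raise ValueError("phase_smooth_window must be odd and >= 1")
    za = hilbert(x.values)
    ia = np.abs(za)
    phase = np.unwrap(np.angle(za))
    if phase_smooth_window > 1:
        kernel = np.ones(phase_smooth_window) / phase_smooth_window
        smoothed = np.convolve(phase, kernel, mode="same")
        # the centred average is biased inside half a window of the ends
        h = phase_smooth_window // 2
        smoothed[:h] = phase[:h]
        smoothed[-h:] = phase[-h:]
        phase_d = smoothed
    else:
        phase_d = phase
    if_hz = np.gradient(phase_d) * x.fs / (2.0 * np.pi)

    valid = np.ones(len(x), dtype=bool)
    margin = max(phase_smooth_window, 10)
    valid[:margin] = False
    valid[-margin:] = False
    dead = ia < 1e-12 * max(np.max(ia), 1e-300)
    valid[dead] = False
    if_hz = if_hz.copy()
    if_hz[dead] = np.nan
    return AnalyticTrack(phase=phase, if_hz=if_hz, ia=ia, fs=x.fs, valid=valid)


def if_range(track: AnalyticTrack, edge_fraction: float = 0.01) -> tuple[float, float]:
    """Minimum and maximum IF away from the series edges.

    ``edge_fraction`` of the samples is discarded at each end (at least the
    track's own invalid margin) before taking the extremes; the Hilbert
    transform's circular boundary makes the edges untrustworthy.
    """
    n = len(track)
    k = max(int(edge_fraction * n), 1)
    sel = track.valid.copy()
    sel[:k] = False
    sel[-k:] = False
    vals = track.if_hz[sel]
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise ValueError("no valid IF samples away from the edges")
    return float(vals.min()), float(vals.max())


def count_extrema(x: UniformSeries, min_prominence: float = 0.0) -> tuple[int, int]:
    """Count strict local maxima and minima exceeding a prominence threshold.

    Prominence follows the usual peak-finding definition (height above the
    higher of the two flanking valleys).  Returns ``(n_maxima, n_minima)``.
    """
    if min_prominence < 0:
        raise ValueError("min_prominence must be >= 0")
    prom = min_prominence if min_prominence > 0 else None
    maxima, _ = find_peaks(x.values, prominence=prom)
    minima, _ = find_peaks(-x.values, prominence=prom)
    return len(maxima), len(minima)
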