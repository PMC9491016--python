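"""Closed-form harmonic-structure theory.

A *harmonic structure* is a sum of sinusoids

    x(t) = sum_n a_n cos(omega_n t + phi_n),   omega_n = n * omega_1,

whose members keep (1) integer frequency ratios to the base with constant
phases, and (2) a finite, non-negative joint instantaneous frequency.  This
module provides the exact joint IF of such sums, the two-tone ``a omega``
criterion, the critical drop-off exponents, and the strong/weak
classification theory for power-law amplitude decay ``a_n = 1/n^gamma``:

* ``gamma > 2``  — strong structure: harmonics add no secondary extrema and
  the peak IF stays finite (``zeta(gamma-1)/zeta(gamma)``) even with
  infinitely many harmonics;
* ``1 <= gamma <= 2`` — weak structure: joint IF is still non-negative but
  small secondary extrema appear and the peak IF diverges as the number of
  harmonics grows.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import zeta as _zeta

__all__ = [
    "SinusoidSum",
    "TwoTone",
    "PowerLawFit",
    "joint_if",
    "two_tone_if",
    "if_nonnegative",
    "two_tone_condition",
    "critical_exponent_three",
    "zeta_peak_if",
    "midpoint_convexity",
    "strong_weak_phase_boundary",
    "canonical_structure",
    "power_law_model",
]


@dataclass(frozen=True)
class SinusoidSum:
    """Model ``sum_n a_n cos(2 pi f_n t + phi_n)`` with increasing ``f_n``.

    The first term is the base; the implied period is ``1 / f_n[0]``.
    """

    a: np.ndarray
    f_hz: np.ndarray
    phi: np.ndarray

    def __post_init__(self) -> None:
        a = np.atleast_1d(np.asarray(self.a, dtype=float))
        f = np.atleast_1d(np.asarray(self.f_hz, dtype=float))
        p = np.atleast_1d(np.asarray(self.phi, dtype=float))
        if not (a.size == f.size == p.size) or a.size == 0:
            raise ValueError("a, f_hz and phi must be equal-length, non-empty")
        if np.any(a < 0):
            raise ValueError("amplitudes must be non-negative")
        if np.any(f <= 0):
            raise ValueError("frequencies must be positive")
        if np.any(np.diff(f) <= 0):
            raise ValueError("terms must be sorted by strictly increasing frequency")
        for name, arr in (("a", a), ("f_hz", f), ("phi", p)):
            object.__setattr__(self, name, arr)

    @property
    def n_terms(self) -> int:
        return self.a.size

    @property
    def period(self) -> float:
        """Base period ``1 / f_1`` in seconds."""
        return 1.0 / self.f_hz[0]

    def evaluate(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        ang = 2.0 * np.pi * np.outer(t, self.f_hz) + self.phi
        return np.cos(ang) @ self.a

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {"amplitude": self.a, "frequency_hz": self.f_hz, "phase_rad": self.phi}
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "SinusoidSum":
        df = pd.read_csv(path)
        return cls(
            df["amplitude"].to_numpy(),
            df["frequency_hz"].to_numpy(),
            df["phase_rad"].to_numpy(),
        )

    def __str__(self) -> str:
        buf = io.StringIO()
        buf.write(f"SinusoidSum with {self.n_terms} terms (T = {self.period:g} s)")
        return buf.getvalue()


@dataclass(frozen=True)
class TwoTone:
    """Two-tone model ``cos(t) + a cos(w t + phi)`` with ``w > 1``."""

    a: float
    w: float
    phi: float = 0.0

    def __post_init__(self) -> None:
        if self.a <= 0:
            raise ValueError("amplitude ratio a must be positive")
        if self.w <= 1:
            raise ValueError("frequency ratio w must exceed 1")


@dataclass(frozen=True)
class PowerLawFit:
    """Power-law fit ``amplitude = k / f^gamma`` in the log-log plane."""

    k: float
    gamma: float
    pearson_r: float
    p_value: float
    n_points: int

    def __post_init__(self) -> None:
        if self.n_points < 2:
            raise ValueError("a power-law fit needs at least 2 points")
        if abs(self.pearson_r) > 1 + 1e-12:
            raise ValueError("|pearson_r| cannot exceed 1")


def _num_den(model: SinusoidSum, t: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Joint-IF numerator (rad/s scale) and squared analytic amplitude.

    With ``c_n = a_n cos(.)`` and ``s_n = a_n sin(.)`` the double sum
    ``sum_{n,m} a_n a_m omega_m cos((omega_n-omega_m) t + (phi_n-phi_m))``
    collapses to ``sum_m omega_m (c_m u + s_m v)`` where ``u = sum c`` and
    ``v = sum s`` — O(N) per time point instead of O(N^2).
    """
    t = np.asarray(t, dtype=float)
    ang = 2.0 * np.pi * np.outer(t, model.f_hz) + model.phi
    c = np.cos(ang) * model.a
    s = np.sin(ang) * model.a
    u = c.sum(axis=1)
    v = s.sum(axis=1)
    omega = 2.0 * np.pi * model.f_hz
    num = u * (c @ omega) + v * (s @ omega)
    den = u * u + v * v
    return num, den


def joint_if(
    model: SinusoidSum, t: np.ndarray, amp_tol: float = 1e-12
) -> tuple[np.ndarray, np.ndarray]:
    """Exact joint instantaneous frequency of a sinusoid sum, in Hz.

    Evaluates the analytic double-sum expression for the joint IF (the
    Hilbert transform of each ``a cos`` term being the matching ``a sin``).
    Returns ``(if_hz, valid)`` where samples with squared analytic amplitude
    below ``amp_tol * (sum a)^2`` are flagged invalid (IF set to NaN).
    """
    num, den = _num_den(model, t)
    scale = float(np.sum(model.a)) ** 2
    bad = den <= amp_tol * scale
    out = np.full(num.shape, np.nan)
    ok = ~bad
    out[ok] = num[ok] / den[ok] / (2.0 * np.pi)
    return out, ok


def two_tone_if(tt: TwoTone, t: np.ndarray, den_tol: float = 1e-12) -> np.ndarray:
    """Joint instantaneous angular frequency of ``cos t + a cos(w t + phi)``.

    Returned in units of the base angular frequency (so a lone base gives 1
    everywhere; divide by ``2 pi`` for Hz if the base is 1 rad/s):

        2 pi f_J = [1 + w a^2 + a (1+w) cos((w-1) t + phi)]
                   / [1 + a^2 + 2 a cos((w-1) t + phi)]

    The sign convention on ``phi`` matches the model ``cos t + a
    cos(w t + phi)``; flipping it only reverses time and leaves every
    extremal property unchanged.  Samples where the denominator vanishes
    (``a = 1`` in antiphase) come back NaN.
    """
    t = np.asarray(t, dtype=float)
    a, w, phi = tt.a, tt.w, tt.phi
    cosang = np.cos((w - 1.0) * t + phi)
    num = 1.0 + w * a * a + a * (1.0 + w) * cosang
    den = 1.0 + a * a + 2.0 * a * cosang
    out = np.full(num.shape, np.nan)
    ok = den > den_tol
    out[ok] = num[ok] / den[ok]
    return out


def if_nonnegative(
    model: SinusoidSum, samples_per_period: int | None = None
) -> tuple[bool, float]:
    """Brute-force check of the non-negative joint IF condition.

    The joint signal repeats with the base period, so the numerator of the
    joint-IF expression is minimised over one dense period grid (default
    ``2**14`` points, at least ``64 * n_terms``).  Returns
    ``(ok, min_numerator)`` with the numerator in rad/s units normalised by
    the base angular frequency; ``ok`` tolerates ``-1e-9 (sum a_n)^2`` of
    floating-point noise because boundary cases (``a omega = 1``) touch
    zero exactly.
    """
    n = samples_per_period or max(2**14, 64 * model.n_terms)
    if n < 64 * model.n_terms:
        raise ValueError("need at least 64 grid points per term")
    t = np.linspace(0.0, model.period, n, endpoint=False)
    num, _ = _num_den(model, t)
    num = num / (2.0 * np.pi * model.f_hz[0])  # per unit base angular freq
    mn = float(num.min())
    tol = 1e-9 * float(np.sum(model.a)) ** 2
    return mn >= -tol, mn


def two_tone_condition(a: float, w: float) -> bool:
    """The ``a omega`` harmonic criterion for a two-tone signal.

    For amplitude ratio ``a`` and frequency ratio ``w`` the joint IF is
    non-negative iff ``a w <= 1`` when ``a <= 1``, and iff ``a w > 1`` when
    ``a > 1`` (the high-frequency tone then dominates and the base is its
    sub-harmonic; harmonic verdicts elsewhere in this package use only the
    decreasing-amplitude branch ``a <= 1``).
    """
    if a <= 0 or w <= 1:
        raise ValueError("need a > 0 and w > 1")
    if a <= 1:
        return a * w <= 1
    return a * w > 1


def critical_exponent_three() -> float:
    """Critical drop-off exponent for three power-law harmonics.

    For ``cos t + 2^-g cos 2t + 3^-g cos 3t`` the joint IF stays
    non-negative iff ``g`` exceeds the root of

        9/4^g + 25/36^g + 128/9^g - 32/3^g - 34/12^g - 96/27^g = 0

    bracketed in (0.9, 1.5); numerically 1.0177.  (The two-tone case has
    critical exponent exactly 1.)
    """

    def lhs(g: float) -> float:
        return (
            9.0 / 4.0**g
            + 25.0 / 36.0**g
            + 128.0 / 9.0**g
            - 32.0 / 3.0**g
            - 34.0 / 12.0**g
            - 96.0 / 27.0**g
        )

    return float(brentq(lhs, 0.9, 1.5, xtol=1e-12, rtol=8.9e-16))


def zeta_peak_if(gamma: float) -> float:
    """Peak joint IF of the infinite power-law structure, in base units.

    With ``a_n = 1/n^gamma`` and all phases equal, the constructive peak of
    the joint IF converges to ``zeta(gamma-1) / zeta(gamma)``, finite only
    for ``gamma > 2`` — the strong-structure regime.

    Raises
    ------
    ValueError
        If ``gamma <= 2`` (the harmonic series in the numerator diverges).
    """
    if gamma <= 2:
        raise ValueError("peak IF diverges for gamma <= 2 (weak structure)")
    return float(_zeta(gamma - 1.0) / _zeta(gamma))


def midpoint_convexity(gamma: float, n_terms: int) -> float:
    """Second derivative (sign-adjusted) of the power-law sum at ``t = pi``.

    For even ``N``, ``sum_n cos(n t) / n^gamma`` has an extremum at ``t=pi``
    which is its only secondary candidate; it is convex — no secondary
    extrema, the strong-structure signature — iff

        sum_{n=1}^{N} (-1)^(n-1) / n^(gamma-2)  >  0,

    which flips sign at ``gamma = 2``.  Odd ``N`` is rejected (an odd
    number of secondary extrema makes the midpoint argument inapplicable).
    """
    if n_terms < 2 or n_terms % 2:
        raise ValueError("n_terms must be even and >= 2")
    n = np.arange(1, n_terms + 1)
    return float(np.sum((-1.0) ** (n - 1) / n ** (gamma - 2.0)))


def strong_weak_phase_boundary(phi: float | np.ndarray) -> float | np.ndarray:
    """Approximate strong/weak boundary amplitude for a base + one harmonic.

    For the 1:2 pair ``sin t + a sin(2t + phi)``, amplitude ratios below
    ``(1/4) (1 + |cos phi|^(2/3))`` leave the summed waveform with a
    single maximum and minimum per cycle (strong); above it a secondary
    extremum appears (weak).  At ``phi = 0`` and ``phi = pi/2`` the
    expression (0.5 and 0.25) coincides with the exact transition found
    by factorising the derivative.  The ``2/3`` power is taken of
    ``|cos phi|`` so the expression is real and even in ``phi``.
    """
    return 0.25 * (1.0 + np.abs(np.cos(phi)) ** (2.0 / 3.0))


_CANONICAL = ("triangle", "sawtooth", "square", "quadratic")


def canonical_structure(kind: str, n_terms: int, base_f: float = 1.0) -> SinusoidSum:
    """Partial Fourier series of a canonical harmonic waveform.

    ``triangle``  : (8/pi^2) sum 1/(2n+1)^2 cos((2n+1) x)      (gamma = 2)
    ``sawtooth``  : (2/pi)   sum 1/n       sin(n x)            (gamma = 1)
    ``square``    : (4/pi)   sum 1/(2n+1)  sin((2n+1) x)       (gamma = 1)
    ``quadratic`` :          sum 1/n^2     sin(n x)            (gamma = 2, strong)

    ``n_terms`` counts the retained sinusoids.  Sine terms are encoded as
    cosines with phase ``-pi/2``.
    """
    if n_terms < 1:
        raise ValueError("n_terms must be >= 1")
    if kind == "triangle":
        m = 2 * np.arange(n_terms) + 1
        return SinusoidSum(8.0 / np.pi**2 / m**2, m * base_f, np.zeros(n_terms))
    if kind == "sawtooth":
        m = np.arange(1, n_terms + 1)
        return SinusoidSum(2.0 / np.pi / m, m * base_f, np.full(n_terms, -np.pi / 2))
    if kind == "square":
        m = 2 * np.arange(n_terms) + 1
        return SinusoidSum(4.0 / np.pi / m, m * base_f, np.full(n_terms, -np.pi / 2))
    if kind == "quadratic":
        m = np.arange(1, n_terms + 1)
        return SinusoidSum(1.0 / m**2, m * base_f, np.full(n_terms, -np.pi / 2))
    raise ValueError(f"unknown canonical kind {kind!r}; choose from {_CANONICAL}")


def power_law_model(
    gamma: float,
    n_terms: int,
    base_f: float = 1.0,
    phases: np.ndarray | None = None,
) -> SinusoidSum:
    """Power-law structure ``a_n = 1/n^gamma`` at frequencies ``n base_f``."""
    if n_terms < 1:
        raise ValueError("n_terms must be >= 1")
    n = np.arange(1, n_terms + 1)
    phi = np.zeros(n_terms) if phases is None else np.asarray(phases, dtype=float)
    if phi.size != n_terms:
        raise ValueError("phases must have n_terms entries")
    return SinusoidSum(1.0 / n**gamma, n * base_f, phi)
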