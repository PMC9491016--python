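"""Segment-wise statistical assessment of harmonic structure.

Given an IMF-style decomposition, the procedure selects a base component
(the one whose mean instantaneous frequency sits closest to the spectral
peak in a chosen band), then tests every faster component against it:

Condition 1 — integer frequency ratio *and* constant phase relationship:
  (i) a one-sample t-test of per-segment IF ratios against the nearest
  integer must *fail to reject* (the ratio is statistically consistent
  with an integer), and (ii) the whole-recording instantaneous phases must
  show a significant distance correlation (a dependence measure that is
  zero iff the phases are independent).

Condition 2 — non-negative joint IF, tested through the two-tone
  criterion: the per-segment product of amplitude and frequency ratios
  must be significantly below (or at) 1, Bonferroni-corrected across the
  candidate pairs.

Pairs passing both are harmonics; ``a w^2 <= 1`` (no secondary extrema
expected) grades them strong rather than weak, with a multi-harmonic
drop-off exponent ``gamma > 2`` taking precedence when available.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np
from scipy import stats

from .analytic import AnalyticTrack, UniformSeries
from .sift import ComponentSet, analytic_tracks
from .spectral import find_base, power_spectrum
from .theory import PowerLawFit

__all__ = [
    "Verdict",
    "SegmentStats",
    "ConditionReport",
    "segment_series",
    "test_integer_ratio",
    "distance_correlation",
    "phase_dependence",
    "test_aw",
    "classify",
    "assess_pairs",
    "merge_components",
]


class Verdict(str, Enum):
    NON_HARMONIC = "non_harmonic"
    WEAK_HARMONIC = "weak_harmonic"
    STRONG_HARMONIC = "strong_harmonic"

    @property
    def rank(self) -> int:
        return ("non_harmonic", "weak_harmonic", "strong_harmonic").index(self.value)


@dataclass(frozen=True)
class SegmentStats:
    """Per-segment mean IF (Hz) and mean IA for each component.

    Rows are components, columns segments.
    """

    mean_if: np.ndarray
    mean_ia: np.ndarray
    segment_s: float

    def __post_init__(self) -> None:
        if self.mean_if.shape != self.mean_ia.shape:
            raise ValueError("mean_if and mean_ia must have the same shape")
        if self.mean_if.shape[1] < 2:
            raise ValueError("need at least 2 segments for standard errors")

    @property
    def n_segments(self) -> int:
        return self.mean_if.shape[1]


@dataclass(frozen=True)
class ConditionReport:
    """Full harmonic test report for one (fast component, base) pair."""

    pair: tuple[int, int]  # (hf index, base index)
    freq_ratio_mean: float
    freq_ratio_sd: float
    nearest_integer: int
    integer_p: float
    integer_pass: bool
    dcor: float
    dcor_p: float
    dcor_pass: bool
    amp_ratio_mean: float
    amp_ratio_sd: float
    aw_mean: float
    aw_p: float
    aw_pass: bool
    aw2_mean: float
    verdict: Verdict
    notes: str = ""

    def __post_init__(self) -> None:
        if self.verdict is not Verdict.NON_HARMONIC:
            if not (self.integer_pass and self.dcor_pass and self.aw_pass):
                raise ValueError("harmonic verdicts require all conditions to pass")


def segment_series(x: UniformSeries, n_segments: int) -> list[UniformSeries]:
    """Split into contiguous equal-length segments; the remainder is dropped."""
    if n_segments < 1:
        raise ValueError("n_segments must be >= 1")
    seg_len = len(x) // n_segments
    if seg_len < 2:
        raise ValueError("segments would be shorter than 2 samples")
    return [
        UniformSeries(
            x.values[i * seg_len : (i + 1) * seg_len], x.fs, x.t0 + i * seg_len / x.fs
        )
        for i in range(n_segments)
    ]


def test_integer_ratio(
    ratios: np.ndarray,
    alpha: float = 0.05,
    mode: str = "nhst",
    tost_margin: float = 0.05,
) -> tuple[int, float, bool]:
    """Test per-segment frequency ratios against the nearest integer.

    Returns ``(nearest, p, passed)``.

    ``mode="nhst"`` (default): one-sample t-test with the integer as the
    null; the test passes when it *fails to reject* (``p > alpha``).
    This mirrors common practice but is logically inverted — it shows
    consistency with an integer, not proof of it, and even a perfectly
    integer ratio is rejected in a fraction ``alpha`` of samples.

    ``mode="tost"``: two one-sided equivalence tests; passes when the
    ratio is shown to lie within ``tost_margin`` of the integer
    (``p < alpha`` on both sides).  Stricter and statistically the
    better-behaved formulation; the reported p is the larger of the two
    one-sided p-values.

    A zero-variance sample degenerates to exact comparison either way.
    """
    ratios = np.asarray(ratios, dtype=float)
    if ratios.size < 2:
        raise ValueError("need at least 2 segments")
    nearest = int(round(float(ratios.mean())))
    if np.ptp(ratios) == 0.0:
        exact = bool(abs(ratios[0] - nearest) <= (tost_margin if mode == "tost" else 0))
        return nearest, 1.0 if exact else 0.0, exact and nearest >= 1
    if mode == "nhst":
        p = float(stats.ttest_1samp(ratios, nearest).pvalue)
        passed = p > alpha
    elif mode == "tost":
        p_low = float(
            stats.ttest_1samp(ratios, nearest - tost_margin, alternative="greater").pvalue
        )
        p_high = float(
            stats.ttest_1samp(ratios, nearest + tost_margin, alternative="less").pvalue
        )
        p = max(p_low, p_high)
        passed = p < alpha
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return nearest, p, bool(passed and nearest >= 1)


def distance_correlation(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Sample distance correlation and its t-test p-value.

    The distance correlation of Székely, Rizzo & Bakirov (2007) is zero
    iff ``x`` and ``y`` are independent, capturing arbitrary (not just
    linear or monotonic) dependence.  The returned statistic is the usual
    V-statistic estimate; significance comes from the bias-corrected
    t-test of Székely & Rizzo (2013): with ``M = n(n-3)/2`` degrees-like
    quantity, ``T = sqrt(M-1) R* / sqrt(1-R*^2)`` is ~ t(M-1) under
    independence.  Cost is O(n^2) memory and time.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n != y.size or n < 10:
        raise ValueError("need equal-length inputs with at least 10 samples")
    if np.ptp(x) == 0.0 or np.ptp(y) == 0.0:
        import warnings

        warnings.warn("distance correlation undefined for constant input; returning 0")
        return 0.0, 1.0
    a = np.abs(x[:, None] - x[None, :])
    b = np.abs(y[:, None] - y[None, :])

    A = a - a.mean(axis=0) - a.mean(axis=1)[:, None] + a.mean()
    B = b - b.mean(axis=0) - b.mean(axis=1)[:, None] + b.mean()
    dcov2 = (A * B).mean()
    dvar_x = (A * A).mean()
    dvar_y = (B * B).mean()
    denom = np.sqrt(dvar_x * dvar_y)
    r = float(np.sqrt(max(dcov2, 0.0) / denom)) if denom > 0 else 0.0

    def u_centre(d: np.ndarray) -> np.ndarray:
        total = d.sum()
        u = d - d.sum(axis=0) / (n - 2) - d.sum(axis=1)[:, None] / (n - 2)
        u += total / ((n - 1) * (n - 2))
        np.fill_diagonal(u, 0.0)
        return u

    def u_product(p: np.ndarray, q: np.ndarray) -> float:
        return float((p * q).sum() / (n * (n - 3)))

    au, bu = u_centre(a), u_centre(b)
    denom_u = np.sqrt(u_product(au, au) * u_product(bu, bu))
    r_star = u_product(au, bu) / denom_u if denom_u > 0 else 0.0
    r_star = float(np.clip(r_star, -1.0, 1.0))
    m = n * (n - 3) / 2.0
    t_stat = np.sqrt(m - 1.0) * r_star / np.sqrt(max(1.0 - r_star**2, 1e-300))
    p = float(stats.t.sf(t_stat, m - 1.0))
    return r, p


def phase_dependence(
    phase_base: np.ndarray,
    phase_hf: np.ndarray,
    max_points: int = 2000,
) -> tuple[float, float]:
    """Distance correlation between two wrapped instantaneous phase vectors.

    Phases are wrapped to (-pi, pi] before the O(n^2) distance
    correlation; inputs longer than ``max_points`` are subsampled with a
    uniform stride to keep the cost bounded.  Returns ``(dcor, p)``.
    """
    pb = np.asarray(phase_base, dtype=float)
    ph = np.asarray(phase_hf, dtype=float)
    if pb.size != ph.size or pb.size < 100:
        raise ValueError("need equal-length phase vectors with >= 100 samples")
    stride = max(1, int(np.ceil(pb.size / max_points)))
    pb = np.angle(np.exp(1j * pb[::stride]))
    ph = np.angle(np.exp(1j * ph[::stride]))
    return distance_correlation(pb, ph)


def test_aw(
    a_ratios: np.ndarray,
    w_ratios: np.ndarray,
    n_pairs_for_correction: int = 1,
    alpha: float = 0.05,
) -> tuple[float, float, bool, float, bool]:
    """Test the two-tone non-negative-IF criterion ``a w <= 1``.

    One-sided one-sample t-test of the per-segment products ``a w``
    against 1 (alternative: mean below 1), Bonferroni-corrected by the
    number of candidate pairs.  Exact boundary samples (all products
    equal to 1) count as a pass, since ``a w = 1`` satisfies the
    criterion.  Also reports the mean of ``a w^2`` and the derived
    strong/weak flag (no secondary extrema expected iff ``a w^2 <= 1``).

    Returns ``(aw_mean, p, passed, aw2_mean, strong)``.
    """
    a_ratios = np.asarray(a_ratios, dtype=float)
    w_ratios = np.asarray(w_ratios, dtype=float)
    if a_ratios.size != w_ratios.size or a_ratios.size < 2:
        raise ValueError("need matching per-segment ratios, at least 2 segments")
    aw = a_ratios * w_ratios
    aw_mean = float(aw.mean())
    if np.ptp(aw) == 0.0:
        p = 0.0 if aw_mean < 1.0 else (1.0 if aw_mean > 1.0 else alpha / 2)
        passed = aw_mean <= 1.0
    else:
        p = float(stats.ttest_1samp(aw, 1.0, alternative="less").pvalue)
        passed = bool(p < alpha / max(n_pairs_for_correction, 1))
    aw2_mean = float((a_ratios * w_ratios**2).mean())
    return aw_mean, p, passed, aw2_mean, aw2_mean <= 1.0


def classify(
    cond1_pass: bool,
    cond2_pass: bool,
    strong_flag: bool | None = None,
    gamma: PowerLawFit | float | None = None,
) -> Verdict:
    """Harmonic decision tree.

    Not a harmonic unless both conditions pass; then strong if the
    amplitude drop-off exponent exceeds 2 (when a multi-harmonic fit is
    available, it aggregates all harmonics and takes precedence) or the
    pairwise ``a w^2 <= 1`` flag holds; weak otherwise.
    """
    if not (cond1_pass and cond2_pass):
        return Verdict.NON_HARMONIC
    if gamma is not None:
        g = gamma.gamma if isinstance(gamma, PowerLawFit) else float(gamma)
        return Verdict.STRONG_HARMONIC if g > 2.0 else Verdict.WEAK_HARMONIC
    if strong_flag:
        return Verdict.STRONG_HARMONIC
    return Verdict.WEAK_HARMONIC


def _segment_track_means(
    tracks: list[AnalyticTrack],
    n_segments: int,
    ia_percentile: float = 50.0,
    min_coverage: float = 0.1,
) -> SegmentStats:
    """Segment means of IF and IA, restricted to quality-controlled cycles.

    Noisy cycles (non-monotonic phase or mean amplitude below the
    ``ia_percentile``-th whole-track percentile) are excluded before
    averaging — they carry the IF of the background, not of the
    component, and would bias the frequency-ratio statistics.  Segments
    where fewer than ``min_coverage`` of the samples lie in good cycles
    do not contain the component in any usable sense (e.g. the
    oscillation was off-burst for the whole segment) and come back NaN;
    the pair tests drop them.
    """
    from .sift import detect_cycles

    n = len(tracks[0])
    seg_len = n // n_segments
    mif = np.full((len(tracks), n_segments), np.nan)
    mia = np.full((len(tracks), n_segments), np.nan)
    for i, tr in enumerate(tracks):
        cycles = detect_cycles(tr, ia_percentile=ia_percentile)
        keep = np.zeros(n, dtype=bool)
        for (lo, hi), good in zip(cycles.bounds, cycles.good):
            if good:
                keep[lo:hi] = True
        for s in range(n_segments):
            sl = slice(s * seg_len, (s + 1) * seg_len)
            sel = keep[sl]
            if sel.mean() < min_coverage:
                continue
            mif[i, s] = np.nanmean(tr.if_hz[sl][sel])
            mia[i, s] = np.nanmean(tr.ia[sl][sel])
    return SegmentStats(mif, mia, seg_len / tracks[0].fs)


def assess_pairs(
    components: ComponentSet,
    base_band: tuple[float, float] = (4.0, 8.0),
    n_segments: int = 20,
    alpha: float = 0.05,
    phase_smooth_window: int = 5,
    welch_seg_s: float = 8.0,
    dcor_max_points: int = 2000,
    cycle_ia_percentile: float = 50.0,
    integer_mode: str = "nhst",
) -> list[ConditionReport]:
    """Run the full harmonic assessment on a component decomposition.

    The base is the component whose average IF lies closest to the
    spectral peak of the reconstructed signal inside ``base_band``
    (Welch's method, ``welch_seg_s`` segments).  Every component faster
    than the base is tested; the returned reports carry all intermediate
    statistics and the final verdict per pair.  Pairs with a weak or
    strong verdict are the merge candidates for waveform-shape
    reconstruction.
    """
    if components.n_components < 2:
        return []
    tracks = analytic_tracks(components, phase_smooth_window)
    seg = _segment_track_means(tracks, n_segments, ia_percentile=cycle_ia_percentile)

    recon = UniformSeries(components.reconstruct(), components.fs)
    spec = power_spectrum(recon, "welch", seg_len=min(welch_seg_s, recon.duration / 2))
    peak = find_base(spec, base_band)
    with np.errstate(invalid="ignore"):
        overall_if = np.nanmean(seg.mean_if, axis=1)
    overall_if = np.where(np.isfinite(overall_if), overall_if, -np.inf)
    base = int(np.argmin(np.abs(overall_if - peak)))

    candidates = [
        i
        for i in range(components.n_components)
        if i != base and overall_if[i] > overall_if[base]
    ]
    reports: list[ConditionReport] = []
    for i in candidates:
        usable = np.isfinite(seg.mean_if[i]) & np.isfinite(seg.mean_if[base])
        if usable.sum() < 2:
            continue
        ratios = seg.mean_if[i][usable] / seg.mean_if[base][usable]
        nearest, p_int, int_pass = test_integer_ratio(ratios, alpha, mode=integer_mode)
        dcor, p_d = phase_dependence(
            tracks[base].phase, tracks[i].phase, max_points=dcor_max_points
        )
        d_pass = bool(p_d < alpha)
        a_ratios = seg.mean_ia[i][usable] / seg.mean_ia[base][usable]
        aw_mean, p_aw, aw_pass, aw2_mean, strong = test_aw(
            a_ratios, ratios, n_pairs_for_correction=len(candidates), alpha=alpha
        )
        cond1 = int_pass and d_pass
        verdict = classify(cond1, aw_pass, strong_flag=strong)
        reports.append(
            ConditionReport(
                pair=(i, base),
                freq_ratio_mean=float(ratios.mean()),
                freq_ratio_sd=float(ratios.std(ddof=1)),
                nearest_integer=nearest,
                integer_p=p_int,
                integer_pass=int_pass,
                dcor=dcor,
                dcor_p=p_d,
                dcor_pass=d_pass,
                amp_ratio_mean=float(a_ratios.mean()),
                amp_ratio_sd=float(a_ratios.std(ddof=1)),
                aw_mean=aw_mean,
                aw_p=p_aw,
                aw_pass=aw_pass,
                aw2_mean=aw2_mean,
                verdict=verdict,
                notes=f"base spectral peak {peak:.3g} Hz; "
                f"Bonferroni over {len(candidates)} pairs; "
                f"dcor subsampled to <= {dcor_max_points} points",
            )
        )
    return reports


def merge_components(components: ComponentSet, indices) -> UniformSeries:
    """Pointwise sum of selected components.

    Valid shape reconstruction for harmonically related components: the
    Hilbert transform is linear, so the merged series has a well-defined
    joint analytic track.
    """
    indices = list(indices)
    if not indices:
        raise ValueError("no indices to merge")
    return UniformSeries(components.components[:, indices].sum(axis=1), components.fs)
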