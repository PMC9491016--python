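"""Segment statistics, condition tests and the harmonic decision tree."""

import itertools

import numpy as np
import pytest
from scipy import stats

import waveshape as ws


class TestSegmentSeries:
    def test_even_split(self):
        x = ws.UniformSeries(np.arange(1000.0), 1.0)
        segs = ws.segment_series(x, 20)
        assert len(segs) == 20
        assert all(len(s) == 50 for s in segs)

    def test_remainder_dropped(self):
        x = ws.UniformSeries(np.arange(103.0), 1.0)
        segs = ws.segment_series(x, 10)
        assert len(segs) == 10
        assert all(len(s) == 10 for s in segs)

    def test_single_segment_truncates(self):
        x = ws.UniformSeries(np.arange(11.0), 1.0)
        (seg,) = ws.segment_series(x, 1)
        assert np.array_equal(seg.values, x.values)

    def test_oversplit_rejected(self):
        with pytest.raises(ValueError):
            ws.segment_series(ws.UniformSeries(np.arange(10.0), 1.0), 10)


class TestIntegerRatio:
    def test_exact_integer_passes(self):
        nearest, p, ok = ws.test_integer_ratio(np.full(20, 2.0))
        assert (nearest, p, ok) == (2, 1.0, True)

    def test_noisy_but_consistent_ratio_passes(self):
        rng = np.random.default_rng(0)
        ratios = 2.0 + 0.1 * rng.standard_normal(20)
        nearest, p, ok = ws.test_integer_ratio(ratios)
        assert nearest == 2 and ok

    def test_clearly_non_integer_fails(self):
        rng = np.random.default_rng(1)
        ratios = 4.2 + 0.2 * rng.standard_normal(20)
        nearest, p, ok = ws.test_integer_ratio(ratios)
        assert nearest == 4 and not ok

    def test_needs_two_segments(self):
        with pytest.raises(ValueError):
            ws.test_integer_ratio(np.array([2.0]))


class TestDistanceCorrelation:
    def test_identical_inputs_give_one(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal(300)
        r, p = ws.distance_correlation(x, x)
        assert r == pytest.approx(1.0, abs=1e-9)
        assert p < 1e-10

    def test_independent_inputs_near_zero(self):
        rng = np.random.default_rng(3)
        r, p = ws.distance_correlation(
            rng.uniform(-np.pi, np.pi, 2000), rng.uniform(-np.pi, np.pi, 2000)
        )
        assert r < 0.1
        assert p > 0.05

    def test_nonlinear_dependence_detected(self):
        # a folded (non-monotonic) deterministic map: near-zero linear
        # correlation, but fully dependent — dcor must flag it
        rng = np.random.default_rng(4)
        x = rng.uniform(-np.pi, np.pi, 1500)
        y = np.cos(x)
        assert abs(np.corrcoef(x, y)[0, 1]) < 0.05
        r, p = ws.distance_correlation(x, y)
        assert r > 0.1
        assert p < 1e-6

    def test_t_test_matches_permutation_oracle(self):
        # moderate dependence: compare the t-approximation against an
        # independent permutation null on the same statistic
        rng = np.random.default_rng(5)
        n = 300
        x = rng.uniform(-np.pi, np.pi, n)
        y = np.angle(np.exp(1j * (2 * x))) + 2.5 * rng.standard_normal(n)
        r, p = ws.distance_correlation(x, y)
        null = np.array(
            [
                ws.distance_correlation(x, rng.permutation(y))[0]
                for _ in range(200)
            ]
        )
        p_perm = (1 + np.sum(null >= r)) / 201
        assert (p < 0.05) == (p_perm < 0.05)

    def test_constant_input_warns_and_returns_zero(self):
        with pytest.warns(UserWarning):
            r, p = ws.distance_correlation(np.zeros(100), np.arange(100.0))
        assert r == 0.0

    def test_phase_dependence_wraps_and_strides(self):
        phase = np.linspace(0, 400 * np.pi, 50_000)
        r, p = ws.phase_dependence(phase, 2 * phase, max_points=500)
        assert r > 0.1
        assert p < 1e-6


class TestAwCriterion:
    def test_harmonic_pair_passes(self):
        rng = np.random.default_rng(6)
        a = 0.27 + 0.04 * rng.standard_normal(20)
        w = 2.0 + 0.1 * rng.standard_normal(20)
        aw, p, ok, aw2, strong = ws.test_aw(a, w)
        assert aw == pytest.approx(0.54, abs=0.05)
        assert ok
        assert aw2 > 1 and not strong  # 0.27 * 4 = 1.08: weak structure

    def test_fast_component_fails(self):
        rng = np.random.default_rng(7)
        a = 0.27 + 0.04 * rng.standard_normal(20)
        w = 10.9 + 0.3 * rng.standard_normal(20)
        aw, p, ok, aw2, strong = ws.test_aw(a, w)
        assert aw > 2.5 and not ok

    def test_exact_boundary_passes(self):
        aw, p, ok, aw2, strong = ws.test_aw(np.full(10, 0.5), np.full(10, 2.0))
        assert aw == 1.0 and ok
        assert not strong  # aw^2 = 2 > 1

    def test_strong_flag_from_aw2(self):
        *_, strong = ws.test_aw(np.full(10, 0.2), np.full(10, 2.0))
        assert strong  # aw2 = 0.8 <= 1

    def test_bonferroni_correction_tightens(self):
        rng = np.random.default_rng(8)
        a = 0.46 + 0.05 * rng.standard_normal(20)
        w = np.full(20, 2.0)
        _, _, ok1, _, _ = ws.test_aw(a, w, n_pairs_for_correction=1)
        _, _, ok50, _, _ = ws.test_aw(a, w, n_pairs_for_correction=50)
        assert ok1 and not ok50

    def test_null_calibration_respects_alpha(self):
        # true aw = 1 with noisy estimates: pass rate must stay below the
        # nominal level after Bonferroni correction over 3 pairs
        rng = np.random.default_rng(9)
        n_pairs, alpha, hits = 3, 0.05, 0
        runs = 1000
        for _ in range(runs):
            a = 0.5 + 0.05 * rng.standard_normal(20)
            w = 2.0 + 0.1 * rng.standard_normal(20)
            hits += ws.test_aw(a, w, n_pairs_for_correction=n_pairs, alpha=alpha)[2]
        assert hits / runs <= alpha  # binomial slack is well inside alpha


class TestClassify:
    def test_condition_failures_are_non_harmonic(self):
        assert ws.classify(False, True) is ws.Verdict.NON_HARMONIC
        assert ws.classify(True, False) is ws.Verdict.NON_HARMONIC

    def test_gamma_splits_strong_and_weak(self):
        assert ws.classify(True, True, gamma=2.08) is ws.Verdict.STRONG_HARMONIC
        assert ws.classify(True, True, gamma=1.5) is ws.Verdict.WEAK_HARMONIC

    def test_gamma_takes_precedence_over_pair_flag(self):
        assert (
            ws.classify(True, True, strong_flag=True, gamma=1.5)
            is ws.Verdict.WEAK_HARMONIC
        )

    def test_monotone_in_condition_flags(self):
        # upgrading any input never downgrades the verdict ordering
        order = [False, True]
        for c1, c2, s in itertools.product(order, order, order):
            base = ws.classify(c1, c2, strong_flag=s)
            for c1b, c2b, sb in itertools.product(order, order, order):
                if (c1b, c2b, sb) >= (c1, c2, s):
                    assert ws.classify(c1b, c2b, strong_flag=sb).rank >= base.rank


def make_component_set(columns, fs):
    mat = np.column_stack(columns)
    return ws.ComponentSet(mat, np.zeros(mat.shape[0]), fs)


def band_noise(n, fs, lo, hi, rng):
    spec = np.fft.rfft(rng.standard_normal(n))
    freqs = np.fft.rfftfreq(n, 1 / fs)
    spec[(freqs < lo) | (freqs > hi)] = 0
    out = np.fft.irfft(spec, n)
    return out / np.std(out)


def construction_components(kind: str, seed: int, snr_db: float = 20.0):
    """Known-structure component sets: the decomposition is given, so the
    assessment statistics are tested in isolation from the sift.  Each
    component carries octave-band noise around its own frequency, the way
    a band-limited decomposition distributes a broadband background."""
    fs, dur, base = 250.0, 120.0, 10.0
    n = int(dur * fs)
    t = np.arange(n) / fs
    rng = np.random.default_rng(seed)
    if kind == "strong":
        model = ws.power_law_model(2.25, 4, base_f=base)
    elif kind == "weak":
        model = ws.power_law_model(1.25, 4, base_f=base)
    else:  # non-harmonic two-tone
        model = ws.SinusoidSum([1.0, 0.75], [base, 2 * base], [0.0, 0.0])
    cols = []
    for a, f, phi in zip(model.a, model.f_hz, model.phi):
        clean = a * np.cos(2 * np.pi * f * t + phi)
        noise_sd = a / np.sqrt(2) / 10 ** (snr_db / 20.0)
        cols.append(clean + noise_sd * band_noise(n, fs, 0.65 * f, 1.5 * f, rng))
    return make_component_set(cols, fs)


class TestAssessPairs:
    def test_single_component_yields_empty_report(self):
        fs = 100.0
        x = np.cos(2 * np.pi * 5 * np.arange(1000) / fs)
        comps = ws.ComponentSet(x[:, None], np.zeros_like(x), fs)
        assert ws.assess_pairs(comps) == []

    @pytest.mark.parametrize("kind,expected", [
        ("strong", ws.Verdict.STRONG_HARMONIC),
        ("weak", ws.Verdict.WEAK_HARMONIC),
        ("non", ws.Verdict.NON_HARMONIC),
    ])
    def test_decision_tree_on_known_constructions(self, kind, expected):
        hits = 0
        n_runs = 20
        for seed in range(n_runs):
            comps = construction_components(kind, seed)
            reports = ws.assess_pairs(
                comps, base_band=(8.0, 12.0), n_segments=20, integer_mode="tost"
            )
            r2 = next(r for r in reports if r.pair[0] == 1)  # the 2:1 pair
            hits += r2.verdict is expected
        assert hits >= 0.95 * n_runs

    def test_slow_am_leaves_verdicts_unchanged(self):
        # Bedrosian robustness: multiply every component by a shared slow
        # envelope and re-assess
        fs, dur, base = 250.0, 120.0, 10.0
        t = np.arange(int(dur * fs)) / fs
        env = 1.0 - 0.4 + 0.4 * (1.0 + np.cos(2 * np.pi * (base / 5) * t)) / 2.0
        for kind in ("strong", "weak", "non"):
            plain = construction_components(kind, seed=1)
            modulated = ws.ComponentSet(
                plain.components * env[:, None], plain.residual, fs
            )
            v_plain = [
                r.verdict
                for r in ws.assess_pairs(plain, base_band=(8, 12), n_segments=20, integer_mode="tost")
            ]
            v_mod = [
                r.verdict
                for r in ws.assess_pairs(modulated, base_band=(8, 12), n_segments=20, integer_mode="tost")
            ]
            assert v_plain == v_mod

    def test_report_invariant_verdict_requires_passes(self):
        with pytest.raises(ValueError):
            ws.ConditionReport(
                pair=(1, 0),
                freq_ratio_mean=2.0,
                freq_ratio_sd=0.1,
                nearest_integer=2,
                integer_p=0.5,
                integer_pass=True,
                dcor=0.3,
                dcor_p=1e-6,
                dcor_pass=False,
                amp_ratio_mean=0.3,
                amp_ratio_sd=0.05,
                aw_mean=0.6,
                aw_p=1e-4,
                aw_pass=True,
                aw2_mean=1.2,
                verdict=ws.Verdict.WEAK_HARMONIC,
            )


class TestMergeComponents:
    def test_single_index_is_identity(self):
        comps = construction_components("strong", 0)
        merged = ws.merge_components(comps, [0])
        assert np.array_equal(merged.values, comps.components[:, 0])

    def test_amplitude_subadditive(self):
        comps = construction_components("strong", 0)
        merged = ws.merge_components(comps, [0, 1])
        ia_merged = ws.analytic_track(merged).ia
        ia_sum = (
            ws.analytic_track(comps.component(0)).ia
            + ws.analytic_track(comps.component(1)).ia
        )
        assert np.all(ia_merged <= ia_sum + 1e-9)

    def test_empty_selection_rejected(self):
        with pytest.raises(ValueError):
            ws.merge_components(construction_components("strong", 0), [])
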