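"""Full pipeline on a synthetic hippocampal LFP: sift, test, merge.

Generates a 1000 s theta-like recording (7.5 Hz base, phase-locked 15 Hz
harmonic at 0.27 relative amplitude, bursts, frequency wander, broadband
noise), decomposes it with the masked EMD sift, and runs the segment-wise
harmonic assessment.  The harmonic conditions should single out the 2:1
component; merging it with the base reconstructs the non-sinusoidal
theta waveform shape.

Takes half a minute or so.
"""

import numpy as np

import waveshape as ws

x = ws.synthetic_lfp(noise=ws.NoiseSpec(white_sd=1.2, pink_sd=0.15, seed=1))
print(f"signal: {x.duration:.0f} s at {x.fs:.0f} Hz")
comps = ws.mask_sift(x)
reports = ws.assess_pairs(comps, integer_mode="tost")

print(f"{'pair':>6} {'omega':>12} {'a':>6} {'dcor':>6} {'aw':>6}  verdict")
for r in reports:
    print(
        f"{r.pair[0]}->{r.pair[1]:>2} {r.freq_ratio_mean:6.2f} ({r.freq_ratio_sd:4.2f})"
        f" {r.amp_ratio_mean:6.2f} {r.dcor:6.3f} {r.aw_mean:6.2f}  {r.verdict.value}"
    )

harmonic = [r for r in reports if r.verdict != ws.Verdict.NON_HARMONIC]
if harmonic:
    pair = harmonic[0].pair
    merged = ws.merge_components(comps, list(pair))
    for label, series in (
        ("base IMF", comps.component(pair[1])),
        ("merged base+harmonic", merged),
    ):
        track = ws.analytic_track(series, 5)
        cycles = ws.detect_cycles(track)
        _, mean, _ = ws.phase_align(track, cycles)
        print(
            f"{label}: phase-aligned IF {mean.mean():.2f} Hz, "
            f"within-cycle swing {np.ptp(mean):.2f} Hz "
            f"({cycles.n_good}/{len(cycles)} cycles kept)"
        )
    print()
    print("The merged component's IF varies strongly within the cycle —")
    print("the asymmetric non-sinusoidal theta shape — while the base IMF")
    print("alone is nearly sinusoidal (flat IF profile).")
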