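"""Strong vs weak harmonic structures: the gamma = 2 boundary.

For power-law amplitude decay a_n = 1/n^gamma, structures with gamma > 2
gain no secondary extrema no matter how many harmonics are added (their
peak IF converges to zeta(gamma-1)/zeta(gamma)); gamma <= 2 structures
develop small secondary extrema and a divergent peak IF.
"""

import numpy as np

import waveshape as ws

print("critical exponent, three harmonics:", f"{ws.critical_exponent_three():.4f}")
print()

t = np.linspace(0, 4, 400_000, endpoint=False)
for gamma in (1.25, 2.25):
    model = ws.power_law_model(gamma, 4)
    x = ws.UniformSeries(model.evaluate(t), float(len(t)))
    n_max, n_min = ws.count_extrema(x, min_prominence=1e-9)
    convex = ws.midpoint_convexity(gamma, 4)
    kind = "strong" if convex > 0 else "weak"
    print(
        f"gamma={gamma}: midpoint second derivative {convex:+.3f} -> {kind}; "
        f"{(n_max + n_min) / 4:.1f} extrema per period (4 harmonics)"
    )

print()
for gamma in (2.5, 3.0, 4.0):
    print(f"limiting peak IF at gamma={gamma}: {ws.zeta_peak_if(gamma):.4f} x base")
print()
print(
    "The gamma=1.25 sum already shows a secondary extremum at mid-cycle;\n"
    "the gamma=2.25 sum stays a single smooth non-sinusoidal cycle, and\n"
    "its peak IF would remain finite even with infinitely many harmonics."
)
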