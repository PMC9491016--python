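"""Harmonic drop-off in two physical models: a spiking neuron and a water wave.

Simulates the FitzHugh–Nagumo neuron (continuous 25 Hz spiking) and the
Abreu shallow-water wave (asymmetric 1 Hz wave), detects harmonic peaks
in their spectra and fits the amplitude drop-off exponent gamma.  Both
waveforms come out strongly harmonic (gamma > 2): sharp but smooth
shapes, no secondary extrema.
"""

import waveshape as ws

print("FitzHugh–Nagumo neuron (10 s @ 100 kHz) ...")
fhn = ws.simulate_fhn()
spec = ws.power_spectrum(fhn)
f0 = ws.find_base(spec, (10, 40))
fit = ws.fit_dropoff(ws.harmonic_peaks(spec, f0, n_max=27))
lo, hi = ws.if_range(ws.analytic_track(fhn), edge_fraction=0.01)
print(f"  fundamental {f0:.1f} Hz; a_n ~ k/n^{fit.gamma:.3f} "
      f"(r={fit.pearson_r:.3f}); IF sweeps {lo:.1f}-{hi:.1f} Hz")

print("Abreu shallow-water wave (100 s @ 10 kHz, r=0.75, phi=-pi/4) ...")
ab = ws.simulate_abreu()
spec = ws.power_spectrum(ab)
f0 = ws.find_base(spec, (0.5, 2.0))
low, high = ws.fit_dropoff(ws.harmonic_peaks(spec, f0, n_max=17), knee=10.0)
lo, hi = ws.if_range(ws.analytic_track(ab), edge_fraction=0.01)
print(f"  fundamental {f0:.1f} Hz; below 10 Hz a_n ~ k/n^{low.gamma:.3f} "
      f"(r={low.pearson_r:.3f}); above, k/n^{high.gamma:.2f} (r={high.pearson_r:.3f})")
print(f"  IF sweeps {lo:.2f}-{hi:.2f} Hz")
print()
print("Both exponents exceed 2: strong harmonic structures, i.e. waveform")
print("shape without secondary extrema — IF stays positive throughout.")
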