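import numpy as np
import pytest

import waveshape as ws


@pytest.fixture(scope="session")
def fhn_paper_run() -> ws.UniformSeries:
    """The reference FitzHugh–Nagumo run: 10 s at 100 kHz, spiking at 25 Hz."""
    return ws.simulate_fhn(ws.FHNParams(), duration=10.0, fs=1e5)


@pytest.fixture(scope="session")
def abreu_paper_run() -> ws.UniformSeries:
    """The reference Abreu wave run: 100 s at 10 kHz, r=0.75, phi=-pi/4."""
    return ws.simulate_abreu(ws.AbreuParams(), duration=100.0, fs=1e4)


def tone(f_hz: float, fs: float, duration: float, phi: float = 0.0) -> ws.UniformSeries:
    t = np.arange(int(round(duration * fs))) / fs
    return ws.UniformSeries(np.cos(2 * np.pi * f_hz * t + phi), fs)
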