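"""Shared fixtures: canonical simulated waveforms.

All fixtures are generated programmatically and seeded so every run is
bit-identical.
"""

import numpy as np
import pytest

from respgate.signal import Signal
from respgate.synthetic import SimulationSpec, gen_sine


@pytest.fixture(scope="session")
def sine_spec() -> SimulationSpec:
    """Reference breathing benchmark: 10 mm amplitude, 5 s period, 100 Hz."""
    return SimulationSpec(pattern="sine", amplitude_mm=10.0, period_s=5.0,
                          duration_s=60.0, dt_s=0.01)


@pytest.fixture(scope="session")
def sine_signal(sine_spec) -> Signal:
    return gen_sine(sine_spec)


def make_jittered_sine(amplitudes, periods, dt=0.01) -> Signal:
    """Phase-continuous concatenation of sine cycles with per-cycle
    amplitude/period, used to construct irregular-breathing archetypes with
    known extrema."""
    chunks = []
    for a, T in zip(amplitudes, periods):
        n = int(round(T / dt))
        tau = dt * np.arange(n)
        chunks.append(a * np.sin(2.0 * np.pi * tau / T))
    return Signal(0.0, dt, np.concatenate(chunks))
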