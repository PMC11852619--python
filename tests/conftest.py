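import numpy as np
import pytest

from ibmkit import SimConfig, UniformSeries, emulate_device, simulate_breath_hold


def make_series(values, rate=100.0, t0=0.0):
    return UniformSeries(np.asarray(values, dtype=float), rate, t0)


def tone(freq, rate, duration, amp=1.0, phase=0.0, t0=0.0):
    t = np.arange(round(duration * rate)) / rate
    return UniformSeries(amp * np.sin(2 * np.pi * freq * t + phase), rate, t0)


@pytest.fixture(scope="session")
def default_sim():
    """One seeded default-condition simulation shared across tests."""
    config = SimConfig(seed=7)
    sternum, xiphoid, truth = simulate_breath_hold(config)
    return config, sternum, xiphoid, truth


@pytest.fixture(scope="session")
def default_log(default_sim):
    config, sternum, xiphoid, truth = default_sim
    log = emulate_device(sternum, xiphoid, heart_rate_bpm=125.0, spo2_pct=97.0)
    return config, log, truth
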