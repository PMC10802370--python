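import numpy as np
import pytest

from infantfc.probe import load_probe_fixture
from infantfc.simulate import RecordingScenario, simulate_recording


@pytest.fixture(scope="session")
def probe_smap():
    return load_probe_fixture("bright_infant")


@pytest.fixture(scope="session")
def clean_recording(probe_smap):
    """Default-scenario recording without motion events (120 s), plus truth."""
    probe, smap = probe_smap
    scen = RecordingScenario(duration_s=120.0, motion_events=(), seed=7)
    return simulate_recording(probe, smap, scen)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
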