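import sys
from pathlib import Path

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

sys.path.insert(0, str(Path(__file__).parent))  # tests/oracles.py

from gaitdtw import DEFAULT_SIGNAL_CHANNELS, GeneratorSpec, make_benchmark

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def channels6():
    """The six discriminative signal channels used for classification."""
    return list(DEFAULT_SIGNAL_CHANNELS[:6])


@pytest.fixture(scope="session")
def corpus9_noiseless():
    """9-subject noiseless benchmark with well-separated mode prototypes."""
    spec = GeneratorSpec(n_subjects=9, n_cycles=12, noise_snr_db=np.inf, seed=5)
    cycles, manifest = make_benchmark(spec)
    return cycles, manifest


@pytest.fixture(scope="session")
def corpus9_snr30():
    """Same benchmark conditions at 30 dB sensor SNR."""
    spec = GeneratorSpec(n_subjects=9, n_cycles=12, noise_snr_db=30.0, seed=5)
    cycles, manifest = make_benchmark(spec)
    return cycles, manifest
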