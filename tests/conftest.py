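import numpy as np
import pytest

from nirsinfo import Recording, SBFTrace, SimulationConfig, generate_study


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def make_recording():
    def _make(data, fs=10.0, rest_len=0, labels=None):
        return Recording(
            data=np.asarray(data, dtype=float),
            fs=fs,
            rest_len=rest_len,
            channel_labels=labels,
        )

    return _make


@pytest.fixture
def random_recording(rng, make_recording):
    data = rng.normal(5.0, 2.0, size=(400, 4))
    return make_recording(data, rest_len=100)


@pytest.fixture(scope="session")
def small_rounds():
    """A handful of default-moment simulation rounds shared across tests."""
    cfg = SimulationConfig(n_rounds=4)
    return generate_study(cfg, seed=2024)


@pytest.fixture
def paired_trace():
    def _make(values, fs=10.0):
        return SBFTrace(values=np.asarray(values, dtype=float), fs=fs)

    return _make
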