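import numpy as np
import pytest

import stimdecode as sd


@pytest.fixture(scope="session")
def montage64():
    return sd.make_montage(64)


@pytest.fixture(scope="session")
def montage8():
    return sd.make_montage(8)


def quick_config(**overrides) -> sd.StudyConfig:
    """A small, fast study configuration for tests."""
    kwargs = dict(n_channels=8, rate=128.0, n_task_epochs=12,
                  rest_duration=48.0, conditions=("task",),
                  grid_spacing=0.03)
    kwargs.update(overrides)
    return sd.StudyConfig(**kwargs)


@pytest.fixture(scope="session")
def tiny_study():
    """Six-subject null study shared across tests (read-only)."""
    return sd.simulate_study(6, quick_config(), seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
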