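import numpy as np
import pytest

from lgct.data import EpochSet, Montage, ku_motor_montage
from lgct.synthetic import SynthConfig, generate_dataset


@pytest.fixture(scope="session")
def ku_montage():
    return ku_motor_montage()


@pytest.fixture(scope="session")
def pair_montage():
    """Minimal montage: one homologous pair."""
    return Montage.from_labels(["C3", "C4"])


@pytest.fixture(scope="session")
def tiny_synth_config(pair_montage):
    """A 1-second, 2-channel, 30-trial dataset: fast enough for training
    smoke tests while exercising the full generative model."""
    return SynthConfig(n_subjects=1, n_sessions=1, trials_per_session=30,
                       n_classes=2, fs=250.0, duration=1.0,
                       montage=pair_montage, erd_depth=0.9, seed=7)


@pytest.fixture(scope="session")
def tiny_epochs(tiny_synth_config) -> EpochSet:
    return generate_dataset(tiny_synth_config).subjects[0]


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
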