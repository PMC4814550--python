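import numpy as np
import pytest

from myospc.conditioning import session_features
from myospc.decoding import build_labels, train_decoder
from myospc.electrodes import load_preset
from myospc.protocols import make_training_protocol
from myospc.synth import synthesize_session


@pytest.fixture(scope="session")
def presets():
    return {k: load_preset(k) for k in ("implant", "gelled", "dry")}


@pytest.fixture(scope="session")
def training_protocol():
    return make_training_protocol()


@pytest.fixture(scope="session")
def training_session(training_protocol):
    return synthesize_session(training_protocol, "implant", rng_seed=7)


@pytest.fixture(scope="session")
def training_data(training_protocol, training_session):
    feats = session_features(training_session)
    labels = build_labels(training_protocol, feats.window_centers)
    return feats, labels


@pytest.fixture(scope="session")
def implant_decoder(training_data):
    feats, labels = training_data
    return train_decoder(feats, labels, trained_on="implant/seed7")


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
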