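import numpy as np
import pytest

from softcalls import playback, synth


@pytest.fixture(scope="session")
def default_model():
    return synth.ExchangeModel()


@pytest.fixture(scope="session")
def male_schedule():
    return playback.build_schedule("M", playback.default_exemplars("M"), seed=11)


@pytest.fixture(scope="session")
def female_schedule():
    return playback.build_schedule("F", playback.default_exemplars("F"), seed=11)


@pytest.fixture(scope="session")
def bird_pair():
    return synth.make_bird_profiles(n_pairs=1, seed=3)[0]


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
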