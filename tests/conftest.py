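import numpy as np
import pytest

from eegstage import ElectrodeLayout, EEGSegment


@pytest.fixture
def default_layout():
    return ElectrodeLayout.default()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_segment(rng, default_layout):
    """A 32-channel, 480-sample segment of white noise at 500 Hz."""
    values = rng.standard_normal((default_layout.n_channels, 480))
    return EEGSegment(values, 500.0, default_layout.channel_names)


@pytest.fixture
def tiny_model_config():
    """A two-branch config on a small input, cheap enough for training tests."""
    from eegstage import preset

    return preset("two_branch", feature_maps=4, fc_sizes=(8,),
                  input_shape=(7, 11, 64))
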