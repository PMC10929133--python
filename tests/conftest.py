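import numpy as np
import pytest

from rblkit.synth import ToothSpec, generate_tooth


@pytest.fixture
def rng():
    return np.random.default_rng(20240311)


@pytest.fixture
def default_tooth():
    """A mid-loss single-root phantom: (regions, landmarks, true_rbl)."""
    return generate_tooth(ToothSpec(bone_loss_fraction=0.4))
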