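import numpy as np
import pytest

from gabawindow.morphology import discretize, make_synthetic_ca1
from gabawindow.mechanisms import (MechanismSet, PassiveParams, IhParams,
                                   SpikeChannelParams, TonicGABAParams,
                                   attach_mechanisms)


@pytest.fixture(scope="session")
def passive_mech():
    """Leak-only mechanism set (no tonic GABA, no I_h, no spike channels)."""
    return MechanismSet(
        passive=PassiveParams(g_leak=0.05, e_leak=-70.0),
        tonic=TonicGABAParams(o=0.0),
        ih=IhParams(g_h=0.0),
        spike=SpikeChannelParams(g_na=0.0, g_k=0.0),
    )


@pytest.fixture(scope="session")
def small_tree(passive_mech):
    """Ball-and-stick with two obliques, ~30 compartments, passive."""
    morph = make_synthetic_ca1(100.0, 2, 50.0, seed=3)
    model = discretize(morph, 10.0)
    attach_mechanisms(model, passive_mech)
    return model


@pytest.fixture(scope="session")
def default_cell():
    """The study cell: synthetic CA1 morphology with default mechanisms."""
    morph = make_synthetic_ca1(400.0, 8, 150.0, seed=1)
    model = discretize(morph, 10.0)
    attach_mechanisms(model, MechanismSet())
    return model


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
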