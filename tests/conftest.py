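import numpy as np
import pytest

from oscillab import (
    ExcitationSpec,
    MechanicalModel,
    NoiseSpec,
    synthesize_record,
)


@pytest.fixture
def ric_model():
    """Reference single-compartment model used across the suite."""
    return MechanicalModel("ric", R=2.77, I=0.01, C=0.02)


@pytest.fixture
def eric_model():
    return MechanicalModel("eric", R=3.0, I=0.01, C=0.02, slope=-0.05)


@pytest.fixture
def noiseless_record(ric_model):
    return synthesize_record(ric_model, noise=NoiseSpec.none(), seed=0)


@pytest.fixture
def default_excitation():
    return ExcitationSpec()
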