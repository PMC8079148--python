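import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("suite", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("suite")

from dicerkin import InstrumentModel, presets  # noqa: E402


@pytest.fixture
def clean_instrument():
    """Distortion-free instrument: g=1, no ND, no delay, no background."""
    return InstrumentModel(
        channel_delay_ps=0.0,
        g_true=1.0,
        nd_attenuation=1.0,
        background_rate=0.0,
        total_counts=1e9,
    )


@pytest.fixture
def study_instrument():
    """Instrument with the full set of distortions at the study settings."""
    return InstrumentModel(background_rate=2.0, total_counts=1e7)


@pytest.fixture
def cy3_control():
    return presets.CY3_NHS_CONTROL


@pytest.fixture
def blt_dsrna():
    return presets.BLT_DSRNA_ALONE


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
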