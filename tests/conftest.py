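import logging

import numpy as np
import pytest

from rehoscope import synth


@pytest.fixture(autouse=True, scope="session")
def quiet_logging():
    logging.getLogger("rehoscope").setLevel(logging.WARNING)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def smoke_design():
    return synth.SynthDesign.smoke(seed=11)


@pytest.fixture(scope="session")
def scaled_design():
    return synth.SynthDesign.scaled(seed=11)


@pytest.fixture(scope="session")
def scaled_subject(scaled_design):
    """One simulated BD subject on the scaled grid (expensive; share it)."""
    bold, motion = synth.generate_subject(scaled_design, "BD", 12345)
    return bold, motion
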