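import numpy as np
import pytest

import quadspy as q


@pytest.fixture(scope="session")
def glycine():
    return q.preset_system("glycine_amine")


@pytest.fixture(scope="session")
def amide():
    return q.preset_system("triglycine_amide")


@pytest.fixture(scope="session")
def powder_small():
    """Small ZCW set for fast sequence-level checks."""
    return q.zcw_set(144)


@pytest.fixture(scope="session")
def powder_tiny():
    return q.zcw_set(55)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20130415)


@pytest.fixture(scope="session")
def exp_standard():
    """The published working point: 2 ms, 35 kHz, 25 kHz MAS, SQ."""
    return q.ExperimentSpec(tau_n_ms=2.0, nu1_n_khz=35.0, selection="SQ")
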