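import numpy as np
import pytest

import innatedyn as idn


@pytest.fixture(scope="session")
def inflammation_model():
    """Default antigen-driven model (bacteria removed) at v_CRA = 1 fM/min."""
    return idn.build_inflammation_model()


@pytest.fixture(scope="session")
def acute_state(inflammation_model):
    ss = idn.find_steady_state(inflammation_model, confirm_horizon=2e4)
    assert ss.label == "stable"
    return ss


@pytest.fixture(scope="session")
def chronic_state(inflammation_model):
    m = inflammation_model
    y0 = m.initial_state()
    y0[m.dynamic_species.index("fibroblasts")] = 0.0
    ss = idn.find_steady_state(m, y0, confirm_horizon=2e4)
    assert ss.label == "stable"
    return ss


@pytest.fixture()
def decay_model():
    return idn.build_toy_model("decay", v=0.5, k=0.1)


@pytest.fixture()
def switch_model():
    return idn.build_toy_model("switch1d")


@pytest.fixture()
def toggle_model():
    return idn.build_toy_model("toggle2d")
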