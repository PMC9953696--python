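import pytest

from neurogem import make_brain_toy_network, make_textbook_respiration_network


def fix_glucose(model, uptake=1.0):
    """Return a copy with glucose uptake fixed (exchange flux = -uptake)."""
    out = model.copy()
    r = out.reaction("EX_glc")
    r.lb = r.ub = -uptake
    r.reversible = r.lb < 0
    return out


def block_oxygen(model):
    out = model.copy()
    r = out.reaction("EX_o2")
    r.lb = 0.0
    r.reversible = False
    return out


@pytest.fixture(scope="session")
def respiration_model():
    return make_textbook_respiration_network()


@pytest.fixture(scope="session")
def brain_model():
    return make_brain_toy_network()


@pytest.fixture()
def aerobic_unit_glucose(respiration_model):
    return fix_glucose(respiration_model)


@pytest.fixture()
def anaerobic_unit_glucose(respiration_model):
    return block_oxygen(fix_glucose(respiration_model))
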