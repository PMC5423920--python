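import pytest

from gsmm import (
    BiomassComposition,
    MediumSpec,
    ToyModelSpec,
    make_cell_model,
    make_maintenance_fit_model,
    make_toy_model,
)


@pytest.fixture
def chain():
    """Chain toy: uptake 10, yield 0.5, single essential route gene."""
    return make_toy_model(ToyModelSpec())


@pytest.fixture
def branched():
    """Two routes with yields 1.0 / 0.5 (gH high, gL low, gT shared)."""
    return make_toy_model(ToyModelSpec(topology="branched", yields=(1.0, 0.5)))


@pytest.fixture
def parallel():
    return make_toy_model(ToyModelSpec(topology="parallel", gpr_pattern="isozyme_or"))


@pytest.fixture
def cycle():
    return make_toy_model(ToyModelSpec(topology="cycle"))


@pytest.fixture(scope="session")
def cell_model():
    return make_cell_model()


@pytest.fixture(scope="session")
def fit_model():
    return make_maintenance_fit_model()


@pytest.fixture(scope="session")
def default_composition():
    return BiomassComposition()


@pytest.fixture(scope="session")
def cell_medium():
    """Synthetic growth medium for the cell model: glucose + minerals."""
    return MediumSpec(
        {
            "EX_glc_e": (-10.0, 0.0),
            "EX_o2_e": (-1000.0, 0.0),
            "EX_nh4_e": (-1000.0, 0.0),
            "EX_h2o_e": (-1000.0, 1000.0),
            "EX_h_e": (-1000.0, 1000.0),
        }
    )
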