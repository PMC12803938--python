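import pytest

from difflux import (
    FVASettings,
    MetaboliteMap,
    build_toy_model,
    diamond_network,
    ensure_exchanges,
    linear_chain,
    toy_metabolite_map,
    two_cycle_network,
)


@pytest.fixture
def toy_model():
    return build_toy_model()


@pytest.fixture
def toy_mapping():
    return MetaboliteMap(toy_metabolite_map())


@pytest.fixture
def ensured_toy(toy_model, toy_mapping):
    """Toy model with the artificial AKG exchange already added."""
    return ensure_exchanges(toy_model, toy_mapping)


@pytest.fixture
def diamond():
    return diamond_network()


@pytest.fixture
def chain():
    return linear_chain()


@pytest.fixture
def two_cycle():
    return two_cycle_network()


@pytest.fixture
def plain_settings():
    """FVA at full optimum with no cap and no loop handling."""
    return FVASettings(fraction_of_optimum=1.0, pfba_factor=None, loopless=False)
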