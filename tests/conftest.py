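import numpy as np
import pytest

from plecswitch.dynamics import Model, ModelConfig
from plecswitch.network import (
    BuildOptions,
    Reaction,
    ReactionNetwork,
    Species,
    build_full_network,
    build_reduced_network,
)


@pytest.fixture(scope="session")
def full_network():
    return build_full_network()


@pytest.fixture(scope="session")
def reduced_network():
    return build_reduced_network()


@pytest.fixture(scope="session")
def closed_network():
    return build_full_network(BuildOptions(include_syn_deg=False))


@pytest.fixture()
def fast_config():
    """Baseline configuration with a bounded integration budget."""
    return ModelConfig(variant="reduced", t_max=2e4)


@pytest.fixture()
def full_config():
    return ModelConfig(variant="full", t_max=2e4)


@pytest.fixture(scope="session")
def baseline_model():
    return Model(ModelConfig(variant="reduced", t_max=2e4))


def make_species(*ids, moiety="M"):
    return [
        Species(id=i, role="free-protein", moieties={moiety: 1}) for i in ids
    ]


def make_network(species, reactions):
    return ReactionNetwork(species, reactions, variant="full")


@pytest.fixture()
def triangle_network():
    """Three isomers connected in a reversible cycle A<->B<->C<->A."""
    sp = make_species("A", "B", "C")
    rxns = [
        Reaction("ab", {"A": 1}, {"B": 1}, True, "conformational", "conf"),
        Reaction("bc", {"B": 1}, {"C": 1}, True, "conformational", "conf"),
        Reaction("ca", {"C": 1}, {"A": 1}, True, "conformational", "conf"),
    ]
    return make_network(sp, rxns)


@pytest.fixture()
def two_state_network():
    sp = make_species("A", "B")
    rxns = [Reaction("ab", {"A": 1}, {"B": 1}, True, "conformational", "conf")]
    return make_network(sp, rxns)
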