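import networkx as nx
import pytest

from longnet.network import Interactome
from longnet.synth import gen_world


@pytest.fixture()
def toy_interactome() -> Interactome:
    """Two components: a triangle with a pendant (a-b-c-a, c-d) and an edge e-f."""
    g = nx.Graph([("a", "b"), ("b", "c"), ("c", "a"), ("c", "d"), ("e", "f")])
    return Interactome(graph=g, species="worm")


@pytest.fixture(scope="session")
def default_world():
    """The default synthetic study world, generated once per session."""
    return gen_world(seed=42)
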