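from __future__ import annotations

import pytest
from hypothesis import HealthCheck, settings

from tfhier.network_io import DirectedNetwork, NetworkCollection

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


def net(name: str, *edges: tuple[str, str], extra_nodes=()) -> DirectedNetwork:
    return DirectedNetwork.from_edges(name, edges, extra_nodes=extra_nodes)


@pytest.fixture
def chain() -> DirectedNetwork:
    """a -> b -> c."""
    return net("chain", ("a", "b"), ("b", "c"))


@pytest.fixture
def cycle_with_fringe() -> DirectedNetwork:
    """e -> a, 3-cycle a -> b -> c -> a, c -> d."""
    return net("fringe", ("e", "a"), ("a", "b"), ("b", "c"), ("c", "a"), ("c", "d"))


@pytest.fixture
def tiny_collection() -> NetworkCollection:
    n1 = net("alpha", ("A", "B"), ("B", "C"), ("C", "A"), ("A", "D"))
    n2 = net("beta", ("A", "B"), ("B", "C"), ("C", "A"), ("B", "E"))
    n3 = net("gamma", ("A", "B"), ("B", "C"), ("C", "A"), ("C", "F"))
    return NetworkCollection(
        networks=(n1, n2, n3),
        class_label={"alpha": "x", "beta": "x", "gamma": "y"},
    )
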