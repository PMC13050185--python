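import numpy as np
import pytest

from kinergm import (
    KinNetwork,
    ModelSpec,
    NodeTable,
    edges,
    generate_attributes,
    nodematch,
    simulate_network,
)


@pytest.fixture
def toy_nodes() -> NodeTable:
    """Five individuals with sex and site attributes."""
    return NodeTable(
        ["a", "b", "c", "d", "e"],
        {
            "sex": ["F", "F", "M", "M", "F"],
            "site": ["A", "A", "B", "B", "C"],
        },
    )


@pytest.fixture
def sexmatch_net() -> tuple[KinNetwork, ModelSpec, np.ndarray]:
    """A moderately sized draw from the binary match model, with its truth."""
    nodes = generate_attributes(120, {"sex": (["1", "2"], [0.5, 0.5])}, seed=4)
    spec = ModelSpec([edges(), nodematch("sex")])
    theta = np.array([-3.0, 0.8])
    net = simulate_network(nodes, spec, theta, seed=9)
    return net, spec, theta
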