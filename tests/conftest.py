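import numpy as np
import networkx as nx
import pytest

from phosphoppi import synthetic_data as syn
from phosphoppi.network import PhosphoPPI


def make_net(edges, phospho, category="ALL"):
    """Small hand-built phospho-PPI for unit tests."""
    g = nx.Graph()
    g.add_edges_from(edges)
    for v in g.nodes:
        g.nodes[v]["phospho"] = v in phospho
    return PhosphoPPI(g, category=category)


@pytest.fixture
def tiny_net():
    # path P1-P2-P3-P4 plus hub edge P2-P5; phospho = {P2, P3}
    return make_net(
        [("P1", "P2"), ("P2", "P3"), ("P3", "P4"), ("P2", "P5")], {"P2", "P3"}
    )


@pytest.fixture(scope="session")
def coupling_bundle():
    """Mid-size dataset with a planted phospho-degree coupling."""
    return syn.generate_bundle(syn.scenario_config("degree_coupling", seed=42, n_nodes=400))


@pytest.fixture(scope="session")
def coupling_net(coupling_bundle):
    from phosphoppi.network import build

    phospho = {v for v, l in coupling_bundle.labels.items() if l}
    return build(coupling_bundle.records, phospho, "ALL")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
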