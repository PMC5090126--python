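import networkx as nx
import numpy as np
import pandas as pd
import pytest

from corrnet import DataMatrix, EdgeRecord, EdgeTable


@pytest.fixture
def rng():
    return np.random.default_rng(20160819)


@pytest.fixture
def small_matrix():
    """4 samples x 3 variables, fully observed."""
    return DataMatrix(
        values=pd.DataFrame(
            {"met_a": [1.0, 2.0, 3.0, 4.0],
             "met_b": [2.0, 1.0, 4.0, 3.0],
             "met_c": [4.0, 3.0, 2.0, 1.0]},
            index=["s1", "s2", "s3", "s4"],
        )
    )


@pytest.fixture
def triangle_table():
    return EdgeTable([
        EdgeRecord("a", "b", 0.9),
        EdgeRecord("b", "c", 0.8),
        EdgeRecord("a", "c", -0.75),
    ])


@pytest.fixture
def triangle_graph(triangle_table):
    from corrnet import build_network
    return build_network(triangle_table)


def random_graph(rng, n_max=8, p=0.4):
    """A random simple graph on 2..n_max labelled vertices."""
    n = int(rng.integers(2, n_max + 1))
    nodes = [f"v{i}" for i in range(n)]
    g = nx.Graph()
    g.add_nodes_from(nodes)
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p:
                g.add_edge(nodes[i], nodes[j])
    return g
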