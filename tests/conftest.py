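import numpy as np
import pytest

from enmpipe import make_world


@pytest.fixture(scope="session")
def world1():
    """Default synthetic world, seed 1 (shared read-only across tests)."""
    return make_world(1)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_ultrametric(n_tips: int, seed: int, depth: float = 20.0):
    from enmpipe.synth import _random_ultrametric_tree

    labels = [f"T{i}" for i in range(n_tips)]
    return _random_ultrametric_tree(labels, depth, np.random.default_rng(seed)), labels


def tree_to_graph(tree):
    """Edge-weighted graph of a dendropy tree (independent path-sum oracle)."""
    import networkx as nx

    g = nx.Graph()
    for node in tree.preorder_node_iter():
        if node.parent_node is not None:
            g.add_edge(id(node.parent_node), id(node), weight=node.edge.length or 0.0)
    leaves = {lf.taxon.label: id(lf) for lf in tree.leaf_node_iter()}
    return g, leaves
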