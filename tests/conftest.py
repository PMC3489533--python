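import itertools

import networkx as nx
import numpy as np
import pytest

from protnet.graph import Interaction, KnowledgeGraph, NetworkObject, SeedList


def build_graph(edges, classes=None):
    """Small-graph helper: edges as (src, tgt) or (src, tgt, mechanism)."""
    g = KnowledgeGraph()
    for nid, cls in (classes or {}).items():
        g.add_object(NetworkObject(id=nid, object_class=cls))
    for e in edges:
        if len(e) == 2:
            g.add_interaction(Interaction(source=e[0], target=e[1]))
        else:
            g.add_interaction(Interaction(source=e[0], target=e[1],
                                          mechanism=e[2]))
    return g


@pytest.fixture
def triangle():
    return build_graph([("A", "B"), ("B", "C"), ("A", "C")])


@pytest.fixture
def star5():
    return build_graph([("hub", f"L{i}") for i in range(5)])


def random_digraph(rng, n_nodes, p_edge=0.25):
    """Random directed graph on node ids n00..; no self-loops."""
    g = KnowledgeGraph()
    ids = [f"n{i:02d}" for i in range(n_nodes)]
    for nid in ids:
        g.add_object(NetworkObject(id=nid))
    for a, b in itertools.permutations(ids, 2):
        if rng.random() < p_edge:
            g.add_interaction(Interaction(source=a, target=b))
    return g


def seed_list(*ids):
    return SeedList(ids=tuple(ids), label="test")
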