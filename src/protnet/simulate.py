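"""Deterministic synthetic interactomes with planted structure.

Real curated interactomes are heavy-tailed: the average protein has a few
dozen interactions while hubs such as p53 or NF-kB carry over a thousand.
The background generator therefore uses preferential attachment, which is
exactly the regime the z-score normalization of the connectivity statistics
exists for.  Planting operations wire a known node into a sampled seed list
(over-connected hub) or reroute seed-pair shortest paths through a known
intermediary (hidden regulator) so recovery can be tested without any
external data.

Two worked-example fixtures are included as plain constructions: a 13-node
directed graph engineered so that a 7-seed set yields the pair-membership
counts N_BD = 7 and K_BD = 5 with the internal/source/target partition used
in this package's tests, and the 13 published over-connectivity report rows
used to validate the connectivity arithmetic.  The 13-node topology is an
engineered stand-in reproducing the published counts, not a copy of any
published edge list (which is not available).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import networkx as nx
import numpy as np

from .graph import (EFFECTS, MECHANISMS, OBJECT_CLASSES, Interaction,
                    KnowledgeGraph, NetworkObject, SeedList)

__all__ = [
    "FixtureSpec",
    "generate_graph",
    "plant_overconnected_hub",
    "plant_hidden_regulator",
    "figure5_fixture",
    "table1_cases",
]

#: a class mix resembling a curated signaling interactome
DEFAULT_CLASS_MIX = {
    "transcription_factor": 0.08,
    "receptor": 0.10,
    "ligand": 0.08,
    "kinase": 0.10,
    "phosphatase": 0.04,
    "protease": 0.04,
    "enzyme": 0.16,
    "complex": 0.05,
    "compound": 0.05,
    "generic": 0.30,
}

_MECHS = sorted(MECHANISMS)
_EFFECTS = sorted(EFFECTS)


@dataclass
class FixtureSpec:
    n_nodes: int = 500
    attachment_parameter: int = 3
    class_mix: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_MIX))
    seed: int = 0
    planted: str = ""

    def __post_init__(self) -> None:
        total = sum(self.class_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class proportions sum to {total}, not 1")
        unknown = set(self.class_mix) - OBJECT_CLASSES
        if unknown:
            raise ValueError(f"unknown classes {sorted(unknown)}")


def generate_graph(spec: FixtureSpec) -> KnowledgeGraph:
    """Directed preferential-attachment interactome.

    An undirected Barabasi-Albert skeleton (m = attachment parameter) is
    oriented edge by edge with a seeded RNG, and nodes receive classes,
    mechanisms and effects from the same stream; identical spec + seed gives
    an identical graph.
    """
    rng = np.random.default_rng(spec.seed)
    skeleton = nx.barabasi_albert_graph(
        spec.n_nodes, spec.attachment_parameter, seed=int(spec.seed))
    g = KnowledgeGraph()
    classes = sorted(spec.class_mix)
    probs = np.array([spec.class_mix[c] for c in classes])
    width = len(str(spec.n_nodes - 1))
    ids = [f"P{idx:0{width}d}" for idx in range(spec.n_nodes)]
    assigned = rng.choice(len(classes), size=spec.n_nodes, p=probs)
    for nid, ci in zip(ids, assigned):
        g.add_object(NetworkObject(id=nid, object_class=classes[ci]))
    for u, v in sorted(skeleton.edges()):
        src, tgt = (ids[u], ids[v]) if rng.random() < 0.5 else (ids[v], ids[u])
        g.add_interaction(Interaction(
            source=src, target=tgt,
            effect=_EFFECTS[rng.integers(len(_EFFECTS))],
            mechanism=_MECHS[rng.integers(len(_MECHS))],
            species="human"))
    return g


def _sample_seeds(g: KnowledgeGraph, n_seeds: int, rng: np.random.Generator,
                  exclude: Sequence[str] = ()) -> list[str]:
    pool = [n for n in g.node_ids if n not in set(exclude)]
    if n_seeds > len(pool):
        raise ValueError("more seeds requested than available nodes")
    idx = rng.choice(len(pool), size=n_seeds, replace=False)
    return [pool[i] for i in sorted(idx)]


def plant_overconnected_hub(
    graph: KnowledgeGraph, n_seeds: int, hub_links: int, seed: int,
) -> tuple[KnowledgeGraph, SeedList, str]:
    """Sample a seed list and wire one node to ``hub_links`` of its members.

    The hub is drawn from the non-seed nodes of smallest existing degree so
    the planted signal is the dominant part of its neighborhood.  Returns
    the modified graph (in place), the seed list, and the hub id.
    """
    if hub_links > n_seeds:
        raise ValueError("cannot link the hub to more nodes than there are seeds")
    rng = np.random.default_rng(seed)
    seeds = _sample_seeds(graph, n_seeds, rng)
    non_seeds = [n for n in graph.node_ids if n not in set(seeds)]
    if not non_seeds:
        raise ValueError("no non-seed node available for the hub")
    non_seeds.sort(key=lambda n: (graph.degree(n, "both"), n))
    hub = non_seeds[0]
    chosen = rng.choice(len(seeds), size=hub_links, replace=False)
    for i in sorted(chosen):
        graph.add_interaction(Interaction(source=hub, target=seeds[i],
                                          mechanism="binding",
                                          species="human"))
    return graph, SeedList(ids=tuple(seeds), label="planted-hub seeds"), hub


def plant_hidden_regulator(
    graph: KnowledgeGraph, n_seeds: int, routed_fraction: float, seed: int,
) -> tuple[KnowledgeGraph, SeedList, str]:
    """Short-circuit seed-pair shortest paths through one planted node.

    A fraction ``routed_fraction`` of the sampled seeds gains bidirectional
    edges to the planted node x (a low-degree non-seed, so its background
    path traffic stays small) and loses its direct edges to the other routed
    seeds.  Every ordered routed seed pair then sits at distance exactly 2
    with x on a shortest path, while the seeds keep their remaining
    background wiring: x becomes a shortest intermediary specifically for
    seed pairs, which is the signal the topological score looks for.
    """
    if not (0 < routed_fraction <= 1):
        raise ValueError("routed_fraction must be in (0, 1]")
    rng = np.random.default_rng(seed)
    seeds = _sample_seeds(graph, n_seeds, rng)
    non_seeds = [n for n in graph.node_ids if n not in set(seeds)]
    if not non_seeds:
        raise ValueError("no non-seed node available to plant")
    non_seeds.sort(key=lambda n: (graph.degree(n, "both"), n))
    planted = non_seeds[0]
    n_routed = max(2, round(routed_fraction * n_seeds))
    routed = seeds[:n_routed]
    mg = graph.nx_graph
    routed_set = set(routed)
    for s in routed:
        for t in list(mg.successors(s)):
            if t in routed_set:
                while mg.has_edge(s, t):
                    mg.remove_edge(s, t)
    for s in routed:
        graph.add_interaction(Interaction(source=s, target=planted,
                                          species="human"))
        graph.add_interaction(Interaction(source=planted, target=s,
                                          species="human"))
    return graph, SeedList(ids=tuple(seeds), label="planted-regulator seeds"), planted


# -- worked-example fixtures ----------------------------------------------

#: edges of the engineered 13-node worked example (synthetic stand-in)
_FIG5_EDGES = [
    ("B", "D"), ("B", "C"),
    ("D", "A"), ("D", "G"), ("D", "K"), ("D", "J"), ("D", "I"),
    ("D", "M"), ("D", "E"),
    ("A", "C"), ("A", "M"),
    ("C", "K"), ("M", "I"),
    ("L", "F"), ("F", "G"),
    ("L", "H"), ("H", "J"),
]

#: the 7 experimentally derived nodes of the worked example
_FIG5_SEEDS = ("A", "B", "G", "I", "J", "K", "L")


def figure5_fixture() -> tuple[KnowledgeGraph, SeedList]:
    """13-node directed graph plus 7-node seed set for the hidden-nodes
    worked example.

    Engineered (synthetic) so that the shortest-path network over the seeds
    has exactly five internal nodes {C, D, F, H, M}, sources {A, B, L},
    targets {A, G, I, J, K}, and the pair-membership counts of node D with
    respect to seed B are N_BD = 7 and K_BD = 5.
    """
    g = KnowledgeGraph()
    for nid in "ABCDEFGHIJKLM":
        g.add_object(NetworkObject(id=nid))
    for s, t in _FIG5_EDGES:
        g.add_interaction(Interaction(source=s, target=t))
    return g, SeedList(ids=_FIG5_SEEDS, label="worked-example seeds")


#: published over-connectivity report rows: (object, class, r, n, R, N,
#: expected, ratio, p, z) with the last four kept as printed strings
_TABLE1_ROWS: list[tuple[str, str, int, int, int, int, str, str, str, str]] = [
    ("Nkx5-1", "transcription_factor", 2, 79, 9, 19603, "0.036", "55.14", "5.668E-04", "10.33"),
    ("NFIC", "transcription_factor", 4, 79, 104, 19603, "0.420", "9.54", "8.277E-04", "5.56"),
    ("USF2", "transcription_factor", 7, 79, 183, 19603, "0.738", "9.49", "9.061E-06", "7.34"),
    ("ITGB6", "receptor", 2, 79, 9, 19603, "0.036", "55.14", "5.668E-04", "10.33"),
    ("VLDLR", "receptor", 3, 79, 22, 19603, "0.089", "33.84", "9.180E-05", "9.8"),
    ("Glypican-1", "receptor", 2, 79, 16, 19603, "0.064", "31.02", "1.855E-03", "7.64"),
    ("LAMA2", "ligand", 2, 79, 7, 19603, "0.028", "70.9", "3.324E-04", "11.77"),
    ("CCL17", "ligand", 2, 79, 11, 19603, "0.044", "45.12", "8.614E-04", "9.31"),
    ("Thrombospondin 2", "ligand", 2, 79, 15, 19603, "0.060", "33.09", "1.627E-03", "7.91"),
    ("LRRK1", "kinase", 2, 79, 5, 19603, "0.020", "99.26", "1.591E-04", "13.98"),
    ("CTRL", "protease", 1, 79, 1, 19603, "0.004", "248.1", "4.030E-03", "15.72"),
    ("Mcpt8", "protease", 1, 79, 1, 19603, "0.004", "248.1", "4.030E-03", "15.72"),
    ("CRIM2", "protease", 1, 79, 2, 19603, "0.008", "124.1", "8.044E-03", "11.07"),
]


@dataclass(frozen=True)
class Table1Case:
    object_name: str
    object_class: str
    r: int
    n: int
    R: int
    N: int
    expected: str
    ratio: str
    p_value: str
    z_score: str


def table1_cases() -> list[Table1Case]:
    """The 13 published over-connectivity rows, integer inputs plus printed
    statistics, for validating the connectivity arithmetic."""
    return [Table1Case(*row) for row in _TABLE1_ROWS]
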