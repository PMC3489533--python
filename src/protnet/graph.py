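"""Directed, mechanism-annotated protein interaction graph and protein lists.

The global interactome is modelled as a directed multigraph of network
objects (proteins, complexes, compounds...) whose edges carry a mechanism
(binding, phosphorylation, transcription regulation, ...), a causative
effect (positive / negative / unspecified) and a species tag.  Connectivity
statistics count DISTINCT counterpart nodes, not raw edges: parallel
mechanisms or orientations between the same pair collapse to one connection,
and self-loops are stored but never counted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import networkx as nx

__all__ = [
    "OBJECT_CLASSES",
    "MECHANISMS",
    "EFFECTS",
    "SPECIES",
    "NetworkObject",
    "Interaction",
    "KnowledgeGraph",
    "SeedList",
    "load_edge_table",
    "save_edge_table",
    "load_node_table",
    "load_seed_file",
    "map_identifiers",
]

OBJECT_CLASSES = frozenset({
    "transcription_factor", "receptor", "ligand", "kinase", "phosphatase",
    "protease", "enzyme", "complex", "compound", "generic",
})

MECHANISMS = frozenset({
    "binding", "cleavage", "covalent_modification", "phosphorylation",
    "dephosphorylation", "transformation", "transport", "catalysis",
    "transcription_regulation", "microRNA_binding",
})

EFFECTS = frozenset({"positive", "negative", "unspecified"})
SPECIES = frozenset({"human", "mouse", "rat", "unspecified"})


@dataclass
class NetworkObject:
    """A node of the interactome: protein, complex, compound or generic."""

    id: str
    name: str = ""
    object_class: str = "generic"
    synonyms: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("network object id must be nonempty")
        if self.object_class not in OBJECT_CLASSES:
            raise ValueError(
                f"unknown object class {self.object_class!r} for node {self.id!r}"
            )
        if not self.name:
            self.name = self.id
        self.synonyms = frozenset(self.synonyms)


@dataclass(frozen=True)
class Interaction:
    """One directed, typed interaction between two network objects."""

    source: str
    target: str
    effect: str = "unspecified"
    mechanism: str = "binding"
    species: str = "unspecified"

    def __post_init__(self) -> None:
        if self.effect not in EFFECTS:
            raise ValueError(f"unknown effect {self.effect!r}")
        if self.mechanism not in MECHANISMS:
            raise ValueError(f"unknown mechanism {self.mechanism!r}")
        if self.species not in SPECIES:
            raise ValueError(f"unknown species {self.species!r}")


class KnowledgeGraph:
    """Directed multigraph of network objects with typed, signed edges.

    Thin wrapper over :class:`networkx.MultiDiGraph`; exposes the
    distinct-neighbor degree and clustering-coefficient conventions that the
    connectivity statistics rely on.
    """

    def __init__(self) -> None:
        self._g = nx.MultiDiGraph()
        self._objects: dict[str, NetworkObject] = {}

    # -- construction -----------------------------------------------------

    def add_object(self, obj: NetworkObject) -> None:
        existing = self._objects.get(obj.id)
        if existing is not None:
            # upgrading a placeholder generic node with real annotation is fine
            if existing.object_class == "generic" or existing == obj:
                self._objects[obj.id] = obj
                self._g.add_node(obj.id)
                return
            raise ValueError(f"duplicate node id {obj.id!r}")
        self._objects[obj.id] = obj
        self._g.add_node(obj.id)

    def ensure_node(self, node_id: str) -> None:
        if node_id not in self._objects:
            self.add_object(NetworkObject(id=node_id))

    def add_interaction(self, edge: Interaction) -> bool:
        """Add an edge; identical duplicates collapse.  Returns True if added."""
        self.ensure_node(edge.source)
        self.ensure_node(edge.target)
        key = (edge.effect, edge.mechanism, edge.species)
        if self._g.has_edge(edge.source, edge.target, key=key):
            return False
        self._g.add_edge(edge.source, edge.target, key=key, interaction=edge)
        return True

    # -- basic queries ----------------------------------------------------

    @property
    def nx_graph(self) -> nx.MultiDiGraph:
        return self._g

    def __contains__(self, node_id: str) -> bool:
        return node_id in self._objects

    def __len__(self) -> int:
        return len(self._objects)

    @property
    def node_ids(self) -> list[str]:
        return sorted(self._objects)

    def object(self, node_id: str) -> NetworkObject:
        try:
            return self._objects[node_id]
        except KeyError:
            raise KeyError(f"unknown node {node_id!r}") from None

    def objects(self) -> Iterator[NetworkObject]:
        for nid in self.node_ids:
            yield self._objects[nid]

    def interactions(self) -> Iterator[Interaction]:
        for _, _, data in self._g.edges(data=True):
            yield data["interaction"]

    @property
    def n_edges(self) -> int:
        return self._g.number_of_edges()

    def nodes_of_class(self, object_class: str) -> list[str]:
        return [o.id for o in self.objects() if o.object_class == object_class]

    def connected_node_count(self) -> int:
        """Number of nodes with at least one non-self interaction (the
        default universe size N for connectivity statistics)."""
        return sum(1 for n in self._objects if self.degree(n, "both") > 0)

    # -- topology ---------------------------------------------------------

    def neighbors(self, node_id: str, direction: str = "both") -> set[str]:
        """Distinct counterpart nodes, self excluded."""
        if node_id not in self._objects:
            raise KeyError(f"unknown node {node_id!r}")
        if direction == "in":
            nbrs = set(self._g.predecessors(node_id))
        elif direction == "out":
            nbrs = set(self._g.successors(node_id))
        elif direction == "both":
            nbrs = set(self._g.predecessors(node_id)) | set(
                self._g.successors(node_id))
        else:
            raise ValueError(f"direction must be in/out/both, got {direction!r}")
        nbrs.discard(node_id)
        return nbrs

    def degree(self, node_id: str, direction: str = "both") -> int:
        """Number of distinct neighbors in the given direction (self and
        parallel edges excluded)."""
        return len(self.neighbors(node_id, direction))

    def has_connection(self, a: str, b: str) -> bool:
        """True when at least one edge joins a and b in either orientation."""
        return self._g.has_edge(a, b) or self._g.has_edge(b, a)

    def clustering_coefficient(self, node_id: str) -> float:
        """C_i = 2 n_i / (k_i (k_i - 1)) on the undirected projection.

        k_i is the distinct-neighbor degree and n_i the number of unordered
        neighbor pairs joined by at least one edge in either orientation.
        Returns 0 for k_i < 2 by convention.
        """
        nbrs = sorted(self.neighbors(node_id, "both"))
        k = len(nbrs)
        if k < 2:
            return 0.0
        n_links = 0
        for i in range(k):
            for j in range(i + 1, k):
                if self.has_connection(nbrs[i], nbrs[j]):
                    n_links += 1
        return 2.0 * n_links / (k * (k - 1))

    def set_topology_summary(self, seeds: "SeedList") -> dict[str, float | int]:
        """Mean degrees and clustering over a node set, plus the split of
        edges internal to the set ("local interactome") vs leaving it."""
        ids = list(seeds.ids)
        if not ids:
            raise ValueError("cannot summarize an empty set")
        member = set(ids)
        mean = lambda xs: sum(xs) / len(xs)
        intra = 0
        outgoing = 0
        for e in self.interactions():
            if e.source == e.target:
                continue
            inside = (e.source in member) + (e.target in member)
            if inside == 2:
                intra += 1
            elif inside == 1:
                outgoing += 1
        return {
            "n_members": len(ids),
            "mean_degree_in": mean([self.degree(i, "in") for i in ids]),
            "mean_degree_out": mean([self.degree(i, "out") for i in ids]),
            "mean_degree_both": mean([self.degree(i, "both") for i in ids]),
            "mean_clustering": mean([self.clustering_coefficient(i) for i in ids]),
            "intra_set_edges": intra,
            "boundary_edges": outgoing,
        }

    def undirected_view(self) -> nx.Graph:
        """Simple undirected projection (parallel edges collapsed, self-loops
        dropped); used by neighborhood-growing algorithms."""
        u = nx.Graph()
        u.add_nodes_from(self._objects)
        for s, t in self._g.edges():
            if s != t:
                u.add_edge(s, t)
        return u

    def simple_digraph(self) -> nx.DiGraph:
        """Simple directed projection with unit edge weights (self-loops
        dropped); shortest paths ignore mechanism and effect."""
        d = nx.DiGraph()
        d.add_nodes_from(self._objects)
        for s, t in self._g.edges():
            if s != t:
                d.add_edge(s, t)
        return d


@dataclass
class SeedList:
    """A mapped protein list: ordered node ids plus the identifiers that
    matched nothing in the graph."""

    ids: tuple[str, ...]
    label: str = "seed list"
    unmapped: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("seed list contains duplicate node ids")
        self.ids = tuple(self.ids)
        self.unmapped = frozenset(self.unmapped)

    def __len__(self) -> int:
        return len(self.ids)

    def __iter__(self) -> Iterator[str]:
        return iter(self.ids)

    def __contains__(self, node_id: str) -> bool:
        return node_id in set(self.ids)


# -- I/O -------------------------------------------------------------------

_EDGE_HEADER = ["source", "target", "effect", "mechanism", "species"]


def load_edge_table(path: str | Path, dialect: str = "tsv") -> KnowledgeGraph:
    """Read an interaction graph from a TSV edge table or a SIF file.

    TSV needs a header line ``source  target  effect  mechanism  species``
    (the last three columns optional, defaulting to unspecified/binding).
    SIF rows are ``source  relation  target``; the relation maps to the
    mechanism when it names one, otherwise the edge is a plain binding.
    Endpoints unseen before become generic nodes; identical rows collapse.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    rows = [(i + 1, ln) for i, ln in enumerate(lines)
            if ln.strip() and not ln.startswith("#")]
    if not rows:
        raise ValueError(f"{path}: empty graph")
    g = KnowledgeGraph()
    if dialect == "sif":
        for lineno, ln in rows:
            parts = ln.split()
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: malformed SIF row {ln!r}")
            src, rel, targets = parts[0], parts[1], parts[2:]
            mech = rel if rel in MECHANISMS else "binding"
            for tgt in targets:
                g.add_interaction(Interaction(src, tgt, mechanism=mech))
        return g
    if dialect != "tsv":
        raise ValueError(f"unknown dialect {dialect!r}")
    header = rows[0][1].rstrip("\n").split("\t")
    if header[:2] != ["source", "target"]:
        raise ValueError(f"{path}:1: expected header starting source<TAB>target")
    col = {name: i for i, name in enumerate(header)}
    for lineno, ln in rows[1:]:
        parts = ln.rstrip("\n").split("\t")
        if len(parts) < 2 or not parts[0] or not parts[1]:
            raise ValueError(f"{path}:{lineno}: malformed row {ln!r}")

        def get(name: str, default: str) -> str:
            i = col.get(name)
            if i is None or i >= len(parts) or not parts[i]:
                return default
            return parts[i]

        try:
            g.add_interaction(Interaction(
                source=parts[0], target=parts[1],
                effect=get("effect", "unspecified"),
                mechanism=get("mechanism", "binding"),
                species=get("species", "unspecified"),
            ))
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: {exc}") from None
    return g


def save_edge_table(graph: KnowledgeGraph, path: str | Path) -> None:
    """Write the edge multiset as a TSV that round-trips through
    :func:`load_edge_table` exactly."""
    edges = sorted(
        (e.source, e.target, e.effect, e.mechanism, e.species)
        for e in graph.interactions()
    )
    with open(path, "w") as fh:
        fh.write("\t".join(_EDGE_HEADER) + "\n")
        for row in edges:
            fh.write("\t".join(row) + "\n")


def load_node_table(graph: KnowledgeGraph, path: str | Path) -> None:
    """Attach node annotation from a TSV ``id  name  class  synonyms``
    (synonyms pipe-separated); unknown ids create new isolated nodes."""
    for lineno, ln in enumerate(Path(path).read_text().splitlines(), start=1):
        if not ln.strip() or ln.startswith("#"):
            continue
        parts = ln.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"{path}:{lineno}: expected id, name, class")
        syn = frozenset(s for s in parts[3].split("|")) if len(parts) > 3 and parts[3] else frozenset()
        graph.add_object(NetworkObject(
            id=parts[0], name=parts[1] or parts[0],
            object_class=parts[2] or "generic", synonyms=syn,
        ))


def load_seed_file(path: str | Path) -> list[str]:
    """One identifier per line; '#' comments and blank lines ignored."""
    out = []
    for ln in Path(path).read_text().splitlines():
        s = ln.split("#", 1)[0].strip()
        if s:
            out.append(s)
    return out


def map_identifiers(graph: KnowledgeGraph, raw_ids: Sequence[str],
                    label: str = "seed list") -> SeedList:
    """Match raw identifiers to graph nodes, case-insensitively, against node
    ids, then names, then synonyms.

    A raw id hitting several nodes contributes all of them.  The output is
    deduplicated with input order of first occurrence preserved; identifiers
    matching nothing are reported in ``unmapped`` (not an error).
    """
    if not raw_ids:
        raise ValueError("empty identifier list")
    by_id: dict[str, list[str]] = {}
    by_name: dict[str, list[str]] = {}
    by_syn: dict[str, list[str]] = {}
    for obj in graph.objects():
        by_id.setdefault(obj.id.lower(), []).append(obj.id)
        by_name.setdefault(obj.name.lower(), []).append(obj.id)
        for s in obj.synonyms:
            by_syn.setdefault(s.lower(), []).append(obj.id)
    mapped: list[str] = []
    seen: set[str] = set()
    unmapped: set[str] = set()
    for raw in raw_ids:
        key = raw.lower()
        hits = by_id.get(key) or by_name.get(key) or by_syn.get(key)
        if not hits:
            unmapped.add(raw)
            continue
        for nid in sorted(set(hits)):
            if nid not in seen:
                seen.add(nid)
                mapped.append(nid)
    return SeedList(ids=tuple(mapped), label=label, unmapped=frozenset(unmapped))
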