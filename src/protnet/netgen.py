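"""Network generation around a root (seed) list, and fragment prioritization.

Seven builders connect an uploaded protein list through the global graph,
from the most stringent to the most explorative:

* direct interactions (DI): only edges among the roots;
* expand by one: roots, their first neighbors, and the bridges of at most
  two non-root objects between roots;
* shortest paths (SP): all minimum-length directed paths between list
  members, bounded by a maximum step count;
* auto-expand (AE): synchronized neighborhood growth that halts as soon as
  two root territories touch;
* analyze network (AN): a super-network built by continued auto-expansion,
  cyclically divided into size-bounded fragments in which an edge is used
  by at most one fragment (nodes may recur);
* AN (transcription factors) / AN (receptors): per-TF (per-receptor)
  networks of all shortest paths from the closest receptor (to the closest
  TF); directional, hence not reciprocal;
* transcription regulation (TR): one network per immediate transcription
  factor of the list;
* model canonical pathways: merges curated linear signaling chains around
  each qualifying root.

Fragments carry the seed-enrichment statistics p and z (hypergeometric, with
r = seed nodes on the fragment, n = fragment size, R = mapped list size,
N = universe after filtration) and the g-score, z plus a per-canonical-
pathway bonus (default 1.25 per pathway, calibrated so fragments without
canonical content keep g = z).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import networkx as nx
import pandas as pd

from .graph import KnowledgeGraph, SeedList
from .stats import EnrichmentCounts, hypergeom_summary, upper_tail_pvalue

__all__ = [
    "NetworkFragment",
    "CanonicalPathway",
    "BuildOptions",
    "DEFAULT_PATHWAY_BONUS",
    "direct_interactions",
    "expand_by_one",
    "shortest_path_build",
    "auto_expand",
    "analyze_network",
    "analyze_network_directed",
    "transcription_regulation",
    "model_canonical_pathways",
    "g_score",
    "score_fragment",
    "count_canonical_fragments",
    "load_pathway_library",
    "ranking_table",
]

#: per-canonical-pathway additive bonus on the z-score
DEFAULT_PATHWAY_BONUS = 1.25


@dataclass
class NetworkFragment:
    """A generated sub-network with its seed content and scores."""

    nodes: frozenset[str]
    edges: frozenset[tuple[str, str]]
    seed_nodes: frozenset[str]
    label: str = ""
    pathways_count: int = 0
    p: float | None = None
    z: float | None = None
    g: float | None = None
    # builder-specific extras
    components: tuple[frozenset[str], ...] = ()
    isolated: frozenset[str] = field(default_factory=frozenset)
    note: str = ""

    def __post_init__(self) -> None:
        for u, v in self.edges:
            if u not in self.nodes or v not in self.nodes:
                raise ValueError(f"edge ({u}, {v}) leaves the fragment")
        if not self.seed_nodes <= self.nodes:
            raise ValueError("seed_nodes must be a subset of nodes")

    @property
    def size(self) -> int:
        return len(self.nodes)


@dataclass
class CanonicalPathway:
    """A curated linear chain of directed signaling steps."""

    pathway_id: str
    name: str
    chain: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.chain) < 2:
            raise ValueError(f"pathway {self.pathway_id!r}: chain length < 2")
        self.chain = tuple(self.chain)

    @property
    def steps(self) -> list[tuple[str, str]]:
        return list(zip(self.chain, self.chain[1:]))


@dataclass
class BuildOptions:
    max_path_length: int = 3
    fragment_size: int = 50
    enrich_with_ligands_targets: bool = False
    direction: str = "both"
    max_radius: int = 3
    rank_key: str = "g"
    pathway_bonus: float = DEFAULT_PATHWAY_BONUS

    def __post_init__(self) -> None:
        if not (2 <= self.fragment_size <= 100):
            raise ValueError("fragment_size must be within [2, 100]")
        if self.max_path_length < 1:
            raise ValueError("max_path_length must be >= 1")


def _mapped_roots(graph: KnowledgeGraph, roots: SeedList) -> list[str]:
    ids = [r for r in roots.ids if r in graph]
    if not ids:
        raise ValueError("no root maps onto the graph")
    return ids


def _induced_fragment(graph: KnowledgeGraph, nodes: Iterable[str],
                      roots: Iterable[str], label: str = "",
                      note: str = "") -> NetworkFragment:
    nodeset = frozenset(nodes)
    dg = graph.simple_digraph()
    edges = frozenset((u, v) for u, v in dg.edges()
                      if u in nodeset and v in nodeset)
    return NetworkFragment(nodes=nodeset, edges=edges,
                           seed_nodes=frozenset(set(roots) & nodeset),
                           label=label, note=note)


# -- DI --------------------------------------------------------------------

def direct_interactions(graph: KnowledgeGraph, roots: SeedList) -> NetworkFragment:
    """Induced subgraph on the root list only.  Isolated roots are retained
    and reported; connected clusters are enumerated largest-first."""
    ids = _mapped_roots(graph, roots)
    frag = _induced_fragment(graph, ids, ids, label="direct interactions")
    u = nx.Graph()
    u.add_nodes_from(frag.nodes)
    u.add_edges_from(frag.edges)
    comps = [frozenset(c) for c in nx.connected_components(u) if len(c) > 1]
    comps.sort(key=lambda c: (-len(c), min(c)))
    isolated = frozenset(n for n in frag.nodes
                         if all(n not in c for c in comps))
    return NetworkFragment(nodes=frag.nodes, edges=frag.edges,
                           seed_nodes=frag.seed_nodes, label=frag.label,
                           components=tuple(comps), isolated=isolated)


# -- expand by one ---------------------------------------------------------

def expand_by_one(graph: KnowledgeGraph, roots: SeedList) -> NetworkFragment:
    """Roots plus first neighbors, pruned to the bridging objects.

    A non-root node survives only if it is interior to some path between two
    DIFFERENT roots whose non-root interior has at most two nodes (the node
    itself, optionally one non-root partner): dangling neighbors that touch
    a single root are removed.
    """
    ids = _mapped_roots(graph, roots)
    rootset = set(ids)
    closure = set(ids)
    for r in ids:
        closure |= graph.neighbors(r, "both")
    u = graph.undirected_view().subgraph(closure)
    roots_adj = {x: {r for r in u.neighbors(x) if r in rootset}
                 for x in closure if x not in rootset}
    keep: set[str] = set(ids)
    nonroots = sorted(closure - rootset)
    for x in nonroots:
        ra = roots_adj[x]
        if not ra:
            continue
        if len(ra) >= 2:
            keep.add(x)
            continue
        for y in u.neighbors(x):
            if y in rootset:
                continue
            if roots_adj.get(y) and len(roots_adj[y] | ra) >= 2:
                keep.add(x)
                break
    return _induced_fragment(graph, keep, ids, label="expand by one")


# -- SP --------------------------------------------------------------------

def _all_shortest_path_union(
    dg: nx.DiGraph, pairs: Iterable[tuple[str, str]], max_len: Optional[int],
) -> tuple[set[str], set[tuple[str, str]]]:
    """Nodes and edges of all minimum-length directed paths for each ordered
    pair, skipping pairs whose minimum exceeds ``max_len``."""
    fwd: dict[str, dict] = {}
    bwd: dict[str, dict] = {}
    rev = dg.reverse(copy=False)
    nodes: set[str] = set()
    edges: set[tuple[str, str]] = set()
    for a, b in pairs:
        if a == b:
            continue
        if a not in fwd:
            fwd[a] = nx.single_source_shortest_path_length(dg, a)
        da = fwd[a]
        if b not in da:
            continue
        d = da[b]
        if max_len is not None and d > max_len:
            continue
        if b not in bwd:
            bwd[b] = nx.single_source_shortest_path_length(rev, b)
        db = bwd[b]
        on_path = {v for v, dav in da.items() if v in db and dav + db[v] == d}
        nodes |= on_path
        for x in on_path:
            for y in dg.successors(x):
                if y in on_path and da[x] + 1 + db.get(y, 1 << 30) == d:
                    edges.add((x, y))
    return nodes, edges


def shortest_path_build(
    graph: KnowledgeGraph, from_list: SeedList,
    to_list: Optional[SeedList] = None,
    options: Optional[BuildOptions] = None,
) -> NetworkFragment:
    """All minimum-length directed paths from every initial node to every
    end node (the two lists default to the same input list)."""
    options = options or BuildOptions()
    src = _mapped_roots(graph, from_list)
    dst = _mapped_roots(graph, to_list) if to_list is not None else src
    dg = graph.simple_digraph()
    pairs = [(a, b) for a in src for b in dst if a != b]
    nodes, edges = _all_shortest_path_union(dg, pairs, options.max_path_length)
    rootset = set(src) | set(dst)
    return NetworkFragment(nodes=frozenset(nodes), edges=frozenset(edges),
                           seed_nodes=frozenset(nodes & rootset),
                           label="shortest paths")


# -- AE --------------------------------------------------------------------

def _grow_territories(u: nx.Graph, roots: Sequence[str], max_radius: int,
                      stop_at_first_contact: bool) -> tuple[dict[str, set[str]], int, bool]:
    """Synchronized breadth-first growth of per-root territories on the
    undirected projection.  Returns (territories, radius, merged)."""
    terr = {r: {r} for r in roots}
    frontier = {r: {r} for r in roots}
    radius = 0
    merged = len(roots) > 1 and _territories_touch(terr)
    while radius < max_radius and not (merged and stop_at_first_contact):
        radius += 1
        any_growth = False
        for r in roots:
            new = set()
            for v in frontier[r]:
                new |= set(u.neighbors(v))
            new -= terr[r]
            if new:
                any_growth = True
            terr[r] |= new
            frontier[r] = new
        if _territories_touch(terr):
            merged = True
            if stop_at_first_contact:
                break
        if not any_growth:
            break
    return terr, radius, merged


def _territories_touch(terr: dict[str, set[str]]) -> bool:
    seen: dict[str, str] = {}
    for r, nodes in terr.items():
        for v in nodes:
            if v in seen and seen[v] != r:
                return True
            seen.setdefault(v, r)
    return False


def _on_root_connecting_paths(u_sub: nx.Graph, roots: Sequence[str]) -> set[str]:
    keep: set[str] = set(roots)
    dist = {r: nx.single_source_shortest_path_length(u_sub, r)
            for r in roots if r in u_sub}
    for i, r1 in enumerate(roots):
        for r2 in roots[i + 1:]:
            d1 = dist.get(r1, {})
            if r2 not in d1:
                continue
            d = d1[r2]
            d2 = dist.get(r2, {})
            keep |= {v for v, dv in d1.items()
                     if v in d2 and dv + d2[v] == d}
    return keep


def auto_expand(graph: KnowledgeGraph, roots: SeedList,
                options: Optional[BuildOptions] = None) -> NetworkFragment:
    """Grow sub-networks around every root simultaneously; halt at the first
    radius where two territories share a node; drop expansion nodes that do
    not lie on any root-to-root connecting path."""
    options = options or BuildOptions()
    ids = _mapped_roots(graph, roots)
    u = graph.undirected_view()
    if len(ids) == 1:
        nodes = {ids[0]} | set(u.neighbors(ids[0]))
        return _induced_fragment(graph, nodes, ids, label="auto-expand",
                                 note="single root: one-step neighborhood")
    terr, radius, merged = _grow_territories(u, ids, options.max_radius, True)
    union = set().union(*terr.values())
    if not merged:
        return _induced_fragment(
            graph, ids, ids, label="auto-expand",
            note=f"no territory contact within radius {radius}; "
                 "expansion nodes removed")
    keep = _on_root_connecting_paths(u.subgraph(union), ids)
    return _induced_fragment(graph, keep, ids, label="auto-expand")


# -- AN --------------------------------------------------------------------

def _super_network(graph: KnowledgeGraph, ids: Sequence[str],
                   max_radius: int) -> set[str]:
    """Simplified auto-expand: keep growing past first contact until all
    mappable roots are mutually connected (or the radius cap)."""
    u = graph.undirected_view()
    terr = {r: {r} for r in ids}
    frontier = {r: {r} for r in ids}
    radius = 0
    while radius < max_radius:
        union = set().union(*terr.values())
        sub = u.subgraph(union)
        comp = {v: i for i, c in enumerate(nx.connected_components(sub))
                for v in c}
        if len({comp[r] for r in ids}) == 1:
            break
        radius += 1
        any_growth = False
        for r in ids:
            new = set()
            for v in frontier[r]:
                new |= set(u.neighbors(v))
            new -= terr[r]
            if new:
                any_growth = True
            terr[r] |= new
            frontier[r] = new
        if not any_growth:
            break
    return set().union(*terr.values())


def analyze_network(
    graph: KnowledgeGraph, roots: SeedList,
    options: Optional[BuildOptions] = None,
    library: Optional[Sequence[CanonicalPathway]] = None,
    universe_size: Optional[int] = None,
) -> list[NetworkFragment]:
    """Super-network construction followed by cyclical edge-disjoint
    fragmentation and statistical ranking.

    Fragments are grown breadth-first around the roots (visited in
    descending root-neighbor count, ties by id), each capped at
    ``fragment_size`` nodes; an edge consumed by a fragment is never reused,
    nodes may recur.  Each fragment is scored (p, z, g, seed count,
    canonical-pathway count) and the list is ranked by the chosen key
    (default g-score, descending).
    """
    options = options or BuildOptions()
    ids = _mapped_roots(graph, roots)
    R = len(ids)
    N = universe_size if universe_size is not None else graph.connected_node_count()
    super_nodes = _super_network(graph, ids, options.max_radius)
    dg = graph.simple_digraph().subgraph(super_nodes)
    pool: set[tuple[str, str]] = {(u, v) for u, v in dg.edges()}
    adj: dict[str, set[str]] = {n: set() for n in super_nodes}
    for u_, v_ in pool:
        adj[u_].add(v_)
        adj[v_].add(u_)
    rootset = set(ids)
    order = sorted(ids, key=lambda r: (-len(adj.get(r, set()) & rootset), r))
    fragments: list[NetworkFragment] = []

    def pool_neighbors(x: str) -> set[str]:
        out = set()
        for y in adj.get(x, ()):  # candidates; verify against live pool
            if (x, y) in pool or (y, x) in pool:
                out.add(y)
        return out

    progress = True
    while progress and pool:
        progress = False
        for root in order:
            if not pool:
                break
            if not pool_neighbors(root):
                continue
            nodes = [root]
            nodeset = {root}
            i = 0
            while i < len(nodes) and len(nodeset) < options.fragment_size:
                for y in sorted(pool_neighbors(nodes[i])):
                    if y not in nodeset:
                        nodes.append(y)
                        nodeset.add(y)
                        if len(nodeset) >= options.fragment_size:
                            break
                i += 1
            edges = {(x, y) for (x, y) in pool
                     if x in nodeset and y in nodeset}
            if not edges:
                continue
            pool -= edges
            used = {x for e in edges for x in e}
            frag = NetworkFragment(
                nodes=frozenset(used), edges=frozenset(edges),
                seed_nodes=frozenset(used & rootset),
                label=f"fragment around {root}")
            fragments.append(score_fragment(frag, R=R, N=N, library=library,
                                            pathway_bonus=options.pathway_bonus))
            progress = True
    return rank_fragments(fragments, key=options.rank_key)


def rank_fragments(fragments: list[NetworkFragment],
                   key: str = "g") -> list[NetworkFragment]:
    def sort_key(f: NetworkFragment):
        if key == "g":
            primary = -(f.g if f.g is not None else -math.inf)
        elif key == "z":
            primary = -(f.z if f.z is not None else -math.inf)
        elif key == "p":
            primary = f.p if f.p is not None else 1.0
        elif key == "seeds":
            primary = -len(f.seed_nodes)
        else:
            raise ValueError(f"unknown ranking key {key!r}")
        return (primary, f.p if f.p is not None else 1.0,
                min(f.nodes) if f.nodes else "")
    return sorted(fragments, key=sort_key)


# -- AN (TF) / AN (receptors) ---------------------------------------------

def analyze_network_directed(
    graph: KnowledgeGraph, roots: SeedList, mode: str = "tf",
    options: Optional[BuildOptions] = None,
) -> list[NetworkFragment]:
    """One network per transcription factor (mode='tf') built from all
    shortest directed paths from the closest receptor(s) to the TF, or one
    per receptor (mode='receptor') toward the closest TF(s).  Paths are
    directional, so the two modes are not reciprocal.  Receptor ties at the
    minimum distance are all retained.
    """
    options = options or BuildOptions()
    ids = _mapped_roots(graph, roots)
    closure = _super_network(graph, ids, options.max_radius)
    tfs = sorted(n for n in closure
                 if graph.object(n).object_class == "transcription_factor")
    receptors = sorted(n for n in closure
                       if graph.object(n).object_class == "receptor")
    if mode == "tf":
        anchors, partners = tfs, receptors
    elif mode == "receptor":
        anchors, partners = receptors, tfs
    else:
        raise ValueError(f"mode must be 'tf' or 'receptor', got {mode!r}")
    dg = graph.simple_digraph()
    rootset = set(ids)
    fragments: list[NetworkFragment] = []
    for anchor in anchors:
        # distances along the signal flow: receptor -> ... -> TF
        if mode == "tf":
            dist = nx.single_source_shortest_path_length(
                dg.reverse(copy=False), anchor)
        else:
            dist = nx.single_source_shortest_path_length(dg, anchor)
        cand = {p: dist[p] for p in partners if p in dist and p != anchor}
        if not cand:
            continue
        dmin = min(cand.values())
        closest = sorted(p for p, d in cand.items() if d == dmin)
        if mode == "tf":
            pairs = [(p, anchor) for p in closest]
        else:
            pairs = [(anchor, p) for p in closest]
        nodes, edges = _all_shortest_path_union(dg, pairs, None)
        if options.enrich_with_ligands_targets:
            rec_nodes = closest if mode == "tf" else [anchor]
            tf_nodes = [anchor] if mode == "tf" else closest
            for rec in rec_nodes:
                for lig in sorted(graph.neighbors(rec, "in")):
                    if graph.object(lig).object_class == "ligand":
                        nodes.add(lig)
                        edges.add((lig, rec))
            for tf in tf_nodes:
                for _, tgt, data in graph.nx_graph.out_edges(tf, data=True):
                    if data["interaction"].mechanism == "transcription_regulation" and tgt != tf:
                        nodes.add(tgt)
                        edges.add((tf, tgt))
        fragments.append(NetworkFragment(
            nodes=frozenset(nodes), edges=frozenset(edges),
            seed_nodes=frozenset(nodes & rootset),
            label=f"{mode}:{anchor}",
            note=f"closest partners: {','.join(closest)} at distance {dmin}"))
    return sorted(fragments, key=lambda f: (-len(f.seed_nodes), f.label))


# -- TR --------------------------------------------------------------------

def transcription_regulation(graph: KnowledgeGraph,
                             roots: SeedList) -> list[NetworkFragment]:
    """One network per immediate transcription factor of the list.

    An immediate TF is any node with a transcription_regulation edge into at
    least one root.  Its network contains the roots upstream of it (reachable
    to the TF through root-only intermediaries) plus its root targets.
    """
    ids = _mapped_roots(graph, roots)
    rootset = set(ids)
    tf_targets: dict[str, set[str]] = {}
    for e in graph.interactions():
        if (e.mechanism == "transcription_regulation"
                and e.target in rootset and e.source != e.target):
            tf_targets.setdefault(e.source, set()).add(e.target)
    fragments: list[NetworkFragment] = []
    dg = graph.simple_digraph()
    for tf in sorted(tf_targets):
        allowed = rootset | {tf}
        sub = dg.subgraph(allowed)
        upstream = {r for r in rootset
                    if r != tf and nx.has_path(sub, r, tf)}
        nodes = {tf} | upstream | tf_targets[tf]
        frag = _induced_fragment(graph, nodes, rootset & nodes,
                                 label=f"TR:{tf}")
        fragments.append(frag)
    return sorted(fragments, key=lambda f: (-len(f.seed_nodes), f.label))


# -- model canonical pathways ---------------------------------------------

def load_pathway_library(path: str | Path,
                         graph: Optional[KnowledgeGraph] = None
                         ) -> list[CanonicalPathway]:
    """TSV ``pathway_id<TAB>name<TAB>node1|node2|...``; when a graph is
    given, every consecutive chain step must be a directed edge in it."""
    out = []
    for lineno, ln in enumerate(Path(path).read_text().splitlines(), 1):
        if not ln.strip() or ln.startswith("#"):
            continue
        parts = ln.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"{path}:{lineno}: expected id, name, chain")
        chain = tuple(x for x in parts[2].split("|") if x)
        pw = CanonicalPathway(pathway_id=parts[0], name=parts[1], chain=chain)
        if graph is not None:
            for u, v in pw.steps:
                if not graph.nx_graph.has_edge(u, v):
                    raise ValueError(
                        f"{path}:{lineno}: chain step {u}->{v} missing "
                        "from graph")
        out.append(pw)
    return out


def model_canonical_pathways(
    graph: KnowledgeGraph, roots: SeedList,
    library: Sequence[CanonicalPathway],
    attach_list_objects: bool = False,
) -> list[NetworkFragment]:
    """Per qualifying root, merge every canonical pathway containing it into
    one network; rank by seed count, ties by smaller size.

    ``attach_list_objects`` additionally pulls in list members regulated by
    a transcription factor already on the network or binding a receptor
    already on the network.
    """
    if not library:
        raise ValueError("empty pathway library")
    ids = _mapped_roots(graph, roots)
    rootset = set(ids)
    fragments: list[NetworkFragment] = []
    for root in ids:
        mine = [pw for pw in library if root in pw.chain]
        if not mine:
            continue
        nodes: set[str] = set()
        edges: set[tuple[str, str]] = set()
        for pw in mine:
            nodes |= set(pw.chain)
            edges |= set(pw.steps)
        if attach_list_objects:
            for present in sorted(nodes):
                cls = graph.object(present).object_class if present in graph else ""
                if cls == "transcription_factor":
                    for _, tgt, data in graph.nx_graph.out_edges(present, data=True):
                        if (data["interaction"].mechanism == "transcription_regulation"
                                and tgt in rootset):
                            nodes.add(tgt)
                            edges.add((present, tgt))
                elif cls == "receptor":
                    for nb in graph.neighbors(present, "both"):
                        if nb in rootset and graph.has_connection(nb, present):
                            nodes.add(nb)
        fragments.append(NetworkFragment(
            nodes=frozenset(nodes), edges=frozenset(edges),
            seed_nodes=frozenset(nodes & rootset),
            label=f"canonical:{root}",
            pathways_count=len(mine)))
    # two-key rule: more list objects first, then the smaller network
    return sorted(fragments,
                  key=lambda f: (-len(f.seed_nodes), f.size, f.label))


# -- scoring ---------------------------------------------------------------

def g_score(z: float, pathways_count: int,
            pathway_bonus: float = DEFAULT_PATHWAY_BONUS) -> float:
    """g = z + bonus * (number of canonical pathways on the network)."""
    return z + pathway_bonus * pathways_count


def count_canonical_fragments(fragment: NetworkFragment,
                              library: Sequence[CanonicalPathway]) -> int:
    """Number of distinct library pathways contributing at least one
    consecutive step (both nodes and the connecting edge) to the fragment."""
    count = 0
    for pw in library:
        for u, v in pw.steps:
            if u in fragment.nodes and v in fragment.nodes and (u, v) in fragment.edges:
                count += 1
                break
    return count


def score_fragment(
    fragment: NetworkFragment, R: int, N: int,
    pathway_bonus: float = DEFAULT_PATHWAY_BONUS,
    library: Optional[Sequence[CanonicalPathway]] = None,
) -> NetworkFragment:
    """Attach p, z and g to a fragment.

    Counts: r = seed nodes on the fragment, n = fragment size, R = mapped
    input list size, N = universe after filtration.  When the null is
    degenerate (sigma = 0) z and g are left unset but p is still reported.
    """
    if N < fragment.size:
        raise ValueError("universe smaller than the fragment")
    if R > N:
        raise ValueError("input list larger than the universe")
    r = min(len(fragment.seed_nodes), R)
    counts = EnrichmentCounts(r=r, n=fragment.size, R=R, N=N)
    summ = hypergeom_summary(counts)
    pathways = (count_canonical_fragments(fragment, library)
                if library is not None else fragment.pathways_count)
    z = summ.z
    g = g_score(z, pathways, pathway_bonus) if z is not None else None
    return NetworkFragment(
        nodes=fragment.nodes, edges=fragment.edges,
        seed_nodes=fragment.seed_nodes, label=fragment.label,
        pathways_count=pathways, p=upper_tail_pvalue(counts), z=z, g=g,
        components=fragment.components, isolated=fragment.isolated,
        note=fragment.note)


def ranking_table(fragments: Sequence[NetworkFragment]) -> pd.DataFrame:
    """Ranking table mirroring the standard analyze-network report."""
    rows = []
    for i, f in enumerate(fragments, start=1):
        rows.append({
            "No": i,
            "Network": f.label or ", ".join(sorted(f.nodes)[:5]),
            "Total nodes": f.size,
            "Seed nodes": len(f.seed_nodes),
            "Pathways": f.pathways_count,
            "p-Value": f.p if f.p is not None else math.nan,
            "zScore": f.z if f.z is not None else math.nan,
            "gScore": f.g if f.g is not None else math.nan,
        })
    return pd.DataFrame(rows, columns=["No", "Network", "Total nodes",
                                       "Seed nodes", "Pathways", "p-Value",
                                       "zScore", "gScore"])
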