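"""Hidden-nodes topological significance scoring.

Given a set K of experimentally derived seed nodes inside a global directed
network of N nodes, the method asks which nodes (often absent from the
experimental list, hence "hidden") sit on the shortest directed paths among
the seeds more often than chance allows.

For a candidate node i and a seed j, count the counterpart nodes t for
which i is strictly internal to at least one minimum-length directed path
j->t or t->j: over the whole network this count is N_ij (<= N-2), over the
other seeds it is K_ij (<= K-1).  Each counterpart is counted once, however
many shortest paths or orientations involve i.  Treating the N_ij marked
counterparts as marked objects and the K-1 seed counterparts as a draw, the
null probability of seeing K_ij or more marked ones is the upper
hypergeometric tail p_ij = P(X >= K_ij | n = K-1, R = N_ij, N' = N-2).
The topological significance score of node i is min_j p_ij; unlike
betweenness centrality the count ignores how many shortest paths bypass i,
which normalizes away raw hub degree.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, Optional, Tuple

import networkx as nx

from .graph import KnowledgeGraph, SeedList
from .stats import EnrichmentCounts, bh_fdr, upper_tail_pvalue

__all__ = [
    "CSSPN",
    "TopoScore",
    "shortest_path_network",
    "pair_membership_counts",
    "topo_pvalue",
    "score_hidden_nodes",
]


@dataclass
class CSSPN:
    """Condition-specific shortest-path network over a seed set K.

    ``members`` is the union of all nodes on all minimum-length directed
    paths between ordered seed pairs; ``path_edges`` the directed edges those
    paths use; ``classification`` labels each member internal (strictly
    inside some used path), else source / target / source_and_target by the
    endpoints it serves.
    """

    seed_set: frozenset[str]
    members: frozenset[str]
    path_edges: frozenset[tuple[str, str]]
    classification: dict[str, str]

    @property
    def internal_nodes(self) -> set[str]:
        return {n for n, c in self.classification.items() if c == "internal"}


@dataclass
class TopoScore:
    node_id: str
    role: str
    per_seed: dict[str, tuple[int, int, float]]  # j -> (N_ij, K_ij, p_ij)
    score: float
    best_seed: str
    q: float | None = None


class _DistanceCache:
    """Lazy BFS distance maps, forward and backward, per node."""

    def __init__(self, digraph: nx.DiGraph) -> None:
        self._g = digraph
        self._rev = digraph.reverse(copy=False)
        self._fwd: Dict[str, dict] = {}
        self._bwd: Dict[str, dict] = {}

    def fwd(self, node: str) -> dict:
        if node not in self._fwd:
            self._fwd[node] = nx.single_source_shortest_path_length(self._g, node)
        return self._fwd[node]

    def bwd(self, node: str) -> dict:
        if node not in self._bwd:
            self._bwd[node] = nx.single_source_shortest_path_length(self._rev, node)
        return self._bwd[node]


def shortest_path_network(graph: KnowledgeGraph, seeds: SeedList) -> CSSPN:
    """Union of all minimum-length directed paths between ordered seed pairs.

    Unreachable pairs contribute nothing; when several equal-length routes
    exist, every node and edge of every route is included.
    """
    K = [s for s in seeds.ids if s in graph]
    if len(K) < 2:
        raise ValueError("need at least 2 mapped seed nodes")
    dg = graph.simple_digraph()
    cache = _DistanceCache(dg)
    members: set[str] = set()
    edges: set[tuple[str, str]] = set()
    is_source: set[str] = set()
    is_target: set[str] = set()
    strictly_internal: set[str] = set()
    for a in K:
        da = cache.fwd(a)
        for b in K:
            if a == b or b not in da:
                continue
            d = da[b]
            db = cache.bwd(b)
            on_path = {v for v, dav in da.items()
                       if v in db and dav + db[v] == d}
            members |= on_path
            strictly_internal |= {v for v in on_path if v not in (a, b)}
            is_source.add(a)
            is_target.add(b)
            for u in on_path:
                for v in dg.successors(u):
                    if v in on_path and da[u] + 1 + db.get(v, 1 << 30) == d:
                        edges.add((u, v))
    classification: dict[str, str] = {}
    for v in members:
        if v in strictly_internal:
            classification[v] = "internal"
        elif v in is_source and v in is_target:
            classification[v] = "source_and_target"
        elif v in is_source:
            classification[v] = "source"
        else:
            classification[v] = "target"
    return CSSPN(seed_set=frozenset(K), members=frozenset(members),
                 path_edges=frozenset(edges), classification=classification)


def _counterparts_through(cache: _DistanceCache, i: str, j: str,
                          candidates: Iterable[str]) -> set[str]:
    """Counterparts t for which i is strictly internal to >=1 shortest
    directed path j->t or t->j."""
    fj, bj = cache.fwd(j), cache.bwd(j)
    fi, bi = cache.fwd(i), cache.bwd(i)
    d_ji = fj.get(i)   # j -> i
    d_ij = bj.get(i)   # i -> j
    out: set[str] = set()
    for t in candidates:
        if t == i or t == j:
            continue
        # i on a shortest j -> t path: d(j,i) + d(i,t) == d(j,t), i != t
        if d_ji is not None and t in fi and t in fj and d_ji + fi[t] == fj[t]:
            out.add(t)
            continue
        # i on a shortest t -> j path: d(t,i) + d(i,j) == d(t,j)
        if d_ij is not None and t in bi and t in bj and bi[t] + d_ij == bj[t]:
            out.add(t)
    return out


def pair_membership_counts(
    graph: KnowledgeGraph, i: str, j: str, seeds: SeedList,
    _cache: Optional[_DistanceCache] = None,
) -> Tuple[int, int]:
    """(N_ij, K_ij): counterpart counts over the whole graph and over the
    seed set.  A counterpart is counted once regardless of orientation or
    path multiplicity."""
    if i not in graph or j not in graph:
        raise KeyError(f"unknown node in pair ({i!r}, {j!r})")
    if i == j:
        raise ValueError("i and j must differ")
    cache = _cache or _DistanceCache(graph.simple_digraph())
    hit = _counterparts_through(cache, i, j, graph.node_ids)
    K_ij = len(hit & (set(seeds.ids) - {i, j}))
    return len(hit), K_ij


def topo_pvalue(N: int, K: int, N_ij: int, K_ij: int,
                universe: Optional[int] = None,
                selection: Optional[int] = None) -> float:
    """Cumulative probability of i appearing in K_ij or more seed-pair
    shortest-path networks by chance.

    Identical to the upper hypergeometric tail with r = K_ij, draw size
    n = K-1, marked R = N_ij, universe N' = N-2.  ``universe`` / ``selection``
    override N-2 / K-1 (used for the reachable-only variant and for seeds
    already on the experimental list).
    """
    n = selection if selection is not None else K - 1
    NN = universe if universe is not None else N - 2
    if not (0 <= K_ij <= min(N_ij, n)):
        raise ValueError(f"need 0 <= K_ij <= min(N_ij, {n}), got K_ij={K_ij}")
    if N_ij > NN:
        raise ValueError(f"N_ij={N_ij} exceeds universe {NN}")
    return upper_tail_pvalue(EnrichmentCounts(r=K_ij, n=n, R=N_ij, N=NN))


def score_hidden_nodes(
    graph: KnowledgeGraph, seeds: SeedList,
    candidates: str = "internal_nodes_of_CSSPN",
    alpha: float = 0.05,
    reachable_only: bool = False,
) -> list[TopoScore]:
    """Score candidate nodes by the minimum per-seed p_ij.

    Candidates default to the internal nodes of the CSSPN (the "hidden"
    intermediaries); ``all_nodes`` scores everything.  For a candidate that
    is itself a seed the selection shrinks to K-2 (it cannot be its own
    counterpart).  ``reachable_only`` replaces the N-2 universe by the
    number of counterparts actually connected to j, for badly disconnected
    graphs.  Output ascending by score, ties by node id; q is BH over the
    scored candidates.
    """
    K = [s for s in seeds.ids if s in graph]
    if len(K) < 2:
        raise ValueError("need at least 2 mapped seed nodes")
    csspn = shortest_path_network(graph, seeds)
    if candidates == "internal_nodes_of_CSSPN":
        cand = sorted(csspn.internal_nodes)
    elif candidates == "all_nodes":
        cand = [n for n in graph.node_ids if n not in set(K)] + sorted(
            set(K) & set(graph.node_ids))
        cand = sorted(set(cand))
    else:
        raise ValueError(f"unknown candidate mode {candidates!r}")
    if not cand:
        return []
    N = len(graph)
    cache = _DistanceCache(graph.simple_digraph())
    kset = set(K)
    scores: list[TopoScore] = []
    for i in cand:
        per_seed: dict[str, tuple[int, int, float]] = {}
        for j in K:
            if j == i:
                continue
            hit = _counterparts_through(cache, i, j, graph.node_ids)
            n_ij = len(hit)
            k_ij = len(hit & (kset - {i, j}))
            selection = len(kset - {i, j})
            if selection == 0:
                continue
            if reachable_only:
                fj, bj = cache.fwd(j), cache.bwd(j)
                reach = (set(fj) | set(bj)) - {i, j}
                uni = max(len(reach), n_ij, selection)
            else:
                uni = N - 2
            p_ij = topo_pvalue(N, len(K), n_ij, k_ij,
                               universe=uni, selection=selection)
            per_seed[j] = (n_ij, k_ij, p_ij)
        if not per_seed:
            continue
        best_seed = min(per_seed, key=lambda j: (per_seed[j][2], j))
        scores.append(TopoScore(
            node_id=i,
            role=csspn.classification.get(i, "outside"),
            per_seed=per_seed,
            score=per_seed[best_seed][2],
            best_seed=best_seed,
        ))
    qs = bh_fdr([s.score for s in scores])
    for s, q in zip(scores, qs):
        s.q = float(q)
    scores.sort(key=lambda s: (s.score, s.node_id))
    return scores
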