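"""One-step over/under-connectivity analysis.

For a candidate protein with global degree R in an interactome of N
connected proteins, the number of distinct seed-list proteins among its
one-step neighbors follows the hypergeometric null: the expected count is
mu = n*R/N for a seed list of effective size n.  The connectivity ratio
actual/expected quantifies "functional relevance"; significance is the
upper hypergeometric tail and a z-score in units of the null dispersion.
Candidates are reported per protein class (transcription factors,
receptors, ligands, kinases, phosphatases, proteases, enzymes, other) and
ranked by descending ratio within each class.

The tested object is excluded from both the draw and the universe
(n = |seeds \\ {object}|, N counts the other nodes): invisible at
interactome scale, but required for the small-graph enumeration identity
P(X >= r) = #{seed placements with >= r neighbors} / C(N, n).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import pandas as pd

from .graph import KnowledgeGraph, SeedList
from .stats import (EnrichmentCounts, bh_fdr, hypergeom_summary,
                    lower_tail_pvalue, upper_tail_pvalue)

__all__ = [
    "ConnectivityResult",
    "InteractomeReport",
    "CLASS_SECTIONS",
    "actual_connectivity",
    "connectivity_stats_from_counts",
    "connectivity_test",
    "scan_overconnected",
    "between_set_connectivity",
    "report_table",
]

#: class sections in report order
CLASS_SECTIONS = ("transcription_factor", "receptor", "ligand", "kinase",
                  "phosphatase", "protease", "enzyme", "other")


@dataclass
class ConnectivityResult:
    object_id: str
    object_class: str
    actual: int
    n: int
    R: int
    N: int
    expected: float
    ratio: float
    p_over: float
    p_under: float
    z: float | None
    q: float | None = None  # BH-adjusted p_over, filled by scan


@dataclass
class InteractomeReport:
    sections: dict[str, list[ConnectivityResult]]
    universe_size: int
    direction: str
    skipped: dict[str, str]

    def all_results(self) -> list[ConnectivityResult]:
        out: list[ConnectivityResult] = []
        for sec in CLASS_SECTIONS:
            out.extend(self.sections.get(sec, []))
        return out


def actual_connectivity(graph: KnowledgeGraph, object_id: str,
                        seeds: SeedList, direction: str = "both") -> int:
    """Distinct seed-list nodes adjacent to the object (object itself never
    counts, even when it sits on the seed list)."""
    nbrs = graph.neighbors(object_id, direction)
    seed_set = set(seeds.ids)
    seed_set.discard(object_id)
    return len(nbrs & seed_set)


def connectivity_stats_from_counts(
    r: int, n: int, R: int, N: int,
    object_id: str = "", object_class: str = "other",
    literal_under: bool = False,
) -> ConnectivityResult:
    """Fill a connectivity row directly from the (Actual, n, R, N) integers.

    This is the arithmetic behind every report column: expected = n*R/N,
    ratio = actual/expected, p from the upper hypergeometric tail, z from
    the exact mean/dispersion.  Used both by the graph-driven test and for
    re-deriving published tables from their printed integer columns.
    """
    counts = EnrichmentCounts(r=r, n=n, R=R, N=N)
    summ = hypergeom_summary(counts)
    expected = summ.mu
    if expected == 0:
        raise ValueError("expected connectivity is zero (R = 0 or n = 0)")
    return ConnectivityResult(
        object_id=object_id, object_class=object_class,
        actual=r, n=n, R=R, N=N,
        expected=expected, ratio=r / expected,
        p_over=upper_tail_pvalue(counts),
        p_under=lower_tail_pvalue(counts, literal_paper_mode=literal_under),
        z=summ.z,
    )


def connectivity_test(
    graph: KnowledgeGraph, object_id: str, seeds: SeedList,
    universe_size: Optional[int] = None, direction: str = "both",
    literal_under: bool = False,
) -> ConnectivityResult:
    """Over/under-connectivity of one object against a seed list.

    ``universe_size`` defaults to the number of connected nodes in the
    graph minus one (the object itself is not a candidate neighbor).
    Objects with zero degree in the chosen direction cannot be tested.
    """
    obj = graph.object(object_id)
    R = graph.degree(object_id, direction)
    if R == 0:
        raise ValueError(f"{object_id!r} has no interactions ({direction})")
    if universe_size is None:
        universe_size = graph.connected_node_count() - 1
    if universe_size < 2:
        raise ValueError("universe must contain at least 2 nodes")
    n = len(set(seeds.ids) - {object_id})
    r = actual_connectivity(graph, object_id, seeds, direction)
    section = obj.object_class if obj.object_class in CLASS_SECTIONS else "other"
    return connectivity_stats_from_counts(
        r=r, n=n, R=R, N=universe_size,
        object_id=object_id, object_class=section,
        literal_under=literal_under,
    )


def scan_overconnected(
    graph: KnowledgeGraph, seeds: SeedList,
    scope: Optional[Iterable[str]] = None,
    direction: str = "both",
    universe_size: Optional[int] = None,
    literal_under: bool = False,
) -> InteractomeReport:
    """Run the connectivity test on every node (or every node of the given
    classes), FDR-correct within each class section, and sort each section
    by descending ratio, ties by ascending p then id."""
    if not seeds.ids:
        raise ValueError("empty seed list")
    if universe_size is None:
        universe_size = graph.connected_node_count() - 1
    wanted = set(scope) if scope is not None else None
    sections: dict[str, list[ConnectivityResult]] = {s: [] for s in CLASS_SECTIONS}
    skipped: dict[str, str] = {}
    for nid in graph.node_ids:
        obj = graph.object(nid)
        section = obj.object_class if obj.object_class in CLASS_SECTIONS else "other"
        if wanted is not None and obj.object_class not in wanted:
            continue
        if graph.degree(nid, direction) == 0:
            skipped[nid] = "no interactions in chosen direction"
            continue
        sections[section].append(connectivity_test(
            graph, nid, seeds, universe_size=universe_size,
            direction=direction, literal_under=literal_under))
    for sec, results in sections.items():
        if results:
            qs = bh_fdr([res.p_over for res in results])
            for res, q in zip(results, qs):
                res.q = float(q)
        results.sort(key=lambda res: (-res.ratio, res.p_over, res.object_id))
    return InteractomeReport(sections=sections, universe_size=universe_size,
                             direction=direction, skipped=skipped)


def between_set_connectivity(
    graph: KnowledgeGraph, set_a: SeedList, set_b: SeedList,
    direction: str = "undirected",
) -> dict:
    """Directional connectivity between two protein lists.

    Counts distinct ordered node pairs with a direct edge A->B and B->A
    (asymmetry of the two counts indicates which list regulates which) and
    tests the count for the requested direction against the hypergeometric
    null where the universe is all ordered node pairs, the marked pairs are
    the graph's connected ordered pairs, and the draw is the |A|x|B| pair
    candidates.
    """
    a = set(set_a.ids) & set(graph.node_ids)
    b = set(set_b.ids) & set(graph.node_ids)
    if not a or not b:
        raise ValueError("both sets must intersect the graph")
    overlap = a & b
    a_to_b = {(x, y) for x in a for y in b
              if x != y and graph.nx_graph.has_edge(x, y)}
    b_to_a = {(x, y) for x in b for y in a
              if x != y and graph.nx_graph.has_edge(x, y)}
    pairs_connected = {frozenset(p) for p in a_to_b | b_to_a}
    V = len(graph)
    N = V * (V - 1)  # ordered pairs that could carry an edge
    # marked pairs: distinct connected ordered pairs in the whole graph
    R = sum(1 for _ in _connected_ordered_pairs(graph))
    if direction == "A_upstream_of_B":
        r = len(a_to_b)
        n = sum(1 for x in a for y in b if x != y)
    elif direction == "B_upstream_of_A":
        r = len(b_to_a)
        n = sum(1 for x in b for y in a if x != y)
    elif direction == "undirected":
        r = len(pairs_connected)
        n = sum(1 for x in a for y in b if x != y)
    else:
        raise ValueError(f"unknown direction {direction!r}")
    n = min(n, N)
    counts = EnrichmentCounts(r=min(r, min(n, R)), n=n, R=R, N=N)
    return {
        "edges_a_to_b": len(a_to_b),
        "edges_b_to_a": len(b_to_a),
        "connected_pairs": len(pairs_connected),
        "overlap": sorted(overlap),
        "direction": direction,
        "counts": counts,
        "p": upper_tail_pvalue(counts),
    }


def _connected_ordered_pairs(graph: KnowledgeGraph):
    seen = set()
    for e in graph.interactions():
        if e.source != e.target and (e.source, e.target) not in seen:
            seen.add((e.source, e.target))
            yield e.source, e.target


def report_table(report: InteractomeReport) -> pd.DataFrame:
    """Flat table mirroring the classic over-connectivity report columns."""
    rows = []
    for sec in CLASS_SECTIONS:
        for res in report.sections.get(sec, []):
            rows.append({
                "class": sec,
                "object": res.object_id,
                "actual": res.actual,
                "n": res.n,
                "R": res.R,
                "N": res.N,
                "expected": res.expected,
                "ratio": res.ratio,
                "p_value": res.p_over,
                "z_score": res.z if res.z is not None else math.nan,
                "q_value": res.q if res.q is not None else math.nan,
            })
    return pd.DataFrame(rows, columns=["class", "object", "actual", "n", "R",
                                       "N", "expected", "ratio", "p_value",
                                       "z_score", "q_value"])
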