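"""Ontology enrichment analysis.

Maps a protein list onto the terms of an ontology (gene-set collection),
computes an upper-tail hypergeometric p-value per term against a
configurable background universe, corrects with Benjamini-Hochberg, and
ranks terms by p-value.  The choice of universe matters: the test is
competitive, so N should reflect what the assay could have detected
(the whole graph, the ontology's protein content, or a custom list).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd

from .graph import KnowledgeGraph, SeedList
from .stats import EnrichmentCounts, bh_fdr, upper_tail_pvalue

__all__ = [
    "OntologyTerm",
    "Ontology",
    "EnrichmentRow",
    "load_gmt",
    "save_gmt",
    "resolve_universe",
    "run_enrichment",
    "enrichment_report",
]


@dataclass
class OntologyTerm:
    term_id: str
    name: str
    members: frozenset[str]
    parent_ids: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"term {self.term_id!r} has no members")
        if self.term_id in self.parent_ids:
            raise ValueError(f"term {self.term_id!r} is its own parent")
        self.members = frozenset(self.members)
        self.parent_ids = frozenset(self.parent_ids)


@dataclass
class Ontology:
    """A named collection of terms; one 'dimension' of functionality."""

    name: str
    terms: list[OntologyTerm]

    def __post_init__(self) -> None:
        ids = [t.term_id for t in self.terms]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate term ids in ontology")

    @property
    def union_members(self) -> frozenset[str]:
        out: set[str] = set()
        for t in self.terms:
            out |= t.members
        return frozenset(out)

    def __len__(self) -> int:
        return len(self.terms)


@dataclass
class EnrichmentRow:
    term_id: str
    term_name: str
    counts: EnrichmentCounts
    p: float
    q: float
    overlap_ids: frozenset[str]


def load_gmt(path: str | Path, name: Optional[str] = None) -> Ontology:
    """Read a GMT file: ``term<TAB>description<TAB>member1<TAB>member2...``

    Duplicate members within a line are collapsed; duplicate term names get
    a numeric suffix so term ids stay unique.
    """
    path = Path(path)
    terms: list[OntologyTerm] = []
    seen: dict[str, int] = {}
    for lineno, ln in enumerate(path.read_text().splitlines(), start=1):
        if not ln.strip():
            continue
        parts = ln.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(
                f"{path}:{lineno}: GMT line needs term, description and "
                f">=1 member (got {len(parts)} columns)")
        raw_id, desc = parts[0], parts[1]
        members = frozenset(m for m in parts[2:] if m)
        count = seen.get(raw_id, 0)
        seen[raw_id] = count + 1
        term_id = raw_id if count == 0 else f"{raw_id}.{count + 1}"
        terms.append(OntologyTerm(term_id=term_id, name=desc or raw_id,
                                  members=members))
    return Ontology(name=name or path.stem, terms=terms)


def save_gmt(ontology: Ontology, path: str | Path) -> None:
    with open(path, "w") as fh:
        for t in ontology.terms:
            fh.write("\t".join([t.term_id, t.name, *sorted(t.members)]) + "\n")


def resolve_universe(
    graph: KnowledgeGraph,
    ontology: Ontology,
    mode: str = "all_graph_nodes",
    custom_ids: Optional[Iterable[str]] = None,
) -> set[str]:
    """Pick the background set N for the enrichment test.

    all_graph_nodes : every node with at least one interaction
    ontology_union  : the ontology's protein content, restricted to the graph
    custom          : a user list, restricted to the graph (dropped ids are
                      simply absent from the result)
    """
    if mode == "all_graph_nodes":
        universe = {n for n in graph.node_ids if graph.degree(n, "both") > 0}
    elif mode == "ontology_union":
        universe = set(ontology.union_members) & set(graph.node_ids)
    elif mode == "custom":
        if custom_ids is None:
            raise ValueError("custom universe mode requires custom_ids")
        universe = set(custom_ids) & set(graph.node_ids)
    else:
        raise ValueError(f"unknown universe mode {mode!r}")
    if not universe:
        raise ValueError("resolved universe is empty")
    return universe


def run_enrichment(
    seeds: SeedList,
    ontology: Ontology,
    universe: set[str],
    min_overlap: int = 1,
) -> list[EnrichmentRow]:
    """Test every term for over-representation of the seed list.

    Per term: r = |list ∩ term ∩ universe|, n = |list ∩ universe|,
    R = |term ∩ universe|, N = |universe|; p is the upper hypergeometric
    tail, q the BH adjustment over the terms that survive the min_overlap
    filter (filtering happens before FDR so the family is the set of
    actually testable terms).  Output sorted by p, ties by term id.
    """
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    eff_list = set(seeds.ids) & universe
    if not eff_list:
        raise ValueError("list does not intersect universe")
    n = len(eff_list)
    N = len(universe)
    tested: list[tuple[OntologyTerm, EnrichmentCounts, frozenset[str]]] = []
    for term in ontology.terms:
        term_in_uni = term.members & universe
        overlap = frozenset(term_in_uni & eff_list)
        if len(overlap) < min_overlap:
            continue
        counts = EnrichmentCounts(r=len(overlap), n=n, R=len(term_in_uni), N=N)
        tested.append((term, counts, overlap))
    if not tested:
        return []
    pvals = [upper_tail_pvalue(c) for _, c, _ in tested]
    qvals = bh_fdr(pvals)
    rows = [
        EnrichmentRow(term_id=t.term_id, term_name=t.name, counts=c,
                      p=p, q=q, overlap_ids=o)
        for (t, c, o), p, q in zip(tested, pvals, qvals)
    ]
    rows.sort(key=lambda r: (r.p, r.term_id))
    return rows


def enrichment_report(rows: Sequence[EnrichmentRow],
                      top_k: Optional[int] = None) -> pd.DataFrame:
    """Tabular report; the ``neg_log10_p`` column is the bar length used in
    the usual enrichment bar charts."""
    if top_k is not None:
        rows = rows[:top_k]
    return pd.DataFrame(
        [{
            "term": r.term_id,
            "name": r.term_name,
            "r": r.counts.r,
            "n": r.counts.n,
            "R": r.counts.R,
            "N": r.counts.N,
            "p": r.p,
            "q": r.q,
            "neg_log10_p": -math.log10(r.p) if r.p > 0 else math.inf,
            "overlap": "|".join(sorted(r.overlap_ids)),
        } for r in rows],
        columns=["term", "name", "r", "n", "R", "N", "p", "q",
                 "neg_log10_p", "overlap"],
    )
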