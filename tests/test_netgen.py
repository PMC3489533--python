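"""Network builders, fragment decomposition and prioritization scores."""

import math

import networkx as nx
import numpy as np
import pytest

from protnet.graph import Interaction, KnowledgeGraph, NetworkObject
from protnet.netgen import (BuildOptions, CanonicalPathway, analyze_network,
                            analyze_network_directed, auto_expand,
                            count_canonical_fragments, direct_interactions,
                            expand_by_one, g_score, load_pathway_library,
                            model_canonical_pathways, ranking_table,
                            score_fragment, shortest_path_build,
                            transcription_regulation)
from protnet.simulate import FixtureSpec, generate_graph
from .conftest import build_graph, seed_list


class TestDirectInteractions:
    def test_no_mutual_edges_all_isolated(self):
        g = build_graph([("a", "x"), ("b", "y"), ("c", "z")])
        frag = direct_interactions(g, seed_list("a", "b", "c"))
        assert frag.edges == frozenset() and frag.isolated == {"a", "b", "c"}

    def test_triangle_plus_isolates(self):
        g = build_graph([("a", "b"), ("b", "c"), ("a", "c"), ("d", "x"),
                        ("e", "x")])
        frag = direct_interactions(g, seed_list("a", "b", "c", "d", "e"))
        assert len(frag.components) == 1 and len(frag.components[0]) == 3
        assert frag.isolated == {"d", "e"}

    def test_58_roots_form_two_clusters_of_19(self):
        # 58 roots wired so 12 + 7 of them interact in two clusters
        roots = [f"r{i:02d}" for i in range(58)]
        c1 = [(roots[i], roots[i + 1]) for i in range(11)]       # 12 nodes
        c2 = [(roots[20 + i], roots[20 + i + 1]) for i in range(6)]  # 7 nodes
        g = build_graph(c1 + c2 + [(r, f"out{r}") for r in roots])
        frag = direct_interactions(g, seed_list(*roots))
        assert len(frag.components) == 2
        assert sum(len(c) for c in frag.components) == 19
        assert len(frag.isolated) == 39


class TestExpandByOne:
    def test_single_bridge_retained(self):
        g = build_graph([("a", "x"), ("x", "b")])
        frag = expand_by_one(g, seed_list("a", "b"))
        assert "x" in frag.nodes

    def test_dangling_neighbor_pruned(self):
        g = build_graph([("a", "x"), ("x", "b"), ("a", "dangle"),
                        ("dangle", "nowhere")])
        frag = expand_by_one(g, seed_list("a", "b"))
        assert "dangle" not in frag.nodes and "x" in frag.nodes

    def test_two_hop_bridge_retained(self):
        g = build_graph([("a", "x"), ("x", "y"), ("y", "b")])
        frag = expand_by_one(g, seed_list("a", "b"))
        assert {"x", "y"} <= frag.nodes

    def test_isolated_roots_kept(self):
        g = build_graph([("z1", "z2")])
        g.add_object(NetworkObject(id="a"))
        g.add_object(NetworkObject(id="b"))
        frag = expand_by_one(g, seed_list("a", "b"))
        assert frag.nodes == {"a", "b"}

    def test_same_root_loop_not_a_bridge(self):
        g = build_graph([("a", "x"), ("x", "y"), ("y", "a")])
        frag = expand_by_one(g, seed_list("a", "b"))
        # x and y connect a only to itself
        assert "x" not in frag.nodes and "y" not in frag.nodes


class TestShortestPathBuild:
    def test_single_intermediate(self):
        g = build_graph([("a", "x"), ("x", "b")])
        frag = shortest_path_build(g, seed_list("a", "b"),
                                   options=BuildOptions(max_path_length=2))
        assert frag.nodes == {"a", "x", "b"}

    def test_pair_exceeding_max_length_skipped(self):
        g = build_graph([("a", "x"), ("x", "y"), ("y", "b")])
        frag = shortest_path_build(g, seed_list("a", "b"),
                                   options=BuildOptions(max_path_length=2))
        assert frag.nodes == set()

    def test_all_minimal_alternatives_included(self):
        g = build_graph([("a", "x"), ("x", "b"), ("a", "y"), ("y", "b")])
        frag = shortest_path_build(g, seed_list("a", "b"))
        # oracle: union of every networkx shortest path
        expected = set()
        for path in nx.all_shortest_paths(g.simple_digraph(), "a", "b"):
            expected |= set(path)
        assert frag.nodes == expected


class TestAutoExpand:
    def test_two_roots_meet_at_radius_one(self):
        g = build_graph([("a", "m"), ("m", "b"), ("a", "junk"),
                        ("b", "junk2")])
        frag = auto_expand(g, seed_list("a", "b"))
        assert frag.nodes == {"a", "m", "b"}

    def test_disconnected_roots_return_roots_with_note(self):
        g = build_graph([("a", "x"), ("b", "y"), ("z1", "z2")])
        frag = auto_expand(g, seed_list("a", "z1"))
        assert frag.nodes == {"a", "z1"}
        assert "no territory contact" in frag.note

    def test_single_root_one_step_neighborhood(self):
        g = build_graph([("a", "x"), ("y", "a"), ("x", "far")])
        frag = auto_expand(g, seed_list("a"))
        assert frag.nodes == {"a", "x", "y"}


@pytest.fixture(scope="module")
def an_run():
    g = generate_graph(FixtureSpec(n_nodes=300, attachment_parameter=3,
                                   seed=21))
    roots = seed_list(*g.node_ids[::5][:40])
    frags = analyze_network(g, roots,
                            options=BuildOptions(fragment_size=20))
    return g, roots, frags


class TestAnalyzeNetwork:
    def test_edge_disjointness(self, an_run):
        _, _, frags = an_run
        seen = set()
        for f in frags:
            assert not (f.edges & seen)
            seen |= f.edges

    def test_fragment_size_bound(self, an_run):
        _, _, frags = an_run
        assert all(f.size <= 20 for f in frags)

    def test_multiple_scored_fragments(self, an_run):
        _, _, frags = an_run
        assert len(frags) > 1
        assert all(f.p is not None for f in frags)

    def test_determinism(self, an_run):
        g, roots, frags = an_run
        again = analyze_network(g, roots,
                                options=BuildOptions(fragment_size=20))
        t1 = ranking_table(frags).to_csv(sep="\t")
        t2 = ranking_table(again).to_csv(sep="\t")
        assert t1 == t2

    def test_fragments_are_subgraphs(self, an_run):
        g, _, frags = an_run
        dg = g.simple_digraph()
        for f in frags:
            assert all(dg.has_edge(u, v) for u, v in f.edges)

    def test_ranked_by_g_descending(self, an_run):
        _, _, frags = an_run
        gs = [f.g for f in frags if f.g is not None]
        assert gs == sorted(gs, reverse=True)


class TestDirectedVariants:
    @pytest.fixture
    def cascade(self):
        # L -> R1 -> k1 -> TF1 ; R2 -> k1 ; TF1 -> target
        return build_graph(
            [("L", "R1"), ("R1", "k1"), ("k1", "TF1"), ("R2", "k1"),
             ("TF1", "tgt", "transcription_regulation")],
            classes={"L": "ligand", "R1": "receptor", "R2": "receptor",
                     "TF1": "transcription_factor"})

    def test_tf_mode_linear_chain(self, cascade):
        frags = analyze_network_directed(
            cascade, seed_list("R1", "k1", "TF1"), mode="tf")
        assert len(frags) == 1
        assert {"R1", "k1", "TF1"} <= frags[0].nodes

    def test_equidistant_receptors_both_retained(self, cascade):
        frags = analyze_network_directed(
            cascade, seed_list("R1", "R2", "k1", "TF1"), mode="tf")
        assert {"R1", "R2"} <= frags[0].nodes

    def test_modes_not_reciprocal(self):
        # asymmetric wiring: receptor reaches TF but not conversely
        g = build_graph([("R", "x"), ("x", "TF"), ("TF", "y")],
                        classes={"R": "receptor",
                                 "TF": "transcription_factor"})
        roots = seed_list("R", "TF")
        tf_frags = analyze_network_directed(g, roots, mode="tf")
        r_frags = analyze_network_directed(g, roots, mode="receptor")
        assert [f.label for f in tf_frags] != [f.label for f in r_frags]

    def test_ligand_target_decoration(self, cascade):
        frags = analyze_network_directed(
            cascade, seed_list("R1", "k1", "TF1"), mode="tf",
            options=BuildOptions(enrich_with_ligands_targets=True))
        assert "L" in frags[0].nodes and "tgt" in frags[0].nodes


class TestTranscriptionRegulation:
    def test_tf_regulating_three_roots(self):
        g = build_graph([("TF", r, "transcription_regulation")
                         for r in ("r1", "r2", "r3")] + [("r1", "r4")])
        frags = transcription_regulation(g, seed_list("r1", "r2", "r3", "r4"))
        assert len(frags) == 1
        assert frags[0].nodes == {"TF", "r1", "r2", "r3"}

    def test_root_regulated_by_two_tfs(self):
        g = build_graph([("T1", "r1", "transcription_regulation"),
                        ("T2", "r1", "transcription_regulation")])
        frags = transcription_regulation(g, seed_list("r1"))
        assert len(frags) == 2

    def test_binding_edges_do_not_qualify(self):
        g = build_graph([("T1", "r1", "binding")])
        assert transcription_regulation(g, seed_list("r1")) == []

    def test_upstream_roots_included(self):
        g = build_graph([("TF", "r1", "transcription_regulation"),
                        ("r2", "TF"), ("r3", "r2")])
        frags = transcription_regulation(g, seed_list("r1", "r2", "r3"))
        assert frags[0].nodes == {"TF", "r1", "r2", "r3"}


class TestCanonicalPathways:
    @pytest.fixture
    def library(self):
        return [
            CanonicalPathway("pw1", "one", ("L1", "R1", "k1", "TF1")),
            CanonicalPathway("pw2", "two", ("L2", "R2", "k1", "TF1", "g1")),
            CanonicalPathway("pw3", "three", ("La", "Ra")),
        ]

    def test_merged_union_of_two_pathways(self, library):
        edges = [s for pw in library for s in pw.steps]
        g = build_graph(edges)
        frags = model_canonical_pathways(g, seed_list("k1"), library)
        # pw1 (4 nodes) + pw2 (5 nodes) share k1 and TF1 -> 7 nodes
        assert len(frags) == 1 and frags[0].size == 7
        assert frags[0].pathways_count == 2

    def test_equal_seed_counts_rank_smaller_first(self, library):
        edges = [s for pw in library for s in pw.steps]
        g = build_graph(edges)
        frags = model_canonical_pathways(g, seed_list("L1", "La"), library)
        assert [f.size for f in frags] == [2, 4]

    def test_root_on_no_pathway_contributes_nothing(self, library):
        edges = [s for pw in library for s in pw.steps] + [("other", "k1")]
        g = build_graph(edges)
        assert model_canonical_pathways(g, seed_list("other"), library) == []

    def test_empty_library_rejected(self):
        g = build_graph([("a", "b")])
        with pytest.raises(ValueError):
            model_canonical_pathways(g, seed_list("a"), [])

    def test_library_io_validates_chain(self, tmp_path):
        g = build_graph([("a", "b"), ("b", "c")])
        p = tmp_path / "pw.tsv"
        p.write_text("pw1\tgood\ta|b|c\n")
        lib = load_pathway_library(p, g)
        assert lib[0].chain == ("a", "b", "c")
        p.write_text("pw1\tbad\ta|c\n")
        with pytest.raises(ValueError, match="missing"):
            load_pathway_library(p, g)


class TestScoring:
    def test_published_gscore_with_two_pathways(self):
        assert g_score(54.15, 2) == pytest.approx(56.65)

    def test_zero_pathways_g_equals_z(self):
        assert g_score(53.05, 0) == pytest.approx(53.05)

    def test_z_from_printed_formulas(self):
        # (r=5, n=10, R=50, N=1000): z = 4.5 / sqrt(0.475 * (1 - 9/999))
        frag = score_fragment(
            __import__("protnet.netgen", fromlist=["NetworkFragment"])
            .NetworkFragment(nodes=frozenset(f"n{i}" for i in range(10)),
                             edges=frozenset(),
                             seed_nodes=frozenset(f"n{i}" for i in range(5))),
            R=50, N=1000)
        assert round(frag.z, 3) == 6.559

    def test_degenerate_sigma_leaves_z_unset(self):
        from protnet.netgen import NetworkFragment
        frag = score_fragment(
            NetworkFragment(nodes=frozenset(["a", "b"]), edges=frozenset(),
                            seed_nodes=frozenset(["a", "b"])),
            R=2, N=2)
        assert frag.z is None and frag.g is None and frag.p is not None

    def test_count_requires_a_consecutive_edge(self):
        from protnet.netgen import NetworkFragment
        lib = [CanonicalPathway("pw", "x", ("a", "b", "c", "d"))]
        with_edge = NetworkFragment(nodes=frozenset("abcd"),
                                    edges=frozenset([("a", "b")]),
                                    seed_nodes=frozenset())
        lone_node = NetworkFragment(nodes=frozenset("a"),
                                    edges=frozenset(),
                                    seed_nodes=frozenset())
        assert count_canonical_fragments(with_edge, lib) == 1
        assert count_canonical_fragments(lone_node, lib) == 0

    def test_two_pathways_sharing_an_edge_count_twice(self):
        from protnet.netgen import NetworkFragment
        lib = [CanonicalPathway("p1", "x", ("a", "b", "c")),
               CanonicalPathway("p2", "y", ("z", "a", "b"))]
        frag = NetworkFragment(nodes=frozenset("ab"),
                               edges=frozenset([("a", "b")]),
                               seed_nodes=frozenset())
        assert count_canonical_fragments(frag, lib) == 2
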