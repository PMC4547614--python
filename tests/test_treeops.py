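"""Rerooting, OTU mapping and Newick/NEXUS export.

Structural assertions run against independent oracles: networkx for
undirected-graph and path-length comparisons, DendroPy for parsing the
exported Newick/NEXUS text back.
"""

from __future__ import annotations

import dendropy
import networkx as nx
import pytest
from hypothesis import given, settings, strategies as st

import phylostore as ps
from phylostore.treeops import (
    EdgeRecord,
    NodeRecord,
    TreeRecord,
    quote_newick_label,
)


def build_tree(edges, root, otu_of=()):
    """Assemble a TreeRecord from (edge_id, source, target, length) rows."""
    otu_of = dict(otu_of)
    tree = TreeRecord(tree_id="t")
    for edge_id, source, target, length in edges:
        tree.edges[edge_id] = EdgeRecord(edge_id, source, target, length)
        for node in (source, target):
            tree.nodes.setdefault(node, NodeRecord(node_id=node))
    if not tree.nodes:
        tree.nodes[root] = NodeRecord(node_id=root)
    for node, otu in otu_of.items():
        tree.nodes[node].otu_ref = otu
    tree.nodes[root].is_root = True
    tree.root_node_id = root
    return tree


def as_graph(tree: TreeRecord, suppress_root: bool = False) -> nx.MultiGraph:
    """Undirected weighted image of the tree; optionally with a degree-2
    root suppressed (its two edge lengths summed), for comparison with a
    rerooted tree."""
    graph = nx.MultiGraph()
    for edge in tree.edges.values():
        graph.add_edge(edge.source, edge.target,
                       weight=edge.length if edge.length is not None else 0.0)
    root = tree.root_node_id
    if suppress_root and graph.degree(root) == 2:
        (a, wa), (b, wb) = [(neighbor, data["weight"]) for _, neighbor, data
                            in graph.edges(root, data=True)]
        graph.remove_node(root)
        graph.add_edge(a, b, weight=wa + wb)
    return graph


def edge_weight_multiset(graph: nx.MultiGraph):
    return sorted(round(d["weight"], 9) for _, _, d in graph.edges(data=True))


def tip_distance_multiset(tree: TreeRecord):
    graph = as_graph(tree)
    tips = {n: tree.nodes[n].otu_ref for n in tree.nodes
            if tree.nodes[n].otu_ref is not None}
    lengths = dict(nx.all_pairs_dijkstra_path_length(graph))
    out = {}
    names = sorted(tips)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            out[tuple(sorted((tips[a], tips[b])))] = round(lengths[a][b], 9)
    return out


class TestReroot:
    def test_reroot_at_current_root_is_identity(self, study_doc):
        tree = ps.get_tree(study_doc, "tree1")
        same = ps.reroot_tree(tree, ps.RootTarget("node", tree.root_node_id))
        assert {(e.source, e.target) for e in same.edges.values()} == \
            {(e.source, e.target) for e in tree.edges.values()}

    def test_unknown_target_rejected(self, study_doc):
        tree = ps.get_tree(study_doc, "tree1")
        with pytest.raises(ps.UnknownTargetError):
            ps.reroot_tree(tree, ps.RootTarget("node", "not-a-node"))

    def test_caterpillar_reroot_flips_exactly_the_path_edges(self):
        # R-(A,I1); I1-(B,I2); I2-(C,D): reroot at the far internal node I2.
        tree = build_tree([
            ("e1", "R", "A", 1.0), ("e2", "R", "I1", 1.0),
            ("e3", "I1", "B", 1.0), ("e4", "I1", "I2", 1.0),
            ("e5", "I2", "C", 1.0), ("e6", "I2", "D", 1.0)],
            root="R", otu_of={"A": "oA", "B": "oB", "C": "oC", "D": "oD"})
        rerooted = ps.reroot_tree(tree, ps.RootTarget("node", "I2"))
        directed = {(e.source, e.target) for e in rerooted.edges.values()}
        # Path edges R->I1, I1->I2 reversed; old degree-2 root suppressed,
        # so R->A and I1->R merge into I1->A.
        assert ("I2", "I1") in directed
        assert ("I1", "A") in directed
        assert ("I2", "C") in directed and ("I2", "D") in directed
        assert "R" not in rerooted.nodes
        oracle = as_graph(tree, suppress_root=True)
        assert nx.is_isomorphic(oracle, as_graph(rerooted))
        assert edge_weight_multiset(oracle) == \
            edge_weight_multiset(as_graph(rerooted))

    def test_edge_target_splits_length_proportionally(self):
        tree = build_tree([("e1", "R", "A", 2.0), ("e2", "R", "B", 1.0)],
                          root="R", otu_of={"A": "oA", "B": "oB"})
        rerooted = ps.reroot_tree(
            tree, ps.RootTarget("edge", "e2", edge_fraction=0.25))
        lengths = sorted(e.length for e in rerooted.edges.values())
        # e2 (length 1.0) splits 0.25/0.75; R (now degree 2) is suppressed,
        # merging its side (0.25) with e1 (2.0).
        assert lengths == [0.75, 2.25]
        assert rerooted.root_node_id.startswith("t_root")

    def test_reroot_back_restores_directed_edges(self):
        # Root with three children, so it survives rerooting un-suppressed.
        tree = build_tree([
            ("e1", "R", "A", 1.0), ("e2", "R", "B", 2.0),
            ("e3", "R", "I", 0.5), ("e4", "I", "C", 1.0),
            ("e5", "I", "D", 1.5)],
            root="R", otu_of={"A": "oA", "B": "oB", "C": "oC", "D": "oD"})
        away = ps.reroot_tree(tree, ps.RootTarget("node", "I"))
        back = ps.reroot_tree(away, ps.RootTarget("node", "R"))
        assert {(e.source, e.target, e.length) for e in back.edges.values()} \
            == {(e.source, e.target, e.length) for e in tree.edges.values()}

    @pytest.mark.parametrize("seed", range(20))
    def test_random_trees_vs_graph_oracle(self, seed):
        """Undirected edge multiset (root-merged) and tip-to-tip path-length
        multiset are invariant under rerooting; brute-force graph oracle."""
        import random

        rng = random.Random(seed)
        doc = ps.generate_study(ps.StudyGenParams(
            n_otus=rng.randint(3, 12), n_trees=1, seed=seed))
        tree = ps.get_tree(doc, "tree1")
        internal = sorted(n for n in tree.nodes
                          if tree.nodes[n].otu_ref is None)
        for _ in range(10):
            if rng.random() < 0.7:
                target = ps.RootTarget("node", rng.choice(internal))
            else:
                target = ps.RootTarget("edge", rng.choice(sorted(tree.edges)),
                                       edge_fraction=rng.random())
            rerooted = ps.reroot_tree(tree, target)
            oracle = as_graph(tree, suppress_root=rerooted.root_node_id !=
                              tree.root_node_id)
            if target.kind == "node":
                assert edge_weight_multiset(oracle) == \
                    edge_weight_multiset(as_graph(rerooted))
            else:
                # Subdivision adds one node/edge but conserves total length.
                assert len(rerooted.nodes) == oracle.number_of_nodes() + 1
                assert round(sum(edge_weight_multiset(oracle)), 6) == \
                    round(sum(edge_weight_multiset(as_graph(rerooted))), 6)
            assert tip_distance_multiset(tree) == tip_distance_multiset(rerooted)
            assert sorted(tree.nodes[n].otu_ref for n in tree.tip_ids()) == \
                sorted(rerooted.nodes[n].otu_ref for n in rerooted.tip_ids())


class TestMapOtu:
    HOMO = ps.TaxonRecord(770315, "Homo sapiens", None, "species")

    def test_mapping_sets_fields_and_preserves_label(self, tiny_doc):
        ps.map_otu(tiny_doc, "otu1", self.HOMO)
        otu = ps.otus_from_doc(tiny_doc)["otu1"]
        assert otu.mapped_taxon_id == 770315
        assert otu.mapped_taxon_name == "Homo sapiens"
        assert otu.original_label == "Homo_sapiens_x23"

    def test_remap_overwrites_only_mapped_fields(self, tiny_doc):
        ps.map_otu(tiny_doc, "otu1", self.HOMO)
        ps.map_otu(tiny_doc, "otu1", ps.TaxonRecord(9606, "Homo", None, "genus"))
        otu = ps.otus_from_doc(tiny_doc)["otu1"]
        assert (otu.mapped_taxon_id, otu.mapped_taxon_name) == (9606, "Homo")
        assert otu.original_label == "Homo_sapiens_x23"

    def test_unmap_restores_unmapped_state(self, tiny_doc):
        pristine = tiny_doc.copy()
        ps.map_otu(tiny_doc, "otu1", self.HOMO)
        ps.map_otu(tiny_doc, "otu1", None)
        assert ps.model_equal(tiny_doc, pristine)

    def test_unknown_otu(self, tiny_doc):
        with pytest.raises(ps.UnknownTargetError):
            ps.map_otu(tiny_doc, "otu99", self.HOMO)


class TestNewickExport:
    def test_three_tip_example(self):
        tree = build_tree([
            ("e1", "n1", "n2", 0.5), ("e2", "n2", "n3", 1),
            ("e3", "n2", "n4", 2), ("e4", "n1", "n5", 3)],
            root="n1", otu_of={"n3": "oA", "n4": "oB", "n5": "oC"})
        otus = {"oA": ps.OtuRecord("oA", "A"), "oB": ps.OtuRecord("oB", "B"),
                "oC": ps.OtuRecord("oC", "C")}
        assert ps.export_newick(tree, otus) == "((A:1,B:2):0.5,C:3);"

    def test_single_tip_tree(self):
        tree = build_tree([], root="n1", otu_of={})
        tree.nodes["n1"].otu_ref = "oA"
        assert ps.export_newick(tree, {"oA": ps.OtuRecord("oA", "A")}) == "A;"

    def test_reserved_characters_are_quoted(self):
        tree = build_tree([("e1", "r", "a", 1.0), ("e2", "r", "b", 1.0)],
                          root="r", otu_of={"a": "o1", "b": "o2"})
        otus = {"o1": ps.OtuRecord("o1", "sp. nov."),
                "o2": ps.OtuRecord("o2", "it's")}
        newick = ps.export_newick(tree, otus)
        assert "'sp. nov.'" in newick
        assert "'it''s'" in newick

    def test_label_modes_and_fallback(self, tiny_doc):
        ps.map_otu(tiny_doc, "otu1", ps.TaxonRecord(770315, "Homo sapiens", None))
        tree = ps.get_tree(tiny_doc, "tree1")
        otus = ps.otus_from_doc(tiny_doc)
        mapped = ps.export_newick(tree, otus, label_mode="mapped_name")
        assert "'Homo sapiens'" in mapped
        # otu2 is unmapped: falls back to its original label.
        assert "'Pan troglodytes'" in mapped
        by_id = ps.export_newick(tree, otus, label_mode="mapped_id")
        assert "770315" in by_id

    @pytest.mark.parametrize("seed", range(25))
    def test_dendropy_reads_back_identical_structure(self, seed):
        """Independent-parser oracle: tip labels and clade sets survive."""
        doc = ps.generate_study(ps.StudyGenParams(
            n_otus=3 + seed % 9, n_trees=1, mapped_fraction=0.4, seed=seed))
        tree = ps.get_tree(doc, "tree1")
        otus = ps.otus_from_doc(doc)
        newick = ps.export_newick(tree, otus)
        parsed = dendropy.Tree.get(data=newick, schema="newick",
                                   preserve_underscores=True,
                                   suppress_internal_node_taxa=True)

        def our_clades():
            children = tree.children()

            def tips_below(node):
                edges = children[node]
                if not edges:
                    return frozenset({otus[tree.nodes[node].otu_ref].original_label})
                return frozenset().union(*(tips_below(e.target) for e in edges))

            return {tips_below(n) for n in tree.nodes
                    if children[n] and n != tree.root_node_id}

        their_clades = set()
        for node in parsed.preorder_internal_node_iter(exclude_seed_node=True):
            their_clades.add(frozenset(
                leaf.taxon.label for leaf in node.leaf_iter()))
        assert their_clades == our_clades()

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.text(
        alphabet=st.characters(min_codepoint=32, max_codepoint=126),
        min_size=1, max_size=25).filter(lambda s: s.strip()))
    def test_quoting_roundtrips_through_dendropy(self, label):
        other = "zzz"
        newick = f"({quote_newick_label(label)}:1,{other}:2);"
        parsed = dendropy.Tree.get(data=newick, schema="newick",
                                   preserve_underscores=True,
                                   suppress_internal_node_taxa=True)
        labels = {leaf.taxon.label for leaf in parsed.leaf_node_iter()}
        assert label in labels


class TestNexusExport:
    def test_header_and_single_tree(self, tiny_doc):
        text = ps.export_nexus(tiny_doc)
        assert text.startswith("#NEXUS")
        assert text.count("TREE ") == 1

    def test_two_trees_share_one_taxa_block(self):
        doc = ps.generate_study(ps.StudyGenParams(n_otus=6, n_trees=2, seed=4))
        text = ps.export_nexus(doc)
        assert text.count("BEGIN TAXA;") == 1
        assert text.count("TREE ") == 2

    def test_dendropy_parses_with_identical_labels(self, study_doc):
        text = ps.export_nexus(study_doc)
        trees = dendropy.TreeList.get(data=text, schema="nexus",
                                      preserve_underscores=True)
        expected = {otu.original_label
                    for otu in ps.otus_from_doc(study_doc).values()}
        parsed_labels = {taxon.label for taxon in trees.taxon_namespace}
        assert parsed_labels == expected
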