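"""Layer assignment rules, element-mediated edges, and network export."""

import pytest

from xylemtrn.errors import ValidationError
from xylemtrn.motifs import ElementProfile
from xylemtrn.trn import (
    TrnEdge,
    TrnNode,
    assign_layers,
    build_edges,
    export_network,
    read_network,
    summarize,
    to_dot,
)


def _profile(gene_id, **counts):
    return ElementProfile(gene_id, {m: counts.get(m.lower(), 0) for m in
                                    ("SNBE", "SMRE", "WBOX", "TGTG")})


@pytest.fixture()
def profiles(small_catalog):
    return {
        "TF_NAC1": _profile("TF_NAC1", snbe=1, smre=1),  # both -> layer 3
        "TF_MYB1": _profile("TF_MYB1", smre=2),  # SMRE-only -> layer 3
        "TF_WRKY1": _profile("TF_WRKY1", snbe=1, smre=1),  # both -> layer 3
        "TF_OTHER1": _profile("TF_OTHER1", snbe=1),  # SNBE-only -> layer 2
        "CW1": _profile("CW1", snbe=1, smre=1, wbox=1),
        "CW2": _profile("CW2", smre=1),  # no SNBE: MYB edges only
        "PCD1": _profile("PCD1", snbe=1, tgtg=1),
    }


@pytest.fixture()
def upregulated():
    return {"TF_NAC1", "TF_MYB1", "TF_WRKY1", "TF_OTHER1"}


class TestAssignLayers:
    def test_rule_order(self, small_catalog, profiles, upregulated):
        nodes, unplaced = assign_layers(profiles, small_catalog, upregulated)
        layer = {n.gene_id: n.layer for n in nodes}
        assert layer["WND1"] == 1  # master switches by role, not by scanning
        assert layer["TF_OTHER1"] == 2  # SNBE only
        assert layer["TF_NAC1"] == 3  # both elements
        assert layer["TF_MYB1"] == 3  # SMRE only
        assert layer["CW1"] == layer["CW2"] == layer["PCD1"] == 4
        assert unplaced == []

    def test_tf_without_elements_unplaced(self, small_catalog, profiles, upregulated):
        profiles["TF_NAC1"] = _profile("TF_NAC1")
        nodes, unplaced = assign_layers(profiles, small_catalog, upregulated)
        assert unplaced == ["TF_NAC1"]
        assert "TF_NAC1" not in {n.gene_id for n in nodes}

    def test_non_upregulated_tfs_ignored(self, small_catalog, profiles):
        nodes, _ = assign_layers(profiles, small_catalog, {"TF_MYB1"})
        tf_nodes = {n.gene_id for n in nodes if n.role == "TF"}
        assert tf_nodes == {"TF_MYB1"}

    def test_overrides_pin_layers(self, small_catalog, profiles, upregulated):
        nodes, _ = assign_layers(
            profiles, small_catalog, upregulated, overrides={"TF_NAC1": 2}
        )
        layer = {n.gene_id: n.layer for n in nodes}
        assert layer["TF_NAC1"] == 2

    def test_layer_invariants_enforced(self):
        with pytest.raises(ValidationError):
            TrnNode("x", 1, "TF", "MYB")  # layer 1 is WND-only
        with pytest.raises(ValidationError):
            TrnNode("x", 4, "TF", "MYB")  # layer 4 is CW/PCD-only


class TestBuildEdges:
    def test_element_mediated_rules(self, small_catalog, profiles, upregulated):
        nodes, _ = assign_layers(profiles, small_catalog, upregulated)
        edges = build_edges(nodes, profiles)
        by_pair = {(e.source, e.target): e for e in edges}
        # WND targets every lower gene with SNBE
        assert ("WND1", "TF_OTHER1") in by_pair
        assert by_pair[("WND1", "PCD1")].element == "SNBE"
        # layer-3 MYB targets strictly lower SMRE genes
        assert by_pair[("TF_MYB1", "CW2")].element == "SMRE"
        assert ("TF_MYB1", "TF_NAC1") not in by_pair  # same layer
        # layer-3 WRKY targets layer-4 W-box genes only
        wrky = [e for e in edges if e.source == "TF_WRKY1"]
        assert [(e.target, e.element) for e in wrky] == [("CW1", "WBOX")]
        # NAC072-class ortholog targets TGTG-carrying PCD genes: exactly one edge
        tgtg = [e for e in edges if e.element == "TGTG"]
        assert [(e.source, e.target) for e in tgtg] == [("TF_NAC1", "PCD1")]

    def test_cw_gene_without_snbe_gets_myb_edges_only(
        self, small_catalog, profiles, upregulated
    ):
        nodes, _ = assign_layers(profiles, small_catalog, upregulated)
        edges = build_edges(nodes, profiles)
        into_cw2 = {(e.source, e.element) for e in edges if e.target == "CW2"}
        assert into_cw2 == {("TF_MYB1", "SMRE")}

    def test_acyclic_and_sound(self, small_catalog, profiles, upregulated):
        nodes, _ = assign_layers(profiles, small_catalog, upregulated)
        edges = build_edges(nodes, profiles)
        layer = {n.gene_id: n.layer for n in nodes}
        for e in edges:
            assert layer[e.source] < layer[e.target]
            assert profiles[e.target].has(e.element)

    def test_no_layer4_genes_no_downstream_edges(self, small_catalog, profiles, upregulated):
        nodes, _ = assign_layers(profiles, small_catalog, upregulated)
        nodes = [n for n in nodes if n.layer < 4]
        edges = build_edges(nodes, profiles)
        assert all(n.layer < 4 for n in nodes)
        assert {e.element for e in edges} <= {"SNBE", "SMRE"}

    def test_adding_a_hit_never_removes_edges(self, small_catalog, profiles, upregulated):
        nodes, _ = assign_layers(profiles, small_catalog, upregulated)
        before = set(build_edges(nodes, profiles))
        profiles["CW2"].hit_counts["WBOX"] += 1
        after = set(build_edges(nodes, profiles))
        assert before <= after

    def test_curated_edges_merged_and_validated(self, small_catalog, profiles, upregulated):
        nodes, _ = assign_layers(profiles, small_catalog, upregulated)
        lit = TrnEdge("WND1", "TF_MYB1", "SNBE", evidence="literature")
        edges = build_edges(nodes, profiles, curated=[lit])
        assert lit in edges
        upward = TrnEdge("CW1", "WND1", "SNBE", evidence="literature")
        with pytest.raises(ValidationError, match="downward"):
            build_edges(nodes, profiles, curated=[upward])


class TestExportAndSummary:
    def test_edgelist_round_trip(self, small_catalog, profiles, upregulated, tmp_path):
        nodes, _ = assign_layers(profiles, small_catalog, upregulated)
        edges = build_edges(nodes, profiles)
        path = tmp_path / "trn.edges.tsv"
        export_network(nodes, edges, path, fmt="edgelist")
        nodes_back, edges_back = read_network(path)
        assert set(nodes_back) == set(nodes)
        assert set(edges_back) == set(edges)

    def test_edgelist_row_count(self, tmp_path):
        nodes = [
            TrnNode("w", 1, "WND", "NAC"),
            TrnNode("t", 2, "TF", "NAC"),
            TrnNode("p", 4, "PCD", "NA"),
        ]
        edges = [TrnEdge("w", "t", "SNBE"), TrnEdge("w", "p", "SNBE")]
        path = tmp_path / "net.tsv"
        export_network(nodes, edges, path, fmt="edgelist")
        lines = path.read_text().rstrip("\n").split("\n")
        assert len(lines) == 3 and lines[0].startswith("source\t")

    def test_dot_ranks_by_layer(self, small_catalog, profiles, upregulated):
        nodes, _ = assign_layers(profiles, small_catalog, upregulated)
        dot = to_dot(nodes, build_edges(nodes, profiles))
        assert dot.count("rank=same") == 4
        assert '"WND1"' in dot.split("\n")[2]  # layer 1 ranked first

    def test_graphml_round_trips_through_networkx(
        self, small_catalog, profiles, upregulated, tmp_path
    ):
        import networkx as nx

        nodes, _ = assign_layers(profiles, small_catalog, upregulated)
        edges = build_edges(nodes, profiles)
        path = tmp_path / "trn.graphml"
        export_network(nodes, edges, path, fmt="graphml")
        g = nx.read_graphml(path)
        assert g.number_of_nodes() == len(nodes)
        assert g.number_of_edges() == len(edges)
        assert g.nodes["WND1"]["layer"] == 1

    def test_unknown_format(self, small_catalog, profiles, upregulated, tmp_path):
        nodes, _ = assign_layers(profiles, small_catalog, upregulated)
        with pytest.raises(ValidationError, match="format"):
            export_network(nodes, [], tmp_path / "x", fmt="sif")

    def test_summary_conservation(self, small_catalog, profiles, upregulated):
        profiles["TF_NAC1"] = _profile("TF_NAC1")  # force one unplaced TF
        nodes, unplaced = assign_layers(profiles, small_catalog, upregulated)
        edges = build_edges(nodes, profiles)
        report = summarize(nodes, edges, unplaced)
        assert sum(report["per_layer"].values()) + report["n_unplaced"] == (
            report["total_input_genes"]
        )
        assert report["per_layer"][1] == 1
        assert report["n_unplaced"] == 1

    def test_empty_network_all_zero(self):
        report = summarize([], [], [])
        assert report["n_nodes"] == 0 and report["n_edges"] == 0
        assert all(v == 0 for v in report["per_layer"].values())
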