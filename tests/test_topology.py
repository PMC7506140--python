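import pytest

from emt_nfatc.topology import (
    ACTIVATION,
    INHIBITION,
    MIRNA,
    NetworkTopology,
    RegulatoryEdge,
    TopologyError,
    core_emt,
    read_topo,
    single_node,
    toggle_switch,
    wildtype_coupled,
    write_topo,
)


class TestValidation:
    def test_edge_rejects_bad_sign_and_mechanism(self):
        with pytest.raises(TopologyError):
            RegulatoryEdge("A", "B", "up")
        with pytest.raises(TopologyError):
            RegulatoryEdge("A", "B", ACTIVATION, "telepathic")

    def test_duplicate_edge_rejected(self):
        with pytest.raises(TopologyError, match="duplicate"):
            NetworkTopology(["A", "B"], [
                RegulatoryEdge("A", "B", ACTIVATION),
                RegulatoryEdge("A", "B", INHIBITION),
            ])

    def test_unknown_node_rejected(self):
        with pytest.raises(TopologyError, match="unknown node"):
            NetworkTopology(["A"], [RegulatoryEdge("A", "B", ACTIVATION)])


class TestShippedCircuits:
    def test_wildtype_is_5_nodes_11_edges_6_activation_5_inhibition(self):
        wt = wildtype_coupled()
        assert len(wt.nodes) == 5
        assert len(wt.edges) == 11
        assert wt.n_activation == 6
        assert wt.n_inhibition == 5

    def test_core_is_3_nodes_with_mirna_silencing_edge(self):
        core = core_emt()
        assert set(core.nodes) == {"SNAIL", "miR200", "ZEB"}
        mirna_edges = [e for e in core.edges if e.mechanism == MIRNA]
        assert len(mirna_edges) == 1
        assert (mirna_edges[0].source, mirna_edges[0].target) == ("miR200", "ZEB")

    def test_core_edges_are_a_subset_of_the_coupled_circuit(self):
        wt = {(e.source, e.target, e.sign) for e in wildtype_coupled().edges}
        core = {(e.source, e.target, e.sign) for e in core_emt().edges}
        assert core <= wt


class TestTopoFiles:
    @pytest.mark.parametrize("factory", [wildtype_coupled, core_emt,
                                         toggle_switch])
    def test_round_trip(self, factory, tmp_path):
        topo = factory()
        path = tmp_path / "t.topo"
        write_topo(topo, path)
        back = read_topo(path)
        assert set(back.nodes) == set(topo.nodes)
        assert back.edges == topo.edges  # structure and order preserved

    def test_unknown_type_code_names_line(self, tmp_path):
        path = tmp_path / "bad.topo"
        path.write_text("Source Target Type\nA B 3\n")
        with pytest.raises(TopologyError, match="line 2"):
            read_topo(path)

    def test_missing_header_rejected(self, tmp_path):
        path = tmp_path / "bad.topo"
        path.write_text("A B 1\n")
        with pytest.raises(TopologyError, match="header"):
            read_topo(path)

    def test_header_only_gives_empty_topology_with_warning(self, tmp_path):
        path = tmp_path / "empty.topo"
        path.write_text("Source Target Type\n")
        with pytest.warns(UserWarning, match="no edges"):
            topo = read_topo(path)
        assert topo.edges == []

    def test_mechanism_column_defaults_to_transcriptional(self, tmp_path):
        path = tmp_path / "m.topo"
        path.write_text("Source Target Type\nA B 1\n")
        topo = read_topo(path)
        assert topo.edges[0].mechanism == "transcriptional"


class TestSignVectors:
    def test_with_signs_preserves_endpoints_and_degrees(self):
        wt = wildtype_coupled()
        flipped = wt.with_signs([not f for f in wt.sign_vector()])
        assert flipped.in_degree() == wt.in_degree()
        assert flipped.out_degree() == wt.out_degree()
        assert flipped.n_activation == wt.n_inhibition

    def test_with_signs_length_mismatch(self):
        with pytest.raises(TopologyError):
            wildtype_coupled().with_signs([True])
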