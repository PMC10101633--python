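"""Readers, validation, binarization, giant component, and size filter."""

import pytest

from dgcd.errors import SchemaError, ValidationError
from dgcd.network_io import (
    BipartiteGraph,
    attach_metadata,
    filter_min_side,
    giant_component,
    read_edge_list,
    read_incidence_matrix,
    read_metadata,
    write_incidence_matrix,
)

from conftest import bip


def write(tmp_path, name, text):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestIncidenceMatrix:
    def test_identity_matrix_cols_to_rows(self, tmp_path):
        p = write(tmp_path, "m.csv", ",c1,c2\nr1,1,0\nr2,0,1\n")
        g = read_incidence_matrix(p, id="m", orientation="cols_to_rows")
        assert g.edges == {("c1", "r1"), ("c2", "r2")}
        assert g.set_a == ("r1", "r2") and g.set_b == ("c1", "c2")

    def test_rows_to_cols_flips_direction(self, tmp_path):
        p = write(tmp_path, "m.csv", ",c1,c2\nr1,1,0\nr2,0,1\n")
        g = read_incidence_matrix(p, orientation="rows_to_cols")
        assert g.edges == {("r1", "c1"), ("r2", "c2")}

    def test_weighted_cell_binarized_to_single_edge(self, tmp_path):
        p = write(tmp_path, "m.csv", ",c1\nr1,3\nr2,0.5\n")
        g = read_incidence_matrix(p)
        assert g.edges == {("c1", "r1"), ("c1", "r2")}

    @pytest.mark.parametrize(
        "body,match",
        [
            (",c1,c2\nr1,0,0\nr2,0,0\n", "no interactions"),
            (",c1,c1\nr1,1,0\n", "duplicate column"),
            (",c1,c2\nr1,1,0\nr1,0,1\n", "duplicate row"),
            (",c1,c2\nr1,1,x\n", "non-numeric"),
            ("", "empty"),
        ],
    )
    def test_invalid_matrices_rejected(self, tmp_path, body, match):
        p = write(tmp_path, "bad.csv", body)
        with pytest.raises(ValidationError, match=match):
            read_incidence_matrix(p)

    def test_parse_error_names_row_and_column(self, tmp_path):
        p = write(tmp_path, "bad.csv", ",c1,c2\nr1,1,0\nr2,oops,1\n")
        with pytest.raises(ValidationError, match=r"'r2'.*'c1'"):
            read_incidence_matrix(p)

    def test_round_trip_preserves_edges_and_label_order(self, tmp_path):
        g = bip("rt", {("a", "x"), ("a", "y"), ("b", "y"), ("c", "z")})
        p = write_incidence_matrix(g, tmp_path / "rt.csv")
        back = read_incidence_matrix(p, id="rt", orientation="cols_to_rows")
        assert back.edges == g.edges
        assert back.set_a == g.set_a and back.set_b == g.set_b


class TestEdgeList:
    def test_sets_inferred_from_columns(self, tmp_path):
        p = write(tmp_path, "e.tsv", "u\tv\nu\tw\n")
        g = read_edge_list(p, id="e")
        assert set(g.set_b) == {"u"} and set(g.set_a) == {"v", "w"}
        assert g.edges == {("u", "v"), ("u", "w")}

    def test_duplicate_rows_deduplicate(self, tmp_path):
        p = write(tmp_path, "e.tsv", "u\tv\nu\tv\n")
        assert len(read_edge_list(p).edges) == 1

    def test_header_row_is_skipped(self, tmp_path):
        p = write(tmp_path, "e.tsv", "source\ttarget\nu\tv\n")
        assert read_edge_list(p).edges == {("u", "v")}

    def test_label_in_both_columns_rejected(self, tmp_path):
        p = write(tmp_path, "e.tsv", "u\tv\nv\tu\n")
        with pytest.raises(ValidationError, match="bipartite"):
            read_edge_list(p)

    def test_empty_file_rejected(self, tmp_path):
        p = write(tmp_path, "e.tsv", "")
        with pytest.raises(ValidationError, match="empty"):
            read_edge_list(p)


class TestGraphInvariants:
    def test_within_set_edge_rejected(self):
        with pytest.raises(ValidationError):
            BipartiteGraph("g", ("a", "b"), ("c",), frozenset({("a", "b")}))

    def test_mixed_orientation_rejected(self):
        with pytest.raises(ValidationError, match="uniformly oriented"):
            BipartiteGraph(
                "g", ("a", "b"), ("c", "d"),
                frozenset({("c", "a"), ("b", "d")}),
            )

    def test_reverse_swaps_source_and_target_roles(self):
        g = bip("g", {("u", "v"), ("u", "w")})
        r = g.reverse()
        assert set(r.sources) == {"v", "w"} and r.targets == ("u",)
        assert r.edges == {("v", "u"), ("w", "u")}


class TestGiantComponent:
    def test_connected_graph_unchanged(self):
        g = bip("g", {("u", "v"), ("u", "w")})
        assert giant_component(g) is g

    def test_largest_component_kept(self):
        # component 1: 5 nodes, component 2: 3 nodes
        g = bip(
            "g",
            {("a", "x"), ("a", "y"), ("b", "y"), ("c", "z")},
            set_a=("x", "y", "z"),
            set_b=("a", "b", "c"),
        )
        gc = giant_component(g)
        assert set(gc.nodes) == {"a", "b", "x", "y"}
        assert gc.edges == {("a", "x"), ("a", "y"), ("b", "y")}

    def test_equal_size_tie_breaks_to_smallest_label(self):
        # two 2-node components; 'a1' < 'b1' lexicographically
        g = bip("g", {("b1", "b2"), ("a1", "a2")})
        gc = giant_component(g)
        assert set(gc.nodes) == {"a1", "a2"}
        # and the documented tie-break is deterministic under relabeling order
        g2 = bip("g", {("a1", "a2"), ("b1", "b2")})
        assert set(giant_component(g2).nodes) == {"a1", "a2"}

    def test_idempotent(self):
        g = bip("g", {("a", "x"), ("b", "y"), ("a", "y")})
        once = giant_component(g)
        twice = giant_component(once)
        assert twice.edges == once.edges and set(twice.nodes) == set(once.nodes)


class TestMinSideFilter:
    @pytest.mark.parametrize(
        "n_a,n_b,k,expected",
        [(5, 5, 5, True), (4, 100, 5, False), (100, 4, 5, False), (1, 1, 1, True)],
    )
    def test_each_side_must_reach_k(self, n_a, n_b, k, expected):
        edges = {(f"b0", f"a{i}") for i in range(n_a)} | {
            (f"b{j}", f"a0") for j in range(n_b)
        }
        g = bip("g", edges,
                set_a=tuple(f"a{i}" for i in range(n_a)),
                set_b=tuple(f"b{j}" for j in range(n_b)))
        assert filter_min_side(g, k) is expected

    def test_k_below_one_rejected(self, single_edge):
        with pytest.raises(ValidationError):
            filter_min_side(single_edge, 0)


class TestMetadata:
    GOOD = (
        "network_id,domain,subgroup,publication_id\n"
        "net1,species_interaction,ant_plant,pub_17\n"
        "net2,species_interaction,host_parasite,pub_03\n"
    )

    def test_reads_rows(self, tmp_path):
        rows = read_metadata(write(tmp_path, "m.csv", self.GOOD))
        assert rows[0] == ("net1", "species_interaction", "ant_plant", "pub_17")
        assert len(rows) == 2

    def test_missing_column_is_schema_error(self, tmp_path):
        p = write(tmp_path, "m.csv", "network_id,domain,subgroup\nn1,d,s\n")
        with pytest.raises(SchemaError, match="publication_id"):
            read_metadata(p)

    def test_duplicate_id_rejected(self, tmp_path):
        p = write(
            tmp_path, "m.csv",
            "network_id,domain,subgroup,publication_id\nn1,d,s,p\nn1,d,s,p\n",
        )
        with pytest.raises(ValidationError, match="duplicate"):
            read_metadata(p)

    def test_empty_publication_id_rejected(self, tmp_path):
        p = write(
            tmp_path, "m.csv",
            "network_id,domain,subgroup,publication_id\nn1,d,s,\n",
        )
        with pytest.raises(ValidationError, match="empty"):
            read_metadata(p)

    def test_attach_reconciles_both_directions(self, tmp_path, caplog):
        rows = read_metadata(write(tmp_path, "m.csv", self.GOOD))
        g = bip("net1", {("u", "v")})
        orphan = bip("net9", {("u", "v")})
        records = attach_metadata([g, orphan], rows)
        assert [r.id for r in records] == ["net1"]
        assert records[0].publication_id == "pub_17"
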