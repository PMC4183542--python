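import math

import pytest

from divshift import (
    RichnessTable,
    join,
    read_chronogram,
    read_richness,
    write_annotated_tree,
)
from divshift.treedata import TreeValidationError


class TestReadChronogram:
    def test_ages_and_stems_read_off(self, three_tip_tree, three_tip_rt):
        ch = three_tip_tree
        assert ch.root_age == pytest.approx(15.0)
        assert sorted(ch.tip_labels()) == ["A", "B", "C"]
        stems = {ch.label(t): three_tip_rt.stem_age[t] for t in ch.tip_ids}
        assert stems == pytest.approx({"A": 10.0, "B": 10.0, "C": 15.0})

    def test_round_trip_identity(self, three_tip_tree, tmp_path):
        out = tmp_path / "rt.nex"
        three_tip_tree.write(out, schema="nexus")
        back = read_chronogram(out)
        assert back.n_tips == three_tip_tree.n_tips
        for nid in three_tip_tree.nodes:
            assert back.age(nid) == pytest.approx(three_tip_tree.age(nid), abs=1e-9)
            assert back.leafset(nid) == three_tip_tree.leafset(nid)

    def test_round_trip_simulated_tree(self, yule_taxon_tree, tmp_path):
        ch = yule_taxon_tree.chronogram
        out = tmp_path / "big.nwk"
        ch.write(out, schema="newick")
        back = read_chronogram(out)
        assert {back.leafset(i) for i in back.nodes} == {ch.leafset(i) for i in ch.nodes}
        for nid in ch.nodes:
            assert back.age(nid) == pytest.approx(ch.age(nid), abs=1e-9)

    def test_node_ids_deterministic_across_reads(self, tmp_path):
        p = tmp_path / "t.nwk"
        p.write_text("((B:10,A:10):5,C:15);\n")  # children deliberately unsorted
        a = read_chronogram(p)
        b = read_chronogram(p)
        assert {i: a.leafset(i) for i in a.nodes} == {i: b.leafset(i) for i in b.nodes}

    def test_non_ultrametric_rejected_with_offender(self, tmp_path):
        p = tmp_path / "bad.nwk"
        p.write_text("((A:10,B:7):5,C:15);\n")
        with pytest.raises(TreeValidationError, match="B"):
            read_chronogram(p)

    def test_missing_branch_length_rejected(self, tmp_path):
        p = tmp_path / "nolen.nwk"
        p.write_text("((A:10,B:10),C:15);\n")
        with pytest.raises((TreeValidationError, ValueError)):
            read_chronogram(p)

    def test_polytomy_resolved_with_warning(self, tmp_path):
        p = tmp_path / "poly.nwk"
        p.write_text("(A:10,B:10,C:10);\n")
        with pytest.warns(UserWarning, match="polytom"):
            ch = read_chronogram(p)
        assert ch.n_tips == 3
        assert all(len(ch.children(i)) == 2 for i in ch.internal_ids)

    def test_duplicate_labels_rejected(self, tmp_path):
        p = tmp_path / "dup.nwk"
        p.write_text("((A:10,A:10):5,C:15);\n")
        with pytest.raises(TreeValidationError, match="duplicate"):
            read_chronogram(p)

    def test_mrca(self, three_tip_tree):
        ch = three_tip_tree
        assert ch.leafset(ch.mrca(["A", "B"])) == frozenset({"A", "B"})
        assert ch.mrca(["A", "C"]) == ch.root_id
        with pytest.raises(KeyError):
            ch.mrca(["A", "Zzz"])


class TestRichness:
    def test_read_table(self, tmp_path):
        p = tmp_path / "r.tsv"
        p.write_text("label\trichness\nA\t1\nB\t10\n")
        table = read_richness(p)
        assert len(table) == 2 and table.total == 11

    def test_zero_count_rejected(self, tmp_path):
        p = tmp_path / "r.tsv"
        p.write_text("A\t0\n")
        with pytest.raises(ValueError):
            read_richness(p)

    def test_non_integer_rejected(self, tmp_path):
        p = tmp_path / "r.tsv"
        p.write_text("A\t2.5\n")
        with pytest.raises(ValueError):
            read_richness(p)

    def test_duplicate_labels_rejected(self, tmp_path):
        p = tmp_path / "r.tsv"
        p.write_text("A\t1\nA\t2\n")
        with pytest.raises(ValueError, match="duplicate"):
            read_richness(p)

    def test_join_requires_matching_labels(self, three_tip_tree):
        with pytest.raises(ValueError, match="C"):
            join(three_tip_tree, RichnessTable({"A": 1, "B": 1}))
        with pytest.raises(ValueError, match="D"):
            join(three_tip_tree, RichnessTable({"A": 1, "B": 1, "C": 1, "D": 2}))

    def test_join_totals(self, three_tip_tree):
        rt = join(three_tip_tree, RichnessTable({"A": 3, "B": 4, "C": 5}))
        assert rt.total_richness == 12 and rt.n_terminals == 3


class TestAnnotatedOutput:
    def test_plain_round_trip(self, three_tip_rt, tmp_path):
        out = tmp_path / "ann.nex"
        write_annotated_tree(three_tip_rt, out)
        back = read_chronogram(out)
        assert back.root_age == pytest.approx(15.0, abs=1e-9)

    def test_annotation_written(self, three_tip_rt, tmp_path):
        out = tmp_path / "ann.nex"
        root = three_tip_rt.chronogram.root_id
        write_annotated_tree(three_tip_rt, out, {root: {"shift": 1}})
        assert "shift" in out.read_text()

    def test_unknown_node_id_rejected(self, three_tip_rt, tmp_path):
        with pytest.raises(KeyError):
            write_annotated_tree(three_tip_rt, tmp_path / "x.nex", {999: {"shift": 1}})
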