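"""Alignment/tree I/O, concatenation and matrix statistics."""

import numpy as np
import pytest

from compqc.seqio import (Alignment, AlignmentFormatError, PhyloTree,
                          Supermatrix, TreeFormatError, concatenate,
                          matrix_stats, prune_to_taxa, read_alignment,
                          read_tree, write_alignment, write_partitions,
                          write_tree)


def write_fasta(path, records):
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n{seq}\n")


class TestReadAlignment:
    def test_basic_fasta(self, tmp_path):
        p = tmp_path / "g.fasta"
        write_fasta(p, [("tax1", "ACDEF"), ("tax2", "GHIKL")])
        aln = read_alignment(p)
        assert aln.n_taxa == 2 and aln.n_sites == 5
        assert aln.name == "g"
        assert aln.sequence("tax2") == "GHIKL"

    def test_unequal_lengths_names_offender(self, tmp_path):
        p = tmp_path / "bad.fasta"
        write_fasta(p, [("rec1", "ACDEF"), ("rec2", "ACDE")])
        with pytest.raises(AlignmentFormatError, match="rec2"):
            read_alignment(p)

    def test_lowercase_uppercased(self, tmp_path):
        p = tmp_path / "g.fasta"
        write_fasta(p, [("a", "acdef"), ("b", "ghikl")])
        assert read_alignment(p).sequence("a") == "ACDEF"

    def test_ambiguity_codes_become_missing(self, tmp_path, caplog):
        p = tmp_path / "g.fasta"
        write_fasta(p, [("a", "ABZC*"), ("b", "AUJOC")])
        with caplog.at_level("WARNING", logger="compqc"):
            aln = read_alignment(p)
        assert aln.sequence("a") == "AXXCX"
        assert aln.sequence("b") == "AXXXC"
        assert "missing" in caplog.text

    def test_duplicate_taxon_label(self, tmp_path):
        p = tmp_path / "g.fasta"
        write_fasta(p, [("a", "AC"), ("a", "AC")])
        with pytest.raises(AlignmentFormatError, match="duplicate"):
            read_alignment(p)

    def test_fasta_roundtrip(self, tmp_path, rng):
        seqs = ["".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY-X"), 120))
                for _ in range(5)]
        aln = Alignment([f"t{i}" for i in range(5)], seqs, name="rt")
        write_alignment(aln, tmp_path / "rt.fasta")
        back = read_alignment(tmp_path / "rt.fasta")
        assert back.taxa == aln.taxa and back.sequences == aln.sequences

    def test_phylip_roundtrip(self, tmp_path):
        aln = Alignment(["taxon_one", "t2"], ["ACDEF", "GHIKL"], name="p")
        write_alignment(aln, tmp_path / "p.phy", format="phylip-relaxed")
        back = read_alignment(tmp_path / "p.phy", format="phylip-relaxed")
        assert back.taxa == aln.taxa and back.sequences == aln.sequences


class TestReadTree:
    def test_parse_with_lengths(self, tmp_path):
        p = tmp_path / "t.nwk"
        p.write_text("((A:0.1,B:0.2):0.05,C:0.3);")
        tree = read_tree(p)
        assert sorted(tree.tip_labels()) == ["A", "B", "C"]
        assert tree.n_edges == 4
        assert tree.total_length() == pytest.approx(0.65)

    def test_missing_lengths_default_zero(self, tmp_path, caplog):
        p = tmp_path / "t.nwk"
        p.write_text("((A,B),C);")
        with caplog.at_level("WARNING", logger="compqc"):
            tree = read_tree(p)
        assert tree.total_length() == 0.0
        assert "branch length" in caplog.text

    def test_duplicate_tips_error(self, tmp_path):
        p = tmp_path / "t.nwk"
        p.write_text("((A:0.1,A:0.2):0.1,C:0.3);")
        with pytest.raises(TreeFormatError, match="duplicate"):
            read_tree(p)

    def test_unbalanced_parentheses(self, tmp_path):
        p = tmp_path / "t.nwk"
        p.write_text("((A:0.1,B:0.2):0.05,C:0.3;")
        with pytest.raises(TreeFormatError):
            read_tree(p)

    def test_newick_roundtrip(self, tmp_path):
        nwk = "((A:0.123456,B:0.2):0.05,(C:0.31,D:1e-06):0.07);"
        tree = PhyloTree.from_newick(nwk)
        write_tree(tree, tmp_path / "t.nwk")
        back = read_tree(tmp_path / "t.nwk")
        assert sorted(back.tip_labels()) == sorted(tree.tip_labels())
        assert back.total_length() == pytest.approx(tree.total_length(), rel=1e-9)
        assert back.to_newick() == tree.to_newick()


def _aln(name, taxa, seqs):
    return Alignment(list(taxa), list(seqs), name=name)


class TestConcatenate:
    def test_length_additivity_and_partitions(self):
        g1 = _aln("g1", ["A", "B"], ["ACD", "ACD"])
        g2 = _aln("g2", ["A", "B"], ["EFGH", "EFGH"])
        sm = concatenate([g1, g2])
        assert sm.total_length == 7
        assert sm.partitions == [("g1", 1, 3), ("g2", 4, 7)]

    def test_missing_taxon_fill_and_occupancy(self):
        g1 = _aln("g1", ["A", "B"], ["ACD", "ACD"])
        g2 = _aln("g2", ["B"], ["EFGH"])
        sm = concatenate([g1, g2], missing_symbol="-")
        assert sm.alignment.sequence("A") == "ACD----"
        assert sm.occupancy == {"A": 1, "B": 2}

    def test_single_gene_identity(self):
        g = _aln("g", ["A", "B"], ["ACD", "CDE"])
        sm = concatenate([g])
        assert sm.alignment.sequences == g.sequences
        assert sm.partitions == [("g", 1, 3)]

    def test_empty_and_duplicates(self):
        with pytest.raises(ValueError):
            concatenate([])
        g = _aln("g", ["A"], ["AC"])
        with pytest.raises(ValueError, match="duplicate"):
            concatenate([g, g])

    def test_taxa_sorted_union(self):
        g1 = _aln("g1", ["C", "A"], ["AC", "AC"])
        g2 = _aln("g2", ["B"], ["DD"])
        assert concatenate([g1, g2]).alignment.taxa == ["A", "B", "C"]

    def test_associative_total(self):
        g1 = _aln("g1", ["A", "B"], ["AC", "CD"])
        g2 = _aln("g2", ["B", "C"], ["DDD", "EEE"])
        g3 = _aln("g3", ["A", "C"], ["F", "G"])
        ab = concatenate([g1, g2])
        step = concatenate([ab.alignment.__class__(ab.alignment.taxa,
                                                   ab.alignment.sequences, "g12"),
                            g3])
        flat = concatenate([g1, g2, g3])
        assert step.total_length == flat.total_length
        assert step.alignment.sequences == flat.alignment.sequences


class TestMatrixStats:
    def test_hand_counted_gaps(self):
        g = _aln("g", ["A", "B"], ["AC-D", "-CDD"])
        stats = matrix_stats(concatenate([g]))
        assert stats.pct_gaps == pytest.approx(25.0)

    def test_partition_length_summaries(self):
        g1 = _aln("g1", ["A"], ["ACD"])
        g2 = _aln("g2", ["A"], ["ACDE"])
        stats = matrix_stats(concatenate([g1, g2]))
        assert stats.mean_partition_len == pytest.approx(3.5)
        assert stats.sd_partition_len == pytest.approx(np.std([3, 4], ddof=1))

    def test_gap_pct_is_cellwise_mean_of_blocks(self, rng):
        genes = []
        for k in range(4):
            n = int(rng.integers(3, 8))
            seqs = ["".join(rng.choice(list("ACDE-X"), n)) for _ in range(3)]
            genes.append(_aln(f"g{k}", ["A", "B", "C"], seqs))
        sm = concatenate(genes)
        cells = "".join(sm.alignment.sequences)
        direct = 100.0 * sum(c in "-X?" for c in cells) / len(cells)
        assert matrix_stats(sm).pct_gaps == pytest.approx(direct)

    def test_clade_means_and_unknown_taxon(self):
        g1 = _aln("g1", ["A", "B"], ["AC", "AC"])
        g2 = _aln("g2", ["A"], ["DD"])
        sm = concatenate([g1, g2])
        stats = matrix_stats(sm, clade_map={"A": "x", "B": "y"})
        assert stats.per_clade_mean_counts == {"x": 2.0, "y": 1.0}
        with pytest.raises(KeyError):
            matrix_stats(sm, clade_map={"Z": "x"})


def test_partition_file_format(tmp_path):
    g1 = _aln("g1", ["A"], ["ACD"])
    g2 = _aln("g2", ["A"], ["EF"])
    sm = concatenate([g1, g2])
    write_partitions(sm, tmp_path / "parts.txt", model="LG+G")
    lines = (tmp_path / "parts.txt").read_text().splitlines()
    assert lines == ["LG+G, g1 = 1-3", "LG+G, g2 = 4-5"]


def test_prune_preserves_patristic_distance():
    tree = PhyloTree.from_newick(
        "(((A:0.1,B:0.2):0.3,C:0.4):0.05,(D:0.6,E:0.7):0.08);")
    pruned = prune_to_taxa(tree, ["A", "C", "D"])
    assert sorted(pruned.tip_labels()) == ["A", "C", "D"]
    # A-to-C path: 0.1 + 0.3 + 0.4 must survive the removal of B
    def depths(t):
        out = {}
        def walk(node, d):
            d += node.length
            if node.is_tip:
                out[node.label] = d
            for c in node.children:
                walk(c, d)
        walk(t.root, -t.root.length)
        return out
    d0, d1 = depths(tree), depths(pruned)
    # pairwise distance A-C computed through the (unchanged) root
    assert (d1["A"] + d1["C"]) == pytest.approx(d0["A"] + d0["C"])
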