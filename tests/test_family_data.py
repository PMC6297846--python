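import pytest

from famexpand.family_data import (
    FamilyDataError,
    GeneRecord,
    SpeciesTaxonomy,
    parse_species_code,
    read_fasta,
    read_gene_positions,
    read_newick,
    read_taxonomy,
    validate_unique_ranks,
    write_fasta,
    write_gene_positions,
    write_newick,
)


class TestFasta:
    def test_single_record(self, tmp_path):
        p = tmp_path / "a.fasta"
        p.write_text(">g1_MUSAC\nATGAAA\n")
        assert read_fasta(str(p)) == [("g1_MUSAC", "ATGAAA")]

    def test_empty_body_is_error_with_line(self, tmp_path):
        p = tmp_path / "a.fasta"
        p.write_text(">g1_MUSAC\n>g2_MUSAC\nATG\n")
        with pytest.raises(FamilyDataError, match=r":1"):
            read_fasta(str(p))

    def test_empty_file_is_error(self, tmp_path):
        p = tmp_path / "a.fasta"
        p.write_text("")
        with pytest.raises(FamilyDataError):
            read_fasta(str(p))

    def test_data_before_header_is_error(self, tmp_path):
        p = tmp_path / "a.fasta"
        p.write_text("ATG\n>g1\nATG\n")
        with pytest.raises(FamilyDataError, match=r":1"):
            read_fasta(str(p))

    def test_round_trip(self, tmp_path):
        records = [("g1_MUSAC", "ATGAAA" * 30), ("g2_ARATH", "ATG")]
        p = tmp_path / "rt.fasta"
        write_fasta(str(p), records)
        assert read_fasta(str(p)) == records


class TestSpeciesCode:
    @pytest.mark.parametrize(
        "label,expected",
        [("LOC103696170_PHODA", "PHODA"), ("Ma01_g14150_MUSAC", "MUSAC")],
    )
    def test_trailing_code(self, label, expected):
        assert parse_species_code(label) == expected

    def test_map_fallback(self):
        assert parse_species_code("gene1", {"gene1": "ARATH"}) == "ARATH"

    def test_unresolved_is_error(self):
        with pytest.raises(FamilyDataError, match="gene1"):
            parse_species_code("gene1")


class TestNewick:
    def test_supports_parsed(self):
        t = read_newick("((a_MUSAC:0.1,b_ARATH:0.2)0.98:0.05,c_AMBTC:0.3);")
        internal = [n for n in t.preorder() if not n.is_leaf and n.parent is not None]
        assert len(internal) == 1 and internal[0].support == pytest.approx(0.98)

    def test_no_supports_is_fine(self):
        t = read_newick("((a_MUSAC:0.1,b_ARATH:0.2):0.05,c_AMBTC:0.3);")
        assert all(n.support is None for n in t.preorder())

    def test_polytomy_allowed(self):
        t = read_newick("(a_MUSAC:1,b_ARATH:1,c_AMBTC:1,d_ORYSA:1);")
        assert len(t.root.children) == 4

    def test_unbalanced_is_error(self):
        with pytest.raises(FamilyDataError):
            read_newick("((a_MUSAC:0.1,b_ARATH:0.2;")

    def test_negative_length_is_error(self):
        with pytest.raises(FamilyDataError, match="negative"):
            read_newick("(a_MUSAC:-0.1,b_ARATH:0.2);")

    def test_round_trip_preserves_everything(self, tmp_path):
        src = "((a_MUSAC:0.123456789,b_ARATH:0.2)0.98:0.05,(c_AMBTC:0.3,d_ORYSA:0.12)0.5:0.07);"
        t = read_newick(src)
        p = tmp_path / "t.nwk"
        write_newick(t, str(p))
        t2 = read_newick(str(p))
        for n1, n2 in zip(t.preorder(), t2.preorder()):
            assert n1.label == n2.label
            assert n1.length == pytest.approx(n2.length, abs=1e-9)
            assert n1.support == n2.support

    def test_branch_marks_round_trip(self):
        t = read_newick("((a_MUSAC:0.1,b_ARATH:0.2) #1 :0.05,c_AMBTC:0.3);")
        marks = [n.branch_mark for n in t.preorder()]
        assert marks.count("1") == 1
        t2 = read_newick(write_newick(t))
        assert [n.branch_mark for n in t2.preorder()] == marks


class TestGeneRecord:
    def test_invalid_species_code(self):
        with pytest.raises(FamilyDataError, match="species code"):
            GeneRecord("g1", "mus", "chr1", 0)

    def test_internal_stop_rejected(self):
        with pytest.raises(FamilyDataError, match="stop"):
            GeneRecord("g1", "MUSAC", "chr1", 0, cds_seq="ATGTAAAAATGA")

    def test_terminal_stop_allowed(self):
        GeneRecord("g1", "MUSAC", "chr1", 0, cds_seq="ATGAAATGA")

    def test_cds_length_multiple_of_three(self):
        with pytest.raises(FamilyDataError, match="divisible"):
            GeneRecord("g1", "MUSAC", "chr1", 0, cds_seq="ATGA")


class TestGenePositions:
    def test_tsv_round_trip(self, tmp_path):
        recs = [
            GeneRecord("g1", "MUSAC", "chr1", 10, "+"),
            GeneRecord("g2", "MUSAC", "chr1", 16, "-"),
            GeneRecord("g3", "MUSAC", "chr2", 3, "unknown"),
        ]
        p = tmp_path / "pos.tsv"
        write_gene_positions(str(p), recs)
        back = read_gene_positions(str(p))
        assert [(r.gene_id, r.chromosome, r.order_rank, r.strand) for r in back] == [
            (r.gene_id, r.chromosome, r.order_rank, r.strand) for r in recs
        ]

    def test_duplicate_rank_is_error(self, tmp_path):
        p = tmp_path / "pos.tsv"
        p.write_text("g1\tMUSAC\tchr1\t5\t+\ng2\tMUSAC\tchr1\t5\t-\n")
        with pytest.raises(FamilyDataError, match="duplicate"):
            read_gene_positions(str(p))

    GFF = (
        "##gff-version 3\n"
        "chr1\tsrc\tgene\t500\t900\t.\t+\t.\tID=gB\n"
        "chr1\tsrc\tgene\t100\t300\t.\t-\t.\tID=gA\n"
        "chr1\tsrc\tmRNA\t100\t300\t.\t-\t.\tID=tA\n"
        "chr1\tsrc\tgene\t900\t950\t.\t+\t.\tID=gC\n"
    )

    def test_gff3_ranks_by_start(self, tmp_path):
        p = tmp_path / "in.gff3"
        p.write_text(self.GFF)
        recs = read_gene_positions(str(p), species_code="MUSAC")
        assert [(r.gene_id, r.order_rank) for r in recs] == [("gA", 0), ("gB", 1), ("gC", 2)]

    def test_gff3_sort_invariance(self, tmp_path):
        lines = self.GFF.splitlines()
        shuffled = "\n".join([lines[0]] + list(reversed(lines[1:]))) + "\n"
        p1, p2 = tmp_path / "a.gff3", tmp_path / "b.gff3"
        p1.write_text(self.GFF)
        p2.write_text(shuffled)
        r1 = read_gene_positions(str(p1), species_code="MUSAC")
        r2 = read_gene_positions(str(p2), species_code="MUSAC")
        assert {(r.gene_id, r.order_rank) for r in r1} == {(r.gene_id, r.order_rank) for r in r2}


class TestTaxonomy:
    def test_read_and_query(self, tmp_path):
        p = tmp_path / "tax.tsv"
        p.write_text("MUSAC\tangiosperms;monocots;commelinids;Zingiberales\n"
                     "ARATH\tangiosperms;dicots;rosids\n")
        tax = read_taxonomy(str(p))
        assert tax.in_lineage("MUSAC", "monocots")
        assert not tax.in_lineage("ARATH", "monocots")
        assert tax.split_lineage("MUSAC", {"monocots", "dicots"}) == "monocots"

    def test_mismatched_roots_rejected(self):
        with pytest.raises(FamilyDataError, match="root"):
            SpeciesTaxonomy({"MUSAC": ["plants"], "ARATH": ["angiosperms"]})

    def test_depth_ordering(self, taxonomy):
        assert taxonomy.is_strictly_deeper({"Poales", "Arecales"}, {"monocots", "dicots"})
        assert not taxonomy.is_strictly_deeper({"monocots"}, {"Poales"})
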