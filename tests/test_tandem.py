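import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from famexpand.family_data import FamilyDataError, GeneRecord
from famexpand.tandem import (
    PARTIAL,
    TandemCluster,
    build_matrix,
    consensus,
    count_loci,
    detect_clusters,
)


def recs(ranks, species="MUSAC", chrom="chr1", strand="+"):
    return [GeneRecord(f"g{r}", species, chrom, r, strand) for r in ranks]


class TestDetectClusters:
    def test_boundary_five_intervening_joins(self):
        out = detect_clusters(recs([10, 16]), max_gap=5)
        assert len(out) == 1 and len(out[0]) == 2

    def test_six_intervening_splits(self):
        assert detect_clusters(recs([10, 17]), max_gap=5) == []
        out = detect_clusters(recs([10, 17]), max_gap=5, keep_singletons=True)
        assert [len(c) for c in out] == [1, 1]

    def test_transitive_chaining(self):
        out = detect_clusters(recs([10, 16, 22]), max_gap=5)
        assert len(out) == 1 and out[0].gene_ids == ["g10", "g16", "g22"]

    def test_input_order_invariance_and_idempotence(self):
        genes = recs([22, 10, 16]) + recs([40, 50], chrom="chr2")
        a = detect_clusters(genes, max_gap=5, keep_singletons=True)
        b = detect_clusters(list(reversed(genes)), max_gap=5, keep_singletons=True)
        key = lambda cs: [(c.species_code, c.chromosome, c.gene_ids) for c in cs]
        assert key(a) == key(b)

    @pytest.mark.parametrize("ranks", [[0, 3, 9, 20, 24, 31], [5, 6, 7], [1, 99]])
    def test_max_gap_monotone(self, ranks):
        counts = [
            len(detect_clusters(recs(ranks), g, keep_singletons=True)) for g in range(0, 12)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_species_grouped_not_mixed(self):
        genes = recs([10, 12]) + recs([10, 12], species="ORYSA")
        out = detect_clusters(genes)
        assert {c.species_code for c in out} == {"MUSAC", "ORYSA"}
        assert all(len({m[0] for m in c.members}) == len(c) for c in out)


class TestCountLoci:
    def test_counts_per_species(self):
        genes = recs([10, 12]) + recs([40, 42], chrom="chr2") + recs([1, 2], species="ORYSA")
        cl = detect_clusters(genes)
        assert count_loci(cl, "MUSAC") == 2
        assert count_loci(cl, "ORYSA") == 1

    def test_empty(self):
        assert count_loci([], "MUSAC") == 0

    def test_unknown_species_is_error(self):
        with pytest.raises(FamilyDataError, match="unknown"):
            count_loci([], "XXXXX", known_species={"MUSAC"})


def cluster(labels, species="AAAAA", chrom="c1", strands=None, ids=None):
    strands = strands or ["+"] * len(labels)
    ids = ids or [f"{species}_{chrom}_{i}" for i in range(len(labels))]
    return TandemCluster(
        species, chrom, [(ids[i], i, strands[i], labels[i]) for i in range(len(labels))]
    )


class TestMatrix:
    def test_auto_order_from_adjacencies(self):
        m = build_matrix([
            cluster(["A1", "A2"], chrom="c1"),
            cluster(["A2", "A3"], chrom="c2"),
            cluster(["A1", "A2", "A3"], chrom="c3"),
        ])
        assert m.column_order == ["A1", "A2", "A3"]

    def test_multiple_genes_per_cell(self):
        c = cluster(["A1", "A2", "A2"], ids=["x", "y", "z"])
        m = build_matrix([c], column_order=["A1", "A2"])
        assert m.render_cell(0, "A2") == "y,z"

    def test_unlabeled_member_renders_partial(self):
        c = cluster(["A1", None, "A2"])
        m = build_matrix([c], column_order=["A1", "A2"])
        assert m.cells[0][PARTIAL]

    def test_row_reversal_detected(self):
        fwd = cluster(["A1", "A2", "A3"], chrom="c1")
        rev = cluster(["A3", "A2", "A1"], chrom="c2")
        m = build_matrix([fwd, fwd, rev], column_order=["A1", "A2", "A3"])
        assert m.reversed_rows == [False, False, True]


class TestConsensus:
    def test_unanimous_plus_is_forward(self):
        m = build_matrix([cluster(["A1"], strands=["+"]), cluster(["A1"], strands=["+"], chrom="c2")],
                         column_order=["A1"])
        assert consensus(m)["A1"] == (1.0, ">")

    def test_tie_is_mixed(self):
        m = build_matrix(
            [cluster(["A1", "A2"], strands=["+", "+"]),
             cluster(["A1", "A2"], strands=["-", "+"], chrom="c2")],
            column_order=["A1", "A2"],
        )
        assert consensus(m)["A1"][1] == "mixed"

    def test_reversed_row_votes_flipped(self):
        fwd = cluster(["A1", "A2"], strands=["+", "-"], chrom="c1")
        fwd2 = cluster(["A1", "A2"], strands=["+", "-"], chrom="c2")
        rev = cluster(["A2", "A1"], strands=["+", "-"], chrom="c3")  # inverted locus
        m = build_matrix([fwd, fwd2, rev], column_order=["A1", "A2"])
        cons = consensus(m)
        assert cons["A1"] == (1.0, ">")
        assert cons["A2"] == (1.0, "<")

    def test_unknown_strands_excluded(self):
        m = build_matrix([cluster(["A1"], strands=["unknown"])], column_order=["A1"])
        assert consensus(m)["A1"][1] == "unknown"

    def test_presence_fraction(self):
        m = build_matrix(
            [cluster(["A1", "A2"]), cluster(["A1"], chrom="c2")],
            column_order=["A1", "A2"],
        )
        cons = consensus(m)
        assert cons["A1"][0] == 1.0
        assert cons["A2"][0] == 0.5

    def test_empty_matrix_is_error(self):
        m = build_matrix([], column_order=["A1"])
        with pytest.raises(FamilyDataError, match="empty"):
            consensus(m)


class TestClusterProperties:
    """Randomized invariants of the cluster rule."""

    rank_sets = st.lists(st.integers(min_value=0, max_value=200), min_size=1,
                         max_size=25, unique=True)

    @given(ranks=rank_sets, max_gap=st.integers(min_value=0, max_value=10))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_order_invariance_and_coverage(self, ranks, max_gap):
        genes = recs(sorted(ranks))
        shuffled = recs(list(reversed(sorted(ranks))))
        a = detect_clusters(genes, max_gap, keep_singletons=True)
        b = detect_clusters(shuffled, max_gap, keep_singletons=True)
        assert [c.gene_ids for c in a] == [c.gene_ids for c in b]
        # every gene lands in exactly one cluster
        all_ids = [g for c in a for g in c.gene_ids]
        assert sorted(all_ids) == sorted(f"g{r}" for r in ranks)
        # within clusters, consecutive gaps respect max_gap; across cluster
        # boundaries they exceed it
        for c in a:
            rs = [m[1] for m in c.members]
            assert all(y - x - 1 <= max_gap for x, y in zip(rs, rs[1:]))
        ends = [c.members[-1][1] for c in a]
        starts = [c.members[0][1] for c in a]
        assert all(s - e - 1 > max_gap for e, s in zip(ends, starts[1:]))

    @given(ranks=rank_sets)
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_max_gap_monotonicity(self, ranks):
        genes = recs(sorted(ranks))
        counts = [len(detect_clusters(genes, g, keep_singletons=True))
                  for g in range(0, 15)]
        assert counts == sorted(counts, reverse=True)
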