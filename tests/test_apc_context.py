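import numpy as np
import pytest

from lincscout.apc_context import (
    CONFIGURATION_LABELS,
    assign_apcgenes,
    classify_configuration,
    configuration_tally,
    relationship_census,
)
from lincscout.errors import ValidationError
from lincscout.io_formats import GENE_MODEL, TRANSCRIPT, GenomicFeature

from oracles import nearest_genes_linear_scan


def gene(fid, start, end, strand="+", contig="c1"):
    return GenomicFeature(contig, start, end, strand, fid, GENE_MODEL)


def linc(fid, start, end, contig="c1"):
    return GenomicFeature(contig, start, end, ".", fid, TRANSCRIPT)


class TestAssignApcgenes:
    def test_nearest_flanking_genes_and_gap_distances(self):
        a = assign_apcgenes(
            linc("L1", 3000, 3500),
            [gene("g1", 1000, 2000, "+"), gene("g2", 5000, 6000, "-")],
        )
        assert (a.upstream_gene, a.upstream_distance_bp) == ("g1", 999)
        assert (a.downstream_gene, a.downstream_distance_bp) == ("g2", 1499)

    def test_contig_start_has_no_upstream_gene(self):
        a = assign_apcgenes(linc("L1", 100, 400),
                            [gene("g1", 1000, 2000)])
        assert a.upstream_gene is None
        assert a.downstream_gene == "g1"

    def test_bookended_gene_has_distance_zero(self):
        a = assign_apcgenes(linc("L1", 2001, 2400),
                            [gene("g1", 1000, 2000)])
        assert a.upstream_distance_bp == 0

    def test_genes_on_other_contigs_ignored(self):
        a = assign_apcgenes(
            linc("L1", 3000, 3500),
            [gene("g1", 1000, 2000, contig="c2")],
        )
        assert a.upstream_gene is None and a.downstream_gene is None

    def test_overlapping_gene_violates_intergenic_precondition(self):
        with pytest.raises(ValidationError, match="overlap"):
            assign_apcgenes(linc("L1", 3000, 3500),
                            [gene("g1", 3400, 4000)])

    def test_tie_broken_toward_smaller_start_and_flagged(self):
        a = assign_apcgenes(
            linc("L1", 3000, 3500),
            [gene("gA", 1500, 2000), gene("gB", 1000, 2000)],
        )
        assert a.upstream_gene == "gB"
        assert a.upstream_tie

    def test_agrees_with_linear_scan_oracle(self):
        """200 random gene layouts (<= 100 genes) vs the naive scan."""
        rng = np.random.default_rng(5150)
        for _ in range(200):
            n = int(rng.integers(0, 101))
            genes, triples = [], []
            for i in range(n):
                start = int(rng.integers(1, 100_000))
                end = start + int(rng.integers(50, 3000))
                if start <= 23_000 and 20_000 <= end:
                    continue  # keep the lincRNA interval gene-free
                genes.append(gene(f"g{i}", start, end))
                triples.append((f"g{i}", start, end))
            a = assign_apcgenes(linc("L", 20_000, 23_000), genes)
            up, up_d, down, down_d = nearest_genes_linear_scan(
                20_000, 23_000, triples
            )
            assert (a.upstream_gene, a.upstream_distance_bp) == (up, up_d)
            assert (a.downstream_gene, a.downstream_distance_bp) == (
                down, down_d
            )


class TestRelationshipCensus:
    def test_one_lincrna_between_two_genes_is_1_to_2(self):
        a = assign_apcgenes(
            linc("L1", 3000, 3500),
            [gene("g1", 1000, 2000), gene("g2", 5000, 6000)],
        )
        census = relationship_census([a])
        assert census["1:2"] == 1

    def test_two_lincrnas_flanking_one_gene_is_2_to_1(self):
        genes = [gene("g1", 5000, 6000)]
        a1 = assign_apcgenes(linc("L1", 3000, 3500), genes)
        a2 = assign_apcgenes(linc("L2", 7000, 7500), genes)
        census = relationship_census([a1, a2])
        assert a1.downstream_gene == a2.upstream_gene == "g1"
        assert census["2:1"] == 1
        assert census["apcGenes"] == 1

    def test_three_consecutive_lincrnas_share_one_gene_n_to_1(self):
        genes = [gene("g1", 20_000, 22_000)]
        assignments = [
            assign_apcgenes(linc(f"L{i}", 1000 * i, 1000 * i + 400), genes)
            for i in (1, 3, 5)
        ]
        assert all(a.downstream_gene == "g1" for a in assignments)
        census = relationship_census(assignments)
        assert census["n:1"] == 1

    def test_empty_input_gives_empty_census(self):
        assert relationship_census([]) == {}


# Hand-derived truth table over the full (geometry x gene strand x call)
# input space: lincRNA left or right of the gene, gene on + or -, call
# F / R / FR. Left of a + gene (or right of a - gene) is the gene's 5'
# side; F means the lincRNA runs on +, so it matches a + gene (same) and
# opposes a - gene.
TRUTH_TABLE = [
    ("left", "+", "F", "C1_5P_SAME"),
    ("left", "+", "R", "C2_5P_OPP"),
    ("left", "+", "FR", "C3_5P_BIDIR"),
    ("left", "-", "F", "C5_3P_OPP"),
    ("left", "-", "R", "C4_3P_SAME"),
    ("left", "-", "FR", "C6_3P_BIDIR"),
    ("right", "+", "F", "C4_3P_SAME"),
    ("right", "+", "R", "C5_3P_OPP"),
    ("right", "+", "FR", "C6_3P_BIDIR"),
    ("right", "-", "F", "C2_5P_OPP"),
    ("right", "-", "R", "C1_5P_SAME"),
    ("right", "-", "FR", "C3_5P_BIDIR"),
]


class TestClassifyConfiguration:
    @pytest.mark.parametrize("geometry,strand,call,expected", TRUTH_TABLE)
    def test_all_twelve_cases(self, geometry, strand, call, expected):
        g = gene("g1", 10_000, 12_000, strand)
        lnc = (linc("L1", 8000, 8500) if geometry == "left"
               else linc("L1", 13_000, 13_500))
        assert classify_configuration(lnc, g, call).label == expected

    def test_every_class_reachable(self):
        labels = {
            classify_configuration(
                linc("L", 8000, 8500) if geom == "left"
                else linc("L", 13_000, 13_500),
                gene("g", 10_000, 12_000, strand),
                call,
            ).label
            for geom, strand, call, _ in TRUTH_TABLE
        }
        assert labels == set(CONFIGURATION_LABELS.values())

    def test_unknown_gene_strand_rejected(self):
        with pytest.raises(ValidationError, match="strand"):
            classify_configuration(
                linc("L", 8000, 8500), gene("g", 10_000, 12_000, "."), "F"
            )

    def test_overlapping_pair_rejected(self):
        with pytest.raises(ValidationError, match="overlap"):
            classify_configuration(
                linc("L", 9000, 11_000), gene("g", 10_000, 12_000, "+"), "F"
            )


def reconstruct_pairs_from_class_counts(counts):
    """Build one synthetic (lincRNA, gene, call) geometry per pair from
    per-class counts keyed C1..C6."""
    layout = {
        "C1_5P_SAME": ("left", "+", "F"),
        "C2_5P_OPP": ("left", "+", "R"),
        "C3_5P_BIDIR": ("left", "+", "FR"),
        "C4_3P_SAME": ("right", "+", "F"),
        "C5_3P_OPP": ("right", "+", "R"),
        "C6_3P_BIDIR": ("right", "+", "FR"),
    }
    pairs = []
    for label, n in counts.items():
        geom, strand, call = layout[label]
        for _ in range(n):
            g = gene("g", 10_000, 12_000, strand)
            lnc = (linc("L", 8000, 8500) if geom == "left"
                   else linc("L", 13_000, 13_500))
            pairs.append((lnc, g, call))
    return pairs


def test_side_and_direction_margins_of_a_46_pair_survey():
    """A survey with per-class counts 16/8/6/9/4/3 must tally 30 pairs on
    the gene's 5' side, 16 on the 3' side, 37 unidirectional and 9
    bidirectional."""
    counts = {
        "C1_5P_SAME": 16, "C2_5P_OPP": 8, "C3_5P_BIDIR": 6,
        "C4_3P_SAME": 9, "C5_3P_OPP": 4, "C6_3P_BIDIR": 3,
    }
    classes = [
        classify_configuration(lnc, g, call)
        for lnc, g, call in reconstruct_pairs_from_class_counts(counts)
    ]
    tally = configuration_tally(classes)
    assert tally["5P_total"] == 30
    assert tally["3P_total"] == 16
    assert tally["unidirectional"] == 37
    assert tally["bidirectional"] == 9
    for label, n in counts.items():
        assert tally[label] == n
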