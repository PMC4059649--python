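import itertools

import numpy as np
import pytest

from lincscout.errors import MissingInputError, ValidationError
from lincscout.io_formats import (
    GENE_MODEL,
    TRANSCRIPT,
    CodingScoreRecord,
    GenomicFeature,
    HitRecord,
)
from lincscout.tu_discovery import (
    CascadeReport,
    FilterThresholds,
    TranscriptUnit,
    apply_coding_potential_filter,
    apply_hit_filter,
    drop_coding_by_orf,
    drop_gene_containing,
    drop_short,
    longest_orf_aa,
    merge_to_transcript_units,
)

from oracles import brute_force_tu_partition, exhaustive_longest_orf


def feat(contig, start, end, fid, role=TRANSCRIPT, strand="."):
    return GenomicFeature(contig, start, end, strand, fid, role)


def tu(tu_id, start, end, sequence=None, contig="c1", gene=False):
    return TranscriptUnit(
        tu_id=tu_id, contig=contig, start=start, end=end,
        members=(feat(contig, start, end, f"m_{tu_id}"),),
        contains_gene_model=gene, sequence=sequence,
    )


class TestMerge:
    def test_disjoint_intervals_stay_separate(self):
        tus = merge_to_transcript_units(
            [feat("c1", 100, 200, "a"), feat("c1", 300, 400, "b")]
        )
        assert len(tus) == 2

    def test_overlap_chain_merges_transitively(self):
        tus = merge_to_transcript_units([
            feat("c1", 100, 200, "a"),
            feat("c1", 150, 300, "b"),
            feat("c1", 250, 400, "c"),
        ])
        assert len(tus) == 1
        assert (tus[0].start, tus[0].end) == (100, 400)
        assert {m.feature_id for m in tus[0].members} == {"a", "b", "c"}

    def test_bookended_intervals_do_not_merge(self):
        tus = merge_to_transcript_units(
            [feat("c1", 100, 200, "a"), feat("c1", 201, 300, "b")]
        )
        assert len(tus) == 2

    def test_merge_ignores_strand(self):
        tus = merge_to_transcript_units([
            feat("c1", 100, 200, "a", strand="+"),
            feat("c1", 150, 300, "b", strand="-"),
        ])
        assert len(tus) == 1

    def test_same_coordinates_different_contigs_stay_separate(self):
        tus = merge_to_transcript_units(
            [feat("c1", 100, 200, "a"), feat("c2", 100, 200, "b")]
        )
        assert len(tus) == 2

    def test_gene_membership_flag(self):
        tus = merge_to_transcript_units([
            feat("c1", 100, 200, "t1"),
            feat("c1", 150, 400, "g1", role=GENE_MODEL),
        ])
        assert tus[0].contains_gene_model

    def test_merge_is_idempotent(self):
        feats = [feat("c1", i * 90 + 1, i * 90 + 120, f"f{i}")
                 for i in range(8)]
        once = merge_to_transcript_units(feats)
        spans1 = {(t.contig, t.start, t.end) for t in once}
        again = merge_to_transcript_units([
            feat(t.contig, t.start, t.end, t.tu_id) for t in once
        ])
        assert spans1 == {(t.contig, t.start, t.end) for t in again}

    def test_unknown_contig_named_in_error(self):
        with pytest.raises(ValidationError, match="c9"):
            merge_to_transcript_units(
                [feat("c9", 1, 10, "a")], known_contigs=["c1"]
            )

    def test_agrees_with_brute_force_oracle(self):
        """200 random instances of <= 50 intervals vs union-find oracle."""
        rng = np.random.default_rng(2024)
        for _ in range(200):
            n = int(rng.integers(0, 51))
            feats = []
            for i in range(n):
                contig = f"c{rng.integers(1, 3)}"
                start = int(rng.integers(1, 1000))
                length = int(rng.integers(1, 120))
                feats.append(feat(contig, start, start + length - 1,
                                  f"f{i}"))
            got = {
                frozenset(m.feature_id for m in t.members)
                for t in merge_to_transcript_units(feats)
            }
            assert got == brute_force_tu_partition(feats)


class TestLongestOrf:
    def test_single_met_then_stop(self):
        assert longest_orf_aa("ATGTAA") == 1

    def test_no_atg_on_either_strand_gives_zero(self):
        assert longest_orf_aa("CCCCCCCCC") == 0

    def test_open_ended_orf_counts_to_last_complete_codon(self):
        assert longest_orf_aa("ATGAAAAA") == 2  # ATG AAA, trailing AA cut

    def test_reverse_strand_scanned(self):
        # revcomp of ATGGCGTAA (ORF of 2 aa) embedded on the minus strand
        seq = "TTACGCCAT"
        assert longest_orf_aa(seq) == 2

    def test_codons_with_n_neither_start_nor_stop(self):
        # N codon inside an ORF extends it; N never matches ATG
        assert longest_orf_aa("ATGNNNTAA") == 2
        assert longest_orf_aa("NTGAAATAA") == 0

    def test_non_nucleotide_character_rejected(self):
        with pytest.raises(ValidationError):
            longest_orf_aa("ATGXXXTAA")

    def test_agrees_with_exhaustive_scan_oracle(self):
        """100 random 600-nt sequences vs the every-position oracle."""
        rng = np.random.default_rng(77)
        bases = np.array(list("ACGTN"))
        for _ in range(100):
            seq = "".join(
                bases[rng.integers(0, 5, 600)]
            )
            assert longest_orf_aa(seq) == exhaustive_longest_orf(seq)


class TestFilterStages:
    def test_gene_containing_discarded(self):
        retained, discarded = drop_gene_containing(
            [tu("TU1", 1, 300, gene=True), tu("TU2", 400, 700)]
        )
        assert [t.tu_id for t in retained] == ["TU2"]
        assert [t.tu_id for t in discarded] == ["TU1"]

    def test_empty_input_is_fine(self):
        assert drop_gene_containing([]) == ([], [])

    @pytest.mark.parametrize(
        "evalue,kept", [(1e-6, False), (1e-5, True), (None, True)]
    )
    def test_hit_filter_is_strict_below_cutoff(self, evalue, kept):
        hits = [] if evalue is None else [
            HitRecord("TU1", "nt1", 99.0, 100, evalue, 200.0)
        ]
        retained, _ = apply_hit_filter([tu("TU1", 1, 300)], hits)
        assert bool(retained) is kept

    def test_hit_for_unknown_tu_warned_and_ignored(self):
        hits = [HitRecord("TU99", "nt1", 99.0, 100, 1e-30, 200.0)]
        with pytest.warns(UserWarning, match="TU99"):
            retained, _ = apply_hit_filter([tu("TU1", 1, 300)], hits)
        assert len(retained) == 1

    @pytest.mark.parametrize("orf_aa,kept", [(101, False), (100, True),
                                             (0, True)])
    def test_orf_filter_boundary_is_strictly_greater(self, orf_aa, kept):
        if orf_aa:
            seq = "ATG" + "GCA" * (orf_aa - 1) + "TAA"
        else:
            seq = "CCC" * 80
        retained, _ = drop_coding_by_orf([tu("TU1", 1, len(seq), seq)])
        assert bool(retained) is kept

    @pytest.mark.parametrize("length,kept",
                             [(199, False), (200, True), (1966, True)])
    def test_length_filter_boundary(self, length, kept):
        retained, _ = drop_short([tu("TU1", 1001, 1000 + length)])
        assert bool(retained) is kept

    @pytest.mark.parametrize(
        "plus,minus,kept",
        [(-1.2, -0.3, True), (-1.2, 0.3, False), (0.0, -1.0, False)],
    )
    def test_coding_potential_requires_both_strands_negative(
        self, plus, minus, kept
    ):
        scores = {"TU1": CodingScoreRecord("TU1", plus, minus)}
        retained, _ = apply_coding_potential_filter(
            [tu("TU1", 1, 300)], scores
        )
        assert bool(retained) is kept

    def test_missing_score_record_lists_tu_ids(self):
        with pytest.raises(MissingInputError, match="TU1"):
            apply_coding_potential_filter([tu("TU1", 1, 300)], {})


class TestCascade:
    def test_bookkeeping_sums_and_monotonicity(self, cascade_result):
        _, report = cascade_result
        report.validate()
        retained = [r["n_retained"] for r in report.to_rows()]
        assert retained == sorted(retained, reverse=True)

    def test_survivors_satisfy_every_predicate(self, bundle, cascade_result):
        candidates, _ = cascade_result
        flagged = {
            h.query_id for h in bundle.hits if h.e_value < 1e-5
        }
        for c in candidates:
            assert c.length >= 200
            assert c.longest_orf_aa <= 100
            assert c.tu_id not in flagged
            assert bundle.scores[c.tu_id].plus_strand_score < 0
            assert bundle.scores[c.tu_id].minus_strand_score < 0

    def test_zero_transcripts_yield_empty_output(self, bundle):
        from lincscout.tu_discovery import run_cascade

        candidates, report = run_cascade(
            [], bundle.genome, [], {}, []
        )
        assert candidates == []
        assert all(r["n_input"] == 0 for r in report.to_rows())

    def test_filter_order_does_not_change_survivors(self, bundle,
                                                    bundle_features):
        """All five filters are independent predicates: any application
        order yields the same survivor set."""
        from lincscout.tu_discovery import attach_sequences

        tus = merge_to_transcript_units(
            bundle_features, known_contigs=bundle.genome.keys()
        )
        attach_sequences(tus, bundle.genome)
        filters = {
            "gene": lambda ts: drop_gene_containing(ts)[0],
            "hits": lambda ts: apply_hit_filter(ts, bundle.hits)[0],
            "orf": lambda ts: drop_coding_by_orf(ts)[0],
            "length": lambda ts: drop_short(ts)[0],
            "cpc": lambda ts: apply_coding_potential_filter(
                ts, bundle.scores)[0],
        }
        reference = None
        for order in itertools.permutations(filters):
            current = tus
            for name in order:
                current = filters[name](current)
            survivors = {t.tu_id for t in current}
            if reference is None:
                reference = survivors
            assert survivors == reference

    def test_report_invariant_violations_detected(self):
        report = CascadeReport()
        report.stages.append(("broken", 10, 3, 5))
        with pytest.raises(ValidationError):
            report.validate()
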