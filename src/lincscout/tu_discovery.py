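"""Transcript-unit construction and the lincRNA filter cascade.

Overlapping assembled transcripts and predicted gene models are merged into
transcript units (TUs): maximal clusters connected by chains of pairwise
interval overlap on the same contig, ignoring strand (the underlying RNA-Seq
is non-strand-specific, so annotated strands of transcripts are not
trusted for merging).

A TU becomes a lincRNA candidate if it survives, in order:

1. no predicted gene model among its members (intergenic);
2. no Nt/Nr/SP similarity hit with E-value < 1e-5;
3. longest ORF on either strand <= 100 aa (six-frame scan);
4. length >= 200 bp;
5. coding-potential score < 0 on both strands;
6. miRNA-precursor screen (annotate-only by default; zero hits expected
   for fungal lincRNAs in practice).

Each stage logs its input/discard/retain counts to a CascadeReport.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Mapping, Sequence

from .errors import MissingInputError, ValidationError
from .io_formats import (
    GENE_MODEL,
    CodingScoreRecord,
    GenomicFeature,
    HitRecord,
    extract_sequence,
)

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})


@dataclass(frozen=True)
class FilterThresholds:
    """Cutoffs of the filter cascade.

    evalue_cutoff: similarity hits below this E-value mark a TU as known
        (strict inequality). max_orf_aa: TUs whose longest ORF exceeds this
        many amino acids are considered coding. min_length_bp: shorter TUs
        are discarded. coding_score_cutoff: both strand scores must fall
        below this to call a TU non-coding.
    """

    evalue_cutoff: float = 1e-5
    max_orf_aa: int = 100
    min_length_bp: int = 200
    coding_score_cutoff: float = 0.0


@dataclass
class TranscriptUnit:
    """A merged cluster of transitively overlapping features."""

    tu_id: str
    contig: str
    start: int
    end: int
    members: tuple[GenomicFeature, ...]
    contains_gene_model: bool
    sequence: str | None = None

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def spliced_length(self) -> int:
        """Length of the union of member exon intervals (bp)."""
        intervals = []
        for m in self.members:
            intervals.extend(m.exons or [(m.start, m.end)])
        intervals.sort()
        total, cur_s, cur_e = 0, None, None
        for s, e in intervals:
            if cur_e is None or s > cur_e + 1:
                if cur_e is not None:
                    total += cur_e - cur_s + 1
                cur_s, cur_e = s, e
            else:
                cur_e = max(cur_e, e)
        if cur_e is not None:
            total += cur_e - cur_s + 1
        return total


@dataclass(frozen=True)
class LincRNACandidate:
    """A TU that survived the full cascade."""

    tu_id: str
    contig: str
    start: int
    end: int
    length: int
    sequence: str
    longest_orf_aa: int
    member_ids: tuple[str, ...]
    mirna_hit: bool = False

    @property
    def interval(self) -> tuple[int, int]:
        return (self.start, self.end)


@dataclass
class CascadeReport:
    """Per-stage count bookkeeping for the filter cascade."""

    stages: list[tuple[str, int, int, int]] = field(default_factory=list)

    def log(self, stage_name: str, n_input: int, n_discarded: int) -> None:
        self.stages.append(
            (stage_name, n_input, n_discarded, n_input - n_discarded)
        )

    def validate(self) -> None:
        prev_retained = None
        for name, n_in, n_disc, n_ret in self.stages:
            if n_in != n_disc + n_ret:
                raise ValidationError(f"stage {name}: counts do not sum")
            if prev_retained is not None and n_in != prev_retained:
                raise ValidationError(
                    f"stage {name}: input {n_in} != previous retained "
                    f"{prev_retained}"
                )
            prev_retained = n_ret

    def to_rows(self) -> list[dict]:
        return [
            {"stage": s, "n_input": i, "n_discarded": d, "n_retained": r}
            for s, i, d, r in self.stages
        ]


# ---------------------------------------------------------------------------
# TU construction
# ---------------------------------------------------------------------------

def merge_to_transcript_units(
    features: Sequence[GenomicFeature],
    known_contigs: Iterable[str] | None = None,
) -> list[TranscriptUnit]:
    """Merge transitively overlapping features into transcript units.

    Overlap is evaluated per contig and ignores strand. Two features merge
    iff they share at least one base; bookended intervals (end + 1 == start)
    stay separate. Because transitive overlap chains on a line collapse to
    interval merging, a single sorted sweep per contig suffices.

    TU identifiers are assigned deterministically as TU1, TU2, ... in
    (contig, start) order.
    """
    if known_contigs is not None:
        known = set(known_contigs)
        for f in features:
            if f.contig not in known:
                raise ValidationError(
                    f"feature {f.feature_id!r} on unknown contig "
                    f"{f.contig!r}"
                )

    by_contig: dict[str, list[GenomicFeature]] = {}
    for f in features:
        by_contig.setdefault(f.contig, []).append(f)

    tus: list[TranscriptUnit] = []
    counter = 0
    for contig in sorted(by_contig):
        feats = sorted(
            by_contig[contig], key=lambda f: (f.start, f.end, f.feature_id)
        )
        cluster: list[GenomicFeature] = []
        cur_end = None
        for f in feats + [None]:  # sentinel flushes the last cluster
            if f is not None and cur_end is not None and f.start <= cur_end:
                cluster.append(f)
                cur_end = max(cur_end, f.end)
                continue
            if cluster:
                counter += 1
                tus.append(TranscriptUnit(
                    tu_id=f"TU{counter}",
                    contig=contig,
                    start=min(m.start for m in cluster),
                    end=max(m.end for m in cluster),
                    members=tuple(cluster),
                    contains_gene_model=any(
                        m.role == GENE_MODEL for m in cluster
                    ),
                ))
            if f is not None:
                cluster = [f]
                cur_end = f.end
    return tus


def attach_sequences(
    tus: Iterable[TranscriptUnit], genome: Mapping[str, str]
) -> None:
    """Fill each TU's plus-strand genomic sequence from the genome."""
    for tu in tus:
        tu.sequence = extract_sequence(genome, tu.contig, tu.start, tu.end)


# ---------------------------------------------------------------------------
# ORF scanning
# ---------------------------------------------------------------------------

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _longest_orf_one_strand(seq: str) -> int:
    """Longest ATG-initiated ORF (aa) over the three forward frames."""
    best = 0
    n = len(seq)
    for frame in range(3):
        open_at: int | None = None  # codon index where current ORF started
        n_codons = (n - frame) // 3
        for ci in range(n_codons):
            codon = seq[frame + 3 * ci: frame + 3 * ci + 3]
            # codons containing N never match ATG and never terminate
            if codon in STOP_CODONS:
                if open_at is not None:
                    best = max(best, ci - open_at)
                    open_at = None
            elif open_at is None and codon == "ATG":
                open_at = ci
        if open_at is not None:  # open-ended ORF: count to last full codon
            best = max(best, n_codons - open_at)
    return best


def longest_orf_aa(sequence: str) -> int:
    """Length (aa) of the longest ATG-initiated ORF over all six frames.

    The count runs from the ATG (Met included) to the codon before the
    first in-frame stop; ORFs still open at the end of the sequence are
    counted to the last complete codon. Returns 0 when no frame contains
    an ATG.
    """
    seq = sequence.upper()
    bad = set(seq) - set("ACGTN")
    if bad:
        raise ValidationError(
            f"non-nucleotide character(s) {sorted(bad)} in sequence"
        )
    return max(
        _longest_orf_one_strand(seq),
        _longest_orf_one_strand(reverse_complement(seq)),
    )


# ---------------------------------------------------------------------------
# filter stages
# ---------------------------------------------------------------------------

def drop_gene_containing(
    tus: Sequence[TranscriptUnit],
    report: CascadeReport | None = None,
    stage_name: str = "gene_containing",
) -> tuple[list[TranscriptUnit], list[TranscriptUnit]]:
    retained = [tu for tu in tus if not tu.contains_gene_model]
    discarded = [tu for tu in tus if tu.contains_gene_model]
    if report is not None:
        report.log(stage_name, len(tus), len(discarded))
    return retained, discarded


def apply_hit_filter(
    tus: Sequence[TranscriptUnit],
    hits: Sequence[HitRecord],
    thresholds: FilterThresholds = FilterThresholds(),
    report: CascadeReport | None = None,
    stage_name: str = "similarity_hits",
) -> tuple[list[TranscriptUnit], list[TranscriptUnit]]:
    """Discard TUs with at least one hit at E-value strictly below cutoff."""
    known_ids = {tu.tu_id for tu in tus}
    flagged: set[str] = set()
    for h in hits:
        if h.query_id not in known_ids:
            warnings.warn(
                f"hit references unknown TU {h.query_id!r}; ignored",
                stacklevel=2,
            )
            continue
        if h.e_value < thresholds.evalue_cutoff:
            flagged.add(h.query_id)
    retained = [tu for tu in tus if tu.tu_id not in flagged]
    discarded = [tu for tu in tus if tu.tu_id in flagged]
    if report is not None:
        report.log(stage_name, len(tus), len(discarded))
    return retained, discarded


def drop_coding_by_orf(
    tus: Sequence[TranscriptUnit],
    thresholds: FilterThresholds = FilterThresholds(),
    report: CascadeReport | None = None,
    stage_name: str = "orf_length",
) -> tuple[list[TranscriptUnit], list[TranscriptUnit]]:
    """Discard TUs whose longest ORF is strictly longer than max_orf_aa."""
    retained, discarded = [], []
    for tu in tus:
        if tu.sequence is None:
            raise ValidationError(f"TU {tu.tu_id}: sequence not extracted")
        if longest_orf_aa(tu.sequence) > thresholds.max_orf_aa:
            discarded.append(tu)
        else:
            retained.append(tu)
    if report is not None:
        report.log(stage_name, len(tus), len(discarded))
    return retained, discarded


def drop_short(
    tus: Sequence[TranscriptUnit],
    thresholds: FilterThresholds = FilterThresholds(),
    report: CascadeReport | None = None,
    stage_name: str = "min_length",
    use_spliced_length: bool = False,
) -> tuple[list[TranscriptUnit], list[TranscriptUnit]]:
    """Discard TUs shorter than min_length_bp (exactly 200 bp is kept).

    Default measures the genomic span; ``use_spliced_length`` switches to
    the union of member exon intervals (identical for single-exon TUs).
    """
    def tu_len(tu: TranscriptUnit) -> int:
        return tu.spliced_length if use_spliced_length else tu.length

    retained = [tu for tu in tus if tu_len(tu) >= thresholds.min_length_bp]
    discarded = [tu for tu in tus if tu_len(tu) < thresholds.min_length_bp]
    if report is not None:
        report.log(stage_name, len(tus), len(discarded))
    return retained, discarded


def apply_coding_potential_filter(
    tus: Sequence[TranscriptUnit],
    scores: Mapping[str, CodingScoreRecord],
    thresholds: FilterThresholds = FilterThresholds(),
    report: CascadeReport | None = None,
    stage_name: str = "coding_potential",
) -> tuple[list[TranscriptUnit], list[TranscriptUnit]]:
    """Keep only TUs scoring below the cutoff on BOTH strands."""
    missing = [tu.tu_id for tu in tus if tu.tu_id not in scores]
    if missing:
        raise MissingInputError(
            f"no coding-potential score for TU(s): {', '.join(missing)}"
        )
    cut = thresholds.coding_score_cutoff
    retained = [
        tu for tu in tus
        if scores[tu.tu_id].plus_strand_score < cut
        and scores[tu.tu_id].minus_strand_score < cut
    ]
    kept = {tu.tu_id for tu in retained}
    discarded = [tu for tu in tus if tu.tu_id not in kept]
    if report is not None:
        report.log(stage_name, len(tus), len(discarded))
    return retained, discarded


# ---------------------------------------------------------------------------
# the full cascade
# ---------------------------------------------------------------------------

def run_cascade(
    features: Sequence[GenomicFeature],
    genome: Mapping[str, str],
    hits: Sequence[HitRecord],
    scores: Mapping[str, CodingScoreRecord],
    mirna_hits: Sequence[HitRecord] = (),
    thresholds: FilterThresholds = FilterThresholds(),
    mirna_filter_mode: str = "annotate",
    use_spliced_length: bool = False,
) -> tuple[list[LincRNACandidate], CascadeReport]:
    """Run TU construction and all six filter stages.

    ``mirna_filter_mode`` is "annotate" (default: matching TUs are kept but
    flagged as putative miRNA precursors) or "discard".
    """
    if mirna_filter_mode not in {"annotate", "discard"}:
        raise ValueError(f"bad mirna_filter_mode {mirna_filter_mode!r}")

    report = CascadeReport()
    tus = merge_to_transcript_units(features, known_contigs=genome.keys())
    attach_sequences(tus, genome)

    tus, _ = drop_gene_containing(tus, report)
    tus, _ = apply_hit_filter(tus, hits, thresholds, report,
                              stage_name="similarity_hits")
    tus, _ = drop_coding_by_orf(tus, thresholds, report)
    tus, _ = drop_short(tus, thresholds, report,
                        use_spliced_length=use_spliced_length)
    tus, _ = apply_coding_potential_filter(tus, scores, thresholds, report)

    mirna_flagged: set[str] = set()
    if mirna_hits:
        kept, dropped = apply_hit_filter(
            tus, mirna_hits, thresholds, report=None,
            stage_name="mirna_precursor",
        )
        mirna_flagged = {tu.tu_id for tu in dropped}
        if mirna_filter_mode == "discard":
            report.log("mirna_precursor", len(tus), len(dropped))
            tus = kept
        else:
            report.log("mirna_precursor", len(tus), 0)
    else:
        report.log("mirna_precursor", len(tus), 0)

    report.validate()
    candidates = [
        LincRNACandidate(
            tu_id=tu.tu_id, contig=tu.contig, start=tu.start, end=tu.end,
            length=tu.length, sequence=tu.sequence or "",
            longest_orf_aa=longest_orf_aa(tu.sequence or ""),
            member_ids=tuple(m.feature_id for m in tu.members),
            mirna_hit=tu.tu_id in mirna_flagged,
        )
        for tu in tus
    ]
    return candidates, report
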