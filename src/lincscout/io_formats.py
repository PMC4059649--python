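"""Readers and writers for every file format the pipeline touches.

Coordinate convention: 1-based, fully inclusive, everywhere in memory
(the GFF/GTF convention). Conversions to Python slices happen only inside
:func:`extract_sequence`.

GFF3/GTF line parsing is delegated to :mod:`gffutils`; FASTA to Biopython;
tabular files (outfmt-6 hit tables, coding-score TSVs, Ct tables, band
tables) to pandas. This module owns validation and the mapping onto the
pipeline's domain types.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from gffutils.feature import feature_from_line

from .errors import MissingInputError, ParseError, ValidationError

STAGES = ("M", "P", "FB")

GENE_MODEL = "gene_model"
TRANSCRIPT = "transcript"

#: outfmt-6 column order (the BLAST tabular default).
OUTFMT6_COLUMNS = (
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
)


@dataclass(frozen=True)
class GenomicFeature:
    """A stranded interval on a named contig.

    ``start``/``end`` are 1-based inclusive. ``strand`` is '+', '-' or '.'
    (unknown). ``exons`` optionally retains the exon intervals a transcript
    was assembled from; when absent the feature is treated as single-exon.
    """

    contig: str
    start: int
    end: int
    strand: str
    feature_id: str
    role: str
    stage: str | None = None
    exons: tuple[tuple[int, int], ...] | None = None

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ValidationError(
                f"feature {self.feature_id!r}: invalid interval "
                f"{self.start}..{self.end} (need 1 <= start <= end)"
            )
        if self.strand not in {"+", "-", "."}:
            raise ValidationError(
                f"feature {self.feature_id!r}: bad strand {self.strand!r}"
            )
        if self.role not in {GENE_MODEL, TRANSCRIPT}:
            raise ValidationError(
                f"feature {self.feature_id!r}: bad role {self.role!r}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def spliced_length(self) -> int:
        if not self.exons:
            return self.length
        return sum(e - s + 1 for s, e in self.exons)

    def overlaps(self, other: "GenomicFeature") -> bool:
        return (
            self.contig == other.contig
            and self.start <= other.end
            and other.start <= self.end
        )


@dataclass(frozen=True)
class HitRecord:
    """One row of an outfmt-6 similarity search result."""

    query_id: str
    subject_id: str
    percent_identity: float
    alignment_length: int
    e_value: float
    bit_score: float
    database_tag: str | None = None

    def __post_init__(self) -> None:
        if self.e_value < 0:
            raise ValidationError(
                f"hit {self.query_id}->{self.subject_id}: negative E-value"
            )


@dataclass(frozen=True)
class CodingScoreRecord:
    """Per-strand coding-potential scores for one transcript unit."""

    query_id: str
    plus_strand_score: float
    minus_strand_score: float


@dataclass
class CtTable:
    """qPCR threshold cycles keyed by (gene_id, stage, replicate).

    Undetected wells arrive as the sentinel "ND" and are stored as cycle 40,
    so downstream arithmetic never sees missing values.
    """

    values: pd.DataFrame  # columns: gene_id, stage, replicate, ct
    reference_gene_id: str = "GAPDH"

    def replicates(self, gene_id: str, stage: str) -> list[float]:
        df = self.values
        sel = df[(df.gene_id == gene_id) & (df.stage == stage)]
        return list(sel.ct)

    @property
    def gene_ids(self) -> list[str]:
        return sorted(self.values.gene_id.unique())


@dataclass(frozen=True)
class BandRow:
    """One lane of an MRA band table (input to mra_orientation)."""

    lincrna_id: str
    stage: str  # "M", "P", "FB" or "pooled"
    lane: str  # P4a, P4b or Pc
    expected_size: int
    observed_sizes: tuple[float, ...]


# ---------------------------------------------------------------------------
# annotation (GFF3 / GTF)
# ---------------------------------------------------------------------------

def read_annotation(
    path: str,
    dialect: str,
    *,
    stage: str | None = None,
) -> list[GenomicFeature]:
    """Read gene models (GFF3) or assembled transcripts (GTF).

    GFF3 ``gene`` rows map 1:1 onto ``gene_model`` features; child rows
    (mRNA/exon/CDS) are ignored. GTF rows are grouped on ``transcript_id``
    and collapsed to the transcript's full genomic span (min start, max end
    over its rows — introns included); exon intervals are retained on the
    feature for spliced-length queries.
    """
    dialect = dialect.upper()
    if dialect not in {"GFF3", "GTF"}:
        raise ValueError(f"unknown annotation dialect {dialect!r}")

    features: list[GenomicFeature] = []
    seen_ids: set[str] = set()
    tx: dict[str, dict] = {}

    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise ParseError(
                    f"{path}: line {lineno}: expected 9 tab-separated "
                    f"columns, found {len(cols)}"
                )
            try:
                start, end = int(cols[3]), int(cols[4])
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: {exc}") from None
            if start > end:
                raise ValidationError(
                    f"{path}: line {lineno}: start {start} > end {end}"
                )
            try:
                feat = feature_from_line(line)
            except Exception as exc:  # gffutils raises plain Exceptions
                raise ParseError(f"{path}: line {lineno}: {exc}") from None

            if dialect == "GFF3":
                if feat.featuretype == "gene":
                    role = GENE_MODEL
                elif feat.featuretype in {"lincRNA", "transcript"}:
                    role = TRANSCRIPT
                else:  # child rows (mRNA/exon/CDS) and other types
                    continue
                fid = (feat.attributes.get("ID") or [None])[0]
                if fid is None:
                    raise ParseError(
                        f"{path}: line {lineno}: {feat.featuretype} row "
                        f"without ID attribute"
                    )
                if fid in seen_ids:
                    raise ValidationError(
                        f"{path}: line {lineno}: duplicate feature id {fid!r}"
                    )
                seen_ids.add(fid)
                features.append(GenomicFeature(
                    contig=cols[0], start=start, end=end,
                    strand=feat.strand if feat.strand in "+-" else ".",
                    feature_id=fid, role=role, stage=stage,
                ))
            else:  # GTF
                tid = (feat.attributes.get("transcript_id") or [None])[0]
                if tid is None:
                    raise ParseError(
                        f"{path}: line {lineno}: GTF row without "
                        f"transcript_id attribute"
                    )
                entry = tx.setdefault(tid, {
                    "contig": cols[0], "start": start, "end": end,
                    "strand": feat.strand if feat.strand in "+-" else ".",
                    "exons": [],
                })
                if entry["contig"] != cols[0]:
                    raise ValidationError(
                        f"{path}: line {lineno}: transcript {tid!r} spans "
                        f"multiple contigs"
                    )
                entry["start"] = min(entry["start"], start)
                entry["end"] = max(entry["end"], end)
                if feat.featuretype == "exon":
                    entry["exons"].append((start, end))

    for tid, entry in tx.items():
        exons = tuple(sorted(entry["exons"])) or None
        features.append(GenomicFeature(
            contig=entry["contig"], start=entry["start"], end=entry["end"],
            strand=entry["strand"], feature_id=tid, role=TRANSCRIPT,
            stage=stage, exons=exons,
        ))
    return features


def write_annotation(
    features: Iterable[GenomicFeature],
    path: str,
    dialect: str = "GFF3",
    source: str = "lincscout",
) -> None:
    """Write features back out; inverse of :func:`read_annotation`.

    Gene models become GFF3 ``gene`` rows; transcripts become GTF exon rows
    (one per retained exon, or a single row spanning the feature).
    """
    dialect = dialect.upper()
    with open(path, "w") as fh:
        if dialect == "GFF3":
            fh.write("##gff-version 3\n")
        for f in sorted(features, key=lambda f: (f.contig, f.start, f.end)):
            if dialect == "GFF3":
                ftype = "gene" if f.role == GENE_MODEL else "lincRNA"
                fh.write(
                    f"{f.contig}\t{source}\t{ftype}\t{f.start}\t{f.end}\t.\t"
                    f"{f.strand}\t.\tID={f.feature_id}\n"
                )
            else:
                exons = f.exons or ((f.start, f.end),)
                for s, e in exons:
                    fh.write(
                        f'{f.contig}\t{source}\texon\t{s}\t{e}\t.\t'
                        f'{f.strand}\t.\tgene_id "{f.feature_id}"; '
                        f'transcript_id "{f.feature_id}";\n'
                    )


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_genome(path: str) -> dict[str, str]:
    """FASTA -> {contig_id: sequence} (uppercased)."""
    return {
        rec.id: str(rec.seq).upper() for rec in SeqIO.parse(path, "fasta")
    }


def write_fasta(sequences: Mapping[str, str], path: str) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="")
        for name, seq in sequences.items()
    ]
    SeqIO.write(records, path, "fasta")


def extract_sequence(
    genome: Mapping[str, str], contig: str, start: int, end: int
) -> str:
    """Plus-strand sequence of the 1-based inclusive interval start..end."""
    if contig not in genome:
        raise ValidationError(f"unknown contig {contig!r}")
    seq = genome[contig]
    if not (1 <= start <= end <= len(seq)):
        raise ValidationError(
            f"interval {start}..{end} outside contig {contig!r} "
            f"(length {len(seq)})"
        )
    return seq[start - 1:end]


# ---------------------------------------------------------------------------
# tabular files
# ---------------------------------------------------------------------------

def read_hits(path: str, database_tag: str | None = None) -> list[HitRecord]:
    """Read a 12-column outfmt-6 hit table."""
    try:
        df = pd.read_csv(path, sep="\t", header=None, comment="#",
                         float_precision="round_trip")
    except pd.errors.EmptyDataError:
        return []
    if df.shape[1] != 12:
        raise ParseError(
            f"{path}: expected 12 outfmt-6 columns, found {df.shape[1]}"
        )
    df.columns = list(OUTFMT6_COLUMNS)
    return [
        HitRecord(
            query_id=str(r.qseqid), subject_id=str(r.sseqid),
            percent_identity=float(r.pident),
            alignment_length=int(r.length),
            e_value=float(r.evalue), bit_score=float(r.bitscore),
            database_tag=database_tag,
        )
        for r in df.itertuples(index=False)
    ]


def write_hits(hits: Iterable[HitRecord], path: str) -> None:
    with open(path, "w") as fh:
        for h in hits:
            fh.write(
                f"{h.query_id}\t{h.subject_id}\t{h.percent_identity:.2f}\t"
                f"{h.alignment_length}\t0\t0\t1\t{h.alignment_length}\t1\t"
                f"{h.alignment_length}\t{h.e_value:g}\t{h.bit_score:.1f}\n"
            )


def read_coding_scores(path: str) -> dict[str, CodingScoreRecord]:
    """TSV with columns query_id, plus_strand_score, minus_strand_score."""
    df = pd.read_csv(path, sep="\t")
    required = {"query_id", "plus_strand_score", "minus_strand_score"}
    if not required.issubset(df.columns):
        raise ParseError(
            f"{path}: coding-score table must have columns {sorted(required)}"
        )
    out: dict[str, CodingScoreRecord] = {}
    for r in df.itertuples(index=False):
        rec = CodingScoreRecord(
            query_id=str(r.query_id),
            plus_strand_score=float(r.plus_strand_score),
            minus_strand_score=float(r.minus_strand_score),
        )
        out[rec.query_id] = rec
    return out


def write_coding_scores(
    scores: Iterable[CodingScoreRecord], path: str
) -> None:
    with open(path, "w") as fh:
        fh.write("query_id\tplus_strand_score\tminus_strand_score\n")
        for s in scores:
            fh.write(
                f"{s.query_id}\t{s.plus_strand_score:g}\t"
                f"{s.minus_strand_score:g}\n"
            )


MAX_CT = 40.0
ND_SENTINEL = "ND"


def read_ct_table(path: str, reference_gene_id: str = "GAPDH") -> CtTable:
    """Read a qPCR Ct table (TSV: gene_id, stage, replicate, ct).

    "ND" (not detected) is imputed as cycle 40. Stages must be M, P or FB.
    """
    df = pd.read_csv(path, sep="\t", dtype={"ct": str})
    required = {"gene_id", "stage", "replicate", "ct"}
    if not required.issubset(df.columns):
        raise ParseError(
            f"{path}: Ct table must have columns {sorted(required)}"
        )
    bad_stage = set(df.stage) - set(STAGES)
    if bad_stage:
        raise ValidationError(
            f"{path}: unknown stage label(s) {sorted(bad_stage)}; "
            f"expected one of {STAGES}"
        )

    def parse_ct(v: str) -> float:
        if str(v).strip() == ND_SENTINEL:
            return MAX_CT
        ct = float(v)
        if not (0.0 <= ct <= MAX_CT) or math.isnan(ct):
            raise ValidationError(
                f"{path}: Ct value {ct} outside [0, {MAX_CT}]"
            )
        return ct

    df = df.assign(
        gene_id=df.gene_id.astype(str),
        stage=df.stage.astype(str),
        replicate=df.replicate.astype(int),
        ct=[parse_ct(v) for v in df.ct],
    )
    return CtTable(values=df, reference_gene_id=reference_gene_id)


def write_ct_table(table: CtTable, path: str) -> None:
    df = table.values.copy()
    df["ct"] = [
        ND_SENTINEL if ct >= MAX_CT else f"{ct:.4f}" for ct in df.ct
    ]
    df.to_csv(path, sep="\t", index=False)


def read_band_table(path: str) -> list[BandRow]:
    """MRA band table: lincrna_id, stage, lane, expected_size, observed_sizes
    (semicolon-separated, empty for no band)."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    required = {"lincrna_id", "stage", "lane", "expected_size",
                "observed_sizes"}
    if not required.issubset(df.columns):
        raise ParseError(
            f"{path}: band table must have columns {sorted(required)}"
        )
    rows: list[BandRow] = []
    for r in df.itertuples(index=False):
        if r.lane not in {"P4a", "P4b", "Pc"}:
            raise ValidationError(f"{path}: unknown lane {r.lane!r}")
        observed = tuple(
            float(x) for x in str(r.observed_sizes).split(";") if x.strip()
        )
        rows.append(BandRow(
            lincrna_id=str(r.lincrna_id), stage=str(r.stage),
            lane=str(r.lane), expected_size=int(float(r.expected_size)),
            observed_sizes=observed,
        ))
    return rows


def write_band_table(rows: Iterable[BandRow], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("lincrna_id\tstage\tlane\texpected_size\tobserved_sizes\n")
        for r in rows:
            obs = ";".join(f"{s:g}" for s in r.observed_sizes)
            fh.write(
                f"{r.lincrna_id}\t{r.stage}\t{r.lane}\t{r.expected_size}\t"
                f"{obs}\n"
            )


def require_file(path: str, what: str) -> str:
    import os

    if not os.path.exists(path):
        raise MissingInputError(f"{what} not found: {path}")
    return path
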