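"""Adjacent protein-coding gene (apcGene) context for lincRNAs.

The apcGene of a lincRNA is the nearest protein-coding gene on either
genomic side. A lincRNA flanked on both sides therefore has two apcGenes
(a 1:2 relationship); a gene flanked by lincRNAs on both sides serves two
of them (2:1); a run of consecutive lincRNAs with no gene between them all
share one nearest gene on that side (n:1).

Each (lincRNA, apcGene) pair falls into one of six configuration classes:
the lincRNA sits on the 5' or the 3' side of the apcGene (in the gene's
own strand frame: upstream of its transcription start is 5'), and is
transcribed in the same direction, the opposite direction, or
bidirectionally.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Protocol, Sequence

from .errors import ValidationError
from .io_formats import GENE_MODEL, GenomicFeature


class _Interval(Protocol):
    contig: str
    start: int
    end: int


@dataclass(frozen=True)
class ApcAssignment:
    """Nearest flanking genes of one lincRNA on the genomic axis."""

    lincrna_id: str
    upstream_gene: str | None  # gene entirely left of the lincRNA
    downstream_gene: str | None  # gene entirely right of the lincRNA
    upstream_distance_bp: int | None
    downstream_distance_bp: int | None
    upstream_tie: bool = False
    downstream_tie: bool = False


#: (side, direction) -> canonical class label
CONFIGURATION_LABELS: Mapping[tuple[str, str], str] = {
    ("5P", "same"): "C1_5P_SAME",
    ("5P", "opposite"): "C2_5P_OPP",
    ("5P", "bidirectional"): "C3_5P_BIDIR",
    ("3P", "same"): "C4_3P_SAME",
    ("3P", "opposite"): "C5_3P_OPP",
    ("3P", "bidirectional"): "C6_3P_BIDIR",
}


@dataclass(frozen=True)
class ConfigurationClass:
    label: str
    side: str  # "5P" or "3P" relative to the apcGene
    direction: str  # "same", "opposite" or "bidirectional"

    def __post_init__(self) -> None:
        if CONFIGURATION_LABELS.get((self.side, self.direction)) != self.label:
            raise ValidationError(
                f"inconsistent configuration {self.label}/{self.side}/"
                f"{self.direction}"
            )


def _is_gene(f: GenomicFeature) -> bool:
    return f.role == GENE_MODEL


def assign_apcgenes(
    lincrna: _Interval,
    genes: Sequence[GenomicFeature],
    lincrna_id: str | None = None,
) -> ApcAssignment:
    """Find the nearest gene entirely left and entirely right of a lincRNA.

    Distances are gap sizes between nearest edges (0 if bookended). Ties at
    equal end (left) or start (right) coordinates are broken toward the
    gene with the smaller start and flagged.
    """
    lid = lincrna_id or getattr(lincrna, "tu_id", None) or getattr(
        lincrna, "feature_id", "lincRNA"
    )
    same_contig = [g for g in genes if g.contig == lincrna.contig]
    for g in same_contig:
        if g.start <= lincrna.end and lincrna.start <= g.end:
            raise ValidationError(
                f"gene {g.feature_id!r} overlaps lincRNA {lid!r}; "
                f"intergenic precondition violated"
            )

    left = [g for g in same_contig if g.end < lincrna.start]
    right = [g for g in same_contig if g.start > lincrna.end]

    up = up_d = None
    up_tie = False
    if left:
        best_end = max(g.end for g in left)
        cands = sorted(
            (g for g in left if g.end == best_end), key=lambda g: g.start
        )
        up_tie = len(cands) > 1
        up = cands[0].feature_id
        up_d = lincrna.start - best_end - 1

    down = down_d = None
    down_tie = False
    if right:
        best_start = min(g.start for g in right)
        cands = sorted(
            (g for g in right if g.start == best_start),
            key=lambda g: g.start,
        )
        down_tie = len(cands) > 1
        down = cands[0].feature_id
        down_d = best_start - lincrna.end - 1

    return ApcAssignment(
        lincrna_id=str(lid), upstream_gene=up, downstream_gene=down,
        upstream_distance_bp=up_d, downstream_distance_bp=down_d,
        upstream_tie=up_tie, downstream_tie=down_tie,
    )


def relationship_census(
    assignments: Sequence[ApcAssignment],
) -> dict[str, int]:
    """Tally lincRNA/apcGene relationship cardinalities.

    Returns counts of:
      - ``1:2`` — lincRNAs with two distinct apcGenes (one per side);
      - ``2:1`` — apcGenes serving exactly two lincRNAs, one on each side;
      - ``n:1`` — apcGenes shared as the same-side nearest gene by two or
        more consecutive lincRNAs (no gene between them);
      - ``apcGenes`` — distinct apcGenes named by any assignment.
    """
    if not assignments:
        return {}
    census = {"1:2": 0, "2:1": 0, "n:1": 0}
    gene_sides: dict[str, dict[str, int]] = {}
    for a in assignments:
        if (
            a.upstream_gene is not None
            and a.downstream_gene is not None
            and a.upstream_gene != a.downstream_gene
        ):
            census["1:2"] += 1
        # the lincRNA sits right of its upstream gene, left of its downstream
        if a.upstream_gene is not None:
            gene_sides.setdefault(a.upstream_gene, {"L": 0, "R": 0})["R"] += 1
        if a.downstream_gene is not None:
            gene_sides.setdefault(a.downstream_gene, {"L": 0, "R": 0})["L"] += 1

    for sides in gene_sides.values():
        if sides["L"] == 1 and sides["R"] == 1:
            census["2:1"] += 1
        # >= 2 lincRNAs sharing this gene as nearest on the SAME side must be
        # consecutive (any intervening gene would be nearer for one of them)
        if sides["L"] >= 2 or sides["R"] >= 2:
            census["n:1"] += 1
    census["apcGenes"] = len(gene_sides)
    return census


def classify_configuration(
    lincrna: _Interval,
    apcgene: GenomicFeature,
    orientation: str,
) -> ConfigurationClass:
    """Map a (lincRNA, apcGene, orientation call) triple to its class.

    ``orientation`` is the MRA call in genome frame: "F" (plus strand),
    "R" (minus strand) or "FR" (bidirectional). The side is 5' when the
    lincRNA lies upstream of the apcGene's transcription start — left of a
    plus-strand gene or right of a minus-strand gene — and 3' otherwise.
    """
    call = getattr(orientation, "call", orientation)
    if call not in {"F", "R", "FR"}:
        raise ValidationError(f"cannot classify orientation {call!r}")
    if apcgene.strand not in {"+", "-"}:
        raise ValidationError(
            f"apcGene {apcgene.feature_id!r} has unknown strand"
        )
    if apcgene.contig != lincrna.contig:
        raise ValidationError("lincRNA and apcGene on different contigs")
    if apcgene.start <= lincrna.end and lincrna.start <= apcgene.end:
        raise ValidationError("lincRNA overlaps its apcGene")

    linc_left_of_gene = lincrna.end < apcgene.start
    if apcgene.strand == "+":
        side = "5P" if linc_left_of_gene else "3P"
    else:
        side = "3P" if linc_left_of_gene else "5P"

    if call == "FR":
        direction = "bidirectional"
    else:
        linc_strand = "+" if call == "F" else "-"
        direction = "same" if linc_strand == apcgene.strand else "opposite"

    return ConfigurationClass(
        label=CONFIGURATION_LABELS[(side, direction)],
        side=side, direction=direction,
    )


def configuration_tally(
    classes: Iterable[ConfigurationClass],
) -> dict[str, int]:
    """Counts per class label plus side/direction margins."""
    tally: dict[str, int] = {lbl: 0 for lbl in CONFIGURATION_LABELS.values()}
    five = three = uni = bidir = 0
    for c in classes:
        tally[c.label] += 1
        if c.side == "5P":
            five += 1
        else:
            three += 1
        if c.direction == "bidirectional":
            bidir += 1
        else:
            uni += 1
    tally.update({
        "5P_total": five, "3P_total": three,
        "unidirectional": uni, "bidirectional": bidir,
    })
    return tally
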