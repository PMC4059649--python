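"""Synthetic multi-stage transcriptome bundles with planted ground truth.

The generator emulates, at desk scale, the inputs of a fungal lincRNA
survey: a multi-contig genome carrying protein-coding genes (each with an
ORF > 100 aa on its annotated strand) and intergenic lincRNA loci (>= 200
bp, no ORF > 100 aa on either strand, rejection-sampled); per-stage
assembled-transcript GTFs including overlapping fragments that exercise TU
merging; similarity-hit and coding-score side tables; three-stage qPCR Ct
matrices with planted correlation classes; and MRA band tables consistent
with planted transcription orientations.

Decoy transcripts are planted so that each fails exactly one filter of the
cascade: "short" (< 200 bp), "long_orf" (ORF > 100 aa), "hit" (receives a
similarity hit below the E-value cutoff), "coding_score" (one CPC strand
score >= 0) and "gene_overlap" (overlaps a predicted gene).

Everything is driven by a single seeded generator per call; rerunning with
the same seed reproduces the bundle byte for byte. The TruthManifest
records every planted element, its designed fate, and the transcript-unit
identifier it ends up in.
"""

from __future__ import annotations

import dataclasses
import itertools
import json
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io_formats import (
    GENE_MODEL,
    TRANSCRIPT,
    STAGES,
    BandRow,
    CodingScoreRecord,
    CtTable,
    GenomicFeature,
    HitRecord,
)
from .tu_discovery import longest_orf_aa, merge_to_transcript_units

_BASES = np.array(list("ACGT"))
_STOPS = {"TAA", "TAG", "TGA"}
_NONSTOP_CODONS = np.array([
    a + b + c
    for a in "ACGT" for b in "ACGT" for c in "ACGT"
    if a + b + c not in _STOPS
])

DECOY_KINDS = ("short", "long_orf", "hit", "coding_score", "gene_overlap")


@dataclass
class GenomeConfig:
    """Layout of the synthetic genome.

    Defaults give two 50-kb contigs with ten genes and six lincRNA loci —
    small enough to run in well under a second, large enough that every
    lincRNA has flanking genes. lincRNA lengths are drawn log-normally
    (median ~560 bp) and clipped to the 200–1966 bp range observed for
    fungal lincRNAs.
    """

    n_contigs: int = 2
    contig_length: int = 50_000
    n_genes: int = 10
    n_lincrnas: int = 6
    gene_orf_aa: int = 150
    lincrna_length_range: tuple[int, int] = (200, 1966)
    lincrna_length_log_median: float = math.log(560.0)
    lincrna_length_log_sd: float = 0.5
    min_spacer: int = 800
    max_spacer: int = 2500
    decoy_counts: dict[str, int] = field(
        default_factory=lambda: {k: 1 for k in DECOY_KINDS}
    )
    bidirectional_fraction: float = 0.2

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class TruthManifest:
    """Ground truth for one generated bundle."""

    seed: int
    config: dict
    contigs: dict[str, int] = field(default_factory=dict)
    genes: list[dict] = field(default_factory=list)
    lincrnas: list[dict] = field(default_factory=list)
    decoys: list[dict] = field(default_factory=list)
    tu_ids: dict[str, str] = field(default_factory=dict)
    pairs: list[dict] = field(default_factory=list)

    def gene_features(self) -> list[GenomicFeature]:
        return [
            GenomicFeature(
                contig=g["contig"], start=g["start"], end=g["end"],
                strand=g["strand"], feature_id=g["id"], role=GENE_MODEL,
            )
            for g in self.genes
        ]

    def lincrna_tu_ids(self) -> set[str]:
        return {self.tu_ids[rec["id"]] for rec in self.lincrnas}

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=1)

    @classmethod
    def from_json(cls, text: str) -> "TruthManifest":
        return cls(**json.loads(text))


# ---------------------------------------------------------------------------
# sequence helpers
# ---------------------------------------------------------------------------

def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, n)])


def _coding_seq(rng: np.random.Generator, orf_aa: int) -> str:
    """ATG + (orf_aa - 1) non-stop codons + TAA: longest ORF >= orf_aa."""
    body = "".join(rng.choice(_NONSTOP_CODONS, orf_aa - 1))
    return "ATG" + body + "TAA"


def _noncoding_seq(
    rng: np.random.Generator, n: int, max_orf_aa: int = 100
) -> str:
    """Random sequence rejection-sampled to carry no ORF > max_orf_aa."""
    for _ in range(200):
        seq = _random_seq(rng, n)
        if longest_orf_aa(seq) <= max_orf_aa:
            return seq
    raise ValidationError(
        f"could not sample a {n}-bp sequence without ORFs > {max_orf_aa} aa"
    )


def _draw_linc_length(rng: np.random.Generator, cfg: GenomeConfig) -> int:
    lo, hi = cfg.lincrna_length_range
    n = int(round(math.exp(rng.normal(
        cfg.lincrna_length_log_median, cfg.lincrna_length_log_sd
    ))))
    return int(min(max(n, lo), hi))


# ---------------------------------------------------------------------------
# genome
# ---------------------------------------------------------------------------

def generate_genome(
    config: GenomeConfig | None = None, seed: int = 0
) -> tuple[dict[str, str], list[GenomicFeature], TruthManifest]:
    """Build the genome, the gene models, and the truth manifest.

    Genes and lincRNA loci are distributed round-robin over the contigs
    and laid out alternately (gene, lincRNA, gene, ...) with random
    intergenic spacers, so most lincRNAs are flanked by genes on both
    sides. Locus-bearing decoys are appended after the last gene of their
    contig.
    """
    cfg = config or GenomeConfig()
    rng = np.random.default_rng(seed)
    manifest = TruthManifest(seed=seed, config=cfg.as_dict())

    contig_names = [f"scaffold_{i + 1}" for i in range(cfg.n_contigs)]
    gene_ids = [f"GL{10001 + i}" for i in range(cfg.n_genes)]
    linc_ids = [f"linc_{i + 1}" for i in range(cfg.n_lincrnas)]
    decoy_ids = [
        (kind, f"decoy_{kind}_{j + 1}")
        for kind in DECOY_KINDS if kind != "gene_overlap"
        for j in range(cfg.decoy_counts.get(kind, 0))
    ]

    def round_robin(items: list) -> list[list]:
        buckets: list[list] = [[] for _ in contig_names]
        for i, item in enumerate(items):
            buckets[i % cfg.n_contigs].append(item)
        return buckets

    gene_buckets = round_robin(gene_ids)
    linc_buckets = round_robin(linc_ids)
    decoy_buckets = round_robin(decoy_ids)

    genome: dict[str, str] = {}
    gene_features: list[GenomicFeature] = []

    for ci, contig in enumerate(contig_names):
        # alternate gene / lincRNA, then trailing genes, then decoys
        order: list[tuple[str, object]] = []
        gq, lq = list(gene_buckets[ci]), list(linc_buckets[ci])
        while gq or lq:
            if gq:
                order.append(("gene", gq.pop(0)))
            if lq:
                order.append(("linc", lq.pop(0)))
        order.extend(("decoy", d) for d in decoy_buckets[ci])

        parts: list[str] = []
        pos = 0  # bases emitted so far
        for kind, item in order:
            spacer = int(rng.integers(cfg.min_spacer, cfg.max_spacer + 1))
            parts.append(_random_seq(rng, spacer))
            pos += spacer
            if kind == "gene":
                strand = "+" if rng.random() < 0.5 else "-"
                cds = _coding_seq(rng, cfg.gene_orf_aa)
                seq = cds if strand == "+" else _revcomp(cds)
                start, end = pos + 1, pos + len(seq)
                manifest.genes.append({
                    "id": item, "contig": contig, "start": start,
                    "end": end, "strand": strand,
                    "orf_aa": cfg.gene_orf_aa,
                })
                gene_features.append(GenomicFeature(
                    contig=contig, start=start, end=end, strand=strand,
                    feature_id=item, role=GENE_MODEL,
                ))
            elif kind == "linc":
                length = _draw_linc_length(rng, cfg)
                seq = _noncoding_seq(rng, length)
                start, end = pos + 1, pos + length
                orientation = _draw_orientation(rng, cfg)
                manifest.lincrnas.append({
                    "id": item, "contig": contig, "start": start,
                    "end": end, "length": length,
                    "orientation": orientation,
                    "stage_orientations": _draw_stage_orientations(
                        rng, orientation
                    ),
                    "stages_present": list(STAGES),
                })
            else:  # locus-bearing decoy
                dkind, did = item
                if dkind == "short":
                    seq = _noncoding_seq(rng, 150)
                elif dkind == "long_orf":
                    seq = (
                        _noncoding_seq(rng, 40)
                        + _coding_seq(rng, 120)
                        + _noncoding_seq(rng, 40)
                    )
                else:  # hit / coding_score: clean lincRNA-like locus
                    seq = _noncoding_seq(rng, _draw_linc_length(rng, cfg))
                start, end = pos + 1, pos + len(seq)
                manifest.decoys.append({
                    "id": did, "kind": dkind, "contig": contig,
                    "start": start, "end": end,
                })
            parts.append(seq)
            pos += len(seq)

        tail = cfg.contig_length - pos
        if tail < 0:
            raise ValidationError(
                f"config infeasible: contig {contig} needs {pos} bp but "
                f"contig_length is {cfg.contig_length}"
            )
        parts.append(_random_seq(rng, tail))
        genome[contig] = "".join(parts)
        manifest.contigs[contig] = cfg.contig_length

    # gene_overlap decoys attach to existing genes (no locus of their own)
    n_overlap = cfg.decoy_counts.get("gene_overlap", 0)
    for j in range(n_overlap):
        g = manifest.genes[j % len(manifest.genes)]
        manifest.decoys.append({
            "id": f"decoy_gene_overlap_{j + 1}", "kind": "gene_overlap",
            "contig": g["contig"], "start": max(1, g["start"] - 80),
            "end": g["start"] + 120, "target_gene": g["id"],
        })
    return genome, gene_features, manifest


def _revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]


def _draw_orientation(rng: np.random.Generator, cfg: GenomeConfig) -> str:
    if rng.random() < cfg.bidirectional_fraction:
        return "FR"
    return "F" if rng.random() < 0.5 else "R"


def _draw_stage_orientations(
    rng: np.random.Generator, pooled: str
) -> dict[str, str]:
    calls = {s: pooled for s in STAGES}
    if pooled == "FR" and rng.random() < 0.5:
        # bidirectional in one or two stages only
        stage = str(rng.choice(list(STAGES)))
        calls[stage] = "F"
    return calls


# ---------------------------------------------------------------------------
# transcripts
# ---------------------------------------------------------------------------

def generate_transcripts(
    manifest: TruthManifest,
    seed: int = 0,
    stage_presence: Mapping[str, Sequence[str]] | None = None,
) -> dict[str, list[GenomicFeature]]:
    """Emit per-stage assembled transcripts for every planted element.

    Gene transcripts extend a short random margin into the flanking
    spacers; every third gene additionally gets two overlapping fragments
    (in stage P) and every second lincRNA is split into two overlapping
    halves, so TU merging is exercised on both planted kinds. Also fills
    ``manifest.tu_ids`` by running the TU merge on the full feature set.
    """
    rng = np.random.default_rng(seed)
    presence = dict(stage_presence or {})
    out: dict[str, list[GenomicFeature]] = {s: [] for s in STAGES}
    origin: dict[str, str] = {}  # transcript id -> planted element id

    def add(stage: str, elem: str, tid: str, contig: str, s: int, e: int):
        out[stage].append(GenomicFeature(
            contig=contig, start=s, end=e, strand=".",
            feature_id=tid, role=TRANSCRIPT, stage=stage,
        ))
        origin[tid] = elem

    for i, g in enumerate(manifest.genes):
        m1 = int(rng.integers(20, 121))
        m2 = int(rng.integers(20, 121))
        add("M", g["id"], f"t_{g['id']}_M", g["contig"],
            max(1, g["start"] - m1), g["end"] + m2)
        if i % 3 == 0:
            mid = (g["start"] + g["end"]) // 2
            add("P", g["id"], f"t_{g['id']}_P1", g["contig"],
                g["start"], mid + 60)
            add("P", g["id"], f"t_{g['id']}_P2", g["contig"],
                mid - 60, g["end"])

    for j, rec in enumerate(manifest.lincrnas):
        stages = list(presence.get(rec["id"], rec["stages_present"]))
        rec["stages_present"] = stages
        for k, stage in enumerate(stages):
            if j % 2 == 0 and k == 0 and rec["length"] >= 300:
                mid = (rec["start"] + rec["end"]) // 2
                add(stage, rec["id"], f"t_{rec['id']}_{stage}a",
                    rec["contig"], rec["start"], mid + 50)
                add(stage, rec["id"], f"t_{rec['id']}_{stage}b",
                    rec["contig"], mid - 50, rec["end"])
            else:
                add(stage, rec["id"], f"t_{rec['id']}_{stage}",
                    rec["contig"], rec["start"], rec["end"])

    for d in manifest.decoys:
        add("M", d["id"], f"t_{d['id']}_M", d["contig"],
            d["start"], d["end"])

    # resolve planted element -> TU id on the merged feature set
    all_feats = manifest.gene_features() + [
        f for stage in STAGES for f in out[stage]
    ]
    tus = merge_to_transcript_units(all_feats)
    member_to_tu = {
        m.feature_id: tu.tu_id for tu in tus for m in tu.members
    }
    manifest.tu_ids = {}
    for tid, elem in origin.items():
        manifest.tu_ids[elem] = member_to_tu[tid]
    for g in manifest.genes:
        manifest.tu_ids[g["id"]] = member_to_tu[g["id"]]
    return out


# ---------------------------------------------------------------------------
# side tables (similarity hits, coding scores, miRNA screen)
# ---------------------------------------------------------------------------

def generate_side_tables(
    manifest: TruthManifest, seed: int = 0
) -> tuple[list[HitRecord], dict[str, CodingScoreRecord], list[HitRecord]]:
    """Hit and coding-score tables consistent with the manifest.

    Hit decoys receive one Nt hit at E = 1e-20. Gene-containing TUs score
    positive on the coding strand; all intergenic TUs score negative on
    both strands except coding-score decoys, which get a positive
    plus-strand score. The miRNA-precursor table is empty (the expected
    zero-hit outcome for fungal lincRNAs).
    """
    if not manifest.tu_ids:
        raise ValidationError(
            "manifest.tu_ids empty: run generate_transcripts first"
        )
    rng = np.random.default_rng(seed)

    gene_tus = {manifest.tu_ids[g["id"]] for g in manifest.genes}
    hit_tus = {
        manifest.tu_ids[d["id"]] for d in manifest.decoys
        if d["kind"] == "hit"
    }
    coding_decoy_tus = {
        manifest.tu_ids[d["id"]] for d in manifest.decoys
        if d["kind"] == "coding_score"
    }

    hits = [
        HitRecord(
            query_id=tu, subject_id=f"nt_known_{i + 1}",
            percent_identity=float(rng.uniform(90, 100)),
            alignment_length=int(rng.integers(100, 400)),
            e_value=1e-20, bit_score=float(rng.uniform(200, 500)),
            database_tag="Nt",
        )
        for i, tu in enumerate(sorted(hit_tus))
    ]

    scores: dict[str, CodingScoreRecord] = {}
    for tu in sorted(set(manifest.tu_ids.values())):
        if tu in gene_tus:
            plus = float(rng.uniform(1.0, 3.0))
            minus = float(rng.uniform(-2.0, -0.2))
        elif tu in coding_decoy_tus:
            plus = float(rng.uniform(0.0, 1.0))
            minus = float(rng.uniform(-2.0, -0.2))
        else:
            plus = float(rng.uniform(-2.0, -0.2))
            minus = float(rng.uniform(-2.0, -0.2))
        scores[tu] = CodingScoreRecord(
            query_id=tu, plus_strand_score=round(plus, 3),
            minus_strand_score=round(minus, 3),
        )
    return hits, scores, []


# ---------------------------------------------------------------------------
# qPCR Ct matrices
# ---------------------------------------------------------------------------

def _base_log2_profile(rng: np.random.Generator) -> np.ndarray:
    """Three distinct stage levels with 2–4 log2-unit steps, shuffled."""
    base = rng.uniform(-2.0, 2.0)
    d1, d2 = rng.uniform(2.0, 4.0, 2)
    levels = np.array([base, base + d1, base + d1 + d2])
    return rng.permutation(levels)


def _partner_linear(
    rng: np.random.Generator, linc_linear: np.ndarray, cls: str
) -> np.ndarray:
    """Partner profile realizing the planted correlation class exactly."""
    x = linc_linear
    if cls == "positive":
        return x * float(2.0 ** rng.uniform(-3.0, 3.0))
    if cls == "negative":
        # affine reflection keeps values inside [min, max] (> 0), r = -1
        return (x.max() + x.min()) - x
    if cls == "none":
        xc = x - x.mean()
        for _ in range(100):
            v = rng.normal(size=3)
            u = v - v.mean()
            u_perp = u - (u @ xc) / (xc @ xc) * xc
            if np.ptp(u_perp) > 1e-6:
                break
        else:
            raise ValidationError("failed to sample an uncorrelated profile")
        spread = np.ptp(u_perp)
        y = u_perp - u_perp.min() + 0.25 * spread
        return y * (x.mean() / y.mean())
    raise ValidationError(f"unknown correlation class {cls!r}")


def generate_ct_matrix(
    pairs: Sequence[tuple[str, str]],
    class_spec: Sequence[str],
    noise_sd: float = 0.0,
    seed: int = 0,
    gapdh_ct: float = 20.0,
    replicates: int = 3,
    undetected: Mapping[str, Sequence[str]] | None = None,
) -> CtTable:
    """Simulate a three-stage qPCR Ct table with planted pair classes.

    Each pair draws a lincRNA profile with strong stage contrast (2–4
    log2 units per step) and a partner profile whose Pearson correlation
    with it is exactly +1, -1 or 0 on the clean values. Profiles are
    converted to Ct around a GAPDH baseline and Gaussian replicate noise
    (``noise_sd`` cycles) is added. ``undetected`` maps gene ids to stages
    forced to the ND sentinel (Ct 40).
    """
    if noise_sd < 0:
        raise ValidationError("noise_sd must be non-negative")
    if len(pairs) != len(class_spec):
        raise ValidationError("pairs and class_spec lengths differ")
    rng = np.random.default_rng(seed)
    undetected = {k: set(v) for k, v in (undetected or {}).items()}

    rows: list[dict] = []

    def emit(gene_id: str, clean_ct: np.ndarray) -> None:
        for si, stage in enumerate(STAGES):
            for rep in range(1, replicates + 1):
                if stage in undetected.get(gene_id, ()):  # ND well
                    ct = 40.0
                else:
                    ct = clean_ct[si] + rng.normal(0.0, noise_sd)
                    ct = float(min(max(ct, 0.0), 40.0))
                rows.append({
                    "gene_id": gene_id, "stage": stage,
                    "replicate": rep, "ct": ct,
                })

    emit("GAPDH", np.full(3, gapdh_ct))
    for (linc_id, apc_id), cls in zip(pairs, class_spec):
        linc_linear = 2.0 ** _base_log2_profile(rng)
        apc_linear = _partner_linear(rng, linc_linear, cls)
        emit(linc_id, gapdh_ct - np.log2(linc_linear))
        emit(apc_id, gapdh_ct - np.log2(apc_linear))

    return CtTable(values=pd.DataFrame(rows), reference_gene_id="GAPDH")


def plant_pairs(
    manifest: TruthManifest,
    class_cycle: Sequence[str] = ("positive", "negative", "none"),
) -> list[dict]:
    """Pair each lincRNA TU with its nearest downstream (else upstream)
    gene and assign planted correlation classes round-robin."""
    pairs: list[dict] = []
    cycle = itertools.cycle(class_cycle)
    for rec in manifest.lincrnas:
        contig_genes = sorted(
            (g for g in manifest.genes if g["contig"] == rec["contig"]),
            key=lambda g: g["start"],
        )
        down = next(
            (g for g in contig_genes if g["start"] > rec["end"]), None
        )
        up = next(
            (g for g in reversed(contig_genes) if g["end"] < rec["start"]),
            None,
        )
        apc = down or up
        if apc is None:
            continue
        pairs.append({
            "lincrna_id": rec["id"],
            "lincrna_tu": manifest.tu_ids.get(rec["id"], rec["id"]),
            "apcgene_id": apc["id"],
            "correlation_class": next(cycle),
        })
    manifest.pairs = pairs
    return pairs


# ---------------------------------------------------------------------------
# MRA band tables
# ---------------------------------------------------------------------------

def generate_mra_bands(
    manifest: TruthManifest,
    seed: int = 0,
    nonspecific_ids: Sequence[str] = (),
) -> list[BandRow]:
    """Band rows (pooled + per-stage) realizing each planted orientation.

    Present lanes get one band within 5% of the expected size; lincRNAs in
    ``nonspecific_ids`` additionally get an out-of-tolerance band at twice
    the expected size (which must not change the call).
    """
    rng = np.random.default_rng(seed)
    rows: list[BandRow] = []
    for rec in manifest.lincrnas:
        expected = {
            lane: int(rng.integers(250, 901))
            for lane in ("P4a", "P4b", "Pc")
        }
        samples = [("pooled", rec["orientation"])] + [
            (s, rec["stage_orientations"][s]) for s in STAGES
        ]
        for stage, call in samples:
            present = {
                "P4a": call in {"F", "FR"},
                "P4b": call in {"R", "FR"},
                "Pc": True,
            }
            for lane in ("P4a", "P4b", "Pc"):
                obs: list[float] = []
                if present[lane]:
                    jitter = rng.uniform(-0.05, 0.05)
                    obs.append(round(expected[lane] * (1 + jitter), 1))
                if rec["id"] in nonspecific_ids and lane == "P4a":
                    obs.append(float(expected[lane] * 2))
                rows.append(BandRow(
                    lincrna_id=rec["id"], stage=stage, lane=lane,
                    expected_size=expected[lane],
                    observed_sizes=tuple(obs),
                ))
    return rows


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

@dataclass
class SyntheticBundle:
    genome: dict[str, str]
    genes: list[GenomicFeature]
    transcripts: dict[str, list[GenomicFeature]]
    hits: list[HitRecord]
    scores: dict[str, CodingScoreRecord]
    mirna_hits: list[HitRecord]
    ct_table: CtTable
    bands: list[BandRow]
    manifest: TruthManifest


def generate_bundle(
    config: GenomeConfig | None = None,
    seed: int = 0,
    noise_sd: float = 0.0,
) -> SyntheticBundle:
    """Generate a complete, internally consistent input bundle.

    Sub-generators get distinct child seeds derived from ``seed`` so the
    whole bundle is reproducible from one integer.
    """
    ss = np.random.SeedSequence(seed)
    seeds = [int(s.generate_state(1)[0] % (2 ** 31)) for s in ss.spawn(5)]
    genome, genes, manifest = generate_genome(config, seeds[0])
    transcripts = generate_transcripts(manifest, seeds[1])
    hits, scores, mirna_hits = generate_side_tables(manifest, seeds[2])
    pairs = plant_pairs(manifest)
    ct = generate_ct_matrix(
        pairs=[(p["lincrna_tu"], p["apcgene_id"]) for p in pairs],
        class_spec=[p["correlation_class"] for p in pairs],
        noise_sd=noise_sd, seed=seeds[3],
    )
    bands = generate_mra_bands(manifest, seeds[4])
    return SyntheticBundle(
        genome=genome, genes=genes, transcripts=transcripts, hits=hits,
        scores=scores, mirna_hits=mirna_hits, ct_table=ct, bands=bands,
        manifest=manifest,
    )


def write_bundle(bundle: SyntheticBundle, out_dir: str) -> dict[str, str]:
    """Write every bundle component to ``out_dir``; returns the paths."""
    import os

    from . import io_formats as iof

    os.makedirs(out_dir, exist_ok=True)
    paths = {
        "genome": os.path.join(out_dir, "genome.fasta"),
        "genes": os.path.join(out_dir, "genes.gff3"),
        "hits": os.path.join(out_dir, "hits_nt_nr_sp.tsv"),
        "scores": os.path.join(out_dir, "cpc_scores.tsv"),
        "mirna": os.path.join(out_dir, "mirna_hits.tsv"),
        "ct": os.path.join(out_dir, "ct_table.tsv"),
        "bands": os.path.join(out_dir, "mra_bands.tsv"),
        "manifest": os.path.join(out_dir, "manifest.json"),
    }
    iof.write_fasta(bundle.genome, paths["genome"])
    iof.write_annotation(bundle.genes, paths["genes"], dialect="GFF3")
    for stage in STAGES:
        p = os.path.join(out_dir, f"transcripts_{stage}.gtf")
        iof.write_annotation(bundle.transcripts[stage], p, dialect="GTF")
        paths[f"transcripts_{stage}"] = p
    iof.write_hits(bundle.hits, paths["hits"])
    iof.write_coding_scores(bundle.scores.values(), paths["scores"])
    iof.write_hits(bundle.mirna_hits, paths["mirna"])
    iof.write_ct_table(bundle.ct_table, paths["ct"])
    iof.write_band_table(bundle.bands, paths["bands"])
    with open(paths["manifest"], "w") as fh:
        fh.write(bundle.manifest.to_json())
    return paths
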