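# Methods

This note records the models, conventions, parameter choices and known
limitations behind lincscout. It documents what the code does and why;
every number quoted here is computed by the package's own tests or by
`scripts/acceptance.py`.

## Coordinates and file formats

All intervals are 1-based and fully inclusive in memory (the GFF/GTF
convention); a feature with `start=1` occupies the first base of its
contig. Conversions to Python slices happen only at sequence extraction.
GFF3 `gene` rows become gene-model features; GTF rows are grouped on
`transcript_id` and collapsed to the transcript's genomic span (introns
included), with the exon intervals retained so a spliced length can still
be queried. Hit tables follow the 12-column BLAST outfmt-6 layout; Ct
tables are TSV keyed by (gene, stage, replicate) with the sentinel `ND`
for undetected wells, imputed as cycle 40 at parse time so downstream
arithmetic never sees missing values.

## Transcript-unit construction

Transcripts from all three developmental stages are pooled with the gene
models before merging; stage tags are preserved on the members. Overlap is
strand-agnostic because the underlying RNA-Seq protocol is
non-strand-specific — two fragments on opposite annotated strands may be
the same transcription unit. Merging requires a shared base: bookended
intervals (`end + 1 == start`) do not merge, and no distance cutoff is
applied (gene models in compact fungal genomes lack experimentally
defined UTRs, so any gap threshold would be arbitrary). Transitive
overlap chains on a line reduce to sorted interval sweeping, which is the
implementation; a quadratic union-find oracle over all pairs verifies it
on 200 random instances in the test suite. TU identifiers are assigned
deterministically in (contig, start) order.

## The filter cascade

Stage order: gene-containing → Nt/Nr/SP similarity → ORF length → minimum
length → coding potential → miRNA-precursor screen. The cutoffs are:

| parameter        | default | meaning                                        |
|------------------|---------|------------------------------------------------|
| `evalue_cutoff`  | 1e-5    | discard on any hit with E *strictly* below it  |
| `max_orf_aa`     | 100     | discard when longest ORF is *strictly* longer  |
| `min_length_bp`  | 200     | discard below; exactly 200 bp is retained      |
| `coding_score_cutoff` | 0  | both strand scores must be *strictly* below    |

The ORF scanner is native: ATG-initiated, all six frames, counted from the
Met through the codon before the first in-frame stop; ORFs still open at
the sequence end count to the last complete codon (a conservative choice
that discards more borderline-coding TUs). Codons containing `N` neither
start nor stop an ORF. The length filter defaults to the genomic span of
the TU (identical to transcript length for the single-exon transcripts
typical of fungal lincRNAs); a spliced-length mode is available when exon
structure is present. The miRNA-precursor screen annotates rather than
discards by default — a discard/keep policy is unobservable when the
screen finds nothing, which is the expected outcome for fungal lincRNAs —
and a flag switches it to discard mode.

All five substantive filters are independent predicates of a TU, so the
survivor set is invariant under the order of application; only the
per-stage bookkeeping depends on order. A test checks all 120 orderings.

## apcGene context

Assignment is purely genomic: the upstream apcGene is the gene with
maximal end among genes entirely left of the lincRNA, the downstream one
has minimal start among genes entirely right; distances are edge-to-edge
gaps (0 when bookended) and ties are broken toward the smaller start
coordinate and flagged. Classification then switches to the gene's strand
frame: a lincRNA upstream of the apcGene's transcription start (left of a
`+` gene, right of a `-` gene) is on its 5′ side. Combined with the
orientation call (same / opposite / bidirectional relative to the gene's
strand) this yields six configuration classes, labelled C1–C6 here in the
order (5′ same, 5′ opposite, 5′ bidirectional, 3′ same, 3′ opposite,
3′ bidirectional). The full 12-case input space (lincRNA side × gene
strand × call) is enumerated in a hand-derived truth table in the tests.
Which of a lincRNA's two apcGenes enters pair analysis is a user
selection; the module classifies any supplied pair.

The relationship census counts lincRNAs with two distinct flanking
apcGenes (1:2), apcGenes flanked by one lincRNA on each side (2:1), and
apcGenes shared as the same-side nearest gene by two or more lincRNAs —
such lincRNAs are necessarily consecutive with no intervening gene (n:1).

## MRA orientation calls

A locus yields three lanes: P-4a (forward-priming nested PCR), P-4b
(reverse-priming) and the template control P-c. A band is "present" when
an observed size is within a fractional tolerance of the predicted size;
the default tolerance is 0.2, a gel-resolution-scale choice (the assay
judges "a size similar to the prediction", not an exact match). Bands
outside tolerance are flagged as nonspecific amplification and never
count as presence. An absent control invalidates the lane set. With a
valid control, (P-4a, P-4b) presence maps to F / R / F-R, and (absent,
absent) yields NONE — transcript undetected — rather than an error.
Per-stage calls are summarized as bidirectional-in-all-stages,
bidirectional-in-some, unidirectional-consistent, or mixed. Pooled-sample
and per-stage calls are independent inputs; conflicts are reported, not
reconciled.

## Expression model

Quantification assumes 100% amplification efficiency: relative expression
is 2^(−ΔCt) with ΔCt = Ct − Ct(GAPDH). Replicates are averaged on the Ct
scale (arithmetic mean of cycles) before the transform, and the replicate
SD is reported on the same scale; reference-gene uncertainty is not
propagated. The log2 base is anchored by the group-I boundary: 3.32 log2
units ≙ a 10-fold difference. Group boundaries follow the stated
inclusive rules — |ratio| ≥ 3.32 in any stage → I; all |ratio| ≤ 1 → III;
otherwise II — so exactly 3.32 is group I and exactly 1 is group III.
Log ratios default to raw relative expression; a flag computes them from
stage-max-normalized profiles instead (the two differ unless both
profiles share a normalizing constant).

Correlation uses the product-moment coefficient of the
stage-max-normalized three-stage profiles. Normalization cannot change r
(scale invariance, asserted to 1e-12 in a property test), and with n = 3
the coefficient is statistically fragile, so no p-value is attached;
classification is strict (positive iff r > 0.8, negative iff r < −0.8). A
constant profile makes r undefined; this is reported as class "none" with
a flag, not an error. Sentinel-40 stages participate as near-zero
expression (2^−20 relative to a Ct-20 reference).

## Synthetic data

The generator's defaults define the test conditions: two 50-kb contigs,
ten genes (ORF 150 aa on the annotated strand), six intergenic lincRNA
loci with log-normally drawn lengths (median ≈ 560 bp, clipped to
200–1966 bp), intergenic spacers of 0.8–2.5 kb, uniform base composition,
and one decoy of each kind (short, long-ORF, similarity-hit,
coding-score, gene-overlap), each violating exactly one filter. lincRNA
loci are rejection-sampled to carry no ORF > 100 aa on either strand,
using the pipeline's own scanner as the planting oracle. A fifth of
planted lincRNAs are bidirectional; half of those are bidirectional in
only a subset of stages. qPCR profiles are planted with exact correlation
structure — positive pairs are scalar multiples (r = +1), negative pairs
are affine reflections (r = −1), "none" pairs are constructed orthogonal
to the centered lincRNA profile (r = 0) — with 2–4 log2 units of
between-stage contrast, then converted to Ct around a GAPDH baseline of
cycle 20 and perturbed with Gaussian replicate noise (3 replicates).

What the generator does *not* emulate: read-level sequencing noise,
assembly fragmentation beyond the planted overlapping fragments,
multi-exon transcripts, biased base composition, amplification-efficiency
variation, or genes whose CPC score disagrees with their ORF content.
Passing the planted-truth tests therefore demonstrates correctness of the
decision logic under clean inputs, not robustness to assembly artifacts.

## Problem sizes and determinism

The test suite and `scripts/acceptance.py` run entirely on generated
data: 200 random instances for each interval oracle, 100 random 600-nt
sequences for the ORF oracle, a 2 × 80-kb genome with ten planted
lincRNAs and fifteen decoys for end-to-end recovery, and 500 simulated
pairs at 0.25-cycle noise for correlation-class recovery (observed
accuracy 1.0 at these settings; the acceptance bar is ≥ 0.95). Every
random draw descends from a single seed via `numpy` SeedSequence
spawning, and bundle generation is byte-reproducible under a fixed seed.

## Known limitations

* Paper-scale results from the original *G. lucidum* survey (6763 TUs →
  402 lincRNAs, 697 apcGenes, 11 positive / 5 negative correlations)
  depend on the original RNA-Seq data and contemporary database versions
  and are not recomputable here; the published per-class survey counts
  and the analytic 3.32 boundary are the recomputable anchors.
* The 200-bp filter's span-vs-spliced ambiguity only matters for
  multi-exon TUs; the default (genomic span) is documented above.
* Pearson r on three points cannot support inference; the correlation
  classes are descriptive screens, not tests.
* The census definition of "n:1" counts sharing apcGenes (each
  contributing its own n); it does not enumerate the lincRNA runs
  themselves.
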