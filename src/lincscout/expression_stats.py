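"""qPCR expression profiling and lincRNA/apcGene co-expression statistics.

Quantification follows the standard comparative-Ct model with 100%
amplification efficiency: relative expression against the GAPDH reference
is 2^(-(Ct - Ct_ref)), with replicates averaged on the Ct scale. Profiles
span the three developmental stages (M mycelia, P primordia, FB fruiting
bodies). Undetected wells carry the sentinel Ct of 40, so they enter the
analysis as near-zero expression rather than missing values.

Pairs of lincRNA and apcGene are characterized two ways:

* the per-stage log2 expression ratio lincRNA/apcGene, binned into groups
  I (|ratio| >= 3.32, i.e. >= 10-fold, in some stage), II (1 < |ratio| <
  3.32 in some stage) and III (|ratio| <= 1 in every stage);
* the Pearson correlation r of the stage-max-normalized profiles,
  classified positive (r > 0.8), negative (r < -0.8) or none. With only
  three stages r is fragile, so no p-value is attached.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .errors import UndefinedNormalizationError, ValidationError
from .io_formats import STAGES, CtTable

GROUP_I_BOUNDARY = 3.32  # log2 units; the printed 10-fold equivalent
GROUP_III_BOUNDARY = 1.0  # log2 units; two-fold
CORRELATION_THRESHOLD = 0.8


@dataclass(frozen=True)
class ExpressionProfile:
    """GAPDH-normalized relative expression across the three stages.

    ``values`` are linear-scale 2^(-dCt); ``ct_sd`` is the replicate
    standard deviation on the Ct scale (cycles).
    """

    gene_id: str
    values: Mapping[str, float]
    ct_sd: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if set(self.values) != set(STAGES):
            raise ValidationError(
                f"profile {self.gene_id!r}: need exactly stages {STAGES}"
            )
        if any(v < 0 for v in self.values.values()):
            raise ValidationError(
                f"profile {self.gene_id!r}: negative expression value"
            )

    def as_array(self) -> np.ndarray:
        return np.array([self.values[s] for s in STAGES], dtype=float)


@dataclass(frozen=True)
class PairAnalysis:
    """Joint characterization of one lincRNA/apcGene pair."""

    lincrna_id: str
    apcgene_id: str
    log2_ratios: Mapping[str, float]
    group: str  # I, II or III
    pearson_r: float | None  # None when undefined (constant profile)
    correlation_class: str  # positive, negative or none
    r_undefined: bool = False
    normalized_ratio: bool = False


def relative_expression(ct: float, ct_ref: float) -> float:
    """2^(-(ct - ct_ref)) — linear relative expression vs the reference."""
    return 2.0 ** (-(ct - ct_ref))


def profiles_from_ct(table: CtTable) -> dict[str, ExpressionProfile]:
    """Build per-gene expression profiles from a Ct table.

    Replicates are averaged on the Ct scale before the 2^(-dCt) transform;
    the replicate SD (cycles) is carried alongside. The reference gene gets
    no profile of its own.
    """
    ref = table.reference_gene_id
    ref_means: dict[str, float] = {}
    for stage in STAGES:
        reps = table.replicates(ref, stage)
        if not reps:
            raise ValidationError(
                f"reference gene {ref!r} has no Ct values for stage {stage}"
            )
        ref_means[stage] = float(np.mean(reps))

    profiles: dict[str, ExpressionProfile] = {}
    for gene in table.gene_ids:
        if gene == ref:
            continue
        values: dict[str, float] = {}
        sds: dict[str, float] = {}
        for stage in STAGES:
            reps = table.replicates(gene, stage)
            if not reps:
                raise ValidationError(
                    f"gene {gene!r} has no Ct values for stage {stage}"
                )
            mean_ct = float(np.mean(reps))
            values[stage] = relative_expression(mean_ct, ref_means[stage])
            sds[stage] = (
                float(np.std(reps, ddof=1)) if len(reps) > 1 else 0.0
            )
        profiles[gene] = ExpressionProfile(
            gene_id=gene, values=values, ct_sd=sds
        )
    return profiles


def normalize_to_stage_max(profile: ExpressionProfile) -> ExpressionProfile:
    """Divide each stage value by the profile maximum (max stage -> 1.0)."""
    peak = max(profile.values.values())
    if peak <= 0:
        raise UndefinedNormalizationError(
            f"profile {profile.gene_id!r} is all zero; cannot normalize"
        )
    return ExpressionProfile(
        gene_id=profile.gene_id,
        values={s: v / peak for s, v in profile.values.items()},
        ct_sd=dict(profile.ct_sd),
    )


def log_ratio_profile(
    linc: ExpressionProfile, apc: ExpressionProfile
) -> dict[str, float]:
    """Per-stage log2(lincRNA / apcGene) expression ratios."""
    ratios: dict[str, float] = {}
    for stage in STAGES:
        denom = apc.values[stage]
        if denom == 0:
            raise ValidationError(
                f"apcGene {apc.gene_id!r} has zero expression in stage "
                f"{stage}; log ratio undefined"
            )
        ratios[stage] = math.log2(linc.values[stage] / denom)
    return ratios


def assign_group(ratios: Mapping[str, float]) -> str:
    """Bin a ratio profile into group I, II or III by its max |log2 ratio|.

    I: >= 3.32 (ten-fold) in at least one stage; III: <= 1 (two-fold) in
    every stage; II: in between.
    """
    peak = max(abs(r) for r in ratios.values())
    if peak >= GROUP_I_BOUNDARY:
        return "I"
    if peak > GROUP_III_BOUNDARY:
        return "II"
    return "III"


def pearson_r(x: Sequence[float], y: Sequence[float]) -> float | None:
    """Product-moment correlation; None when either vector is constant."""
    if len(x) != len(y):
        raise ValidationError(
            f"length mismatch: {len(x)} vs {len(y)} values"
        )
    if len(x) < 3:
        raise ValidationError("need at least 3 paired values")
    xa, ya = np.asarray(x, dtype=float), np.asarray(y, dtype=float)
    if np.ptp(xa) == 0 or np.ptp(ya) == 0:
        return None
    return float(stats.pearsonr(xa, ya).statistic)


def classify_correlation(r: float | None) -> str:
    """positive iff r > 0.8, negative iff r < -0.8, otherwise none."""
    if r is None:
        return "none"
    if r > CORRELATION_THRESHOLD:
        return "positive"
    if r < -CORRELATION_THRESHOLD:
        return "negative"
    return "none"


def analyze_pair(
    linc: ExpressionProfile,
    apc: ExpressionProfile,
    normalized_ratio: bool = False,
) -> PairAnalysis:
    """Full group + correlation analysis of one lincRNA/apcGene pair.

    Log ratios use raw relative expression by default;
    ``normalized_ratio=True`` computes them from stage-max-normalized
    profiles instead. The correlation is always computed on normalized
    profiles (Pearson r is invariant to that scaling anyway).
    """
    if normalized_ratio:
        ratios = log_ratio_profile(
            normalize_to_stage_max(linc), normalize_to_stage_max(apc)
        )
    else:
        ratios = log_ratio_profile(linc, apc)
    nl, na = normalize_to_stage_max(linc), normalize_to_stage_max(apc)
    r = pearson_r(nl.as_array(), na.as_array())
    return PairAnalysis(
        lincrna_id=linc.gene_id,
        apcgene_id=apc.gene_id,
        log2_ratios=ratios,
        group=assign_group(ratios),
        pearson_r=r,
        correlation_class=classify_correlation(r),
        r_undefined=r is None,
        normalized_ratio=normalized_ratio,
    )
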