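"""Summary reporting across pipeline stages.

Collects length statistics for the candidate set (count, mean, range,
fraction longer than 1 kb), configuration-class tallies, orientation
counts, and expression group / correlation-class tables into one bundle
of data frames plus a plain-text summary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .apc_context import ConfigurationClass, configuration_tally
from .expression_stats import PairAnalysis
from .tu_discovery import CascadeReport, LincRNACandidate


@dataclass
class ReportBundle:
    length_stats: dict
    configuration_tally: dict[str, int]
    group_counts: dict[str, int]
    correlation_counts: dict[str, int]
    cascade: pd.DataFrame | None = None
    summary_text: str = ""

    def tables(self) -> dict[str, pd.DataFrame]:
        out = {
            "length_stats": pd.DataFrame([self.length_stats]),
            "configuration_tally": pd.DataFrame(
                sorted(self.configuration_tally.items()),
                columns=["class", "count"],
            ),
            "group_counts": pd.DataFrame(
                sorted(self.group_counts.items()),
                columns=["group", "count"],
            ),
            "correlation_counts": pd.DataFrame(
                sorted(self.correlation_counts.items()),
                columns=["class", "count"],
            ),
        }
        if self.cascade is not None:
            out["cascade"] = self.cascade
        return out


def length_stats(lengths: Sequence[int], long_cutoff_bp: int = 1000) -> dict:
    """n, mean (nearest bp), min, max and % longer than the cutoff.

    Mean is rounded to the nearest integer bp and the long fraction to one
    decimal percent, the precision used when such surveys are reported.
    """
    n = len(lengths)
    if n == 0:
        return {
            "n": 0, "mean_bp": None, "min_bp": None, "max_bp": None,
            "pct_longer_than_1kb": None,
        }
    arr = np.asarray(lengths, dtype=float)
    return {
        "n": n,
        "mean_bp": int(round(float(arr.mean()))),
        "min_bp": int(arr.min()),
        "max_bp": int(arr.max()),
        "pct_longer_than_1kb": round(
            100.0 * float((arr > long_cutoff_bp).sum()) / n, 1
        ),
    }


def run_report(
    candidates: Sequence[LincRNACandidate] = (),
    configurations: Iterable[ConfigurationClass] = (),
    pair_analyses: Sequence[PairAnalysis] = (),
    cascade: CascadeReport | None = None,
) -> ReportBundle:
    """Assemble the end-of-run summary; every tally sums to its input."""
    lstats = length_stats([c.length for c in candidates])
    conf = configuration_tally(configurations)

    groups = {"I": 0, "II": 0, "III": 0}
    corr = {"positive": 0, "negative": 0, "none": 0}
    for pa in pair_analyses:
        groups[pa.group] += 1
        corr[pa.correlation_class] += 1

    lines = [
        f"lincRNA candidates: {lstats['n']}",
    ]
    if lstats["n"]:
        lines.append(
            f"  length: mean {lstats['mean_bp']} bp, range "
            f"{lstats['min_bp']}-{lstats['max_bp']} bp, "
            f"{lstats['pct_longer_than_1kb']}% > 1 kb"
        )
    if conf.get("5P_total", 0) + conf.get("3P_total", 0) > 0:
        lines.append(
            f"configurations: {conf.get('5P_total', 0)} on 5' side, "
            f"{conf.get('3P_total', 0)} on 3' side; "
            f"{conf.get('unidirectional', 0)} unidirectional, "
            f"{conf.get('bidirectional', 0)} bidirectional"
        )
    if pair_analyses:
        lines.append(
            f"expression groups I/II/III: {groups['I']}/{groups['II']}/"
            f"{groups['III']}; correlations +/-/none: "
            f"{corr['positive']}/{corr['negative']}/{corr['none']}"
        )

    cascade_df = (
        pd.DataFrame(cascade.to_rows()) if cascade is not None else None
    )
    return ReportBundle(
        length_stats=lstats,
        configuration_tally=conf,
        group_counts=groups,
        correlation_counts=corr,
        cascade=cascade_df,
        summary_text="\n".join(lines),
    )
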