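"""Nucleotide composition: overall and position-specific GC statistics.

All fractions are computed over the sense codons only (terminal stop
excluded) so that composition, ENC and RSCU share one codon universe.
Fractions are stored in [0, 1]; report tables render the percent-scale
metrics as 100x at output time.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .seqio import CodingSequence


@dataclass(frozen=True)
class CompositionProfile:
    """Overall base fractions plus positional GC for one CDS.

    p1/p2/p3 are the GC fraction at codon positions 1/2/3; p12 their
    first-and-second-position mean, the response variable of the neutrality
    plot; a3..c3 are the single-base fractions at the third position whose
    ratios form the PR2 coordinates.
    """

    a_pct: float
    t_pct: float
    g_pct: float
    c_pct: float
    p1: float
    p2: float
    p3: float
    a3: float
    t3: float
    g3: float
    c3: float

    @property
    def gc_pct(self) -> float:
        return self.g_pct + self.c_pct

    @property
    def p12(self) -> float:
        return (self.p1 + self.p2) / 2.0

    @property
    def gc3(self) -> float:
        return self.g3 + self.c3

    def as_dict(self) -> dict[str, float]:
        return {
            "a_pct": self.a_pct, "t_pct": self.t_pct,
            "g_pct": self.g_pct, "c_pct": self.c_pct, "gc_pct": self.gc_pct,
            "p1": self.p1, "p2": self.p2, "p3": self.p3, "p12": self.p12,
            "a3": self.a3, "t3": self.t3, "g3": self.g3, "c3": self.c3,
            "gc3": self.gc3,
        }


def profile(cds: CodingSequence) -> CompositionProfile:
    """Compute the composition profile of one CDS over its sense codons."""
    sense = cds.sense_codons
    if not sense:
        raise ValueError(f"{cds.seq_id}: no sense codons")
    n = len(sense)
    pos_counts = [Counter(c[k] for c in sense) for k in range(3)]
    overall = pos_counts[0] + pos_counts[1] + pos_counts[2]
    tot = 3 * n

    def gc(counter: Counter) -> float:
        return (counter["G"] + counter["C"]) / sum(counter.values())

    return CompositionProfile(
        a_pct=overall["A"] / tot,
        t_pct=overall["T"] / tot,
        g_pct=overall["G"] / tot,
        c_pct=overall["C"] / tot,
        p1=gc(pos_counts[0]),
        p2=gc(pos_counts[1]),
        p3=gc(pos_counts[2]),
        a3=pos_counts[2]["A"] / n,
        t3=pos_counts[2]["T"] / n,
        g3=pos_counts[2]["G"] / n,
        c3=pos_counts[2]["C"] / n,
    )


#: Metrics stored as fractions but reported x100 (percent) in summary tables.
PERCENT_METRICS = ("gc_pct", "p1", "p2", "p3", "p12")

#: Metric order of the group-characteristics table.
SUMMARY_METRICS = (
    "length_nt", "gc_pct", "p1", "p2", "p3", "p12",
    "enc", "gravy", "aromaticity",
)


@dataclass(frozen=True)
class GroupSummary:
    group: str
    n: int
    mean: dict[str, float]
    sd: dict[str, float]


def summarize_group(metrics: pd.DataFrame, group: str) -> GroupSummary:
    """Mean and sample SD (n-1 denominator; 0 when n == 1) per metric.

    `metrics` holds one row per sequence with columns from SUMMARY_METRICS
    (missing columns are skipped).  Percent-scale metrics are multiplied by
    100 here, matching the display convention of the characteristics table.
    """
    if len(metrics) == 0:
        raise ValueError(f"group {group!r}: no sequences to summarize")
    mean: dict[str, float] = {}
    sd: dict[str, float] = {}
    for m in SUMMARY_METRICS:
        if m not in metrics.columns:
            continue
        vals = np.asarray(metrics[m], dtype=float)
        scale = 100.0 if m in PERCENT_METRICS else 1.0
        mean[m] = float(np.mean(vals)) * scale
        sd[m] = float(np.std(vals, ddof=1)) * scale if len(vals) >= 2 else 0.0
    return GroupSummary(group=group, n=len(metrics), mean=mean, sd=sd)
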