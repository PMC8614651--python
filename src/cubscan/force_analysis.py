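"""Mutation pressure vs natural selection diagnostics.

Three classic views: the parity-rule-2 (PR2) plot of third-position purine/
pyrimidine balance, the neutrality regression of P12 on P3, and the
frequency distribution of the (ENCexp - ENCobs)/ENCexp ratio.  A neutrality
slope near 1 says directional mutation pressure moves all codon positions
together; a slope near 0 says selection pins first/second positions while
the third drifts.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats as sps

from .composition import CompositionProfile
from .genetic_code import CODON_TO_AA, FAMILY_SIZE
from .seqio import CodingSequence


@dataclass(frozen=True)
class Pr2Point:
    """AT bias A3/(A3+T3) and GC bias G3/(G3+C3); (0.5, 0.5) = no bias."""

    at_bias: float
    gc_bias: float

    @property
    def defined(self) -> bool:
        return not (math.isnan(self.at_bias) or math.isnan(self.gc_bias))


def pr2_point(profile: CompositionProfile) -> Pr2Point:
    at_den = profile.a3 + profile.t3
    gc_den = profile.g3 + profile.c3
    if at_den == 0 or gc_den == 0:
        warnings.warn("PR2 point undefined: zero third-position denominator",
                      stacklevel=2)
        return Pr2Point(
            at_bias=profile.a3 / at_den if at_den else float("nan"),
            gc_bias=profile.g3 / gc_den if gc_den else float("nan"),
        )
    return Pr2Point(at_bias=profile.a3 / at_den, gc_bias=profile.g3 / gc_den)


def pr2_point_fourfold(cds: CodingSequence) -> Pr2Point:
    """PR2 restricted to third bases of fourfold-degenerate families, where
    the third position is fully synonymous."""
    counts = {"A": 0, "T": 0, "G": 0, "C": 0}
    for codon in cds.sense_codons:
        if FAMILY_SIZE[CODON_TO_AA[codon]] == 4:
            counts[codon[2]] += 1
    at_den = counts["A"] + counts["T"]
    gc_den = counts["G"] + counts["C"]
    return Pr2Point(
        at_bias=counts["A"] / at_den if at_den else float("nan"),
        gc_bias=counts["G"] / gc_den if gc_den else float("nan"),
    )


@dataclass(frozen=True)
class NeutralityFit:
    slope: float
    intercept: float
    r: float
    p_value: float
    n: int


def neutrality_fit(points: Sequence[tuple[float, float]]) -> NeutralityFit:
    """OLS of P12 on P3 with Pearson r and its two-sided p-value."""
    if len(points) < 3:
        raise ValueError(f"neutrality fit needs >= 3 points, got {len(points)}")
    p3 = np.array([p for p, _ in points], dtype=float)
    p12 = np.array([q for _, q in points], dtype=float)
    if np.ptp(p3) == 0:
        raise ValueError("neutrality fit undefined: P3 has zero variance")
    res = sps.linregress(p3, p12)
    return NeutralityFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r=float(res.rvalue),
        p_value=float(res.pvalue),
        n=len(points),
    )


@dataclass(frozen=True)
class EncRatioHistogram:
    bin_edges: tuple[float, ...]
    bin_counts: tuple[int, ...]
    n: int


def enc_ratio_histogram(ratios: Iterable[float], bin_width: float = 0.05
                        ) -> EncRatioHistogram:
    """Histogram of ENC ratios with half-open bins [edge, edge + width) and
    edges aligned so that 0 is always an edge."""
    vals = np.asarray(list(ratios), dtype=float)
    if vals.size == 0:
        raise ValueError("no ratios to histogram")
    if bin_width <= 0:
        raise ValueError("bin width must be positive")
    k0 = math.floor(np.min(vals) / bin_width)
    k1 = math.floor(np.max(vals) / bin_width) + 1
    edges = np.arange(k0, k1 + 1) * bin_width
    counts, _ = np.histogram(vals, bins=edges)
    return EncRatioHistogram(
        bin_edges=tuple(float(e) for e in edges),
        bin_counts=tuple(int(c) for c in counts),
        n=int(vals.size),
    )
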