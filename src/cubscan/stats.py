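"""Correlation battery over composition metrics, ENC and RSCU.

Spearman rank correlation is the default method throughout (the only method
the source tables name); Pearson is available by switch.  Spearman p-values
use exact permutation enumeration for n <= 10 without ties and the usual
t-approximation otherwise.  No multiple-testing correction is applied;
significance is flagged at the conventional 0.05 / 0.01 stars.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass(frozen=True)
class CorrelationCell:
    r: float
    p_value: float
    n: int
    method: str
    significance: str   # "ns" | "p<0.05" | "p<0.01"; "undefined" when r is NaN

    @property
    def defined(self) -> bool:
        return not math.isnan(self.r)


def _stars(p: float) -> str:
    if math.isnan(p):
        return "undefined"
    if p < 0.01:
        return "p<0.01"
    if p < 0.05:
        return "p<0.05"
    return "ns"


def _undefined(n: int, method: str) -> CorrelationCell:
    return CorrelationCell(float("nan"), float("nan"), n, method, "undefined")


@lru_cache(maxsize=16)
def _exact_spearman_null(n: int) -> np.ndarray:
    """Sorted |rho| over all n! rank pairings (tie-free null distribution)."""
    base = np.arange(1, n + 1, dtype=float)
    denom = n * (n * n - 1)
    rhos = np.array([
        1.0 - 6.0 * np.sum((base - np.array(perm, dtype=float)) ** 2) / denom
        for perm in itertools.permutations(range(1, n + 1))
    ])
    return np.sort(np.abs(rhos))


def spearman(x: Sequence[float], y: Sequence[float]) -> CorrelationCell:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("spearman needs two equal-length vectors of size >= 3")
    rx, ry = sps.rankdata(x), sps.rankdata(y)
    if np.ptp(rx) == 0 or np.ptp(ry) == 0:
        return _undefined(x.size, "spearman")
    rho, p_t = sps.spearmanr(x, y)
    ties = (np.unique(x).size < x.size) or (np.unique(y).size < y.size)
    if x.size <= 10 and not ties:
        null = _exact_spearman_null(x.size)
        # two-sided exact p: fraction of pairings at least as extreme
        p = float(np.mean(null >= abs(rho) - 1e-12))
    else:
        p = float(p_t)
    return CorrelationCell(float(rho), p, int(x.size), "spearman", _stars(p))


def pearson(x: Sequence[float], y: Sequence[float]) -> CorrelationCell:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("pearson needs two equal-length vectors of size >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return _undefined(x.size, "pearson")
    r, p = sps.pearsonr(x, y)
    return CorrelationCell(float(r), float(p), int(x.size), "pearson", _stars(p))


def _corr(x, y, method: str) -> CorrelationCell:
    return spearman(x, y) if method == "spearman" else pearson(x, y)


def correlation_matrix(
    metrics: pd.DataFrame,
    pairs: Sequence[tuple[str, str]],
    method: str = "spearman",
) -> pd.DataFrame:
    """Correlate the requested metric pairs over the rows of one group's
    per-sequence metrics table.  Returns a tidy frame (x, y, r, p, n, stars).
    """
    if len(metrics) < 3:
        raise ValueError("need >= 3 sequences for a correlation matrix")
    rows = []
    for xm, ym in pairs:
        cell = _corr(metrics[xm], metrics[ym], method)
        rows.append({
            "x": xm, "y": ym, "r": cell.r, "p_value": cell.p_value,
            "n": cell.n, "significance": cell.significance,
        })
    return pd.DataFrame(rows)


#: Pair grids mirroring the source report's correlation tables.
OVERALL_VS_THIRD_PAIRS = [
    (a, b)
    for a in ("a_pct", "t_pct", "g_pct", "c_pct", "gc_pct")
    for b in ("a3", "t3", "g3", "c3", "gc3")
]
ENC_VS_POSITION_PAIRS = [("enc", p) for p in ("p1", "p2", "p3", "p12")]
GC_VS_POSITION_PAIRS = [("gc_pct", p) for p in ("p1", "p2", "p3", "p12")]


def rscu_gc3_heatmap(
    rscu_matrix: pd.DataFrame,
    gc3: pd.Series,
    method: str = "spearman",
) -> pd.DataFrame:
    """Per-codon correlation of RSCU against GC3 across one group's
    sequences.  Codons with zero variance (uniform usage, including codons
    never observed) are flagged rather than correlated."""
    if len(rscu_matrix) < 3:
        raise ValueError("need >= 3 sequences for the RSCU-GC3 heatmap")
    gc3 = gc3.reindex(rscu_matrix.index)
    rows = []
    for codon in rscu_matrix.columns:
        col = rscu_matrix[codon].astype(float)
        if np.ptp(col.values) == 0 or np.ptp(gc3.values) == 0:
            rows.append({"codon": codon, "r": float("nan"),
                         "p_value": float("nan"), "n": len(col),
                         "significance": "uniform_usage"})
            continue
        cell = _corr(col.values, gc3.values, method)
        rows.append({"codon": codon, "r": cell.r, "p_value": cell.p_value,
                     "n": cell.n, "significance": cell.significance})
    return pd.DataFrame(rows).set_index("codon")
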