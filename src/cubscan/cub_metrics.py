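"""Codon usage bias indices: Wright's ENC, expected ENC from GC3, and RSCU.

ENC (effective number of codons) ranges from 20 — every amino acid served by
a single codon — to 61, all sense codons used evenly.  The observed value is
Wright's class-averaged homozygosity estimator; the expected value is the
null curve a gene would follow if GC3 alone (mutation pressure) set its
codon usage.  RSCU rescales each codon's count by its family's uniform-usage
expectation, so 1 means "as expected", >1.6 flags an over-represented codon.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable

import numpy as np

from .genetic_code import (
    AA_TO_CODONS,
    CODON_TO_AA,
    DEGENERACY_CLASSES,
    FAMILY_SIZE,
    SYNONYMOUS_CODONS,
)
from .seqio import CodingSequence

#: Wright's weights: number of families per degeneracy class.
_CLASS_WEIGHTS = {2: 9, 3: 1, 4: 5, 6: 3}

ENC_MIN = 20.0
ENC_MAX = 61.0


@dataclass(frozen=True)
class CodonCountTable:
    """Counts over sense codons only; stop codons are never keys."""

    counts: dict[str, int]
    total: int

    @staticmethod
    def from_counts(counts: dict[str, int]) -> "CodonCountTable":
        for codon in counts:
            if codon not in CODON_TO_AA:
                raise ValueError(f"not a sense codon: {codon}")
        return CodonCountTable(counts=dict(counts), total=sum(counts.values()))


def count_codons(cds: CodingSequence) -> CodonCountTable:
    counts: dict[str, int] = {}
    for codon in cds.sense_codons:
        counts[codon] = counts.get(codon, 0) + 1
    return CodonCountTable(counts=counts, total=len(cds.sense_codons))


def pool_counts(tables: Iterable[CodonCountTable]) -> CodonCountTable:
    counts: dict[str, int] = {}
    for t in tables:
        for codon, n in t.counts.items():
            counts[codon] = counts.get(codon, 0) + n
    return CodonCountTable.from_counts(counts)


@dataclass(frozen=True)
class EncResult:
    enc_obs: float
    enc_exp: float
    enc_ratio: float


def enc_observed(table: CodonCountTable) -> float:
    """Wright's ENC.

    Per synonymous family with codon total n >= 2, the homozygosity
    estimate is F = (n * sum(p_i^2) - 1) / (n - 1).  Families with n < 2 or
    F <= 0 are dropped; F is floored at 1/k so a family cannot contribute
    more effective codons than it has.  Class means F2/F3/F4/F6 combine as
    ENC = 2 + 9/F2 + 1/F3 + 5/F4 + 3/F6, capped at 61.  A missing 3-fold
    class is imputed as (F2+F4)/2; a missing 2-, 4- or 6-fold class leaves
    ENC undefined (NaN) with a warning.
    """
    per_class: dict[int, list[float]] = {k: [] for k in _CLASS_WEIGHTS}
    any_usable = False
    for k, aas in DEGENERACY_CLASSES.items():
        for aa in aas:
            fam = AA_TO_CODONS[aa]
            n = sum(table.counts.get(c, 0) for c in fam)
            if n < 2:
                continue
            any_usable = True
            p = np.array([table.counts.get(c, 0) for c in fam], dtype=float) / n
            f_hat = (n * float(np.sum(p * p)) - 1.0) / (n - 1.0)
            if f_hat <= 0.0:
                continue
            per_class[k].append(max(f_hat, 1.0 / k))
    if not any_usable:
        raise ValueError("ENC undefined: no synonymous family has 2 or more codons")
    f_bar: dict[int, float | None] = {
        k: (float(np.mean(v)) if v else None) for k, v in per_class.items()
    }
    if f_bar[3] is None and f_bar[2] is not None and f_bar[4] is not None:
        f_bar[3] = (f_bar[2] + f_bar[4]) / 2.0
    missing = [k for k in (2, 3, 4, 6) if f_bar[k] is None]
    if missing:
        warnings.warn(
            f"ENC undefined: no usable family in degeneracy class(es) {missing}",
            stacklevel=2,
        )
        return float("nan")
    enc = 2.0 + sum(_CLASS_WEIGHTS[k] / f_bar[k] for k in (2, 3, 4, 6))
    return min(enc, ENC_MAX)


def enc_expected(s: float) -> float:
    """Expected ENC under mutation pressure alone at GC3 = s:
    2 + s + 29 / (s^2 + (1-s)^2)."""
    if not 0.0 <= s <= 1.0:
        raise ValueError(f"GC3 fraction must be in [0, 1], got {s}")
    return 2.0 + s + 29.0 / (s * s + (1.0 - s) * (1.0 - s))


def enc_ratio(enc_obs: float, enc_exp: float) -> float:
    """(ENCexp - ENCobs) / ENCexp — positive when observed bias exceeds the
    mutation-pressure expectation."""
    if enc_exp == 0:
        raise ValueError("expected ENC is zero")
    return (enc_exp - enc_obs) / enc_exp


def enc_result(table: CodonCountTable, gc3: float) -> EncResult:
    obs = enc_observed(table)
    exp = enc_expected(gc3)
    return EncResult(enc_obs=obs, enc_exp=exp, enc_ratio=enc_ratio(obs, exp))


#: RSCU classification bands.
RSCU_CLASSES = ("rare", "unbiased", "preferred", "over_represented")
OVER_REPRESENTED_THRESHOLD = 1.6


def classify_rscu(value: float) -> str:
    if value > OVER_REPRESENTED_THRESHOLD:
        return "over_represented"
    if value > 1.0:
        return "preferred"
    if value == 1.0:
        return "unbiased"
    return "rare"


@dataclass(frozen=True)
class RscuTable:
    rscu: dict[str, float]
    rscu_class: dict[str, str]


def rscu(table: CodonCountTable) -> RscuTable:
    """RSCU over the 59 synonymous sense codons.

    RSCU_ij = x_ij / ((1/k_i) * sum_j x_ij) for family i of size k_i; a
    family never observed yields zeros for all its codons.
    """
    values: dict[str, float] = {}
    for aa, fam in AA_TO_CODONS.items():
        k = FAMILY_SIZE[aa]
        if k == 1:
            continue
        fam_total = sum(table.counts.get(c, 0) for c in fam)
        for c in fam:
            if fam_total == 0:
                values[c] = 0.0
            else:
                values[c] = table.counts.get(c, 0) / (fam_total / k)
    values = {c: values[c] for c in SYNONYMOUS_CODONS}
    classes = {c: classify_rscu(v) for c, v in values.items()}
    return RscuTable(rscu=values, rscu_class=classes)
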