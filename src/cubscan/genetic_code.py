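"""Standard genetic code tables and synonymous-family structure.

Everything downstream (ENC, RSCU, correspondence analysis, the synthetic
generator) shares one description of the standard code: the 61 sense codons,
the synonymous family of each amino acid, and the degeneracy classes that
enter Wright's effective-number-of-codons estimator.  The tables are derived
from Biopython's translation table 1 rather than typed by hand.
"""

from __future__ import annotations

from Bio.Data import CodonTable
from Bio.SeqUtils.ProtParamData import kd as KYTE_DOOLITTLE

_TABLE = CodonTable.unambiguous_dna_by_id[1]

#: The three stop codons of the standard code.
STOP_CODONS: tuple[str, ...] = tuple(sorted(_TABLE.stop_codons))

#: codon -> one-letter amino acid, for the 61 sense codons.
CODON_TO_AA: dict[str, str] = dict(_TABLE.forward_table)

#: The 61 sense codons in lexicographic order.
SENSE_CODONS: tuple[str, ...] = tuple(sorted(CODON_TO_AA))

#: amino acid -> sorted tuple of its synonymous codons.
AA_TO_CODONS: dict[str, tuple[str, ...]] = {}
for _codon, _aa in CODON_TO_AA.items():
    AA_TO_CODONS.setdefault(_aa, [])
for _codon in SENSE_CODONS:
    AA_TO_CODONS[CODON_TO_AA[_codon]].append(_codon)
AA_TO_CODONS = {aa: tuple(cods) for aa, cods in AA_TO_CODONS.items()}

#: amino acid -> family size (degeneracy): 1, 2, 3, 4 or 6 under the standard code.
FAMILY_SIZE: dict[str, int] = {aa: len(c) for aa, c in AA_TO_CODONS.items()}

#: degeneracy class -> amino acids in it (singleton Met/Trp excluded from ENC).
DEGENERACY_CLASSES: dict[int, tuple[str, ...]] = {
    k: tuple(sorted(aa for aa, sz in FAMILY_SIZE.items() if sz == k))
    for k in (2, 3, 4, 6)
}

# Wright's estimator weights: 9 two-fold, 1 three-fold (Ile), 5 four-fold,
# 3 six-fold (Leu/Ser/Arg) families.
assert tuple(len(DEGENERACY_CLASSES[k]) for k in (2, 3, 4, 6)) == (9, 1, 5, 3)

#: The 59 synonymous sense codons: 61 minus the single-codon families ATG (Met)
#: and TGG (Trp).  This is the codon universe of RSCU and of the ordination.
SYNONYMOUS_CODONS: tuple[str, ...] = tuple(
    c for c in SENSE_CODONS if FAMILY_SIZE[CODON_TO_AA[c]] > 1
)
assert len(SYNONYMOUS_CODONS) == 59

#: The 20 amino acids, alphabetical one-letter order.
AMINO_ACIDS: tuple[str, ...] = tuple(sorted(AA_TO_CODONS))


def is_gc(base: str) -> bool:
    return base in ("G", "C")


def third_base(codon: str) -> str:
    return codon[2]
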