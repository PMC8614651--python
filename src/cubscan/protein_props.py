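"""Protein-level properties of a CDS: amino-acid usage, GRAVY, aromaticity.

GRAVY is the grand average of Kyte-Doolittle hydropathy over the protein's
residues (negative = hydrophilic/soluble); aromaticity is the relative
frequency of Phe + Tyr + Trp.  Both are delegated to Biopython's
ProteinAnalysis, which implements exactly these definitions.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio.Seq import Seq
from Bio.SeqUtils.ProtParam import ProteinAnalysis

from .genetic_code import AMINO_ACIDS
from .seqio import CodingSequence


def translate(cds: CodingSequence) -> str:
    """Standard-code translation of the sense codons (terminal stop dropped)."""
    return str(Seq("".join(cds.sense_codons)).translate(table=1))


@dataclass(frozen=True)
class ProteinProfile:
    aa_freq: dict[str, float]
    gravy: float
    aromaticity: float


def protein_profile(protein: str) -> ProteinProfile:
    if not protein:
        raise ValueError("empty protein sequence")
    pa = ProteinAnalysis(protein)
    freq = pa.amino_acids_percent  # percent scale in Biopython >= 1.82
    return ProteinProfile(
        aa_freq={aa: float(freq.get(aa, 0.0)) / 100.0 for aa in AMINO_ACIDS},
        gravy=float(pa.gravy()),
        aromaticity=float(pa.aromaticity()),
    )


def profile_cds(cds: CodingSequence) -> ProteinProfile:
    return protein_profile(translate(cds))
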