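"""Reading, validating and codon-tokenizing coding sequences.

A record is accepted only if it looks like a clean CDS: no ambiguous bases,
length a multiple of three, an ATG start, a single terminal stop and no
internal stop codon.  Rejections are data (seq_id, reason), never exceptions,
so a dirty FASTA degrades to a smaller dataset plus a rejection log.
"""

from __future__ import annotations

import gzip
import warnings
from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO

from .genetic_code import STOP_CODONS

#: Rejection reasons, in the fixed order validation applies them.
REJECTION_REASONS = (
    "ambiguous_base",
    "not_multiple_of_3",
    "bad_start",
    "bad_stop",
    "internal_stop",
)

_VALID_BASES = frozenset("ACGT")


@dataclass(frozen=True)
class CodingSequence:
    """One validated CDS with its group label and codon tokenization."""

    seq_id: str
    group: str
    sequence: str
    codons: tuple[str, ...]

    @property
    def length_nt(self) -> int:
        return len(self.sequence)

    @property
    def sense_codons(self) -> tuple[str, ...]:
        """All codons except the terminal stop — the universe every
        downstream metric (composition, ENC, RSCU) is computed on."""
        return self.codons[:-1]


@dataclass
class GroupedDataset:
    sequences: list[CodingSequence] = field(default_factory=list)
    groups: set[str] = field(default_factory=set)
    rejected: list[tuple[str, str]] = field(default_factory=list)

    def by_group(self) -> dict[str, list[CodingSequence]]:
        out: dict[str, list[CodingSequence]] = {g: [] for g in sorted(self.groups)}
        for s in self.sequences:
            out[s.group].append(s)
        return out


def _open_text(path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def read_fasta(path) -> list[tuple[str, str]]:
    """Read a (possibly gzipped) FASTA into (seq_id, sequence) pairs.

    Record order is preserved, headers are truncated at the first whitespace,
    sequences are uppercased and RNA ``U`` is normalized to ``T``.
    """
    with _open_text(path) as fh:
        records = [
            (rec.id, str(rec.seq).upper().replace("U", "T"))
            for rec in SeqIO.parse(fh, "fasta")
        ]
    if not records:
        warnings.warn(f"no FASTA records found in {path}", stacklevel=2)
    return records


def write_fasta(sequences: list[CodingSequence], path) -> None:
    with open(path, "wt") as fh:
        for s in sequences:
            fh.write(f">{s.seq_id}\n{s.sequence}\n")


def validate_cds(seq_id: str, raw: str, group: str):
    """Validate one raw sequence; return a :class:`CodingSequence` or a
    ``(seq_id, reason)`` rejection tuple.

    Checks run in a fixed order (ambiguity, frame, start, stop, internal
    stop) so the reported reason is deterministic.
    """
    seq = raw.upper().replace("U", "T")
    if not set(seq) <= _VALID_BASES:
        return (seq_id, "ambiguous_base")
    if len(seq) == 0 or len(seq) % 3 != 0:
        return (seq_id, "not_multiple_of_3")
    codons = tuple(seq[i : i + 3] for i in range(0, len(seq), 3))
    if codons[0] != "ATG":
        return (seq_id, "bad_start")
    if codons[-1] not in STOP_CODONS:
        return (seq_id, "bad_stop")
    if any(c in STOP_CODONS for c in codons[:-1]):
        return (seq_id, "internal_stop")
    return CodingSequence(seq_id=seq_id, group=group, sequence=seq, codons=codons)


def read_group_table(path) -> dict[str, str]:
    """Two-column TSV (seq_id, group); a header row is tolerated."""
    mapping: dict[str, str] = {}
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno + 1}: expected 2 tab-separated columns")
            sid, grp = parts[0].strip(), parts[1].strip()
            if lineno == 0 and sid.lower() in ("seq_id", "id", "sequence_id"):
                continue
            mapping[sid] = grp
    return mapping


def load_dataset(fasta, group_table) -> GroupedDataset:
    """Load a FASTA plus group-assignment table into a validated dataset.

    Every FASTA id must appear in the group table; a missing id is a hard
    error (silent label-less sequences would corrupt group statistics).
    """
    records = read_fasta(fasta)
    if not records:
        raise ValueError(f"no sequences found in {fasta}")
    groups_map = read_group_table(group_table)
    missing = [sid for sid, _ in records if sid not in groups_map]
    if missing:
        raise KeyError(
            f"sequence id(s) missing from group table: {', '.join(missing)}"
        )
    ds = GroupedDataset()
    for sid, raw in records:
        result = validate_cds(sid, raw, groups_map[sid])
        if isinstance(result, CodingSequence):
            ds.sequences.append(result)
            ds.groups.add(result.group)
        else:
            ds.rejected.append(result)
    return ds


def write_rejections(ds: GroupedDataset, path) -> None:
    with open(path, "wt") as fh:
        fh.write("seq_id\treason\n")
        for sid, reason in ds.rejected:
            fh.write(f"{sid}\t{reason}\n")
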