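"""Sequence records and FASTA I/O.

Sequences are amino-acid strings over the 20 standard one-letter codes plus
``X`` for an unknown residue.  FASTA headers are split into an identifier
(first whitespace-delimited token) and an optional species / description
label (the remainder).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

from Bio import SeqIO
from Bio.SeqRecord import SeqRecord as _BioRecord
from Bio.Seq import Seq

#: The 20 standard amino acids in fixed alphabetical one-letter order.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: Full residue alphabet accepted in sequence records.
ALPHABET = AMINO_ACIDS + "X"

_ALPHABET_SET = frozenset(ALPHABET)


@dataclass(frozen=True)
class SequenceRecord:
    """An amino-acid sequence with an identifier and optional species label."""

    id: str
    residues: str
    species: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence id must be non-empty")
        if not self.residues:
            raise ValueError(f"sequence {self.id!r}: residues must be non-empty")
        for pos, ch in enumerate(self.residues, start=1):
            if ch not in _ALPHABET_SET:
                raise ValueError(
                    f"sequence {self.id!r}: invalid character {ch!r} at position {pos}"
                )

    def __len__(self) -> int:
        return len(self.residues)


def _clean(raw: str, seq_id: str) -> str:
    seq = raw.upper().rstrip("*")
    for pos, ch in enumerate(seq, start=1):
        if ch not in _ALPHABET_SET:
            raise ValueError(
                f"sequence {seq_id!r}: invalid character {ch!r} at position {pos}"
            )
    return seq


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a (multi-)FASTA file into a list of :class:`SequenceRecord`.

    The header's first token becomes the record id; any remainder becomes the
    species label.  Sequences are upper-cased and trailing ``*`` stop
    characters are stripped.

    Raises
    ------
    ValueError
        On an empty file, a duplicate id (named in the message), or a
        character outside the 21-letter alphabet (position reported).
    """
    path = Path(path)
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        desc_rest = rec.description[len(rec.id):].strip() or None
        if rec.id in seen:
            raise ValueError(f"duplicate sequence id {rec.id!r} in {path}")
        seen.add(rec.id)
        records.append(
            SequenceRecord(id=rec.id, residues=_clean(str(rec.seq), rec.id),
                           species=desc_rest)
        )
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path) -> None:
    """Write records as FASTA (id + optional species on the header line)."""
    bio = [
        _BioRecord(Seq(r.residues), id=r.id, description=r.species or "")
        for r in records
    ]
    SeqIO.write(bio, str(path), "fasta")
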