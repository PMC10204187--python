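"""Pairwise global alignment of orthologs to a reference.

Alignments are optimal Needleman-Wunsch global alignments under affine gap
penalties (Gotoh), computed with Biopython's :class:`Bio.Align.PairwiseAligner`.
Among co-optimal alignments the aligner's first-reported traceback is used,
which is deterministic for fixed inputs and parameters.

Scoring conventions:

* a gap run of length ``L`` costs ``gap_open + (L - 1) * gap_extend``;
* terminal gaps are penalized (true global alignment);
* ``X`` (unknown residue) scores 0 against every residue and never counts
  as an identity.

The percent identity denominator is, by default, the total number of
alignment columns including gap columns (the common "global identity"
convention); ``denominator="aligned"`` restricts it to gap-free columns.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field
from typing import Dict, Literal

from Bio import Align
from Bio.Align import substitution_matrices

from .io import SequenceRecord

#: Gap marker used in alignment rows and residue maps.
GAP = "-"


@dataclass(frozen=True)
class ScoringParams:
    """Substitution matrix and affine gap penalties (positive costs)."""

    matrix_name: str = "BLOSUM62"
    gap_open: float = 11.0
    gap_extend: float = 1.0

    def __post_init__(self) -> None:
        if self.gap_open <= 0 or self.gap_extend <= 0:
            raise ValueError("gap penalties must be positive")
        if self.gap_extend > self.gap_open:
            raise ValueError("gap_extend must not exceed gap_open")


@dataclass(frozen=True)
class PairwiseAlignment:
    """A gapped reference/query alignment with score and identity."""

    ref_row: str
    query_row: str
    score: float
    n_columns: int
    n_identities: int
    identity_pct: float

    def __post_init__(self) -> None:
        if len(self.ref_row) != len(self.query_row):
            raise ValueError("alignment rows differ in length")
        if len(self.ref_row) != self.n_columns:
            raise ValueError("n_columns inconsistent with rows")
        for a, b in zip(self.ref_row, self.query_row):
            if a == GAP and b == GAP:
                raise ValueError("column with gap in both rows")


@dataclass(frozen=True)
class ResidueMap:
    """Reference-anchored residue correspondence for one ortholog.

    ``mapped[i]`` is the ortholog residue aligned to reference position
    ``i + 1`` (1-based reference numbering), or the gap marker.  Query
    insertions relative to the reference are counted per preceding reference
    position but not mapped.
    """

    mapped: str
    insertions: Dict[int, int] = field(default_factory=dict)

    @property
    def entries(self) -> Dict[int, str]:
        """{reference position -> ortholog residue or gap marker}."""
        return {i + 1: ch for i, ch in enumerate(self.mapped)}

    def residue_at(self, position: int) -> str:
        if not 1 <= position <= len(self.mapped):
            raise IndexError(f"reference position {position} out of range")
        return self.mapped[position - 1]

    def __len__(self) -> int:
        return len(self.mapped)


@functools.lru_cache(maxsize=8)
def _make_aligner(matrix_name: str, gap_open: float, gap_extend: float) -> Align.PairwiseAligner:
    try:
        matrix = substitution_matrices.load(matrix_name)
    except FileNotFoundError as exc:
        raise ValueError(f"unknown substitution matrix {matrix_name!r}") from exc
    if "X" in matrix.alphabet:
        m = matrix.copy()
        for ch in m.alphabet:
            m["X", ch] = 0.0
            m[ch, "X"] = 0.0
    else:  # extend alphabet with an all-zero X row/column
        import numpy as np

        alphabet = matrix.alphabet + "X"
        m = substitution_matrices.Array(alphabet=alphabet, dims=2)
        for a in matrix.alphabet:
            for b in matrix.alphabet:
                m[a, b] = matrix[a, b]
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = m
    aligner.open_gap_score = -float(gap_open)
    aligner.extend_gap_score = -float(gap_extend)
    return aligner


def align_global(
    ref: SequenceRecord,
    query: SequenceRecord,
    params: ScoringParams = ScoringParams(),
    denominator: Literal["columns", "aligned"] = "columns",
) -> PairwiseAlignment:
    """Optimal global alignment of ``query`` against ``ref``.

    Returns the maximum-score Needleman-Wunsch alignment under affine gap
    penalties; ties are resolved deterministically (first traceback).
    """
    aligner = _make_aligner(params.matrix_name, params.gap_open, params.gap_extend)
    result = aligner.align(ref.residues, query.residues)
    aln = result[0]
    ref_row, query_row = str(aln[0]), str(aln[1])
    n_columns = len(ref_row)
    n_identities = sum(
        1
        for a, b in zip(ref_row, query_row)
        if a == b and a != GAP and a != "X"
    )
    if denominator == "aligned":
        denom = sum(
            1 for a, b in zip(ref_row, query_row) if a != GAP and b != GAP
        )
    else:
        denom = n_columns
    identity_pct = 100.0 * n_identities / denom if denom else 0.0
    return PairwiseAlignment(
        ref_row=ref_row,
        query_row=query_row,
        score=float(aln.score),
        n_columns=n_columns,
        n_identities=n_identities,
        identity_pct=identity_pct,
    )


def map_to_reference(aln: PairwiseAlignment) -> ResidueMap:
    """Project an alignment onto reference numbering.

    Each reference position receives the query residue aligned there or the
    gap marker; query insertions (gap in the reference row) are tallied per
    preceding reference position.
    """
    mapped: list[str] = []
    insertions: Dict[int, int] = {}
    ref_pos = 0
    for a, b in zip(aln.ref_row, aln.query_row):
        if a == GAP:
            insertions[ref_pos] = insertions.get(ref_pos, 0) + 1
        else:
            ref_pos += 1
            mapped.append(b)
    return ResidueMap(mapped="".join(mapped), insertions=insertions)


def alignment_fasta(aln: PairwiseAlignment, ref_id: str, query_id: str) -> str:
    """Render an aligned pair as two gapped FASTA records."""
    return f">{ref_id}\n{aln.ref_row}\n>{query_id}\n{aln.query_row}\n"
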