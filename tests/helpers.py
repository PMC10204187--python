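"""Shared test utilities: an independent alignment oracle and structure builders.

The alignment oracle enumerates *all* global alignments of two sequences and
scores each one directly under affine gap penalties (a gap run of length L
costs open + (L-1)*extend).  It shares no code with the package's alignment
path, so score agreement is a genuine two-route check.
"""

from __future__ import annotations

import itertools
from pathlib import Path
from typing import Dict, Iterator, List, Tuple

import gemmi

from Bio.Align import substitution_matrices


def matrix_lookup(name: str = "BLOSUM62") -> Dict[Tuple[str, str], float]:
    """Substitution matrix as a plain dict, with X scoring 0 vs everything."""
    m = substitution_matrices.load(name)
    table = {}
    for a in m.alphabet:
        for b in m.alphabet:
            table[(a, b)] = 0.0 if "X" in (a, b) else float(m[a, b])
    return table


def brute_force_score(
    a: str,
    b: str,
    sub: Dict[Tuple[str, str], float],
    gap_open: float = 11.0,
    gap_extend: float = 1.0,
) -> float:
    """Maximum affine-gap score over an exhaustive enumeration of all
    global alignments of ``a`` and ``b``."""
    best = float("-inf")
    la, lb = len(a), len(b)

    def rec(i: int, j: int, score: float, state: int) -> None:
        # state: 0 = last column was a match/mismatch, 1 = gap in b, 2 = gap in a
        nonlocal best
        if i == la and j == lb:
            if score > best:
                best = score
            return
        if i < la and j < lb:
            rec(i + 1, j + 1, score + sub[(a[i], b[j])], 0)
        if i < la:
            rec(i + 1, j, score - (gap_extend if state == 1 else gap_open), 1)
        if j < lb:
            rec(i, j + 1, score - (gap_extend if state == 2 else gap_open), 2)

    rec(0, 0, 0.0, 0)
    return best


def enumerate_alignments(a: str, b: str) -> Iterator[Tuple[str, str]]:
    """Yield every global alignment of ``a`` and ``b`` as two gapped rows."""
    la, lb = len(a), len(b)

    def rec(i: int, j: int, ra: List[str], rb: List[str]):
        if i == la and j == lb:
            yield "".join(ra), "".join(rb)
            return
        if i < la and j < lb:
            yield from rec(i + 1, j + 1, ra + [a[i]], rb + [b[j]])
        if i < la:
            yield from rec(i + 1, j, ra + [a[i]], rb + ["-"])
        if j < lb:
            yield from rec(i, j + 1, ra + ["-"], rb + [b[j]])

    yield from rec(0, 0, [], [])


def score_alignment_rows(
    ra: str,
    rb: str,
    sub: Dict[Tuple[str, str], float],
    gap_open: float = 11.0,
    gap_extend: float = 1.0,
) -> float:
    """Score a gapped alignment directly: affine penalty per gap run."""
    score = 0.0
    prev = 0
    for x, y in zip(ra, rb):
        if x != "-" and y != "-":
            score += sub[(x, y)]
            prev = 0
        elif y == "-":
            score -= gap_extend if prev == 1 else gap_open
            prev = 1
        else:
            score -= gap_extend if prev == 2 else gap_open
            prev = 2
    return score


# ---------------------------------------------------------------------------
# Synthetic structure fixtures (built programmatically, written as text)

THREE_LETTER = {
    one: three
    for one, three in zip(
        "ACDEFGHIKLMNPQRSTVWY",
        [
            "ALA", "CYS", "ASP", "GLU", "PHE", "GLY", "HIS", "ILE", "LYS",
            "LEU", "MET", "ASN", "PRO", "GLN", "ARG", "SER", "THR", "VAL",
            "TRP", "TYR",
        ],
    )
}

AtomSpec = Tuple[str, Tuple[float, float, float]]  # (atom name, xyz)


def build_structure(
    chains: Dict[str, List[Tuple[str, int, List[AtomSpec]]]],
) -> gemmi.Structure:
    """Build a gemmi Structure from {chain_id: [(one_letter, seqid, atoms)]}."""
    st = gemmi.Structure()
    st.name = "synthetic"
    model = gemmi.Model("1")
    for chain_id, residues in chains.items():
        chain = gemmi.Chain(chain_id)
        serial = 1
        for one, seqid, atoms in residues:
            res = gemmi.Residue()
            res.name = THREE_LETTER[one]
            res.seqid = gemmi.SeqId(seqid, " ")
            for atom_name, (x, y, z) in atoms:
                atom = gemmi.Atom()
                atom.name = atom_name
                atom.pos = gemmi.Position(x, y, z)
                atom.element = gemmi.Element(atom_name[0])
                atom.occ = 1.0
                atom.serial = serial
                serial += 1
                res.add_atom(atom)
            chain.add_residue(res)
        model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    return st


def write_structure(st: gemmi.Structure, path: Path) -> Path:
    if path.suffix == ".cif":
        st.make_mmcif_document().write_file(str(path))
    else:
        st.write_pdb(str(path))
    return path


def ca_chain(sequence: str, spacing: float = 3.8, start_seqid: int = 1,
             origin: Tuple[float, float, float] = (0.0, 0.0, 0.0)):
    """Residue specs for a straight C-alpha trace of ``sequence``."""
    ox, oy, oz = origin
    return [
        (aa, start_seqid + i, [("CA", (ox + i * spacing, oy, oz))])
        for i, aa in enumerate(sequence)
    ]
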