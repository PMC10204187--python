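"""Active-site neighborhoods from structure, in reference numbering.

The "close vicinity of the active site" is operationalized as a distance
query: every residue having an in-scope atom within ``radius_A`` of any
in-scope atom of an anchor residue (default anchors: the catalytic triad)
belongs to the neighborhood.  Structure chains are mapped onto reference
numbering by global sequence alignment, so heteromeric files whose chains
cover different segments of the precursor (e.g. Ntn-hydrolase alpha and
beta subunits) all contribute to a single reference-numbered position set.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, FrozenSet, List, Literal, Optional, Tuple

import gemmi
import numpy as np

from .align import GAP, ResidueMap, ScoringParams, align_global
from .io import SequenceRecord
from .profile import ReferenceAnnotation

_BACKBONE = frozenset({"N", "CA", "C", "O", "OXT"})


@dataclass(frozen=True)
class ResidueAtoms:
    """One polymer residue: name, author number, one-letter code, atoms."""

    name: str
    seqid: int
    one_letter: str
    atom_names: Tuple[str, ...]
    coords: np.ndarray  # (n_atoms, 3) float, Angstrom

    def scoped_coords(self, scope: str) -> np.ndarray:
        if scope == "all-atom":
            return self.coords
        if scope == "c-alpha":
            idx = [i for i, n in enumerate(self.atom_names) if n == "CA"]
        elif scope == "side-chain":
            idx = [i for i, n in enumerate(self.atom_names) if n not in _BACKBONE]
            if not idx:  # glycine: fall back to CA so the residue is not invisible
                idx = [i for i, n in enumerate(self.atom_names) if n == "CA"]
        else:
            raise ValueError(f"unknown atom scope {scope!r}")
        return self.coords[idx]


@dataclass(frozen=True)
class ChainModel:
    id: str
    residues: Tuple[ResidueAtoms, ...]

    @property
    def sequence(self) -> str:
        return "".join(r.one_letter for r in self.residues)


@dataclass(frozen=True)
class StructureModel:
    """First model of a structure file: protein chains with coordinates."""

    chains: Tuple[ChainModel, ...]


@dataclass(frozen=True)
class NeighborhoodParams:
    """Distance-query parameters for the active-site neighborhood."""

    radius_A: float = 8.0
    anchor_positions: Optional[FrozenSet[int]] = None  # default: triad
    atom_scope: Literal["all-atom", "side-chain", "c-alpha"] = "all-atom"

    def __post_init__(self) -> None:
        if self.radius_A <= 0:
            raise ValueError("radius_A must be positive")


def _one_letter(resname: str) -> str:
    info = gemmi.find_tabulated_residue(resname)
    if info is not None and info.is_amino_acid():
        code = info.one_letter_code.upper()
        return code if code.isalpha() and code != " " else "X"
    return "X"


def _is_amino_acid(resname: str) -> bool:
    info = gemmi.find_tabulated_residue(resname)
    return info is not None and info.is_amino_acid()


def read_structure(path: str | Path) -> StructureModel:
    """Read a PDB or mmCIF file into a :class:`StructureModel`.

    Only the first model is used; alternate locations are reduced to a
    single conformer; waters and non-peptide heteroatoms are excluded.
    Non-standard amino acids map to ``X``.
    """
    path = Path(path)
    try:
        st = gemmi.read_structure(str(path))
    except Exception as exc:
        raise ValueError(f"cannot read structure {path}: {exc}") from exc
    st.remove_alternative_conformations()
    st.remove_hydrogens()
    st.remove_waters()
    if len(st) == 0:
        raise ValueError(f"structure {path} contains no models")
    model = st[0]
    chains: List[ChainModel] = []
    for chain in model:
        residues: List[ResidueAtoms] = []
        for res in chain:
            if not _is_amino_acid(res.name):
                continue
            atom_names = tuple(a.name for a in res)
            coords = np.array([[a.pos.x, a.pos.y, a.pos.z] for a in res], dtype=float)
            if coords.size == 0 or not np.isfinite(coords).all():
                raise ValueError(
                    f"residue {res.name} {res.seqid.num} in chain {chain.name}: "
                    "missing or non-finite coordinates"
                )
            residues.append(
                ResidueAtoms(
                    name=res.name,
                    seqid=res.seqid.num,
                    one_letter=_one_letter(res.name),
                    atom_names=atom_names,
                    coords=coords,
                )
            )
        if residues:
            chains.append(ChainModel(id=chain.name, residues=tuple(residues)))
    if not chains:
        raise ValueError(f"structure {path} contains no protein chains")
    return StructureModel(chains=tuple(chains))


@dataclass(frozen=True)
class ChainReferenceMap:
    """Correspondence between one structure chain and reference numbering."""

    chain_id: str
    residue_map: ResidueMap              # reference position -> chain residue letter
    ref_to_residue: Dict[int, int]       # reference position -> chain residue index


def chain_to_reference(
    chain: ChainModel,
    annotation: ReferenceAnnotation,
    params: ScoringParams = ScoringParams(),
    min_identity_pct: float = 20.0,
) -> ChainReferenceMap:
    """Map a chain's residues onto reference numbering by global alignment.

    Raises if the mapping alignment's identity is below ``min_identity_pct``
    (likely the wrong chain).  Identity here is measured over aligned pairs
    so that a short subunit chain mapping perfectly onto a segment of the
    precursor reference is not rejected for its terminal gaps.
    """
    if not chain.residues:
        raise ValueError(f"chain {chain.id!r} has no residues")
    query = SequenceRecord(id=f"chain_{chain.id}", residues=chain.sequence)
    aln = align_global(annotation.reference, query, params, denominator="aligned")
    if aln.identity_pct < min_identity_pct:
        raise ValueError(
            f"chain {chain.id!r} aligns at {aln.identity_pct:.1f}% identity "
            f"(< {min_identity_pct}%): not a match to the reference"
        )
    mapped: List[str] = []
    ref_to_residue: Dict[int, int] = {}
    ref_pos, q_idx = 0, 0
    for a, b in zip(aln.ref_row, aln.query_row):
        if a != GAP:
            ref_pos += 1
            mapped.append(b)
            if b != GAP:
                ref_to_residue[ref_pos] = q_idx
        if b != GAP:
            q_idx += 1
    return ChainReferenceMap(
        chain_id=chain.id,
        residue_map=ResidueMap(mapped="".join(mapped)),
        ref_to_residue=ref_to_residue,
    )


def _min_dist(a: np.ndarray, b: np.ndarray) -> float:
    d = a[:, None, :] - b[None, :, :]
    return float(np.sqrt((d * d).sum(axis=2)).min())


def neighborhood(
    structure: StructureModel,
    annotation: ReferenceAnnotation,
    params: NeighborhoodParams = NeighborhoodParams(),
    scoring: ScoringParams = ScoringParams(),
) -> List[int]:
    """Reference positions of residues near the anchor residues.

    A residue is in the neighborhood when any of its in-scope atoms lies
    within ``radius_A`` of any in-scope atom of any anchor residue, across
    all chains.  Anchors themselves are always included.  Output is
    deduplicated and ascending.
    """
    positions, _ = neighborhood_with_distances(structure, annotation, params, scoring)
    return positions


def neighborhood_with_distances(
    structure: StructureModel,
    annotation: ReferenceAnnotation,
    params: NeighborhoodParams = NeighborhoodParams(),
    scoring: ScoringParams = ScoringParams(),
) -> Tuple[List[int], Dict[int, float]]:
    """Like :func:`neighborhood`, also returning per-position minimum distances."""
    anchors = params.anchor_positions
    if anchors is None:
        anchors = frozenset(annotation.triad_positions)
    if not anchors:
        raise ValueError("no anchor positions given and annotation has no triad")

    # Map each chain; chains that fail the identity floor are skipped.
    chain_maps: List[Tuple[ChainModel, ChainReferenceMap]] = []
    for chain in sorted(structure.chains, key=lambda c: c.id):
        try:
            chain_maps.append((chain, chain_to_reference(chain, annotation, scoring)))
        except ValueError:
            continue
    if not chain_maps:
        raise ValueError("no structure chain maps onto the reference")

    anchor_coords: List[np.ndarray] = []
    resolved_anchors: set[int] = set()
    for chain, cmap in chain_maps:
        for pos in anchors:
            idx = cmap.ref_to_residue.get(pos)
            if idx is not None:
                coords = chain.residues[idx].scoped_coords(params.atom_scope)
                if coords.size:
                    anchor_coords.append(coords)
                    resolved_anchors.add(pos)
    if not anchor_coords:
        raise ValueError(
            f"no anchor position of {sorted(anchors)} resolvable in the structure"
        )
    anchor_xyz = np.vstack(anchor_coords)

    min_dist: Dict[int, float] = {}
    for chain, cmap in chain_maps:
        for pos, idx in cmap.ref_to_residue.items():
            coords = chain.residues[idx].scoped_coords(params.atom_scope)
            if not coords.size:
                continue
            d = _min_dist(coords, anchor_xyz)
            if pos not in min_dist or d < min_dist[pos]:
                min_dist[pos] = d
    hits = {p for p, d in min_dist.items() if d <= params.radius_A}
    hits |= resolved_anchors
    positions = sorted(hits)
    return positions, {p: min_dist.get(p, 0.0) for p in positions}
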