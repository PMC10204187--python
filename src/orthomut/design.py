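"""Substitution-candidate ranking and ortholog selection for modeling.

Candidates at the focal site are the non-reference residues classified as
evolutionarily favored, ranked by raw observed frequency (the residues most
often found in nature), with log-odds and alphabetical order as tie-breaks.

Ortholog selection for structural modeling applies two criteria: (i) a
distinct combination of residues ("signature") at the designated
binding-site positions, and (ii) overall sequence identity to the reference
inside a window (default 25-65%, bounds inclusive).  Within each target
focal residue the selection is a deterministic greedy sweep in descending
identity (ties by id), skipping duplicated signatures.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Mapping, Optional, Sequence, Tuple

from .align import GAP, PairwiseAlignment, ResidueMap
from .profile import ConservationProfile, ReferenceAnnotation, SitePreference

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SubstitutionCandidate:
    """A ranked (position, ref->alt) mutagenesis proposal."""

    position: int
    ref_residue: str
    alt_residue: str
    frequency: float
    log_odds: float
    rank: int

    def __post_init__(self) -> None:
        if self.alt_residue == self.ref_residue:
            raise ValueError("candidate must differ from the reference residue")

    @property
    def label(self) -> str:
        """Mutation label, e.g. ``M200W``."""
        return f"{self.ref_residue}{self.position}{self.alt_residue}"


@dataclass(frozen=True)
class SelectionCriteria:
    """Identity window and signature criteria for modeling selection."""

    identity_min_pct: float = 25.0
    identity_max_pct: float = 65.0
    orthologs_per_residue: int = 5
    target_residues: Tuple[str, ...] = ()
    binding_site_positions: Tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if not 0 <= self.identity_min_pct < self.identity_max_pct <= 100:
            raise ValueError("identity window must satisfy 0 <= min < max <= 100")
        if self.orthologs_per_residue < 1:
            raise ValueError("orthologs_per_residue must be >= 1")


@dataclass(frozen=True)
class OrthologSignature:
    """An ortholog's residues at the binding-site positions, plus identity."""

    ortholog_id: str
    focal_residue: str
    signature: Tuple[str, ...]
    identity_pct: float
    species: Optional[str] = None


@dataclass
class ModelingSelection:
    """Chosen orthologs per target focal residue, with criteria echo."""

    chosen: Dict[str, List[OrthologSignature]]
    criteria: SelectionCriteria
    warnings: List[str] = field(default_factory=list)


def candidate_substitutions(
    profile: ConservationProfile,
    preference: SitePreference,
    annotation: ReferenceAnnotation,
    k: int = 5,
) -> List[SubstitutionCandidate]:
    """The top-``k`` favored non-reference residues at the focal site.

    Sorted by observed frequency descending; ties by log-odds descending,
    then alphabetically.  Returns fewer than ``k`` (with a logged warning)
    when fewer favored non-reference residues exist.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    position = preference.position
    ref_residue = profile.ref_sequence[position - 1]
    pool = [
        (aa, profile.frequency(position, aa), preference.log_odds[aa])
        for aa in sorted(preference.favored)
        if aa != ref_residue
    ]
    pool.sort(key=lambda t: (-t[1], -t[2], t[0]))
    if len(pool) < k:
        logger.warning(
            "only %d favored non-reference residues at position %d (requested %d)",
            len(pool), position, k,
        )
    return [
        SubstitutionCandidate(
            position=position,
            ref_residue=ref_residue,
            alt_residue=aa,
            frequency=freq,
            log_odds=lo,
            rank=i + 1,
        )
        for i, (aa, freq, lo) in enumerate(pool[:k])
    ]


def compute_signatures(
    maps: Mapping[str, ResidueMap],
    alignments: Mapping[str, PairwiseAlignment],
    criteria: SelectionCriteria,
    annotation: ReferenceAnnotation,
    species: Optional[Mapping[str, Optional[str]]] = None,
) -> List[OrthologSignature]:
    """Binding-site signatures and focal residues for every ortholog.

    ``maps`` and ``alignments`` are keyed by ortholog id; the signature is
    the ordered tuple of residues (or gap markers) the ortholog places at
    ``criteria.binding_site_positions``.
    """
    positions = criteria.binding_site_positions or annotation.binding_site_positions
    if not positions:
        raise ValueError("binding_site_positions must be set to compute signatures")
    if annotation.focal_position is None:
        raise ValueError("annotation must define a focal position")
    out: List[OrthologSignature] = []
    for oid, rmap in maps.items():
        out.append(
            OrthologSignature(
                ortholog_id=oid,
                focal_residue=rmap.residue_at(annotation.focal_position),
                signature=tuple(rmap.residue_at(p) for p in positions),
                identity_pct=alignments[oid].identity_pct,
                species=(species or {}).get(oid),
            )
        )
    return out


def select_orthologs(
    signatures: Sequence[OrthologSignature],
    criteria: SelectionCriteria,
) -> ModelingSelection:
    """Greedy per-residue selection under the identity window and
    signature-distinctness criteria.

    For each target residue: keep orthologs carrying that focal residue with
    identity inside the (inclusive) window, sweep in descending identity
    (ties by lexicographic id), skip duplicated signatures, and stop at
    ``orthologs_per_residue``.  Shortfalls become warnings, never errors.
    """
    if not signatures:
        raise ValueError("signatures must be non-empty")
    targets = criteria.target_residues or tuple(
        sorted({s.focal_residue for s in signatures if s.focal_residue != GAP})
    )
    chosen: Dict[str, List[OrthologSignature]] = {}
    warnings: List[str] = []
    for target in targets:
        pool = [
            s
            for s in signatures
            if s.focal_residue == target
            and criteria.identity_min_pct <= s.identity_pct <= criteria.identity_max_pct
        ]
        pool.sort(key=lambda s: (-s.identity_pct, s.ortholog_id))
        picked: List[OrthologSignature] = []
        seen: set[Tuple[str, ...]] = set()
        for s in pool:
            if s.signature in seen:
                continue
            picked.append(s)
            seen.add(s.signature)
            if len(picked) == criteria.orthologs_per_residue:
                break
        if len(picked) < criteria.orthologs_per_residue:
            warnings.append(
                f"target residue {target}: only {len(picked)} of "
                f"{criteria.orthologs_per_residue} orthologs selected"
            )
        chosen[target] = picked
    return ModelingSelection(chosen=chosen, criteria=criteria, warnings=warnings)


def selection_rows(selection: ModelingSelection) -> List[dict]:
    """Flat rows (target residue, ortholog, identity, signature) for TSV/JSON."""
    rows = []
    for target, picks in selection.chosen.items():
        for s in picks:
            rows.append(
                {
                    "target_residue": target,
                    "ortholog_id": s.ortholog_id,
                    "species": s.species or "",
                    "identity_pct": round(s.identity_pct, 2),
                    "signature": "".join(s.signature),
                }
            )
    return rows
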