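"""Reference-anchored conservation profile (PSSM) and site classification.

The profile tallies, for every reference position, which residue each
ortholog places there (via its :class:`~orthomut.align.ResidueMap`).  Per-site
frequencies are computed over covered orthologs only — gaps are excluded from
the denominator and reported separately, so alignment-length artifacts do not
depress residue frequencies.  ``X`` residues count toward coverage but are
excluded from the 20-residue count table.

A residue is *favored* at a site when its (pseudocount-smoothed) observed
frequency exceeds its expected frequency and its raw count meets a support
threshold; *avoided* when the smoothed frequency falls below expectation.
The expected frequency is, by default, the pooled background frequency of
the residue across all aligned non-gap cells of the ortholog set; a uniform
1/20 background is available as an alternative.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, FrozenSet, Iterable, Literal, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .align import GAP, ResidueMap
from .io import AMINO_ACIDS, SequenceRecord

_AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
_N_AA = len(AMINO_ACIDS)
MAX_ENTROPY_BITS = math.log2(_N_AA)


@dataclass(frozen=True)
class ReferenceAnnotation:
    """Reference sequence plus named functional positions.

    ``triad_positions`` are the catalytic anchor residues (for EcAIII the
    threonine triad 179/197/230); ``focal_position`` is the mutagenesis
    target site (EcAIII Met200); ``binding_site_positions`` is the ordered
    list of substrate-binding-site positions used for ortholog signatures.
    """

    reference: SequenceRecord
    triad_positions: FrozenSet[int] = frozenset()
    focal_position: Optional[int] = None
    named_positions: Dict[str, int] = field(default_factory=dict)
    binding_site_positions: Tuple[int, ...] = ()

    def __post_init__(self) -> None:
        length = len(self.reference)
        every = set(self.triad_positions) | set(self.named_positions.values())
        every |= set(self.binding_site_positions)
        if self.focal_position is not None:
            every.add(self.focal_position)
        bad = [p for p in every if not 1 <= p <= length]
        if bad:
            raise ValueError(
                f"annotated positions {sorted(bad)} outside 1..{length}"
            )


@dataclass
class ConservationProfile:
    """Per-reference-position residue counts/frequencies (the PSSM).

    ``counts`` is a (L, 20) array in alphabetical residue order
    (ACDEFGHIKLMNPQRSTVWY); ``frequencies`` are normalized over the
    standard-residue counts of each covered position.
    """

    ref_sequence: str
    counts: np.ndarray            # (L, 20) float
    gap_counts: np.ndarray        # (L,) int
    x_counts: np.ndarray          # (L,) int
    n_orthologs: int
    background: np.ndarray        # (20,) float, sums to 1
    pseudocount: float
    frequencies: np.ndarray       # (L, 20) float

    @property
    def length(self) -> int:
        return len(self.ref_sequence)

    @property
    def coverage(self) -> np.ndarray:
        """Orthologs contributing a residue (incl. X) at each position."""
        return np.rint(self.counts.sum(axis=1) + self.x_counts).astype(int)

    def _check_position(self, position: int) -> int:
        if not 1 <= position <= self.length:
            raise IndexError(f"reference position {position} out of 1..{self.length}")
        return position - 1

    def _check_covered(self, position: int) -> int:
        i = self._check_position(position)
        if self.coverage[i] == 0:
            raise ValueError(f"reference position {position} has zero coverage")
        return i

    def frequency(self, position: int, residue: str) -> float:
        return float(self.frequencies[self._check_position(position), _AA_INDEX[residue]])

    def modal_residue(self, position: int) -> str:
        i = self._check_covered(position)
        return AMINO_ACIDS[int(np.argmax(self.frequencies[i]))]

    def modal_frequency(self, position: int) -> float:
        i = self._check_covered(position)
        return float(self.frequencies[i].max())

    @property
    def modal_frequencies(self) -> np.ndarray:
        return self.frequencies.max(axis=1)

    def to_frame(self) -> pd.DataFrame:
        """Profile as a table: position, reference residue, coverage, 20 frequencies."""
        df = pd.DataFrame(self.frequencies, columns=list(AMINO_ACIDS))
        df.insert(0, "coverage", self.coverage)
        df.insert(0, "ref_residue", list(self.ref_sequence))
        df.insert(0, "position", np.arange(1, self.length + 1))
        return df


@dataclass(frozen=True)
class SitePreference:
    """Favored/avoided residue classification at one site."""

    position: int
    favored: FrozenSet[str]
    avoided: FrozenSet[str]
    log_odds: Dict[str, float]

    def __post_init__(self) -> None:
        if self.favored & self.avoided:
            raise ValueError("a residue cannot be both favored and avoided")


def build_profile(
    annotation: ReferenceAnnotation,
    maps: Sequence[ResidueMap],
    pseudocount: float = 1.0,
) -> ConservationProfile:
    """Tally residue maps into a reference-anchored conservation profile.

    Every map must cover all reference positions (one entry per position).
    The background is the pooled residue frequency over all non-gap, non-X
    cells of all maps.  The pseudocount is stored for downstream smoothing
    of log-odds; raw frequencies are reported unsmoothed.
    """
    if not maps:
        raise ValueError("at least one residue map is required")
    if pseudocount < 0:
        raise ValueError("pseudocount must be non-negative")
    length = len(annotation.reference)
    for m in maps:
        if len(m) != length:
            raise ValueError(
                f"residue map length {len(m)} != reference length {length}"
            )
    # Encode maps as a (n, L) byte matrix and count via bincount per column.
    mat = np.frombuffer(
        "".join(m.mapped for m in maps).encode("ascii"), dtype=np.uint8
    ).reshape(len(maps), length)
    lut = np.full(256, -1, dtype=np.int64)
    for aa, i in _AA_INDEX.items():
        lut[ord(aa)] = i
    lut[ord("X")] = _N_AA          # X bucket
    lut[ord(GAP)] = _N_AA + 1      # gap bucket
    codes = lut[mat]
    if (codes < 0).any():
        raise ValueError("residue map contains characters outside the alphabet")
    counts_all = np.zeros((length, _N_AA + 2), dtype=np.int64)
    for j in range(length):
        counts_all[j] = np.bincount(codes[:, j], minlength=_N_AA + 2)
    counts = counts_all[:, :_N_AA].astype(float)
    x_counts = counts_all[:, _N_AA]
    gap_counts = counts_all[:, _N_AA + 1]

    pooled = counts.sum(axis=0)
    total = pooled.sum()
    background = pooled / total if total > 0 else np.full(_N_AA, 1.0 / _N_AA)

    row_sums = counts.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        frequencies = np.where(
            row_sums[:, None] > 0, counts / np.maximum(row_sums, 1)[:, None], 0.0
        )
    return ConservationProfile(
        ref_sequence=annotation.reference.residues,
        counts=counts,
        gap_counts=gap_counts,
        x_counts=x_counts,
        n_orthologs=len(maps),
        background=background,
        pseudocount=float(pseudocount),
        frequencies=frequencies,
    )


def classify_preferences(
    profile: ConservationProfile,
    position: int,
    min_count: int = 5,
    background: Literal["pooled", "uniform"] = "pooled",
) -> SitePreference:
    """Classify residues at a site as favored or avoided vs. expectation.

    Favored: smoothed observed frequency above background and raw count of
    at least ``min_count``.  Avoided: smoothed frequency below a positive
    background.  Log-odds (base 2) of the smoothed frequency over background
    are reported for all 20 residues; a zero background with a non-zero
    observation yields ``+inf``.
    """
    i = profile._check_covered(position)
    bg = (
        profile.background
        if background == "pooled"
        else np.full(_N_AA, 1.0 / _N_AA)
    )
    counts = profile.counts[i]
    denom = counts.sum() + _N_AA * profile.pseudocount
    smoothed = (counts + profile.pseudocount) / denom if denom > 0 else counts

    favored, avoided = set(), set()
    log_odds: Dict[str, float] = {}
    for k, aa in enumerate(AMINO_ACIDS):
        if bg[k] > 0:
            log_odds[aa] = math.log2(smoothed[k] / bg[k]) if smoothed[k] > 0 else -math.inf
        else:
            log_odds[aa] = math.inf if smoothed[k] > 0 else 0.0
        if smoothed[k] > bg[k] and counts[k] >= min_count:
            favored.add(aa)
        elif smoothed[k] < bg[k] and bg[k] > 0:
            avoided.add(aa)
    return SitePreference(
        position=position,
        favored=frozenset(favored),
        avoided=frozenset(avoided),
        log_odds=log_odds,
    )


def conserved_sites(
    profile: ConservationProfile,
    min_modal_freq: float = 0.9,
    min_coverage_frac: float = 0.5,
) -> list[int]:
    """Positions whose modal residue frequency and coverage meet thresholds."""
    if not 0 <= min_modal_freq <= 1 or not 0 <= min_coverage_frac <= 1:
        raise ValueError("thresholds must lie in [0, 1]")
    modal = profile.modal_frequencies
    covered = profile.coverage >= min_coverage_frac * profile.n_orthologs
    hit = (modal >= min_modal_freq) & covered & (profile.coverage > 0)
    return [int(i + 1) for i in np.nonzero(hit)[0]]


def site_entropy(profile: ConservationProfile, position: int) -> float:
    """Shannon entropy (bits) of the 20-residue frequency vector at a site."""
    i = profile._check_covered(position)
    f = profile.frequencies[i]
    nz = f[f > 0]
    return float(-(nz * np.log2(nz)).sum()) if nz.size else 0.0


def most_variable_site(profile: ConservationProfile, positions: Iterable[int]) -> int:
    """The position of maximal entropy in a set; ties go to the lowest position."""
    positions = sorted(set(positions))
    if not positions:
        raise ValueError("positions set must be non-empty")
    best_pos, best_h = None, -1.0
    for p in positions:
        h = site_entropy(profile, p)
        if h > best_h:
            best_pos, best_h = p, h
    return int(best_pos)


# ---------------------------------------------------------------------------
# Profile table I/O

_TABLE_FLOAT_FMT = "%.6f"


def write_profile_table(profile: ConservationProfile, path: str | Path) -> None:
    """Write the profile as a TSV: position, ref residue, coverage, 20 frequencies."""
    df = profile.to_frame()
    df.to_csv(path, sep="\t", index=False, float_format=_TABLE_FLOAT_FMT)


def read_profile_table(path: str | Path) -> ConservationProfile:
    """Read a profile TSV written by :func:`write_profile_table`.

    Also ingests externally produced tables of the same shape whose residue
    columns are counts or otherwise row-normalizable numbers; rows are
    normalized to frequencies when they do not already sum to 1.
    """
    try:
        df = pd.read_csv(path, sep="\t")
    except Exception as exc:
        raise ValueError(f"cannot parse profile table {path}: {exc}") from exc
    required = ["position", "ref_residue", "coverage"] + list(AMINO_ACIDS)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"profile table {path}: missing columns {missing}")
    aa_cols = list(AMINO_ACIDS)
    for col in ["position", "coverage"] + aa_cols:
        bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
        if bad.any() or df[col].isna().any():
            row = int(np.argmax((bad | df[col].isna()).to_numpy())) + 2
            raise ValueError(
                f"profile table {path}: non-numeric cell at row {row}, column {col!r}"
            )
    values = df[aa_cols].to_numpy(dtype=float)
    if (values < 0).any():
        raise ValueError(f"profile table {path}: negative residue values")
    row_sums = values.sum(axis=1)
    freqs = values.copy()
    off = np.abs(row_sums - 1.0) > 1e-3
    norm_rows = off & (row_sums > 0)
    freqs[norm_rows] = values[norm_rows] / row_sums[norm_rows, None]
    coverage = df["coverage"].to_numpy(dtype=float)
    counts = freqs * coverage[:, None]
    ref_seq = "".join(df["ref_residue"].astype(str))
    return ConservationProfile(
        ref_sequence=ref_seq,
        counts=counts,
        gap_counts=np.zeros(len(df), dtype=int),
        x_counts=np.zeros(len(df), dtype=int),
        n_orthologs=int(coverage.max()) if len(coverage) else 0,
        background=(
            counts.sum(axis=0) / counts.sum() if counts.sum() > 0
            else np.full(_N_AA, 1.0 / _N_AA)
        ),
        pseudocount=1.0,
        frequencies=freqs,
    )


def preference_report(preferences: Iterable[SitePreference]) -> list[dict]:
    """JSON-ready site-preference report (position, favored, avoided, log-odds)."""
    return [
        {
            "position": p.position,
            "favored": sorted(p.favored),
            "avoided": sorted(p.avoided),
            "log_odds": {k: (v if math.isfinite(v) else str(v)) for k, v in p.log_odds.items()},
        }
        for p in preferences
    ]
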