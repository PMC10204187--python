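"""End-to-end pipeline: align -> profile -> neighborhood -> candidates -> selection.

The pipeline is configured from a YAML file (or a :class:`PipelineConfig`
built in code), writes diffable TSV/JSON reports into an output directory,
and records a manifest with the fully resolved configuration, package
version, input digests, and a content digest for every output file.  Reports
carry no timestamps, so two runs with identical config and inputs are
byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import pandas as pd
import yaml

from .align import ResidueMap, ScoringParams, align_global, map_to_reference
from .design import (
    SelectionCriteria,
    candidate_substitutions,
    compute_signatures,
    select_orthologs,
    selection_rows,
)
from .io import read_fasta
from .profile import (
    ReferenceAnnotation,
    build_profile,
    classify_preferences,
    conserved_sites,
    most_variable_site,
    preference_report,
    site_entropy,
    write_profile_table,
)
from .structure import NeighborhoodParams, neighborhood_with_distances, read_structure

logger = logging.getLogger(__name__)


def _package_version() -> str:
    from importlib.metadata import version

    try:
        return version("orthomut")
    except Exception:  # pragma: no cover - not installed
        return "unknown"


@dataclass
class ProfileOptions:
    pseudocount: float = 1.0
    min_modal_freq: float = 0.9
    min_coverage_frac: float = 0.5
    min_count: int = 5
    n_candidates: int = 5


@dataclass
class PipelineConfig:
    """Paths, parameters, and thresholds for one pipeline run."""

    reference_fasta: str
    ortholog_fasta: str
    output_dir: str
    structure_file: Optional[str] = None
    triad_positions: Tuple[int, ...] = ()
    focal_position: Optional[int] = None
    binding_site_positions: Tuple[int, ...] = ()
    scoring: ScoringParams = field(default_factory=ScoringParams)
    profile_options: ProfileOptions = field(default_factory=ProfileOptions)
    neighborhood_params: NeighborhoodParams = field(default_factory=NeighborhoodParams)
    selection: SelectionCriteria = field(default_factory=SelectionCriteria)
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        kwargs = dict(raw)
        if "scoring" in kwargs:
            kwargs["scoring"] = ScoringParams(**kwargs["scoring"])
        if "profile_options" in kwargs:
            kwargs["profile_options"] = ProfileOptions(**kwargs["profile_options"])
        if "neighborhood_params" in kwargs:
            np_raw = dict(kwargs["neighborhood_params"])
            if np_raw.get("anchor_positions") is not None:
                np_raw["anchor_positions"] = frozenset(np_raw["anchor_positions"])
            kwargs["neighborhood_params"] = NeighborhoodParams(**np_raw)
        if "selection" in kwargs:
            sel = dict(kwargs["selection"])
            if "target_residues" in sel:
                sel["target_residues"] = tuple(sel["target_residues"])
            if "binding_site_positions" in sel:
                sel["binding_site_positions"] = tuple(sel["binding_site_positions"])
            kwargs["selection"] = SelectionCriteria(**sel)
        for key in ("triad_positions", "binding_site_positions"):
            if key in kwargs and kwargs[key] is not None:
                kwargs[key] = tuple(kwargs[key])
        return cls(**kwargs)

    def resolved(self) -> dict:
        """JSON-serializable fully resolved configuration."""
        d = asdict(self)
        np_ = d["neighborhood_params"]
        if np_.get("anchor_positions") is not None:
            np_["anchor_positions"] = sorted(np_["anchor_positions"])
        return d


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


class PipelineError(RuntimeError):
    """A stage failure, tagged with the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages and write the report bundle; returns the manifest.

    Raises :class:`PipelineError` on a stage failure; outputs produced up to
    that point are retained and the manifest is written with a FAILED marker.
    """
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package": "orthomut",
        "version": _package_version(),
        "config": config.resolved(),
        "inputs": {},
        "outputs": {},
        "status": "RUNNING",
    }
    manifest_path = out_dir / "manifest.json"

    def fail(stage: str, message: str) -> PipelineError:
        manifest["status"] = f"FAILED at {stage}"
        manifest["error"] = message
        _write_json(manifest, manifest_path)
        return PipelineError(stage, message)

    def record_output(name: str, path: Path) -> None:
        manifest["outputs"][name] = {"path": path.name, "sha256": _sha256(path)}

    # -- inputs -------------------------------------------------------------
    stage = "read-inputs"
    try:
        for label, p in [("reference_fasta", config.reference_fasta),
                         ("ortholog_fasta", config.ortholog_fasta),
                         ("structure_file", config.structure_file)]:
            if p is None:
                continue
            path = Path(p)
            if not path.exists():
                raise FileNotFoundError(f"input file not found: {path}")
            manifest["inputs"][label] = {"path": str(path), "sha256": _sha256(path)}
        reference = read_fasta(config.reference_fasta)[0]
        orthologs = read_fasta(config.ortholog_fasta)
    except Exception as exc:
        raise fail(stage, str(exc)) from exc
    logger.info("[%s] reference %s (%d aa), %d orthologs",
                stage, reference.id, len(reference), len(orthologs))

    annotation = ReferenceAnnotation(
        reference=reference,
        triad_positions=frozenset(config.triad_positions),
        focal_position=config.focal_position,
        binding_site_positions=tuple(config.binding_site_positions),
    )

    # -- align --------------------------------------------------------------
    stage = "align"
    try:
        alignments = {o.id: align_global(reference, o, config.scoring)
                      for o in orthologs}
        maps: Dict[str, ResidueMap] = {
            oid: map_to_reference(aln) for oid, aln in alignments.items()
        }
    except Exception as exc:
        raise fail(stage, str(exc)) from exc
    logger.info("[%s] %d pairwise global alignments", stage, len(alignments))

    # -- profile ------------------------------------------------------------
    stage = "profile"
    try:
        opts = config.profile_options
        profile = build_profile(annotation, list(maps.values()), opts.pseudocount)
        profile_path = out_dir / "profile.tsv"
        write_profile_table(profile, profile_path)
        record_output("profile_tsv", profile_path)
        conserved = conserved_sites(profile, opts.min_modal_freq, opts.min_coverage_frac)
    except Exception as exc:
        raise fail(stage, str(exc)) from exc
    logger.info("[%s] %d positions, %d conserved sites", stage,
                profile.length, len(conserved))

    # -- neighborhood (optional) --------------------------------------------
    stage = "neighborhood"
    binding_positions = tuple(config.binding_site_positions)
    if config.structure_file:
        try:
            structure = read_structure(config.structure_file)
            positions, dists = neighborhood_with_distances(
                structure, annotation, config.neighborhood_params, config.scoring
            )
            nbr_path = out_dir / "neighborhood.json"
            _write_json(
                {
                    "anchors": sorted(
                        config.neighborhood_params.anchor_positions
                        or annotation.triad_positions
                    ),
                    "radius_A": config.neighborhood_params.radius_A,
                    "atom_scope": config.neighborhood_params.atom_scope,
                    "positions": positions,
                    "min_distance_A": {str(p): round(d, 3) for p, d in dists.items()},
                },
                nbr_path,
            )
            record_output("neighborhood_json", nbr_path)
            if not binding_positions:
                binding_positions = tuple(positions)
            logger.info("[%s] %d positions within %.1f A", stage,
                        len(positions), config.neighborhood_params.radius_A)
        except Exception as exc:
            raise fail(stage, str(exc)) from exc

    # -- preferences & candidates -------------------------------------------
    stage = "candidates"
    try:
        if annotation.focal_position is None:
            raise ValueError("focal_position must be set for candidate ranking")
        focal = annotation.focal_position
        preference = classify_preferences(
            profile, focal, min_count=config.profile_options.min_count
        )
        pref_path = out_dir / "preferences.json"
        _write_json(preference_report([preference]), pref_path)
        record_output("preferences_json", pref_path)
        candidates = candidate_substitutions(
            profile, preference, annotation, k=config.profile_options.n_candidates
        )
        cand_path = out_dir / "candidates.tsv"
        pd.DataFrame(
            [
                {
                    "rank": c.rank,
                    "mutation": c.label,
                    "alt_residue": c.alt_residue,
                    "frequency": round(c.frequency, 6),
                    "log_odds": round(c.log_odds, 4),
                }
                for c in candidates
            ]
        ).to_csv(cand_path, sep="\t", index=False)
        record_output("candidates_tsv", cand_path)
    except Exception as exc:
        raise fail(stage, str(exc)) from exc
    logger.info("[%s] %d substitution candidates at position %d", stage,
                len(candidates), focal)

    # -- ortholog selection --------------------------------------------------
    stage = "select"
    try:
        criteria = config.selection
        if not criteria.binding_site_positions and binding_positions:
            criteria = SelectionCriteria(
                identity_min_pct=criteria.identity_min_pct,
                identity_max_pct=criteria.identity_max_pct,
                orthologs_per_residue=criteria.orthologs_per_residue,
                target_residues=criteria.target_residues
                or tuple(c.alt_residue for c in candidates),
                binding_site_positions=binding_positions,
            )
        species = {o.id: o.species for o in orthologs}
        signatures = compute_signatures(maps, alignments, criteria, annotation, species)
        selection = select_orthologs(signatures, criteria)
        rows = selection_rows(selection)
        sel_tsv = out_dir / "selection.tsv"
        pd.DataFrame(
            rows, columns=["target_residue", "ortholog_id", "species",
                           "identity_pct", "signature"]
        ).to_csv(sel_tsv, sep="\t", index=False)
        record_output("selection_tsv", sel_tsv)
        sel_json = out_dir / "selection.json"
        _write_json(
            {
                "criteria": {
                    "identity_min_pct": criteria.identity_min_pct,
                    "identity_max_pct": criteria.identity_max_pct,
                    "orthologs_per_residue": criteria.orthologs_per_residue,
                    "target_residues": list(criteria.target_residues),
                    "binding_site_positions": list(criteria.binding_site_positions),
                },
                "chosen": rows,
                "warnings": selection.warnings,
            },
            sel_json,
        )
        record_output("selection_json", sel_json)
    except Exception as exc:
        raise fail(stage, str(exc)) from exc
    logger.info("[%s] %d orthologs selected (%d warnings)", stage,
                len(rows), len(selection.warnings))

    # -- summary & manifest ---------------------------------------------------
    summary = {
        "n_orthologs": len(orthologs),
        "reference_length": profile.length,
        "n_conserved_sites": len(conserved),
        "focal_position": focal,
        "focal_entropy_bits": round(site_entropy(profile, focal), 4),
        "candidates": [c.label for c in candidates],
        "n_selected": len(rows),
    }
    summary_path = out_dir / "summary.json"
    _write_json(summary, summary_path)
    record_output("summary_json", summary_path)

    manifest["status"] = "OK"
    _write_json(manifest, manifest_path)
    return manifest
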