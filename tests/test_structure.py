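"""Structure parsing, chain-to-reference mapping, and neighborhood queries."""

import numpy as np
import pytest

from helpers import build_structure, ca_chain, write_structure
from orthomut.io import SequenceRecord
from orthomut.profile import ReferenceAnnotation
from orthomut.structure import (
    NeighborhoodParams,
    StructureModel,
    chain_to_reference,
    neighborhood,
    read_structure,
)


def ann_for(seq, triad=(), focal=None):
    return ReferenceAnnotation(
        reference=SequenceRecord(id="ref", residues=seq),
        triad_positions=frozenset(triad),
        focal_position=focal,
    )


class TestReadStructure:
    def test_minimal_two_residue_pdb(self, tmp_path):
        st = build_structure({"A": ca_chain("MK")})
        path = write_structure(st, tmp_path / "toy.pdb")
        model = read_structure(path)
        assert len(model.chains) == 1
        assert model.chains[0].sequence == "MK"
        assert len(model.chains[0].residues) == 2

    def test_mmcif_equivalent_to_pdb(self, tmp_path):
        st = build_structure({"A": ca_chain("MKW")})
        pdb = read_structure(write_structure(st, tmp_path / "toy.pdb"))
        cif = read_structure(write_structure(st, tmp_path / "toy.cif"))
        assert pdb.chains[0].sequence == cif.chains[0].sequence
        np.testing.assert_allclose(
            pdb.chains[0].residues[0].coords, cif.chains[0].residues[0].coords
        )

    def test_altloc_reduced_to_single_conformer(self, tmp_path):
        # hand-written PDB with A/B altlocs for one atom
        text = (
            "ATOM      1  CA AMET A   1       0.000   0.000   0.000  0.60 20.00           C\n"
            "ATOM      2  CA BMET A   1       5.000   0.000   0.000  0.40 20.00           C\n"
            "ATOM      3  CA  LYS A   2       3.800   0.000   0.000  1.00 20.00           C\n"
            "END\n"
        )
        path = tmp_path / "altloc.pdb"
        path.write_text(text)
        model = read_structure(path)
        assert len(model.chains[0].residues[0].coords) == 1

    def test_waters_excluded(self, tmp_path):
        text = (
            "ATOM      1  CA  MET A   1       0.000   0.000   0.000  1.00 20.00           C\n"
            "HETATM    2  O   HOH A 101       9.000   9.000   9.000  1.00 20.00           O\n"
            "END\n"
        )
        path = tmp_path / "wat.pdb"
        path.write_text(text)
        model = read_structure(path)
        assert [r.name for r in model.chains[0].residues] == ["MET"]

    def test_unreadable_file_is_error(self, tmp_path):
        path = tmp_path / "empty.pdb"
        path.write_text("")
        with pytest.raises(ValueError):
            read_structure(path)


class TestChainToReference:
    def test_identical_chain_maps_identically(self, tmp_path):
        seq = "MKWACDEFGH"
        st = build_structure({"A": ca_chain(seq)})
        model = read_structure(write_structure(st, tmp_path / "a.pdb"))
        cmap = chain_to_reference(model.chains[0], ann_for(seq))
        assert cmap.ref_to_residue == {i + 1: i for i in range(len(seq))}

    def test_truncated_chain_shifts_correctly(self, tmp_path):
        seq = "MKWACDEFGH"
        st = build_structure({"A": ca_chain(seq[2:])})
        model = read_structure(write_structure(st, tmp_path / "t.pdb"))
        cmap = chain_to_reference(model.chains[0], ann_for(seq))
        assert 1 not in cmap.ref_to_residue and 2 not in cmap.ref_to_residue
        assert cmap.ref_to_residue[3] == 0
        assert cmap.ref_to_residue[10] == 7

    def test_split_chains_cover_reference_segments(self, tmp_path):
        # two chains = alpha/beta subunits of one precursor reference
        seq = "MKWACDEFGHILNPQRSTVY"
        st = build_structure(
            {"A": ca_chain(seq[:10]), "B": ca_chain(seq[10:], origin=(0, 50, 0))}
        )
        model = read_structure(write_structure(st, tmp_path / "ab.pdb"))
        cmap_b = chain_to_reference(model.chains[1], ann_for(seq))
        assert min(cmap_b.ref_to_residue) == 11
        assert max(cmap_b.ref_to_residue) == 20

    def test_unrelated_chain_is_rejected(self, tmp_path):
        st = build_structure({"A": ca_chain("WWWWYYYY")})
        model = read_structure(write_structure(st, tmp_path / "x.pdb"))
        with pytest.raises(ValueError, match="identity"):
            chain_to_reference(model.chains[0], ann_for("AAAAGGGGLLLL"))


def toy_model(coords_seq):
    """StructureModel with one CA residue per (letter, xyz)."""
    st = build_structure(
        {"A": [(aa, i + 1, [("CA", xyz)]) for i, (aa, xyz) in enumerate(coords_seq)]}
    )
    import tempfile, os
    from pathlib import Path

    with tempfile.TemporaryDirectory() as d:
        return read_structure(write_structure(st, Path(d) / "m.pdb"))


class TestNeighborhood:
    def test_pair_within_radius(self):
        model = toy_model([("M", (0, 0, 0)), ("K", (5, 0, 0))])
        ann = ann_for("MK", triad=(1,))
        assert neighborhood(model, ann, NeighborhoodParams(radius_A=8)) == [1, 2]

    def test_small_radius_keeps_anchors_only(self):
        model = toy_model([("M", (0, 0, 0)), ("K", (5, 0, 0))])
        ann = ann_for("MK", triad=(1,))
        assert neighborhood(model, ann, NeighborhoodParams(radius_A=2)) == [1]

    def test_collinear_three_residue_cutoff(self):
        model = toy_model([("M", (0, 0, 0)), ("K", (6, 0, 0)), ("W", (12, 0, 0))])
        ann = ann_for("MKW", triad=(1,))
        assert neighborhood(model, ann, NeighborhoodParams(radius_A=8)) == [1, 2]

    def test_monotone_in_radius(self):
        rng = np.random.default_rng(2)
        seq = "MKWACDEFGH"
        coords = [(aa, tuple(rng.uniform(0, 20, 3))) for aa in seq]
        model = toy_model(coords)
        ann = ann_for(seq, triad=(1,))
        prev = set()
        for radius in (2, 5, 8, 12, 30):
            cur = set(neighborhood(model, ann, NeighborhoodParams(radius_A=radius)))
            assert prev <= cur
            prev = cur

    def test_rigid_motion_invariance(self):
        rng = np.random.default_rng(4)
        seq = "MKWACDEFGH"
        pts = rng.uniform(0, 15, (len(seq), 3))
        # random rotation (QR) + translation
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        moved = pts @ q.T + np.array([100.0, -50.0, 7.0])
        ann = ann_for(seq, triad=(3,))
        params = NeighborhoodParams(radius_A=7)
        a = neighborhood(toy_model(list(zip(seq, map(tuple, pts)))), ann, params)
        b = neighborhood(toy_model(list(zip(seq, map(tuple, moved)))), ann, params)
        assert a == b

    def test_chain_order_invariance(self, tmp_path):
        seq = "MKWACDEFGHILNPQRSTVY"
        half_a, half_b = ca_chain(seq[:10]), ca_chain(seq[10:], origin=(0, 4, 0))
        m1 = read_structure(
            write_structure(build_structure({"A": half_a, "B": half_b}), tmp_path / "1.pdb")
        )
        m2 = read_structure(
            write_structure(build_structure({"B": half_b, "A": half_a}), tmp_path / "2.pdb")
        )
        ann = ann_for(seq, triad=(5,))
        params = NeighborhoodParams(radius_A=6)
        assert neighborhood(m1, ann, params) == neighborhood(m2, ann, params)

    def test_unresolvable_anchor_is_error(self):
        model = toy_model([("M", (0, 0, 0)), ("K", (5, 0, 0))])
        ann = ann_for("MKW", triad=(3,))  # position 3 absent from structure
        with pytest.raises(ValueError, match="anchor"):
            neighborhood(model, ann, NeighborhoodParams(radius_A=8))

    def test_radius_must_be_positive(self):
        with pytest.raises(ValueError):
            NeighborhoodParams(radius_A=0)
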