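"""Conservation profile: counts, frequencies, classification, entropy, tables."""

import math

import numpy as np
import pytest

from orthomut.align import GAP, ResidueMap
from orthomut.io import AMINO_ACIDS, SequenceRecord
from orthomut.profile import (
    ReferenceAnnotation,
    build_profile,
    classify_preferences,
    conserved_sites,
    most_variable_site,
    read_profile_table,
    site_entropy,
    write_profile_table,
)

MK = ReferenceAnnotation(reference=SequenceRecord(id="r", residues="MK"))


def maps_from(rows):
    return [ResidueMap(mapped=row) for row in rows]


@pytest.fixture()
def toy_profile():
    # 4 orthologs over reference "MK": pos1 {M,M,L,L}, pos2 {K,K,K,-}
    return build_profile(MK, maps_from(["MK", "MK", "LK", "L-"]), pseudocount=0.0)


class TestBuildProfile:
    def test_identical_family_is_fully_conserved(self, annotation):
        ref = annotation.reference.residues
        profile = build_profile(annotation, maps_from([ref] * 10), pseudocount=0.0)
        assert (profile.coverage == 10).all()
        for pos in (1, len(ref) // 2, len(ref)):
            assert profile.modal_frequency(pos) == 1.0
            assert profile.modal_residue(pos) == ref[pos - 1]
            assert site_entropy(profile, pos) == 0.0

    def test_hand_enumerated_toy_family(self, toy_profile):
        p = toy_profile
        assert p.frequency(1, "M") == 0.5
        assert p.frequency(1, "L") == 0.5
        assert p.coverage[1] == 3
        assert p.frequency(2, "K") == 1.0
        assert p.gap_counts[1] == 1
        assert p.n_orthologs == 4

    def test_background_is_pooled_over_non_gap_cells(self, toy_profile):
        # cells: M,M,L,L,K,K,K -> M 2/7, L 2/7, K 3/7
        idx = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
        assert toy_profile.background[idx["M"]] == pytest.approx(2 / 7)
        assert toy_profile.background[idx["K"]] == pytest.approx(3 / 7)
        assert toy_profile.background.sum() == pytest.approx(1.0)

    def test_x_counts_toward_coverage_not_frequencies(self):
        p = build_profile(MK, maps_from(["MK", "XK"]), pseudocount=0.0)
        assert p.coverage[0] == 2
        assert p.x_counts[0] == 1
        assert p.frequency(1, "M") == 1.0  # normalized over standard residues

    def test_zero_maps_is_error(self):
        with pytest.raises(ValueError, match="at least one"):
            build_profile(MK, [], 1.0)

    def test_negative_pseudocount_is_error(self):
        with pytest.raises(ValueError, match="pseudocount"):
            build_profile(MK, maps_from(["MK"]), -0.5)

    def test_permutation_invariance(self, annotation):
        rng = np.random.default_rng(3)
        ref = annotation.reference.residues
        rows = []
        for _ in range(30):
            row = list(ref)
            for j in rng.choice(len(ref), size=5, replace=False):
                row[j] = AMINO_ACIDS[rng.integers(20)]
            rows.append("".join(row))
        a = build_profile(annotation, maps_from(rows))
        b = build_profile(annotation, maps_from(rows[::-1]))
        np.testing.assert_array_equal(a.counts, b.counts)
        np.testing.assert_array_equal(a.frequencies, b.frequencies)

    def test_frequency_normalization_invariant(self, benchmark):
        p = benchmark["profile"]
        covered = p.counts.sum(axis=1) > 0
        np.testing.assert_allclose(p.frequencies[covered].sum(axis=1), 1.0, atol=1e-9)
        assert (p.coverage + p.gap_counts == p.n_orthologs).all()

    def test_adding_reference_copy_never_lowers_modal_reference_frequency(self, toy_profile):
        before = build_profile(MK, maps_from(["MK", "MK", "LK", "L-"]))
        after = build_profile(MK, maps_from(["MK", "MK", "LK", "L-", "MK"]))
        for pos in (1, 2):
            if before.modal_residue(pos) == "MK"[pos - 1]:
                assert after.modal_frequency(pos) >= before.modal_frequency(pos)


class TestClassifyPreferences:
    def test_enriched_residues_are_favored(self):
        # pos1 frequencies M=0.5, L=0.5 vs pooled background below 0.5 each
        p = build_profile(MK, maps_from(["MK", "MK", "LK", "LK"]), pseudocount=0.0)
        pref = classify_preferences(p, 1, min_count=1)
        assert {"M", "L"} <= pref.favored

    def test_uniform_site_equal_to_background_is_neither(self):
        # single position, all four residues at 1/4 = background exactly
        ann = ReferenceAnnotation(reference=SequenceRecord(id="r", residues="A"))
        p = build_profile(ann, maps_from(["A", "C", "D", "E"]), pseudocount=0.0)
        pref = classify_preferences(p, 1, min_count=1)
        assert pref.favored == frozenset()
        assert pref.avoided == frozenset()

    def test_min_count_blocks_singletons(self):
        p = build_profile(MK, maps_from(["MK"] * 99 + ["WK"]), pseudocount=0.0)
        pref = classify_preferences(p, 1, min_count=5)
        assert "W" not in pref.favored

    def test_log_odds_reported_for_all_residues(self, toy_profile):
        pref = classify_preferences(toy_profile, 1, min_count=1)
        assert set(pref.log_odds) == set(AMINO_ACIDS)

    def test_uncovered_position_is_error(self):
        p = build_profile(MK, maps_from(["M-", "M-"]))
        with pytest.raises(ValueError, match="zero coverage"):
            classify_preferences(p, 2)


class TestConservedSites:
    def test_identical_family_returns_all_positions(self, annotation):
        ref = annotation.reference.residues
        p = build_profile(annotation, maps_from([ref] * 5))
        assert conserved_sites(p, 1.0, 1.0) == list(range(1, len(ref) + 1))

    def test_variable_site_excluded_at_high_threshold(self, toy_profile):
        sites = conserved_sites(toy_profile, min_modal_freq=0.9, min_coverage_frac=0.5)
        assert 1 not in sites
        assert 2 in sites

    def test_threshold_out_of_range_is_error(self, toy_profile):
        with pytest.raises(ValueError):
            conserved_sites(toy_profile, min_modal_freq=1.5)

    def test_antitone_in_modal_threshold(self):
        rng = np.random.default_rng(11)
        ref = "".join(AMINO_ACIDS[i] for i in rng.integers(0, 20, size=12))
        ann = ReferenceAnnotation(reference=SequenceRecord(id="r", residues=ref))
        for trial in range(10):
            rows = [
                "".join(
                    AMINO_ACIDS[rng.integers(20)] if rng.random() < 0.4 else ref[j]
                    for j in range(len(ref))
                )
                for _ in range(25)
            ]
            p = build_profile(ann, maps_from(rows))
            prev = None
            for thr in (0.5, 0.7, 0.9, 1.0):
                cur = set(conserved_sites(p, thr, 0.5))
                if prev is not None:
                    assert cur <= prev
                prev = cur


class TestEntropy:
    def test_single_residue_site_is_zero_bits(self):
        p = build_profile(MK, maps_from(["MK"] * 3))
        assert site_entropy(p, 1) == 0.0

    def test_even_two_way_split_is_one_bit(self, toy_profile):
        p = build_profile(MK, maps_from(["MK", "MK", "LK", "LK"]))
        assert site_entropy(p, 1) == pytest.approx(1.0)

    def test_half_quarter_quarter_is_one_and_a_half_bits(self):
        p = build_profile(MK, maps_from(["MK", "MK", "LK", "WK"]))
        assert site_entropy(p, 1) == pytest.approx(1.5)

    def test_entropy_bounds_on_random_profiles(self):
        rng = np.random.default_rng(5)
        ref = "ACDEFGHIKL"
        ann = ReferenceAnnotation(reference=SequenceRecord(id="r", residues=ref))
        for _ in range(10):
            rows = [
                "".join(AMINO_ACIDS[rng.integers(20)] for _ in ref) for _ in range(15)
            ]
            p = build_profile(ann, maps_from(rows))
            for pos in range(1, len(ref) + 1):
                assert 0.0 <= site_entropy(p, pos) <= math.log2(20) + 1e-12


class TestMostVariableSite:
    def test_picks_the_split_site_among_conserved(self, toy_profile):
        assert most_variable_site(toy_profile, {1, 2}) == 1

    def test_tie_breaks_to_lowest_position(self):
        ann = ReferenceAnnotation(reference=SequenceRecord(id="r", residues="MKW"))
        p = build_profile(ann, maps_from(["MKW", "LCW"]))
        # positions 1 and 2 both 50/50 (1 bit); 3 conserved
        assert most_variable_site(p, {1, 2, 3}) == 1
        assert most_variable_site(p, {2, 3}) == 2

    def test_empty_set_is_error(self, toy_profile):
        with pytest.raises(ValueError):
            most_variable_site(toy_profile, set())


class TestProfileTable:
    def test_round_trip_reproduces_frequencies(self, tmp_path, benchmark):
        p = benchmark["profile"]
        path = tmp_path / "profile.tsv"
        write_profile_table(p, path)
        back = read_profile_table(path)
        assert back.ref_sequence == p.ref_sequence
        np.testing.assert_allclose(back.frequencies, p.frequencies, atol=1e-6)
        np.testing.assert_array_equal(back.coverage, p.coverage)

    def test_single_position_profile_is_two_lines(self, tmp_path):
        ann = ReferenceAnnotation(reference=SequenceRecord(id="r", residues="M"))
        p = build_profile(ann, maps_from(["M"]))
        path = tmp_path / "one.tsv"
        write_profile_table(p, path)
        assert len(path.read_text().strip().splitlines()) == 2

    def test_toy_row_content(self, tmp_path, toy_profile):
        path = tmp_path / "toy.tsv"
        write_profile_table(toy_profile, path)
        header, row1, _ = path.read_text().strip().splitlines()
        cols = header.split("\t")
        vals = dict(zip(cols, row1.split("\t")))
        assert vals["position"] == "1"
        assert vals["ref_residue"] == "M"
        assert float(vals["M"]) == pytest.approx(0.5)
        assert float(vals["L"]) == pytest.approx(0.5)

    def test_reader_normalizes_count_tables(self, tmp_path):
        # externally produced table with counts instead of frequencies
        header = "position\tref_residue\tcoverage\t" + "\t".join(AMINO_ACIDS)
        counts = {"A": 30, "C": 10}
        row = ["1", "A", "40"] + [str(counts.get(aa, 0)) for aa in AMINO_ACIDS]
        path = tmp_path / "counts.tsv"
        path.write_text(header + "\n" + "\t".join(row) + "\n")
        p = read_profile_table(path)
        assert p.frequency(1, "A") == pytest.approx(0.75)
        assert p.frequency(1, "C") == pytest.approx(0.25)

    def test_malformed_cell_reports_row_and_column(self, tmp_path, toy_profile):
        path = tmp_path / "bad.tsv"
        write_profile_table(toy_profile, path)
        text = path.read_text().replace("0.500000", "oops", 1)
        path.write_text(text)
        with pytest.raises(ValueError, match="row"):
            read_profile_table(path)

    def test_missing_column_is_error(self, tmp_path):
        path = tmp_path / "short.tsv"
        path.write_text("position\tref_residue\n1\tM\n")
        with pytest.raises(ValueError, match="missing columns"):
            read_profile_table(path)
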