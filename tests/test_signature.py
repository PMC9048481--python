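"""Signature scheme, fixture matrices, match counting, conserved/distinct sets."""

import numpy as np
import pytest

import tubsig
from tubsig.signature import (
    MOTIF_POSITIONS,
    PROFILE_POSITIONS,
    ResidueProfile,
    conserved_distinct_positions,
)

ALPHABET = list("ACDEFGHIKLMNPQRSTVWY")


def random_profile(rng, label="p"):
    return ResidueProfile(
        sequence_id=label,
        residues={pos: str(rng.choice(ALPHABET)) for pos in tubsig.SIGNATURE_POSITIONS},
    )


class TestFixtures:
    def test_table3_shape(self, table3):
        assert len(table3) == 18  # betaIII reference column + 17 taxa
        for profile in table3.values():
            assert set(tubsig.SIGNATURE_POSITIONS) <= set(profile.residues)

    @pytest.mark.parametrize(
        "table,label,pos,want",
        [
            ("table3", "Ob", 124, "C"),
            ("table1", "betaI", 239, "C"),
            ("table1", "betaIII_Hs", 239, "S"),
            ("table2", "betaVI_Gg", 124, "C"),
        ],
    )
    def test_spot_values(self, table, label, pos, want, request):
        matrix = request.getfixturevalue(table)
        assert matrix[label].get(pos) == want

    def test_unknown_fixture_rejected(self):
        with pytest.raises(ValueError, match="unknown fixture"):
            tubsig.load_fixture_matrix("table9")

    def test_per_table_betaIII_columns_disagree_at_189(self, table1, table3):
        # the two sources print different betaIII residues at 189; both kept as printed
        assert table1["betaIII_Hs"].get(189) == "I"
        assert table3["betaIII"].get(189) == "L"

    def test_scheme_structure(self, scheme):
        assert len(scheme.positions) == 25
        for subset in scheme.subsets.values():
            assert subset <= frozenset(scheme.positions)
        for profile in scheme.reference_profiles.values():
            assert set(scheme.positions) <= set(profile.residues)
        assert "H3" in scheme.structure_note[124]


class TestMatchCount:
    def test_octopus_shares_seven_positions(self, table3):
        ref = tubsig.table_reference_profile("table3")
        assert tubsig.match_count(table3["Ob"], ref, tubsig.SIGNATURE_POSITIONS) == 7

    def test_self_match_is_subset_size(self, table3):
        for profile in table3.values():
            assert tubsig.match_count(profile, profile, tubsig.BETAV12) == len(tubsig.BETAV12)

    def test_absent_and_x_never_match(self):
        a = ResidueProfile("a", {33: "X", 35: None, 37: "V"})
        b = ResidueProfile("b", {33: "X", 35: "N", 37: "V"})
        assert tubsig.match_count(a, b, (33, 35, 37)) == 1

    def test_matches_brute_force_oracle(self, scheme):
        rng = np.random.default_rng(42)
        ref = scheme.reference_profiles["betaIII"]
        for _ in range(200):
            profile = random_profile(rng)
            for name, subset in scheme.subsets.items():
                brute = sum(
                    1
                    for pos in subset
                    if profile.residues[pos] == ref.residues[pos]
                )
                assert tubsig.match_count(profile, ref, subset) == brute

    def test_consistent_with_identical_positions(self, scheme):
        rng = np.random.default_rng(7)
        ref = scheme.reference_profiles["betaIII"]
        for _ in range(50):
            profile = random_profile(rng)
            for subset in scheme.subsets.values():
                assert tubsig.match_count(profile, ref, subset) == len(
                    tubsig.identical_positions(profile, ref, subset)
                )


class TestIdenticalPositions:
    def test_betaV_matches_betaIII_at_twelve_positions(self, table1):
        ident = tubsig.identical_positions(
            table1["betaV"], table1["betaIII_Hs"], tubsig.SIGNATURE_POSITIONS
        )
        assert ident == tubsig.BETAV12

    def test_disjoint_alphabets_share_nothing(self):
        a = ResidueProfile("a", {p: "A" for p in tubsig.SIGNATURE_POSITIONS})
        b = ResidueProfile("b", {p: "G" for p in tubsig.SIGNATURE_POSITIONS})
        assert tubsig.identical_positions(a, b, tubsig.SIGNATURE_POSITIONS) == frozenset()


class TestConservedDistinct:
    CONTRAST = ["betaI", "betaIIA", "betaIIB", "betaIVA", "betaIVB"]

    def test_human_betaIII_vs_major_isotypes(self, table1):
        # brute force over the printed matrix: betaIVA shares S48/S335, betaIIA/B share S364
        out = conserved_distinct_positions(
            [table1["betaIII_Hs"]],
            [table1[c] for c in self.CONTRAST],
            tubsig.SIGNATURE_POSITIONS,
        )
        assert frozenset(tubsig.SIGNATURE_POSITIONS) - out == {48, 335, 364}

    def test_six_vertebrate_betaIII_columns(self, table1):
        focal = [table1[c] for c in
                 ["betaIII_Hs", "betaIII_Mm", "betaIII_Gg", "betaIII_Gj", "betaIII_Xl", "betaIII_Ss"]]
        out = conserved_distinct_positions(
            focal, [table1[c] for c in self.CONTRAST], tubsig.SIGNATURE_POSITIONS
        )
        assert out == {35, 55, 56, 84, 91, 124, 126, 189, 239, 275, 332, 333, 351}
        assert tubsig.UNIVERSAL8 < out  # properly contains the curated universal set

    def test_focal_equal_contrast_is_empty(self, table1):
        profiles = [table1["betaIII_Hs"]]
        assert conserved_distinct_positions(
            profiles, profiles, tubsig.SIGNATURE_POSITIONS
        ) == frozenset()

    def test_strict_all_nested_in_majority(self, table1):
        rng = np.random.default_rng(3)
        labels = list(table1)
        for _ in range(20):
            focal = [table1[l] for l in rng.choice(labels, 3)]
            contrast = [table1[l] for l in rng.choice(labels, 4)]
            strict = conserved_distinct_positions(
                focal, contrast, tubsig.SIGNATURE_POSITIONS, "strict_all"
            )
            majority = conserved_distinct_positions(
                focal, contrast, tubsig.SIGNATURE_POSITIONS, "majority"
            )
            assert strict <= majority

    def test_order_invariance(self, table1):
        focal = [table1[c] for c in ["betaIII_Hs", "betaIII_Mm"]]
        contrast = [table1[c] for c in self.CONTRAST]
        forward = conserved_distinct_positions(focal, contrast, tubsig.SIGNATURE_POSITIONS)
        backward = conserved_distinct_positions(
            focal[::-1], contrast[::-1], tubsig.SIGNATURE_POSITIONS
        )
        assert forward == backward

    def test_unknown_rule_rejected(self, table1):
        with pytest.raises(ValueError, match="rule"):
            conserved_distinct_positions(
                [table1["betaIII_Hs"]], [table1["betaI"]], (239,), "plurality"
            )


class TestSubsetOverlap:
    def test_universal_hits_six_cancer_positions(self):
        assert tubsig.subset_overlap(tubsig.UNIVERSAL8, tubsig.CANCER_MUTATED17) == 6

    def test_betaV12_hits_eight_cancer_positions(self):
        assert tubsig.subset_overlap(tubsig.BETAV12, tubsig.CANCER_MUTATED17) == 8

    def test_empty_set(self):
        assert tubsig.subset_overlap(tubsig.UNIVERSAL8, ()) == 0


@pytest.mark.parametrize(
    "taxon,all25,betaV12,universal8",
    [
        ("So1", 5, 3, 1),
        ("So2", 4, 1, None),  # third column inconsistent in the source; not asserted
        ("Ed", 7, 4, 3),
        ("Ob", 7, 4, 3),
        ("Ac", 2, 0, 0),
        ("Dm1", 4, 2, 1),
        ("Em", 4, 3, 3),
    ],
)
def test_comparison_table_regression(table3, taxon, all25, betaV12, universal8):
    """Match counts from the invertebrate matrix reproduce the published summary rows."""
    ref = tubsig.table_reference_profile("table3")
    profile = table3[taxon]
    assert tubsig.match_count(profile, ref, tubsig.SIGNATURE_POSITIONS) == all25
    assert tubsig.match_count(profile, ref, tubsig.BETAV12) == betaV12
    if universal8 is not None:
        assert tubsig.match_count(profile, ref, tubsig.UNIVERSAL8) == universal8


def test_extract_profile_from_reference(scheme, reference):
    rec = tubsig.SequenceRecord(id="ref", residues=reference.residues)
    nmap = tubsig.build_numbering_map(rec.residues, reference.residues)
    profile = tubsig.extract_profile(rec, nmap, scheme)
    assert set(profile.residues) == set(PROFILE_POSITIONS)
    assert profile.get(239) == "S" and profile.get(124) == "C" and profile.get(126) == "N"


def test_extract_profile_truncated_record(scheme, reference):
    rec = tubsig.SequenceRecord(id="trunc", residues=reference.residues[:100])
    nmap = tubsig.build_numbering_map(rec.residues, reference.residues)
    profile = tubsig.extract_profile(rec, nmap, scheme)
    assert profile.get(84) is not None
    assert all(profile.get(p) is None for p in PROFILE_POSITIONS if p >= 124)
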