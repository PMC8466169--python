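"""Genotype inference from diallel cross tables: soundness, recovery, bounds."""

import itertools

import pytest

from dssm import (
    CrossRecord,
    InferenceBoundError,
    UnsatisfiableError,
    VarietyGenotype,
    canonicalize_assignment,
    check_consistency,
    consistent_assignments,
    iter_consistent_assignments,
    min_alleles,
    variety,
)
from dssm.fixtures import FixtureSpec, generate_fixture


@pytest.fixture
def pct_records():
    """The classic three-variety fruit-set pattern that breaks a two-group model."""
    return [
        CrossRecord("Picholine", "Cayon", "no_fruit"),
        CrossRecord("Cayon", "Picholine", "no_fruit"),
        CrossRecord("Tanche", "Picholine", "no_fruit"),
        CrossRecord("Tanche", "Cayon", "fruit"),
    ]


@pytest.fixture
def pct_assignment():
    return {n: variety(n) for n in ("Picholine", "Cayon", "Tanche")}


class TestCheckConsistency:
    def test_published_assignment_explains_the_pattern(self, pct_records, pct_assignment):
        assert check_consistency(pct_records, pct_assignment) == []

    def test_every_two_group_assignment_fails(self, pct_records):
        """Fruit-set outcomes cannot be explained by stigma groups alone."""
        names = ("Picholine", "Cayon", "Tanche")
        for groups in itertools.product(("G1", "G2"), repeat=3):
            assignment = {
                n: VarietyGenotype(n, g, ("R1", "R1")) for n, g in zip(names, groups)
            }
            violations = check_consistency(pct_records, assignment, loci="dsi")
            assert violations, f"two-group assignment {groups} should fail"

    def test_empty_records_no_violations(self, pct_assignment):
        assert check_consistency([], pct_assignment) == []

    def test_unassigned_name_raises(self, pct_records):
        with pytest.raises(KeyError, match="Cayon"):
            check_consistency(pct_records, {"Picholine": variety("Picholine")})

    def test_pollen_test_constrains_only_stigma_screen(self):
        # Tanche x Picholine germinates (different groups) though no fruit sets
        rec = CrossRecord("Tanche", "Picholine", "pollen_germinated", method="pollen_test")
        a = {"Tanche": variety("Tanche"), "Picholine": variety("Picholine")}
        assert check_consistency([rec], a) == []
        rec = CrossRecord("Picholine", "Cayon", "no_germination", method="pollen_test")
        a = {"Picholine": variety("Picholine"), "Cayon": variety("Cayon")}
        assert check_consistency([rec], a) == []

    def test_allow_dsd_accepts_leaky_fruit(self):
        # Tanche selfing fruit: impossible strictly, explained by degradation
        rec = CrossRecord("Tanche", "Tanche", "fruit", selfing=True)
        a = {"Tanche": variety("Tanche")}
        assert check_consistency([rec], a)  # strict: violation
        assert check_consistency([rec], a, allow_dsd=True) == []

    def test_fruit_threshold_downgrades_trace_fruit(self):
        rec = CrossRecord("Picholine", "Cayon", "fruit", n_fruit=2, n_flowers=400)
        a = {n: variety(n) for n in ("Picholine", "Cayon")}
        assert check_consistency([rec], a)  # any fruit counts by default
        assert check_consistency([rec], a, fruit_threshold=5) == []


class TestConsistentAssignments:
    def test_symmetric_no_fruit_pair_admits_same_group(self):
        records = [
            CrossRecord("A", "B", "no_fruit"),
            CrossRecord("B", "A", "no_fruit"),
        ]
        results = consistent_assignments(records, max_alleles=2)
        assert any(
            a["A"].dsi_group == a["B"].dsi_group for a in results
        )

    def test_two_group_model_cannot_explain_pct(self, pct_records):
        assert consistent_assignments(pct_records, loci="dsi", max_alleles=2) == []

    def test_full_model_recovers_published_assignment(self, pct_records, pct_assignment):
        results = consistent_assignments(pct_records)
        assert canonicalize_assignment(pct_assignment) in results

    @pytest.mark.parametrize("seed", range(8))
    def test_generate_and_recover_round_trip(self, seed):
        panel, records = generate_fixture(FixtureSpec(n_varieties=4, seed=seed))
        target = canonicalize_assignment(panel)
        assert any(a == target for a in iter_consistent_assignments(records))

    def test_soundness_every_result_rechecks_clean(self):
        panel, records = generate_fixture(FixtureSpec(n_varieties=3, seed=11))
        for assignment in consistent_assignments(records):
            assert check_consistency(records, assignment) == []

    def test_relabeling_within_codominant_class_preserves_consistency(self):
        panel, records = generate_fixture(FixtureSpec(n_varieties=4, seed=5))
        assert check_consistency(records, panel) == []
        swap = {"R1": "R3", "R3": "R1"}
        relabeled = {
            n: VarietyGenotype(
                n, v.dsi_group, tuple(swap.get(a, a) for a in v.pasi)
            )
            for n, v in panel.items()
        }
        assert check_consistency(records, relabeled) == []

    def test_variety_bound_enforced(self):
        records = [
            CrossRecord(f"V{i}", f"V{j}", "unknown")
            for i in range(9)
            for j in range(9)
            if i != j
        ]
        with pytest.raises(InferenceBoundError, match="check_consistency"):
            consistent_assignments(records)


class TestMinAlleles:
    def test_empty_records_need_one_allele(self):
        assert min_alleles([]) == 1

    def test_generated_records_bounded_by_generating_alleles(self):
        panel, records = generate_fixture(FixtureSpec(n_varieties=4, seed=3))
        used = {a for v in panel.values() for a in v.pasi}
        assert min_alleles(records) <= len(used)

    def test_compatible_triangle_needs_degradation(self):
        """Three pairwise fully fruiting varieties are impossible with two
        stigma groups; allowing degradation-derived fruit makes one
        short-lived allele sufficient."""
        tri = [
            CrossRecord(a, b, "fruit")
            for a in "XYZ"
            for b in "XYZ"
            if a != b
        ]
        with pytest.raises(UnsatisfiableError):
            min_alleles(tri)
        assert min_alleles(tri, allow_dsd=True) == 1
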