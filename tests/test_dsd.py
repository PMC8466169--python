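"""Determinant degradation: effective sets, selfing windows, late crosses."""

import numpy as np
import pytest

from dssm import (
    DsdConfig,
    EffectiveDeterminants,
    VarietyGenotype,
    dssm_verdict,
    effective_determinants,
    late_cross_possible,
    selfing_possible,
    variety,
)
from dssm.genetics import STABLE_ALLELES


@pytest.fixture
def det():
    return DsdConfig()  # deterministic, defaults 3/5/10


class TestEffectiveDeterminants:
    def test_before_onset_nothing_degrades(self, det):
        static = EffectiveDeterminants(0, "S1", frozenset({"R2", "R3"}))
        out = effective_determinants(static, 0, det)
        assert out.pasi == {"R2", "R3"} and out.dsi == "S1"
        out = effective_determinants(static, det.onset_day - 1, det)
        assert out.pasi == {"R2", "R3"}

    def test_short_lived_gone_at_full_day(self, det):
        static = EffectiveDeterminants(0, "S1", frozenset({"R2", "R3"}))
        out = effective_determinants(static, det.full_day, det)
        assert out.pasi == {"R3"}
        assert out.dsi is None  # DSI degradable by default

    def test_stable_pair_persists_through_window(self, det):
        static = EffectiveDeterminants(0, None, frozenset({"R1", "R3"}))
        out = effective_determinants(static, det.ovule_access_day_max, det)
        assert out.pasi == {"R1", "R3"}

    def test_monotone_non_increasing_in_deterministic_mode(self, det):
        static = EffectiveDeterminants(0, "S2", frozenset({"R2", "R4", "R1"}))
        prev = static.pasi
        for day in range(det.ovule_access_day_max + 1):
            cur = effective_determinants(static, day, det).pasi
            assert cur <= prev
            prev = cur

    def test_negative_day_rejected(self, det):
        with pytest.raises(ValueError):
            effective_determinants(
                EffectiveDeterminants(0, None, frozenset({"R1"})), -1, det
            )


class TestSelfing:
    @pytest.mark.parametrize("group", ["G1", "G2"])
    @pytest.mark.parametrize("pair", [("R1", "R3"), ("R1", "R4")])
    def test_stable_self_determinant_blocks_forever(self, group, pair, det):
        v = VarietyGenotype("v", group, pair)
        assert selfing_possible(v, det) == (False, None)

    @pytest.mark.parametrize("group", ["G1", "G2"])
    def test_r2r3_selfs_at_full_day(self, group, det):
        v = VarietyGenotype("v", group, ("R2", "R3"))
        assert selfing_possible(v, det) == (True, det.full_day)

    def test_no_selfing_anywhere_with_dsd_off(self, all_genotypes):
        off = DsdConfig.off()
        for v in all_genotypes:
            assert selfing_possible(v, off) == (False, None)

    def test_no_selfing_when_dsi_not_degradable(self, all_genotypes):
        cfg = DsdConfig(dsi_degradable=False)
        for v in all_genotypes:
            assert selfing_possible(v, cfg) == (False, None)

    def test_stability_rule_predicts_self_fertility_exactly(self, all_genotypes, det):
        """Self-fertile iff the self pollen class contains no stable allele."""
        for v in all_genotypes:
            expected = not (v.pollen_determinants & STABLE_ALLELES)
            assert selfing_possible(v, det)[0] == expected

    def test_earliest_day_within_window(self, all_genotypes, det):
        for v in all_genotypes:
            ok, day = selfing_possible(v, det)
            if ok:
                assert det.onset_day <= day <= det.ovule_access_day_max


class TestLateCross:
    def test_fully_compatible_cross_fruits_immediately(self, tanche, cayon, det):
        assert late_cross_possible(tanche, cayon, det) == (True, 0)

    def test_stable_shared_determinant_blocks_late_cross(self, tanche, picholine, det):
        # germinates (1-0) but ovary R3 and pollen R3 are both stable
        assert dssm_verdict(tanche, picholine).code == "1-0"
        assert late_cross_possible(tanche, picholine, det) == (False, None)

    def test_same_group_without_dsi_degradation_never_fruits(self, det):
        v = VarietyGenotype("v", "G1", ("R1", "R3"))
        w = VarietyGenotype("w", "G1", ("R1", "R3"))
        cfg = DsdConfig(dsi_degradable=False)
        assert late_cross_possible(v, w, cfg) == (False, None)

    def test_short_lived_block_lapses(self, det):
        host = VarietyGenotype("h", "G2", ("R2", "R4"))
        donor = VarietyGenotype("d", "G1", ("R1", "R2"))  # pollen {R2}
        assert dssm_verdict(host, donor).code == "1-0"
        assert late_cross_possible(host, donor, det) == (True, det.full_day)

    def test_reduces_to_verdict_when_dsd_off(self, all_genotypes):
        off = DsdConfig.off()
        subset = all_genotypes[::3]
        for host in subset:
            for donor in subset:
                ok, day = late_cross_possible(host, donor, off)
                assert ok == dssm_verdict(host, donor).fruit
                assert day == (0 if ok else None)


class TestStochasticMode:
    def test_requires_rng(self):
        cfg = DsdConfig(mode="stochastic")
        v = variety("Tanche")
        with pytest.raises(ValueError, match="rng"):
            selfing_possible(v, cfg)

    def test_rate_one_matches_deterministic_outcome(self, all_genotypes):
        """With unit removal rates every degradable determinant is gone at
        onset, so the selfing *predicate* equals the deterministic one."""
        rates = {a: 1.0 for a in ("R2", "R4", "R5", "R6", "S1", "S2")}
        cfg = DsdConfig(mode="stochastic", degradation_rate_per_day=rates)
        det = DsdConfig()
        rng = np.random.default_rng(0)
        for v in all_genotypes:
            assert selfing_possible(v, cfg, rng)[0] == selfing_possible(v, det)[0]

    def test_partial_rates_converge_to_deterministic_predicate(self):
        """1000 replicates at rate 0.5: a short-lived-only genotype selfs in
        almost every trajectory, a stable-blocked one in none."""
        cfg = DsdConfig(mode="stochastic")
        rng = np.random.default_rng(1)
        leaky = VarietyGenotype("leaky", "G2", ("R2", "R3"))
        blocked = VarietyGenotype("blocked", "G1", ("R1", "R3"))
        n = 1000
        leaky_hits = sum(selfing_possible(leaky, cfg, rng)[0] for _ in range(n))
        blocked_hits = sum(selfing_possible(blocked, cfg, rng)[0] for _ in range(n))
        assert blocked_hits == 0
        # P(all three degradable copies decay within the access window) ~ 1
        assert leaky_hits / n > 0.95

    def test_stable_allele_escape_hatch_gives_partial_selfing(self):
        """Giving a 'stable' allele a small rate models varieties reported
        partially self-fertile despite a stable self-determinant."""
        cfg = DsdConfig(
            mode="stochastic", degradation_rate_per_day={"R1": 0.1, "R3": 0.1}
        )
        rng = np.random.default_rng(2)
        salonenque_type = VarietyGenotype("s", "G1", ("R3", "R5"))
        hits = sum(selfing_possible(salonenque_type, cfg, rng)[0] for _ in range(500))
        assert 0 < hits < 500  # leakage, not certainty
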