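"""Stochastic orchard-season simulator and the paternity-paradox diagnostic.

The simulator models one bloom season of a mixed orchard.  Every day of a
variety's bloom window, each of its flowers receives a Poisson number of
pollen grains sampled (with replacement) from that day's pollen cloud — the
planting-proportion-weighted mixture of all varieties currently in bloom,
including the flower's own variety.  Each deposited grain is pushed through
the two screens on *effective* determinant sets: degradation (the ``dsd``
module) can unblock an initially incompatible grain days after deposition,
as long as its tube still has ovule access.  One ovule per flower, first
passing grain wins; embryo paternity is simulator ground truth.

The diagnostic answers the orchard-management question behind paradoxical
paternity tests: a genotyped embryo's father that one screen accepts and
the other rejects can only have sired the seed if a determinant degraded —
direct evidence that compatible pollen was insufficient on that flower.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
import numpy as np
import pandas as pd

from .genetics import PollenClass, VarietyGenotype, pollen_phenotype
from .compatibility import dsi_screen, dssm_verdict, pasi_screen
from .dsd import DsdConfig

__all__ = [
    "OrchardVariety",
    "OrchardConfig",
    "VarietyReport",
    "FruitSetReport",
    "PaternityDiagnosis",
    "pollen_cloud",
    "simulate_season",
    "diagnose_paternity",
]


@dataclass(frozen=True)
class OrchardVariety:
    """One variety's share of the orchard and its bloom window (days)."""

    genotype: VarietyGenotype
    proportion: float
    bloom_start: int
    bloom_end: int

    def __post_init__(self) -> None:
        if self.proportion < 0:
            raise ValueError(f"negative planting proportion for {self.genotype.name}")
        if self.bloom_end < self.bloom_start:
            raise ValueError(f"empty bloom window for {self.genotype.name}")

    def in_bloom(self, day: int) -> bool:
        return self.bloom_start <= day <= self.bloom_end


@dataclass(frozen=True)
class OrchardConfig:
    varieties: tuple[OrchardVariety, ...]
    flowers_per_variety: int = 100
    pollen_per_flower_per_day: float = 5.0
    season_length: int = 30

    def __post_init__(self) -> None:
        object.__setattr__(self, "varieties", tuple(self.varieties))
        if not self.varieties:
            raise ValueError("an orchard needs at least one variety")
        total = sum(v.proportion for v in self.varieties)
        if not math.isclose(total, 1.0, rel_tol=1e-6):
            raise ValueError(f"planting proportions must sum to 1, got {total:g}")
        if self.pollen_per_flower_per_day <= 0:
            raise ValueError("pollen production must be positive")
        for v in self.varieties:
            if not (0 <= v.bloom_start and v.bloom_end <= self.season_length):
                raise ValueError(
                    f"bloom window of {v.genotype.name} outside the season"
                )
        names = [v.genotype.name for v in self.varieties]
        if len(set(names)) != len(names):
            raise ValueError("duplicate variety names in orchard")


def _variety_weights(orchard: OrchardConfig, day: int) -> list[tuple[OrchardVariety, float]]:
    blooming = [(v, v.proportion) for v in orchard.varieties if v.in_bloom(day)]
    total = sum(w for _, w in blooming)
    if total <= 0:
        return []
    return [(v, w / total) for v, w in blooming]


def pollen_cloud(orchard: OrchardConfig, day: int) -> dict[PollenClass, float]:
    """Normalized pollen-class composition of the air on one day.

    Weights are planting proportions of the varieties in bloom, aggregated
    by pollen phenotype; empty when nothing blooms.
    """
    cloud: dict[PollenClass, float] = {}
    for v, w in _variety_weights(orchard, day):
        pc = pollen_phenotype(v.genotype)
        cloud[pc] = cloud.get(pc, 0.0) + w
    return cloud


@dataclass
class VarietyReport:
    flowers: int
    fruit_count: int = 0
    selfed_count: int = 0
    dsd_event_count: int = 0
    fathers: Counter = field(default_factory=Counter)
    set_days: list[int] = field(default_factory=list)

    @property
    def fruit_set(self) -> float:
        return self.fruit_count / self.flowers if self.flowers else 0.0

    @property
    def selfing_rate(self) -> float:
        """Fraction of set fruit fathered by the host's own pollen."""
        return self.selfed_count / self.fruit_count if self.fruit_count else 0.0


@dataclass
class FruitSetReport:
    seed: int
    per_variety: dict[str, VarietyReport]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for name, r in self.per_variety.items():
            rows.append(
                {
                    "variety": name,
                    "flowers": r.flowers,
                    "fruit": r.fruit_count,
                    "fruit_set": r.fruit_set,
                    "selfing_rate": r.selfing_rate,
                    "dsd_events": r.dsd_event_count,
                    "fathers": ";".join(
                        f"{f}:{n}" for f, n in sorted(r.fathers.items())
                    ),
                }
            )
        return pd.DataFrame(rows).set_index("variety")


def _grain_pass_age(
    host: VarietyGenotype,
    donor: VarietyGenotype,
    config: DsdConfig,
    rng: np.random.Generator,
) -> float:
    """Days after deposition until this grain passes both screens (inf if never).

    Draws one degradation trajectory per determinant copy, so a grain's
    fate is fixed once sampled.  Age 0 means the grain was compatible
    outright.
    """
    if dsi_screen(host, donor):
        dsi_age = 0.0
    elif config.mode == "off":
        return math.inf
    else:
        dsi_age = min(
            config.removal_day(host.stigma_dsi, rng, dsi=True),
            config.removal_day(donor.pollen_dsi, rng, dsi=True),
        )
    shared = donor.pollen_determinants & host.ovary_determinants
    pasi_age = 0.0
    for a in shared:
        if config.mode == "off":
            return math.inf
        lapse = min(config.removal_day(a, rng), config.removal_day(a, rng))
        pasi_age = max(pasi_age, lapse)
    age = max(dsi_age, pasi_age)
    return age if age <= config.ovule_access_day_max else math.inf


def simulate_season(
    orchard: OrchardConfig,
    dsd_config: DsdConfig | None = None,
    seed: int = 0,
) -> FruitSetReport:
    """Simulate one season; reproducible for a given seed.

    Each flower keeps the deposited grains of its variety's bloom window; a
    grain deposited on day ``t`` that needs ``a`` days of degradation sets
    the fruit on day ``t + a``.  The earliest-fertilizing grain wins (ties
    broken by deposition order), all later grains are moot.
    """
    config = dsd_config or DsdConfig.off()
    rng = np.random.default_rng(seed)
    report = FruitSetReport(seed=seed, per_variety={})

    # Day-indexed donor tables so every flower shares the same cloud.
    clouds = {day: _variety_weights(orchard, day) for day in range(orchard.season_length + 1)}

    for ov in orchard.varieties:
        host = ov.genotype
        rep = VarietyReport(flowers=orchard.flowers_per_variety)
        report.per_variety[host.name] = rep
        for _ in range(orchard.flowers_per_variety):
            best_day: float = math.inf
            best_donor: VarietyGenotype | None = None
            for day in range(ov.bloom_start, ov.bloom_end + 1):
                cloud = clouds[day]
                if not cloud:
                    continue
                n_grains = rng.poisson(orchard.pollen_per_flower_per_day)
                if n_grains == 0:
                    continue
                donors = [c[0].genotype for c in cloud]
                weights = np.array([c[1] for c in cloud])
                picks = rng.choice(len(donors), size=n_grains, p=weights)
                for k in picks:
                    donor = donors[int(k)]
                    age = _grain_pass_age(host, donor, config, rng)
                    if math.isinf(age):
                        continue
                    set_day = day + age
                    if set_day < best_day:
                        best_day = set_day
                        best_donor = donor
            if best_donor is not None:
                rep.fruit_count += 1
                rep.fathers[best_donor.name] += 1
                rep.set_days.append(int(best_day))
                if best_donor.name == host.name:
                    rep.selfed_count += 1
                if not dssm_verdict(host, best_donor).fruit:
                    rep.dsd_event_count += 1
    return report


@dataclass(frozen=True)
class PaternityDiagnosis:
    """Model reading of one host/assigned-father pair from a paternity test."""

    dsi_verdict: str  # "Accept" | "Reject"
    pasi_verdict: str
    dsd_flag: bool
    recommendation: str

    def __post_init__(self) -> None:
        expected = (self.dsi_verdict == "Accept") != (self.pasi_verdict == "Accept")
        if self.dsd_flag != expected:
            raise ValueError(
                "dsd_flag must mark exactly-one-screen-accepts disagreement"
            )


_RECOMMEND_DSD = (
    "compatible pollen insufficient — determinant degradation let an "
    "incompatible father through; plant suitable pollinizers"
)
_RECOMMEND_OK = "father fully compatible; no action indicated"
_RECOMMEND_DOUBLE = (
    "father incompatible at both screens; if the assignment is correct both "
    "screens must have lapsed — verify markers, then treat as severe "
    "pollinizer shortage"
)


def diagnose_paternity(
    host: VarietyGenotype, father: VarietyGenotype
) -> PaternityDiagnosis:
    """Screen-by-screen verdicts for a marker-assigned father of a host's embryo.

    The assignment itself (molecular markers) is taken as given.  A split
    verdict — exactly one screen accepts — is the paradoxical signature:
    the embryo can only exist if degradation of an S-determinant operated,
    i.e. the flower saw too little fully compatible pollen.
    """
    dsi_ok = dsi_screen(host, father)
    pasi_ok = pasi_screen(host, father)
    flag = dsi_ok != pasi_ok
    if flag:
        rec = _RECOMMEND_DSD
    elif dsi_ok:  # both accept
        rec = _RECOMMEND_OK
    else:
        rec = _RECOMMEND_DOUBLE
    return PaternityDiagnosis(
        dsi_verdict="Accept" if dsi_ok else "Reject",
        pasi_verdict="Accept" if pasi_ok else "Reject",
        dsd_flag=flag,
        recommendation=rec,
    )
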