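"""Time-dependent degradation of S-determinants (DS-D).

The strict two-screen model forbids all selfing, yet many varieties set
some fruit under bags.  The resolution adopted here is that several
determinants are unstable: they degrade roughly 3-5 days after pollen
deposition, while pollen tubes keep making headway toward the ovules for
5-10 days.  A rejected-but-alive pollen tube can therefore fertilize late,
once the determinant that blocked it has decayed — on either side of the
interaction, since degradation affects pollen-tube and pistil determinants
alike.

Stability is allele-specific: R2, R4, R5 and R6 determinants are
short-lived, R1 and R3 are stable (varieties whose self pollen carries R1
or R3 against an ovary carrying the same allele are never self-fertile).
The di-allelic S determinants are degradable too (otherwise the stigma
screen could never lapse and no selfing would exist at all).

Two operating modes:

* ``deterministic`` — every degradable determinant disappears exactly at
  ``full_day`` (all-or-none step; convenient for prediction and testing).
* ``stochastic`` — each determinant decays independently with a per-day
  removal probability starting at ``onset_day`` (geometric waiting time),
  which models *partial* self-fertility.  Rates default to 0.5/day for
  short-lived alleles and 0.0 for stable ones; giving a stable allele a
  small nonzero rate is the supported way to model varieties such as
  Salonenque (R3R5) or Leccino (R1R5) that are reported partially
  self-fertile despite a stable self-determinant.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .genetics import (
    SHORT_LIVED_ALLELES,
    DeterminantSet,
    VarietyGenotype,
)
from .compatibility import dssm_verdict, dsi_screen

__all__ = [
    "DsdConfig",
    "EffectiveDeterminants",
    "effective_determinants",
    "selfing_possible",
    "late_cross_possible",
]

_DEFAULT_SHORT_LIVED_RATE = 0.5


@dataclass(frozen=True)
class DsdConfig:
    """Stability classes, timing window, and mode of determinant degradation.

    Days count from pollen deposition.  ``onset_day``/``full_day`` bound the
    3-5 day degradation window; ``ovule_access_day_max`` is the last day a
    pollen tube can still reach an ovule (tubes progress for 5-10 days).
    """

    onset_day: int = 3
    full_day: int = 5
    ovule_access_day_max: int = 10
    short_lived: frozenset[str] = SHORT_LIVED_ALLELES
    dsi_degradable: bool = True
    mode: str = "deterministic"  # "off" | "deterministic" | "stochastic"
    degradation_rate_per_day: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.mode not in ("off", "deterministic", "stochastic"):
            raise ValueError(f"unknown DS-D mode {self.mode!r}")
        if not (0 <= self.onset_day <= self.full_day <= self.ovule_access_day_max):
            raise ValueError(
                "require 0 <= onset_day <= full_day <= ovule_access_day_max, got "
                f"{self.onset_day}/{self.full_day}/{self.ovule_access_day_max}"
            )
        for a, r in self.degradation_rate_per_day.items():
            if not (0.0 <= r <= 1.0):
                raise ValueError(f"degradation rate for {a} must be in [0, 1], got {r}")
        object.__setattr__(self, "short_lived", frozenset(self.short_lived))

    @classmethod
    def off(cls) -> "DsdConfig":
        """No degradation anywhere: the strict two-screen model."""
        return cls(mode="off")

    def rate_for(self, determinant: str, *, dsi: bool = False) -> float:
        """Per-day stochastic removal probability of one determinant."""
        if dsi and not self.dsi_degradable:
            return 0.0
        if determinant in self.degradation_rate_per_day:
            return self.degradation_rate_per_day[determinant]
        if dsi or determinant in self.short_lived:
            return _DEFAULT_SHORT_LIVED_RATE
        return 0.0

    def removal_day(
        self,
        determinant: str,
        rng: np.random.Generator | None = None,
        *,
        dsi: bool = False,
    ) -> float:
        """Day from deposition at which one determinant copy disappears.

        ``math.inf`` when it never does.  Deterministic mode is a step at
        ``full_day``; stochastic mode draws a geometric waiting time with
        daily success probability ``rate_for(determinant)``, starting at
        ``onset_day`` (so rates -> 1 degrade at onset, recovering the
        all-or-none behaviour in the limit).
        """
        if self.mode == "off":
            return math.inf
        if self.mode == "deterministic":
            degradable = self.dsi_degradable if dsi else determinant in self.short_lived
            return float(self.full_day) if degradable else math.inf
        rate = self.rate_for(determinant, dsi=dsi)
        if rate <= 0.0:
            return math.inf
        if rng is None:
            raise ValueError("stochastic DS-D requires a numpy Generator (rng=...)")
        return float(self.onset_day + rng.geometric(rate) - 1)


@dataclass(frozen=True)
class EffectiveDeterminants:
    """Determinant load still present on one side of a cross at a given day."""

    day: int
    dsi: str | None
    pasi: DeterminantSet


def effective_determinants(
    static: EffectiveDeterminants,
    day: int,
    config: DsdConfig,
    rng: np.random.Generator | None = None,
) -> EffectiveDeterminants:
    """Degrade a day-0 determinant load forward to ``day``.

    In deterministic mode the result is a monotone non-increasing set over
    time; in stochastic mode each determinant's removal day is drawn
    independently, so repeated calls resample (pre-draw removal days via
    :meth:`DsdConfig.removal_day` when a single trajectory must be
    followed, as the orchard simulator does).
    """
    if day < 0:
        raise ValueError(f"day must be non-negative, got {day}")
    dsi = static.dsi
    if dsi is not None and config.removal_day(dsi, rng, dsi=True) <= day:
        dsi = None
    pasi = frozenset(
        a for a in static.pasi if config.removal_day(a, rng) > day
    )
    return EffectiveDeterminants(day=day, dsi=dsi, pasi=pasi)


def _late_window_search(
    host: VarietyGenotype,
    donor: VarietyGenotype,
    config: DsdConfig,
    rng: np.random.Generator | None,
) -> tuple[bool, int | None]:
    """Earliest day both screens pass on effective determinant sets."""
    # One removal-day realization per determinant copy, per side.
    stigma_gone = config.removal_day(host.stigma_dsi, rng, dsi=True)
    pollen_dsi_gone = config.removal_day(donor.pollen_dsi, rng, dsi=True)
    ovary_gone = {a: config.removal_day(a, rng) for a in host.ovary_determinants}
    tube_gone = {a: config.removal_day(a, rng) for a in donor.pollen_determinants}

    # The stigma block lapses when either interacting determinant is gone.
    dsi_ok_day = 0.0 if dsi_screen(host, donor) else min(stigma_gone, pollen_dsi_gone)
    # Each shared R allele blocks until one of its two copies is gone; the
    # ovary screen passes once the last shared allele has lapsed.
    shared = donor.pollen_determinants & host.ovary_determinants
    pasi_ok_day = max((min(tube_gone[a], ovary_gone[a]) for a in shared), default=0.0)

    earliest = max(dsi_ok_day, pasi_ok_day)
    if earliest <= config.ovule_access_day_max:
        return True, int(earliest)
    return False, None


def late_cross_possible(
    host: VarietyGenotype,
    donor: VarietyGenotype,
    config: DsdConfig,
    rng: np.random.Generator | None = None,
) -> tuple[bool, int | None]:
    """Can this cross ever set fruit, and from which day after deposition?

    A strict "1-1" cross fruits immediately: ``(True, 0)``.  Otherwise the
    blocked determinants must degrade before the pollen tube loses ovule
    access; the returned day is the earliest on which both screens pass
    (exact in deterministic mode, one sampled trajectory in stochastic
    mode).
    """
    if dssm_verdict(host, donor).fruit:
        return True, 0
    if config.mode == "off":
        return False, None
    return _late_window_search(host, donor, config, rng)


def selfing_possible(
    v: VarietyGenotype,
    config: DsdConfig,
    rng: np.random.Generator | None = None,
) -> tuple[bool, int | None]:
    """Can a variety set fruit with its own pollen, and from which day?

    Selfing requires the stigma block to lapse (hence ``dsi_degradable``)
    *and* every self-shared R determinant to decay on at least one side
    within the ovule-access window.  Under the default stability classes,
    genotypes whose pollen class contains a stable allele (R1 or R3) also
    present in their own ovary — e.g. R1R3, R1R4 — are never self-fertile,
    while e.g. R2R3 selfs from ``full_day`` (pollen R2 and ovary R2 decay,
    leaving stable ovary R3 facing an empty pollen determinant set).
    """
    if config.mode == "off" or not config.dsi_degradable:
        return False, None
    return _late_window_search(v, v, config, rng)
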