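"""The two successive incompatibility screens and everything derived from them.

A cross host x donor is evaluated in two stages:

1. **Stigma screen** (di-allelic): pollen germinates only when the donor's
   expressed S determinant differs from the host stigma's — equivalently,
   only inter-group crosses (G1 x G2 or G2 x G1) pass.
2. **Ovary screen** (poly-allelic): a pollen tube is rejected when any of
   its (dominance-filtered) R determinants is also expressed by the host
   ovary, where both host alleles are codominant.

Verdicts are coded ``"1-1"`` (germination and fruit), ``"1-0"``
(germination, no fruit) and ``"0-0"``; ``"0-1"`` is unconstructible because
the ovary screen only ever sees pollen tubes that passed the stigma.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, NamedTuple

import pandas as pd

from .genetics import (
    VarietyGenotype,
    enumerate_female_genotypes,
    enumerate_pollen_classes,
    format_determinants,
)

__all__ = [
    "CrossVerdict",
    "AsymmetryResult",
    "PanelFrequencies",
    "dsi_screen",
    "pasi_screen",
    "dssm_verdict",
    "build_matrix",
    "asymmetry",
    "mate_availability",
]


@dataclass(frozen=True)
class CrossVerdict:
    """Outcome of the two successive screens for one host x donor cross.

    ``pasi_pass`` is ``None`` when the stigma screen failed: the ovary
    screen is then never exercised, which is what makes "0-1" impossible.
    """

    dsi_pass: bool
    pasi_pass: bool | None

    def __post_init__(self) -> None:
        if not self.dsi_pass and self.pasi_pass is not None:
            raise ValueError(
                "the ovary screen is not evaluated when the stigma screen rejects"
            )
        if self.dsi_pass and self.pasi_pass is None:
            raise ValueError("pasi_pass is required when the stigma screen passes")

    @property
    def code(self) -> str:
        if not self.dsi_pass:
            return "0-0"
        return "1-1" if self.pasi_pass else "1-0"

    @property
    def fruit(self) -> bool:
        return self.code == "1-1"

    def __str__(self) -> str:
        return self.code


def dsi_screen(host: VarietyGenotype, donor: VarietyGenotype) -> bool:
    """True iff donor pollen germinates on the host stigma (groups differ)."""
    return donor.pollen_dsi != host.stigma_dsi


def pasi_screen(host: VarietyGenotype, donor: VarietyGenotype) -> bool:
    """True iff the donor pollen tube escapes rejection at the host ovary."""
    return donor.pollen_determinants.isdisjoint(host.ovary_determinants)


def dssm_verdict(host: VarietyGenotype, donor: VarietyGenotype) -> CrossVerdict:
    """Apply the stigma screen, then — only if it passed — the ovary screen."""
    if not dsi_screen(host, donor):
        return CrossVerdict(dsi_pass=False, pasi_pass=None)
    return CrossVerdict(dsi_pass=True, pasi_pass=pasi_screen(host, donor))


class AsymmetryResult(NamedTuple):
    forward: CrossVerdict  # a as host, b as donor
    reverse: CrossVerdict  # b as host, a as donor

    @property
    def asymmetric(self) -> bool:
        return self.forward.code != self.reverse.code


def asymmetry(a: VarietyGenotype, b: VarietyGenotype) -> AsymmetryResult:
    """Verdicts of a x b and b x a; asymmetry arises from pollen-side dominance.

    Example: an R1R2 host rejects codominant R1R3 pollen (shared R1), while
    the reciprocal cross succeeds because R1 is silenced by R2 in the R1R2
    parent's pollen.
    """
    return AsymmetryResult(dssm_verdict(a, b), dssm_verdict(b, a))


def build_matrix() -> pd.DataFrame:
    """The 20 x 9 ovary-screen compatibility matrix (180 cells).

    Rows are female PASI genotypes, columns pollen classes, cell 1 when the
    pollen class is disjoint from the female pair (compatible at the ovary),
    0 otherwise.  The stigma screen is group-level and is reported
    separately by :func:`dssm_verdict`, not folded into this matrix.
    """
    rows = enumerate_female_genotypes()
    cols = enumerate_pollen_classes()
    data = [
        [int(frozenset(pair).isdisjoint(pc)) for pc in cols]
        for pair in rows
    ]
    return pd.DataFrame(
        data,
        index=pd.Index(["".join(p) for p in rows], name="female_genotype"),
        columns=pd.Index([format_determinants(pc) for pc in cols], name="pollen_class"),
    )


@dataclass(frozen=True)
class PanelFrequencies:
    """Normalized genotype frequencies of a reference variety panel."""

    weights: Mapping[VarietyGenotype, float]

    def __post_init__(self) -> None:
        if not self.weights:
            raise ValueError("empty panel")
        total = float(sum(self.weights.values()))
        if total <= 0:
            raise ValueError("panel weights must have positive total mass")
        if any(w < 0 for w in self.weights.values()):
            raise ValueError("panel weights must be non-negative")
        object.__setattr__(
            self, "weights", {g: w / total for g, w in self.weights.items()}
        )

    @classmethod
    def from_counts(cls, counts: Mapping[VarietyGenotype, float]) -> "PanelFrequencies":
        return cls(weights=dict(counts))

    def items(self):
        return self.weights.items()


def mate_availability(host: VarietyGenotype, panel: PanelFrequencies) -> float:
    """Probability that a random panel pollen donor is fully compatible.

    Sums the panel weight over donor genotypes whose verdict on ``host`` is
    "1-1".  Degradation is not considered: this is strict-screen mate
    availability, the quantity a grower planning pollinizers cares about.
    """
    return sum(
        w for donor, w in panel.items() if dssm_verdict(host, donor).fruit
    )
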