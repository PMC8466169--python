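"""Allele and genotype model for the two-locus sporophytic SI system of olive.

The olive tree carries two self-incompatibility loci that act in sequence:

* a **di-allelic** locus (alleles ``S1``, ``S2``) screening pollen on the
  stigma.  ``S2`` is dominant over ``S1`` on both sides, so only two
  phenotypic groups exist: G1 (genotype S1S2, expressing S2) and G2
  (genotype S1S1, expressing S1).  S2S2 plants cannot arise because a G1 x
  G1 cross is incompatible at this locus.
* a **poly-allelic** locus (alleles ``R1``..``R6``) screening pollen tubes
  at the ovary, with the sporophytic dominance hierarchy
  ``R6 > R2 > R1 = R3 = R5 > R4`` acting on the pollen side only; in the
  ovary both alleles are codominantly expressed.

This module is the data model: validated genotypes, the dominance filter,
genotype-to-phenotype derivation for pollen and pistil, the enumerations of
admissible female genotypes (20) and pollen classes (9), and the compact
variety notation ``"1-[R1R3]_R1R3"`` used to describe varieties.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from functools import lru_cache
from itertools import combinations_with_replacement
from typing import Iterable

__all__ = [
    "GenotypeError",
    "DSI_ALLELES",
    "PASI_ALLELES",
    "PASI_RANK",
    "DSI_GROUPS",
    "PasiPair",
    "DeterminantSet",
    "VarietyGenotype",
    "PollenClass",
    "dominance_filter",
    "pollen_phenotype",
    "pistil_phenotype",
    "enumerate_female_genotypes",
    "enumerate_pollen_classes",
    "parse_genotype_notation",
    "format_genotype_notation",
]


class GenotypeError(ValueError):
    """Raised for inadmissible alleles, pairs, or malformed notation."""


DSI_ALLELES: tuple[str, ...] = ("S1", "S2")
PASI_ALLELES: tuple[str, ...] = ("R1", "R2", "R3", "R4", "R5", "R6")
DSI_GROUPS: tuple[str, ...] = ("G1", "G2")

#: Pollen-side dominance rank; higher rank silences lower rank, equal ranks
#: are codominant (R1, R3, R5 form the single multi-member rank class).
PASI_RANK: dict[str, int] = {"R6": 4, "R2": 3, "R1": 2, "R3": 2, "R5": 2, "R4": 1}

#: Alleles whose determinants are empirically short-lived vs stable; used as
#: the default stability classes by the degradation module.
SHORT_LIVED_ALLELES: frozenset[str] = frozenset({"R2", "R4", "R5", "R6"})
STABLE_ALLELES: frozenset[str] = frozenset({"R1", "R3"})

PasiPair = tuple[str, str]
DeterminantSet = frozenset[str]

#: G1 plants are S1S2 heterozygotes; G2 plants are S1S1 homozygotes.
DSI_GENOTYPE_OF_GROUP: dict[str, tuple[str, str]] = {
    "G1": ("S1", "S2"),
    "G2": ("S1", "S1"),
}
#: Determinant expressed by a group on both stigma and pollen sides: S2 is
#: dominant in the S1S2 heterozygote, S1 is all an S1S1 homozygote has.
DSI_EXPRESSED: dict[str, str] = {"G1": "S2", "G2": "S1"}


def _allele_index(a: str) -> int:
    return PASI_ALLELES.index(a)


def normalize_pasi_pair(pair: Iterable[str]) -> PasiPair:
    """Validate and canonically order (by allele index) a PASI allele pair.

    Raises :class:`GenotypeError` for unknown alleles, pairs that are not
    two alleles, and the inadmissible R6R6 homozygote (an R6 pollen parent
    always clashes with an R6-carrying ovary, so R6R6 offspring cannot be
    produced).
    """
    alleles = tuple(pair)
    if len(alleles) != 2:
        raise GenotypeError(f"a PASI genotype is a pair of alleles, got {alleles!r}")
    for a in alleles:
        if a not in PASI_ALLELES:
            raise GenotypeError(
                f"unknown PASI allele {a!r}; expected one of {', '.join(PASI_ALLELES)}"
            )
    ordered = tuple(sorted(alleles, key=_allele_index))
    if ordered == ("R6", "R6"):
        raise GenotypeError(
            "inadmissible genotype R6R6: R6 is top-dominant, so R6 pollen is "
            "always rejected by an R6-carrying ovary and R6R6 offspring cannot exist"
        )
    return ordered  # type: ignore[return-value]


def dominance_filter(pair: Iterable[str]) -> DeterminantSet:
    """Determinants a sporophyte with PASI genotype ``pair`` puts on its pollen.

    Returns the subset of the two alleles not dominated by the other under
    the rank order R6 > R2 > R1 = R3 = R5 > R4.  Equal ranks are codominant
    (both retained); a homozygote expresses its single allele.
    """
    a, b = normalize_pasi_pair(pair)
    ra, rb = PASI_RANK[a], PASI_RANK[b]
    if ra > rb:
        return frozenset({a})
    if rb > ra:
        return frozenset({b})
    return frozenset({a, b})


@dataclass(frozen=True)
class PollenClass:
    """Sporophytically determined determinant load of a variety's pollen."""

    dsi: str  # expressed di-allelic determinant, "S1" or "S2"
    pasi: DeterminantSet  # non-dominated poly-allelic determinants

    def __post_init__(self) -> None:
        if self.dsi not in DSI_ALLELES:
            raise GenotypeError(f"unknown DSI determinant {self.dsi!r}")
        object.__setattr__(self, "pasi", frozenset(self.pasi))

    def __str__(self) -> str:
        return f"{self.dsi}_{format_determinants(self.pasi)}"


@dataclass(frozen=True)
class VarietyGenotype:
    """Joint genotype of a variety at the two SI loci.

    ``dsi_group`` is "G1" (S1S2) or "G2" (S1S1); ``pasi`` is the unordered
    allele pair at the poly-allelic locus, stored sorted.  Both inadmissible
    homozygotes (S2S2, R6R6) are rejected at construction.
    """

    name: str
    dsi_group: str
    pasi: PasiPair

    def __post_init__(self) -> None:
        if self.dsi_group not in DSI_GROUPS:
            raise GenotypeError(
                f"unknown DSI group {self.dsi_group!r} for {self.name!r}; "
                "expected G1 (S1S2) or G2 (S1S1) — S2S2 cannot exist"
            )
        object.__setattr__(self, "pasi", normalize_pasi_pair(self.pasi))

    # -- phenotype views ---------------------------------------------------
    @property
    def dsi_genotype(self) -> tuple[str, str]:
        return DSI_GENOTYPE_OF_GROUP[self.dsi_group]

    @property
    def stigma_dsi(self) -> str:
        """Di-allelic determinant presented by the stigma (S2 > S1)."""
        return DSI_EXPRESSED[self.dsi_group]

    @property
    def pollen_dsi(self) -> str:
        """Di-allelic determinant carried by the pollen (sporophytic)."""
        return DSI_EXPRESSED[self.dsi_group]

    @property
    def ovary_determinants(self) -> DeterminantSet:
        """PASI determinants expressed in the ovary: both alleles, codominant."""
        return frozenset(self.pasi)

    @property
    def pollen_determinants(self) -> DeterminantSet:
        """PASI determinants on the pollen side after dominance filtering."""
        return dominance_filter(self.pasi)

    @property
    def notation(self) -> str:
        return format_genotype_notation(self)

    def __str__(self) -> str:
        return f"{self.name} ({self.notation})"


def pollen_phenotype(v: VarietyGenotype) -> PollenClass:
    """Full pollen phenotype (both loci) of a variety's pollen grains."""
    return PollenClass(dsi=v.pollen_dsi, pasi=v.pollen_determinants)


def pistil_phenotype(v: VarietyGenotype) -> tuple[str, DeterminantSet]:
    """(stigma DSI determinant, ovary PASI determinant set) of a variety."""
    return v.stigma_dsi, v.ovary_determinants


@lru_cache(maxsize=1)
def enumerate_female_genotypes() -> tuple[PasiPair, ...]:
    """All 20 admissible PASI genotypes in canonical lexicographic order.

    Unordered pairs over six alleles give 21 combinations; removing the
    inadmissible R6R6 leaves 15 heterozygotes plus 5 homozygotes.  R4R4 is
    admissible though not yet observed in any variety panel.
    """
    pairs = [
        p
        for p in combinations_with_replacement(PASI_ALLELES, 2)
        if p != ("R6", "R6")
    ]
    return tuple(pairs)


@lru_cache(maxsize=1)
def enumerate_pollen_classes() -> tuple[DeterminantSet, ...]:
    """The 9 distinct pollen determinant sets over all admissible genotypes.

    Dominance collapses the 20 genotypes onto six singletons {R1}..{R6} plus
    the three codominant doubletons {R1,R3}, {R1,R5}, {R3,R5}.  Ordered
    singletons-first, then doubletons, each lexicographically.
    """
    seen = {dominance_filter(p) for p in enumerate_female_genotypes()}
    key = lambda s: (len(s), tuple(sorted(_allele_index(a) for a in s)))
    return tuple(sorted(seen, key=key))


# -- variety notation ------------------------------------------------------
#
# Canonical form: "<1|2>-[<stigma alleles>]_<pollen alleles>", e.g.
# "1-[R1R3]_R1R3" for a G1 plant with ovary [R1R3] and codominant pollen.
# The compact digit dialect "1-[13]_13" is accepted on input; output always
# uses explicit allele names (digits are ambiguous past R9 and hide typos).

_NOTATION_RE = re.compile(r"^\s*([12])\s*-\s*\[([^\]]+)\]\s*_\s*(\S+)\s*$")
_ALLELE_TOKEN_RE = re.compile(r"R[1-6]|[1-6]")


def _parse_allele_tokens(text: str, where: str) -> list[str]:
    tokens = _ALLELE_TOKEN_RE.findall(text)
    if not tokens or "".join(tokens) != text.replace(" ", ""):
        raise GenotypeError(f"cannot read PASI alleles in {where} part {text!r}")
    return [t if t.startswith("R") else f"R{t}" for t in tokens]


def format_determinants(determinants: Iterable[str]) -> str:
    return "".join(sorted(determinants, key=_allele_index))


def format_genotype_notation(v: VarietyGenotype) -> str:
    group_digit = "1" if v.dsi_group == "G1" else "2"
    return (
        f"{group_digit}-[{format_determinants(v.pasi)}]"
        f"_{format_determinants(v.pollen_determinants)}"
    )


def parse_genotype_notation(text: str, name: str | None = None) -> VarietyGenotype:
    """Parse variety notation like ``"1-[R1R3]_R1R3"`` or compact ``"1-[13]_13"``.

    The pollen suffix is validated against the dominance filter: a suffix
    that contradicts the hierarchy (e.g. ``"1-[R1R3]_R3"``, hiding one of
    two codominant alleles) is rejected rather than silently corrected.
    """
    m = _NOTATION_RE.match(text)
    if m is None:
        raise GenotypeError(
            f"malformed genotype notation {text!r}; expected e.g. '1-[R1R3]_R1R3'"
        )
    group = "G1" if m.group(1) == "1" else "G2"
    pair = _parse_allele_tokens(m.group(2), "stigma")
    if len(pair) != 2:
        raise GenotypeError(
            f"stigma part of {text!r} must list exactly two alleles, got {pair}"
        )
    suffix = frozenset(_parse_allele_tokens(m.group(3), "pollen"))
    v = VarietyGenotype(name=name or text.strip(), dsi_group=group, pasi=tuple(pair))
    if suffix != v.pollen_determinants:
        raise GenotypeError(
            f"pollen suffix {format_determinants(suffix)!r} of {text!r} contradicts "
            f"the dominance hierarchy, which gives "
            f"{format_determinants(v.pollen_determinants)!r} for [{format_determinants(v.pasi)}]"
        )
    return v
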