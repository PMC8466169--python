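"""Packaged reference data: named variety genotypes, panel frequencies, and
the published paternity-paradox case table.

Genotypes marked ``"stated"`` are as published for those varieties (group
membership from pollen tests, R pairs from diallel fruit-set analysis).
Genotypes marked ``"inferred"`` are **synthetic placeholders**: the
literature gives the variety's group but not its R pair, so a pair was
chosen here that is consistent with the variety's published cross outcomes.
They let the case table be evaluated end to end but should not be cited as
deciphered genotypes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

from .genetics import VarietyGenotype
from .compatibility import PanelFrequencies

__all__ = [
    "variety",
    "known_varieties",
    "reference_panel_counts",
    "reference_panel",
    "PaternityCase",
    "PATERNITY_CASES",
]

# name -> (group, pair, source)
_VARIETIES: dict[str, tuple[str, tuple[str, str], str]] = {
    # stated in the literature
    "Picholine": ("G1", ("R1", "R3"), "stated"),
    "Arbequina": ("G1", ("R1", "R3"), "stated"),
    "Cayon": ("G1", ("R1", "R4"), "stated"),
    "Tanche": ("G2", ("R2", "R3"), "stated"),
    "Manzanilla": ("G2", ("R1", "R2"), "stated"),
    "Leccino": ("G1", ("R1", "R5"), "stated"),
    "Grossane": ("G1", ("R1", "R5"), "stated"),
    "Frantoio": ("G1", ("R4", "R5"), "stated"),
    "Cailletier": ("G1", ("R4", "R5"), "stated"),
    "Moraiolo": ("G1", ("R4", "R6"), "stated"),
    "Barnea": ("G1", ("R1", "R6"), "stated"),
    "Santa Caterina": ("G1", ("R2", "R3"), "stated"),
    "Salonenque": ("G1", ("R3", "R5"), "stated"),
    "Dolce Agogia": ("G2", ("R2", "R3"), "stated"),
    "Kalamata": ("G2", ("R2", "R4"), "stated"),
    "Picholine Marocaine": ("G2", ("R2", "R4"), "stated"),
    "Bouteillan": ("G2", ("R2", "R4"), "stated"),
    "Aglandau": ("G2", ("R2", "R5"), "stated"),
    "Koroneiki": ("G2", ("R2", "R6"), "stated"),
    "Amellau": ("G2", ("R3", "R4"), "stated"),
    "Rosciola": ("G2", ("R3", "R5"), "stated"),
    "Erbano": ("G2", ("R4", "R5"), "stated"),
    "Istrska Belica": ("G2", ("R4", "R6"), "stated"),
    # synthetic: group published, R pair chosen consistent with outcomes
    "Cayet Roux": ("G2", ("R4", "R5"), "inferred"),
    "Lucques": ("G2", ("R2", "R3"), "inferred"),
    "Petit Ribier": ("G1", ("R4", "R5"), "inferred"),
    "Picual": ("G2", ("R3", "R4"), "inferred"),
    "Oliviere": ("G2", ("R2", "R4"), "inferred"),
    "VerdaleH": ("G2", ("R2", "R4"), "inferred"),
    "Verdale de Millas": ("G2", ("R2", "R4"), "inferred"),
    "Cayanne": ("G1", ("R4", "R5"), "inferred"),
    "Clermontaise": ("G1", ("R4", "R5"), "inferred"),
    "Redouneil": ("G1", ("R3", "R5"), "inferred"),
}


def variety(name: str) -> VarietyGenotype:
    """Look up a packaged variety genotype by name."""
    try:
        group, pair, _ = _VARIETIES[name]
    except KeyError:
        raise KeyError(
            f"unknown variety {name!r}; see known_varieties()"
        ) from None
    return VarietyGenotype(name=name, dsi_group=group, pasi=pair)


def known_varieties(source: str | None = None) -> dict[str, VarietyGenotype]:
    """All packaged varieties, optionally filtered by ``"stated"``/``"inferred"``."""
    return {
        n: variety(n)
        for n, (_, _, src) in _VARIETIES.items()
        if source is None or src == source
    }


def genotype_source(name: str) -> str:
    """``"stated"`` (published) or ``"inferred"`` (synthetic placeholder)."""
    return _VARIETIES[name][2]


# Published occurrence counts of R-allele pairs among deciphered varieties,
# split by stigma-screen group (26 G1 + 39 G2 varieties).
_PANEL_COUNTS_G1 = {
    ("R1", "R2"): 0, ("R1", "R3"): 3, ("R1", "R4"): 7, ("R1", "R5"): 2,
    ("R1", "R6"): 1, ("R2", "R3"): 2, ("R2", "R4"): 3, ("R2", "R5"): 0,
    ("R2", "R6"): 2, ("R3", "R4"): 1, ("R3", "R5"): 1, ("R3", "R6"): 0,
    ("R4", "R5"): 3, ("R4", "R6"): 1, ("R5", "R6"): 0,
}
_PANEL_COUNTS_G2 = {
    ("R1", "R2"): 3, ("R1", "R3"): 0, ("R1", "R4"): 0, ("R1", "R5"): 0,
    ("R1", "R6"): 0, ("R2", "R3"): 7, ("R2", "R4"): 10, ("R2", "R5"): 1,
    ("R2", "R6"): 4, ("R3", "R4"): 3, ("R3", "R5"): 1, ("R3", "R6"): 1,
    ("R4", "R5"): 8, ("R4", "R6"): 1, ("R5", "R6"): 0,
}


def reference_panel_counts() -> dict[tuple[str, tuple[str, str]], int]:
    """Occurrence counts keyed by (group, R pair) for deciphered varieties."""
    out: dict[tuple[str, tuple[str, str]], int] = {}
    for group, table in (("G1", _PANEL_COUNTS_G1), ("G2", _PANEL_COUNTS_G2)):
        for pair, n in table.items():
            out[(group, pair)] = n
    return out


def reference_panel() -> PanelFrequencies:
    """The packaged reference panel: genotype frequencies of the 65
    deciphered varieties, one weighted entry per (group, R pair)."""
    counts = {
        VarietyGenotype(name=f"{g}-{a}{b}", dsi_group=g, pasi=(a, b)): n
        for (g, (a, b)), n in reference_panel_counts().items()
        if n > 0
    }
    return PanelFrequencies.from_counts(counts)


@dataclass(frozen=True)
class PaternityCase:
    """One published row of paradoxical paternity diagnoses.

    ``hosts`` x ``fathers`` expands to every pairwise combination the row
    covers; the three printed columns are the published stigma-screen
    verdict, ovary-screen verdict, and whether determinant degradation must
    have operated for the assigned embryo to exist.  ``anomalous_pairs``
    lists (host, father) combinations whose printed verdicts contradict the
    model under the varieties' stated genotypes (publication
    inconsistencies, kept for the record and excluded from agreement
    checks).
    """

    hosts: tuple[str, ...]
    fathers: tuple[str, ...]
    printed_dsi: str  # "Accept" | "Reject"
    printed_pasi: str
    printed_dsd: bool
    anomalous_pairs: frozenset[tuple[str, str]] = frozenset()

    def pairs(self) -> Iterable[tuple[str, str]]:
        for h in self.hosts:
            for f in self.fathers:
                yield h, f

    def clean_pairs(self) -> Iterable[tuple[str, str]]:
        for p in self.pairs():
            if p not in self.anomalous_pairs:
                yield p


PATERNITY_CASES: tuple[PaternityCase, ...] = (
    # G2 hosts
    PaternityCase(("Aglandau",), ("Frantoio", "Petit Ribier"), "Accept", "Reject", True),
    PaternityCase(("Aglandau",), ("Cayet Roux",), "Reject", "Reject", False),
    PaternityCase(
        ("Bouteillan", "Oliviere", "VerdaleH", "Verdale de Millas"),
        ("Aglandau", "Bouteillan", "VerdaleH", "Manzanilla"),
        "Reject", "Reject", False,
    ),
    PaternityCase(("Lucques", "Tanche"), ("Aglandau", "Bouteillan"), "Reject", "Reject", False),
    PaternityCase(("Lucques", "Tanche"), ("Picholine", "Arbequina"), "Accept", "Reject", True),
    PaternityCase(("Cayet Roux",), ("Aglandau",), "Reject", "Accept", True),
    # G1 hosts
    PaternityCase(
        ("Grossane",), ("Frantoio", "Petit Ribier"), "Accept", "Reject", False,
        # printed stigma-screen "Accept" for a G1 x G1 pair contradicts the
        # group model; known publication anomaly.
        anomalous_pairs=frozenset({("Grossane", "Frantoio"), ("Grossane", "Petit Ribier")}),
    ),
    PaternityCase(
        ("Cayanne", "Cayon", "Clermontaise"), ("Picholine", "Arbequina"),
        "Reject", "Accept", True,
        # Cayon's stated pair R1R4 shares R1 with Picholine/Arbequina pollen,
        # so the model rejects at the ovary while the row prints Accept.
        anomalous_pairs=frozenset({("Cayon", "Picholine"), ("Cayon", "Arbequina")}),
    ),
    PaternityCase(("Picholine", "Arbequina"), ("Amellau", "Picual"), "Accept", "Reject", True),
    PaternityCase(("Frantoio", "Petit Ribier"), ("Cayet Roux",), "Accept", "Reject", True),
    PaternityCase(
        ("Redouneil", "Salonenque"), ("Amellau", "Frantoio", "Petit Ribier"),
        "Reject", "Reject", False,
        # Amellau is printed as a G1 father in this row but is a stated G2
        # variety, which would flip the stigma verdict; excluded.
        anomalous_pairs=frozenset({("Redouneil", "Amellau"), ("Salonenque", "Amellau")}),
    ),
)
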