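"""Synthetic variety panels and diallel cross tables for testing and demos.

The generator emulates, structurally, a cross-outcome compilation: a panel
of varieties with known joint genotypes, and one record per performed
host x donor combination (including bagged selfings).  Outcomes are what
the two-screen model predicts for the generating genotypes; optional
degradation noise injects the paradoxical "fruit from an incompatible
pair" rows that real compilations contain, but only for pairs where
determinant degradation could genuinely produce fruit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .genetics import VarietyGenotype, enumerate_female_genotypes
from .compatibility import dssm_verdict
from .dsd import DsdConfig, late_cross_possible, selfing_possible
from .inference import CrossRecord
from .varieties import reference_panel_counts

__all__ = ["FixtureSpec", "generate_fixture"]


@dataclass(frozen=True)
class FixtureSpec:
    """What to generate.

    ``genotype_source`` is ``"reference_frequencies"`` (sample genotypes with
    the packaged panel's occurrence weights), ``"uniform"`` (uniform over
    all 40 admissible joint genotypes), or an explicit list of
    :class:`VarietyGenotype`.  ``record_completeness`` is the fraction of
    the full ordered diallel (selfings included) that was "performed";
    ``dsd_noise`` flips, with probability ``dsd_noise_rate``, the outcome
    of incompatible pairs that could fruit through determinant degradation.
    """

    n_varieties: int = 4
    genotype_source: str | Sequence[VarietyGenotype] = "uniform"
    record_completeness: float = 1.0
    dsd_noise: bool = False
    dsd_noise_rate: float = 0.5
    dsd_config: DsdConfig = field(default_factory=DsdConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.record_completeness <= 1.0:
            raise ValueError("record_completeness must be in [0, 1]")
        if not 0.0 <= self.dsd_noise_rate <= 1.0:
            raise ValueError("dsd_noise_rate must be in [0, 1]")
        if isinstance(self.genotype_source, str):
            if self.genotype_source not in ("reference_frequencies", "uniform"):
                raise ValueError(
                    f"unknown genotype source {self.genotype_source!r}"
                )
            if self.n_varieties < 1:
                raise ValueError("n_varieties must be at least 1")


def _sample_genotypes(spec: FixtureSpec, rng: np.random.Generator) -> list[VarietyGenotype]:
    if not isinstance(spec.genotype_source, str):
        return list(spec.genotype_source)
    if spec.genotype_source == "uniform":
        combos = [
            (g, pair) for g in ("G1", "G2") for pair in enumerate_female_genotypes()
        ]
        weights = np.full(len(combos), 1.0 / len(combos))
    else:
        items = sorted(reference_panel_counts().items())
        combos = [(g, pair) for (g, pair), n in items if n > 0]
        weights = np.array([n for (_, _), n in items if n > 0], dtype=float)
        weights /= weights.sum()
    picks = rng.choice(len(combos), size=spec.n_varieties, p=weights)
    out = []
    for i, k in enumerate(picks, start=1):
        g, pair = combos[int(k)]
        out.append(VarietyGenotype(name=f"V{i:02d}", dsi_group=g, pasi=pair))
    return out


def generate_fixture(
    spec: FixtureSpec,
) -> tuple[dict[str, VarietyGenotype], list[CrossRecord]]:
    """Generate (panel, records); deterministic for a given spec (seed included).

    Records cover the full ordered diallel host x donor, selfings on the
    diagonal, each kept with probability ``record_completeness``.  Without
    noise every record is the strict model verdict, so the generating panel
    itself has zero consistency violations against the records.
    """
    rng = np.random.default_rng(spec.seed)
    genotypes = _sample_genotypes(spec, rng)
    panel = {v.name: v for v in genotypes}
    if len(panel) != len(genotypes):
        raise ValueError("explicit genotype list contains duplicate names")

    records: list[CrossRecord] = []
    if spec.record_completeness == 0.0:
        return panel, records
    for host in genotypes:
        for donor in genotypes:
            if rng.random() >= spec.record_completeness:
                continue
            is_self = host.name == donor.name
            fruits = dssm_verdict(host, donor).fruit
            outcome = "fruit" if fruits else "no_fruit"
            if spec.dsd_noise and not fruits:
                leaky, _ = (
                    selfing_possible(host, spec.dsd_config)
                    if is_self
                    else late_cross_possible(host, donor, spec.dsd_config)
                )
                if leaky and rng.random() < spec.dsd_noise_rate:
                    outcome = "fruit"
            records.append(
                CrossRecord(
                    host=host.name,
                    donor=donor.name,
                    outcome=outcome,
                    method="fruit_test",
                    selfing=is_self,
                )
            )
    return panel, records
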