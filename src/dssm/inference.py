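"""Constraint-based inference of SI genotypes from diallel cross outcomes.

Historically, S-genotypes of olive varieties were attributed by hand:
propose group memberships and R-allele pairs, check every published cross,
revise.  This module mechanizes that reasoning as an exhaustive
backtracking search.  A *cross record* (host, donor, outcome, method)
constrains candidate genotypes: pollen-germination tests see only the
stigma screen, fruit tests see both screens in sequence.  An *assignment*
maps every variety name to a joint genotype; it is consistent when no
record is violated.

The search also reproduces the historical argument that a single di-allelic
locus cannot explain the data: run it with ``loci="dsi"`` and the classic
Picholine/Cayon/Tanche outcome pattern is unsatisfiable, whereas the full
two-locus model explains it.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .genetics import (
    PASI_ALLELES,
    VarietyGenotype,
    enumerate_female_genotypes,
)
from .compatibility import dsi_screen, dssm_verdict
from .dsd import DsdConfig, late_cross_possible, selfing_possible

__all__ = [
    "CrossRecord",
    "iter_consistent_assignments",
    "Violation",
    "InferenceBoundError",
    "UnsatisfiableError",
    "check_consistency",
    "consistent_assignments",
    "min_alleles",
    "canonicalize_assignment",
]

OUTCOMES = ("fruit", "no_fruit", "pollen_germinated", "no_germination", "unknown")
METHODS = ("fruit_test", "pollen_test")

#: Alleles interchangeable under relabeling: the codominant middle rank.
_CODOMINANT_CLASS = ("R1", "R3", "R5")


@dataclass(frozen=True)
class CrossRecord:
    """One host x pollen-source observation.

    ``pollen_test`` outcomes (germination) constrain only the stigma
    screen; ``fruit_test`` outcomes constrain the full two-screen verdict.
    A record with ``host == donor`` is a selfing observation (bagged
    inflorescence) and must say so via ``selfing``.
    """

    host: str
    donor: str
    outcome: str
    method: str = "fruit_test"
    selfing: bool = False
    n_fruit: int | None = None
    n_flowers: int | None = None

    def __post_init__(self) -> None:
        if self.outcome not in OUTCOMES:
            raise ValueError(f"unknown outcome {self.outcome!r}; expected {OUTCOMES}")
        if self.method not in METHODS:
            raise ValueError(f"unknown method {self.method!r}; expected {METHODS}")
        if self.host == self.donor and not self.selfing:
            raise ValueError(
                f"record {self.host} x {self.donor} has host == donor but is not "
                "marked as a selfing observation"
            )
        if self.selfing and self.host != self.donor:
            raise ValueError("a selfing record must have host == donor")


@dataclass(frozen=True)
class Violation:
    record: CrossRecord
    reason: str


class InferenceBoundError(ValueError):
    """Search bound exceeded; check a candidate assignment instead."""


class UnsatisfiableError(ValueError):
    """No assignment exists within the admissible allele set."""


def _effective_outcome(record: CrossRecord, fruit_threshold: int) -> str:
    """Fold a fruit count below the threshold into ``no_fruit``.

    The literature reports occasional fruit from nominally incompatible
    pairs; a configurable count threshold decides how much fruit falsifies
    incompatibility (default: any fruit counts as fruit).
    """
    if (
        record.outcome == "fruit"
        and record.n_fruit is not None
        and record.n_fruit < fruit_threshold
    ):
        return "no_fruit"
    return record.outcome


def _record_ok(
    record: CrossRecord,
    host: VarietyGenotype,
    donor: VarietyGenotype,
    *,
    loci: str,
    allow_dsd: bool,
    dsd_config: DsdConfig,
    fruit_threshold: int,
) -> str | None:
    """None when the record is satisfied, else a human-readable reason."""
    outcome = _effective_outcome(record, fruit_threshold)
    if outcome == "unknown":
        return None
    germinates = dsi_screen(host, donor)
    if record.method == "pollen_test" or outcome in ("pollen_germinated", "no_germination"):
        if outcome in ("pollen_germinated", "fruit") and not germinates:
            return "pollen germinated but genotypes are in the same stigma group"
        if outcome == "no_germination" and germinates:
            return "no germination observed but stigma groups differ"
        return None
    # fruit-test outcome under the full model (or stigma screen alone)
    if loci == "dsi":
        fruits = germinates
    else:
        fruits = dssm_verdict(host, donor).fruit
    if outcome == "fruit" and not fruits:
        if allow_dsd:
            possible, _ = (
                selfing_possible(host, dsd_config)
                if record.selfing
                else late_cross_possible(host, donor, dsd_config)
            )
            if possible:
                return None
        return "fruit observed but the cross is predicted incompatible"
    if outcome == "no_fruit" and fruits:
        return "no fruit observed but the cross is predicted fully compatible"
    return None


def check_consistency(
    records: Sequence[CrossRecord],
    assignment: Mapping[str, VarietyGenotype],
    *,
    allow_dsd: bool = False,
    dsd_config: DsdConfig | None = None,
    loci: str = "both",
    fruit_threshold: int = 1,
) -> list[Violation]:
    """All records violated by an assignment, with reasons.

    ``allow_dsd`` accepts a "fruit" record from a strictly incompatible
    pair when degradation could have produced it (late cross or selfing
    under ``dsd_config``, default deterministic).  ``loci="dsi"`` evaluates
    fruit records against the stigma screen alone — the single-locus
    two-group model whose insufficiency motivated the two-locus one.
    """
    if loci not in ("both", "dsi"):
        raise ValueError(f"loci must be 'both' or 'dsi', got {loci!r}")
    config = dsd_config or DsdConfig()
    out: list[Violation] = []
    for rec in records:
        try:
            host, donor = assignment[rec.host], assignment[rec.donor]
        except KeyError as e:
            raise KeyError(f"record names an unassigned variety: {e.args[0]!r}") from None
        reason = _record_ok(
            rec, host, donor,
            loci=loci, allow_dsd=allow_dsd, dsd_config=config,
            fruit_threshold=fruit_threshold,
        )
        if reason is not None:
            out.append(Violation(rec, reason))
    return out


def _genotype_domain(loci: str, max_alleles: int) -> list[tuple[str, tuple[str, str]]]:
    if loci == "dsi":
        # R pair is irrelevant to the stigma screen; pin it to keep the
        # domain at the two group labels.
        return [("G1", ("R1", "R1")), ("G2", ("R1", "R1"))]
    return [
        (g, pair)
        for g in ("G1", "G2")
        for pair in enumerate_female_genotypes()
        if len({*pair}) <= max_alleles  # cheap pre-filter; full count checked in search
    ]


def _canonical_rank2_order(alleles_in_first_use_order: Iterable[str]) -> bool:
    """True when codominant-class alleles appear in canonical R1, R3, R5 order."""
    seen = [a for a in alleles_in_first_use_order if a in _CODOMINANT_CLASS]
    return seen == list(_CODOMINANT_CLASS[: len(seen)])


def iter_consistent_assignments(
    records: Sequence[CrossRecord],
    *,
    max_alleles: int = 6,
    max_varieties: int = 8,
    loci: str = "both",
    allow_dsd: bool = False,
    dsd_config: DsdConfig | None = None,
    fruit_threshold: int = 1,
    max_states: int = 10_000_000,
):
    """Yield every assignment consistent with the records, up to relabeling.

    Exhaustive backtracking over varieties in order of first appearance,
    pruning a partial assignment as soon as any record between assigned
    varieties is violated.  Symmetry is broken within the codominant rank
    class (R1 = R3 = R5): those alleles must be introduced in canonical
    order, so each relabeling orbit is reported once.  The stigma-group
    swap G1 <-> G2 is *not* broken (both labelings are returned; no record
    can distinguish them).

    Raises :class:`InferenceBoundError` when the variety count exceeds
    ``max_varieties`` or the search would visit more than ``max_states``
    partial states — use :func:`check_consistency` with candidate
    assignments instead.
    """
    names: list[str] = []
    for rec in records:
        for n in (rec.host, rec.donor):
            if n not in names:
                names.append(n)
    if len(names) > max_varieties:
        raise InferenceBoundError(
            f"{len(names)} varieties exceeds the exhaustive-search bound of "
            f"{max_varieties}; use check_consistency with a candidate assignment"
        )
    if not names:
        yield {}
        return

    config = dsd_config or DsdConfig()
    domain = _genotype_domain(loci, max_alleles)
    genotypes = [VarietyGenotype(name="*", dsi_group=g, pasi=p) for g, p in domain]
    index = {n: i for i, n in enumerate(names)}
    # records checkable once variety k is assigned (all other names <= k)
    by_last: list[list[CrossRecord]] = [[] for _ in names]
    for rec in records:
        by_last[max(index[rec.host], index[rec.donor])].append(rec)

    # Memoized pairwise predicates over domain indices: the same genotype
    # pair is probed for thousands of partial assignments, so screens are
    # evaluated once per (host, donor) domain combination.
    code_cache: dict[tuple[int, int], str] = {}
    late_cache: dict[tuple[int, int], bool] = {}

    def code(hi: int, di: int) -> str:
        c = code_cache.get((hi, di))
        if c is None:
            c = code_cache[(hi, di)] = dssm_verdict(genotypes[hi], genotypes[di]).code
        return c

    def late_ok(hi: int, di: int, selfing: bool) -> bool:
        ok = late_cache.get((hi, di))
        if ok is None:
            host, donor = genotypes[hi], genotypes[di]
            ok, _ = (
                selfing_possible(host, config)
                if selfing
                else late_cross_possible(host, donor, config)
            )
            late_cache[(hi, di)] = ok
        return ok

    def rec_ok(rec: CrossRecord, hi: int, di: int) -> bool:
        outcome = _effective_outcome(rec, fruit_threshold)
        if outcome == "unknown":
            return True
        if rec.method == "pollen_test" or outcome in ("pollen_germinated", "no_germination"):
            germinates = code(hi, di) != "0-0"
            if outcome in ("pollen_germinated", "fruit"):
                return germinates
            if outcome == "no_germination":
                return not germinates
            return True
        fruits = code(hi, di) != "0-0" if loci == "dsi" else code(hi, di) == "1-1"
        if outcome == "fruit":
            return fruits or (allow_dsd and late_ok(hi, di, rec.selfing))
        return not fruits  # no_fruit

    chosen: list[int] = []  # domain index per assigned variety
    allele_order: list[str] = []  # PASI alleles in order of first use
    states = 0
    # interned genotype objects: at most |names| x |domain| distinct
    named_geno: dict[tuple[str, int], VarietyGenotype] = {}

    def named(n: str, i: int) -> VarietyGenotype:
        g = named_geno.get((n, i))
        if g is None:
            g = named_geno[(n, i)] = VarietyGenotype(
                name=n, dsi_group=domain[i][0], pasi=domain[i][1]
            )
        return g

    def extend(k: int):
        nonlocal states
        if k == len(names):
            yield {n: named(n, i) for n, i in zip(names, chosen)}
            return
        for gi, (group, pair) in enumerate(domain):
            states += 1
            if states > max_states:
                raise InferenceBoundError(
                    f"search exceeded {max_states} states; tighten max_alleles "
                    "or use check_consistency with a candidate assignment"
                )
            new_alleles = [a for a in dict.fromkeys(pair) if a not in allele_order]
            trial_order = allele_order + new_alleles
            if len(set(trial_order)) > max_alleles:
                continue
            if not _canonical_rank2_order(trial_order):
                continue
            chosen.append(gi)
            ok = all(
                rec_ok(rec, chosen[index[rec.host]], chosen[index[rec.donor]])
                for rec in by_last[k]
            )
            if ok:
                allele_order.extend(new_alleles)
                yield from extend(k + 1)
                del allele_order[len(allele_order) - len(new_alleles):]
            chosen.pop()

    yield from extend(0)


def consistent_assignments(
    records: Sequence[CrossRecord],
    **kwargs,
) -> list[dict[str, VarietyGenotype]]:
    """All consistent assignments as a list; see
    :func:`iter_consistent_assignments` for parameters.

    Under-constrained record sets can admit very many assignments; prefer
    the iterator form when only membership or existence is needed.
    """
    return list(iter_consistent_assignments(records, **kwargs))


def canonicalize_assignment(
    assignment: Mapping[str, VarietyGenotype]
) -> dict[str, VarietyGenotype]:
    """Relabel codominant-class alleles into canonical first-use order.

    Maps an assignment onto the representative of its relabeling orbit that
    the search reports: among R1/R3/R5 (mutually codominant, hence
    interchangeable), the first such allele encountered scanning varieties
    in name-insertion order becomes R1, the next R3, then R5.
    """
    perm: dict[str, str] = {}
    targets = iter(_CODOMINANT_CLASS)
    for v in assignment.values():
        for a in v.pasi:
            if a in _CODOMINANT_CLASS and a not in perm:
                perm[a] = next(targets)
    # unseen codominant alleles keep an arbitrary unused slot
    unused = [t for t in _CODOMINANT_CLASS if t not in perm.values()]
    for a in _CODOMINANT_CLASS:
        if a not in perm:
            perm[a] = unused.pop(0)
    out = {}
    for name, v in assignment.items():
        pair = tuple(perm.get(a, a) for a in v.pasi)
        out[name] = VarietyGenotype(name=name, dsi_group=v.dsi_group, pasi=pair)
    return out


def min_alleles(
    records: Sequence[CrossRecord],
    *,
    max_varieties: int = 8,
    loci: str = "both",
    allow_dsd: bool = False,
    dsd_config: DsdConfig | None = None,
    fruit_threshold: int = 1,
) -> int:
    """Smallest number of distinct R alleles that can explain the records.

    Tries allele budgets 1..6 in turn and returns the first for which a
    consistent assignment exists; raises :class:`UnsatisfiableError` when
    even the full allele set cannot explain the data (e.g. a mutually
    fully-compatible triangle, impossible with two stigma groups unless
    degradation is allowed to account for the fruit).
    """
    for k in range(1, len(PASI_ALLELES) + 1):
        found = next(
            iter_consistent_assignments(
                records,
                max_alleles=k,
                max_varieties=max_varieties,
                loci=loci,
                allow_dsd=allow_dsd,
                dsd_config=dsd_config,
                fruit_threshold=fruit_threshold,
            ),
            None,
        )
        if found is not None:
            return k
    raise UnsatisfiableError(
        "no assignment with up to six R alleles explains these records"
    )
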