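# Methods

## Model structure

The package models olive self-incompatibility as two loci screening pollen
in sequence, with sporophytic determination on both sides (the pollen
phenotype comes from the diploid pollen parent, not the haploid grain).

**Stigma screen.** The di-allelic locus has alleles S1, S2 with S2
dominant in both stigma and pollen. Genotypes are S1S1 (group G2,
expressing S1) and S1S2 (group G1, expressing S2); S2S2 is inadmissible
because a G1 × G1 cross is itself incompatible, so both parents of an
S2S2 offspring would have had to pass pollen the model forbids. Rejection
is determinant match: pollen germinates iff the expressed determinants
differ, which reduces exactly to "groups differ". The table the locus
states is two expression rules; the rejection pairing itself is not
separately tabulated, so phenotype-match rejection is adopted as the rule —
it is the unique simple rule reproducing the inter-group-only germination
pattern.

**Ovary screen.** The poly-allelic locus has six alleles R1–R6. Pollen
side, dominance ranks are R6 (4) > R2 (3) > R1 = R3 = R5 (2) > R4 (1); the
pollen expresses the non-dominated subset of its parent's pair (both
alleles when ranks tie, one otherwise). Ovary side, both alleles are
codominant. A pollen tube is rejected iff its expressed set intersects the
ovary set. R6R6 is inadmissible for the same recursive reason as S2S2
(top-dominant R6 pollen is always rejected by an R6-carrying ovary).
Homozygotes R1R1–R5R5 are admissible — that is what makes the female
genotype count 20 (15 heterozygotes + 5 homozygotes) — with R4R4 so far
unobserved in real panels but allowed by the model. Dominance collapses
the 20 genotypes to 9 pollen classes: the six singletons and the three
codominant doubletons R1R3, R1R5, R3R5.

Verdict coding: `0-0` (stigma rejects; the ovary screen is never
exercised), `1-0`, `1-1`. The `CrossVerdict` type makes `0-1`
unconstructible rather than merely unreached.

**Cross asymmetry** falls out of pollen-side dominance: host R1R2 rejects
codominant R1R3 pollen (shared R1) while the reciprocal cross succeeds
because R2 silences R1 in the R1R2 parent's pollen.

## Degradation of S-determinants

Several determinants are unstable after pollen deposition. Stability
classes default to: short-lived = {R2, R4, R5, R6}, stable = {R1, R3}.
This classification is forced by the self-fertility pattern of deciphered
varieties: R2R3-, R2R5-, R3R5-type varieties are reported partially
self-fertile while R1R3 and R1R4 varieties never are. The S alleles are
degradable too (`dsi_degradable=True`); without that no selfing could
exist at all.

Timing defaults (whole days from pollen deposition of each grain):

| parameter | default | meaning |
|---|---|---|
| `onset_day` | 3 | degradation can begin |
| `full_day` | 5 | deterministic mode: degradable determinants gone |
| `ovule_access_day_max` | 10 | last day a tube can still reach an ovule |

These are the reported 3–5-day degradation window and 5–10-day pollen-tube
progression. Degradation acts on *both* sides of the interaction: a shared
allele stops blocking when either its pollen-side or ovary-side copy is
gone. Both clocks run from deposition of the grain under consideration;
the underlying observations date events from pollination, and no separate
pistil-age clock is reported, so a single interaction timeline is used.

Two modes:

* **deterministic** — all-or-none step at `full_day`. Chosen as the
  default for predictability and testability; earliest possible
  fertilization day of a blocked cross is then `full_day` (or 0 for an
  unblocked one).
* **stochastic** — each determinant copy decays independently with a
  per-day probability from `onset_day` (geometric waiting time). Default
  rates: 0.5/day for short-lived alleles and the S alleles, 0.0 for stable
  ones. As rates → 1 the outcome predicate converges to the deterministic
  mode. This mode exists because real self-fertility is *partial*:
  leakage, not certainty.

**Known discrepancy.** Salonenque (R3R5) and Leccino (R1R5) are reported
partially self-fertile, yet their self pollen class contains a stable
allele also present in their own ovary, so the strict stability rule
predicts no selfing for them. The published account does not resolve this.
The package does not silently patch it: the deterministic mode predicts no
selfing for those genotypes, and the supported way to model them is a
small nonzero stochastic rate for the "stable" allele
(`degradation_rate_per_day={"R1": 0.1}` etc.).

A second config hook left at its neutral default: degradation timing is
identical in G1 and G2 hosts, although slight group differences in
incompatibility response have been reported.

## Orchard simulator

One ovule per flower; first-passing-grain-wins. Each day of its variety's
bloom window a flower receives Poisson(`pollen_per_flower_per_day`,
default 5) grains sampled with replacement from the day's pollen cloud —
varieties in bloom weighted by planting proportion, the host variety
included. A grain deposited on day *t* needing *a* days of degradation
(0 for a fully compatible grain, ∞ if a stable determinant blocks) sets
the fruit on day *t + a* provided *a* ≤ `ovule_access_day_max`; the
earliest-fertilizing grain fathers the embryo, ties broken by deposition
order. Paternity is simulator ground truth — marker-based paternity
inference is out of scope, which is also why the diagnostic below takes
the father as given.

No spatial dispersal, wind or insect vectors, and no ovule competition:
the published account gives none of these, and the quantities of interest
(fruit/no-fruit, father identity, selfing rate, set day) do not require
them. Fruit set per flower is therefore an upper bound: every flower whose
cloud ever contains a passable grain eventually sets.

Defaults (`flowers_per_variety=100`, `season_length=30`, bloom windows
per variety) are orchard-scale conventions chosen to keep per-variety
sampling error on selfing rates around a few percent; the acceptance
script uses 60 flowers per variety for the same reason.

**Paternity diagnostic.** For a host and a marker-assigned father, both
screens are read independently. Exactly one accepting is the paradoxical
signature: the embryo can only exist if a determinant degraded, i.e. the
flower saw too little fully compatible pollen — the actionable
recommendation is to plant suitable pollinizers. The packaged case table
(`dssm.varieties.PATERNITY_CASES`) encodes the published diagnosis rows;
three of its (host, father) combinations contradict the varieties' own
stated genotypes (a G1 × G1 pair printed as stigma-Accept; a host whose
stated pair forces ovary-Reject where Accept is printed; a father printed
in the wrong group) and are flagged `anomalous_pairs` rather than matched.
Varieties whose R pair is not published carry `source="inferred"`
placeholder pairs chosen consistent with their printed outcomes; they are
synthetic and marked as such.

## Genotype inference

`consistent_assignments` is an exhaustive backtracking search over joint
genotypes (2 groups × 20 pairs per variety), pruning as soon as any record
among assigned varieties is violated. Record semantics: pollen-test
outcomes constrain only the stigma screen; fruit-test outcomes constrain
the full verdict (`fruit` ⇒ `1-1`, `no_fruit` ⇒ not `1-1`), with two
escape valves — `allow_dsd` accepts fruit from pairs where degradation
could produce it, and `fruit_threshold` lets a configurable fruit count
stand in for the quantitative threshold the data need (default: any fruit
counts, since per-cross counts are rarely comparable across studies).

Symmetry handling: permuting the mutually codominant alleles R1/R3/R5
maps consistent assignments to consistent assignments, so the search
breaks that orbit by requiring first use in canonical order
(`canonicalize_assignment` maps any assignment to its representative).
The global group swap G1 ↔ G2 is *also* an exact symmetry — every record
predicate depends only on group equality — and is deliberately not broken:
both labelings are returned because no cross table can distinguish them.
Search is bounded at 8 varieties and 10⁷ states; beyond that the
user is told to validate candidate assignments with `check_consistency`
instead. Under-constrained tables can admit millions of assignments, so
`iter_consistent_assignments` streams them and `min_alleles` stops at the
first witness.

`loci="dsi"` evaluates fruit records against the stigma screen alone,
mechanizing the historical insufficiency argument: the
Picholine/Cayon/Tanche pattern has zero single-locus assignments but is
satisfiable (with 2 R alleles minimum) under the two-locus model.

## Synthetic data

`generate_fixture` emulates a cross-outcome compilation: a panel sampled
either uniformly over the 40 admissible joint genotypes or from the
packaged occurrence counts of the 65 deciphered reference varieties, and a
complete ordered diallel (selfings included) of strict model verdicts,
thinned by `record_completeness`. `dsd_noise` injects "fruit from an
incompatible pair" rows — but only where degradation could genuinely act,
mirroring how real compilations acquired their paradoxical rows. What the
generator does **not** emulate: observation error, bag leakage by foreign
pollen, variety synonymy/misnaming, andromonoecy-driven flower-type
variation, and quantitative fruit counts. Passing generate-and-recover
tests therefore show the search is sound and complete against the model's
own semantics, not that real tables are this clean.

## Numerical and engineering choices

* Days are whole integers; all stochastic draws flow from a single
  `numpy` `default_rng(seed)`, so every simulation and fixture is
  reproducible bit-for-bit under its seed.
* Canonical allele order R1 < … < R6 everywhere (display, matrix axes,
  pair normalization); the published material fixes no order.
* Notation output always uses explicit allele names (`1-[R1R3]_R1R3`);
  the compact digit dialect is accepted on input only, since two-digit
  strings are ambiguous and hide typos. A pollen suffix inconsistent with
  the dominance hierarchy is an error, not silently corrected.
* The allele set is fixed at six. Additional alleles (an R7 above R6)
  would slot into `PASI_RANK`, but no published pair requires one, so the
  hierarchy is not user-extensible through config.
* Mate availability is strict-screen (`1-1` only): degradation-derived
  late fruiting is excluded on purpose, since a grower planning
  pollinizers should not count on leakage.

## Known limitations

* Categorical verdicts only; no fruit-set percentages and no likelihood
  model over fruit counts.
* The Salonenque/Leccino self-fertility discrepancy (above) is documented,
  not resolved.
* Inferred (placeholder) R pairs for a handful of case-table varieties are
  synthetic; conclusions about those specific varieties should not be
  drawn from them.
* The simulator's pollen cloud is panmictic within a day; orchards with
  strong spatial structure will show weaker pollinizer effects than
  simulated.
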