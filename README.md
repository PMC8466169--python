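# dssm-olive

A modeling toolkit for self-incompatibility (SI) in the olive tree
(*Olea europaea* L.), built around a **dual-successive-screen model**: two
SI loci acting in sequence, plus time-dependent degradation of
S-determinants. It is written for researchers working on olive mating
systems and for orchard planners who need to pick pollinizers, interpret
paternity tests, or assign S-genotypes from cross data.

## The model

Olive cross outcomes have long been contradictory: pollen-germination
tests and fruit-set tests disagree, nominally incompatible pairs sometimes
fruit, and "self-incompatible" varieties self under bags. The model
implemented here reconciles these observations with three mechanisms:

1. **Di-allelic screen (DSI), at the stigma.** One locus with alleles
   *S1*, *S2* and *S2* dominant. Only two phenotypic groups exist — G1
   (*S1S2*) and G2 (*S1S1*); *S2S2* cannot arise. Pollen germinates only
   on a stigma of the *other* group.
2. **Poly-allelic screen (PASI), at the ovary.** A second locus with
   alleles *R1*–*R6* under the sporophytic pollen-side dominance hierarchy
   *R6* > *R2* > *R1* = *R3* = *R5* > *R4*; in the ovary both alleles are
   codominant. A pollen tube that germinated is rejected near the ovary if
   any of its expressed R determinants is also expressed there. This gives
   20 admissible female genotypes (*R6R6* excluded), 9 pollen classes, and
   a 20 × 9 compatibility matrix.
3. **Degradation of S-determinants (DS-D).** Determinants of *R2*, *R4*,
   *R5*, *R6* (and the S alleles) are short-lived: they decay roughly 3–5
   days after pollination, while pollen tubes retain ovule access for
   5–10 days. A blocked-but-alive tube can therefore fertilize late once
   the blocking determinant has decayed — which is what produces partial
   selfing and "paradoxical" paternity-test results.

A cross verdict is coded `1-1` (germination then fruit), `1-0`
(germination, no fruit) or `0-0`; `0-1` is impossible by construction.

On top of the predictive core the package provides an orchard-season
simulator (pollen clouds, Poisson pollen arrivals, per-flower screening
with degradation, father attribution), a paternity-paradox diagnostic, a
constraint-based inference engine that recovers S-genotype assignments
from diallel cross tables, delimited-text I/O for all of it, and a
synthetic fixture generator.

## Worked example

```python
from dssm import dssm_verdict, selfing_possible, DsdConfig, variety

tanche, cayon, picholine = map(variety, ["Tanche", "Cayon", "Picholine"])
print(dssm_verdict(picholine, cayon).code)   # 0-0  same group: no germination
print(dssm_verdict(tanche, picholine).code)  # 1-0  germinates, ovary shares R3
print(dssm_verdict(tanche, cayon).code)      # 1-1  efficient pollinizer
print(selfing_possible(tanche, DsdConfig())) # (True, 5)
print(selfing_possible(picholine, DsdConfig()))  # (False, None)
```

The verdicts reproduce the classic field puzzle — Picholine and Cayon are
mutually incompatible and Picholine cannot pollinate Tanche, yet Cayon
pollinates Tanche well — which no single two-group classification can
explain. The selfing calls show why Tanche (R2R3) is partially
self-fertile from day 5 (its blocking R2 determinants decay on both sides)
while Picholine (R1R3) never selfs (stable R1/R3 determinants face their
own ovary copies).

The `examples/` directory holds one short script per capability
(`predict_cross.py`, `compatibility_matrix.py`, `mate_availability.py`,
`selfing_windows.py`, `orchard_season.py`, `paternity_paradox.py`,
`infer_genotypes.py`); each prints its numbers with a line of
interpretation. A thin CLI exposes the same operations:

```sh
dssm predict --host Tanche --donor Cayon
dssm matrix -o matrix.csv
dssm simulate --orchard orchard.yaml --dsd deterministic --seed 1
dssm diagnose --host Aglandau --father Frantoio
dssm infer --records crosses.csv --min-alleles
```

## File formats

Variety panels (`name,dsi_group,pasi_pair[,notation]`), cross records
(`host,donor,outcome,method,n_fruit,n_flowers` — one observation per
line), and YAML orchard/degradation configs; see `src/dssm/io.py`
docstrings. Variety notation is `"1-[R1R3]_R1R3"` (group digit, ovary
pair, pollen class); the compact digit form `"1-[13]_13"` is accepted on
input.

## Scope notes

Verdicts are categorical: the model predicts which crosses can fruit, not
quantitative fruit-set percentages. Molecular mapping of the loci, pollen
dispersal physics and flower-type (andromonoecy) ratios are out of scope.
See `docs/methods.md` for model assumptions, parameter defaults, and known
limitations.
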