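"""Which genotypes can self once S-determinants start degrading?

Under the default configuration, short-lived determinants (R2, R4, R5, R6)
decay at day 5 after pollen deposition while R1 and R3 persist; pollen
tubes keep ovule access through day 10.  A genotype selfs exactly when its
own pollen class contains no stable allele shared with its ovary.
"""

from dssm import DsdConfig, VarietyGenotype, selfing_possible
from dssm.genetics import enumerate_female_genotypes, format_determinants

cfg = DsdConfig()  # deterministic: onset day 3, full degradation day 5
print("female pair  pollen class  self-fertile  earliest day")
for pair in enumerate_female_genotypes():
    v = VarietyGenotype("x", "G2", pair)
    ok, day = selfing_possible(v, cfg)
    print(
        f"{format_determinants(pair):11s}  "
        f"{format_determinants(v.pollen_determinants):12s}  "
        f"{'yes' if ok else 'no':12s}  {day if ok else '-'}"
    )

off = DsdConfig.off()
none_self = all(
    not selfing_possible(VarietyGenotype("x", g, p), off)[0]
    for g in ("G1", "G2")
    for p in enumerate_female_genotypes()
)
print(f"\nwith degradation disabled, no genotype selfs: {none_self}")
print("R1R3 and R1R4 never self (stable R1 faces its own ovary copy);")
print("R2R3 selfs from day 5, the day its blocking R2 determinants decay.")
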