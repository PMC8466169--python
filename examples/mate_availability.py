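"""Chance that a random orchard neighbour is a working pollinizer.

Uses the packaged reference panel (occurrence counts of the 65 deciphered
varieties by group and R pair).  The probability depends on the host's own
genotype: same R pair, different group, different answer — because the R
pair frequencies differ between the two stigma groups.
"""

from dssm import mate_availability, reference_panel, variety

panel = reference_panel()
for name in ("Tanche", "Santa Caterina", "Picholine", "Cayon", "Koroneiki"):
    v = variety(name)
    p = mate_availability(v, panel)
    print(f"{name:16s} {v.notation:18s} P(random donor fully compatible) = {p:.3f}")

print(
    "\nTanche and Santa Caterina share the R2R3 pair but sit in different\n"
    "stigma groups, so their pollinizer pools differ. All values are far\n"
    "below 0.5: most random neighbours are not working pollinizers."
)
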