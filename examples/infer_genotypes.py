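"""Infer S-genotypes from a diallel cross table, and recover a known panel.

First: the classic three-variety fruit-set pattern is unsatisfiable for a
single di-allelic locus (no group assignment works) but explained by the
two-locus model.  Second: a synthetic four-variety panel is recovered from
its own complete diallel.
"""

from dssm import (
    CrossRecord,
    canonicalize_assignment,
    consistent_assignments,
    iter_consistent_assignments,
    min_alleles,
)
from dssm.fixtures import FixtureSpec, generate_fixture

pattern = [
    CrossRecord("Picholine", "Cayon", "no_fruit"),
    CrossRecord("Cayon", "Picholine", "no_fruit"),
    CrossRecord("Tanche", "Picholine", "no_fruit"),
    CrossRecord("Tanche", "Cayon", "fruit"),
]
single = consistent_assignments(pattern, loci="dsi", max_alleles=2)
print(f"single-locus (two-group) assignments explaining the pattern: {len(single)}")
print(f"minimum R alleles under the two-locus model: {min_alleles(pattern)}")
full = consistent_assignments(pattern)
print(f"two-locus assignments: {len(full)}; e.g.")
for name, g in full[0].items():
    print(f"  {name:10s} {g.notation}")

panel, records = generate_fixture(FixtureSpec(n_varieties=4, seed=7))
target = canonicalize_assignment(panel)
found = any(a == target for a in iter_consistent_assignments(records))
print(f"\nsynthetic 4-variety panel, {len(records)} diallel records:")
for name, g in panel.items():
    print(f"  {name} {g.notation}")
print(f"generating panel recovered among consistent assignments: {found}")
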