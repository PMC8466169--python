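"""Diagnose paradoxical paternity-test results.

Marker-based paternity tests sometimes name a father the host should have
rejected.  Reading the pair through both screens separates the cases: when
exactly one screen accepts, the embryo can only exist because an
S-determinant degraded — the flower lacked fully compatible pollen.
"""

from dssm import diagnose_paternity, variety

pairs = [
    ("Aglandau", "Frantoio"),     # stigma accepts, ovary rejects -> decay needed
    ("Lucques", "Aglandau"),      # both reject: assignment itself is suspect
    ("Cayet Roux", "Aglandau"),   # stigma rejects, ovary accepts -> decay needed
    ("Tanche", "Cayon"),          # fully compatible father, nothing paradoxical
]
for host, father in pairs:
    d = diagnose_paternity(variety(host), variety(father))
    print(f"host {host} x father {father}:")
    print(f"  stigma {d.dsi_verdict}, ovary {d.pasi_verdict}, "
          f"degradation operated: {'Yes' if d.dsd_flag else 'No'}")
    print(f"  -> {d.recommendation}")
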