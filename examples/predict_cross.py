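"""Predict cross outcomes for the classic three-variety puzzle.

Picholine and Cayon never set fruit on each other, Picholine cannot
pollinate Tanche — yet Cayon pollinates Tanche well.  Two stigma groups
alone cannot explain that; the two successive screens can.
"""

from dssm import asymmetry, dssm_verdict, variety

trio = ["Picholine", "Cayon", "Tanche"]
print("verdict codes (host row x donor column); 1-1 = germination + fruit")
print(f"{'':12s}" + "".join(f"{d:>12s}" for d in trio))
for h in trio:
    cells = [
        dssm_verdict(variety(h), variety(d)).code if h != d else "-"
        for d in trio
    ]
    print(f"{h:12s}" + "".join(f"{c:>12s}" for c in cells))

res = asymmetry(variety("Manzanilla"), variety("Arbequina"))
print(
    f"\nManzanilla x Arbequina: {res.forward.code}, reciprocal {res.reverse.code}"
    f" -> asymmetric: {res.asymmetric}"
)
print(
    "Asymmetry arises on the pollen side: R1 is silenced by R2 in Manzanilla's\n"
    "pollen (so Arbequina's R1R3 ovary accepts it), while Arbequina's codominant\n"
    "R1R3 pollen shares R1 with the Manzanilla ovary and is rejected."
)
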