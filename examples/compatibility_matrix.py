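"""Build the 20 x 9 ovary-screen compatibility matrix.

Rows are the 20 admissible female R-allele pairs, columns the 9 pollen
classes that dominance filtering leaves; a 1 means the pollen class shares
no determinant with the female pair (compatible at the ovary, given the
stigma screen already passed).
"""

from dssm import build_matrix

m = build_matrix()
print(m.to_string())
print(
    f"\n{m.shape[0]} female genotypes x {m.shape[1]} pollen classes = "
    f"{m.size} cells; {int(m.to_numpy().sum())} compatible (1), "
    f"{int(m.size - m.to_numpy().sum())} incompatible (0)."
)
print("Every row has at least one 0: a female always rejects its own pollen class.")
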