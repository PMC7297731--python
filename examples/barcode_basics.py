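"""Compute a Rips persistence barcode and its entropy summaries by hand.

Four points at the corners of a unit square have one 1-cycle: the loop is
born when the sides appear (filtration 1) and filled when the diagonals
arrive (sqrt 2).  The entropies condense bar lengths into single numbers:
traditional persistent entropy weights long bars up, the Boltzmann variant
weights them down via the Betti energy E = (length)^2 * kBT.
"""

import numpy as np

import wph

square = np.array([[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0]], dtype=float)
dist = np.sqrt(((square[:, None] - square[None]) ** 2).sum(-1))

filtration = wph.build_rips_filtration(dist, max_dim=2)
barcode = wph.compute_persistence(filtration)

print("dim-0 bars (birth, death):")
for birth, death in barcode.get(0):
    print(f"  [{birth:.3f}, {death:.3f})")
print("dim-1 bars (birth, death):")
for birth, death in barcode.get(1):
    print(f"  [{birth:.3f}, {death:.3f})")

pe = wph.persistent_entropy(barcode, 0)
bpe = wph.boltzmann_persistent_entropy(barcode, 0)
print(f"dim-0 persistent entropy     : {pe:.4f}")
print(f"dim-0 Boltzmann pers. entropy: {bpe:.4f}")
print(
    "The three finite dim-0 bars all have length 1 (each corner merges with a\n"
    "neighbour at the side length), so both entropies equal ln 3 = 1.0986; the\n"
    "single dim-1 bar spans [1, 1.414): the square's loop."
)
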