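"""Slow-mode mobility profile of an idealized β-sandwich.

The slowest non-zero modes of the contact network carry the collective,
domain-scale motions.  Summing the six slowest modes gives a per-residue
mobility profile; edge strands move more than buried ones.
"""

import numpy as np

from gnmunfold import build_kirchhoff, decompose, make_beta_sandwich, mode_subset_msf

structure = make_beta_sandwich(strand_length=8)
decomp = decompose(build_kirchhoff(structure))
slow = mode_subset_msf(decomp, k_slowest=6)

print(f"sites: {len(structure)},  non-zero modes: {decomp.nonzero_modes.size}")
print(f"six-mode MSF range: {slow.min():.3f} – {slow.max():.3f} Å² (γ = 1)")
for strand in range(8):
    seg = slow[strand * 8:(strand + 1) * 8]
    print(f"  strand {strand + 1}: mean six-mode MSF = {seg.mean():.3f} Å²")
# Strands 1/4/5/8 are sheet edges: higher values mean larger collective
# mobility, the coarse-grained analogue of floppy loops and termini.
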