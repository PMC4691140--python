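# Fab-fragment domain and CDR annotation (author numbering, inclusive ranges)
# label chain start end
# Ig domains: conventional boundaries; adjust to the structure at hand.
VL L 1 110
CL L 111 214
VH H 1 118
CH H 119 220
# Hypervariable (complementarity-determining) loops
L1 L 26 37
L2 L 56 61
L3 L 97 102
H1 H 28 32
H2 H 50 58
H3 H 102 109
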