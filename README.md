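# gnmunfold

Coarse-grained intrinsic dynamics and thermal unfolding of proteins from
native-structure topology alone, built around the Gaussian network model
(GNM) and aimed at multi-domain proteins such as antibody Fab fragments,
where domain stability and unfolding order matter for engineering and
formulation.

## The model

A protein is reduced to its Cα sites; every pair within a cutoff
r_c = 7.3 Å is joined by a harmonic spring of uniform force constant γ.
All statistics follow from the Kirchhoff (connectivity) matrix Γ — the
graph Laplacian of the contact network — through its pseudoinverse:

- cross-correlations ⟨ΔR_i·ΔR_j⟩ = (k_BT/γ)[Γ⁺]_ij, with the mean-square
  fluctuation (MSF) on the diagonal;
- Debye–Waller B-factors B_i = (8π²/3)⟨ΔR_i²⟩, used to calibrate γ against
  a crystallographic B column by matching means;
- the mean-square fluctuation of the internal distance (MSFID)
  ⟨ΔR_ij²⟩ = (3k_BT/γ)([Γ⁺]_ii + [Γ⁺]_jj − 2[Γ⁺]_ij), a per-pair
  flexibility measure;
- slow-mode profiles from the lowest non-zero eigenmodes of Γ (six by
  default), isolating collective domain motions.

Unfolding is simulated by iterating the model: compute MSFID over all
non-zero modes, rupture the live non-backbone contact with the largest
value, rebuild Γ, repeat until only backbone springs remain.  Because a
pair's distance fluctuation grows linearly with temperature, the k-th
rupture maps to a reduced temperature T_k/T0 = m₁/m_k (m_k = MSFID of the
pair broken at step k, per k_BT/γ); the running maximum of this ratio gives
a non-decreasing melting curve whose flat stretches are cooperative jumps —
whole domains collapsing at one temperature.  Melt temperatures in Kelvin
follow by assigning T0 (room temperature, 300 K, by convention).

## Worked example

`python examples/unfold_two_domain.py` builds a 36-site, two-domain
synthetic network whose first domain is packed loosely (half the internal
contacts of its compact twin), unfolds it, and prints:

```
sites: 36, ruptures: 62
first rupture: pair (3, 5) at T/T0 = 1.0
final reduced temperature: 1.743
cooperative jump at T/T0 = 1.721: LNNC 32 -> 47 (15 contacts)
cooperative jump at T/T0 = 1.743: LNNC 47 -> 62 (15 contacts)
unfolding order: ['A', 'B'] (planted weak domain: A)
  A: melts at 337 K (T0 = 300 K)
  B: melts at 516 K (T0 = 300 K)
```

LNNC is the loss number of native contacts.  The planted weak domain A
finishes rupturing before B and at a lower temperature, and each domain's
collapse shows up as a cooperative jump: flexibility encoded in the native
topology dictates the unfolding order.  The other examples cover spring
constant calibration (`bfactor_calibration.py`), slow-mode mobility
(`slow_mode_mobility.py`) and pairwise flexibility maps
(`msfid_flexibility_map.py`).

## Analysing a real Fab fragment

```
python examples/fab_analysis.py <structure.pdb> [light_chain heavy_chain]
```

runs the full pipeline on a crystal structure: γ calibration against the
experimental B column, per-domain and per-CDR slow-mode mobility (using the
shipped `data/fab_annotation.txt` — VL/CL/VH/CH boundaries and the six
hypervariable loops L1 26–37, L2 56–61, L3 97–102, H1 28–32, H2 50–58,
H3 102–109 on author numbering), the unfolding trajectory with contact-map
snapshots, domain rupture order and melt temperatures.  For the
phosphocholine-binding antibody McPC603 the Fab crystal structure is
available from the PDB (candidate entries 1MCP and 2MCP cover this
fragment; either can be supplied — the package accepts any PDB path).
Placing a Cα-only copy at `data/mcpc603_fab_ca.pdb` (chains L and H)
enables the crystallographic benchmark in `tests/test_acceptance.py`,
which checks the fitted γ, the CL → CH → VH → VL rupture order, the
constant/variable-region melt temperatures and the surviving VL
folding-core strands (residues 39–44, 51–55, 90–96).

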