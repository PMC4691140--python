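# Methods

## Model

The package implements the isotropic Gaussian network model over Cα sites.
Residue pairs with Cα–Cα distance ≤ r_c are connected by identical
harmonic springs; the Kirchhoff matrix Γ (graph Laplacian of the contact
network: off-diagonal −1 per contact, diagonal = contact degree) encodes
the quadratic fluctuation Hamiltonian.  Equilibrium fluctuation statistics
are linear functionals of the Moore–Penrose pseudoinverse Γ⁺, realized by
full eigendecomposition with rigid-body (zero) modes removed.

Key identities used throughout:

- ⟨ΔR_i·ΔR_j⟩ = (k_BT/γ)[Γ⁺]_ij (cross-correlation; MSF on the diagonal)
- B_i = (8π²/3)⟨ΔR_i²⟩ (Debye–Waller)
- ⟨ΔR_ij²⟩ = (3k_BT/γ)([Γ⁺]_ii + [Γ⁺]_jj − 2[Γ⁺]_ij) (MSFID)

The per-site statistics carry the prefactor k_BT/γ and the
internal-distance statistic carries 3k_BT/γ.  These constants are kept as
stated; note that every rank-based product of the package — mode shapes,
domain comparisons, rupture order, Pearson correlations — is invariant to
them.  MSFID equals 3× the effective resistance between the two nodes of
the contact graph, a fact the cooperativity fixtures exploit (disjoint
loops have exactly independent resistances).

Temperature enters only through k_BT/γ.  The implementation works in units
k_BT = 1, so γ has units k_BT/Å² and all fluctuations scale as 1/γ.

## Parameters

| parameter | default | meaning |
|---|---|---|
| r_c | 7.3 Å | contact cutoff, inclusive (d ≤ r_c) |
| γ | fitted or 1 | spring constant, k_BT/Å² |
| slow modes | 6 | modes summed for the collective-mobility profile |
| zero-mode tolerance | 1e-9 · λ_max (relative) | robust as unfolding fragments the network |
| min_jump_size | 20 | contacts per cooperative jump at protein scale (use ~8 on 30–40-site synthetics) |
| T0 | 300 K | physical anchor of the reduced-temperature scale |
| snapshot LNNC | 600, 990, 1310, 1470 | trajectory checkpoints for Fab-scale runs |

γ calibration ("normalization") matches the mean of the theoretical
B-factors to the mean of the experimental column, γ =
mean(B_theo at γ=1)/mean(B_exp); a least-squares variant is available
(`method="lsq"`) since mean matching is a convention, not a law.  Mean
matching is exactly unbiased under zero-mean additive noise, which is why
noisy recovery in the tests is tight.

MSFID maps and the unfolding loop use all non-zero modes (the full
pseudoinverse); the six-mode restriction applies only to the
collective-mobility profile.  Both choices are exposed as arguments.

## Unfolding procedure

1. Decompose the current Γ; compute MSFID of every live breakable contact
   over all non-zero modes.
2. Rupture the contact with the largest MSFID.  Ties (within 1e-12
   relative, to absorb eigen-solver noise on symmetric networks) break to
   the lexicographically smallest index pair.
3. Rebuild Γ and repeat until no breakable contact remains.

"Breakable" excludes sequence-adjacent pairs within one chain: those
springs model the covalent backbone, stay in Γ permanently, and keep each
chain connected, so fragmentation stops at the domain level.  Inter-chain
contacts are always breakable.  When a rupture disconnects the graph, the
relative zero-mode threshold simply drops one more mode per component;
pairs in different components share no contact, so they never become
rupture candidates.

### Temperature reconstruction

The mapping from rupture order to temperature is a reconstruction, not a
measured quantity.  The assumption: a contact breaks when its distance
fluctuation reaches a fixed critical amplitude, and MSFID is linear in T,
so the breaking temperature of the pair ruptured at step k satisfies
T_k/T0 = m₁/m_k with m_k its MSFID per k_BT/γ at the moment of rupture and
m₁ that of the first rupture.  Rupturing a contact can only soften the
remaining network (effective resistances cannot decrease), so cascades
occur where the raw ratio falls below its running maximum; the reported
curve is that running maximum, read as cooperative rupture at constant
temperature.  Whether the flat-run reading is the only admissible
monotonicization is an open choice; rupture order, jump membership and
per-domain attribution are independent of it, and Kelvin melt temperatures
inherit its assumptions and should be read as estimates.

A cooperative jump is a maximal run of ≥ min_jump_size consecutive events
at one reported temperature (float-equal, which is exact because the
running maximum copies the previous value bit-for-bit).  A region's melt
temperature is the temperature of the jump that ruptures the largest share
of its internal contacts — not its first or last rupture — times T0; the
unfolding order ranks domains by the median step of their internal
ruptures.

## Synthetic data

The generators define the conditions the test suite measures under:

- **Linear chain** (spacing 3.8 Å): path-graph topology; spectrum oracle
  4 sin²(kπ/2N).
- **Two-domain network**: two confined self-avoiding random walks
  (3.8 Å bonds, 3.4 Å excluded volume) joined by an extended linker.  The
  weak domain is regenerated from its seed at progressively larger
  excluded-volume separations until its internal contact count first drops
  to ≤ fraction × the compact count — packing geometry is perturbed, the
  cutoff rule stays the sole source of topology.  Defaults used in the
  recovery studies: 15 sites per domain, weak fraction 0.5, sizes chosen so
  one full unfolding takes ~40 ms and a 100-seed study stays interactive.
- **β-sandwich**: two stacked four-strand sheets (4.8 Å rise, 5.0 Å strand
  spacing, 6.5 Å sheet separation — fixture choices for a clean contact
  pattern, not structural constants).
- **Pseudo-experimental B-factors**: model B-factors at a known γ plus
  seeded Gaussian noise with sd = fraction × mean(B), clipped at a small
  positive floor.  Study conditions: 150 sites, 30% noise, 200 noise
  draws.

What these do *not* emulate: real secondary-structure geometry, contact
anisotropy, crystal contacts, B-factor artefacts (TLS, refinement
restraints), or disulfides.  Passing the planted-recovery tests shows the
machinery is correct and the flexibility→early-rupture mechanism operates;
it does not by itself validate predictions on any particular crystal
structure, which is what the optional crystallographic benchmark is for.

## Numerical choices

- Dense `scipy.linalg.eigh` on the full Kirchhoff matrix; deterministic
  eigenvector sign (first non-negligible entry positive) for reproducible
  outputs.
- Zero modes counted by a relative threshold and checked against graph
  connected components in the tests.
- The unfolding engine contains no randomness; identical inputs give
  byte-identical trajectories.
- Altloc policy in PDB parsing: highest occupancy, ties by altloc id;
  residues without a Cα are skipped with a warning; first model only
  unless requested; insertion codes sort after the bare residue number in
  identity and range membership.

## Design choices and limitations

- The Fab domain boundaries shipped in `data/fab_annotation.txt`
  (VL 1–110, CL 111–214, VH 1–118, CH1 119–220) are conventional
  immunoglobulin limits on author numbering; the CDR loops are the
  standard hypervariable ranges for this antibody.  Both are overridable
  via a plain-text config.
- The greedy largest-MSFID rule is a quasi-static approximation: it
  assumes temperature rises slowly enough that the single loosest contact
  always fails next.  No refolding, no non-native contacts, no kinetics —
  the model presumes the native topology is the energy minimum throughout,
  so partially misfolded states are outside its scope.
- Absolute Kelvin temperatures are anchored only by the choice T0 = 300 K
  and typically overestimate calorimetric melting points, since the
  uniform-spring network ignores the chemistry of individual interactions;
  differences and orderings between regions are the robust read-out.
- The library is the interface: analyses are composed from the importable
  API (see `examples/`), with plain-text writers for every tabular
  product; figures are optional artifacts rendered with matplotlib's Agg
  backend.
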