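"""Synthetic Cα structures with known ground truth.

Everything downstream — the contact topology, the normal modes, the
unfolding cascade — is a deterministic function of a point cloud, so test
structures with planted properties can stand in for crystal structures:

* a collinear chain whose Kirchhoff matrix is the path-graph Laplacian with
  a closed-form spectrum;
* a two-domain random-walk globule with a planted weak (loosely packed)
  domain, the test bed for the flexibility-ruptures-first prediction;
* an idealized β-sandwich (two stacked four-strand sheets), a qualitative
  stand-in for an immunoglobulin fold;
* pseudo-experimental B-factor columns built from the model's own
  fluctuations at a known spring constant plus seeded noise, the test bed
  for spring-constant calibration.

Generators are pure functions of their arguments (one seeded NumPy
generator each, never global state) and regenerate bit-identical
coordinates for identical arguments.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .gnm import DEFAULT_CUTOFF, build_kirchhoff, decompose, residue_msf, theoretical_bfactors
from .structure_io import CoarseGrainedStructure, Site

__all__ = [
    "TwoDomainTruth",
    "make_linear_chain",
    "make_two_domain_network",
    "make_beta_sandwich",
    "make_pseudo_experimental_bfactors",
    "make_random_globule",
]

_BOND_LENGTH = 3.8      # Å, consecutive-Cα (virtual bond) distance
_MIN_SEPARATION = 3.4   # Å, excluded-volume floor for non-adjacent sites


def _sites_from_coords(coords: np.ndarray, chain_id: str = "A",
                       first_resnum: int = 1,
                       label: str = "synthetic") -> CoarseGrainedStructure:
    sites = [
        Site(chain_id, first_resnum + k, "", "ALA",
             (float(x), float(y), float(z)))
        for k, (x, y, z) in enumerate(np.asarray(coords, float))
    ]
    return CoarseGrainedStructure(sites, source_label=label)


def make_linear_chain(n: int, spacing: float = _BOND_LENGTH) -> CoarseGrainedStructure:
    """Collinear chain of n sites along x, residues numbered 1..n.

    At spacing 3.8 Å and the default 7.3 Å cutoff only (i, i+1) pairs are
    contacts, so the Kirchhoff matrix is the path-graph Laplacian, whose
    eigenvalues are known in closed form — the module's spectral oracle.
    """
    if n < 2:
        raise ValueError("need n >= 2")
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    coords = np.zeros((n, 3))
    coords[:, 0] = spacing * np.arange(n)
    return _sites_from_coords(coords, label=f"chain-n{n}")


# ---------------------------------------------------------------------------
# confined random walks

def _confined_walk(
    n: int,
    rng: np.random.Generator,
    radius: float,
    center: np.ndarray,
    min_sep: float = _MIN_SEPARATION,
    max_restarts: int = 200,
) -> np.ndarray:
    """Fixed-bond-length self-avoiding walk inside a ball.

    Steps of length 3.8 Å in uniformly random directions, rejected when they
    leave the ball of the given radius around `center` or come within
    `min_sep` of a non-adjacent previous site.  A larger excluded-volume
    separation packs the chain more loosely and leaves fewer contacts under
    the cutoff rule.  Deterministic for a given generator state.
    """
    for _ in range(max_restarts):
        pts = np.empty((n, 3))
        pts[0] = center
        ok = True
        for k in range(1, n):
            placed = False
            for _try in range(200):
                v = rng.normal(size=3)
                v *= _BOND_LENGTH / np.linalg.norm(v)
                cand = pts[k - 1] + v
                if np.linalg.norm(cand - center) > radius:
                    continue
                if k >= 2:
                    d = np.linalg.norm(pts[:k - 1] - cand, axis=1)
                    if (d < min_sep).any():
                        continue
                pts[k] = cand
                placed = True
                break
            if not placed:
                ok = False
                break
        if ok:
            return pts
    raise RuntimeError(f"could not place a {n}-site walk in radius {radius:.1f} Å")


def _compact_radius(n: int) -> float:
    # empirical: a 3.8 Å-bond walk with 3.4 Å excluded volume packs
    # comfortably at ~2.2 Å³ effective per-site radius scaling
    return max(2.2 * n ** (1 / 3) + 3.0, 7.0)


def _internal_contacts(coords: np.ndarray, cutoff: float) -> int:
    """Non-backbone contact count of a single-chain point cloud."""
    topo = build_kirchhoff(_sites_from_coords(coords), cutoff)
    return sum(1 for (i, j) in topo.contacts if j - i > 1)


def make_random_globule(n: int, seed: int,
                        radius: float | None = None) -> CoarseGrainedStructure:
    """A single compact random-walk globule of n sites."""
    rng = np.random.default_rng(seed)
    r = _compact_radius(n) if radius is None else radius
    coords = _confined_walk(n, rng, r, np.zeros(3))
    return _sites_from_coords(coords, label=f"globule-n{n}-s{seed}")


@dataclass(frozen=True)
class TwoDomainTruth:
    """Planted ground truth of a two-domain network."""

    weak_label: str
    domain_indices: dict[str, tuple[int, ...]]
    weak_internal_contacts: int
    strong_internal_contacts: int


def make_two_domain_network(
    n_per_domain: int,
    weak_contact_fraction: float,
    seed: int,
    cutoff: float = DEFAULT_CUTOFF,
) -> tuple[CoarseGrainedStructure, TwoDomainTruth]:
    """Two globular domains on one chain, domain A loosely packed.

    Domain A (sites 0..n-1) and domain B (the last n sites) are confined
    random walks bridged by a short extended linker.  Domain B is packed at
    the compact excluded-volume separation; domain A is regenerated from the
    same seed at progressively larger excluded-volume separations (with a
    proportionally widened confinement radius) until its internal
    (non-backbone) contact count first drops to
    ≤ weak_contact_fraction × the compact count.  Packing geometry is the
    only thing perturbed — the cutoff rule remains the sole source of
    topology.  At fraction 1.0 the domains are statistically exchangeable.
    The planted truth names A the weak domain.
    """
    if not 0.0 < weak_contact_fraction <= 1.0:
        raise ValueError("weak_contact_fraction must be in (0, 1]")
    if n_per_domain < 4:
        raise ValueError("need at least 4 sites per domain")

    n = n_per_domain
    r0 = _compact_radius(n)

    def walk_a(min_sep: float) -> np.ndarray:
        radius = r0 + 2.5 * (min_sep - _MIN_SEPARATION)
        return _confined_walk(n, np.random.default_rng(seed), radius,
                              np.zeros(3), min_sep)

    coords_a = walk_a(_MIN_SEPARATION)
    target = weak_contact_fraction * _internal_contacts(coords_a, cutoff)
    if weak_contact_fraction < 1.0:
        for min_sep in np.arange(_MIN_SEPARATION + 0.2, cutoff, 0.2):
            coords_try = walk_a(float(min_sep))
            if _internal_contacts(coords_try, cutoff) <= target:
                coords_a = coords_try
                break
        else:
            raise RuntimeError("packing search failed to reach the target fraction")

    # domain B: compact, regenerated from a derived seed, centred away from A
    rng_b = np.random.default_rng(seed + 1_000_003)
    reach_a = float(np.max(np.linalg.norm(coords_a, axis=1)))
    center_b = np.array([reach_a + r0 + 8.0, 0.0, 0.0])
    coords_b = _confined_walk(n, rng_b, r0, center_b)

    # extended linker from A's last site toward B's first site, 3.8 Å steps
    a_end, b_start = coords_a[-1], coords_b[0]
    gap = np.linalg.norm(b_start - a_end)
    n_link = max(int(np.ceil(gap / _BOND_LENGTH)) - 1, 0)
    link = [a_end + (b_start - a_end) * ((k + 1) / (n_link + 1))
            for k in range(n_link)]
    coords = np.vstack([coords_a, np.array(link).reshape(-1, 3), coords_b])

    structure = _sites_from_coords(
        coords, label=f"two-domain-n{n}-f{weak_contact_fraction}-s{seed}")
    idx_a = tuple(range(n))
    idx_b = tuple(range(n + n_link, 2 * n + n_link))
    truth = TwoDomainTruth(
        weak_label="A",
        domain_indices={"A": idx_a, "B": idx_b},
        weak_internal_contacts=_count_internal(structure, idx_a, cutoff),
        strong_internal_contacts=_count_internal(structure, idx_b, cutoff),
    )
    return structure, truth


def _count_internal(structure: CoarseGrainedStructure,
                    indices: tuple[int, ...], cutoff: float) -> int:
    idx = set(indices)
    topo = build_kirchhoff(structure, cutoff)
    return sum(1 for (i, j) in topo.contacts
               if i in idx and j in idx and j - i > 1)


def make_beta_sandwich(
    strand_length: int = 8,
    rise: float = 4.8,
    strand_spacing: float = 5.0,
    sheet_separation: float = 6.5,
) -> CoarseGrainedStructure:
    """Idealized β-sandwich: two stacked four-strand antiparallel sheets.

    A qualitative immunoglobulin-fold-like fixture; the 4.8 Å per-residue
    rise and 5.0 Å strand spacing are fixture choices for a clean contact
    pattern at the default cutoff, not structural constants.  Strands are
    threaded in serpentine order within each sheet so consecutive residues
    stay bonded.
    """
    coords = []
    for sheet in range(2):
        for strand in range(4):
            xs = np.arange(strand_length) * rise
            if strand % 2 == 1:
                xs = xs[::-1]
            for x in xs:
                coords.append((x, strand * strand_spacing, sheet * sheet_separation))
    return _sites_from_coords(np.array(coords), label="beta-sandwich")


def make_pseudo_experimental_bfactors(
    structure: CoarseGrainedStructure,
    true_gamma: float,
    noise_sd_fraction: float,
    seed: int,
    cutoff: float = DEFAULT_CUTOFF,
) -> CoarseGrainedStructure:
    """Fill the experimental B column from the model's own fluctuations.

    The column is the Debye–Waller B-factor at the given spring constant
    plus seeded zero-mean Gaussian noise with standard deviation
    noise_sd_fraction × mean(B); negative results are clipped at a small
    positive floor.  With zero noise the spring-constant calibration must
    recover true_gamma exactly.
    """
    if true_gamma <= 0:
        raise ValueError("true_gamma must be positive")
    rng = np.random.default_rng(seed)
    decomp = decompose(build_kirchhoff(structure, cutoff))
    b = theoretical_bfactors(residue_msf(decomp, gamma=true_gamma))
    noisy = b + rng.normal(0.0, noise_sd_fraction * b.mean(), size=b.size)
    floor = 1e-3 * b.mean()
    n_clip = int((noisy < floor).sum())
    if n_clip:
        import logging
        logging.getLogger(__name__).info(
            "clipped %d negative pseudo-experimental B-factors", n_clip)
        noisy = np.maximum(noisy, floor)
    return structure.with_bfactors(noisy)
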