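"""Gaussian network model core.

The model treats a protein as an elastic network over its Cα sites: every
residue pair closer than a cutoff distance rc (7.3 Å by default) is joined
by a harmonic spring of uniform force constant γ.  All fluctuation
statistics follow from the graph Laplacian of the contact network — the
Kirchhoff matrix Γ — through its Moore–Penrose pseudoinverse:

    cross-correlation  ⟨ΔRi·ΔRj⟩ = (kBT/γ) [Γ⁺]ij
    mean-square fluct. ⟨ΔRi²⟩    = (kBT/γ) [Γ⁺]ii
    B-factor           Bi        = (8π²/3) ⟨ΔRi²⟩
    distance fluct.    ⟨ΔRij²⟩   = (3kBT/γ) ([Γ⁺]ii + [Γ⁺]jj − 2[Γ⁺]ij)

The pseudoinverse is realized by eigendecomposition with the zero modes
(one per connected component, the rigid-body translations) removed.  The
implementation works in units where kBT = 1, so γ carries units of kBT/Å²
and every statistic scales as 1/γ.  Note the distance-fluctuation statistic
(MSFID) carries a prefactor of 3kBT/γ while the per-site statistics carry
kBT/γ; all rank-based results (mode shapes, contact rupture order,
correlation coefficients) are invariant to these constant prefactors.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.linalg import eigh
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "KirchhoffTopology",
    "ModeDecomposition",
    "FluctuationReport",
    "GammaFit",
    "InvalidModeError",
    "DEFAULT_CUTOFF",
    "BFACTOR_PREFACTOR",
    "MSFID_PREFACTOR",
    "build_kirchhoff",
    "topology_from_contacts",
    "decompose",
    "residue_msf",
    "mode_subset_msf",
    "cross_correlation",
    "msfid_matrix",
    "theoretical_bfactors",
    "fit_gamma",
    "fluctuation_report",
    "connected_component_count",
]

DEFAULT_CUTOFF = 7.3
"""Default contact cutoff rc in Å."""

BFACTOR_PREFACTOR = 8.0 * np.pi**2 / 3.0
"""Debye–Waller constant relating mean-square fluctuation to B-factor."""

MSFID_PREFACTOR = 3.0
"""Prefactor (in units of kBT/γ) of the internal-distance fluctuation."""

ZERO_MODE_RTOL = 1e-9
"""Relative eigenvalue threshold below which a mode counts as rigid-body."""


class InvalidModeError(ValueError):
    """Raised when a mode subset includes a zero mode or is out of range."""


@dataclass(frozen=True)
class KirchhoffTopology:
    """Contact set and connectivity (Kirchhoff) matrix of a network.

    The matrix is the graph Laplacian: −1 off-diagonal for each contact,
    0 otherwise, with the diagonal holding the contact degree so every row
    sums to zero.
    """

    n_sites: int
    cutoff_rc: float
    contacts: frozenset[tuple[int, int]]

    def __post_init__(self):
        for i, j in self.contacts:
            if not (0 <= i < j < self.n_sites):
                raise ValueError(f"invalid contact pair ({i}, {j})")

    @property
    def matrix(self) -> np.ndarray:
        """Dense n×n Kirchhoff matrix (float array of integer values)."""
        g = np.zeros((self.n_sites, self.n_sites))
        for i, j in self.contacts:
            g[i, j] = g[j, i] = -1.0
        np.fill_diagonal(g, -g.sum(axis=1))
        return g

    @property
    def n_contacts(self) -> int:
        return len(self.contacts)

    def degree(self) -> np.ndarray:
        d = np.zeros(self.n_sites, dtype=int)
        for i, j in self.contacts:
            d[i] += 1
            d[j] += 1
        return d

    def without_contact(self, pair: tuple[int, int]) -> "KirchhoffTopology":
        pair = (min(pair), max(pair))
        if pair not in self.contacts:
            raise ValueError(f"{pair} is not a contact")
        return KirchhoffTopology(self.n_sites, self.cutoff_rc,
                                 self.contacts - {pair})


@dataclass(frozen=True)
class ModeDecomposition:
    """Eigendecomposition of a Kirchhoff matrix.

    Eigenvalues ascending; eigenvectors orthonormal columns with a
    deterministic sign (first non-negligible entry positive).  Modes with
    λ < zero_tolerance·λmax are flagged as zero modes — one per connected
    component of the contact graph.
    """

    eigenvalues: np.ndarray
    eigenvectors: np.ndarray
    zero_mode_count: int
    zero_tolerance: float

    @property
    def n_sites(self) -> int:
        return self.eigenvalues.shape[0]

    @property
    def nonzero_modes(self) -> np.ndarray:
        """Indices of the non-rigid modes, slowest first."""
        return np.arange(self.zero_mode_count, self.n_sites)

    def slowest_modes(self, k: int) -> np.ndarray:
        """Indices of the k slowest non-zero modes."""
        nz = self.nonzero_modes
        if k > nz.size:
            raise InvalidModeError(
                f"requested {k} slow modes but only {nz.size} non-zero modes exist")
        return nz[:k]

    def _check_subset(self, mode_subset: Sequence[int] | None) -> np.ndarray:
        if mode_subset is None:
            return self.nonzero_modes
        subset = np.asarray(list(mode_subset), dtype=int)
        if subset.size == 0:
            raise InvalidModeError("empty mode subset")
        if subset.min() < 0 or subset.max() >= self.n_sites:
            raise InvalidModeError("mode index out of range")
        if (subset < self.zero_mode_count).any():
            raise InvalidModeError("mode subset contains a zero (rigid-body) mode")
        return subset

    def pseudoinverse(self, mode_subset: Sequence[int] | None = None) -> np.ndarray:
        """Γ⁺ restricted to the given modes (all non-zero modes by default)."""
        subset = self._check_subset(mode_subset)
        u = self.eigenvectors[:, subset]
        return (u / self.eigenvalues[subset]) @ u.T


@dataclass(frozen=True)
class GammaFit:
    """Result of calibrating the spring constant against experiment."""

    gamma: float                # kBT/Å²
    pearson_r: float            # scale-free agreement of the two series
    method: str                 # "mean" or "lsq"


@dataclass(frozen=True)
class FluctuationReport:
    """All fluctuation statistics derived from one decomposition."""

    gamma: float
    msf: np.ndarray
    cross_correlation: np.ndarray
    bfactors: np.ndarray
    msfid: np.ndarray
    mode_subset: tuple[int, ...]


# ---------------------------------------------------------------------------

def build_kirchhoff(structure, cutoff_rc: float = DEFAULT_CUTOFF) -> KirchhoffTopology:
    """Build the contact topology of a structure at cutoff rc.

    A pair (i, j), i≠j, is a contact iff its Euclidean Cα–Cα distance is
    ≤ rc (inclusive boundary).
    """
    coords = structure.coordinates if hasattr(structure, "coordinates") else np.asarray(structure, float)
    n = coords.shape[0]
    if n < 2:
        raise ValueError("need at least 2 sites to build a network")
    if cutoff_rc <= 0:
        raise ValueError("cutoff_rc must be positive")
    d = squareform(pdist(coords))
    ii, jj = np.nonzero(np.triu(d <= cutoff_rc, k=1))
    contacts = frozenset((int(i), int(j)) for i, j in zip(ii, jj))
    return KirchhoffTopology(n, float(cutoff_rc), contacts)


def topology_from_contacts(
    n_sites: int,
    contacts: Iterable[tuple[int, int]],
    cutoff_rc: float = DEFAULT_CUTOFF,
) -> KirchhoffTopology:
    """Topology from an explicit contact list (for tests and replays)."""
    return KirchhoffTopology(
        n_sites, float(cutoff_rc),
        frozenset((min(i, j), max(i, j)) for i, j in contacts),
    )


def connected_component_count(topology: KirchhoffTopology) -> int:
    """Number of connected components of the contact graph."""
    from scipy.sparse import coo_matrix
    from scipy.sparse.csgraph import connected_components

    if not topology.contacts:
        return topology.n_sites
    rows, cols = zip(*topology.contacts)
    adj = coo_matrix(
        (np.ones(len(rows)), (rows, cols)),
        shape=(topology.n_sites, topology.n_sites),
    )
    ncomp, _ = connected_components(adj, directed=False)
    return int(ncomp)


def decompose(
    topology: KirchhoffTopology,
    zero_tolerance: float = ZERO_MODE_RTOL,
) -> ModeDecomposition:
    """Full eigendecomposition of the Kirchhoff matrix, ascending order."""
    gamma_matrix = topology.matrix
    vals, vecs = eigh(gamma_matrix)
    # deterministic sign: first entry of non-negligible magnitude positive
    for k in range(vecs.shape[1]):
        col = vecs[:, k]
        nz = np.nonzero(np.abs(col) > 1e-8 * np.abs(col).max())[0]
        if nz.size and col[nz[0]] < 0:
            vecs[:, k] = -col
    lam_max = float(vals[-1]) if vals.size else 0.0
    threshold = zero_tolerance * max(lam_max, 1.0)
    zero_count = int(np.sum(vals < threshold))
    return ModeDecomposition(vals, vecs, zero_count, zero_tolerance)


def residue_msf(
    decomp: ModeDecomposition,
    gamma: float = 1.0,
    mode_subset: Sequence[int] | None = None,
) -> np.ndarray:
    """Per-site mean-square fluctuation ⟨ΔRi²⟩ = (kBT/γ) Σₖ uₖ(i)²/λₖ."""
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    subset = decomp._check_subset(mode_subset)
    u = decomp.eigenvectors[:, subset]
    return (u**2 / decomp.eigenvalues[subset]).sum(axis=1) / gamma


def mode_subset_msf(
    decomp: ModeDecomposition,
    gamma: float = 1.0,
    k_slowest: int = 6,
) -> np.ndarray:
    """MSF restricted to the k slowest non-zero (collective) modes.

    The slowest modes carry the large-scale collective motions; summing a
    handful of them (six by default) isolates domain-level mobility from
    local geometric irregularity.
    """
    return residue_msf(decomp, gamma, decomp.slowest_modes(k_slowest))


def cross_correlation(
    decomp: ModeDecomposition,
    gamma: float = 1.0,
    mode_subset: Sequence[int] | None = None,
) -> np.ndarray:
    """Fluctuation cross-correlation matrix ⟨ΔRi·ΔRj⟩ = (kBT/γ)[Γ⁺]ij."""
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    return decomp.pseudoinverse(mode_subset) / gamma


def msfid_matrix(
    decomp: ModeDecomposition,
    gamma: float = 1.0,
    mode_subset: Sequence[int] | None = None,
) -> np.ndarray:
    """Mean-square fluctuation of inter-residue distances (MSFID).

    msfid(i,j) = (3kBT/γ)([Γ⁺]ii + [Γ⁺]jj − 2[Γ⁺]ij); symmetric with a zero
    diagonal.  Large entries mark flexible pairings — the basis of the
    contact-rupture criterion in the unfolding simulator.
    """
    g = cross_correlation(decomp, gamma, mode_subset)
    d = np.diag(g)
    m = MSFID_PREFACTOR * (d[:, None] + d[None, :] - 2.0 * g)
    np.fill_diagonal(m, 0.0)
    return m


def theoretical_bfactors(msf: np.ndarray) -> np.ndarray:
    """Debye–Waller B-factors Bi = (8π²/3)·⟨ΔRi²⟩, in Å²."""
    msf = np.asarray(msf, float)
    if (msf < 0).any():
        raise ValueError("mean-square fluctuations must be non-negative")
    return BFACTOR_PREFACTOR * msf


def fit_gamma(
    theoretical_shape: np.ndarray,
    experimental: np.ndarray,
    method: str = "mean",
) -> GammaFit:
    """Calibrate the spring constant γ against an experimental series.

    ``theoretical_shape`` is the per-site series (MSF or B-factors) computed
    at γ = 1; the model predicts ``theoretical_shape / γ``.  With the default
    mean-matching estimator, γ is chosen so the theoretical and experimental
    means coincide: γ = mean(theoretical) / mean(experimental).  The
    alternative ``method="lsq"`` minimizes the squared residuals instead.
    The Pearson correlation between the two series is reported as the
    scale-free measure of agreement.
    """
    th = np.asarray(theoretical_shape, float)
    ex = np.asarray(experimental, float)
    if th.shape != ex.shape or th.ndim != 1 or th.size < 2:
        raise ValueError("series must be 1-D, equal length >= 2")
    if not np.isfinite(ex).all():
        raise ValueError("experimental series contains non-finite values")
    if ex.mean() <= 0:
        raise ValueError("experimental mean must be positive")
    if method == "mean":
        gamma = th.mean() / ex.mean()
    elif method == "lsq":
        gamma = float(th @ th) / float(th @ ex)
    else:
        raise ValueError(f"unknown method {method!r}")
    r = float(np.corrcoef(th, ex)[0, 1])
    return GammaFit(float(gamma), r, method)


def fluctuation_report(
    decomp: ModeDecomposition,
    gamma: float = 1.0,
    mode_subset: Sequence[int] | None = None,
) -> FluctuationReport:
    """Bundle MSF, cross-correlations, B-factors and MSFID in one pass."""
    cc = cross_correlation(decomp, gamma, mode_subset)
    msf = np.diag(cc).copy()
    d = msf
    msfid = MSFID_PREFACTOR * (d[:, None] + d[None, :] - 2.0 * cc)
    np.fill_diagonal(msfid, 0.0)
    subset = decomp._check_subset(mode_subset)
    return FluctuationReport(
        gamma=float(gamma),
        msf=msf,
        cross_correlation=cc,
        bfactors=theoretical_bfactors(msf),
        msfid=msfid,
        mode_subset=tuple(int(k) for k in subset),
    )
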