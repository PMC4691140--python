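"""Iterative contact-breaking unfolding simulator.

Thermal unfolding is mimicked by rupturing native contacts one at a time in
order of their internal-distance fluctuation (MSFID): at each step the full
network is re-decomposed, the MSFID of every live breakable contact is
computed over all non-zero modes, and the contact with the largest value —
the loosest pairing — is deleted.  Re-decomposition after every rupture
captures the nonlinear softening of the network as it falls apart.
Backbone springs (sequence-adjacent sites within one chain) are covalent
and never rupture, so chains soften and fragment into domains but never
disperse into free residues.

Because the distance fluctuation of a pair grows linearly with temperature
while the rupture threshold is a fixed critical amplitude, the temperature
at which a contact breaks is inversely proportional to its per-kBT MSFID
coefficient.  The reduced temperature of the k-th rupture is therefore
reconstructed as T_k/T0 = m₁/m_k, where m_k is the MSFID of the pair broken
at step k and m₁ that of the very first rupture; the reported curve is the
running maximum of this ratio, so stretches where ruptures lower the raw
temperature read as cooperative cascades at constant temperature — the
sudden jumps of the melting curve.  This temperature mapping is a
reconstruction (see docs/methods.md); ranks and rupture order do not
depend on it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .gnm import (
    KirchhoffTopology,
    MSFID_PREFACTOR,
    decompose,
    cross_correlation,
)
from .structure_io import CoarseGrainedStructure

__all__ = [
    "UnfoldEvent",
    "UnfoldingTrajectory",
    "Jump",
    "MeltingSummary",
    "breakable_pairs",
    "unfold",
    "reduced_temperatures",
    "detect_jumps",
    "melting_summary",
    "DEFAULT_MIN_JUMP_SIZE",
    "DEFAULT_SNAPSHOT_LNNC",
]

DEFAULT_MIN_JUMP_SIZE = 20
"""Contacts that must break at one temperature to count as a cooperative jump."""

DEFAULT_SNAPSHOT_LNNC = (600, 990, 1310, 1470)
"""Default trajectory snapshot points, as loss numbers of native contacts."""


@dataclass(frozen=True)
class UnfoldEvent:
    """One rupture: step k breaks `pair` at MSFID `msfid` (kBT/γ units)."""

    step: int                    # 1-based
    pair: tuple[int, int]
    msfid: float
    lnnc: int                    # loss number of native contacts == step
    raw_t_over_t0: float
    t_over_t0: float             # running maximum of raw_t_over_t0


@dataclass
class UnfoldingTrajectory:
    """Ordered rupture events plus retained topology snapshots."""

    events: list[UnfoldEvent]
    initial_topology: KirchhoffTopology
    snapshots: dict[int, KirchhoffTopology] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.events)

    @property
    def msfid_sequence(self) -> np.ndarray:
        return np.array([e.msfid for e in self.events])

    @property
    def temperatures(self) -> np.ndarray:
        return np.array([e.t_over_t0 for e in self.events])

    def topology_at(self, lnnc: int) -> KirchhoffTopology:
        """Reconstruct the topology after the first `lnnc` ruptures."""
        if not 0 <= lnnc <= len(self.events):
            raise ValueError(f"lnnc {lnnc} outside trajectory of {len(self.events)}")
        contacts = set(self.initial_topology.contacts)
        for e in self.events[:lnnc]:
            contacts.discard(e.pair)
        return KirchhoffTopology(self.initial_topology.n_sites,
                                 self.initial_topology.cutoff_rc,
                                 frozenset(contacts))


@dataclass(frozen=True)
class Jump:
    """A cooperative rupture: ≥min_jump_size contacts at one temperature."""

    t_over_t0: float
    lnnc_before: int
    lnnc_after: int

    @property
    def size(self) -> int:
        return self.lnnc_after - self.lnnc_before


@dataclass
class MeltingSummary:
    """Per-domain rupture profile, unfolding order and melt temperatures."""

    rupture_steps: dict[str, list[int]]    # label -> steps breaking its internal contacts
    unfolding_order: list[str]             # labels by median internal rupture step
    melt_kelvin: dict[str, float]          # label -> T0·(T/T0) of its majority jump
    t0_kelvin: float
    excluded: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------

def breakable_pairs(
    topology: KirchhoffTopology,
    structure: CoarseGrainedStructure,
) -> set[tuple[int, int]]:
    """Contacts eligible for thermal rupture.

    Every contact except backbone pairs — sites adjacent in chain order
    within one chain — which model covalent bonds and never break.
    """
    backbone = structure.backbone_adjacent_pairs()
    return {p for p in topology.contacts if p not in backbone}


def _msfid_of_pairs(
    topology: KirchhoffTopology,
    pairs: Sequence[tuple[int, int]],
) -> np.ndarray:
    """MSFID (kBT/γ = 1 units) of the given pairs under the full spectrum."""
    decomp = decompose(topology)
    g = decomp.pseudoinverse()
    d = np.diag(g)
    idx = np.array(pairs)
    return MSFID_PREFACTOR * (d[idx[:, 0]] + d[idx[:, 1]] - 2.0 * g[idx[:, 0], idx[:, 1]])


def unfold(
    structure: CoarseGrainedStructure,
    topology: KirchhoffTopology | None = None,
    snapshot_lnnc: Iterable[int] = (),
) -> UnfoldingTrajectory:
    """Run the greedy rupture cascade until no breakable contact remains.

    Each step decomposes the current Kirchhoff matrix from scratch, computes
    the MSFID of all live breakable contacts over all non-zero modes, and
    deletes the maximal one (ties: lexicographically smallest pair).  The
    engine is fully deterministic.

    Parameters
    ----------
    structure : the Cα structure (supplies backbone adjacency).
    topology : starting topology; built from the structure at the default
        cutoff when omitted.
    snapshot_lnnc : loss numbers at which to retain a topology snapshot.
    """
    from .gnm import build_kirchhoff

    if topology is None:
        topology = build_kirchhoff(structure)
    requested = sorted(set(int(x) for x in snapshot_lnnc))
    breakable = breakable_pairs(topology, structure)

    events: list[UnfoldEvent] = []
    snapshots: dict[int, KirchhoffTopology] = {}
    current = topology
    live = sorted(breakable)
    step = 0
    while live:
        step += 1
        msfids = _msfid_of_pairs(current, live)
        if not np.isfinite(msfids).all() or (msfids <= 0).all():
            bad = live[int(np.argmax(~np.isfinite(msfids)))]
            raise ArithmeticError(
                f"degenerate MSFID at step {step} (pair {bad})")
        # lexicographic tie-break: values within 1e-12 relative of the max
        # count as tied (numerical noise breaks exact symmetry); `live` is
        # sorted, so the first tied entry is the smallest pair
        m_max = float(msfids.max())
        k = int(np.argmax(msfids >= m_max - 1e-12 * max(m_max, 1.0)))
        pair = live[k]
        current = current.without_contact(pair)
        live = live[:k] + live[k + 1:]
        events.append(UnfoldEvent(step, pair, float(msfids[k]), step,
                                  np.nan, np.nan))
        if step in requested:
            snapshots[step] = current

    for lnnc in requested:
        if lnnc > len(events):
            warnings.warn(
                f"snapshot at LNNC {lnnc} beyond final count {len(events)}; omitted",
                stacklevel=2,
            )

    if events:
        raw, reported = reduced_temperatures([e.msfid for e in events])
        events = [
            UnfoldEvent(e.step, e.pair, e.msfid, e.lnnc, float(r), float(t))
            for e, r, t in zip(events, raw, reported)
        ]
    return UnfoldingTrajectory(events, topology, snapshots)


def reduced_temperatures(msfid_sequence: Sequence[float]) -> tuple[np.ndarray, np.ndarray]:
    """Reconstruct rupture temperatures from the MSFID sequence.

    Returns ``(raw, reported)`` where ``raw[k] = m₁/m_k`` (m_k the MSFID of
    the k-th ruptured pair, per kBT/γ) and ``reported`` is its running
    maximum — non-decreasing, starting at exactly 1.0.  A raw value below
    the running maximum means the rupture happened during a cooperative
    cascade at the cascade's temperature.
    """
    m = np.asarray(msfid_sequence, float)
    if m.size == 0:
        raise ValueError("empty trajectory")
    bad = np.nonzero(~np.isfinite(m) | (m <= 0))[0]
    if bad.size:
        raise ArithmeticError(f"non-positive or non-finite MSFID at step {bad[0] + 1}")
    raw = m[0] / m
    return raw, np.maximum.accumulate(raw)


def detect_jumps(
    trajectory: UnfoldingTrajectory,
    min_jump_size: int = DEFAULT_MIN_JUMP_SIZE,
) -> list[Jump]:
    """Cooperative jumps: maximal runs of events at one reported temperature.

    A run of at least ``min_jump_size`` consecutive events sharing a single
    running-maximum temperature is a jump; strictly increasing temperatures
    produce none.
    """
    events = trajectory.events
    jumps: list[Jump] = []
    i = 0
    while i < len(events):
        j = i
        while j + 1 < len(events) and events[j + 1].t_over_t0 == events[i].t_over_t0:
            j += 1
        if j - i + 1 >= min_jump_size:
            jumps.append(Jump(events[i].t_over_t0, events[i].lnnc - 1, events[j].lnnc))
        i = j + 1
    return jumps


def melting_summary(
    trajectory: UnfoldingTrajectory,
    domain_indices: Mapping[str, Sequence[int]],
    t0_kelvin: float = 300.0,
    min_jump_size: int = DEFAULT_MIN_JUMP_SIZE,
) -> MeltingSummary:
    """Attribute ruptures to domains and estimate melt temperatures.

    A rupture is internal to a domain when both endpoints lie in the
    domain's index set.  Each domain's melt temperature is
    t0_kelvin × (T/T0) of the jump that breaks the largest share of its
    internal contacts; the unfolding order sorts domains by the median step
    at which their internal contacts break.  Domains with no internal
    breakable contact are excluded with a warning.
    """
    index_sets = {lab: set(idx) for lab, idx in domain_indices.items()}
    steps: dict[str, list[int]] = {lab: [] for lab in index_sets}
    for e in trajectory.events:
        i, j = e.pair
        for lab, s in index_sets.items():
            if i in s and j in s:
                steps[lab].append(e.step)

    excluded = [lab for lab, st in steps.items() if not st]
    for lab in excluded:
        warnings.warn(f"domain {lab!r} has no internal breakable contact; excluded",
                      stacklevel=2)
        del steps[lab]

    jumps = detect_jumps(trajectory, min_jump_size)
    melt: dict[str, float] = {}
    for lab, st in steps.items():
        if jumps:
            counts = [sum(1 for k in st if jp.lnnc_before < k <= jp.lnnc_after)
                      for jp in jumps]
            best = int(np.argmax(counts))
            if counts[best] > 0:
                melt[lab] = t0_kelvin * jumps[best].t_over_t0
                continue
        # no jump captures this domain: use the temperature at its median rupture
        med_step = int(np.median(st))
        melt[lab] = t0_kelvin * trajectory.events[med_step - 1].t_over_t0

    order = sorted(steps, key=lambda lab: (float(np.median(steps[lab])), lab))
    return MeltingSummary(steps, order, melt, float(t0_kelvin), excluded)
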