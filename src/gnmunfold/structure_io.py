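"""Coarse-grained structure input/output.

Reads Cα-level structures from PDB files, writes them back out, serializes
contact maps as plain-text pair lists, and resolves named residue-range
annotations (immunoglobulin domains, CDR loops) to site indices.

Only ATOM records are considered; HETATM, waters and all non-Cα atoms are
ignored.  Each site carries the author chain identifier, residue number with
insertion code, residue name, Cα coordinates in Å and, when present, the
crystallographic B-factor of the Cα atom in Å².
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gemmi
import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "Site",
    "CoarseGrainedStructure",
    "DomainAnnotation",
    "AnnotationError",
    "EmptyStructureError",
    "read_structure",
    "write_structure",
    "write_contact_map",
    "read_contact_map",
    "read_annotation",
    "default_fab_annotation",
    "resolve_annotation",
]


class EmptyStructureError(ValueError):
    """Raised when parsing/filtering leaves zero Cα sites."""


class AnnotationError(ValueError):
    """Raised when an annotation range resolves to no site."""


@dataclass(frozen=True)
class Site:
    """One Cα site: identity, position and optional experimental B-factor."""

    chain_id: str
    residue_number: int
    insertion_code: str
    residue_name: str
    position: tuple[float, float, float]
    experimental_bfactor: float | None = None

    @property
    def residue_key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.residue_number, self.insertion_code)


@dataclass
class CoarseGrainedStructure:
    """An ordered list of Cα sites in file order (0-based internal indices)."""

    sites: list[Site]
    source_label: str = ""

    def __post_init__(self) -> None:
        seen: set[tuple[str, int, str]] = set()
        for s in self.sites:
            if not all(math.isfinite(c) for c in s.position):
                raise ValueError(f"non-finite coordinates for site {s.residue_key}")
            if s.residue_key in seen:
                raise ValueError(f"duplicate residue identity {s.residue_key}")
            seen.add(s.residue_key)

    def __len__(self) -> int:
        return len(self.sites)

    @property
    def coordinates(self) -> np.ndarray:
        """(n, 3) array of Cα positions in Å."""
        return np.array([s.position for s in self.sites], dtype=float)

    @property
    def experimental_bfactors(self) -> np.ndarray:
        """(n,) array of experimental B-factors; NaN where absent."""
        return np.array(
            [math.nan if s.experimental_bfactor is None else s.experimental_bfactor
             for s in self.sites],
            dtype=float,
        )

    @property
    def chain_ids(self) -> list[str]:
        return [s.chain_id for s in self.sites]

    def with_bfactors(self, bfactors: Sequence[float]) -> "CoarseGrainedStructure":
        """Copy of the structure with the experimental B column replaced."""
        if len(bfactors) != len(self.sites):
            raise ValueError("bfactor vector length mismatch")
        sites = [
            Site(s.chain_id, s.residue_number, s.insertion_code, s.residue_name,
                 s.position, float(b))
            for s, b in zip(self.sites, bfactors)
        ]
        return CoarseGrainedStructure(sites, source_label=self.source_label)

    def backbone_adjacent_pairs(self) -> set[tuple[int, int]]:
        """Index pairs of consecutive sites within one chain.

        These model the covalent backbone: they are ordinary springs in the
        network but are never candidates for thermal rupture.
        """
        pairs: set[tuple[int, int]] = set()
        for i in range(len(self.sites) - 1):
            a, b = self.sites[i], self.sites[i + 1]
            if a.chain_id == b.chain_id:
                pairs.add((i, i + 1))
        return pairs


def _pick_altloc(atoms: list[gemmi.Atom]) -> gemmi.Atom:
    # highest occupancy wins; ties broken by altloc identifier order
    return min(atoms, key=lambda a: (-a.occ, a.altloc or ""))


def read_structure(
    path: str | Path,
    chain_filter: set[str] | None = None,
    model_index: int = 0,
) -> CoarseGrainedStructure:
    """Read a PDB file into a Cα-level structure.

    One site per residue possessing a Cα atom, in file order.  Residues with
    several Cα altlocs keep the highest-occupancy one (ties by altloc id).
    Residues lacking a Cα are skipped with a warning.  Only the requested
    model is read (the first by default).

    Parameters
    ----------
    path : path to a PDB file.
    chain_filter : if given, keep only sites from these chain ids.
    model_index : 0-based model to read from multi-model files.
    """
    path = Path(path)
    try:
        st = gemmi.read_pdb(str(path))
    except (RuntimeError, ValueError, OSError) as exc:
        raise ValueError(f"cannot parse PDB file {path}: {exc}") from exc
    if len(st) == 0:
        raise EmptyStructureError(f"no models in {path}")
    if model_index >= len(st):
        raise ValueError(f"model_index {model_index} out of range ({len(st)} models)")
    model = st[model_index]

    sites: list[Site] = []
    for chain in model:
        if chain_filter is not None and chain.name not in chain_filter:
            continue
        for residue in chain:
            if residue.het_flag != "A":  # ATOM records only
                continue
            cas = [a for a in residue if a.name == "CA" and a.element.name != "Ca"]
            if not cas:
                logger.warning(
                    "residue %s %d%s in %s has no CA atom; skipped",
                    residue.name, residue.seqid.num, residue.seqid.icode.strip(),
                    path.name,
                )
                continue
            atom = _pick_altloc(cas)
            sites.append(
                Site(
                    chain_id=chain.name,
                    residue_number=residue.seqid.num,
                    insertion_code=residue.seqid.icode.strip(),
                    residue_name=residue.name,
                    position=(atom.pos.x, atom.pos.y, atom.pos.z),
                    experimental_bfactor=float(atom.b_iso),
                )
            )
    if not sites:
        raise EmptyStructureError(f"no Cα sites after filtering in {path}")
    return CoarseGrainedStructure(sites, source_label=path.name)


def write_structure(structure: CoarseGrainedStructure, path: str | Path) -> None:
    """Write the Cα trace as a minimal single-model PDB file."""
    lines = []
    serial = 0
    for s in structure.sites:
        serial += 1
        b = 0.0 if s.experimental_bfactor is None else s.experimental_bfactor
        x, y, z = s.position
        lines.append(
            f"ATOM  {serial:>5} {'CA':^4}{'':1}{s.residue_name:>3} "
            f"{s.chain_id[:1]:1}{s.residue_number:>4}{s.insertion_code[:1]:1}   "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{b:6.2f}          "
            f"{'C':>2}  "
        )
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# contact-map serialization

_CONTACT_HEADER = "#i\tj"


def write_contact_map(topology, path: str | Path) -> None:
    """Write a topology's contact set as a tab-separated pair list.

    One 0-based index pair ``i<j`` per line, sorted lexicographically, after
    a single header line.  Round-trips losslessly through
    :func:`read_contact_map`.
    """
    pairs = sorted(tuple(sorted(p)) for p in topology.contacts)
    with open(path, "w") as fh:
        fh.write(_CONTACT_HEADER + "\n")
        for i, j in pairs:
            fh.write(f"{i}\t{j}\n")


def read_contact_map(path: str | Path) -> set[tuple[int, int]]:
    """Read a contact-pair file written by :func:`write_contact_map`."""
    contacts: set[tuple[int, int]] = set()
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        i_s, j_s = line.split("\t")
        i, j = int(i_s), int(j_s)
        contacts.add((min(i, j), max(i, j)))
    return contacts


# ---------------------------------------------------------------------------
# domain / CDR annotations

def _range_key(num: int, icode: str) -> tuple[int, str]:
    # insertion codes sort after the bare number: 100 < 100A < 100B
    return (num, icode)


@dataclass(frozen=True)
class ResidueRange:
    """An inclusive author-numbered residue range on one chain."""

    label: str
    chain_id: str
    start: int
    end: int
    start_icode: str = ""
    end_icode: str = ""

    def contains(self, site: Site) -> bool:
        if site.chain_id != self.chain_id:
            return False
        key = _range_key(site.residue_number, site.insertion_code)
        return (_range_key(self.start, self.start_icode) <= key
                <= _range_key(self.end, self.end_icode))


@dataclass
class DomainAnnotation:
    """Named residue ranges (domains, CDR loops) on author numbering."""

    ranges: list[ResidueRange] = field(default_factory=list)

    def labels(self) -> list[str]:
        seen: list[str] = []
        for r in self.ranges:
            if r.label not in seen:
                seen.append(r.label)
        return seen


def _parse_resid(token: str) -> tuple[int, str]:
    """Split '100' / '100A' into (100, '') / (100, 'A')."""
    token = token.strip()
    if token and token[-1].isalpha():
        return int(token[:-1]), token[-1]
    return int(token), ""


def read_annotation(path: str | Path) -> DomainAnnotation:
    """Read a plain-text annotation: ``label chain start end`` per line.

    Blank lines and ``#`` comments are ignored; start/end may carry an
    insertion code suffix (e.g. ``100A``).
    """
    ranges: list[ResidueRange] = []
    for line in Path(path).read_text().splitlines():
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        label, chain, start_s, end_s = line.split()
        start, s_ic = _parse_resid(start_s)
        end, e_ic = _parse_resid(end_s)
        ranges.append(ResidueRange(label, chain, start, end, s_ic, e_ic))
    return DomainAnnotation(ranges)


def default_fab_annotation(light_chain: str = "L", heavy_chain: str = "H") -> DomainAnnotation:
    """Fab-fragment defaults: the four Ig domains and the six CDR loops.

    CDR ranges follow the standard hypervariable-loop numbering for this
    antibody: L1 26–37, L2 56–61, L3 97–102 on the light chain and H1 28–32,
    H2 50–58, H3 102–109 on the heavy chain.  The VL/CL/VH/CH1 boundaries are
    conventional immunoglobulin domain limits on author numbering; override
    them with :func:`read_annotation` if the structure deviates.
    """
    L, H = light_chain, heavy_chain
    return DomainAnnotation([
        ResidueRange("VL", L, 1, 110),
        ResidueRange("CL", L, 111, 214),
        ResidueRange("VH", H, 1, 118),
        ResidueRange("CH", H, 119, 220),
        ResidueRange("L1", L, 26, 37),
        ResidueRange("L2", L, 56, 61),
        ResidueRange("L3", L, 97, 102),
        ResidueRange("H1", H, 28, 32),
        ResidueRange("H2", H, 50, 58),
        ResidueRange("H3", H, 102, 109),
    ])


def resolve_annotation(
    annotation: DomainAnnotation,
    structure: CoarseGrainedStructure,
) -> dict[str, list[int]]:
    """Map each annotation label to the sorted 0-based site indices it covers.

    Ranges are inclusive on both ends, on author (PDB) numbering per chain.
    A label may span several ranges (its index sets are unioned).  A label
    resolving to zero sites raises :class:`AnnotationError`.
    """
    out: dict[str, set[int]] = {lab: set() for lab in annotation.labels()}
    for rng in annotation.ranges:
        for idx, site in enumerate(structure.sites):
            if rng.contains(site):
                out[rng.label].add(idx)
    for lab, idxs in out.items():
        if not idxs:
            raise AnnotationError(f"annotation label {lab!r} resolves to no site")
    return {lab: sorted(idxs) for lab, idxs in out.items()}
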