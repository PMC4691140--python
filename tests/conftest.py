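import numpy as np
import pytest

from gnmunfold.gnm import KirchhoffTopology, topology_from_contacts


def pdb_atom_line(serial, name, resname, chain, resnum, x, y, z,
                  occ=1.0, b=0.0, altloc=" ", icode=" ", element="C"):
    """One fixed-column PDB ATOM record."""
    return (
        f"ATOM  {serial:>5} {name:^4}{altloc}{resname:>3} {chain}"
        f"{resnum:>4}{icode}   {x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{b:6.2f}"
        f"          {element:>2}  "
    )


@pytest.fixture
def three_residue_pdb(tmp_path):
    """Three Cα-only residues on two chains with B-factors 10/20/30."""
    lines = [
        pdb_atom_line(1, "CA", "ALA", "A", 1, 0.0, 0.0, 0.0, b=10.0),
        pdb_atom_line(2, "CA", "GLY", "H", 2, 3.8, 0.0, 0.0, b=20.0),
        pdb_atom_line(3, "CA", "SER", "A", 3, 7.6, 0.0, 0.0, b=30.0),
        "END",
    ]
    path = tmp_path / "three.pdb"
    path.write_text("\n".join(lines) + "\n")
    return path


def random_connected_topology(n, rng, extra_edge_prob=0.15):
    """Random single-chain-like topology: a backbone path plus random chords.

    Connected by construction, so it carries exactly one zero mode.
    """
    contacts = {(i, i + 1) for i in range(n - 1)}
    for i in range(n):
        for j in range(i + 2, n):
            if rng.random() < extra_edge_prob:
                contacts.add((i, j))
    return topology_from_contacts(n, contacts)


def dense_pseudoinverse(topology: KirchhoffTopology) -> np.ndarray:
    """Independent oracle: Moore–Penrose pseudoinverse of the dense matrix."""
    return np.linalg.pinv(topology.matrix, hermitian=True)
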