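from __future__ import annotations

import numpy as np
import pytest

from sh2fp.structure import Atom, Frame, Residue, Trajectory
from sh2fp.synth import table1_style_fixture

from oracles import ORACLE_ROLES


def make_residue(name3: str, number: int, chain: str,
                 atoms: list[tuple[str, tuple[float, float, float]]],
                 serial_start: int = 1) -> Residue:
    """Build a residue from (atom name, xyz) pairs; elements derived."""
    res = Residue(name3=name3, number=number, chain=chain)
    for i, (name, xyz) in enumerate(atoms):
        element = "H" if name.lstrip("0123456789").startswith("H") else \
            name.lstrip("0123456789")[0]
        res.atoms.append(Atom(serial=serial_start + i, name=name,
                              element=element, coords=np.array(xyz)))
    return res


def two_atom_frame(lig_res: str, lig_atom: str, rec_res: str, rec_atom: str,
                   separation: float) -> Frame:
    """One ligand atom at the origin, one receptor atom at (separation, 0, 0)."""
    return Frame(index=0, residues=[
        make_residue(lig_res, 1, "B", [(lig_atom, (0.0, 0.0, 0.0))]),
        make_residue(rec_res, 2, "A", [(rec_atom, (separation, 0.0, 0.0))],
                     serial_start=10),
    ])


def random_two_chain_frame(rng: np.random.Generator,
                           n_residues_per_chain: int = 6,
                           box: float = 18.0) -> Frame:
    """Random whole residues from the oracle vocabulary, two chains."""
    vocab = sorted(ORACLE_ROLES)
    residues = []
    serial = 1
    for ci, chain in enumerate(("B", "A")):
        for ri in range(n_residues_per_chain):
            name3 = vocab[int(rng.integers(len(vocab)))]
            center = rng.uniform(0.0, box, size=3)
            atoms = []
            for aname in ORACLE_ROLES[name3]:
                atoms.append((aname, tuple(center + rng.uniform(-1.5, 1.5, 3))))
            residues.append(make_residue(name3, 100 * ci + ri + 1, chain,
                                         atoms, serial_start=serial))
            serial += len(atoms)
    return Frame(index=0, residues=residues)


@pytest.fixture(scope="session")
def table1_fixture():
    """(trajectory, ground truth, peptide) of the canned three-region fixture."""
    return table1_style_fixture(n_frames=100, seed=1)


@pytest.fixture()
def single_frame_trajectory() -> Trajectory:
    frame = two_atom_frame("ASP", "OD1", "LYS", "NZ", 2.8)
    return Trajectory(frames=[frame])
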