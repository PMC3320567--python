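"""Coordinate model and I/O for multi-frame receptor/peptide complexes.

A :class:`Trajectory` is an ordered list of :class:`Frame` objects sharing a
single topology (same chains, residues and atom names in every frame); each
frame corresponds to one ``MODEL`` of a multi-model PDB file, i.e. one saved
snapshot of a molecular-dynamics run.  Frame spacing ``dt`` defaults to 1 ps
when a file format cannot carry it.

Two on-disk formats are supported:

``pdb_multimodel``
    standard PDB with ``MODEL``/``ENDMDL`` records (read and written through
    gemmi); phosphotyrosine ``PTR`` is accepted as either ``ATOM`` or
    ``HETATM``.
``frame_table``
    a flat CSV with header ``frame,chain,resnum,resname,atomname,x,y,z``,
    one row per atom per frame — convenient for hand-built tests.

Alternate-location indicators other than blank or ``A`` are dropped on read.
Insertion codes are rejected.  Inputs are assumed imaged/unwrapped; there is
no periodic-boundary handling.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np
import pandas as pd

FRAME_TABLE_COLUMNS = ["frame", "chain", "resnum", "resname", "atomname", "x", "y", "z"]


class MalformedRecordError(ValueError):
    """A structure file record could not be parsed (message names the line)."""


class TopologyError(ValueError):
    """Frames of one trajectory do not share an identical topology."""


class UnknownChainError(KeyError):
    """A requested chain id is absent from the frame."""


@dataclass
class Atom:
    serial: int
    name: str
    element: str
    coords: np.ndarray

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise ValueError(f"atom {self.name!r}: coords must be a finite 3-vector")
        if not self.name:
            raise ValueError("atom name must be non-empty")
        if not self.element:
            self.element = element_from_name(self.name)

    @property
    def is_hydrogen(self) -> bool:
        return self.element.upper() in ("H", "D")


@dataclass
class Residue:
    name3: str
    number: int
    chain: str
    atoms: list[Atom] = field(default_factory=list)

    def atom(self, name: str) -> Atom:
        for a in self.atoms:
            if a.name == name:
                return a
        raise KeyError(f"{self.chain}/{self.name3}{self.number} has no atom {name!r}")

    def heavy_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if not a.is_hydrogen]

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain, self.number, self.name3)


@dataclass
class Frame:
    index: int
    residues: list[Residue] = field(default_factory=list)

    def chains(self) -> list[str]:
        seen: list[str] = []
        for r in self.residues:
            if r.chain not in seen:
                seen.append(r.chain)
        return seen

    def topology_signature(self) -> tuple:
        return tuple(
            (r.chain, r.number, r.name3, tuple(a.name for a in r.atoms))
            for r in self.residues
        )

    def n_atoms(self) -> int:
        return sum(len(r.atoms) for r in self.residues)

    def residue(self, chain: str, number: int) -> Residue:
        for r in self.residues:
            if r.chain == chain and r.number == number:
                return r
        raise KeyError(f"no residue {chain}/{number} in frame {self.index}")


@dataclass
class Trajectory:
    frames: list[Frame]
    dt: float | None = None  # ps between frames; None means unknown (treat as 1 ps)

    def __post_init__(self) -> None:
        if not self.frames:
            raise ValueError("a trajectory needs at least one frame")
        validate_topology(self.frames)

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def dt_ps(self) -> float:
        return 1.0 if self.dt is None else self.dt

    def equals(self, other: "Trajectory", atol: float = 0.0) -> bool:
        if self.n_frames != other.n_frames:
            return False
        if self.frames[0].topology_signature() != other.frames[0].topology_signature():
            return False
        for fa, fb in zip(self.frames, other.frames):
            ca = np.array([a.coords for r in fa.residues for a in r.atoms])
            cb = np.array([a.coords for r in fb.residues for a in r.atoms])
            if not np.allclose(ca, cb, atol=atol, rtol=0.0):
                return False
        return True


def element_from_name(atom_name: str) -> str:
    """Derive the element symbol from a PDB atom name (digits stripped)."""
    stripped = atom_name.lstrip("0123456789 ")
    if not stripped:
        raise ValueError(f"cannot derive element from atom name {atom_name!r}")
    return stripped[0].upper()


def validate_topology(frames: list[Frame]) -> None:
    """Enforce identical topology across frames; never silently repair."""
    ref = frames[0].topology_signature()
    keys = [(r.chain, r.number) for r in frames[0].residues]
    if len(set(keys)) != len(keys):
        dup = next(k for k in keys if keys.count(k) > 1)
        raise TopologyError(f"duplicate residue {dup[0]}/{dup[1]} within a frame")
    for fr in frames[1:]:
        if fr.topology_signature() != ref:
            raise TopologyError(
                f"frame {fr.index} topology differs from frame 0; "
                "all MODELs must contain the same atoms"
            )


# ---------------------------------------------------------------------------
# reading

def read_trajectory(path: str | Path, format: str = "pdb_multimodel",
                    dt: float | None = None) -> Trajectory:
    """Read a trajectory; frames appear in file order (frame i = file model i)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "pdb_multimodel":
        return _read_pdb(path, dt)
    if format == "frame_table":
        return _read_frame_table(path, dt)
    raise ValueError(f"unknown trajectory format {format!r}")


def _prevalidate_pdb(path: Path) -> None:
    # gemmi is permissive; this scan produces the line-numbered diagnostics
    # for truncated records and insertion codes before handing off to it.
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6].strip()
            if rec not in ("ATOM", "HETATM"):
                continue
            if len(line.rstrip("\n")) < 54:
                raise MalformedRecordError(
                    f"{path}:{lineno}: {rec} record shorter than coordinate fields")
            try:
                int(line[22:26])
                float(line[30:38]); float(line[38:46]); float(line[46:54])
            except ValueError:
                raise MalformedRecordError(
                    f"{path}:{lineno}: unparseable serial/resnum/coordinates") from None
            if line[26] != " ":
                raise MalformedRecordError(
                    f"{path}:{lineno}: insertion codes are not supported")


def _read_pdb(path: Path, dt: float | None) -> Trajectory:
    _prevalidate_pdb(path)
    st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    if len(st) == 0:
        raise MalformedRecordError(f"{path}: no MODEL/ATOM records found")
    frames: list[Frame] = []
    for mi, model in enumerate(st):
        residues: list[Residue] = []
        for chain in model:
            for res in chain:
                atoms = []
                for a in res:
                    if a.altloc not in ("\0", "", "A"):
                        continue
                    atoms.append(Atom(
                        serial=a.serial,
                        name=a.name,
                        element=a.element.name if a.element.name != "X"
                        else element_from_name(a.name),
                        coords=np.array([a.pos.x, a.pos.y, a.pos.z]),
                    ))
                if atoms:
                    residues.append(Residue(res.name, res.seqid.num, chain.name, atoms))
        frames.append(Frame(index=mi, residues=residues))
    try:
        return Trajectory(frames=frames, dt=dt)
    except TopologyError as exc:
        raise TopologyError(f"{path}: {exc}") from None


def _read_frame_table(path: Path, dt: float | None) -> Trajectory:
    df = pd.read_csv(path)
    missing = [c for c in FRAME_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise MalformedRecordError(f"{path}: missing frame_table columns {missing}")
    if df.empty:
        raise MalformedRecordError(f"{path}: empty frame table")
    frames: list[Frame] = []
    for fi, (fval, sub) in enumerate(df.groupby("frame", sort=True)):
        residues: list[Residue] = []
        current: Residue | None = None
        for serial, row in enumerate(sub.itertuples(index=False), start=1):
            key = (str(row.chain), int(row.resnum), str(row.resname))
            if current is None or current.key != key:
                current = Residue(name3=key[2], number=key[1], chain=key[0])
                residues.append(current)
            name = str(row.atomname)
            current.atoms.append(Atom(
                serial=serial, name=name, element=element_from_name(name),
                coords=np.array([row.x, row.y, row.z])))
        frames.append(Frame(index=fi, residues=residues))
    return Trajectory(frames=frames, dt=dt)


# ---------------------------------------------------------------------------
# writing

def write_trajectory(traj: Trajectory, path: str | Path,
                     format: str = "pdb_multimodel") -> Path:
    """Write a trajectory; round-trips identifiers exactly and coordinates to
    3 decimals (PDB precision)."""
    path = Path(path)
    if format == "pdb_multimodel":
        _write_pdb(traj, path)
    elif format == "frame_table":
        _write_frame_table(traj, path)
    else:
        raise ValueError(f"unknown trajectory format {format!r}")
    return path


_STANDARD_AA = set(
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO "
    "SER THR TRP TYR VAL".split())


def _write_pdb(traj: Trajectory, path: Path) -> None:
    st = gemmi.Structure()
    st.name = "sh2fp"
    for fr in traj.frames:
        model = gemmi.Model(fr.index + 1)
        chains: dict[str, gemmi.Chain] = {}
        for res in fr.residues:
            ch = chains.get(res.chain)
            if ch is None:
                ch = gemmi.Chain(res.chain)
                chains[res.chain] = ch
            gres = gemmi.Residue()
            gres.name = res.name3
            gres.seqid = gemmi.SeqId(res.number, " ")
            gres.het_flag = "A" if res.name3 in _STANDARD_AA else "H"
            for a in res.atoms:
                ga = gemmi.Atom()
                ga.name = a.name
                ga.element = gemmi.Element(a.element)
                ga.pos = gemmi.Position(*(float(round(c, 3)) for c in a.coords))
                gres.add_atom(ga)
            ch.add_residue(gres)
        for ch in chains.values():
            model.add_chain(ch)
        st.add_model(model)
    st.setup_entities()
    st.write_pdb(str(path))


def _write_frame_table(traj: Trajectory, path: Path) -> None:
    rows = []
    for fr in traj.frames:
        for res in fr.residues:
            for a in res.atoms:
                rows.append((fr.index, res.chain, res.number, res.name3, a.name,
                             a.coords[0], a.coords[1], a.coords[2]))
    pd.DataFrame(rows, columns=FRAME_TABLE_COLUMNS).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# selections

def select_residues(frame: Frame, chain: str) -> list[Residue]:
    """Residues of one chain in ascending sequence-number order."""
    found = [r for r in frame.residues if r.chain == chain]
    if not found:
        raise UnknownChainError(
            f"chain {chain!r} not in frame {frame.index}; "
            f"available chains: {frame.chains()}")
    return sorted(found, key=lambda r: r.number)
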