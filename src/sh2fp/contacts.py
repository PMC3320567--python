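"""Per-frame geometric detection of ligand/receptor contacts.

Three interaction kinds are detected between a ligand chain (the
phosphopeptide) and a receptor chain (the SH2 domain), with the cutoffs used
for VMD-style trajectory analysis of SH2-phosphopeptide complexes:

* salt bridge — anionic oxygen / cationic nitrogen pairs at <= 3.2 A;
* hydrogen bond — donor/acceptor heavy-atom pairs at <= 3.0 A with a
  donor-H-acceptor angle >= 120 deg (180 deg = linear) whenever the donor
  carries at least one hydrogen in the structure; hydrogen-free structures
  fall back to the distance criterion alone and record no angle;
* hydrophobic — apolar heavy-atom pairs at <= 5.0 A.

All cutoff comparisons are inclusive.  Only cross-chain pairs are evaluated.
An atom pair reported as a salt bridge in a frame is not double-reported as
a hydrogen bond in the same frame.  Donor-bound hydrogens are identified
geometrically (element H within ``H_BOND_LENGTH_MAX`` of the donor heavy
atom) rather than by name tables.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from . import chemistry
from .structure import Frame, Residue, Trajectory, select_residues

log = logging.getLogger(__name__)

#: tolerance absorbing binary rounding of decimal coordinates at the cutoffs
EPS = 1e-9

#: a hydrogen within this distance of a donor heavy atom is bonded to it
H_BOND_LENGTH_MAX = 1.25

KINDS = ("saltbridge", "hbond", "hydrophobic")


@dataclass(frozen=True)
class DetectionParams:
    """Geometric cutoffs; defaults are the standard VMD-style values."""

    saltbridge_cutoff: float = 3.2   # A, O..N of charged residues
    hbond_cutoff: float = 3.0        # A, donor..acceptor heavy atoms
    hbond_angle_min: float = 120.0   # deg, D-H-A (180 = linear)
    hydrophobic_cutoff: float = 5.0  # A, apolar heavy atoms
    protonated_his: bool = False     # treat His ND1/NE2 as cationic

    def __post_init__(self) -> None:
        for name in ("saltbridge_cutoff", "hbond_cutoff", "hydrophobic_cutoff"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 < self.hbond_angle_min <= 180.0:
            raise ValueError("hbond_angle_min must be in (0, 180]")

    def cutoff_for(self, kind: str) -> float:
        return {"saltbridge": self.saltbridge_cutoff,
                "hbond": self.hbond_cutoff,
                "hydrophobic": self.hydrophobic_cutoff}[kind]


@dataclass(frozen=True)
class AtomRef:
    """Identity of one atom within a frame."""

    chain: str
    resnum: int
    resname: str
    atomname: str
    serial: int


@dataclass(frozen=True)
class ContactEvent:
    frame: int
    ligand_atom: AtomRef
    receptor_atom: AtomRef
    kind: str
    distance: float
    angle: float | None = None

    @property
    def pair_key(self) -> tuple[tuple[str, int, str], tuple[str, int, str]]:
        la, ra = self.ligand_atom, self.receptor_atom
        return ((la.chain, la.resnum, la.resname), (ra.chain, ra.resnum, ra.resname))


class _ChainSelection:
    """Heavy atoms of one chain with chemistry masks, plus its hydrogens."""

    def __init__(self, frame: Frame, chain: str, params: DetectionParams):
        self.refs: list[AtomRef] = []
        coords: list[np.ndarray] = []
        anion, cation, donor, acceptor, apolar = [], [], [], [], []
        h_coords: list[np.ndarray] = []
        h_res: list[tuple[str, int]] = []
        for res in select_residues(frame, chain):
            for a in res.atoms:
                if a.is_hydrogen:
                    h_coords.append(a.coords)
                    h_res.append((res.chain, res.number))
                    continue
                self.refs.append(AtomRef(res.chain, res.number, res.name3,
                                         a.name, a.serial))
                coords.append(a.coords)
                anion.append(chemistry.is_anionic_oxygen(res.name3, a.name))
                cation.append(chemistry.is_cationic_nitrogen(
                    res.name3, a.name, params.protonated_his))
                donor.append(chemistry.is_hbond_donor(res.name3, a.name))
                acceptor.append(chemistry.is_hbond_acceptor(res.name3, a.name))
                apolar.append(chemistry.is_apolar(res.name3, a.name))
        self.coords = np.array(coords) if coords else np.empty((0, 3))
        self.anion = np.array(anion, dtype=bool)
        self.cation = np.array(cation, dtype=bool)
        self.donor = np.array(donor, dtype=bool)
        self.acceptor = np.array(acceptor, dtype=bool)
        self.apolar = np.array(apolar, dtype=bool)
        self.h_coords = np.array(h_coords) if h_coords else np.empty((0, 3))
        self.h_res = h_res

    def hydrogens_on(self, idx: int) -> np.ndarray:
        """Coordinates of hydrogens bonded to heavy atom ``idx`` (same residue)."""
        if len(self.h_coords) == 0:
            return np.empty((0, 3))
        ref = self.refs[idx]
        same = np.array([hr == (ref.chain, ref.resnum) for hr in self.h_res])
        if not same.any():
            return np.empty((0, 3))
        cand = self.h_coords[same]
        d = np.linalg.norm(cand - self.coords[idx], axis=1)
        return cand[d <= H_BOND_LENGTH_MAX]


def _sorted(events: list[ContactEvent]) -> list[ContactEvent]:
    return sorted(events, key=lambda e: (e.ligand_atom.serial,
                                         e.receptor_atom.serial, e.kind))


def _masked_pairs(lig: _ChainSelection, rec: _ChainSelection,
                  lig_mask: np.ndarray, rec_mask: np.ndarray,
                  cutoff: float):
    """Yield (i, j, distance) over masked cross-chain pairs within cutoff."""
    li = np.flatnonzero(lig_mask)
    rj = np.flatnonzero(rec_mask)
    if len(li) == 0 or len(rj) == 0:
        return
    d = cdist(lig.coords[li], rec.coords[rj])
    for a, b in zip(*np.nonzero(d <= cutoff + EPS)):
        yield int(li[a]), int(rj[b]), float(d[a, b])


def detect_salt_bridges(frame: Frame, ligand_chain: str, receptor_chain: str,
                        params: DetectionParams = DetectionParams()) -> list[ContactEvent]:
    """Anionic-O / cationic-N cross-chain pairs within the salt-bridge cutoff."""
    lig = _ChainSelection(frame, ligand_chain, params)
    rec = _ChainSelection(frame, receptor_chain, params)
    events = []
    for lmask, rmask in ((lig.anion, rec.cation), (lig.cation, rec.anion)):
        for i, j, d in _masked_pairs(lig, rec, lmask, rmask, params.saltbridge_cutoff):
            events.append(ContactEvent(frame.index, lig.refs[i], rec.refs[j],
                                       "saltbridge", d))
    return _sorted(events)


def _dha_angle(donor: np.ndarray, hydrogens: np.ndarray,
               acceptor: np.ndarray) -> float | None:
    """Largest donor-H-acceptor angle in degrees; None without hydrogens."""
    if len(hydrogens) == 0:
        return None
    v1 = donor - hydrogens
    v2 = acceptor - hydrogens
    cosang = np.sum(v1 * v2, axis=1) / (
        np.linalg.norm(v1, axis=1) * np.linalg.norm(v2, axis=1))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))).max())


def detect_hydrogen_bonds(frame: Frame, ligand_chain: str, receptor_chain: str,
                          params: DetectionParams = DetectionParams()) -> list[ContactEvent]:
    """Donor/acceptor heavy-atom pairs within cutoff passing the angle test.

    One event is emitted per (ligand atom, receptor atom) pair if *either*
    donor->acceptor assignment satisfies the criteria; the recorded angle is
    the best passing D-H-A angle, or None when the pair qualified through a
    hydrogen-free donor.
    """
    lig = _ChainSelection(frame, ligand_chain, params)
    rec = _ChainSelection(frame, receptor_chain, params)
    suppressed = {(e.ligand_atom, e.receptor_atom)
                  for e in detect_salt_bridges(frame, ligand_chain,
                                               receptor_chain, params)}
    candidates: dict[tuple[int, int], float] = {}
    for lmask, rmask in ((lig.donor, rec.acceptor), (lig.acceptor, rec.donor)):
        for i, j, d in _masked_pairs(lig, rec, lmask, rmask, params.hbond_cutoff):
            candidates[(i, j)] = d
    events = []
    for (i, j), d in candidates.items():
        if (lig.refs[i], rec.refs[j]) in suppressed:
            continue
        passed = False
        best_angle: float | None = None
        assignments = []
        if lig.donor[i] and rec.acceptor[j]:
            assignments.append((lig.coords[i], lig.hydrogens_on(i), rec.coords[j]))
        if rec.donor[j] and lig.acceptor[i]:
            assignments.append((rec.coords[j], rec.hydrogens_on(j), lig.coords[i]))
        for dxyz, hxyz, axyz in assignments:
            ang = _dha_angle(dxyz, hxyz, axyz)
            if ang is None:
                passed = True  # hydrogen-free donor: distance criterion alone
            elif ang >= params.hbond_angle_min - EPS:
                passed = True
                if best_angle is None or ang > best_angle:
                    best_angle = ang
        if passed:
            events.append(ContactEvent(frame.index, lig.refs[i], rec.refs[j],
                                       "hbond", d, best_angle))
    return _sorted(events)


def detect_hydrophobic(frame: Frame, ligand_chain: str, receptor_chain: str,
                       params: DetectionParams = DetectionParams()) -> list[ContactEvent]:
    """Apolar heavy-atom cross-chain pairs within the hydrophobic cutoff."""
    lig = _ChainSelection(frame, ligand_chain, params)
    rec = _ChainSelection(frame, receptor_chain, params)
    events = [
        ContactEvent(frame.index, lig.refs[i], rec.refs[j], "hydrophobic", d)
        for i, j, d in _masked_pairs(lig, rec, lig.apolar, rec.apolar,
                                     params.hydrophobic_cutoff)
    ]
    return _sorted(events)


def detect_frame(frame: Frame, ligand_chain: str, receptor_chain: str,
                 params: DetectionParams = DetectionParams()) -> list[ContactEvent]:
    """All three detectors on one frame, in deterministic order."""
    events = (detect_salt_bridges(frame, ligand_chain, receptor_chain, params)
              + detect_hydrogen_bonds(frame, ligand_chain, receptor_chain, params)
              + detect_hydrophobic(frame, ligand_chain, receptor_chain, params))
    return _sorted(events)


def detect_all(traj: Trajectory, ligand_chain: str, receptor_chain: str,
               params: DetectionParams = DetectionParams()) -> list[ContactEvent]:
    """Concatenated per-frame detections ordered by (frame, serials, kind).

    A chain absent from the trajectory yields an empty event list with a
    warning instead of an error, so pipelines over peptide-free systems
    degrade gracefully.
    """
    chains = traj.frames[0].chains()
    for chain, label in ((ligand_chain, "ligand"), (receptor_chain, "receptor")):
        if chain not in chains:
            msg = (f"{label} chain {chain!r} absent from trajectory "
                   f"(chains: {chains}); no contacts detected")
            log.warning(msg)
            warnings.warn(msg, stacklevel=2)
            return []
    events: list[ContactEvent] = []
    for frame in traj.frames:
        events.extend(detect_frame(frame, ligand_chain, receptor_chain, params))
    return events


def min_heavy_distance(res_a: Residue, res_b: Residue) -> float:
    """Minimum heavy-atom distance between two residues."""
    a = np.array([x.coords for x in res_a.heavy_atoms()])
    b = np.array([x.coords for x in res_b.heavy_atoms()])
    return float(cdist(a, b).min())
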