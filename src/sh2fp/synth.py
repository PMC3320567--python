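"""Synthetic multi-frame complexes with planted contacts and ground truth.

The generator emulates the statistical structure of a solute-only MD
trajectory of a receptor/phosphopeptide complex: a fixed topology whose
planted atom pairs sit inside their contact cutoff in a scheduled fraction
of frames ("on" frames) and far outside it otherwise, with isotropic
Gaussian positional jitter on every atom.  It makes no attempt at physical
realism (an explicit non-goal): residues are built from schematic
axis-oriented templates in which the planted key atom forms the tip facing
the opposing chain and every other heavy atom sits at least ``TAIL_GAP``
angstroms behind it along the contact axis.  Together with a >=
``LANE_SPACING`` separation between ligand residues and an >= 8 A clearance
for unplanted residues, this guarantees that the planted contacts are the
*only* cross-chain contacts of any kind — so the returned
:class:`GroundTruth` is exact, not approximate.

Schedules are either ``deterministic`` (round(occupancy x n_frames) evenly
spaced on-frames) or ``bernoulli`` (i.i.d. per frame).  All randomness
derives from the single spec seed; each contact gets an independent
substream keyed by its index.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import chemistry
from .contacts import DetectionParams
from .occupancy import ResKey, _side_of
from .peptides import make_peptide
from .structure import Atom, Frame, Residue, Trajectory

TAIL_GAP = 3.5        # A between a key atom and its residue's other atoms
LANE_SPACING = 14.0   # A between ligand residues
FAR_OFFSET = 30.0     # A: x-placement of unplanted residues
DEFAULT_OFF_DISTANCE = 8.0

_DEFAULT_ON = {"saltbridge": 2.8, "hbond": 2.9, "hydrophobic": 4.5}


class SyntheticSpecError(ValueError):
    """Invalid or geometrically conflicting synthetic specification."""


@dataclass(frozen=True)
class ResidueSpec:
    name3: str
    number: int
    key_atom: str | None = None


@dataclass(frozen=True)
class PlantedContact:
    ligand: ResidueSpec
    receptor: ResidueSpec
    kind: str  # saltbridge | hbond | hydrophobic
    occupancy: float
    schedule: str = "deterministic"  # or "bernoulli"
    on_distance: float | None = None   # defaults per kind, inside the cutoff
    off_distance: float = DEFAULT_OFF_DISTANCE

    def resolved_on(self) -> float:
        return self.on_distance if self.on_distance is not None else _DEFAULT_ON[self.kind]


@dataclass(frozen=True)
class SyntheticSpec:
    n_frames: int
    planted: tuple[PlantedContact, ...]
    dt: float = 1.0
    jitter_sigma: float = 0.0
    seed: int = 0
    ligand_chain: str = "B"
    receptor_chain: str = "A"
    include_hydrogens: bool = True  # hydrogens on hbond donors
    extra_ligand: tuple[ResidueSpec, ...] = ()
    extra_receptor: tuple[ResidueSpec, ...] = ()


@dataclass(frozen=True)
class PlantedTruth:
    ligand_res: ResKey
    receptor_res: ResKey
    kind: str
    key_atoms: tuple[str, str]
    on_frames: tuple[int, ...]
    occupancy: float       # |on frames| / n_frames actually planted
    class_label: str       # expected m/s/hs pair, ligand side first


@dataclass(frozen=True)
class GroundTruth:
    contacts: tuple[PlantedTruth, ...]
    n_frames: int
    n_atoms: int
    residues_per_chain: dict[str, int] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# validation

def _chemistry_ok(c: PlantedContact) -> str | None:
    lig, rec = c.ligand, c.receptor
    if c.kind == "saltbridge":
        fwd = (chemistry.is_anionic_oxygen(lig.name3, lig.key_atom)
               and chemistry.is_cationic_nitrogen(rec.name3, rec.key_atom))
        bwd = (chemistry.is_cationic_nitrogen(lig.name3, lig.key_atom)
               and chemistry.is_anionic_oxygen(rec.name3, rec.key_atom))
        if not (fwd or bwd):
            return "salt bridge needs an anionic-O / cationic-N key-atom pair"
    elif c.kind == "hbond":
        fwd = (chemistry.is_hbond_donor(lig.name3, lig.key_atom)
               and chemistry.is_hbond_acceptor(rec.name3, rec.key_atom))
        bwd = (chemistry.is_hbond_acceptor(lig.name3, lig.key_atom)
               and chemistry.is_hbond_donor(rec.name3, rec.key_atom))
        if not (fwd or bwd):
            return "hbond needs a donor/acceptor key-atom pair"
        if (chemistry.is_anionic_oxygen(lig.name3, lig.key_atom)
                and chemistry.is_cationic_nitrogen(rec.name3, rec.key_atom)) or (
                chemistry.is_cationic_nitrogen(lig.name3, lig.key_atom)
                and chemistry.is_anionic_oxygen(rec.name3, rec.key_atom)):
            return ("hbond key atoms form a salt-bridge pair; the detector "
                    "would report it as a salt bridge")
    elif c.kind == "hydrophobic":
        if not (chemistry.is_apolar(lig.name3, lig.key_atom)
                and chemistry.is_apolar(rec.name3, rec.key_atom)):
            return "hydrophobic contact needs apolar key atoms on both sides"
    else:
        return f"unknown contact kind {c.kind!r}"
    return None


def validate_spec(spec: SyntheticSpec,
                  params: DetectionParams = DetectionParams()) -> None:
    if spec.n_frames < 1:
        raise SyntheticSpecError("n_frames must be >= 1")
    if spec.jitter_sigma < 0:
        raise SyntheticSpecError("jitter_sigma must be >= 0")
    lig_key_atom: dict[int, str] = {}
    rec_seen: set[int] = set()
    min_xcomp = 1.0
    lig_counts: dict[int, int] = {}
    for c in spec.planted:
        lig_counts[c.ligand.number] = lig_counts.get(c.ligand.number, 0) + 1
    if any(n > 1 for n in lig_counts.values()):
        min_xcomp = 0.8  # shared ligand residues fan their partners on a cone
    for c in spec.planted:
        if not 0.0 <= c.occupancy <= 1.0:
            raise SyntheticSpecError(f"occupancy {c.occupancy} outside [0, 1]")
        if c.schedule not in ("deterministic", "bernoulli"):
            raise SyntheticSpecError(f"unknown schedule {c.schedule!r}")
        if c.ligand.key_atom is None or c.receptor.key_atom is None:
            raise SyntheticSpecError("planted contacts need key atoms on both sides")
        problem = _chemistry_ok(c)
        if problem:
            raise SyntheticSpecError(f"{c.ligand}/{c.receptor}: {problem}")
        cutoff = params.cutoff_for(c.kind)
        on, off = c.resolved_on(), c.off_distance
        if not on <= cutoff < off:
            raise SyntheticSpecError(
                f"need on_distance <= {cutoff} < off_distance, got {on}/{off}")
        margin = min(cutoff - on, off - cutoff,
                     on * min_xcomp + TAIL_GAP - params.hydrophobic_cutoff)
        if spec.jitter_sigma > 0 and margin < 4.0 * spec.jitter_sigma:
            raise SyntheticSpecError(
                f"jitter_sigma {spec.jitter_sigma} too large: distance margin "
                f"{margin:.3f} A < 4 sigma")
        if on < 2.0:
            raise SyntheticSpecError("on_distance below 2.0 A risks accidental "
                                     "contacts between flanking atoms")
        prev = lig_key_atom.get(c.ligand.number)
        if prev is not None and prev != c.ligand.key_atom:
            raise SyntheticSpecError(
                f"conflicting placements: ligand residue {c.ligand.number} "
                f"planted with two key atoms ({prev}, {c.ligand.key_atom})")
        lig_key_atom[c.ligand.number] = c.ligand.key_atom
        if c.receptor.number in rec_seen:
            raise SyntheticSpecError(
                f"conflicting placements: receptor residue {c.receptor.number} "
                "used by more than one planted contact")
        rec_seen.add(c.receptor.number)


# ---------------------------------------------------------------------------
# schedules

def deterministic_on_frames(occupancy: float, n_frames: int) -> tuple[int, ...]:
    """Evenly spaced on-frames; exactly round(occupancy * n) of them."""
    k = round(occupancy * n_frames)
    return tuple(math.floor(j * n_frames / k) for j in range(k)) if k else ()


def _bernoulli_on_frames(occupancy: float, n_frames: int, seed: int,
                         contact_index: int) -> tuple[int, ...]:
    rng = np.random.default_rng([seed, 7919, contact_index])
    return tuple(int(i) for i in np.flatnonzero(rng.random(n_frames) < occupancy))


# ---------------------------------------------------------------------------
# geometry

def _perp_basis(d: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    ref = np.array([0.0, 0.0, 1.0]) if abs(d[2]) < 0.9 else np.array([0.0, 1.0, 0.0])
    u = np.cross(d, ref)
    u /= np.linalg.norm(u)
    return u, np.cross(d, u)


_LATERAL = [(0.0, 0.0), (0.7, 0.0), (-0.7, 0.0), (0.0, 0.7), (0.0, -0.7),
            (0.7, 0.7), (-0.7, 0.7), (0.7, -0.7), (-0.7, -0.7)]


def _place_residue(name3: str, tip: np.ndarray, tail_dir: np.ndarray,
                   key_atom: str | None) -> dict[str, np.ndarray]:
    """Key atom at ``tip``; other heavy atoms staggered behind it."""
    names = chemistry.residue_heavy_atoms(name3)
    if key_atom is not None and key_atom not in names:
        raise SyntheticSpecError(f"{name3} has no heavy atom {key_atom!r}")
    u, v = _perp_basis(tail_dir)
    coords: dict[str, np.ndarray] = {}
    others = [n for n in names if n != key_atom]
    if key_atom is not None:
        coords[key_atom] = tip.copy()
    for i, name in enumerate(others):
        depth = TAIL_GAP + 1.4 * (i // len(_LATERAL))
        du, dv = _LATERAL[i % len(_LATERAL)]
        coords[name] = tip + tail_dir * depth + u * du + v * dv
    return coords


def _contact_direction(slot: int, n_slots: int) -> np.ndarray:
    """Unit vector toward the receptor; fans on a cone when a ligand residue
    hosts several partners."""
    if n_slots == 1:
        return np.array([1.0, 0.0, 0.0])
    phi = 2.0 * math.pi * slot / n_slots
    d = np.array([0.8, 0.6 * math.cos(phi), 0.6 * math.sin(phi)])
    return d / np.linalg.norm(d)


def _donor_side(c: PlantedContact) -> str | None:
    """Which side of a planted hbond donates ('ligand' preferred)."""
    if c.kind != "hbond":
        return None
    if chemistry.is_hbond_donor(c.ligand.name3, c.ligand.key_atom):
        return "ligand"
    return "receptor"


# ---------------------------------------------------------------------------
# generation

def generate(spec: SyntheticSpec,
             params: DetectionParams = DetectionParams()) -> tuple[Trajectory, GroundTruth]:
    """Build the trajectory and its exact ground truth from a validated spec."""
    validate_spec(spec, params)
    n = spec.n_frames

    # schedules and truth records
    truths: list[PlantedTruth] = []
    schedules: list[tuple[int, ...]] = []
    for idx, c in enumerate(spec.planted):
        if c.schedule == "deterministic":
            on = deterministic_on_frames(c.occupancy, n)
        else:
            on = _bernoulli_on_frames(c.occupancy, n, spec.seed, idx)
        schedules.append(on)
        label = (f"{_side_of(c.ligand.name3, {c.ligand.key_atom})}-"
                 f"{_side_of(c.receptor.name3, {c.receptor.key_atom})}")
        truths.append(PlantedTruth(
            ligand_res=(spec.ligand_chain, c.ligand.number, c.ligand.name3),
            receptor_res=(spec.receptor_chain, c.receptor.number, c.receptor.name3),
            kind=c.kind, key_atoms=(c.ligand.key_atom, c.receptor.key_atom),
            on_frames=on, occupancy=len(on) / n, class_label=label))

    # static placement of ligand residues: one lane per residue
    lig_numbers = sorted({c.ligand.number for c in spec.planted}
                         | {r.number for r in spec.extra_ligand})
    lane_of = {num: i for i, num in enumerate(lig_numbers)}
    by_lig: dict[int, list[int]] = {}
    for idx, c in enumerate(spec.planted):
        by_lig.setdefault(c.ligand.number, []).append(idx)

    lig_res_spec: dict[int, ResidueSpec] = {}
    for c in spec.planted:
        lig_res_spec[c.ligand.number] = c.ligand
    for r in spec.extra_ligand:
        lig_res_spec.setdefault(r.number, r)

    lig_coords: dict[int, dict[str, np.ndarray]] = {}
    directions: dict[int, np.ndarray] = {}  # per contact index
    for num, rspec in sorted(lig_res_spec.items()):
        origin = np.array([0.0, LANE_SPACING * lane_of[num], 0.0])
        contact_ids = by_lig.get(num, [])
        if contact_ids:
            lig_coords[num] = _place_residue(
                rspec.name3, origin, np.array([-1.0, 0.0, 0.0]), rspec.key_atom)
            for slot, idx in enumerate(contact_ids):
                directions[idx] = _contact_direction(slot, len(contact_ids))
        else:
            far = origin + np.array([-FAR_OFFSET, 0.0, 0.0])
            lig_coords[num] = _place_residue(
                rspec.name3, far, np.array([-1.0, 0.0, 0.0]), None)

    # receptor residues: planted ones move along their contact axis per frame
    rec_static: dict[int, dict[str, np.ndarray]] = {}
    for i, r in enumerate(spec.extra_receptor):
        far = np.array([FAR_OFFSET, LANE_SPACING * (len(lig_numbers) + i), 0.0])
        rec_static[r.number] = _place_residue(r.name3, far, np.array([1.0, 0.0, 0.0]), None)

    # hydrogens planted on hbond donors (names H01, H02, ... per residue)
    h_atoms: dict[tuple[str, int], list[tuple[str, int]]] = {}
    if spec.include_hydrogens:
        for idx, c in enumerate(spec.planted):
            if _donor_side(c) == "ligand":
                key = (spec.ligand_chain, c.ligand.number)
            elif _donor_side(c) == "receptor":
                key = (spec.receptor_chain, c.receptor.number)
            else:
                continue
            h_atoms.setdefault(key, []).append((f"H{len(h_atoms.get(key, [])) + 1:02d}", idx))

    jitter_rng = np.random.default_rng([spec.seed, 104729])

    frames: list[Frame] = []
    for fi in range(n):
        serial = 0
        residues: list[Residue] = []

        def add_residue(chain: str, rspec: ResidueSpec,
                        coords: dict[str, np.ndarray],
                        hydrogens: list[tuple[str, np.ndarray]] = ()):
            nonlocal serial
            res = Residue(name3=rspec.name3, number=rspec.number, chain=chain)
            for aname in chemistry.residue_heavy_atoms(rspec.name3):
                serial += 1
                res.atoms.append(Atom(serial=serial, name=aname,
                                      element=aname.lstrip("0123456789")[0],
                                      coords=coords[aname]))
            for hname, hxyz in hydrogens:
                serial += 1
                res.atoms.append(Atom(serial=serial, name=hname, element="H",
                                      coords=hxyz))
            residues.append(res)

        # receptor placement for this frame
        rec_coords: dict[int, tuple[ResidueSpec, dict[str, np.ndarray]]] = {}
        key_tip: dict[int, tuple[np.ndarray, np.ndarray]] = {}  # contact -> (lig tip, rec tip)
        for idx, c in enumerate(spec.planted):
            d = directions[idx]
            lig_tip = lig_coords[c.ligand.number][c.ligand.key_atom]
            dist = c.resolved_on() if fi in schedules[idx] else c.off_distance
            rec_tip = lig_tip + d * dist
            rec_coords[c.receptor.number] = (
                c.receptor, _place_residue(c.receptor.name3, rec_tip, d, c.receptor.key_atom))
            key_tip[idx] = (lig_tip, rec_tip)

        def donor_hydrogens(chain_key: tuple[str, int],
                            base: dict[str, np.ndarray]) -> list[tuple[str, np.ndarray]]:
            out = []
            for hname, idx in h_atoms.get(chain_key, []):
                c = spec.planted[idx]
                lig_tip, rec_tip = key_tip[idx]
                if _donor_side(c) == "ligand":
                    donor, other = lig_tip, rec_tip
                else:
                    donor, other = rec_tip, lig_tip
                u = other - donor
                u /= np.linalg.norm(u)
                out.append((hname, donor + u * 1.0))
            return out

        for num in sorted(lig_res_spec):
            rspec = lig_res_spec[num]
            add_residue(spec.ligand_chain, rspec, lig_coords[num],
                        donor_hydrogens((spec.ligand_chain, num), lig_coords[num]))
        for num in sorted(set(rec_coords) | set(rec_static)):
            if num in rec_coords:
                rspec, coords = rec_coords[num]
                add_residue(spec.receptor_chain, rspec, coords,
                            donor_hydrogens((spec.receptor_chain, num), coords))
            else:
                rspec = next(r for r in spec.extra_receptor if r.number == num)
                add_residue(spec.receptor_chain, rspec, rec_static[num])

        if spec.jitter_sigma > 0:
            flat = [a for r in residues for a in r.atoms]
            noise = jitter_rng.normal(0.0, spec.jitter_sigma, size=(len(flat), 3))
            for a, dx in zip(flat, noise):
                a.coords = a.coords + dx

        frames.append(Frame(index=fi, residues=residues))

    traj = Trajectory(frames=frames, dt=spec.dt)
    per_chain: dict[str, int] = {}
    for r in frames[0].residues:
        per_chain[r.chain] = per_chain.get(r.chain, 0) + 1
    gt = GroundTruth(contacts=tuple(truths), n_frames=n,
                     n_atoms=frames[0].n_atoms(), residues_per_chain=per_chain)
    return traj, gt


# ---------------------------------------------------------------------------
# canned fixture

def table1_style_fixture(n_frames: int = 100, seed: int = 1,
                         jitter_sigma: float = 0.02):
    """A 9-residue Tip114-like peptide against a mock receptor, with one
    stable planted contact in each interface region:

    * region I   — pY114 phosphate <-> Lys591 NZ salt bridge (s-s),
    * region II  — Gln117 NE2 <-> Tyr657 OH side-chain hydrogen bond (s-s),
    * region III — Val119 CG1 <-> Met648 SD hydrophobic contact (s-s).

    Returns (trajectory, ground_truth, peptide).
    """
    peptide = make_peptide(114, "GyRPQNVLT", "B")
    planted = (
        PlantedContact(ResidueSpec("PTR", 114, "O1P"),
                       ResidueSpec("LYS", 591, "NZ"), "saltbridge", 0.90),
        PlantedContact(ResidueSpec("GLN", 117, "NE2"),
                       ResidueSpec("TYR", 657, "OH"), "hbond", 0.60),
        PlantedContact(ResidueSpec("VAL", 119, "CG1"),
                       ResidueSpec("MET", 648, "SD"), "hydrophobic", 0.45),
    )
    extra = tuple(
        ResidueSpec(peptide.name3_at(num), num)
        for num in peptide.residue_numbers() if num not in (114, 117, 119))
    spec = SyntheticSpec(n_frames=n_frames, planted=planted, seed=seed,
                         jitter_sigma=jitter_sigma, extra_ligand=extra)
    traj, gt = generate(spec)
    return traj, gt, peptide


# ---------------------------------------------------------------------------
# ground-truth sidecar

def ground_truth_to_csv(gt: GroundTruth, path) -> None:
    rows = []
    for t in gt.contacts:
        rows.append({
            "ligand_chain": t.ligand_res[0], "ligand_number": t.ligand_res[1],
            "ligand_name3": t.ligand_res[2], "ligand_key_atom": t.key_atoms[0],
            "receptor_chain": t.receptor_res[0], "receptor_number": t.receptor_res[1],
            "receptor_name3": t.receptor_res[2], "receptor_key_atom": t.key_atoms[1],
            "kind": t.kind, "occupancy": t.occupancy, "class_label": t.class_label,
            "on_frames": ";".join(str(i) for i in t.on_frames),
        })
    pd.DataFrame(rows).to_csv(path, index=False)
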