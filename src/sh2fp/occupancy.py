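"""Residue-pair occupancies, the >30% stability filter and m/s/hs labels.

Per-frame contact events are aggregated into one :class:`PairProfile` per
(ligand residue, receptor residue) pair.  A frame counts toward an
interaction kind if at least one event of that kind occurs in it (atom-level
multiplicity is collapsed).  Occupancy is the fraction of analyzed frames in
which the contact is present; frames, not nanoseconds, are the denominator
(snapshots are evenly spaced).

Each residue participates through one *side* per frame and kind:

* ``m``  — only main-chain atoms are involved;
* ``s``  — any polar side-chain atom is involved (fully apolar side chains
  such as Ile/Leu/Val also report as ``s``);
* ``hs`` — only the apolar atoms of a side chain that *does* possess polar
  atoms are involved (e.g. the Gln CB/CG methylenes).

The stability filter keeps a pair when its best single (kind, sides)
combination is present in strictly more than ``threshold`` of the frames
("more than 30%"); polar kinds (salt bridge, hydrogen bond) take precedence
over hydrophobic when both qualify, and a single class label is reported per
pair, ligand side first (e.g. ``"s-m"``).
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import chemistry
from .contacts import ContactEvent, min_heavy_distance
from .peptides import PeptideDef, offset_of, region_of
from .structure import Trajectory

STABILITY_THRESHOLD = 0.30

ResKey = tuple[str, int, str]  # (chain, number, name3)

_KIND_PRIORITY = {"saltbridge": 0, "hbond": 1, "hydrophobic": 2}
_POLAR_KINDS = ("saltbridge", "hbond")


@dataclass
class PairProfile:
    """Frame sets for one ligand/receptor residue pair, split by kind+sides."""

    ligand_res: ResKey
    receptor_res: ResKey
    n_frames: int
    # (kind, ligand side, receptor side) -> frame indices
    frames: dict[tuple[str, str, str], set[int]] = field(default_factory=dict)

    @property
    def frames_by_kind(self) -> dict[str, set[int]]:
        out: dict[str, set[int]] = defaultdict(set)
        for (kind, _, _), fr in self.frames.items():
            out[kind] |= fr
        return dict(out)

    @property
    def frames_by_sides(self) -> dict[tuple[str, str], set[int]]:
        out: dict[tuple[str, str], set[int]] = defaultdict(set)
        for (_, ls, rs), fr in self.frames.items():
            out[(ls, rs)] |= fr
        return dict(out)

    def occupancy(self, kind: str) -> float:
        return len(self.frames_by_kind.get(kind, ())) / self.n_frames


@dataclass(frozen=True)
class InteractionRecord:
    """One stable interaction: the Table-style single-class residue pair."""

    ligand_res: ResKey
    receptor_res: ResKey
    kind: str
    class_label: str  # e.g. "s-s", "m-s", "hs-s"; ligand side first
    occupancy: float
    region: str | None


@dataclass
class InteractionTable:
    peptide: PeptideDef | None
    records: list[InteractionRecord]
    n_frames: int


def _side_of(resname: str, atom_names: set[str]) -> str:
    """m/s/hs attribution for one residue from its participating heavy atoms."""
    roles = [chemistry.atom_role(resname, a) for a in atom_names]
    side_polar = any(not r.backbone and r.polarity != "apolar" for r in roles)
    side_apolar = any(not r.backbone and r.polarity == "apolar" for r in roles)
    if side_polar:
        return "s"
    if side_apolar:
        return "hs" if chemistry.sidechain_has_polar(resname) else "s"
    return "m"


def accumulate(events: list[ContactEvent], traj: Trajectory) -> list[PairProfile]:
    """Collapse atomic events into per-residue-pair frame sets."""
    n = traj.n_frames
    # (pair, kind, frame) -> participating atom names per residue
    atoms: dict[tuple, tuple[set[str], set[str]]] = defaultdict(
        lambda: (set(), set()))
    for e in events:
        if not 0 <= e.frame < n:
            raise ValueError(
                f"event references frame {e.frame} outside trajectory of {n} frames")
        lig_key, rec_key = e.pair_key
        la, ra = atoms[(lig_key, rec_key, e.kind, e.frame)]
        la.add(e.ligand_atom.atomname)
        ra.add(e.receptor_atom.atomname)
    profiles: dict[tuple[ResKey, ResKey], PairProfile] = {}
    for (lig_key, rec_key, kind, frame), (la, ra) in atoms.items():
        prof = profiles.get((lig_key, rec_key))
        if prof is None:
            prof = PairProfile(lig_key, rec_key, n)
            profiles[(lig_key, rec_key)] = prof
        combo = (kind, _side_of(lig_key[2], la), _side_of(rec_key[2], ra))
        prof.frames.setdefault(combo, set()).add(frame)
    return sorted(profiles.values(),
                  key=lambda p: (p.ligand_res[1], p.receptor_res[1]))


def stable_interactions(profiles: list[PairProfile],
                        peptide: PeptideDef | None,
                        threshold: float = STABILITY_THRESHOLD) -> InteractionTable:
    """Apply the strict >threshold occupancy filter and assign class labels.

    With ``peptide=None`` no region labels are assigned and ligand residues
    are not checked against a window; with a peptide given, a ligand residue
    outside the pY-1..pY+7 window is an error.
    """
    if not 0.0 <= threshold < 1.0:
        raise ValueError("threshold must be in [0, 1)")
    records: list[InteractionRecord] = []
    n_frames = profiles[0].n_frames if profiles else 0
    for prof in profiles:
        best = None  # (polar?, -occupancy, kind priority, sides) ordering
        for (kind, ls, rs), fr in prof.frames.items():
            occ = len(fr) / prof.n_frames
            if not occ > threshold:
                continue
            rank = (0 if kind in _POLAR_KINDS else 1,
                    -occ, _KIND_PRIORITY[kind], ls, rs)
            if best is None or rank < best[0]:
                best = (rank, kind, ls, rs, occ)
        if best is None:
            continue
        _, kind, ls, rs, occ = best
        region = None
        if peptide is not None:
            region = region_of(offset_of(peptide, prof.ligand_res[1]))
        records.append(InteractionRecord(
            ligand_res=prof.ligand_res, receptor_res=prof.receptor_res,
            kind=kind, class_label=f"{ls}-{rs}", occupancy=occ, region=region))
    records.sort(key=lambda r: (r.ligand_res[1], r.receptor_res[1]))
    return InteractionTable(peptide=peptide, records=records, n_frames=n_frames)


def profile_trajectory(traj: Trajectory, ligand_chain: str, receptor_chain: str,
                       peptide: PeptideDef | None = None,
                       params=None,
                       threshold: float = STABILITY_THRESHOLD) -> InteractionTable:
    """Convenience pipeline: detect -> accumulate -> stability filter."""
    from .contacts import DetectionParams, detect_all
    params = params or DetectionParams()
    events = detect_all(traj, ligand_chain, receptor_chain, params)
    return stable_interactions(accumulate(events, traj), peptide, threshold)


def distance_timeseries(traj: Trajectory,
                        ligand_chain: str, ligand_resnum: int,
                        receptor_chain: str, receptor_resnum: int,
                        window: tuple[int, int] | None = None) -> pd.DataFrame:
    """Minimum heavy-atom distance between two residues per frame.

    ``window`` is a half-open (start, stop) frame range; None means all
    frames.  Returns a DataFrame with columns ``frame``, ``time_ps`` and
    ``distance_A`` — the shape exported to CSV.
    """
    start, stop = window if window is not None else (0, traj.n_frames)
    if not (0 <= start < stop <= traj.n_frames):
        raise ValueError(
            f"empty or out-of-range window ({start}, {stop}) "
            f"for a {traj.n_frames}-frame trajectory")
    rows = []
    for frame in traj.frames[start:stop]:
        ra = frame.residue(ligand_chain, ligand_resnum)
        rb = frame.residue(receptor_chain, receptor_resnum)
        rows.append((frame.index, frame.index * traj.dt_ps,
                     min_heavy_distance(ra, rb)))
    return pd.DataFrame(rows, columns=["frame", "time_ps", "distance_A"])
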