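"""Test-only brute-force contact detectors with an independent role table.

These oracles re-derive the expected contact sets from first principles:
pure-Python O(n^2) loops over all cross-chain atom pairs, with a hand-written
atom-role table for a small residue vocabulary (independent of the packaged
chemistry tables).  They exist solely to cross-check the vectorized
detectors and must never import them.
"""

from __future__ import annotations

import math

# residue -> atom -> set of role tags:
#   an = anionic O, cat = cationic N, don = H-bond donor, acc = H-bond
#   acceptor, ap = apolar heavy atom
_BB = {"N": {"don"}, "CA": set(), "C": set(), "O": {"acc"}}

ORACLE_ROLES: dict[str, dict[str, set[str]]] = {
    "GLY": {**_BB},
    "ALA": {**_BB, "CB": {"ap"}},
    "SER": {**_BB, "CB": set(), "OG": {"don", "acc"}},
    "VAL": {**_BB, "CB": {"ap"}, "CG1": {"ap"}, "CG2": {"ap"}},
    "LEU": {**_BB, "CB": {"ap"}, "CG": {"ap"}, "CD1": {"ap"}, "CD2": {"ap"}},
    "MET": {**_BB, "CB": {"ap"}, "CG": {"ap"}, "SD": {"ap"}, "CE": {"ap"}},
    "ASP": {**_BB, "CB": {"ap"}, "CG": set(),
            "OD1": {"an", "acc"}, "OD2": {"an", "acc"}},
    "LYS": {**_BB, "CB": {"ap"}, "CG": {"ap"}, "CD": {"ap"}, "CE": set(),
            "NZ": {"cat", "don"}},
    "GLN": {**_BB, "CB": {"ap"}, "CG": {"ap"}, "CD": set(),
            "OE1": {"acc"}, "NE2": {"don"}},
    "TYR": {**_BB, "CB": {"ap"}, "CG": {"ap"}, "CD1": {"ap"}, "CD2": {"ap"},
            "CE1": {"ap"}, "CE2": {"ap"}, "CZ": {"ap"}, "OH": {"don", "acc"}},
}

EPS = 1e-9


def _atoms(frame, chain):
    out = []
    for res in frame.residues:
        if res.chain != chain:
            continue
        for a in res.atoms:
            if a.element.upper() in ("H", "D"):
                continue
            out.append(((res.chain, res.number, a.name),
                        ORACLE_ROLES[res.name3][a.name], tuple(a.coords)))
    return out


def _pairs_within(lig_atoms, rec_atoms, ltag, rtag, cutoff):
    found = set()
    for lid, lroles, lxyz in lig_atoms:
        if ltag not in lroles:
            continue
        for rid, rroles, rxyz in rec_atoms:
            if rtag not in rroles:
                continue
            if math.dist(lxyz, rxyz) <= cutoff + EPS:
                found.add((lid, rid))
    return found


def brute_salt_bridges(frame, ligand_chain, receptor_chain, cutoff=3.2):
    lig, rec = _atoms(frame, ligand_chain), _atoms(frame, receptor_chain)
    return (_pairs_within(lig, rec, "an", "cat", cutoff)
            | _pairs_within(lig, rec, "cat", "an", cutoff))


def brute_hydrogen_bonds(frame, ligand_chain, receptor_chain,
                         cutoff=3.0, sb_cutoff=3.2):
    """Hydrogen-free frames only: distance criterion, salt bridges excluded."""
    lig, rec = _atoms(frame, ligand_chain), _atoms(frame, receptor_chain)
    sb = brute_salt_bridges(frame, ligand_chain, receptor_chain, sb_cutoff)
    found = (_pairs_within(lig, rec, "don", "acc", cutoff)
             | _pairs_within(lig, rec, "acc", "don", cutoff))
    return found - sb


def brute_hydrophobic(frame, ligand_chain, receptor_chain, cutoff=5.0):
    lig, rec = _atoms(frame, ligand_chain), _atoms(frame, receptor_chain)
    return _pairs_within(lig, rec, "ap", "ap", cutoff)


def event_pairs(events):
    """Project detector events onto the oracle's (ligand, receptor) id pairs."""
    return {((e.ligand_atom.chain, e.ligand_atom.resnum, e.ligand_atom.atomname),
             (e.receptor_atom.chain, e.receptor_atom.resnum,
              e.receptor_atom.atomname)) for e in events}
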