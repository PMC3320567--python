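"""Show the geometric criteria of the three contact detectors.

Builds minimal two-residue frames and scans separations/angles to expose the
admission boundaries: 3.2 A for salt bridges, 3.0 A + 120 deg for hydrogen
bonds, 5.0 A for hydrophobic contacts (all inclusive).
"""

import math

import numpy as np

from sh2fp import detect_hydrogen_bonds, detect_hydrophobic, detect_salt_bridges
from sh2fp.structure import Atom, Frame, Residue


def residue(name3, number, chain, atoms, serial_start=1):
    res = Residue(name3=name3, number=number, chain=chain)
    for i, (name, xyz) in enumerate(atoms):
        el = "H" if name.startswith("H") else name[0]
        res.atoms.append(Atom(serial_start + i, name, el, np.array(xyz)))
    return res


def pair(lig, latom, rec, ratom, d):
    return Frame(0, [residue(lig, 1, "B", [(latom, (0, 0, 0))]),
                     residue(rec, 2, "A", [(ratom, (d, 0, 0))], 10)])


grid = [k / 100 for k in range(250, 601)]
sb = max(d for d in grid if d <= 4.0 and
         detect_salt_bridges(pair("LYS", "NZ", "ASP", "OD1", d), "B", "A"))
hp = max(d for d in grid if
         detect_hydrophobic(pair("VAL", "CG1", "LEU", "CD1", d), "B", "A"))
print(f"largest Lys NZ .. Asp OD1 separation reported as salt bridge: {sb} A")
print(f"largest Val CG1 .. Leu CD1 separation reported as hydrophobic: {hp} A")


def hbond_frame(d, angle_deg):
    alpha = math.radians(angle_deg)
    beta = math.pi - alpha - math.asin(math.sin(alpha) / d)
    h = (math.cos(beta), math.sin(beta), 0.0)
    return Frame(0, [residue("SER", 1, "B", [("OG", (0, 0, 0)), ("HG", h)]),
                     residue("GLY", 2, "A", [("O", (d, 0, 0))], 10)])


hb = max(d for d in grid if d <= 3.5 and
         detect_hydrogen_bonds(hbond_frame(d, 180.0), "B", "A"))
ang = min(a for a in range(90, 181) if
          detect_hydrogen_bonds(hbond_frame(2.9, float(a)), "B", "A"))
print(f"largest Ser OG .. O separation reported as hydrogen bond: {hb} A")
print(f"smallest admitted donor-H-acceptor angle at 2.9 A: {ang} deg")

# The boundaries are inclusive: a pair exactly at the cutoff is detected.
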