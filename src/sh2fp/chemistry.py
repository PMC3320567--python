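"""Table-driven atom chemistry: backbone/side-chain partition and polarity roles.

Every heavy atom of the supported residues (the 20 standard amino acids,
phosphotyrosine ``PTR`` and the terminal caps ``ACE``/``NME``) is assigned
exactly one :class:`AtomRole`.  The table is shipped as a plain-text file
(``data/chemistry.tsv``) so users can inspect or override it.

Polarity vocabulary
-------------------
``donor`` / ``acceptor`` / ``donor_and_acceptor``
    hydrogen-bond capable nitrogen and oxygen atoms.
``charged_positive`` / ``charged_negative``
    the cationic nitrogens (Lys NZ, Arg NE/NH1/NH2) and anionic oxygens
    (Asp OD1/OD2, Glu OE1/OE2, and the PTR phosphate oxygens including the
    bridging oxygen) that define salt bridges.
``apolar``
    carbon or sulfur atoms not covalently bonded to N or O in the residue's
    standard topology; aromatic ring carbons (Phe/Tyr/Trp/His) count as
    apolar, as do Cys SG and Met SD.
``other_polar``
    everything else (carbonyl carbons, carbons bonded to heteroatoms, the
    PTR phosphorus, His ring nitrogens under the neutral default).

Histidine is neutral by default: ND1/NE2 are ``donor_and_acceptor`` and do
not form salt bridges unless the ``protonated_his`` switch of the detection
parameters is enabled.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from importlib import resources
from pathlib import Path

POLARITIES = frozenset({
    "donor", "acceptor", "donor_and_acceptor",
    "charged_positive", "charged_negative", "apolar", "other_polar",
})

#: residues whose (chain, number) the ligand window machinery may see
SUPPORTED_RESIDUES = (
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO "
    "SER THR TRP TYR VAL PTR ACE NME"
).split()


class UnknownAtomError(KeyError):
    """Raised for a (residue, atom) pair absent from the chemistry table."""


@dataclass(frozen=True)
class AtomRole:
    """Backbone flag plus polarity class for one named atom of one residue."""

    backbone: bool
    polarity: str

    def __post_init__(self) -> None:
        if self.polarity not in POLARITIES:
            raise ValueError(f"unknown polarity {self.polarity!r}")


def _default_table_path() -> Path:
    return Path(str(resources.files("sh2fp").joinpath("data/chemistry.tsv")))


@lru_cache(maxsize=4)
def load_table(path: str | None = None) -> dict[tuple[str, str], AtomRole]:
    """Load a chemistry table; ``path=None`` loads the packaged default."""
    p = Path(path) if path is not None else _default_table_path()
    table: dict[tuple[str, str], AtomRole] = {}
    for lineno, line in enumerate(p.read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 4:
            raise ValueError(f"{p}:{lineno}: expected 4 tab-separated fields")
        res, atom, bb, pol = parts
        key = (res, atom)
        if key in table:
            raise ValueError(f"{p}:{lineno}: duplicate entry {key}")
        table[key] = AtomRole(backbone=(bb == "mc"), polarity=pol)
    return table


def atom_role(name3: str, atom_name: str, table_path: str | None = None) -> AtomRole:
    """Role of ``atom_name`` in residue ``name3``; unknown pairs raise."""
    table = load_table(table_path)
    try:
        return table[(name3.upper(), atom_name.upper())]
    except KeyError:
        if name3.upper() not in SUPPORTED_RESIDUES:
            raise UnknownAtomError(f"unsupported residue {name3!r}") from None
        raise UnknownAtomError(
            f"atom {atom_name!r} of residue {name3!r} not in chemistry table"
        ) from None


@lru_cache(maxsize=128)
def sidechain_has_polar(name3: str, table_path: str | None = None) -> bool:
    """True iff the side chain of ``name3`` has any non-apolar heavy atom.

    This is the precondition for the 'hs' (hydrophobic-part-of-a-polar-side-
    chain) interaction class: residues whose side chains are entirely apolar
    (Ile, Leu, Val, Ala, Cys, Met, Phe, Gly) can never be labelled 'hs'.
    """
    table = load_table(table_path)
    res = name3.upper()
    if res not in SUPPORTED_RESIDUES:
        raise UnknownAtomError(f"unsupported residue {res!r}")
    return any(
        not role.backbone and role.polarity != "apolar"
        for (r, atom), role in table.items()
        if r == res and not atom.startswith("H")
    )


# ---------------------------------------------------------------------------
# detection-facing predicates

_HIS_RING_N = {("HIS", "ND1"), ("HIS", "NE2")}


def is_anionic_oxygen(name3: str, atom_name: str) -> bool:
    role = atom_role(name3, atom_name)
    return role.polarity == "charged_negative" and _element_of(atom_name) == "O"


def is_cationic_nitrogen(name3: str, atom_name: str, protonated_his: bool = False) -> bool:
    if protonated_his and (name3.upper(), atom_name.upper()) in _HIS_RING_N:
        return True
    role = atom_role(name3, atom_name)
    return role.polarity == "charged_positive" and _element_of(atom_name) == "N"


def is_hbond_donor(name3: str, atom_name: str) -> bool:
    role = atom_role(name3, atom_name)
    return (role.polarity in ("donor", "donor_and_acceptor", "charged_positive")
            and _element_of(atom_name) in ("N", "O"))


def is_hbond_acceptor(name3: str, atom_name: str) -> bool:
    role = atom_role(name3, atom_name)
    return (role.polarity in ("acceptor", "donor_and_acceptor", "charged_negative")
            and _element_of(atom_name) in ("N", "O"))


def is_apolar(name3: str, atom_name: str) -> bool:
    return atom_role(name3, atom_name).polarity == "apolar"


#: alias phosphate names excluded when *building* residues (read both ways)
_BUILD_EXCLUDE = {("PTR", "OP1"), ("PTR", "OP2"), ("PTR", "OP3")}


def residue_heavy_atoms(name3: str, table_path: str | None = None) -> list[str]:
    """Canonical heavy-atom names of a residue (no OXT, no name aliases)."""
    table = load_table(table_path)
    res = name3.upper()
    if res not in SUPPORTED_RESIDUES:
        raise UnknownAtomError(f"unsupported residue {res!r}")
    return [atom for (r, atom) in table
            if r == res and atom != "OXT"
            and (r, atom) not in _BUILD_EXCLUDE
            and _element_of(atom) != "H"]


def _element_of(atom_name: str) -> str:
    stripped = atom_name.lstrip("0123456789")
    return stripped[:1].upper()
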