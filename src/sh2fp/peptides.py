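"""pY-anchored phosphopeptide windows and interface-region assignment.

SH2 domains read their ligands relative to the phosphotyrosine (pY): the
peptide windows handled here are 9 residues long, spanning pY-1 .. pY+7, and
are written in one-letter code with a lower-case ``y`` marking the pY (e.g.
``"GyRPQNVLT"`` for the Tip Y114 peptide, residues 113-121).

The binding interface is dissected into three regions by pY offset:

* region I   — the phosphotyrosine itself and pY+1,
* region II  — pY+2 and pY+3 (the specificity pocket),
* region III — pY+4 .. pY+8 (the C-terminal extension).

pY-1 falls outside this scheme and is reported as ``"flank"``.  The +8 slot
is kept for generality although 9-residue pY-1..pY+7 windows never populate
it.
"""

from __future__ import annotations

from dataclasses import dataclass

ONE_TO_THREE = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
    "y": "PTR",
}

WINDOW_LENGTH = 9
REGION_FLANK = "flank"


class PeptideError(ValueError):
    """Invalid peptide definition or out-of-window residue number."""


@dataclass(frozen=True)
class PeptideDef:
    """A 9-residue pY-1..pY+7 ligand window anchored at ``py_number``."""

    py_number: int
    sequence: str  # one-letter, 'y' at position 1 marks the phosphotyrosine
    chain: str

    def __post_init__(self) -> None:
        if len(self.sequence) != WINDOW_LENGTH:
            raise PeptideError(
                f"peptide sequence must be {WINDOW_LENGTH} residues, "
                f"got {len(self.sequence)}")
        if self.sequence[1] != "y":
            raise PeptideError(
                "position 2 of the sequence must be the phosphotyrosine "
                "marker 'y' (window is pY-1 .. pY+7)")
        bad = [c for c in self.sequence if c not in ONE_TO_THREE]
        if bad:
            raise PeptideError(f"unknown one-letter residue codes {bad}")

    @property
    def start_number(self) -> int:
        return self.py_number - 1

    @property
    def end_number(self) -> int:
        return self.py_number + 7

    def residue_numbers(self) -> range:
        return range(self.start_number, self.end_number + 1)

    def name3_at(self, residue_number: int) -> str:
        return ONE_TO_THREE[self.sequence[residue_number - self.start_number]]

    def one_letter_at(self, residue_number: int) -> str:
        letter = self.sequence[residue_number - self.start_number]
        return "pY" if letter == "y" else letter

    def contains(self, residue_number: int) -> bool:
        return self.start_number <= residue_number <= self.end_number


def make_peptide(py_number: int, sequence: str, chain: str) -> PeptideDef:
    """Build a validated pY-anchored 9-residue window definition."""
    return PeptideDef(py_number=py_number, sequence=sequence, chain=chain)


def offset_of(peptide: PeptideDef, residue_number: int) -> int:
    """pY offset (-1 .. +7) of an absolute residue number within the window."""
    if not peptide.contains(residue_number):
        raise PeptideError(
            f"residue {residue_number} outside peptide window "
            f"{peptide.start_number}-{peptide.end_number}")
    return residue_number - peptide.py_number


def region_of(offset: int) -> str:
    """Interface region for a pY offset: I, II, III or 'flank' (pY-1)."""
    if offset == -1:
        return REGION_FLANK
    if offset in (0, 1):
        return "I"
    if offset in (2, 3):
        return "II"
    if 4 <= offset <= 8:
        return "III"
    raise PeptideError(f"pY offset {offset} outside the supported range [-1, +8]")
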