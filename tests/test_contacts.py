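"""Geometric contact detectors: cutoffs, angles, oracle equivalence."""

import math
import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sh2fp.contacts import (DetectionParams, detect_all, detect_frame,
                            detect_hydrogen_bonds, detect_hydrophobic,
                            detect_salt_bridges)
from sh2fp.structure import Frame, Trajectory

from conftest import make_residue, random_two_chain_frame, two_atom_frame
from oracles import (brute_hydrogen_bonds, brute_hydrophobic,
                     brute_salt_bridges, event_pairs)


def h_position(donor_acceptor_distance: float, angle_deg: float) -> tuple:
    """Hydrogen 1.0 A from a donor at the origin such that the D-H-A angle
    (vertex at H, acceptor on the +x axis) equals ``angle_deg``."""
    L = donor_acceptor_distance
    alpha = math.radians(angle_deg)
    angle_a = math.asin(math.sin(alpha) / L)  # law of sines, |DH| = 1
    beta = math.pi - alpha - angle_a          # angle at the donor
    return (math.cos(beta), math.sin(beta), 0.0)


def hbond_frame(distance: float, angle_deg: float | None) -> Frame:
    """Ser OG donor (origin) vs a backbone O acceptor at ``distance`` on +x;
    ``angle_deg=None`` omits the hydrogen."""
    atoms = [("OG", (0.0, 0.0, 0.0))]
    if angle_deg is not None:
        atoms.append(("HG", h_position(distance, angle_deg)))
    return Frame(index=0, residues=[
        make_residue("SER", 1, "B", atoms),
        make_residue("GLY", 2, "A", [("O", (distance, 0.0, 0.0))],
                     serial_start=10),
    ])


class TestSaltBridges:
    def test_inside_cutoff(self):
        frame = two_atom_frame("LYS", "NZ", "ASP", "OD1", 2.8)
        events = detect_salt_bridges(frame, "B", "A")
        assert len(events) == 1
        assert events[0].kind == "saltbridge"
        assert events[0].distance == pytest.approx(2.8)

    def test_boundary_inclusive_and_beyond(self):
        assert len(detect_salt_bridges(
            two_atom_frame("LYS", "NZ", "ASP", "OD2", 3.2), "B", "A")) == 1
        assert len(detect_salt_bridges(
            two_atom_frame("LYS", "NZ", "ASP", "OD2", 3.21), "B", "A")) == 0

    def test_neutral_his_is_not_a_cation(self):
        frame = two_atom_frame("ASP", "OD1", "HIS", "NE2", 3.0)
        assert detect_salt_bridges(frame, "B", "A") == []
        promoted = DetectionParams(protonated_his=True)
        assert len(detect_salt_bridges(frame, "B", "A", promoted)) == 1


class TestHydrogenBonds:
    def test_linear_donor_inside_cutoff(self):
        events = detect_hydrogen_bonds(hbond_frame(2.9, 180.0), "B", "A")
        assert len(events) == 1
        assert events[0].angle == pytest.approx(180.0, abs=1e-6)

    def test_bent_donor_rejected(self):
        assert detect_hydrogen_bonds(hbond_frame(2.9, 100.0), "B", "A") == []

    def test_angle_boundary_inclusive(self):
        events = detect_hydrogen_bonds(hbond_frame(2.9, 120.0), "B", "A")
        assert len(events) == 1
        assert events[0].angle == pytest.approx(120.0, abs=1e-6)

    def test_distance_boundary(self):
        assert len(detect_hydrogen_bonds(hbond_frame(3.0, 180.0), "B", "A")) == 1
        assert detect_hydrogen_bonds(hbond_frame(3.01, 180.0), "B", "A") == []

    def test_hydrogen_free_fallback_records_no_angle(self):
        events = detect_hydrogen_bonds(hbond_frame(2.9, None), "B", "A")
        assert len(events) == 1
        assert events[0].angle is None

    def test_salt_bridge_pair_not_double_reported(self):
        frame = two_atom_frame("LYS", "NZ", "ASP", "OD1", 2.8)
        assert detect_hydrogen_bonds(frame, "B", "A") == []
        kinds = [e.kind for e in detect_frame(frame, "B", "A")]
        assert kinds == ["saltbridge"]


class TestHydrophobic:
    def test_sulfur_counts_as_apolar(self):
        frame = two_atom_frame("VAL", "CG1", "MET", "SD", 4.5)
        events = detect_hydrophobic(frame, "B", "A")
        assert len(events) == 1

    def test_outside_cutoff(self):
        frame = two_atom_frame("VAL", "CG1", "LEU", "CD1", 5.5)
        assert detect_hydrophobic(frame, "B", "A") == []

    def test_boundary_inclusive(self):
        frame = two_atom_frame("VAL", "CG1", "LEU", "CD1", 5.0)
        assert len(detect_hydrophobic(frame, "B", "A")) == 1

    def test_polar_atoms_excluded(self):
        frame = two_atom_frame("SER", "OG", "LEU", "CD1", 4.0)
        assert detect_hydrophobic(frame, "B", "A") == []


class TestOracleEquivalence:
    """The vectorized detectors must match an independent O(n^2) brute force
    on random hydrogen-free frames."""

    @pytest.mark.parametrize("seed", range(20))
    def test_all_kinds(self, seed):
        frame = random_two_chain_frame(np.random.default_rng(seed))
        assert event_pairs(detect_salt_bridges(frame, "B", "A")) == \
            brute_salt_bridges(frame, "B", "A")
        assert event_pairs(detect_hydrogen_bonds(frame, "B", "A")) == \
            brute_hydrogen_bonds(frame, "B", "A")
        assert event_pairs(detect_hydrophobic(frame, "B", "A")) == \
            brute_hydrophobic(frame, "B", "A")


@settings(derandomize=True, max_examples=30, deadline=None)
@given(seed=st.integers(0, 10_000), shrink=st.floats(0.3, 1.0))
def test_cutoff_monotonicity(seed, shrink):
    """Shrinking any cutoff never adds events; enlarging never removes."""
    frame = random_two_chain_frame(np.random.default_rng(seed))
    base = DetectionParams()
    small = DetectionParams(saltbridge_cutoff=base.saltbridge_cutoff * shrink,
                            hbond_cutoff=base.hbond_cutoff * shrink,
                            hydrophobic_cutoff=base.hydrophobic_cutoff * shrink)
    for detect in (detect_salt_bridges, detect_hydrogen_bonds, detect_hydrophobic):
        assert event_pairs(detect(frame, "B", "A", small)) <= \
            event_pairs(detect(frame, "B", "A", base))


@pytest.mark.parametrize("seed", range(5))
def test_chain_swap_symmetry(seed):
    """Swapping ligand/receptor labels transposes roles but preserves the
    set of unordered atom pairs per kind."""
    frame = random_two_chain_frame(np.random.default_rng(seed))
    for detect in (detect_salt_bridges, detect_hydrogen_bonds, detect_hydrophobic):
        fwd = {frozenset(p) for p in event_pairs(detect(frame, "B", "A"))}
        rev = {frozenset(p) for p in event_pairs(detect(frame, "A", "B"))}
        assert fwd == rev


class TestDetectAll:
    def test_single_frame_equals_union(self):
        frame = random_two_chain_frame(np.random.default_rng(42))
        traj = Trajectory(frames=[frame])
        assert detect_all(traj, "B", "A") == detect_frame(frame, "B", "A")

    def test_deterministic_ordering(self, table1_fixture):
        traj, _, _ = table1_fixture
        events = detect_all(traj, "B", "A")
        key = [(e.frame, e.ligand_atom.serial, e.receptor_atom.serial, e.kind)
               for e in events]
        assert key == sorted(key)

    def test_missing_chain_warns_and_returns_empty(self, single_frame_trajectory):
        with pytest.warns(UserWarning, match="chain 'X'"):
            assert detect_all(single_frame_trajectory, "X", "A") == []


def test_detection_params_validation():
    with pytest.raises(ValueError):
        DetectionParams(hbond_cutoff=-1.0)
    with pytest.raises(ValueError):
        DetectionParams(hbond_angle_min=0.0)
    with pytest.raises(ValueError):
        DetectionParams(hbond_angle_min=190.0)
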