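"""Occupancy aggregation, the strict >30% filter, class labels, time series."""

import math

import numpy as np
import pytest

from sh2fp.contacts import AtomRef, ContactEvent, detect_all
from sh2fp.occupancy import (PairProfile, accumulate, distance_timeseries,
                             profile_trajectory, stable_interactions)
from sh2fp.peptides import PeptideError, make_peptide
from sh2fp.structure import Frame, Trajectory
from sh2fp.synth import (PlantedContact, ResidueSpec, SyntheticSpec, generate)

from conftest import make_residue


def planted_pipeline(kind, lig, rec, occupancy, n_frames=10, schedule="deterministic"):
    spec = SyntheticSpec(
        n_frames=n_frames, seed=5,
        planted=(PlantedContact(lig, rec, kind, occupancy, schedule=schedule),))
    traj, gt = generate(spec)
    events = detect_all(traj, "B", "A")
    return traj, gt, events


class TestAccumulate:
    def test_fractional_occupancy(self):
        traj, gt, events = planted_pipeline(
            "saltbridge", ResidueSpec("ASP", 7, "OD1"),
            ResidueSpec("LYS", 42, "NZ"), occupancy=0.4)
        profiles = accumulate(events, traj)
        assert len(profiles) == 1
        prof = profiles[0]
        assert prof.occupancy("saltbridge") == pytest.approx(0.4)
        assert prof.frames_by_kind["saltbridge"] == set(gt.contacts[0].on_frames)

    def test_full_occupancy(self):
        traj, _, events = planted_pipeline(
            "hydrophobic", ResidueSpec("VAL", 1, "CG1"),
            ResidueSpec("LEU", 2, "CD1"), occupancy=1.0)
        assert accumulate(events, traj)[0].occupancy("hydrophobic") == 1.0

    def test_atom_multiplicity_collapsed(self):
        """Several events of one kind in one frame count that frame once."""
        frame = Frame(index=0, residues=[
            make_residue("ASP", 1, "B", [("OD1", (0, 0, 0)), ("OD2", (0, 1.0, 0))]),
            make_residue("LYS", 2, "A", [("NZ", (2.5, 0.5, 0))], serial_start=5)])
        traj = Trajectory(frames=[frame])
        events = detect_all(traj, "B", "A")
        assert len(events) == 2  # both carboxylate oxygens within cutoff
        prof = accumulate(events, traj)[0]
        assert prof.occupancy("saltbridge") == 1.0

    def test_unknown_frame_rejected(self, single_frame_trajectory):
        ref = AtomRef("B", 1, "ASP", "OD1", 1)
        ref2 = AtomRef("A", 2, "LYS", "NZ", 2)
        bad = ContactEvent(frame=5, ligand_atom=ref, receptor_atom=ref2,
                           kind="saltbridge", distance=2.8)
        with pytest.raises(ValueError, match="frame 5"):
            accumulate([bad], single_frame_trajectory)


def _profile(occ_by_combo: dict, n_frames=100, lignum=114, ligname="PTR",
             recnum=591, recname="LYS"):
    frames = {combo: set(range(round(occ * n_frames)))
              for combo, occ in occ_by_combo.items()}
    return PairProfile(ligand_res=("B", lignum, ligname),
                       receptor_res=("A", recnum, recname),
                       n_frames=n_frames, frames=frames)


class TestStabilityFilter:
    def test_strictly_greater_than_threshold(self):
        pep = make_peptide(114, "GyRPQNVLT", "B")
        for occ, kept in ((0.29, False), (0.30, False), (0.31, True)):
            table = stable_interactions(
                [_profile({("saltbridge", "s", "s"): occ})], pep)
            assert bool(table.records) is kept, occ

    def test_polar_precedence_over_hydrophobic(self):
        pep = make_peptide(114, "GyRPQNVLT", "B")
        prof = _profile({("hbond", "s", "s"): 0.4, ("hydrophobic", "s", "s"): 0.6})
        rec = stable_interactions([prof], pep).records[0]
        assert rec.kind == "hbond"
        assert rec.occupancy == pytest.approx(0.4)

    def test_hydrophobic_wins_when_polar_below_threshold(self):
        pep = make_peptide(114, "GyRPQNVLT", "B")
        prof = _profile({("hbond", "s", "s"): 0.2, ("hydrophobic", "hs", "s"): 0.6})
        rec = stable_interactions([prof], pep).records[0]
        assert rec.kind == "hydrophobic"
        assert rec.class_label == "hs-s"

    def test_ligand_outside_window_rejected(self):
        pep = make_peptide(114, "GyRPQNVLT", "B")
        prof = _profile({("saltbridge", "s", "s"): 0.5}, lignum=500)
        with pytest.raises(PeptideError):
            stable_interactions([prof], pep)

    def test_no_peptide_skips_regions_and_window(self):
        prof = _profile({("saltbridge", "s", "s"): 0.5}, lignum=500)
        table = stable_interactions([prof], None)
        assert table.records[0].region is None

    def test_threshold_monotonicity(self, table1_fixture):
        traj, _, pep = table1_fixture
        profiles = accumulate(detect_all(traj, "B", "A"), traj)
        kept = {}
        for thr in (0.2, 0.3, 0.5, 0.7):
            kept[thr] = {(r.ligand_res, r.receptor_res)
                         for r in stable_interactions(profiles, pep, thr).records}
        assert kept[0.7] <= kept[0.5] <= kept[0.3] <= kept[0.2]


class TestClassLabels:
    def test_sidechain_to_mainchain_is_s_m(self):
        """Polar ligand side chain against a receptor backbone carbonyl."""
        traj, _, events = planted_pipeline(
            "hbond", ResidueSpec("GLN", 3, "NE2"), ResidueSpec("GLY", 9, "O"),
            occupancy=0.5)
        table = stable_interactions(accumulate(events, traj), None)
        assert [r.class_label for r in table.records] == ["s-m"]

    def test_apolar_part_of_polar_sidechain_is_hs(self):
        traj, _, events = planted_pipeline(
            "hydrophobic", ResidueSpec("GLN", 3, "CB"),
            ResidueSpec("MET", 9, "SD"), occupancy=0.5)
        table = stable_interactions(accumulate(events, traj), None)
        assert [r.class_label for r in table.records] == ["hs-s"]

    def test_fully_apolar_sidechain_reports_s(self):
        traj, _, events = planted_pipeline(
            "hydrophobic", ResidueSpec("VAL", 3, "CG1"),
            ResidueSpec("LEU", 9, "CD1"), occupancy=0.5)
        table = stable_interactions(accumulate(events, traj), None)
        assert [r.class_label for r in table.records] == ["s-s"]


class TestDistanceTimeseries:
    def test_rigid_fixture_constant_series(self):
        traj, _, _ = planted_pipeline(
            "saltbridge", ResidueSpec("ASP", 7, "OD1"),
            ResidueSpec("LYS", 42, "NZ"), occupancy=1.0, n_frames=8)
        df = distance_timeseries(traj, "B", 7, "A", 42)
        assert len(df) == 8
        np.testing.assert_allclose(df.distance_A, 2.8, atol=1e-9)

    def test_sinusoidal_displacement_recovered(self):
        planted = [6.0 + 2.0 * math.sin(2 * math.pi * i / 25) for i in range(50)]
        frames = [Frame(index=i, residues=[
            make_residue("VAL", 1, "B", [("CG1", (0, 0, 0))]),
            make_residue("LEU", 2, "A", [("CD1", (d, 0, 0))], serial_start=5)])
            for i, d in enumerate(planted)]
        traj = Trajectory(frames=frames, dt=2.0)
        df = distance_timeseries(traj, "B", 1, "A", 2)
        np.testing.assert_allclose(df.distance_A, planted, atol=1e-9)
        assert df.distance_A.max() == pytest.approx(max(planted))
        assert list(df.time_ps) == [2.0 * i for i in range(50)]

    def test_final_fraction_window(self):
        """A 24-frame mock with the final-15-frame window yields 15 values."""
        traj, _, _ = planted_pipeline(
            "saltbridge", ResidueSpec("ASP", 7, "OD1"),
            ResidueSpec("LYS", 42, "NZ"), occupancy=1.0, n_frames=24)
        df = distance_timeseries(traj, "B", 7, "A", 42, window=(9, 24))
        assert len(df) == 15
        assert list(df.frame) == list(range(9, 24))

    def test_empty_window_rejected(self, single_frame_trajectory):
        with pytest.raises(ValueError, match="window"):
            distance_timeseries(single_frame_trajectory, "B", 1, "A", 2,
                                window=(1, 1))


def test_pipeline_matches_ground_truth_exactly(table1_fixture):
    traj, gt, pep = table1_fixture
    table = profile_trajectory(traj, "B", "A", pep)
    got = {(r.ligand_res, r.receptor_res): (r.kind, r.class_label, r.occupancy)
           for r in table.records}
    expected = {(t.ligand_res, t.receptor_res): (t.kind, t.class_label, t.occupancy)
                for t in gt.contacts}
    assert got == expected
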