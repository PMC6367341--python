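"""PDB parsing, Kabsch superposition, Rg, trajectory plateaus, contacts."""

import numpy as np
import pytest

from albind import (
    parse_structure, parse_trajectory, kabsch_superpose, radius_of_gyration,
    trajectory_stats, find_polar_contacts,
)
from albind.synthetic import gen_trajectory
from conftest import pdb_line


def _rotation_z(deg):
    a = np.deg2rad(deg)
    return np.array([[np.cos(a), -np.sin(a), 0],
                     [np.sin(a), np.cos(a), 0],
                     [0, 0, 1.0]])


def _quat_to_rot(q):
    w, x, y, z = q / np.linalg.norm(q)
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])


def _quaternion_grid_rmsd(mobile, reference):
    """Independent superposition oracle: quaternion search refined to <1 deg.

    Coarse random-uniform quaternion sweep followed by shrinking local
    perturbations; never touches the SVD-based implementation.
    """
    rng = np.random.default_rng(12345)
    mob = mobile - mobile.mean(axis=0)
    ref = reference - reference.mean(axis=0)

    def rmsd_of(q):
        moved = mob @ _quat_to_rot(q).T
        return np.sqrt(np.mean(np.sum((moved - ref) ** 2, axis=1)))

    qs = rng.standard_normal((4000, 4))
    vals = [rmsd_of(q) for q in qs]
    best_q = qs[int(np.argmin(vals))]
    best = min(vals)
    for scale in np.geomspace(0.2, 0.001, 12):  # down to ~0.1 deg steps
        for _ in range(60):
            q = best_q + scale * rng.standard_normal(4)
            val = rmsd_of(q)
            if val < best:
                best, best_q = val, q
    return best


class TestParseStructure:
    def test_three_atom_fixture(self, three_atom_pdb):
        model = parse_structure(three_atom_pdb)
        assert len(model) == 3
        assert np.allclose(model.coords[0], [1.0, 2.0, 3.0])
        assert list(model.elements) == ["N", "C", "C"]
        assert model.masses[0] == pytest.approx(14.007, abs=0.01)

    def test_altloc_keeps_first(self, altloc_pdb):
        model = parse_structure(altloc_pdb)
        assert len(model) == 2
        assert np.allclose(model.coords[0], [0.0, 0.0, 0.0])

    def test_strip_water(self, water_pdb):
        assert len(parse_structure(water_pdb, strip_water=True)) == 1
        assert len(parse_structure(water_pdb)) == 2

    def test_malformed_line_skipped_with_warning(self, three_atom_pdb):
        text = three_atom_pdb.replace("END", "ATOM  garbage\nEND")
        with pytest.warns(UserWarning, match="malformed"):
            model = parse_structure(text)
        assert len(model) == 3

    def test_no_atoms_rejected(self):
        with pytest.raises(Exception):
            parse_structure("HEADER  empty\nEND\n")


class TestKabsch:
    def test_identity_on_equal_sets(self):
        coords = np.random.default_rng(0).standard_normal((10, 3))
        R, t, rmsd = kabsch_superpose(coords, coords)
        assert rmsd == pytest.approx(0.0, abs=1e-10)
        assert np.allclose(R, np.eye(3), atol=1e-10)

    def test_rigid_motion_removed(self):
        rng = np.random.default_rng(1)
        ref = rng.standard_normal((25, 3))
        mobile = ref @ _rotation_z(37.0).T + np.array([5.0, -2.0, 1.0])
        _, _, rmsd = kabsch_superpose(mobile, ref)
        assert rmsd == pytest.approx(0.0, abs=1e-9)

    def test_proper_rotation_always(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            a = rng.standard_normal((8, 3))
            b = rng.standard_normal((8, 3))
            R, _, _ = kabsch_superpose(a, b)
            assert np.linalg.det(R) == pytest.approx(1.0, abs=1e-9)

    def test_matches_quaternion_grid_oracle(self):
        rng = np.random.default_rng(3)
        for trial in range(3):
            ref = rng.standard_normal((50, 3))
            mobile = (ref @ _rotation_z(25.0 + 10 * trial).T
                      + 0.1 * rng.standard_normal((50, 3)) + [1.0, 2.0, 3.0])
            _, _, rmsd = kabsch_superpose(mobile, ref)
            oracle = _quaternion_grid_rmsd(mobile, ref)
            assert abs(rmsd - oracle) < 1e-3

    def test_degenerate_sets_rejected(self):
        line = np.column_stack([np.arange(5.0), np.zeros(5), np.zeros(5)])
        with pytest.raises(ValueError, match="collinear|degenerate"):
            kabsch_superpose(line, line + 1.0)
        with pytest.raises(ValueError):
            kabsch_superpose(np.zeros((2, 3)), np.zeros((2, 3)))


class TestRadiusOfGyration:
    def test_single_atom(self):
        assert radius_of_gyration(np.zeros((1, 3)), [12.0]) == 0.0

    def test_two_unit_masses(self):
        coords = np.array([[1.0, 0, 0], [-1.0, 0, 0]])
        assert radius_of_gyration(coords, [1.0, 1.0]) == pytest.approx(1.0)

    def test_uniform_lattice_closed_form(self):
        # 5x5x5 unit lattice: per-axis variance 2, Rg = sqrt(6)
        axes = np.arange(5.0)
        coords = np.array([[x, y, z] for x in axes for y in axes for z in axes])
        direct = np.sqrt(np.mean(np.sum((coords - coords.mean(0)) ** 2, axis=1)))
        assert radius_of_gyration(coords) == pytest.approx(np.sqrt(6.0), rel=1e-12)
        assert radius_of_gyration(coords) == pytest.approx(direct, rel=1e-12)

    def test_rigid_motion_invariance_and_scaling(self):
        rng = np.random.default_rng(4)
        coords = rng.standard_normal((30, 3))
        masses = rng.uniform(1, 16, 30)
        base = radius_of_gyration(coords, masses)
        moved = coords @ _rotation_z(63.0).T + [10.0, -3.0, 7.0]
        assert radius_of_gyration(moved, masses) == pytest.approx(base, rel=1e-12)
        assert radius_of_gyration(2.5 * coords, masses) == pytest.approx(
            2.5 * base, rel=1e-12)

    def test_mass_weighting_matters(self):
        coords = np.array([[0.0, 0, 0], [1.0, 0, 0]])
        heavy_left = radius_of_gyration(coords, [15.999, 1.008])
        assert heavy_left < radius_of_gyration(coords, [1.0, 1.0])


class TestTrajectoryStats:
    def test_identical_frames(self):
        model, traj = gen_trajectory(n_atoms=40, n_frames=20, plateau_rmsd=0.0,
                                     plateau_rg=10.0, seed=0)
        stats = trajectory_stats(traj, model)
        assert np.allclose(stats["rmsd"], 0.0, atol=1e-9)
        assert np.ptp(stats["rg"]) == pytest.approx(0.0, abs=1e-9)
        assert stats["plateau_start"] == traj.times[0]

    def test_planted_plateau_recovered(self):
        model, traj = gen_trajectory(plateau_rmsd=3.4, plateau_rg=27.6, seed=1)
        stats = trajectory_stats(traj, model)
        assert abs(stats["plateau_mean_rmsd"] - 3.4) / 3.4 < 0.02
        assert abs(stats["plateau_mean_rg"] - 27.6) / 27.6 < 0.02
        # construction mean over the detected plateau frames
        sel = traj.times >= stats["plateau_start"]
        assert stats["plateau_mean_rmsd"] == pytest.approx(
            np.mean(stats["rmsd"][sel]), abs=0.05)

    def test_plateau_not_declared_during_ramp(self):
        model, traj = gen_trajectory(seed=2)
        stats = trajectory_stats(traj, model)
        ramp_end = 0.4 * traj.times[-1]
        assert stats["plateau_start"] >= 0.5 * ramp_end

    def test_frame_order_reversal_same_values(self):
        from albind import Trajectory
        model, traj = gen_trajectory(n_atoms=30, n_frames=12, seed=3)
        rev = Trajectory(coords=traj.coords[::-1].copy(), times=traj.times)
        a = trajectory_stats(traj, model)["rmsd"]
        b = trajectory_stats(rev, model)["rmsd"]
        assert np.allclose(sorted(a), sorted(b))

    def test_fixed_window(self):
        model, traj = gen_trajectory(seed=4)
        stats = trajectory_stats(traj, model, window=(30000.0, 60000.0))
        assert stats["plateau_start"] == 30000.0

    def test_empty_selection_rejected(self):
        model, traj = gen_trajectory(n_atoms=10, n_frames=5, seed=5)
        with pytest.raises(ValueError, match="selection"):
            trajectory_stats(traj, model, selection=np.zeros(10, bool))


class TestPolarContacts:
    def test_planted_arginine_geometry(self, arg_contact_pair):
        ligand, protein = arg_contact_pair
        records = find_polar_contacts(ligand, protein, cutoff=3.5)
        hbonds = [r for r in records if r.classification == "hbond_candidate"]
        assert sorted(round(r.distance, 2) for r in hbonds) == [3.09, 3.23]
        assert all(r.protein_residue == "ARG197" for r in hbonds)

    def test_pair_beyond_cutoff_excluded(self, arg_contact_pair):
        ligand, protein = arg_contact_pair
        records = find_polar_contacts(ligand, protein, cutoff=3.5)
        assert not any(r.protein_residue == "ASP10" for r in records)

    def test_carbon_pairs_not_hbond_candidates(self, arg_contact_pair):
        ligand, protein = arg_contact_pair
        records = find_polar_contacts(ligand, protein, cutoff=3.5)
        cz = [r for r in records if r.protein_atom == "CZ"]
        assert cz and all(r.classification != "hbond_candidate" for r in cz)

    def test_distances_match_euclidean_oracle(self, arg_contact_pair):
        ligand, protein = arg_contact_pair
        for r in find_polar_contacts(ligand, protein, cutoff=10.0):
            j = list(protein.names).index(r.protein_atom)
            d = np.linalg.norm(ligand.coords[0] - protein.coords[j])
            assert r.distance == pytest.approx(d, rel=1e-12)


def test_multi_model_pdb_parsed_as_trajectory(three_atom_pdb):
    body = three_atom_pdb.replace("END\n", "")
    text = ("MODEL     1\n" + body + "ENDMDL\n"
            "MODEL     2\n" + body.replace(" 1.000", " 2.000") + "ENDMDL\nEND\n")
    ref, traj = parse_trajectory(text, dt_ps=10.0)
    assert traj.n_frames == 2
    assert traj.times[1] == 10.0
    assert len(ref) == 3
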