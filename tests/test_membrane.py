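"""Superposition, R_g, COM displacement, H-bonds, unwrapping, crossings,
lipid radial density."""

import numpy as np
import pytest

from contactmodes import membrane as mb
from contactmodes import synth
from conftest import make_bead_structure, make_trajectory
from oracles import quaternion_superpose_rmsd


def rot_z(theta):
    return np.array([[np.cos(theta), -np.sin(theta), 0],
                     [np.sin(theta), np.cos(theta), 0], [0, 0, 1]])


class TestSuperpose:
    def test_identical_structures(self, rng):
        P = rng.normal(size=(6, 3))
        R, t, rmsd = mb.superpose(P, P)
        assert rmsd == pytest.approx(0.0, abs=1e-10)
        np.testing.assert_allclose(R, np.eye(3), atol=1e-8)

    def test_rigid_motion_gives_zero_rmsd(self, rng):
        P = rng.normal(size=(7, 3))
        Q = P @ rot_z(np.pi / 2).T + np.array([3.0, -1.0, 8.0])
        _, _, rmsd = mb.superpose(P, Q)
        assert rmsd == pytest.approx(0.0, abs=1e-10)

    def test_rotation_is_proper(self, rng):
        P = rng.normal(size=(5, 3))
        Q = rng.normal(size=(5, 3))
        R, _, _ = mb.superpose(P, Q)
        assert np.linalg.det(R) == pytest.approx(1.0, abs=1e-10)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_quaternion_oracle(self, seed):
        rng = np.random.default_rng(seed)
        P = rng.normal(size=(5, 3))
        Q = rng.normal(size=(5, 3))
        _, _, rmsd = mb.superpose(P, Q)
        assert rmsd == pytest.approx(quaternion_superpose_rmsd(P, Q), abs=1e-8)

    def test_collinear_subset_rejected(self):
        P = np.array([[0.0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]])
        with pytest.raises(ValueError, match="collinear"):
            mb.superpose(P, P + 1.0)


class TestRgAndRmsdSeries:
    def test_two_unit_mass_atoms_two_angstrom_apart(self):
        assert mb.radius_of_gyration(np.array([[0.0, 0, 0], [2, 0, 0]])) == 1.0

    def test_single_atom_is_zero(self):
        assert mb.radius_of_gyration(np.array([[5.0, 5, 5]])) == 0.0

    def test_matches_brute_force_definition(self, rng):
        xyz = rng.normal(size=(100, 3))
        w = rng.uniform(1, 16, 100)
        com = (w[:, None] * xyz).sum(0) / w.sum()
        want = np.sqrt((w * ((xyz - com) ** 2).sum(1)).sum() / w.sum())
        assert mb.radius_of_gyration(xyz, masses=w) == pytest.approx(want, abs=1e-10)

    def test_rigid_motion_invariance(self, rng):
        xyz = rng.normal(size=(20, 3))
        moved = xyz @ rot_z(0.4).T + np.array([1.0, 2.0, 3.0])
        assert (mb.radius_of_gyration(moved)
                == pytest.approx(mb.radius_of_gyration(xyz), abs=1e-10))

    def test_rigid_motion_trajectory_rmsd_is_zero(self, rng):
        s = make_bead_structure([2, 2, 2], rng)
        coords = [s.reference_coordinates @ rot_z(0.3 * k).T + k
                  for k in range(5)]
        traj = make_trajectory(s, coords)
        series = mb.rmsd_series(traj, s.reference_coordinates)
        np.testing.assert_allclose(series.values, 0.0, atol=1e-10)

    def test_jittered_trajectory_rmsd_matches_expectation(self, rng):
        """After fitting, E[RMSD^2] = sigma^2 (3N-6)/N for small jitter."""
        s = make_bead_structure([4] * 50, rng)  # N = 200 atoms
        sigma = 0.3
        coords = [s.reference_coordinates + rng.normal(0, sigma, (200, 3))
                  for _ in range(40)]
        series = mb.rmsd_series(make_trajectory(s, coords),
                                s.reference_coordinates)
        want = sigma * np.sqrt(3 - 6 / 200)
        assert series.values.mean() == pytest.approx(want, rel=0.1)


class TestCOM:
    def test_protein_at_bilayer_com_is_zero(self, rng):
        s = make_bead_structure([1, 1], rng)
        c = np.array([[0.0, 0, 5.0], [0, 0, 5.0]])
        traj = make_trajectory(s, [c])
        series = mb.com_displacement_along_normal(traj, np.array([0]),
                                                  np.array([1]), axis=2)
        assert series.values[0] == 0.0

    def test_fifteen_angstrom_shift(self, rng):
        s = make_bead_structure([1, 1], rng)
        c = np.array([[0.0, 0, 20.0], [0, 0, 5.0]])
        traj = make_trajectory(s, [c])
        series = mb.com_displacement_along_normal(traj, np.array([0]),
                                                  np.array([1]), axis=2)
        assert series.values[0] == pytest.approx(15.0)

    def test_empty_subset_rejected(self, rng):
        s = make_bead_structure([1, 1], rng)
        traj = make_trajectory(s, [s.reference_coordinates])
        with pytest.raises(ValueError):
            mb.com_displacement_along_normal(traj, np.array([], dtype=int),
                                             np.array([1]))


class TestHbonds:
    def _triad(self, d_da, theta_deg):
        u = np.array([1.0, 0.0, 0.0])
        th = np.deg2rad(theta_deg)
        h_dir = np.array([np.cos(th), np.sin(th), 0.0])
        return np.array([[0.0, 0, 0], h_dir, u * d_da])

    def test_ideal_collinear_geometry_counted(self):
        crit = mb.HBondCriteria(donors=[(0, 1)], acceptors=[2])
        n, pairs = mb.count_hbonds(self._triad(3.0, 0.0), crit)
        assert n == 1 and pairs == [(0, 1, 2)]

    def test_distance_beyond_cutoff_not_counted(self):
        crit = mb.HBondCriteria(donors=[(0, 1)], acceptors=[2])
        assert mb.count_hbonds(self._triad(3.6, 0.0), crit)[0] == 0

    def test_angle_beyond_cutoff_not_counted(self):
        crit = mb.HBondCriteria(donors=[(0, 1)], acceptors=[2])
        assert mb.count_hbonds(self._triad(3.0, 25.0), crit)[0] == 0

    def test_fixture_matches_planned_set_exactly(self):
        coords, crit, truth = synth.generate_hbond_fixture(50, 0.4, seed=9)
        n, pairs = mb.count_hbonds(coords, crit)
        assert sorted(p[0] // 3 for p in pairs) == sorted(truth.satisfying_triads)

    @pytest.mark.parametrize("grid_attr,values", [
        ("distance_cutoff_A", [2.8, 3.2, 3.5, 4.0, 5.0]),
        ("angle_cutoff_deg", [5.0, 10.0, 20.0, 40.0, 80.0]),
    ])
    def test_count_monotone_in_cutoffs(self, grid_attr, values):
        coords, crit, _ = synth.generate_hbond_fixture(40, 0.5, seed=4)
        counts = []
        for v in values:
            kw = {"donors": crit.donors, "acceptors": crit.acceptors,
                  "distance_cutoff_A": crit.distance_cutoff_A,
                  "angle_cutoff_deg": crit.angle_cutoff_deg, grid_attr: v}
            counts.append(mb.count_hbonds(coords, mb.HBondCriteria(**kw))[0])
        assert counts == sorted(counts)

    def test_inconsistent_hydrogen_skips_donor(self):
        coords = np.array([[0.0, 0, 0], [2.0, 0, 0], [3.0, 0, 0]])
        crit = mb.HBondCriteria(donors=[(0, 1)], acceptors=[2])
        with pytest.warns(UserWarning, match="covalently"):
            n, _ = mb.count_hbonds(coords, crit)
        assert n == 0


class TestUnwrapAndCrossings:
    def test_wrap_crossing_example(self):
        np.testing.assert_allclose(mb.unwrap_axis(np.array([9.0, 1.0]), 10.0),
                                   [9.0, 11.0])

    def test_constant_series_unchanged(self):
        np.testing.assert_allclose(mb.unwrap_axis(np.full(5, 3.0), 10.0), 3.0)

    def test_round_trip_recovers_hidden_path(self):
        wrapped, boxes, truth = synth.generate_slab_world(
            n_particles=50, n_frames=200, seed=3, drift=0.4)
        unw = mb.unwrap_axis(wrapped, boxes)
        np.testing.assert_allclose(unw, truth.continuous_paths, atol=1e-9)

    def test_monotonic_traversal_is_one_event(self):
        z = np.linspace(-20.0, 20.0, 40)
        events = mb.count_crossings(z, -15.0, 15.0)
        assert len(events) == 1 and events[0].direction == +1

    def test_incomplete_entry_is_no_event(self):
        z = np.array([-20.0, -10.0, 0.0, -10.0, -20.0])
        assert mb.count_crossings(z, -15.0, 15.0) == []

    def test_return_trip_counts_both_directions(self):
        z = np.array([-20.0, 0.0, 20.0, 0.0, -20.0])
        events = mb.count_crossings(z, -15.0, 15.0)
        assert [e.direction for e in events] == [+1, -1]

    def test_slab_world_counts_match_ground_truth(self):
        wrapped, boxes, truth = synth.generate_slab_world(
            n_particles=200, n_frames=300, box_z=60.0, slab=(22.0, 38.0),
            drift=0.25, diffusion=1.5, seed=17)
        events = mb.count_crossings(mb.unwrap_axis(wrapped, boxes),
                                    22.0, 38.0, box_z=60.0)
        got = [(e.particle_id, e.start_frame, e.end_frame, e.direction)
               for e in events]
        want = [(e.particle_id, e.start_frame, e.end_frame, e.direction)
                for e in truth.crossing_events]
        assert got == want

    def test_net_crossings_equal_net_image_displacement(self):
        """Conservation: per particle, (+1) - (-1) events equals the number
        of slab images between start and end positions."""
        wrapped, boxes, truth = synth.generate_slab_world(
            n_particles=100, n_frames=300, box_z=60.0, slab=(22.0, 38.0),
            drift=0.5, diffusion=2.0, seed=23)
        paths = truth.continuous_paths
        net = np.zeros(100, dtype=int)
        for e in truth.crossing_events:
            net[e.particle_id] += e.direction

        def gap(x):  # gap index when outside all slab images, else None
            k = int(np.floor((x - 22.0) / 60.0))
            return k if x - k * 60.0 > 38.0 else None

        for p in range(100):
            a, b = gap(paths[0, p]), gap(paths[-1, p])
            if a is not None and b is not None:
                assert net[p] == b - a

    def test_bad_slab_rejected(self):
        with pytest.raises(ValueError):
            mb.count_crossings(np.zeros(3), 5.0, 5.0)


class TestLipidDensity:
    def test_single_marker_lands_in_correct_shell(self):
        frame = np.array([[0.0, 0, 0], [5.0, 0, 0]])
        prof = mb.lipid_radial_density([frame], np.array([1]), np.array([0]),
                                       np.array([0.0, 4.0, 8.0]))
        vol2 = 4 / 3 * np.pi * (8.0 ** 3 - 4.0 ** 3)
        assert prof.number_density[0] == 0.0
        assert prof.number_density[1] == pytest.approx(1.0 / vol2)

    def test_uniform_markers_give_flat_profile(self, rng):
        n = 40000
        pts = rng.uniform(0, 80.0, size=(n, 3))
        frame = np.vstack([[[40.0, 40.0, 40.0]], pts])
        edges = np.array([5.0, 10.0, 15.0, 20.0, 25.0])
        prof = mb.lipid_radial_density([frame], np.arange(1, n + 1),
                                       np.array([0]), edges)
        rho = n / 80.0 ** 3
        np.testing.assert_allclose(prof.number_density, rho, rtol=0.12)

    def test_planted_enrichment_recovered(self):
        markers, prot, truth = synth.generate_lipid_shell_fixture(
            n_markers=60000, enrichment_factor=3.0, inner_radius=10.0,
            box=80.0, seed=6)
        frame = np.vstack([prot, markers])
        prof = mb.lipid_radial_density([frame], np.arange(1, len(markers) + 1),
                                       np.array([0]),
                                       np.array([0.0, 10.0, 20.0, 30.0]))
        ratio = prof.number_density[0] / prof.number_density[1:].mean()
        assert ratio == pytest.approx(3.0, rel=0.2)

    def test_empty_protein_rejected(self):
        with pytest.raises(ValueError):
            mb.lipid_radial_density([np.zeros((3, 3))], np.array([1]),
                                    np.array([], dtype=int),
                                    np.array([0.0, 5.0]))
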