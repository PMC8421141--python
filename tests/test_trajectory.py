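"""Trajectory geometry: axis contouring, plane projection, bend angles,
Kabsch RMSD, clustering and hydrogen-bond contact maps."""

import numpy as np
import pandas as pd
import pytest
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform
from scipy.spatial.transform import Rotation

from bendscape.simulate import HBondFixture, generate_toy_trajectory
from bendscape.trajectory import (Trajectory, bend_angle_axis, cluster_frames,
                                  hbond_contact_map, helix_axis, kabsch_rmsd,
                                  pairwise_rmsd_matrix, project_best_fit_plane)


def _ladder_frame(n_bp, rise=0.34):
    """Paired atoms straddling a straight z axis: midpoints collinear."""
    frame = np.zeros((2 * n_bp, 3))
    for i in range(n_bp):
        frame[2 * i] = (1.0, 0.0, i * rise)
        frame[2 * i + 1] = (-1.0, 0.0, i * rise)
    pairing = [(2 * i, 2 * i + 1) for i in range(n_bp)]
    return frame, pairing


class TestHelixAxis:
    def test_collinear_midpoints_unchanged(self):
        frame, pairing = _ladder_frame(30)
        axis = helix_axis(frame, pairing)
        assert len(axis) == 30
        expected = np.column_stack([np.zeros(30), np.zeros(30),
                                    0.34 * np.arange(30)])
        np.testing.assert_allclose(axis.points, expected, atol=1e-12)

    def test_ideal_helix_axis_recovered(self):
        # helix radius 1 nm, pitch 10.5 bp about the z axis
        n_bp, rise, radius = 60, 0.34, 1.0
        phase = 2 * np.pi * np.arange(n_bp) / 10.5
        strand1 = np.column_stack([radius * np.cos(phase),
                                   radius * np.sin(phase),
                                   rise * np.arange(n_bp)])
        strand2 = np.column_stack([radius * np.cos(phase + np.pi),
                                   radius * np.sin(phase + np.pi),
                                   rise * np.arange(n_bp)])
        frame = np.vstack([strand1, strand2])
        pairing = [(i, n_bp + i) for i in range(n_bp)]
        axis = helix_axis(frame, pairing)
        true_line = np.column_stack([np.zeros(n_bp), np.zeros(n_bp),
                                     rise * np.arange(n_bp)])
        rms = np.sqrt(np.mean(np.sum((axis.points - true_line) ** 2, axis=1)))
        assert rms < 0.15

    def test_too_few_bp_rejected(self):
        frame, pairing = _ladder_frame(8)
        with pytest.raises(ValueError):
            helix_axis(frame, pairing)


class TestBestFitPlane:
    def test_planar_input_identity(self, rng):
        pts = np.column_stack([rng.normal(size=30), rng.normal(size=30),
                               np.zeros(30)])
        proj, planarity = project_best_fit_plane(pts)
        np.testing.assert_allclose(proj, pts, atol=1e-12)
        assert planarity == pytest.approx(0.0, abs=1e-9)

    def test_alternating_heights_over_circle(self):
        n, h = 40, 0.3
        phi = np.linspace(0, 2 * np.pi, n, endpoint=False)
        z = h * np.where(np.arange(n) % 2 == 0, 1.0, -1.0)
        pts = np.column_stack([5 * np.cos(phi), 5 * np.sin(phi), z])
        proj, planarity = project_best_fit_plane(pts)
        # symmetric about z = 0: plane is z = 0, out-of-plane RMS = h
        assert np.allclose(proj[:, 2], 0.0, atol=1e-9)
        rg = np.sqrt(np.mean(np.sum((pts - pts.mean(0)) ** 2, axis=1)))
        assert planarity == pytest.approx(100 * h / rg, rel=1e-9)

    def test_normal_equivariant_under_rotation(self, rng):
        pts = np.column_stack([rng.normal(size=25), rng.normal(size=25),
                               0.1 * rng.normal(size=25)])
        rot = Rotation.from_euler("xyz", [0.3, -1.1, 0.7]).as_matrix()
        _, p0 = project_best_fit_plane(pts)
        _, p1 = project_best_fit_plane(pts @ rot.T)
        assert p1 == pytest.approx(p0, rel=1e-9)

    def test_collinear_rejected(self):
        pts = np.column_stack([np.arange(10.0), np.zeros(10), np.zeros(10)])
        with pytest.raises(ValueError):
            project_best_fit_plane(pts)


class TestBendAngleAxis:
    def test_straight_axis_zero(self):
        pts = np.column_stack([np.arange(100.0), np.zeros(100), np.zeros(100)])
        assert bend_angle_axis(pts, center_bp=50) == pytest.approx(0.0, abs=1e-9)

    @pytest.mark.parametrize("bend", [40.0, 90.0, 147.0])
    def test_constructed_kink_recovered(self, bend):
        # rotate the downstream half of a straight axis by the bend angle
        n = 120
        pts = np.column_stack([np.arange(n, dtype=float), np.zeros(n),
                               np.zeros(n)])
        c = 60
        ang = np.radians(bend)
        rot = np.array([[np.cos(ang), -np.sin(ang), 0],
                        [np.sin(ang), np.cos(ang), 0], [0, 0, 1.0]])
        pts[c:] = (pts[c:] - pts[c]) @ rot.T + pts[c]
        assert bend_angle_axis(pts, center_bp=c) == pytest.approx(bend, abs=0.5)

    def test_circular_arc_tangent_rotation(self):
        # arc of radius R: theta equals the turn over the spanned region
        R = 200.0
        s = np.arange(120.0)
        phi = s / R
        pts = np.column_stack([R * np.sin(phi), R * (1 - np.cos(phi)),
                               np.zeros(120)])
        got = bend_angle_axis(pts, center_bp=60, span_bp=30, gap_bp=30)
        # v1, v2 are chords of 30 bp separated by 30 bp: turn = 60 bp / R
        assert got == pytest.approx(np.degrees(60.0 / R), abs=0.01)

    def test_out_of_range_reports_required_length(self):
        pts = np.column_stack([np.arange(50.0), np.zeros(50), np.zeros(50)])
        with pytest.raises(ValueError, match="50 points"):
            bend_angle_axis(pts, center_bp=25)


class TestKabschRMSD:
    def test_identical_zero(self, rng):
        a = rng.normal(size=(20, 3))
        assert kabsch_rmsd(a, a) == pytest.approx(0.0, abs=1e-9)

    def test_rigid_transform_zero(self, rng):
        a = rng.normal(size=(20, 3))
        rot = Rotation.from_euler("zyx", [1.0, 0.4, -2.2]).as_matrix()
        b = a @ rot.T + np.array([3.0, -1.0, 7.0])
        assert kabsch_rmsd(a, b) == pytest.approx(0.0, abs=1e-9)

    def test_three_point_analytic_case(self):
        # equilateral triangle vs the same triangle stretched along x:
        # optimal superposition is the identity by symmetry
        a = np.array([[1.0, 0.0, 0.0],
                      [-0.5, np.sqrt(3) / 2, 0.0],
                      [-0.5, -np.sqrt(3) / 2, 0.0]])
        b = a * np.array([2.0, 1.0, 1.0])
        expected = np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1)))
        assert kabsch_rmsd(a, b) == pytest.approx(expected, rel=1e-9)

    def test_no_reflection_allowed(self):
        a = np.array([[1.0, 0, 0], [0, 1.0, 0], [0, 0, 1.0], [1, 1, 1.0]])
        b = a * np.array([1.0, 1.0, -1.0])      # mirror image
        assert kabsch_rmsd(a, b) > 0.1

    def test_mismatched_selection_rejected(self, rng):
        with pytest.raises(ValueError):
            kabsch_rmsd(rng.normal(size=(5, 3)), rng.normal(size=(6, 3)))


class TestClusterFrames:
    def test_three_synthetic_families_recovered_exactly(self, rng):
        fams = [rng.normal(scale=15.0, size=(10, 3)) for _ in range(3)]
        traj, labels = generate_toy_trajectory(30, fams, noise=0.2, rng=rng)
        got, reps, _ = cluster_frames(traj, n_clusters=3)
        # same partition up to label permutation
        for k in range(3):
            members = got[labels == k]
            assert len(set(members)) == 1
        assert len(set(got[reps])) == 3

    def test_three_distinct_frames_become_singletons(self, rng):
        fams = [rng.normal(scale=15.0, size=(8, 3)) for _ in range(3)]
        coords = np.stack(fams)
        topo = pd.DataFrame({"residue_id": [f"X{i}" for i in range(8)],
                             "chain_id": ["A"] * 8, "atom_name": ["CA"] * 8})
        traj = Trajectory(coords, topo)
        labels, reps, _ = cluster_frames(traj, n_clusters=3)
        assert sorted(labels) == [0, 1, 2]

    def test_four_frame_average_linkage_merge_order(self, rng):
        fams = [rng.normal(scale=12.0, size=(6, 3)) for _ in range(4)]
        coords = np.stack(fams)
        topo = pd.DataFrame({"residue_id": [f"X{i}" for i in range(6)],
                             "chain_id": ["A"] * 6, "atom_name": ["CA"] * 6})
        traj = Trajectory(coords, topo)
        mat = pairwise_rmsd_matrix(traj)
        z = linkage(squareform(mat, checks=False), method="average")
        # hand-computed average linkage: first merge = closest pair
        i, j = np.unravel_index(np.argmin(mat + np.eye(4) * 1e9), mat.shape)
        assert {int(z[0, 0]), int(z[0, 1])} == {i, j}
        assert z[0, 2] == pytest.approx(mat[i, j])
        # second merge distance is the average of member distances
        rest = [k for k in range(4) if k not in (i, j)]
        d_pair_rest = {k: 0.5 * (mat[i, k] + mat[j, k]) for k in rest}
        candidates = [mat[rest[0], rest[1]], *d_pair_rest.values()]
        assert z[1, 2] == pytest.approx(min(candidates))

    def test_deterministic(self, rng):
        fams = [rng.normal(scale=15.0, size=(6, 3)) for _ in range(3)]
        traj, _ = generate_toy_trajectory(12, fams, noise=0.1, rng=rng)
        l1, r1, _ = cluster_frames(traj, 3)
        l2, r2, _ = cluster_frames(traj, 3)
        assert np.array_equal(l1, l2) and r1 == r2


class TestHBondContactMap:
    @staticmethod
    def _traj_with_fixture(fix, n_frames=4):
        base = np.array([[50.0, 50.0, 50.0], [52.0, 50.0, 50.0],
                         [54.0, 50.0, 50.0]])
        traj, _ = generate_toy_trajectory(n_frames, [base], noise=0.0,
                                          hbond_fixtures=[fix], seed=1)
        donors = pd.DataFrame({"donor_idx": [3], "h_idx": [4],
                               "residue": ["DON"]})
        acceptors = pd.DataFrame({"atom_idx": [5], "residue": ["ACC"]})
        return traj, donors, acceptors

    def test_ideal_geometry_detected(self):
        traj, d, a = self._traj_with_fixture(
            HBondFixture(da_distance=2.9, dha_angle_deg=180.0))
        cmap = hbond_contact_map(traj, d, a)
        assert cmap.values["DON"] == 1.0
        assert cmap.values["ACC"] == 1.0

    def test_distance_boundary(self):
        traj, d, a = self._traj_with_fixture(
            HBondFixture(da_distance=3.6, dha_angle_deg=180.0))
        cmap = hbond_contact_map(traj, d, a)
        assert cmap.values["DON"] == 0.0

    def test_angle_boundary(self):
        ok, _, _ = self._traj_with_fixture(
            HBondFixture(da_distance=3.0, dha_angle_deg=121.0))
        bad, d, a = self._traj_with_fixture(
            HBondFixture(da_distance=3.0, dha_angle_deg=119.0))
        assert hbond_contact_map(ok, d, a).values["DON"] == 1.0
        assert hbond_contact_map(bad, d, a).values["DON"] == 0.0

    def test_multiple_bonds_capped_at_one(self):
        # three acceptors all bonded to one donor residue in every frame
        base = np.array([[50.0, 50.0, 50.0], [52.0, 50.0, 50.0],
                         [54.0, 50.0, 50.0]])
        fixes = [HBondFixture(donor_pos=(10.0 * k, 0.0, 0.0),
                              donor_residue="DON", acceptor_residue=f"ACC{k}")
                 for k in range(3)]
        traj, _ = generate_toy_trajectory(5, [base], noise=0.0,
                                          hbond_fixtures=fixes, seed=2)
        donors = pd.DataFrame({"donor_idx": [3, 6, 9], "h_idx": [4, 7, 10],
                               "residue": ["DON"] * 3})
        acceptors = pd.DataFrame({"atom_idx": [5, 8, 11],
                                  "residue": ["ACC0", "ACC1", "ACC2"]})
        cmap = hbond_contact_map(traj, donors, acceptors)
        assert cmap.values["DON"] == 1.0      # capped, not 3

    def test_donor_without_hydrogen_skipped(self):
        traj, d, a = self._traj_with_fixture(HBondFixture())
        d.loc[0, "h_idx"] = -1
        cmap = hbond_contact_map(traj, d, a)
        assert cmap.values["DON"] == 0.0


class TestRigidMotionInvariance:
    def test_bend_angle_and_planarity_invariant(self, rng):
        n = 100
        pts = np.cumsum(rng.normal(scale=0.3, size=(n, 3)), axis=0)
        rot = Rotation.from_euler("xyz", [0.5, 1.0, -0.3]).as_matrix()
        moved = pts @ rot.T + np.array([10.0, -5.0, 2.0])
        a0 = bend_angle_axis(pts, 50, span_bp=20, gap_bp=20)
        a1 = bend_angle_axis(moved, 50, span_bp=20, gap_bp=20)
        assert a1 == pytest.approx(a0, abs=1e-9)
        _, p0 = project_best_fit_plane(pts)
        _, p1 = project_best_fit_plane(moved)
        assert p1 == pytest.approx(p0, rel=1e-6)

    def test_planar_projection_preserves_bend_angle(self, rng):
        # for planar axes the projected and 3D bend angles coincide
        n = 100
        xy = np.cumsum(rng.normal(scale=0.4, size=(n, 2)), axis=0)
        pts = np.column_stack([xy, np.zeros(n)])
        proj, _ = project_best_fit_plane(pts)
        a3d = bend_angle_axis(pts, 50, span_bp=20, gap_bp=20)
        aproj = bend_angle_axis(proj, 50, span_bp=20, gap_bp=20)
        assert aproj == pytest.approx(a3d, abs=1e-9)
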