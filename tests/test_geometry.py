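"""Ring-axis frames, ICD sign rules, torsions, pose grids and the
coarse-grained interaction score."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.distance import pdist
from scipy.spatial.transform import Rotation

from azocyd.geometry import (
    MAGIC_ANGLE_DEG,
    AxisFrame,
    Pose,
    Structure,
    classify_location,
    dihedral,
    dipole_axis_angle,
    icd_sign,
    make_scan_grid,
    orientation_weight,
    pair_energy,
    place_pose,
    read_xyz,
    ring_axis,
    scan_profile,
    angle_history_stats,
    write_xyz,
)
from azocyd.synth import gen_toy_complex
from conftest import make_bead


def heptagon(radius=0.5, z=0.0):
    ang = 2 * np.pi * np.arange(7) / 7
    coords = np.column_stack([radius * np.cos(ang), radius * np.sin(ang),
                              np.full(7, z)])
    return Structure(labels=["O"] * 7, coords=coords,
                     selections={"ring": list(range(7))})


class TestRingAxis:
    def test_planar_heptagon_axis_is_z(self):
        frame = ring_axis(heptagon(), "ring")
        assert np.allclose(np.abs(frame.axis), [0, 0, 1], atol=1e-12)
        assert np.allclose(frame.origin, 0.0, atol=1e-12)

    def test_rotated_ring_axis_rotates_identically(self):
        rot = Rotation.from_euler("x", 30, degrees=True)
        ring = heptagon()
        rotated = Structure(labels=ring.labels, coords=rot.apply(ring.coords),
                            selections=ring.selections)
        frame = ring_axis(rotated, "ring")
        expected = rot.apply([0, 0, 1.0])
        assert min(np.linalg.norm(frame.axis - expected),
                   np.linalg.norm(frame.axis + expected)) < 1e-12

    def test_toward_point_fixes_sign(self):
        frame = ring_axis(heptagon(), "ring", toward=np.array([0, 0, 5.0]))
        assert frame.axis[2] > 0
        frame = ring_axis(heptagon(), "ring", toward=np.array([0, 0, -5.0]))
        assert frame.axis[2] < 0

    def test_collinear_selection_rejected(self):
        s = Structure(labels=["O"] * 3,
                      coords=np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0.0]]),
                      selections={"line": [0, 1, 2]})
        with pytest.raises(ValueError, match="collinear"):
            ring_axis(s, "line")

    def test_noisy_ring_axis_within_2_degrees(self):
        ring, _, truth = gen_toy_complex(noise_nm=0.01, seed=9)
        frame = ring_axis(ring, "glycosidic_oxygens")
        cosang = abs(np.dot(frame.axis, truth["axis"]))
        assert np.degrees(np.arccos(min(cosang, 1.0))) < 2.0


class TestDipoleAngle:
    @pytest.mark.parametrize("vec, expected", [
        ((0, 0, 1.0), 0.0),
        ((0, 0, -1.0), 0.0),    # antiparallel folds to 0
        ((1.0, 0, 1.0), 45.0),
        ((1.0, 0, 0), 90.0),
    ])
    def test_reference_angles(self, vec, expected, z_frame):
        assert dipole_axis_angle(np.array(vec), z_frame) == pytest.approx(expected)

    def test_zero_vector_rejected(self, z_frame):
        with pytest.raises(ValueError):
            dipole_axis_angle(np.zeros(3), z_frame)


class TestClassifyLocation:
    def test_origin_is_inside(self, z_frame):
        assert classify_location(np.zeros(3), z_frame) == "inside"

    def test_far_beyond_rim_is_outside(self, z_frame):
        assert classify_location(np.array([0, 0, 1.4]), z_frame) == "outside"

    def test_rim_plane_counts_inside(self, z_frame):
        # closed boundary tie rule
        assert classify_location(np.array([0, 0, 0.4]), z_frame,
                                 rim_offsets=(0.4, 0.4)) == "inside"

    def test_radial_exit(self, z_frame):
        assert classify_location(np.array([0.8, 0, 0]), z_frame,
                                 radial_cutoff=0.4) == "outside"


class TestIcdSign:
    def test_parallel_inside_positive_unit_weight(self):
        sign, w = icd_sign(0.0, "inside")
        assert sign == 1 and w == pytest.approx(1.0)

    def test_magic_angle_null(self):
        sign, w = icd_sign(54.7356, "inside")
        assert sign == 0
        assert abs(w) < 1e-6

    def test_outside_below_magic_angle_negative(self):
        sign, _ = icd_sign(26.3, "outside")
        assert sign == -1

    def test_perpendicular_inside_negative(self):
        sign, w = icd_sign(90.0, "inside")
        assert sign == -1 and w == pytest.approx(-0.5)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            icd_sign(120.0, "inside")

    @given(theta=st.floats(0.0, 90.0))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_inside_outside_antisymmetry(self, theta):
        s_in, _ = icd_sign(theta, "inside")
        s_out, _ = icd_sign(theta, "outside")
        assert s_in == -s_out

    def test_weight_root_is_magic_angle(self):
        from scipy.optimize import brentq
        root = brentq(orientation_weight, 1e-9, 90.0 - 1e-9, xtol=1e-12)
        assert root == pytest.approx(MAGIC_ANGLE_DEG, abs=1e-9)
        assert round(root, 1) == 54.7


class TestDihedral:
    def test_planar_cis_zero(self):
        assert dihedral([0, 1, 0], [0, 0, 0], [1, 0, 0], [1, 1, 0]) == pytest.approx(0.0)

    def test_planar_trans_180(self):
        assert dihedral([0, 1, 0], [0, 0, 0], [1, 0, 0], [1, -1, 0]) == pytest.approx(180.0)

    def test_clockwise_construction_fixes_sign(self):
        # sighting from p2 toward p3 (+x), the far bond at -z is a clockwise
        # quarter turn from the near bond at +y: +90 by the IUPAC convention
        assert dihedral([0, 1, 0], [0, 0, 0], [1, 0, 0], [1, 0, -1]) == pytest.approx(90.0)
        assert dihedral([0, 1, 0], [0, 0, 0], [1, 0, 0], [1, 0, 1]) == pytest.approx(-90.0)

    def test_coincident_points_rejected(self):
        with pytest.raises(ValueError):
            dihedral([0, 0, 0], [0, 0, 0], [1, 0, 0], [1, 1, 0])


class TestScanGrid:
    @pytest.mark.parametrize("start, stop, n_expected", [
        (2.5, -2.5, 101),   # E-isomer approach
        (2.5, -0.2, 55),    # Z-isomer approach
        (4.0, 0.5, 71),     # dimer approach
    ])
    def test_protocol_pose_counts(self, start, stop, n_expected):
        grid = make_scan_grid(start, stop, 0.05, [0.0])
        assert len(grid) == n_expected
        assert grid[0].displacement == start
        assert grid[-1].displacement == pytest.approx(stop)

    def test_distances_descend_from_start(self):
        grid = make_scan_grid(2.5, -2.5, 0.05, [0.0])
        d = [p.displacement for p in grid]
        assert d == sorted(d, reverse=True)

    def test_dihedral_axis_multiplies_grid(self):
        grid = make_scan_grid(2.5, -0.2, 0.05, [-120.0, 0.0, 90.0])
        assert len(grid) == 55 * 3

    def test_oversized_step_single_point_with_warning(self):
        with pytest.warns(UserWarning):
            grid = make_scan_grid(1.0, 0.5, 2.0, [0.0])
        assert len(grid) == 1 and grid[0].displacement == 1.0


class TestPlacePose:
    def test_zero_pose_centers_on_origin(self, z_frame):
        _, rod, _ = gen_toy_complex(theta_deg=20.0, penetration_nm=0.3)
        placed = place_pose(rod, z_frame, Pose(0.0, 0.0))
        assert np.allclose(placed.centroid(), z_frame.origin, atol=1e-12)

    def test_full_turn_is_identity(self, z_frame):
        _, rod, _ = gen_toy_complex(theta_deg=30.0)
        a = place_pose(rod, z_frame, Pose(0.7, 0.0))
        b = place_pose(rod, z_frame, Pose(0.7, 360.0))
        assert np.allclose(a.coords, b.coords, atol=1e-12)

    @given(disp=st.floats(-2.0, 2.0), ang=st.floats(-180.0, 180.0))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_rigidity_preserves_distances(self, disp, ang):
        frame = AxisFrame(origin=np.zeros(3), axis=np.array([0.0, 0.0, 1.0]))
        _, rod, _ = gen_toy_complex(theta_deg=25.0)
        placed = place_pose(rod, frame, Pose(disp, ang))
        assert np.allclose(pdist(placed.coords), pdist(rod.coords), atol=1e-12)


class TestPairEnergy:
    def test_lj_minimum_at_sigma_two_sixth(self, bead_pair):
        a, b = bead_pair
        e = pair_energy(a, b, cutoff_nm=2.5)
        assert e.vdw == pytest.approx(-0.2, rel=1e-10)
        assert e.electrostatic == 0.0
        assert e.total == e.vdw

    def test_beyond_cutoff_zero(self):
        a = make_bead("A", (0, 0, 0))
        b = make_bead("B", (0, 0, 3.0))  # 10 sigma, cutoff 5 sigma
        e = pair_energy(a, b, cutoff_nm=1.5)
        assert e.total == 0.0

    def test_coulomb_attraction_hand_value(self):
        a = make_bead("A", (0, 0, 0), charge=1.0, sigma=1e-3, eps=0.0)
        b = make_bead("B", (0, 0, 1.0), charge=-1.0, sigma=1e-3, eps=0.0)
        e = pair_energy(a, b, cutoff_nm=2.5, dielectric=78.5)
        assert e.electrostatic == pytest.approx(-33.2063711 / 78.5, rel=1e-10)
        assert e.electrostatic < 0

    def test_overlap_rejected(self):
        a = make_bead("A", (0, 0, 0))
        b = make_bead("B", (0, 0, 1e-9))
        with pytest.raises(ValueError, match="overlap"):
            pair_energy(a, b)

    def test_symmetry_and_rigid_motion_invariance(self):
        rng = np.random.default_rng(8)
        coords_a = rng.normal(size=(4, 3))
        coords_b = rng.normal(size=(3, 3)) + [0, 0, 2.0]
        def struct(c):
            n = len(c)
            return Structure(labels=["X"] * n, coords=c,
                             charges=rng.normal(size=n) * 0.1,
                             lj_sigma=np.full(n, 0.3),
                             lj_epsilon=np.full(n, 0.2))
        a, b = struct(coords_a), struct(coords_b)
        e_ab = pair_energy(a, b)
        e_ba = pair_energy(b, a)
        assert e_ab.total == pytest.approx(e_ba.total, rel=1e-12)
        rot = Rotation.from_euler("zyx", [11, 23, 37], degrees=True)
        shift = np.array([0.3, -0.7, 1.1])
        a2 = Structure(a.labels, rot.apply(a.coords) + shift, a.charges,
                       a.lj_sigma, a.lj_epsilon)
        b2 = Structure(b.labels, rot.apply(b.coords) + shift, b.charges,
                       b.lj_sigma, b.lj_epsilon)
        assert pair_energy(a2, b2).total == pytest.approx(e_ab.total, rel=1e-9)


class TestScanProfile:
    @staticmethod
    def toy_system():
        host = make_bead("H", (0, 0, 0), charge=0.0, sigma=0.3, eps=0.5)
        mobile = make_bead("G", (0, 0, 0), charge=0.0, sigma=0.3, eps=0.5)
        frame = AxisFrame(origin=np.zeros(3), axis=np.array([0, 0, 1.0]))
        return host, mobile, frame

    def test_attractive_pair_mbe_at_lj_minimum(self):
        host, mobile, frame = self.toy_system()
        grid = make_scan_grid(2.5, 0.25, 0.005, [0.0])
        prof = scan_profile(host, mobile, frame, grid, cutoff_nm=1.5)
        assert prof.mbe_energy.total < 0
        assert prof.mbe_pose.displacement == pytest.approx(0.3 * 2 ** (1 / 6), abs=0.005)
        assert prof.mbe_energy.total == pytest.approx(-0.5, rel=0.01)

    def test_mbe_not_exceeded_anywhere(self):
        host, mobile, frame = self.toy_system()
        grid = make_scan_grid(2.5, 0.25, 0.01, [0.0, 90.0])
        prof = scan_profile(host, mobile, frame, grid)
        assert all(e.total >= prof.mbe_energy.total for e in prof.energies)

    def test_tail_beyond_cutoff_is_zero(self):
        host, mobile, frame = self.toy_system()
        grid = make_scan_grid(2.5, 0.25, 0.05, [0.0])
        prof = scan_profile(host, mobile, frame, grid, cutoff_nm=1.5)
        assert prof.energies[0].total == 0.0

    def test_repulsive_system_minimizes_at_max_separation(self):
        host = make_bead("H", (0, 0, 0), charge=1.0, sigma=1e-3, eps=0.0)
        mobile = make_bead("G", (0, 0, 0), charge=1.0, sigma=1e-3, eps=0.0)
        frame = AxisFrame(origin=np.zeros(3), axis=np.array([0, 0, 1.0]))
        grid = make_scan_grid(2.0, 0.2, 0.05, [0.0])
        prof = scan_profile(host, mobile, frame, grid, cutoff_nm=5.0)
        assert prof.mbe_pose.displacement == 2.0
        assert prof.mbe_energy.total > 0


class TestAngleHistory:
    def test_identical_frames_zero_sd(self, z_frame):
        _, rod, _ = gen_toy_complex(theta_deg=20.0)
        stats = angle_history_stats([rod, rod, rod], "dipole", z_frame)
        assert stats.mean == pytest.approx(20.0, abs=1e-9)
        assert stats.sd == 0.0
        assert stats.n == 3

    def test_known_angles_mean_and_sd(self, z_frame):
        rods = [gen_toy_complex(theta_deg=t)[1] for t in (10.0, 20.0, 30.0)]
        stats = angle_history_stats(rods, "dipole", z_frame)
        assert stats.mean == pytest.approx(20.0, abs=1e-9)
        assert stats.sd == pytest.approx(10.0, abs=1e-9)  # sample sd

    def test_wobble_trajectory_recovers_mean(self, z_frame):
        rng = np.random.default_rng(17)
        rods = [gen_toy_complex(theta_deg=t)[1]
                for t in rng.normal(25.0, 3.0, size=60)]
        stats = angle_history_stats(rods, "dipole", z_frame)
        assert stats.mean == pytest.approx(25.0, abs=1.0)


class TestToyComplexTruth:
    @pytest.mark.parametrize("theta", [0.0, 45.0, 90.0])
    def test_declared_angle_reproduced(self, theta, z_frame):
        _, rod, truth = gen_toy_complex(theta_deg=theta)
        i, j = rod.selections["dipole"]
        ang = dipole_axis_angle(rod.coords[j] - rod.coords[i], z_frame)
        assert ang == pytest.approx(theta, abs=1e-9)

    @pytest.mark.parametrize("penetration", [0.0, 0.2, 0.8, -0.6])
    def test_declared_location_matches_classifier(self, penetration, z_frame):
        _, rod, truth = gen_toy_complex(penetration_nm=penetration)
        observed = classify_location(rod.centroid(), z_frame,
                                     tuple(truth["rim_offsets"]),
                                     truth["radial_cutoff"])
        assert observed == truth["location"]


class TestXyzIO:
    def test_round_trip_nm_units(self, tmp_path):
        ring = heptagon()
        path = tmp_path / "ring.xyz"
        write_xyz(path, ring, units="nm")
        back = read_xyz(path, units="nm")
        assert back.labels == ring.labels
        assert np.allclose(back.coords, ring.coords, atol=1e-6)

    def test_angstrom_conversion(self, tmp_path):
        s = Structure(labels=["C"], coords=np.array([[0.1, 0.2, 0.3]]))
        path = tmp_path / "one.xyz"
        write_xyz(path, s, units="angstrom")
        text = path.read_text().splitlines()
        assert text[2].split()[1] == "1.000000"  # 0.1 nm = 1 A
        back = read_xyz(path, units="angstrom")
        assert np.allclose(back.coords, s.coords)
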