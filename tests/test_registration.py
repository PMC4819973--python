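"""Landmark, fast, centerline-ICP, and trajectory registration methods."""

import sys

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.transform import Rotation

from usnav.errors import (
    DegenerateGeometryError,
    InsufficientLandmarksError,
    NoCorrespondenceError,
    UsnavError,
)
from usnav.geometry import RigidTransform
from usnav.registration import (
    Centerline,
    IcpParams,
    LandmarkSet,
    evaluate_registration_displacement,
    icp_register_centerlines,
    register_fast,
    register_landmarks,
    register_trajectory_to_airway,
    run_external_i2i,
)

from .conftest import make_stream, random_rigid


def brute_force_grid_rms(moving, fixed, step_deg=4.0):
    """Independent oracle: exhaustive Euler-angle grid search for the
    rigid transform minimizing paired-point rms (translation solved in
    closed form per rotation via centroid alignment)."""
    m = moving - moving.mean(axis=0)
    f = fixed - fixed.mean(axis=0)
    a = np.deg2rad(np.arange(0.0, 360.0, step_deg))
    b = np.deg2rad(np.arange(0.0, 180.0 + step_deg / 2, step_deg))
    best = np.inf
    for eb in b:  # loop over middle angle; vectorize the other two
        rots = Rotation.from_euler(
            "zyz",
            np.array(np.meshgrid(a, [eb], a)).reshape(3, -1).T,
        ).as_matrix()
        rm = np.einsum("rij,nj->rni", rots, m)
        cost = ((rm - f[None]) ** 2).sum(axis=(1, 2))
        best = min(best, cost.min())
    return np.sqrt(best / len(m))


class TestLandmarkRegistration:
    def test_identity_on_equal_sets(self, rng):
        pts = {f"p{i}": rng.uniform(-30, 30, 3) for i in range(4)}
        res = register_landmarks(LandmarkSet(dict(pts)), LandmarkSet(dict(pts)))
        assert res.transform.is_close(RigidTransform.identity(), atol=1e-9)
        assert res.rms_residual < 1e-9

    def test_exact_recovery_of_known_transform(self):
        truth = RigidTransform.from_axis_angle([0, 0, 1], 30.0, [5.0, -2.0, 1.0])
        moving = {
            "a": [0.0, 0.0, 0.0], "b": [10.0, 0.0, 0.0],
            "c": [0.0, 10.0, 0.0], "d": [3.0, 4.0, 5.0],
        }
        fixed = {k: truth.apply(v) for k, v in moving.items()}
        res = register_landmarks(LandmarkSet(moving), LandmarkSet(fixed))
        assert res.transform.is_close(truth, atol=1e-9)
        assert res.rms_residual < 1e-9

    @given(st.integers(min_value=0, max_value=10_000_000))
    @settings(max_examples=25, deadline=None)
    def test_noise_free_recovery_property(self, seed):
        rng = np.random.default_rng(seed)
        truth = random_rigid(rng)
        pts = rng.uniform(-50, 50, (5, 3))
        moving = {f"m{i}": p for i, p in enumerate(pts)}
        fixed = {k: truth.apply(v) for k, v in moving.items()}
        res = register_landmarks(LandmarkSet(moving), LandmarkSet(fixed))
        assert res.transform.is_close(truth, atol=1e-8)
        assert res.rms_residual < 1e-8

    def test_matches_brute_force_oracle_on_noisy_points(self, rng):
        truth = RigidTransform.from_axis_angle([1, 2, 3], 25.0, [4.0, 1.0, -2.0])
        pts = rng.uniform(-20, 20, (4, 3))
        noisy = truth.apply(pts) + rng.normal(0, 0.1, (4, 3))
        res = register_landmarks(
            LandmarkSet({f"p{i}": p for i, p in enumerate(pts)}),
            LandmarkSet({f"p{i}": p for i, p in enumerate(noisy)}),
        )
        oracle = brute_force_grid_rms(pts, noisy)
        # the closed-form optimum can never lose to a grid search
        assert res.rms_residual <= oracle + 1e-9

    def test_too_few_common_names(self):
        a = LandmarkSet({"x": [0, 0, 0], "y": [1, 0, 0], "z": [0, 1, 0]})
        b = LandmarkSet({"x": [0, 0, 0], "y": [1, 0, 0], "w": [0, 1, 0]})
        with pytest.raises(InsufficientLandmarksError):
            register_landmarks(a, b)

    def test_collinear_landmarks_rejected(self):
        line = {"a": [0, 0, 0], "b": [1, 0, 0], "c": [2.0, 0, 0]}
        with pytest.raises(DegenerateGeometryError):
            register_landmarks(LandmarkSet(dict(line)), LandmarkSet(dict(line)))

    def test_never_returns_reflection(self, rng):
        # near-planar noisy points can tempt the fit into a reflection
        pts = rng.uniform(-10, 10, (4, 3)) * [1, 1, 0.01]
        mirrored = pts * [1, 1, -1] + rng.normal(0, 0.5, (4, 3))
        res = register_landmarks(
            LandmarkSet({f"p{i}": p for i, p in enumerate(pts)}),
            LandmarkSet({f"p{i}": p for i, p in enumerate(mirrored)}),
        )
        assert np.linalg.det(res.transform.rotation) > 0


class TestFastRegistration:
    def test_identity_case(self):
        res = register_fast([0, 0, 0], [0, 0, 0], [0, 0, 1.0], [0, 0, 1.0])
        assert res.transform.is_close(RigidTransform.identity(), atol=1e-12)

    def test_pure_translation(self):
        res = register_fast([0, 0, 0], [0, 0, 10.0], [0, 0, 1.0], [0, 0, 1.0])
        np.testing.assert_allclose(res.transform.translation, [0, 0, 10], atol=1e-12)
        np.testing.assert_allclose(res.transform.rotation, np.eye(3), atol=1e-12)

    def test_axis_alignment_with_zero_landmark_residual(self):
        res = register_fast([0, 0, 0], [0, 0, 0], [1.0, 0, 0], [0, 0, 1.0])
        np.testing.assert_allclose(
            res.transform.apply_vectors([0, 0, 1.0]), [1, 0, 0], atol=1e-12
        )
        assert res.rms_residual < 1e-12

    def test_minimal_rotation_angle(self):
        res = register_fast([0, 0, 0], [0, 0, 0],
                            np.array([1.0, 1.0, 0]) / np.sqrt(2), [1.0, 0, 0])
        angle = np.degrees(
            np.arccos((np.trace(res.transform.rotation) - 1) / 2)
        )
        assert angle == pytest.approx(45.0, abs=1e-9)

    def test_antiparallel_axes_deterministic(self):
        r1 = register_fast([0, 0, 0], [0, 0, 0], [0, 0, -1.0], [0, 0, 1.0])
        r2 = register_fast([0, 0, 0], [0, 0, 0], [0, 0, -1.0], [0, 0, 1.0])
        np.testing.assert_array_equal(r1.transform.rotation, r2.transform.rotation)
        np.testing.assert_allclose(
            r1.transform.apply_vectors([0, 0, 1.0]), [0, 0, -1], atol=1e-12
        )


def _l_path(n=40):
    """An L-shaped polyline in the x-y plane."""
    leg1 = np.column_stack([np.linspace(0, 20, n), np.zeros(n), np.zeros(n)])
    leg2 = np.column_stack([np.full(n, 20.0), np.linspace(0.5, 20, n), np.zeros(n)])
    return Centerline(np.vstack([leg1, leg2]))


class TestCenterlineICP:
    def test_self_registration_is_identity(self):
        path = _l_path()
        res = icp_register_centerlines(path, path)
        assert res.rms_residual < 1e-9
        assert res.transform.is_close(RigidTransform.identity(), atol=1e-6)

    def test_perpendicular_unit_displacement_recovered(self):
        n = 30
        fixed = Centerline(
            np.column_stack([np.linspace(0, 30, n), np.zeros(n), np.zeros(n)])
        )
        moving = Centerline(fixed.points + [0.0, 1.0, 0.0])
        res = icp_register_centerlines(moving, fixed)
        # recovered displacement magnitude 1.0 along -y
        assert np.linalg.norm(res.transform.translation) == pytest.approx(
            1.0, abs=1e-6
        )
        assert res.rms_residual < 1e-6

    def test_l_shape_rotation_translation_recovered(self):
        truth = RigidTransform.from_axis_angle([0, 0, 1], 5.0, [2.0, 0.0, 0.0])
        fixed = _l_path()
        moving = Centerline(truth.invert().apply(fixed.points))
        res = icp_register_centerlines(moving, fixed)
        assert res.transform.is_close(truth, atol=1e-3)
        assert res.rms_residual < 1e-3

    def test_residuals_monotone_non_increasing(self, rng):
        for _ in range(10):
            fixed = _l_path()
            offset = RigidTransform.from_axis_angle(
                rng.standard_normal(3), rng.uniform(0, 8),
                rng.uniform(-3, 3, 3),
            )
            moving = Centerline(offset.apply(fixed.points))
            res = icp_register_centerlines(moving, fixed)
            r = np.array(res.per_iteration_residuals)
            assert np.all(np.diff(r) <= 1e-12)
            assert r[-1] <= r[0] + 1e-12

    def test_point_to_segment_not_vertex(self):
        # a coarse 2-point fixed line still yields ~zero residual for a
        # moving point mid-segment: correspondence is the projection
        fixed = Centerline(np.array([[0.0, 0, 0], [10.0, 0, 0]]))
        moving = Centerline(np.array([[4.7, 0.0, 0.0], [5.3, 0.0, 0.0]]))
        res = icp_register_centerlines(moving, fixed)
        assert res.rms_residual < 1e-9


def _helix_stream(points, axis_dirs):
    poses = []
    for p, d in zip(points, axis_dirs):
        d = d / np.linalg.norm(d)
        # build a rotation mapping local +z onto d
        v = np.cross([0, 0, 1.0], d)
        c = float(np.dot([0, 0, 1.0], d))
        if c < -1 + 1e-9:
            rot = np.diag([1.0, -1.0, -1.0])
        else:
            vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
            rot = np.eye(3) + vx + vx @ vx / (1 + c)
        poses.append(RigidTransform(rot, p))
    return make_stream(np.arange(len(poses), dtype=float) * 10.0, poses)


class TestTrajectoryToAirway:
    def _airway(self, n=60):
        t = np.linspace(0, 1, n)
        pts = np.column_stack([40 * t, 8 * np.sin(2 * np.pi * t), 10 * t])
        return Centerline(pts).with_tangents()

    def test_on_centerline_trajectory_gives_identity(self):
        airway = self._airway()
        stream = _helix_stream(airway.points[::2], airway.tangents[::2])
        res = register_trajectory_to_airway(stream, airway)
        assert res.rms_residual < 1e-6
        assert res.transform.is_close(RigidTransform.identity(), atol=1e-4)

    def test_known_offset_recovered(self):
        airway = self._airway()
        truth = RigidTransform.from_axis_angle([0, 0, 1], 3.0, [3.0, -2.0, 1.0])
        inv = truth.invert()
        pts = inv.apply(airway.points[::2])
        dirs = inv.apply_vectors(airway.tangents[::2])
        stream = _helix_stream(pts, dirs)
        res = register_trajectory_to_airway(stream, airway)
        # recovered within 0.5 mm / 1 deg
        assert np.linalg.norm(res.transform.translation - truth.translation) < 0.5
        rel = res.transform.rotation.T @ truth.rotation
        angle = np.degrees(np.arccos(np.clip((np.trace(rel) - 1) / 2, -1, 1)))
        assert angle < 1.0

    def test_orientation_gate_excludes_antiparallel_branch(self):
        # Y-tree: trunk along +x splitting into branches +y-ish and -y-ish
        trunk = np.column_stack([np.linspace(0, 10, 11),
                                 np.zeros(11), np.zeros(11)])
        branch_a = trunk[-1] + np.column_stack(
            [np.linspace(0.5, 10, 10), np.linspace(0.5, 10, 10), np.zeros(10)]
        )
        airway = Centerline(np.vstack([trunk, branch_a])).with_tangents()
        # trajectory geometrically near branch A but pointing the other way
        stream = _helix_stream(
            branch_a + [0.0, 0.3, 0.0],
            np.tile([-1.0, -1.0, 0.0], (len(branch_a), 1)),
        )
        with pytest.raises(NoCorrespondenceError):
            register_trajectory_to_airway(
                stream, airway, IcpParams(max_angle_deg=45.0, min_samples=5)
            )
        # aligned orientations are accepted on the same geometry
        res = register_trajectory_to_airway(
            _helix_stream(branch_a + [0.0, 0.3, 0.0],
                          np.tile([1.0, 1.0, 0.0], (len(branch_a), 1))),
            airway, IcpParams(max_angle_deg=45.0, min_samples=5),
        )
        assert res.n_correspondences == len(branch_a)

    def test_min_samples_enforced(self):
        airway = self._airway()
        stream = _helix_stream(airway.points[:3], airway.tangents[:3])
        with pytest.raises(UsnavError):
            register_trajectory_to_airway(stream, airway,
                                          IcpParams(min_samples=10))


class TestDisplacementValidation:
    def test_identity_gives_zero(self, rng):
        lm = LandmarkSet({f"p{i}": rng.uniform(-10, 10, 3) for i in range(4)})
        per, summary = evaluate_registration_displacement(
            lm, RigidTransform.identity()
        )
        assert all(v == 0 for v in per.values())
        assert summary["mean"] == 0 and summary["max"] == 0

    def test_pythagorean_translation(self):
        lm = LandmarkSet({"a": [0, 0, 0], "b": [5, 5, 5]})
        t = RigidTransform(np.eye(3), [3.0, 4.0, 0.0])
        per, summary = evaluate_registration_displacement(lm, t)
        assert per["a"] == pytest.approx(5.0)
        assert per["b"] == pytest.approx(5.0)
        assert summary["mean"] == pytest.approx(5.0)

    def test_rotation_displacement_root_two(self, rz90):
        lm = LandmarkSet({"p": [1.0, 0.0, 0.0]})
        per, _ = evaluate_registration_displacement(lm, rz90)
        assert per["p"] == pytest.approx(np.sqrt(2.0), abs=1e-12)

    def test_invariant_to_relabeling(self, rng):
        pts = [rng.uniform(-10, 10, 3) for _ in range(4)]
        t = random_rigid(rng)
        s1 = evaluate_registration_displacement(
            LandmarkSet({f"a{i}": p for i, p in enumerate(pts)}), t
        )[1]
        s2 = evaluate_registration_displacement(
            LandmarkSet({f"z{i}": p for i, p in enumerate(reversed(pts))}), t
        )[1]
        assert s1 == s2


class TestExternalI2IHook:
    def test_subprocess_contract_round_trip(self, tmp_path, rng):
        t = random_rigid(rng)
        from usnav.io import write_transform

        ref = tmp_path / "result.txt"
        write_transform(t, tmp_path / "canned.txt")
        tool = tmp_path / "tool.py"
        tool.write_text(
            "import shutil, sys\nshutil.copy(sys.argv[1], sys.argv[2])\n"
        )
        got = run_external_i2i(
            f"{sys.executable} {tool} {tmp_path / 'canned.txt'} {{output}}",
            "mov.mhd", "fix.mhd", ref,
        )
        assert got.is_close(t, atol=1e-12)

    def test_failing_tool_raises(self, tmp_path):
        with pytest.raises(UsnavError):
            run_external_i2i(
                f"{sys.executable} -c 'import sys; sys.exit(3)'",
                "m", "f", tmp_path / "out.txt",
            )
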