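"""Euler conventions, the pose-composition mapping, and region assignment."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from spcet.geometry import (
    GeometryDelta,
    ParticlePose,
    TiltGeometry,
    assign_regions,
    compose_projection_pose,
    euler_to_matrix,
    matrix_to_euler,
    tilt_matrix,
)


class TestEuler:
    def test_identity(self):
        assert np.allclose(euler_to_matrix((0, 0, 0)), np.eye(3))

    def test_degenerate_axis(self):
        # at phi = 0 the first and last rotations share the z axis
        assert np.allclose(euler_to_matrix((90, 0, 0)), euler_to_matrix((0, 0, 90)))

    def test_matches_scipy_convention(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            ang = rng.uniform([-180, 1, -180], [180, 179, 180])
            ours = euler_to_matrix(ang)
            ref = Rotation.from_euler("ZYZ", ang, degrees=True).as_matrix()
            assert np.allclose(ours, ref, atol=1e-12)

    def test_round_trip_random(self):
        rng = np.random.default_rng(1)
        worst = 0.0
        for _ in range(10_000):
            R = Rotation.random(rng=rng).as_matrix()
            R2 = euler_to_matrix(matrix_to_euler(R))
            worst = max(worst, np.abs(R2 - R).max())
        assert worst < 1e-9
        # determinant preserved
        assert np.isclose(np.linalg.det(R2), 1.0)

    def test_gimbal_lock_canonicalized(self):
        theta, phi, psi = matrix_to_euler(euler_to_matrix((30, 0, 40)))
        assert psi == 0.0 and np.isclose(theta, 70.0)
        t2, p2, s2 = matrix_to_euler(euler_to_matrix((30, 180, 40)))
        assert s2 == 0.0 and np.isclose(p2, 180.0)
        assert np.allclose(euler_to_matrix((t2, p2, s2)), euler_to_matrix((30, 180, 40)))


class TestComposeProjectionPose:
    def test_zero_tilt_ignores_z(self):
        tilt = TiltGeometry(0, 0.0, 0.0)
        part = ParticlePose(0, (10.0, -4.0, 7.0), (0, 0, 0))
        pose = compose_projection_pose(tilt, part)
        assert np.allclose(pose.shift, (10.0, -4.0))
        assert np.allclose(euler_to_matrix(pose.angles), np.eye(3))

    def test_on_axis_particle(self):
        for alpha in (0.0, 30.0, 85.3):
            tilt = TiltGeometry(0, alpha, 0.0)
            for z in (-20.0, 0.0, 13.5):
                pose = compose_projection_pose(tilt, ParticlePose(0, (0, 0, z), (5, 50, 10)))
                assert np.allclose(pose.shift, (0.0, 0.0), atol=1e-12)

    def test_matches_matrix_oracle(self):
        """Brute-force oracle: explicit 3x3 rotation products and projection."""
        rng = np.random.default_rng(2)
        for _ in range(10_000):
            alpha, beta = rng.uniform(-180, 180), rng.uniform(-60, 60)
            ang = rng.uniform([-180, 1, -180], [180, 179, 180])
            pos = rng.uniform(-30, 30, 3)
            sx, sy = rng.uniform(-5, 5, 2)
            tilt = TiltGeometry(0, alpha, beta, sx, sy)
            pose = compose_projection_pose(tilt, ParticlePose(0, pos, ang))
            # oracle with scipy rotations
            M = (
                Rotation.from_euler("z", alpha, degrees=True)
                * Rotation.from_euler("y", beta, degrees=True)
                * Rotation.from_euler("z", -alpha, degrees=True)
            ).as_matrix()
            Q = M @ Rotation.from_euler("ZYZ", ang, degrees=True).as_matrix()
            u = M @ pos
            assert np.allclose(pose.shift, (u[0] + sx, u[1] + sy), atol=1e-10)
            assert np.allclose(euler_to_matrix(pose.angles), Q, atol=1e-10)

    def test_specific_oracle_case(self):
        tilt = TiltGeometry(0, 85.3, 30.0)
        part = ParticlePose(0, (12.0, 8.0, -5.0), (20.0, 40.0, 60.0))
        pose = compose_projection_pose(tilt, part)
        M = tilt_matrix(85.3, 30.0)
        u = M @ np.array([12.0, 8.0, -5.0])
        assert np.allclose(pose.shift, u[:2], atol=1e-10)
        assert np.allclose(
            euler_to_matrix(pose.angles), M @ euler_to_matrix((20, 40, 60)), atol=1e-10
        )

    def test_region_delta_applied(self):
        tilt = TiltGeometry(0, 10.0, 30.0)
        part = ParticlePose(0, (5.0, 5.0, 5.0), (10, 20, 30))
        base = compose_projection_pose(tilt, part)
        moved = compose_projection_pose(tilt, part, GeometryDelta(d_shift_x=2.0, d_shift_y=-1.0))
        assert np.allclose(np.subtract(moved.shift, base.shift), (2.0, -1.0))


class TestRegions:
    def test_region_count_4x4x2(self):
        rng = np.random.default_rng(3)
        pos = rng.uniform(0, [512, 512, 256], size=(5000, 3))
        idx = assign_regions(pos, (4, 4, 2), (512, 512, 256))
        assert idx.min() >= 0 and idx.max() < 32
        assert len(np.unique(idx)) == 32  # G = 32 regions

    def test_center_falls_in_upper_cell(self):
        idx = assign_regions([(256.0, 256.0, 128.0)], (4, 4, 2), (512, 512, 256))
        assert idx[0] == 2 + 4 * 2 + 16 * 1

    def test_partition_counts(self):
        rng = np.random.default_rng(4)
        pos = rng.uniform(0, [100, 100, 50], size=(1000, 3))
        idx = assign_regions(pos, (2, 2, 2), (100, 100, 50))
        counts = np.bincount(idx, minlength=8)
        assert counts.sum() == 1000
        assert np.all(np.abs(counts - 125) < 5 * np.sqrt(125))

    def test_outside_position_names_particle(self):
        with pytest.raises(ValueError, match="particle 1"):
            assign_regions([(1, 1, 1), (600, 1, 1)], (2, 2, 2), (512, 512, 256))


def test_tilt_geometry_validates_ranges():
    with pytest.raises(ValueError):
        TiltGeometry(0, 0.0, 95.0)
    with pytest.raises(ValueError):
        TiltGeometry(0, 200.0, 0.0)


def test_in_plane_equivariance(noiseless_ds):
    """At zero tilt, an extra in-plane rotation (outer Z angle) rotates the
    projection image content by the same amount."""
    from scipy.ndimage import rotate

    from spcet.projector import FourierProjector

    pr = FourierProjector(noiseless_ds.phantom)
    part = noiseless_ds.particles[0]
    base = pr.project(euler_to_matrix(part.angles))
    delta = 25.0
    turned = pr.project(euler_to_matrix((delta, 0, 0)) @ euler_to_matrix(part.angles))
    # scipy rotates in array (row, col) orientation, opposite to the (x, y) sense
    expected = rotate(base, -delta, reshape=False, order=3, mode="constant")
    n = base.shape[0]
    inner = slice(n // 4, 3 * n // 4)
    cc = np.corrcoef(turned[inner, inner].ravel(), expected[inner, inner].ravel())[0, 1]
    assert cc > 0.98
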