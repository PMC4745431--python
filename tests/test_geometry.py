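import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from spinereg.geometry import (Pose, ProjectionModel, Ray, backproject_ray,
                               estimate_source_position, initial_registration,
                               project_point, rigid_fit, triangulate_rays)

from oracles import line_cost


@pytest.fixture()
def simple_model():
    # source 1000 mm above a z=0 detector, 470 px at 1 mm pitch
    return ProjectionModel(source=(0, 0, 1000), detector_origin=(-235, -235, 0),
                           u_axis=(1, 0, 0), v_axis=(0, 1, 0),
                           pixel_spacing=(1.0, 1.0), image_size=(470, 470))


class TestProjectPoint:
    def test_central_ray(self, simple_model):
        assert project_point(simple_model, (0, 0, 0)) == pytest.approx((235, 235))

    def test_magnification_two(self, simple_model):
        # a point halfway to the detector projects at 2x lateral magnification
        assert project_point(simple_model, (10, 0, 500)) == pytest.approx((255, 235))

    def test_source_is_degenerate(self, simple_model):
        with pytest.raises(ValueError):
            project_point(simple_model, simple_model.source)

    def test_parallel_ray_has_no_intersection(self, simple_model):
        with pytest.raises(ValueError, match="no intersection"):
            project_point(simple_model, (50, 0, 1000))


class TestBackprojectRay:
    def test_central_pixel_points_down(self, simple_model):
        ray = backproject_ray(simple_model, 235, 235)
        assert ray.origin == pytest.approx(simple_model.source)
        assert ray.direction == pytest.approx((0, 0, -1))

    def test_distinct_pixels_give_distinct_directions(self, simple_model):
        r1 = backproject_ray(simple_model, 100, 100)
        r2 = backproject_ray(simple_model, 101, 100)
        assert np.linalg.norm(r1.direction - r2.direction) > 0
        assert r1.origin == pytest.approx(r2.origin)

    @pytest.mark.parametrize("u,v", [(0, 0), (235, 235), (469, 469), (12.25, 301.5)])
    def test_project_backproject_identity(self, simple_model, u, v):
        ray = backproject_ray(simple_model, u, v)
        for t in (100.0, 500.0, 900.0):
            uu, vv = project_point(simple_model, ray.at(t))
            assert (uu, vv) == pytest.approx((u, v), abs=1e-9)


class TestTriangulateRays:
    def test_skew_lines_midpoint_and_gap(self):
        a = Ray((0, 0, 0), (1, 0, 0))
        b = Ray((0, 0, 1), (0, 1, 0))
        point, gap = triangulate_rays(a, b)
        assert point == pytest.approx((0, 0, 0.5))
        assert gap == pytest.approx(1.0)

    def test_intersecting_rays_recover_common_point(self):
        p = np.array([3.0, -2.0, 7.0])
        a = Ray(p - 5 * np.array([1.0, 0.2, 0.1]), (1, 0.2, 0.1))
        b = Ray(p - 4 * np.array([0.1, 1.0, -0.3]), (0.1, 1.0, -0.3))
        point, gap = triangulate_rays(a, b)
        assert point == pytest.approx(p, abs=1e-9)
        assert gap == pytest.approx(0.0, abs=1e-9)

    def test_parallel_rays_error(self):
        with pytest.raises(ValueError, match="degenerate"):
            triangulate_rays(Ray((0, 0, 0), (1, 0, 0)), Ray((0, 1, 0), (1, 0, 0)))

    def test_symmetric_in_ray_order(self):
        a = Ray((0, 1, 2), (0.3, 0.4, 0.5))
        b = Ray((5, -1, 0), (-0.2, 0.9, 0.1))
        pa, ga = triangulate_rays(a, b)
        pb, gb = triangulate_rays(b, a)
        assert pa == pytest.approx(pb)
        assert ga == pytest.approx(gb)


class TestEstimateSourcePosition:
    def _lines_from_source(self, source, markers):
        # each line joins an up-deck marker to its projection on the z=0 plane
        lines = []
        for m in markers:
            d = m - source
            t = -source[2] / d[2]
            lines.append((m, source + t * d))
        return lines

    def test_exact_recovery_from_five_markers(self):
        source = np.array([30.0, -20.0, 980.0])
        markers = np.array([[0, 0, 500], [40, 10, 520], [-35, 25, 480],
                            [10, -45, 510], [-20, -30, 490]], float)
        lines = self._lines_from_source(source, markers)
        assert estimate_source_position(lines) == pytest.approx(source, abs=1e-6)

    def test_two_lines_equal_triangulation(self):
        p = np.array([0.0, 0.0, 1000.0])
        lines = [(p + np.array([5, 0, -10.0]), p + np.array([10, 0, -20.0])),
                 (p + np.array([0, 4, -8.0]), p + np.array([0, 8, -16.0]))]
        est = estimate_source_position(lines)
        assert est == pytest.approx(p, abs=1e-9)
        rays = [Ray(p0, np.subtract(p1, p0)) for p0, p1 in lines]
        tri, _ = triangulate_rays(*rays)
        assert est == pytest.approx(tri, abs=1e-9)

    def test_noisy_lines_within_two_mm_and_beats_grid(self, rng):
        source = np.array([10.0, 5.0, 1000.0])
        markers = np.array([[0, 0, 500], [60, 20, 520], [-55, 35, 480],
                            [20, -65, 510], [-40, -50, 490]], float)
        lines = []
        for m, hit in self._lines_from_source(source, markers):
            lines.append((m + rng.uniform(-0.1, 0.1, 3), hit + rng.uniform(-0.1, 0.1, 3)))
        est = estimate_source_position(lines)
        assert np.linalg.norm(est - source) < 2.0
        # least-squares answer is at least as good as a brute-force grid scan
        grid = np.arange(-2.0, 2.01, 0.5)
        best_grid = min(line_cost(source + np.array([dx, dy, dz]), lines)
                        for dx in grid for dy in grid for dz in grid)
        assert line_cost(est, lines) <= best_grid + 1e-12

    def test_fewer_than_two_lines_error(self):
        with pytest.raises(ValueError):
            estimate_source_position([((0, 0, 0), (1, 0, 0))])

    def test_parallel_lines_error(self):
        lines = [((0, 0, 0), (1, 0, 0)), ((0, 1, 0), (1, 1, 0)), ((0, 0, 5), (1, 0, 5))]
        with pytest.raises(ValueError):
            estimate_source_position(lines)


@pytest.fixture()
def marker_cloud(rng):
    return rng.uniform(-30, 30, size=(7, 3))


class TestRigidFit:
    def test_pure_translation(self, marker_cloud):
        T, rms = rigid_fit(marker_cloud, marker_cloud + [1.0, 2.0, 3.0])
        assert T[:3, :3] == pytest.approx(np.eye(3), abs=1e-9)
        assert T[:3, 3] == pytest.approx([1, 2, 3], abs=1e-9)
        assert rms == pytest.approx([0, 0, 0], abs=1e-9)

    def test_rotation_about_centroid(self, marker_cloud):
        R = Rotation.from_euler("z", 90, degrees=True).as_matrix()
        c = marker_cloud.mean(axis=0)
        dst = (marker_cloud - c) @ R.T + c
        T, rms = rigid_fit(marker_cloud, dst)
        assert T[:3, :3] == pytest.approx(R, abs=1e-9)
        assert np.max(rms) < 1e-9

    def test_exact_for_arbitrary_rigid_motion(self, rng, marker_cloud):
        R = Rotation.random(random_state=7).as_matrix()
        t = rng.uniform(-50, 50, 3)
        T, rms = rigid_fit(marker_cloud, marker_cloud @ R.T + t)
        assert T[:3, :3] == pytest.approx(R, abs=1e-9)
        assert T[:3, 3] == pytest.approx(t, abs=1e-9)
        assert np.max(rms) < 1e-9

    def test_noise_residuals_track_sigma(self, marker_cloud):
        # anisotropic fiducial noise comparable to an optical tracker's
        sigma = np.array([0.34, 0.28, 0.26])
        rms_all = []
        for seed in range(100):
            r = np.random.default_rng(seed)
            dst = marker_cloud + r.normal(0, sigma, size=marker_cloud.shape)
            _, rms = rigid_fit(marker_cloud, dst)
            rms_all.append(rms)
        mean_rms = np.mean(rms_all, axis=0)
        # rigid dof absorb part of the noise; per-axis RMS within 50% of sigma
        assert np.all(mean_rms > 0.5 * sigma)
        assert np.all(mean_rms < 1.5 * sigma)

    def test_too_few_points_error(self):
        with pytest.raises(ValueError):
            rigid_fit([[0, 0, 0], [1, 0, 0]], [[0, 0, 0], [1, 0, 0]])

    def test_collinear_points_error(self):
        src = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]], float)
        with pytest.raises(ValueError, match="collinear"):
            rigid_fit(src, src + 1.0)


class TestPose:
    def test_zero_pose_is_identity(self):
        assert Pose().to_matrix() == pytest.approx(np.eye(4))

    def test_matrix_is_proper_rigid(self):
        T = Pose(1, -2, 3, 10, 20, -30, center=(5, 5, 5)).to_matrix()
        R = T[:3, :3]
        assert R @ R.T == pytest.approx(np.eye(3), abs=1e-12)
        assert np.linalg.det(R) == pytest.approx(1.0)

    def test_matrix_roundtrip(self):
        p = Pose(4.5, -1.0, 2.0, 12.0, -7.0, 33.0, center=(1, 2, 3))
        q = Pose.from_matrix(p.to_matrix(), center=(1, 2, 3))
        assert q.params == pytest.approx(p.params, abs=1e-9)

    def test_rotation_pivots_at_center(self):
        c = np.array([10.0, 0.0, 0.0])
        p = Pose(0, 0, 0, 0, 0, 90, center=c)
        assert p.apply(c) == pytest.approx(c, abs=1e-12)
        assert p.apply([11.0, 0, 0]) == pytest.approx([10.0, 1.0, 0.0], abs=1e-12)


class TestInitialRegistration:
    def _scene(self):
        from spinereg.phantom import default_models

        ap, la = default_models()
        ct_points = np.array([[10.0, 5.0, -8.0], [-12.0, 3.0, 6.0], [2.0, -14.0, 9.0]])
        return ap, la, ct_points

    def test_recovers_generating_pose(self):
        ap, la, ct = self._scene()
        truth = Pose(3, -2, 4, 4, -3, 5, center=ct.mean(axis=0))
        world = truth.apply(ct)
        ap_px = [project_point(ap, w) for w in world]
        la_px = [project_point(la, w) for w in world]
        est = initial_registration(ap_px, la_px, ap, la, ct)
        err = np.linalg.norm(est.apply(ct) - world, axis=1)
        assert np.max(err) < 1e-6

    def test_identity_when_points_already_in_world(self):
        ap, la, ct = self._scene()
        ap_px = [project_point(ap, p) for p in ct]
        la_px = [project_point(la, p) for p in ct]
        est = initial_registration(ap_px, la_px, ap, la, ct)
        assert est.params == pytest.approx(np.zeros(6), abs=1e-6)

    def test_perturbed_picks_stay_within_search_range(self):
        # +-2 px pick error should typically land inside the +-5 mm / +-5 deg
        # search box; asserted on the mean over seeds (3-point fits have
        # heavy rotational tails when picks cluster)
        ap, la, _ = self._scene()
        ct = np.array([[18.0, 5.0, -14.0], [-17.0, 4.0, 13.0], [3.0, -15.0, 14.0]])
        truth = Pose(2, -1, 3, 2, -2, 3, center=ct.mean(axis=0))
        world = truth.apply(ct)
        terr, rerr = [], []
        for seed in range(20):
            r = np.random.default_rng(seed)
            ap_px = np.array([project_point(ap, w) for w in world]) + r.uniform(-2, 2, (3, 2))
            la_px = np.array([project_point(la, w) for w in world]) + r.uniform(-2, 2, (3, 2))
            d = initial_registration(ap_px, la_px, ap, la, ct).params - truth.params
            terr.append(np.abs(d[:3]).max())
            rerr.append(np.abs(d[3:]).max())
        assert np.mean(terr) < 5.0
        assert np.mean(rerr) < 5.0

    def test_collinear_points_error(self):
        ap, la, _ = self._scene()
        ct = np.array([[0, 0, 0], [5, 0, 0], [10, 0, 0]], float)
        ap_px = [project_point(ap, p) for p in ct]
        la_px = [project_point(la, p) for p in ct]
        with pytest.raises(ValueError):
            initial_registration(ap_px, la_px, ap, la, ct)
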