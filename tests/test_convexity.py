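import numpy as np
import pytest

from cavscan.convexity import (
    SphereFitError,
    assign_helices,
    exact_sphere_through_4,
    fit_sphere_ransac,
    helix_segments,
    interface_convexity,
    least_squares_sphere,
    scaffold_face_convexity,
    signed_convexity,
)
from cavscan.fixtures import (
    CapCloudSpec,
    make_cap_cloud,
    make_concave_bundle,
    make_ideal_helix,
    make_toy_dimer,
)
from cavscan.structio import DegenerateGeometryError

from conftest import random_rigid_transform


def sphere_samples(radius, n, seed, noise=0.0, center=(0, 0, 0)):
    rng = np.random.default_rng(seed)
    v = rng.normal(size=(n, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    pts = radius * v + np.asarray(center, float)
    if noise:
        pts = pts + rng.normal(0, noise, pts.shape)
    return pts


class TestExactSphere:
    def test_regular_tetrahedron_on_unit_sphere(self):
        tet = np.array([[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]]) / np.sqrt(3)
        fit = exact_sphere_through_4(tet)
        np.testing.assert_allclose(fit.center, 0.0, atol=1e-9)
        assert fit.radius == pytest.approx(1.0, abs=1e-9)

    def test_coplanar_points_degenerate(self):
        pts = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [1, 1, 0]], float)
        assert exact_sphere_through_4(pts) is None

    def test_random_quadruples_lie_on_returned_sphere(self):
        rng = np.random.default_rng(2)
        checked = 0
        while checked < 100:
            P = rng.uniform(-10, 10, (4, 3))
            fit = exact_sphere_through_4(P)
            if fit is None:
                continue
            res = np.abs(np.linalg.norm(P - fit.center, axis=1) - fit.radius)
            assert res.max() < 1e-8
            checked += 1


class TestLeastSquaresSphere:
    def test_exact_samples_exact_parameters(self):
        pts = sphere_samples(7.5, 50, seed=3, center=(1, -2, 3))
        fit = least_squares_sphere(pts)
        assert fit.radius == pytest.approx(7.5, abs=1e-9)
        np.testing.assert_allclose(fit.center, [1, -2, 3], atol=1e-9)

    def test_noisy_samples_recover_radius(self):
        pts = sphere_samples(10.0, 200, seed=4, noise=0.1)
        fit = least_squares_sphere(pts)
        assert fit.radius == pytest.approx(10.0, rel=0.02)

    def test_collinear_points_rejected(self):
        line = np.column_stack([np.arange(10.0), np.zeros(10), np.zeros(10)])
        with pytest.raises(DegenerateGeometryError):
            least_squares_sphere(line)


class TestRansac:
    def test_noiseless_sphere_all_inliers(self):
        pts = sphere_samples(1.0, 100, seed=5)
        fit = fit_sphere_ransac(pts, seed=0)
        assert fit.radius == pytest.approx(1.0, abs=1e-9)
        assert len(fit.inlier_ids) == 100

    def test_noiseless_equals_least_squares(self):
        pts = sphere_samples(12.0, 80, seed=6, center=(5, 5, 5))
        r_ransac = fit_sphere_ransac(pts, seed=1).radius
        r_ls = least_squares_sphere(pts).radius
        assert r_ransac == pytest.approx(r_ls, abs=1e-6)

    def test_cap_with_outliers_recovers_radius_and_inliers(self):
        cloud = make_cap_cloud(
            CapCloudSpec(radius=20.0, noise_sigma=0.3, outlier_fraction=0.3, seed=7)
        )
        fit = fit_sphere_ransac(cloud.points, seed=7)
        assert fit.radius == pytest.approx(20.0, rel=0.05)
        true_inliers = np.flatnonzero(cloud.inlier_mask)
        recovered = np.intersect1d(fit.inlier_ids, true_inliers)
        assert len(recovered) >= 0.95 * len(true_inliers)

    def test_default_parameters_recorded(self):
        pts = sphere_samples(5.0, 30, seed=8)
        fit = fit_sphere_ransac(pts, seed=0)
        assert fit.inlier_threshold == 1.0
        assert fit.max_iter == 100_000

    def test_seeded_determinism_bit_for_bit(self):
        cloud = make_cap_cloud(
            CapCloudSpec(radius=15.0, noise_sigma=0.3, outlier_fraction=0.2, seed=9)
        )
        a = fit_sphere_ransac(cloud.points, seed=123)
        b = fit_sphere_ransac(cloud.points, seed=123)
        assert (a.center == b.center).all()
        assert a.radius == b.radius
        assert (a.inlier_ids == b.inlier_ids).all()
        assert a.iterations_run == b.iterations_run

    def test_degenerate_cloud_raises(self):
        grid = np.array([[x, y, 0.0] for x in range(5) for y in range(5)])
        with pytest.raises(SphereFitError):
            fit_sphere_ransac(grid + np.random.default_rng(0).normal(0, 1e-12, grid.shape),
                              seed=0)


class TestSignRule:
    def _cap(self, R=10.0, n=60, seed=0):
        rng = np.random.default_rng(seed)
        cos = rng.uniform(np.cos(np.radians(45)), 1.0, n)
        sin = np.sqrt(1 - cos**2)
        th = rng.uniform(0, 2 * np.pi, n)
        return R * np.column_stack([sin * np.cos(th), sin * np.sin(th), cos])

    def test_body_at_center_is_convex(self):
        cap = self._cap()
        fit = least_squares_sphere(cap)
        body = np.random.default_rng(1).normal(0, 0.5, (20, 3))  # near center
        res = signed_convexity(cap, body, fit)
        assert res.shape_class == "convex"
        assert res.convexity == pytest.approx(+1 / 10.0, rel=1e-6)

    def test_body_beyond_cap_is_concave(self):
        cap = self._cap()
        fit = least_squares_sphere(cap)
        body = np.random.default_rng(1).normal(0, 0.5, (20, 3)) + np.array([0, 0, 14.0])
        res = signed_convexity(cap, body, fit)
        assert res.shape_class == "concave"
        assert res.convexity == pytest.approx(-1 / 10.0, rel=1e-6)

    def test_mirror_antisymmetry(self):
        """Reflecting the body through the cap centroid flips the sign."""
        cap = self._cap(seed=2)
        fit = least_squares_sphere(cap)
        body = np.random.default_rng(3).normal(0, 0.5, (20, 3))
        res = signed_convexity(cap, body, fit)
        g = cap.mean(axis=0)
        res_m = signed_convexity(cap, 2 * g - body, fit)
        assert res_m.sign_dot == pytest.approx(-res.sign_dot, rel=1e-9)
        assert res_m.convexity == pytest.approx(-res.convexity, rel=1e-9)

    def test_huge_radius_classed_flat(self):
        from cavscan.convexity import SphereFit

        fit = SphereFit(center=np.array([0, 0, 1e5]), radius=1e5,
                        inlier_ids=np.arange(4), rms_residual=0.0)
        res = signed_convexity(np.eye(3), np.eye(3) * 2 + 1, fit)
        assert res.shape_class == "flat"
        assert res.convexity == 0.0

    def test_rigid_invariance_of_convexity(self):
        cap = self._cap(seed=4)
        body = np.random.default_rng(5).normal(0, 0.5, (20, 3))
        fit = least_squares_sphere(cap)
        base = signed_convexity(cap, body, fit)
        R, t = random_rigid_transform(np.random.default_rng(6))
        fit2 = least_squares_sphere(cap @ R.T + t)
        moved = signed_convexity(cap @ R.T + t, body @ R.T + t, fit2)
        assert moved.convexity == pytest.approx(base.convexity, abs=1e-9)
        assert moved.shape_class == base.shape_class


class TestInterfaceConvexity:
    def test_knob_and_socket_have_opposite_signs(self, dimer):
        knob = interface_convexity(dimer, ["A"], ["B"], seed=2)
        sock = interface_convexity(dimer, ["B"], ["A"], seed=2)
        assert knob.shape_class == "convex"
        assert sock.shape_class == "concave"
        assert knob.convexity * sock.convexity < 0

    def test_complementary_curvatures_close(self, dimer):
        """|kappa| of knob and socket agree with the generating spheres."""
        knob = interface_convexity(dimer, ["A"], ["B"], seed=2)
        sock = interface_convexity(dimer, ["B"], ["A"], seed=2)
        assert abs(knob.convexity) == pytest.approx(
            dimer.metadata["kappa_knob_true"], rel=0.10
        )
        assert abs(sock.convexity) == pytest.approx(
            abs(dimer.metadata["kappa_socket_true"]), rel=0.10
        )

    def test_too_small_interface_raises(self, dimer_far):
        with pytest.raises(SphereFitError):
            interface_convexity(dimer_far, ["A"], ["B"], seed=0)


class TestSecondaryStructure:
    def test_ideal_ca_helix_all_interior_h(self, helix20):
        labels = assign_helices(helix20)["A"]
        assert set(labels[:-3]) == {"H"}

    def test_ideal_backbone_helix_interior_h(self, helix20_backbone):
        labels = assign_helices(helix20_backbone)["A"]
        assert set(labels[1:-1]) == {"H"}

    def test_extended_strand_not_helical(self):
        from conftest import ca_structure

        strand = ca_structure([[3.5 * i, 0, 0] for i in range(15)])
        assert "H" not in assign_helices(strand)["A"]

    def test_bundle_has_five_runs(self, bundle15):
        segs = helix_segments(bundle15)
        assert len(segs) == 5
        expected = [("A", 20 * k, 20 * (k + 1)) for k in range(5)]
        assert segs == expected


class TestScaffoldFace:
    def test_concave_bundle_recovers_curvature(self, bundle15):
        res = scaffold_face_convexity(bundle15, seed=3)
        assert res.is_concave
        assert abs(res.convexity) == pytest.approx(1 / 15.0, rel=0.15)

    def test_convex_bundle_classified_convex(self):
        bundle = make_concave_bundle(face_radius=15.0, face="convex")
        res = scaffold_face_convexity(bundle, seed=3)
        assert res.shape_class == "convex"
        assert not res.is_concave

    def test_missing_helices_raise(self, helix20):
        with pytest.raises(ValueError):
            scaffold_face_convexity(helix20, face_helices=(1, 3, 5))
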