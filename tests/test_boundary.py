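"""Control splines, RBF displacement interpolation and boundary snapping."""

import numpy as np
import pytest
import shapely
from shapely.geometry import LineString

from morphomovie.boundary import (
    ControlSpline,
    ControlVectorSet,
    boundary_velocity_field,
    control_vectors,
    fit_gaussian_rbf,
    intersect_spline,
    load_splines,
    save_splines,
)
from morphomovie.errors import MappingError
from morphomovie.meshing import triangulate
from morphomovie.trajectory import (
    BoundaryShape,
    TrajectoryConfig,
    attach_flank,
    generate_synthetic_trajectory,
)


def semicircle_shape(r=1.0, n=241, depth=0.5):
    phi = np.linspace(-np.pi / 2, np.pi / 2, n)
    return attach_flank(np.column_stack([r * np.cos(phi), r * np.sin(phi)]),
                        depth=depth)


class TestIntersectSpline:
    def test_horizontal_ray_hits_bud_tip(self):
        shape = semicircle_shape()
        ray = ControlSpline("ray", [[0.0, 0.0], [5.0, 0.0]])
        pts = intersect_spline(ray, shape)
        assert pts.shape == (1, 2)
        np.testing.assert_allclose(pts[0], [1.0, 0.0], atol=1e-8)

    def test_spline_outside_shape(self):
        shape = semicircle_shape()
        far = ControlSpline("far", [[0.0, 5.0], [5.0, 5.0]])
        assert len(intersect_spline(far, shape)) == 0

    def test_flank_intersections_excluded(self):
        shape = semicircle_shape()
        through = ControlSpline("through", [[-2.0, 0.0], [5.0, 0.0]])
        pts = intersect_spline(through, shape)
        # crosses the flank left edge and the bud; only the bud point kept
        assert np.all(pts[:, 0] > shape.flank_x + 1e-9)

    def test_curved_spline_matches_bisection_oracle(self):
        shape = semicircle_shape()
        t = np.linspace(0, 1, 50)
        wave = np.column_stack([2.2 * t - 0.1, 0.35 * np.sin(6 * t)])
        spline = ControlSpline("wave", wave)
        pts = intersect_spline(spline, shape, exclude_flank=False)
        # oracle: dense sampling + bisection on the inside/outside indicator
        poly = shape.polygon()
        line = LineString(wave)
        ts = np.linspace(0, line.length, 20001)
        samples = shapely.line_interpolate_point(line, ts)
        inside = shapely.contains_xy(
            poly, *shapely.get_coordinates(samples).T)
        roots = []
        for k in np.flatnonzero(np.diff(inside.astype(int)) != 0):
            lo, hi = ts[k], ts[k + 1]
            for _ in range(60):
                mid = 0.5 * (lo + hi)
                p = line.interpolate(mid)
                if poly.contains(p) == bool(inside[k]):
                    lo = mid
                else:
                    hi = mid
            roots.append(np.asarray(line.interpolate(0.5 * (lo + hi)).coords)[0])
        roots = np.asarray(roots)
        assert len(pts) == len(roots)
        for p in pts:
            assert np.min(np.hypot(*(roots - p).T)) < 1e-6


class TestControlVectors:
    def radial_splines(self, angles_deg):
        out = []
        for a in np.radians(angles_deg):
            out.append(ControlSpline(f"r{a:.2f}",
                                     [[0.0, 0.0],
                                      [6 * np.cos(a), 6 * np.sin(a)]]))
        return out

    def test_identical_shapes_give_zero_vectors(self):
        shape = semicircle_shape()
        cv = control_vectors(self.radial_splines([-40, 0, 40]), shape, shape)
        np.testing.assert_allclose(cv.vectors, 0.0, atol=1e-9)

    def test_uniform_scaling_gives_radial_vectors(self):
        shape = semicircle_shape(depth=0.0)
        s = 1.2
        scaled = BoundaryShape(outline=s * shape.outline)
        cv = control_vectors(self.radial_splines([-50, -20, 20, 50]),
                             shape, scaled)
        # a ray through the scaling center meets the scaled polygon at
        # exactly s times its first intersection point
        np.testing.assert_allclose(cv.tips, s * cv.origins, atol=1e-8)
        mags = np.hypot(*cv.vectors.T)
        radii = np.hypot(*cv.origins.T)
        np.testing.assert_allclose(mags, (s - 1) * radii, atol=1e-8)

    def test_origins_and_tips_on_their_outlines(self):
        seq = generate_synthetic_trajectory(TrajectoryConfig(frames=3))
        splines = self.radial_splines([-60, -25, 25, 60])
        cv = control_vectors(splines, seq[0], seq[1])
        ring0 = LineString(np.vstack([seq[0].outline, seq[0].outline[:1]]))
        ring1 = LineString(np.vstack([seq[1].outline, seq[1].outline[:1]]))
        for o, t in zip(cv.origins, cv.tips):
            assert ring0.distance(shapely.points(o)) < 1e-6
            assert ring1.distance(shapely.points(t)) < 1e-6

    def test_mismatched_intersection_counts_raise(self):
        shape = semicircle_shape()
        # grazes the small shape but clearly crosses the scaled one
        graze = ControlSpline("graze", [[0.0, 1.3], [3.0, 1.3]])
        big = BoundaryShape(outline=1.6 * shape.outline)
        with pytest.raises(MappingError):
            control_vectors([graze], shape, big)


class TestGaussianRBF:
    def test_zero_vectors_give_zero_interpolant(self):
        cv = ControlVectorSet(origins=np.array([[0.0, 0], [1, 0], [0, 1]]),
                              tips=np.array([[0.0, 0], [1, 0], [0, 1]]))
        rbf = fit_gaussian_rbf(cv, ridge=0.0)
        np.testing.assert_allclose(rbf.coefficients, 0.0, atol=1e-12)
        probe = np.random.default_rng(0).normal(size=(10, 2))
        np.testing.assert_allclose(rbf(probe), 0.0, atol=1e-12)

    def test_center_exactness_with_zero_ridge(self):
        rng = np.random.default_rng(3)
        cv = ControlVectorSet(origins=rng.uniform(-1, 1, (12, 2)),
                              tips=rng.uniform(-1, 1, (12, 2)))
        rbf = fit_gaussian_rbf(cv, ridge=0.0)
        np.testing.assert_allclose(rbf(cv.origins), cv.vectors, atol=1e-8)

    def test_single_center_closed_form(self):
        cv = ControlVectorSet(origins=np.array([[0.0, 0.0]]),
                              tips=np.array([[1.0, 0.0]]))
        rbf = fit_gaussian_rbf(cv, width=1.0, ridge=0.0)
        np.testing.assert_allclose(rbf([[0.0, 0.0]]), [[1.0, 0.0]], atol=1e-12)
        d = 1.7
        np.testing.assert_allclose(
            rbf([[d, 0.0]]), [[np.exp(-d**2 / 2), 0.0]], atol=1e-12)

    def test_smoothness_along_outline(self):
        # bounded discrete second differences for width >= center spacing
        seq = generate_synthetic_trajectory(TrajectoryConfig(frames=3))
        splines = TestControlVectors().radial_splines([-60, -30, 0, 30, 60])
        cv = control_vectors(splines, seq[0], seq[1])
        rbf = fit_gaussian_rbf(cv)
        vals = rbf(seq[0].outline)
        d2 = np.abs(np.diff(vals, n=2, axis=0))
        assert d2.max() <= 2.0 * np.abs(vals).max()


class TestBoundaryVelocityField:
    def test_zero_interpolant_zero_field(self):
        seq = generate_synthetic_trajectory(TrajectoryConfig(frames=3))
        mesh = triangulate(seq[0], 0.3)
        cv = ControlVectorSet(origins=np.array([[1.0, 0.0]]),
                              tips=np.array([[1.0, 0.0]]))
        rbf = fit_gaussian_rbf(cv)
        disp = boundary_velocity_field(rbf, mesh, seq[0], snap=False)
        np.testing.assert_allclose(disp, 0.0, atol=1e-12)

    def test_snap_puts_nodes_on_next_outline(self):
        seq = generate_synthetic_trajectory(TrajectoryConfig(frames=3))
        mesh = triangulate(seq[0], 0.3)
        splines = TestControlVectors().radial_splines([-60, -30, 0, 30, 60])
        cv = control_vectors(splines, seq[0], seq[1])
        rbf = fit_gaussian_rbf(cv)
        disp = boundary_velocity_field(rbf, mesh, seq[1], snap=True)
        ring1 = LineString(np.vstack([seq[1].outline, seq[1].outline[:1]]))
        moving = np.setdiff1d(np.arange(mesh.n_boundary), mesh.flank_nodes)
        pts = mesh.boundary_ring[moving] + disp[moving]
        for p in pts:
            assert ring1.distance(shapely.points(p)) < 1e-8

    def test_flank_nodes_fixed(self):
        seq = generate_synthetic_trajectory(TrajectoryConfig(frames=3))
        mesh = triangulate(seq[0], 0.3)
        splines = TestControlVectors().radial_splines([-60, 0, 60])
        cv = control_vectors(splines, seq[0], seq[1])
        rbf = fit_gaussian_rbf(cv)
        disp = boundary_velocity_field(rbf, mesh, seq[1], snap=True)
        np.testing.assert_allclose(disp[mesh.flank_nodes], 0.0, atol=0)

    def test_centers_on_mesh_nodes_reproduced_before_snap(self):
        seq = generate_synthetic_trajectory(TrajectoryConfig(frames=3))
        mesh = triangulate(seq[0], 0.3)
        # put control-vector origins exactly on non-flank boundary nodes
        moving = np.setdiff1d(np.arange(mesh.n_boundary), mesh.flank_nodes)
        origins = mesh.boundary_ring[moving[::5]]
        rng = np.random.default_rng(1)
        tips = origins + rng.normal(scale=0.02, size=origins.shape)
        cv = ControlVectorSet(origins=origins, tips=tips)
        rbf = fit_gaussian_rbf(cv, ridge=0.0)
        disp = boundary_velocity_field(rbf, mesh, seq[1], snap=False)
        np.testing.assert_allclose(disp[moving[::5]], cv.vectors, atol=1e-8)


def test_spline_io_round_trip(tmp_path):
    sets = {"a": [ControlSpline("s0", [[0, 0], [1, 2]]),
                  ControlSpline("s1", [[0, 1], [2, 1], [3, 0]])]}
    save_splines(sets, tmp_path / "sp.json")
    back = load_splines(tmp_path / "sp.json")
    assert back["a"][1].name == "s1"
    np.testing.assert_allclose(back["a"][1].points, sets["a"][1].points)
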