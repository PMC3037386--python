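"""Clone ingestion, scoring, map selection, mixing and shape statistics."""

import numpy as np
import pytest

from morphomovie.clones import (
    AlignmentTransform,
    ExperimentalClone,
    best_match,
    clone_extents,
    clone_score,
    full_scan_comparisons,
    map_score,
    mean_filter,
    overlap_score,
    rasterize_mask_to_mesh,
)
from morphomovie.errors import ParameterError
from morphomovie.fate import DiffusionConfig, simulate_matrix
from morphomovie.fixtures import (
    fit_alignment,
    render_triangles_to_mask,
    sample_clone_cells,
    threshold_virtual_clone,
)
from morphomovie.meshing import edge_neighbors, triangulate
from morphomovie.trajectory import BoundaryShape


class TestCloneScore:
    def toy(self):
        mesh = triangulate(BoundaryShape(outline=np.array(
            [[0, 0], [1, 0], [1, 1], [0, 1]], dtype=float)), 0.45)
        return mesh

    def test_clone_outside_support_scores_zero(self):
        mesh = self.toy()
        v = np.zeros(mesh.n_triangles)
        v[0] = 1.0
        clone = ExperimentalClone(triangles=[mesh.n_triangles - 1])
        if mesh.n_triangles > 1:
            assert clone_score(v, clone, mesh.areas) == 0.0

    def test_exact_indicator_scores_one(self):
        mesh = self.toy()
        clone = ExperimentalClone(triangles=np.arange(3))
        v = np.zeros(mesh.n_triangles)
        v[:3] = 1.0
        assert clone_score(v, clone, mesh.areas) == pytest.approx(1.0)

    def test_moving_clone_triangle_out_never_increases(self):
        # exhaustive check on a small mesh: swap each in-support clone
        # triangle for each out-of-support triangle
        mesh = self.toy()
        rng = np.random.default_rng(0)
        v = rng.uniform(size=mesh.n_triangles)
        v[v < 0.4] = 0.0
        inside = np.flatnonzero(v > 0.05 * v.max())
        outside = np.setdiff1d(np.arange(mesh.n_triangles), inside)
        if len(inside) < 2 or len(outside) == 0:
            pytest.skip("degenerate toy mesh")
        base_set = inside[:2]
        base = clone_score(v, ExperimentalClone(triangles=base_set), mesh.areas)
        for t_in in base_set:
            for t_out in outside:
                moved = np.append(np.setdiff1d(base_set, [t_in]), t_out)
                s = clone_score(v, ExperimentalClone(triangles=moved),
                                mesh.areas)
                assert s <= base + 1e-12

    def test_score_bounds(self, movie_small, cfg_mixing):
        n0 = movie_small.meshes[0].n_triangles
        fields = simulate_matrix(movie_small, np.eye(n0), 0, cfg_mixing)
        areas = movie_small.meshes[-1].areas
        rng = np.random.default_rng(1)
        for _ in range(20):
            tri = rng.choice(len(areas), 5, replace=False)
            s = clone_score(fields[:, rng.integers(n0)],
                            ExperimentalClone(triangles=tri), areas)
            assert 0.0 <= s <= 1.0

    def test_empty_clone_rejected(self):
        with pytest.raises(ParameterError):
            clone_score(np.ones(3), ExperimentalClone(triangles=[]))


class TestBestMatchAndMapScore:
    def test_recovery_of_generating_seed(self, movie_small):
        cfg = DiffusionConfig(diffusion=1e-4)
        n0 = movie_small.meshes[0].n_triangles
        fields = simulate_matrix(movie_small, np.eye(n0), 0, cfg)
        rng = np.random.default_rng(3)
        hits = 0
        seeds = rng.choice(n0, 10, replace=False)
        for s in seeds:
            clone = ExperimentalClone(
                triangles=threshold_virtual_clone(fields[:, s]))
            b, _ = best_match(movie_small, clone, cfg)
            hits += (b == s)
        assert hits >= 9

    def test_argmax_beats_random_seeds(self, movie_small, cfg_mixing):
        n0 = movie_small.meshes[0].n_triangles
        fields = simulate_matrix(movie_small, np.eye(n0), 0, cfg_mixing)
        areas = movie_small.meshes[-1].areas
        clone = ExperimentalClone(
            triangles=threshold_virtual_clone(fields[:, 11]))
        _, best = best_match(movie_small, clone, cfg_mixing)
        rng = np.random.default_rng(4)
        for s in rng.integers(0, n0, 100):
            v = fields[:, s]
            assert clone_score(v, clone, areas) <= best + 1e-12

    def test_comparison_count(self, movie_small, cfg_mixing):
        n0 = movie_small.meshes[0].n_triangles
        fields = simulate_matrix(movie_small, np.eye(n0), 0, cfg_mixing)
        clones = [ExperimentalClone(
            triangles=threshold_virtual_clone(fields[:, s]))
            for s in (3, 7, 11)]
        score = map_score(movie_small, clones, cfg_mixing)
        assert score.comparisons == n0 * 3
        assert full_scan_comparisons(3156, 13) == 3156 * 13

    def test_total_is_product_and_permutation_invariant(self, movie_small,
                                                        cfg_mixing):
        n0 = movie_small.meshes[0].n_triangles
        fields = simulate_matrix(movie_small, np.eye(n0), 0, cfg_mixing)
        clones = [ExperimentalClone(
            triangles=threshold_virtual_clone(fields[:, s]))
            for s in (3, 7, 11, 19)]
        a = map_score(movie_small, clones, cfg_mixing)
        b = map_score(movie_small, clones[::-1], cfg_mixing)
        assert a.total == pytest.approx(np.prod(a.best_scores), rel=1e-12)
        assert a.total == pytest.approx(b.total, rel=1e-12)

    def test_generating_movie_beats_distractor(self, movie_small,
                                               movie_distractor):
        cfg = DiffusionConfig(diffusion=1e-4)
        n0 = movie_small.meshes[0].n_triangles
        fields = simulate_matrix(movie_small, np.eye(n0), 0, cfg)
        areas = movie_small.meshes[-1].areas
        rng = np.random.default_rng(11)
        seeds = rng.choice(n0, 20, replace=False)
        clones = [ExperimentalClone(
            triangles=sample_clone_cells(fields[:, s], areas, 60, rng))
            for s in seeds]
        sa = map_score(movie_small, clones, cfg)
        sb = map_score(movie_distractor, clones, cfg)
        assert sa.total > sb.total


class TestMeanFilterAndOverlap:
    def test_zero_iterations_is_normalized_indicator(self, mesh_coarse):
        clone = ExperimentalClone(triangles=[0, 1, 2])
        v = mean_filter(clone, mesh_coarse, iterations=0)
        assert v.sum() == pytest.approx(1.0)
        np.testing.assert_allclose(v[clone.triangles], 1 / 3)

    def test_distribution_sums_to_one_each_iteration(self, mesh_coarse):
        clone = ExperimentalClone(triangles=[4])
        for k in range(5):
            v = mean_filter(clone, mesh_coarse, iterations=k)
            assert v.sum() == pytest.approx(1.0, abs=1e-12)

    def test_raw_averaging_never_increases_max(self, mesh_coarse):
        # the mean filter's averaging step is a convex combination
        en = edge_neighbors(mesh_coarse)
        rng = np.random.default_rng(5)
        for _ in range(100):
            v = rng.uniform(size=mesh_coarse.n_triangles)
            total = v.copy()
            count = np.ones(mesh_coarse.n_triangles)
            np.add.at(total, en.tri_a, v[en.tri_b])
            np.add.at(total, en.tri_b, v[en.tri_a])
            np.add.at(count, en.tri_a, 1.0)
            np.add.at(count, en.tri_b, 1.0)
            assert (total / count).max() <= v.max() + 1e-12

    def test_overlap_symmetry(self, mesh_coarse):
        rng = np.random.default_rng(6)
        n = mesh_coarse.n_triangles
        for _ in range(100):
            a = rng.uniform(size=n)
            a[rng.uniform(size=n) < 0.5] = 0.0
            b = rng.uniform(size=n)
            b[rng.uniform(size=n) < 0.5] = 0.0
            a = a / max(a.sum(), 1e-300)
            b = b / max(b.sum(), 1e-300)
            assert overlap_score(a, b) == pytest.approx(overlap_score(b, a),
                                                        abs=1e-12)

    def test_disjoint_supports_overlap_zero(self, mesh_coarse):
        n = mesh_coarse.n_triangles
        a = np.zeros(n)
        b = np.zeros(n)
        a[: n // 2] = 1.0 / (n // 2)
        b[n // 2:] = 1.0 / (n - n // 2)
        assert overlap_score(a, b) == 0.0

    def test_identical_distributions_overlap_one(self, mesh_coarse):
        clone = ExperimentalClone(triangles=[2, 3, 4])
        v = mean_filter(clone, mesh_coarse, iterations=3)
        assert overlap_score(v, v) == pytest.approx(1.0)


class TestCloneExtents:
    def test_whole_bud_clone_isotropic(self, mesh_coarse):
        # triangles lying entirely in the bud (x >= 0, flank excluded)
        verts_x = mesh_coarse.points[mesh_coarse.triangles, 0]
        bud = np.flatnonzero(verts_x.min(axis=1) >= -1e-9)
        pd, ap, ratio, label = clone_extents(
            ExperimentalClone(triangles=bud), mesh_coarse)
        # one boundary-layer of triangles is lost to the strict vertex
        # filter at this coarse resolution
        assert pd == pytest.approx(1.0, abs=0.1)
        assert ap == pytest.approx(1.0, abs=0.1)
        assert label == "isotropic"

    def test_elongated_clone_anisotropic(self, trajectory72):
        mesh = triangulate(trajectory72[0], 0.12)
        c = mesh.centroids
        band = np.flatnonzero((c[:, 0] > 0.1) & (c[:, 0] < 0.8)
                              & (np.abs(c[:, 1]) < 0.08))
        pd, ap, ratio, label = clone_extents(
            ExperimentalClone(triangles=band), mesh)
        assert ratio > 1.5
        assert label == "anisotropic"

    def test_ratio_is_fraction_ratio(self, mesh_coarse):
        clone = ExperimentalClone(triangles=[0, 5, 9])
        pd, ap, ratio, _ = clone_extents(clone, mesh_coarse)
        assert ratio == pytest.approx(pd / ap)


class TestRasterize:
    def test_full_mask_includes_all_triangles(self, mesh_coarse):
        align = fit_alignment(mesh_coarse, size=120)
        mask = np.ones((120, 120), dtype=bool)
        clone = rasterize_mask_to_mesh(mask, mesh_coarse, align)
        assert clone.n == mesh_coarse.n_triangles

    def test_empty_mask_empty_clone(self, mesh_coarse):
        align = fit_alignment(mesh_coarse, size=120)
        clone = rasterize_mask_to_mesh(np.zeros((120, 120), bool),
                                       mesh_coarse, align)
        assert clone.n == 0

    def test_disc_mask_area_within_ten_percent(self, trajectory72):
        mesh = triangulate(trajectory72[0], 0.12)
        size = 200
        align = fit_alignment(mesh, size=size)
        # disc of radius 0.45 centered in the bud, drawn in image pixels
        center = align.model_to_image(np.array([[0.5, 0.0]]))[0]
        r_pix = 0.45 / align.scale
        yy, xx = np.mgrid[0:size, 0:size]
        img_x = xx + 0.5
        img_y = size - yy - 0.5
        mask = (img_x - center[0])**2 + (img_y - center[1])**2 <= r_pix**2
        clone = rasterize_mask_to_mesh(mask, mesh, align)
        area = mesh.areas[clone.triangles].sum()
        assert area == pytest.approx(np.pi * 0.45**2, rel=0.10)

    def test_round_trip_through_rendered_mask(self, mesh_coarse):
        align = fit_alignment(mesh_coarse, size=200)
        chosen = np.array([5, 6, 7, 12])
        mask = render_triangles_to_mask(mesh_coarse, chosen, align, size=200)
        back = rasterize_mask_to_mesh(mask, mesh_coarse, align)
        # at this resolution most chosen triangles survive the round trip
        assert len(np.intersect1d(chosen, back.triangles)) >= 3


def test_alignment_transform_round_trip():
    t = AlignmentTransform(scale=0.03, rotation_deg=12.0,
                           translation=(-1.0, 0.5))
    rng = np.random.default_rng(0)
    pts = rng.normal(size=(20, 2))
    np.testing.assert_allclose(
        t.model_to_image(t.image_to_model(pts)), pts, atol=1e-12)
    back = AlignmentTransform.from_dict(t.to_dict())
    assert back == t
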