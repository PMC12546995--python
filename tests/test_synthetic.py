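"""Synthetic head-population generator: determinism, truth placement, views."""

import numpy as np
import pytest

import cranioguide as cg
from cranioguide.errors import InvalidInputError
from cranioguide.geometry import closest_point_on_mesh, mesh_edge_length
from cranioguide.mapping import select_subset, training_rows_from_records
from cranioguide.synthetic import (CORRESPONDENCE_10, FACIAL_ANGLES_24,
                                   default_synthetic_subset)


class TestSphereHead:
    def test_truth_points_at_sphere_radius(self):
        # axis fiducials coincide with icosphere vertices → exact radius;
        # facial points sit on faces, inside by at most the faceting sag
        sub = cg.make_sphere_head(radius=90.0, refinement=4)
        np.testing.assert_allclose(
            np.linalg.norm(sub.cranial.as_array(), axis=1), 90.0, atol=1e-9)
        facial_radii = np.linalg.norm(sub.facial.points, axis=1)
        assert np.abs(facial_radii - 90.0).max() < mesh_edge_length(sub.mesh)

    def test_truth_points_on_mesh(self):
        sub = cg.make_sphere_head(radius=90.0, refinement=3)
        _, dist = closest_point_on_mesh(sub.mesh,
                                        np.vstack([sub.cranial.as_array(),
                                                   sub.facial.points]))
        assert dist.max() < 1e-6

    def test_deterministic(self):
        a = cg.make_sphere_head(radius=80.0, refinement=3)
        b = cg.make_sphere_head(radius=80.0, refinement=3)
        np.testing.assert_array_equal(a.mesh.vertices, b.mesh.vertices)
        np.testing.assert_array_equal(a.facial.points, b.facial.points)

    def test_surface_area_close_to_analytic(self):
        sub = cg.make_sphere_head(radius=1.0, refinement=4)
        assert sub.mesh.area == pytest.approx(4 * np.pi, rel=0.01)

    def test_invalid_arguments(self):
        with pytest.raises(InvalidInputError):
            cg.make_sphere_head(radius=-1.0)
        with pytest.raises(InvalidInputError):
            cg.make_sphere_head(radius=1.0, refinement=1)


class TestPopulation:
    def test_zero_sd_gives_mean_ellipsoid(self):
        priors = {"x": (95.0, 0.0), "y": (75.0, 0.0), "z": (92.0, 0.0)}
        subs = cg.sample_population(1, priors, seed=0, facial_angle_sd=0.0)
        assert subs[0].shape == {"x": 95.0, "y": 75.0, "z": 92.0}

    def test_reproducible_from_seed(self):
        a = cg.sample_population(4, seed=42)
        b = cg.sample_population(4, seed=42)
        for sa, sb in zip(a, b):
            np.testing.assert_array_equal(sa.mesh.vertices, sb.mesh.vertices)
            np.testing.assert_array_equal(sa.facial.points, sb.facial.points)

    def test_sample_means_near_priors(self):
        n = 100
        priors = {"x": (95.0, 5.0), "y": (75.0, 4.0), "z": (92.0, 5.0)}
        subs = cg.sample_population(n, priors, seed=1)
        for key, (mean, sd) in priors.items():
            values = np.array([s.shape[key] for s in subs])
            assert abs(values.mean() - mean) < 3 * sd / np.sqrt(n)

    def test_nonpositive_prior_rejected(self):
        with pytest.raises(InvalidInputError):
            cg.sample_population(2, {"x": (-5.0, 1.0)}, seed=0)

    def test_geometry_reproduces_stored_cranial_truth(self, small_population):
        # cross-module consistency: the ray constructions land on the
        # stored axis fiducials within one edge length
        for sub in small_population[:4]:
            edge = mesh_edge_length(sub.mesh)
            iz = cg.estimate_iz(sub.mesh, sub.cranial.nz, sub.cranial.lpa,
                                sub.cranial.rpa)
            cz = cg.estimate_cz(sub.mesh, sub.cranial.nz, iz, sub.cranial.lpa,
                                sub.cranial.rpa)
            assert np.linalg.norm(iz - sub.cranial.iz) < edge
            assert np.linalg.norm(cz - sub.cranial.cz) < edge


class TestRenderViews:
    def test_nine_distinct_affine_frames(self, small_population, views):
        renders = cg.render_views(small_population[0], views)
        assert len({v.view.view_id for v in renders}) == 9
        for i in range(9):
            for j in range(i + 1, 9):
                dA = np.abs(renders[i].affine.A - renders[j].affine.A).max()
                assert dA > 1e-6

    def test_noiseless_render_matches_documented_affine(self, small_population,
                                                        views):
        sub = small_population[1]
        for render in cg.render_views(sub, views, jitter_sigma=0.0):
            np.testing.assert_allclose(
                render.facial.points, render.affine.apply(sub.facial.points),
                atol=1e-12)
            np.testing.assert_allclose(
                render.cranial.as_array(),
                render.affine.apply(sub.cranial.as_array()), atol=1e-12)

    def test_normalized_coordinates_in_unit_cube(self, small_population, views):
        for render in cg.render_views(small_population[2], views):
            assert render.facial.points.min() >= 0.0
            assert render.facial.points.max() <= 1.0

    def test_correspondence_fit_recovers_view_affine(self, small_population,
                                                     views):
        sub = small_population[3]
        idx = list(CORRESPONDENCE_10)
        for render in cg.render_views(sub, views, jitter_sigma=0.0):
            T = cg.fit_view_affine(sub.facial.points[idx],
                                   render.facial.points[idx])
            np.testing.assert_allclose(T.A, render.affine.A, atol=1e-8)
            np.testing.assert_allclose(T.b, render.affine.b, atol=1e-8)

    def test_jitter_sd_matches_request(self, small_population, views):
        sub = small_population[0]
        sigma = 0.005
        deltas = []
        for rep in range(100):
            render = cg.render_views(sub, [views[4]], jitter_sigma=sigma,
                                     seed=rep)[0]
            clean = cg.render_views(sub, [views[4]], jitter_sigma=0.0)[0]
            deltas.append(render.facial.points - clean.facial.points)
        sd = np.std(np.stack(deltas))
        assert sd == pytest.approx(sigma, rel=0.10)


class TestTrainingTable:
    def test_row_count_is_subjects_times_views(self, small_population, views):
        records = cg.build_training_table(small_population[:2], views, seed=0)
        assert len(records) == 2 * 9

    def test_ground_truth_mode_is_identifiable(self, small_population, views,
                                               subset):
        rng = np.random.default_rng(3)
        gt = {c: (rng.normal(0, 0.1, (60, 3)), rng.normal(0, 0.1, 3))
              for c in ("Iz", "LPA", "RPA", "Cz")}
        records = cg.build_training_table(small_population, views,
                                          ground_truth=gt, seed=4)
        from cranioguide.mapping import fit_linear_headmap
        hmap = fit_linear_headmap(training_rows_from_records(records, subset),
                                  subset)
        for c, (A, b) in gt.items():
            np.testing.assert_allclose(hmap.targets[c][0], A, atol=1e-8)
            np.testing.assert_allclose(hmap.targets[c][1], b, atol=1e-8)

    def test_rows_regenerate_bit_identically(self, small_population, views):
        a = cg.build_training_table(small_population[:3], views,
                                    jitter_sigma=0.004, seed=9)
        b = cg.build_training_table(small_population[:3], views,
                                    jitter_sigma=0.004, seed=9)
        assert a == b


class TestConventions:
    def test_facial_point_zero_is_the_nasion(self, small_population):
        for sub in small_population[:3]:
            np.testing.assert_array_equal(sub.facial.points[0], sub.cranial.nz)

    def test_default_subset_covers_20_of_24(self):
        spec = default_synthetic_subset()
        assert spec.nf == 20
        assert len(FACIAL_ANGLES_24) == 24
        assert set(spec.indices) <= set(range(24))
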