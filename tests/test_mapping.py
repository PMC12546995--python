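"""Affine frame conversion and the stacked linear head map."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import cranioguide as cg
from cranioguide.errors import DegeneracyError, InvalidInputError
from cranioguide.mapping import (AffineTransform, FacialLandmarks, SubsetSpec,
                                 fit_linear_headmap, nz_index, select_subset,
                                 training_rows_from_records)


def random_points(rng, n=10):
    return rng.normal(0, 1, (n, 3))


def ols_oracle(X, Y):
    """Independent per-coordinate normal-equations solve (reference semantics)."""
    Xa = np.hstack([X, np.ones((len(X), 1))])
    G = Xa.T @ Xa
    coef = np.column_stack([np.linalg.solve(G, Xa.T @ Y[:, j]) for j in range(3)])
    return coef[:-1], coef[-1]


class TestFitViewAffine:
    def test_identity(self):
        rng = np.random.default_rng(0)
        src = random_points(rng)
        T = cg.fit_view_affine(src, src)
        np.testing.assert_allclose(T.A, np.eye(3), atol=1e-12)
        np.testing.assert_allclose(T.b, 0, atol=1e-12)

    def test_pure_translation(self):
        rng = np.random.default_rng(1)
        src = random_points(rng)
        T = cg.fit_view_affine(src, src + [0.1, 0.2, 0.3])
        np.testing.assert_allclose(T.A, np.eye(3), atol=1e-10)
        np.testing.assert_allclose(T.b, [0.1, 0.2, 0.3], atol=1e-10)

    def test_recovers_generating_affine(self):
        rng = np.random.default_rng(2)
        A = np.eye(3) + 0.3 * rng.normal(0, 1, (3, 3))
        b = rng.normal(0, 1, 3)
        src = random_points(rng)
        T = cg.fit_view_affine(src, src @ A.T + b)
        np.testing.assert_allclose(T.A, A, atol=1e-8)
        np.testing.assert_allclose(T.b, b, atol=1e-8)

    def test_coplanar_source_rejected(self):
        rng = np.random.default_rng(3)
        src = random_points(rng)
        src[:, 2] = 0.0
        with pytest.raises(DegeneracyError):
            cg.fit_view_affine(src, src)

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(InvalidInputError):
            cg.fit_view_affine(np.zeros((5, 3)), np.zeros((4, 3)))


class TestAffineTransform:
    @settings(deadline=None, max_examples=25)
    @given(st.integers(0, 10_000))
    def test_compose_then_apply_equals_sequential(self, seed):
        rng = np.random.default_rng(seed)
        T1 = AffineTransform(np.eye(3) + 0.2 * rng.normal(size=(3, 3)),
                             rng.normal(size=3))
        T2 = AffineTransform(np.eye(3) + 0.2 * rng.normal(size=(3, 3)),
                             rng.normal(size=3))
        pts = rng.normal(size=(6, 3))
        np.testing.assert_allclose(T1.compose(T2).apply(pts),
                                   T1.apply(T2.apply(pts)), atol=1e-12)

    @settings(deadline=None, max_examples=25)
    @given(st.integers(0, 10_000))
    def test_inverse_round_trip(self, seed):
        rng = np.random.default_rng(seed)
        T = AffineTransform(np.eye(3) + 0.2 * rng.normal(size=(3, 3)),
                            rng.normal(size=3))
        pts = rng.normal(size=(8, 3))
        np.testing.assert_allclose(
            cg.map_points(T.inverse(), cg.map_points(T, pts)), pts, atol=1e-9)

    def test_map_points_identity_and_scale(self):
        pts = np.array([[1.0, 1.0, 1.0]])
        np.testing.assert_array_equal(
            cg.map_points(AffineTransform.identity(), pts), pts)
        np.testing.assert_allclose(
            cg.map_points(AffineTransform(2 * np.eye(3), np.zeros(3)), pts),
            [[2, 2, 2]])


class TestSubsets:
    def test_single_index(self):
        f = FacialLandmarks(np.arange(72, dtype=float).reshape(24, 3),
                            convention="synthetic-24")
        spec = SubsetSpec("one", "synthetic-24", (5,))
        np.testing.assert_array_equal(select_subset(f, spec), [15, 16, 17])

    def test_default_camera_subset_has_nf_20(self):
        spec = cg.default_subset("camera468")
        assert spec.nf == 20
        rng = np.random.default_rng(0)
        f = FacialLandmarks(rng.random((468, 3)), convention="camera468")
        assert select_subset(f, spec).shape == (60,)

    def test_permuted_spec_permutes_vector(self):
        rng = np.random.default_rng(4)
        f = FacialLandmarks(rng.random((24, 3)), convention="synthetic-24")
        idx = (3, 11, 7)
        v1 = select_subset(f, SubsetSpec("a", "synthetic-24", idx))
        v2 = select_subset(f, SubsetSpec("b", "synthetic-24", (7, 3, 11)))
        np.testing.assert_array_equal(v1.reshape(3, 3)[[2, 0, 1]].reshape(-1), v2)

    def test_duplicate_indices_rejected(self):
        with pytest.raises(InvalidInputError):
            SubsetSpec("bad", "synthetic-24", (1, 1, 2))

    def test_nz_index_by_convention(self):
        assert nz_index("camera468") == 168
        assert nz_index("synthetic-24") == 0


def make_rows(rng, n_rows=70, nf=5, coef=None):
    X = rng.normal(0, 1, (n_rows, 3 * nf))
    if coef is None:
        A = rng.normal(0, 0.5, (3 * nf, 3))
        b = rng.normal(0, 0.5, 3)
    else:
        A, b = coef
    Y = X @ A + b
    return X, Y, A, b


class TestFitLinearHeadMap:
    def _rows_dict(self, X, Y):
        return {c: list(zip(X, Y)) for c in ("Iz", "LPA", "RPA", "Cz")}

    def test_noiseless_recovery(self):
        rng = np.random.default_rng(5)
        nf = 5
        X, Y, A, b = make_rows(rng, nf=nf)
        spec = SubsetSpec("toy", "synthetic-24", tuple(range(nf)))
        hmap = fit_linear_headmap(self._rows_dict(X, Y), spec)
        for c in ("Iz", "LPA", "RPA", "Cz"):
            np.testing.assert_allclose(hmap.targets[c][0], A, atol=1e-8)
            np.testing.assert_allclose(hmap.targets[c][1], b, atol=1e-8)

    def test_constant_target_gives_zero_coefficients(self):
        rng = np.random.default_rng(6)
        nf = 5
        X = rng.normal(0, 1, (70, 3 * nf))
        Y = np.tile([1.0, 2.0, 3.0], (70, 1))
        spec = SubsetSpec("toy", "synthetic-24", tuple(range(nf)))
        hmap = fit_linear_headmap(self._rows_dict(X, Y), spec)
        np.testing.assert_allclose(hmap.targets["Iz"][0], 0, atol=1e-10)
        np.testing.assert_allclose(hmap.targets["Iz"][1], [1, 2, 3], atol=1e-10)

    def test_noisy_fit_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(7)
        nf = 5
        X, Y, _, _ = make_rows(rng, nf=nf)
        Y = Y + rng.normal(0, 0.05, Y.shape)
        spec = SubsetSpec("toy", "synthetic-24", tuple(range(nf)))
        hmap = fit_linear_headmap(self._rows_dict(X, Y), spec)
        A_ref, b_ref = ols_oracle(X, Y)
        np.testing.assert_allclose(hmap.targets["Cz"][0], A_ref, atol=1e-8)
        np.testing.assert_allclose(hmap.targets["Cz"][1], b_ref, atol=1e-8)

    def test_insufficient_rows_rejected(self):
        rng = np.random.default_rng(8)
        X, Y, _, _ = make_rows(rng, n_rows=10, nf=5)
        spec = SubsetSpec("toy", "synthetic-24", tuple(range(5)))
        with pytest.raises(InvalidInputError):
            fit_linear_headmap(self._rows_dict(X, Y), spec)

    def test_rank_deficiency_named_without_ridge(self):
        rng = np.random.default_rng(9)
        X = rng.normal(0, 1, (70, 15))
        X[:, 1] = X[:, 0]  # collinear columns
        Y = rng.normal(0, 1, (70, 3))
        spec = SubsetSpec("toy", "synthetic-24", tuple(range(5)))
        with pytest.raises(DegeneracyError):
            fit_linear_headmap(self._rows_dict(X, Y), spec)
        # ridge rescues the same design
        hmap = fit_linear_headmap(self._rows_dict(X, Y), spec, ridge=1e-6)
        assert np.isfinite(hmap.targets["Iz"][0]).all()


class TestPredictCranial:
    def test_zero_map_returns_intercepts_and_copies_nz(self):
        nf = 20
        spec = SubsetSpec("syn", "synthetic-24",
                          tuple(range(nf)))
        targets = {c: (np.zeros((3 * nf, 3)), np.array([0.1, 0.2, 0.3]) * (i + 1))
                   for i, c in enumerate(("Iz", "LPA", "RPA", "Cz"))}
        hmap = cg.LinearHeadMap(targets=targets, subset=spec)
        rng = np.random.default_rng(10)
        f = FacialLandmarks(rng.random((24, 3)), convention="synthetic-24")
        pred = cg.predict_cranial(hmap, f)
        np.testing.assert_array_equal(pred.nz, f.points[0])
        np.testing.assert_allclose(pred.iz, [0.1, 0.2, 0.3])
        np.testing.assert_allclose(pred.cz, [0.4, 0.8, 1.2])
        assert pred.frame == "normalized-camera"
        assert pred.method == "three-point"

    def test_round_trip_on_training_row(self, small_population, views, subset):
        records = cg.build_training_table(small_population[:6], views, seed=3)
        rows = training_rows_from_records(records, subset)
        hmap = fit_linear_headmap(rows, subset, ridge=1e-10)
        rec = records[0]
        f = FacialLandmarks(np.asarray(rec["facial"]), convention="synthetic-24")
        pred = cg.predict_cranial(hmap, f)
        # in-sample prediction is close but not exact (geometry targets)
        assert np.linalg.norm(pred.iz - rec["targets"]["Iz"]) < 0.1

    def test_convention_mismatch_rejected(self):
        spec = SubsetSpec("syn", "synthetic-24", tuple(range(20)))
        targets = {c: (np.zeros((60, 3)), np.zeros(3))
                   for c in ("Iz", "LPA", "RPA", "Cz")}
        hmap = cg.LinearHeadMap(targets=targets, subset=spec)
        f = FacialLandmarks(np.zeros((468, 3)), convention="camera468")
        with pytest.raises(InvalidInputError):
            cg.predict_cranial(hmap, f)

    def test_translation_equivariance_does_not_hold(self):
        # the map is affine in landmark coordinates, not a rigid-motion model
        rng = np.random.default_rng(11)
        nf = 20
        spec = SubsetSpec("syn", "synthetic-24", tuple(range(nf)))
        targets = {c: (rng.normal(0, 0.1, (3 * nf, 3)), rng.normal(0, 0.1, 3))
                   for c in ("Iz", "LPA", "RPA", "Cz")}
        hmap = cg.LinearHeadMap(targets=targets, subset=spec)
        f = FacialLandmarks(rng.random((24, 3)), convention="synthetic-24")
        shifted = FacialLandmarks(f.points + 0.1, convention="synthetic-24")
        delta = cg.predict_cranial(hmap, shifted).iz - cg.predict_cranial(hmap, f).iz
        assert not np.allclose(delta, 0.1, atol=1e-3)


class TestFacialLandmarks:
    def test_wrong_count_rejected(self):
        with pytest.raises(InvalidInputError):
            FacialLandmarks(np.zeros((10, 3)), convention="camera468")

    def test_frame_bounds_validation(self):
        pts = np.zeros((24, 3))
        pts[0, 0] = 1.5
        f = FacialLandmarks(pts, convention="synthetic-24")
        with pytest.raises(InvalidInputError):
            f.validate_frame_bounds()
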