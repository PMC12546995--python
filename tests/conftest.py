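import numpy as np
import pytest

import cranioguide as cg
from cranioguide.synthetic import default_synthetic_subset


@pytest.fixture(scope="session")
def unit_sphere():
    """Unit-radius icosphere head with canonical axis fiducials."""
    return cg.make_sphere_head(radius=1.0, refinement=3)


@pytest.fixture(scope="session")
def unit_sphere_fine():
    return cg.make_sphere_head(radius=1.0, refinement=4)


@pytest.fixture(scope="session")
def ellipsoid():
    """Semi-axes (1.0, 0.8, 0.9): the analytic ellipsoid oracle substrate."""
    return cg.make_ellipsoid_head([1.0, 0.8, 0.9], refinement=4)


@pytest.fixture(scope="session")
def views():
    return cg.nine_view_grid()


@pytest.fixture(scope="session")
def subset():
    return default_synthetic_subset()


@pytest.fixture(scope="session")
def small_population():
    return cg.sample_population(12, seed=101)


@pytest.fixture(scope="session")
def atlas_head():
    """Mean-shape ellipsoid head used as the atlas in registration tests."""
    return cg.make_ellipsoid_head([95.0, 75.0, 92.0], refinement=3,
                                  subject_id="atlas")


@pytest.fixture(scope="session")
def atlas_bundle(atlas_head):
    layout = cg.compute_layout(atlas_head.mesh, atlas_head.cranial, "10-20",
                               source="atlas")
    return cg.AtlasBundle(cranial=atlas_head.cranial,
                          layouts={"10-20": layout})


@pytest.fixture(scope="session")
def fitted_map(small_population, views, subset):
    """Geometry-mode linear head map fitted on the small population."""
    from cranioguide.mapping import fit_linear_headmap, training_rows_from_records
    records = cg.build_training_table(small_population, views, seed=7)
    return fit_linear_headmap(training_rows_from_records(records, subset), subset)


def sphere_sagittal(fraction: float) -> np.ndarray:
    """Closed-form 10-20 midline point on the unit sphere (Nz at +x)."""
    theta = np.pi * fraction
    return np.array([np.cos(theta), 0.0, np.sin(theta)])


def sphere_coronal(fraction: float) -> np.ndarray:
    theta = np.pi * fraction
    return np.array([0.0, np.cos(theta), np.sin(theta)])


def sphere_ring(fraction: float) -> np.ndarray:
    z = np.sin(np.deg2rad(18.0))
    r = np.cos(np.deg2rad(18.0))
    alpha = 2.0 * np.pi * fraction
    return np.array([r * np.cos(alpha), r * np.sin(alpha), z])


def sphere_circle_arc(p1, p2, p3, fraction: float) -> np.ndarray:
    """Point at an arc-length fraction of the circle arc p1→p2→p3 cut from
    the unit sphere by the plane of the three points (constant-speed circle
    parametrization: fractions equal angle fractions)."""
    n = np.cross(p2 - p1, p3 - p1)
    n = n / np.linalg.norm(n)
    center = n * (n @ p1)
    radius = np.linalg.norm(p1 - center)
    u = (p1 - center) / radius
    v = np.cross(n, u)

    def angle(p):
        d = p - center
        return np.arctan2(d @ v, d @ u) % (2 * np.pi)

    a2, a3 = angle(p2), angle(p3)
    a = fraction * a3 if a2 <= a3 else -fraction * (2 * np.pi - a3)
    return center + radius * (np.cos(a) * u + np.sin(a) * v)
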