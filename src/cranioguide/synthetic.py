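"""Synthetic head populations with ground-truth landmarks.

Stands in for a licensed 3D head-scan library: heads are triangulated
ellipsoids (icosphere tessellations scaled by per-subject semi-axes) in
millimeter coordinates, facing +x with +z up and the left ear at +y.
Each subject carries

* cranial ground truth — the axis intersections (Nz, Iz, LPA, RPA, Cz)
  snapped onto the faceted surface;
* facial ground truth — a fixed set of 24 points at named ellipsoidal
  angular positions over the anterior surface (face contour, brows, eyes,
  nose, mouth, chin), also snapped onto the mesh.  Facial point 0 sits at
  the nasion, mirroring the camera convention's Nz-identity landmark.

Per-subject facial variation is emulated by small Gaussian perturbations
of each point's angular position (the Nz-identity point excepted), so
faces vary smoothly and independently of the three gross shape
parameters — without this, multi-subject facial data would carry only
three degrees of freedom per view and any stacked regression on it would
be structurally degenerate, which real faces are not.

A nine-view camera grid (three vertical × three horizontal stations)
emulates a multi-view rendering protocol: each view applies a rigid
rotation followed by an orthographic normalization of the head bounding
box into the unit square with a margin, standing in for a face detector's
normalized output frame.  The exact per-view affine is recorded so the
frame-conversion fit can be checked against it.  Gaussian jitter is added
to facial landmarks only; cranial reference points stay exact, mirroring
a pipeline whose cranial ground truth is curated rather than detected.

All generators are pure functions of (parameters, seed).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import trimesh

from .cranial import CranialLandmarks
from .errors import InvalidInputError
from .geometry import closest_point_on_mesh
from .mapping import (AffineTransform, FacialLandmarks, SubsetSpec,
                      select_subset)

#: (azimuth°, elevation°) of the 24 synthetic facial points; index 0 is the
#: nasion-identity point.  Azimuth is measured from +x toward +y (left),
#: elevation from the horizontal plane toward +z.
FACIAL_ANGLES_24 = (
    (0, 0),                     # 0  nasion
    (0, 14),                    # 1  brow midpoint
    (-14, 10), (14, 10),        # 2  3  inner brows
    (-33, 8), (33, 8),          # 4  5  outer brows
    (-12, 2), (12, 2),          # 6  7  inner eye corners
    (-30, 2), (30, 2),          # 8  9  outer eye corners
    (0, -12),                   # 10 nose tip
    (-10, -14), (10, -14),      # 11 12 nose alae
    (0, -20),                   # 13 subnasale
    (-24, -26), (24, -26),      # 14 15 mouth corners
    (0, -24),                   # 16 upper lip
    (0, -33),                   # 17 lower lip
    (0, -46),                   # 18 chin tip
    (-44, -36), (44, -36),      # 19 20 jaw
    (-58, -12), (58, -12),      # 21 22 lower face contour
    (0, 28),                    # 23 forehead
)

SYNTHETIC_CONVENTION = "synthetic-24"

#: Default 20-point regression subset (drops brow midpoint, subnasale, lips).
DEFAULT_SYNTHETIC_SUBSET_INDICES = (
    0, 2, 3, 4, 5, 6, 7, 8, 9, 10, 11, 12, 14, 15, 18, 19, 20, 21, 22, 23
)

#: The 10 matched points used for per-view affine frame fits: nasion, the
#: four eye corners, nose tip, mouth corners, chin and forehead.
CORRESPONDENCE_10 = (0, 6, 7, 8, 9, 10, 14, 15, 18, 23)

#: Population priors: semi-axis (mean, sd) in mm along x (depth), y (width),
#: z (height) — adult-head-like proportions.
DEFAULT_SHAPE_PRIORS = {"x": (95.0, 5.0), "y": (75.0, 4.0), "z": (92.0, 5.0)}

#: Per-subject angular perturbation (deg) of facial-feature positions.
DEFAULT_FACIAL_ANGLE_SD = 3.0


def default_synthetic_subset(convention: str = SYNTHETIC_CONVENTION) -> SubsetSpec:
    if convention != SYNTHETIC_CONVENTION:
        raise InvalidInputError(f"no default subset for convention {convention!r}")
    return SubsetSpec("synthetic-default20", convention, DEFAULT_SYNTHETIC_SUBSET_INDICES)


@dataclass(frozen=True)
class SyntheticSubject:
    """One generated head: mesh plus cranial/facial ground truth (head-mm)."""

    subject_id: str
    mesh: trimesh.Trimesh
    cranial: CranialLandmarks
    facial: FacialLandmarks
    shape: dict
    seed: int


@dataclass(frozen=True)
class CameraView:
    """One camera station: a rigid frame ahead of per-subject normalization."""

    view_id: str
    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "rotation", np.asarray(self.rotation, float).reshape(3, 3))
        object.__setattr__(self, "translation", np.asarray(self.translation, float).reshape(3))


@dataclass(frozen=True)
class ViewRender:
    """A subject seen from one view, in the normalized camera frame."""

    view: CameraView
    facial: FacialLandmarks
    cranial: CranialLandmarks
    affine: AffineTransform  #: exact head-mm → normalized-camera map


def _rot_z(deg: float) -> np.ndarray:
    c, s = np.cos(np.deg2rad(deg)), np.sin(np.deg2rad(deg))
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def _rot_y(deg: float) -> np.ndarray:
    c, s = np.cos(np.deg2rad(deg)), np.sin(np.deg2rad(deg))
    return np.array([[c, 0.0, s], [0.0, 1.0, 0.0], [-s, 0.0, c]])


def nine_view_grid(yaw_deg=(-30.0, 0.0, 30.0),
                   pitch_deg=(20.0, 0.0, -20.0)) -> list[CameraView]:
    """The 3×3 view grid: (top, middle, bottom) × (left, center, right)."""
    rows = ("top", "middle", "bottom")
    cols = ("left", "center", "right")
    views = []
    for row, pitch in zip(rows, pitch_deg):
        for col, yaw in zip(cols, yaw_deg):
            views.append(CameraView(f"{row}-{col}", _rot_y(pitch) @ _rot_z(yaw),
                                    np.zeros(3)))
    return views


def _ellipsoid_point(axes: np.ndarray, az_deg: float, el_deg: float) -> np.ndarray:
    az, el = np.deg2rad(az_deg), np.deg2rad(el_deg)
    return axes * np.array([np.cos(el) * np.cos(az),
                            np.cos(el) * np.sin(az),
                            np.sin(el)])


def _build_subject(axes, subject_id: str, seed: int, refinement: int,
                   angle_offsets) -> SyntheticSubject:
    axes = np.asarray(axes, dtype=float)
    base = trimesh.creation.icosphere(subdivisions=refinement)
    mesh = trimesh.Trimesh(vertices=base.vertices * axes, faces=base.faces,
                           process=False)
    a, b, c = axes
    cranial_raw = np.array([[a, 0, 0], [-a, 0, 0], [0, b, 0], [0, -b, 0], [0, 0, c]],
                           dtype=float)
    cranial_pts, _ = closest_point_on_mesh(mesh, cranial_raw)
    facial_raw = np.array([
        _ellipsoid_point(axes, az + daz, el + del_)
        for (az, el), (daz, del_) in zip(FACIAL_ANGLES_24, angle_offsets)
    ])
    facial_pts, _ = closest_point_on_mesh(mesh, facial_raw)
    facial_pts[0] = cranial_pts[0]  # the Nz-identity point is the nasion itself
    cranial = CranialLandmarks(*cranial_pts, frame="head-mm", method="three-point")
    facial = FacialLandmarks(facial_pts, convention=SYNTHETIC_CONVENTION,
                             frame="head-mm")
    return SyntheticSubject(subject_id=subject_id, mesh=mesh, cranial=cranial,
                            facial=facial,
                            shape={"x": float(a), "y": float(b), "z": float(c)},
                            seed=seed)


def make_sphere_head(radius: float = 90.0, refinement: int = 4) -> SyntheticSubject:
    """A spherical head: the analytic oracle substrate.

    Ground-truth fiducials sit at the axis intersections ``(±r, 0, 0)``,
    ``(0, ±r, 0)`` and ``(0, 0, r)`` (snapped to the faceted surface).
    """
    if radius <= 0:
        raise InvalidInputError("radius must be positive")
    if refinement < 2:
        raise InvalidInputError("refinement must be >= 2")
    zero = [(0.0, 0.0)] * len(FACIAL_ANGLES_24)
    return _build_subject((radius, radius, radius), f"sphere-r{radius:g}", 0,
                          refinement, zero)


def make_ellipsoid_head(axes, refinement: int = 3,
                        subject_id: str | None = None) -> SyntheticSubject:
    """A deterministic ellipsoid head with unperturbed facial points."""
    axes = np.asarray(axes, dtype=float)
    if (axes <= 0).any():
        raise InvalidInputError("semi-axes must be positive")
    zero = [(0.0, 0.0)] * len(FACIAL_ANGLES_24)
    return _build_subject(axes, subject_id or "ellipsoid", 0, refinement, zero)


def sample_population(n_subjects: int, shape_priors: dict | None = None,
                      seed: int = 0, refinement: int = 3,
                      facial_angle_sd: float = DEFAULT_FACIAL_ANGLE_SD
                      ) -> list[SyntheticSubject]:
    """Draw ``n_subjects`` ellipsoid heads from Gaussian semi-axis priors.

    Semi-axes are truncated at ±3 sd to keep every head head-like; facial
    angular positions receive per-subject Gaussian offsets of
    ``facial_angle_sd`` degrees (never the Nz-identity point).
    """
    if n_subjects < 1:
        raise InvalidInputError("n_subjects must be >= 1")
    priors = dict(DEFAULT_SHAPE_PRIORS)
    priors.update(shape_priors or {})
    for k, (mean, sd) in priors.items():
        if mean <= 0 or sd < 0:
            raise InvalidInputError(f"shape prior {k!r} must have positive mean, sd >= 0")
    rng = np.random.default_rng(seed)
    subjects = []
    for i in range(n_subjects):
        axes = [np.clip(rng.normal(m, s), m - 3 * s, m + 3 * s)
                for m, s in (priors["x"], priors["y"], priors["z"])]
        offsets = rng.normal(0.0, facial_angle_sd, size=(len(FACIAL_ANGLES_24), 2))
        offsets[0] = 0.0
        subjects.append(_build_subject(axes, f"subj{i:04d}", seed, refinement,
                                       offsets))
    return subjects


def render_views(subject: SyntheticSubject, views, jitter_sigma: float = 0.0,
                 seed: int = 0, margin: float = 0.1,
                 rng: np.random.Generator | None = None) -> list[ViewRender]:
    """Project a subject into each view's normalized camera frame.

    Per view the head is rigidly rotated, then scaled isotropically so its
    bounding box fits the unit square with a fractional ``margin``; facial
    landmarks receive i.i.d. Gaussian ``jitter_sigma`` (normalized units),
    cranial points stay exact.
    """
    views = list(views)
    if not views:
        raise InvalidInputError("at least one view is required")
    if rng is None:
        rng = np.random.default_rng(seed)
    renders = []
    for view in views:
        R, t = view.rotation, view.translation
        rotated = subject.mesh.vertices @ R.T + t
        bbmin = rotated.min(axis=0)
        extent = float((rotated.max(axis=0) - bbmin).max())
        s = 1.0 / (extent * (1.0 + 2.0 * margin))
        b = -s * bbmin + (margin * extent * s) * np.ones(3) + s * 0.0
        affine = AffineTransform(s * R, s * t + b)
        facial_n = affine.apply(subject.facial.points)
        if jitter_sigma > 0:
            facial_n = facial_n + rng.normal(0.0, jitter_sigma, size=facial_n.shape)
        cranial_n = affine.apply(subject.cranial.as_array())
        renders.append(ViewRender(
            view=view,
            facial=FacialLandmarks(facial_n, convention=subject.facial.convention,
                                   frame="normalized-camera"),
            cranial=CranialLandmarks(*cranial_n, frame="normalized-camera",
                                     method=subject.cranial.method),
            affine=affine,
        ))
    return renders


def build_training_table(subjects, views, ground_truth: dict | None = None,
                         jitter_sigma: float = 0.0, seed: int = 0,
                         subset: SubsetSpec | None = None) -> list[dict]:
    """One training record per (subject, view), JSON-serializable.

    In geometry mode (default) the targets are each view's exact
    normalized-frame cranial truth.  When ``ground_truth`` supplies per-
    target ``(A_c, b_c)`` coefficients (in the flattened-subset space),
    targets are generated exactly from that linear model applied to the
    clean facial row — the identifiability regime.  Jitter lands on the
    facial inputs only, after targets are formed.
    """
    subjects = list(subjects)
    rng = np.random.default_rng(seed)
    if subset is None:
        subset = default_synthetic_subset()
    records = []
    for subject in subjects:
        clean = render_views(subject, views, jitter_sigma=0.0, rng=rng)
        for render in clean:
            if ground_truth is not None:
                row = select_subset(render.facial, subset)
                targets = {c: (row @ A + np.asarray(b, float).reshape(3)).tolist()
                           for c, (A, b) in ground_truth.items()}
            else:
                cr = render.cranial
                targets = {"Iz": cr.iz.tolist(), "LPA": cr.lpa.tolist(),
                           "RPA": cr.rpa.tolist(), "Cz": cr.cz.tolist()}
            pts = render.facial.points
            if jitter_sigma > 0:
                pts = pts + rng.normal(0.0, jitter_sigma, size=pts.shape)
            records.append({
                "subject": subject.subject_id,
                "view": render.view.view_id,
                "convention": subject.facial.convention,
                "facial": pts.tolist(),
                "targets": targets,
            })
    return records
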