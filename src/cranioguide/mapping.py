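"""Face-to-cranial landmark regression.

Two linear pieces make up the mapping machinery:

* a per-view affine frame conversion ``dst = A·src + b`` fitted by least
  squares on a small set of matched facial points, used to move cranial
  reference points between the head-surface millimeter frame and the
  normalized camera frame of each view; and
* the stacked multi-view, multi-subject linear head map: for each target
  fiducial ``c ∈ {Iz, LPA, RPA, Cz}`` an affine regression from the
  flattened coordinates of ``Nf`` selected facial landmarks (a row vector
  of length ``3·Nf``) to the target's 3D position,
  ``p_c = f·A_c + b_c``, solved as three ordinary least-squares problems
  (one per output coordinate) over all subject × view rows.  The
  normal-equations/pseudo-inverse form is the reference semantics; the
  implementation uses a numerically stable LAPACK solve.

The nasion is never regressed: the facial landmark convention designates
one facial point as Nz (point #168, 0-based, in the 468-point camera
convention) and it is copied verbatim into every prediction.

Predictions are affine in landmark *coordinates*, not a rigid-motion
model: translating all facial inputs by ``t`` changes each prediction by
an ``A_c``-dependent amount, not by ``t``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

from .cranial import CranialLandmarks
from .errors import DegeneracyError, InvalidInputError

#: Regression targets; Nz is copied from the facial landmarks instead.
REGRESSED_TARGETS = ("Iz", "LPA", "RPA", "Cz")

#: Facial point index that coincides with the nasion, per convention.
NZ_INDEX = {"camera468": 168, "headmodel68": 27}

_CONVENTION_SIZES = {"camera468": 468, "headmodel68": 68}
_SYNTHETIC_RE = re.compile(r"^synthetic-(\d+)$")


def convention_size(convention: str) -> int:
    if convention in _CONVENTION_SIZES:
        return _CONVENTION_SIZES[convention]
    m = _SYNTHETIC_RE.match(convention)
    if m:
        return int(m.group(1))
    raise InvalidInputError(f"unknown facial landmark convention {convention!r}")


def nz_index(convention: str) -> int:
    """Index of the facial point identified with Nz (0-based)."""
    if convention in NZ_INDEX:
        return NZ_INDEX[convention]
    if _SYNTHETIC_RE.match(convention):
        return 0
    raise InvalidInputError(f"unknown facial landmark convention {convention!r}")


@dataclass(frozen=True)
class FacialLandmarks:
    """Ordered 3D facial points with their source convention and frame."""

    points: np.ndarray
    convention: str = "camera468"
    frame: str = "normalized-camera"

    def __post_init__(self):
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 3:
            raise InvalidInputError("facial points must form an (n, 3) array")
        expected = convention_size(self.convention)
        if len(pts) != expected:
            raise InvalidInputError(
                f"convention {self.convention!r} expects {expected} points, got {len(pts)}"
            )
        if self.frame not in ("head-mm", "normalized-camera"):
            raise InvalidInputError(f"unknown frame {self.frame!r}")
        object.__setattr__(self, "points", pts)

    @property
    def nz(self) -> np.ndarray:
        return self.points[nz_index(self.convention)]

    def validate_frame_bounds(self, slack: float = 0.0) -> None:
        """Check the normalized-frame invariant: x, y within [0, 1]."""
        if self.frame == "normalized-camera":
            xy = self.points[:, :2]
            if (xy < -slack).any() or (xy > 1 + slack).any():
                raise InvalidInputError(
                    "normalized-camera facial landmarks must have x, y in [0, 1]"
                )


@dataclass(frozen=True)
class SubsetSpec:
    """An ordered facial-point subset used as regression input (default Nf=20)."""

    name: str
    convention: str
    indices: tuple[int, ...]

    def __post_init__(self):
        idx = tuple(int(i) for i in self.indices)
        if len(set(idx)) != len(idx):
            raise InvalidInputError("subset indices must be unique")
        n = convention_size(self.convention)
        if any(i < 0 or i >= n for i in idx):
            raise InvalidInputError(f"subset index out of range for {self.convention!r}")
        object.__setattr__(self, "indices", idx)

    @property
    def nf(self) -> int:
        return len(self.indices)

    def to_dict(self) -> dict:
        return {"name": self.name, "convention": self.convention,
                "indices": list(self.indices)}

    @classmethod
    def from_dict(cls, d: dict) -> "SubsetSpec":
        return cls(d["name"], d["convention"], tuple(d["indices"]))


#: Default 20-point subset for the 468-point camera convention: face oval,
#: eye corners, brows, nose bridge/tip/sides, mouth, chin, forehead.
DEFAULT_CAMERA468_SUBSET = SubsetSpec(
    "camera468-default20", "camera468",
    (10, 151, 152, 234, 454, 33, 133, 362, 263, 70, 300,
     1, 4, 98, 327, 61, 291, 13, 14, 168),
)


def default_subset(convention: str) -> SubsetSpec:
    if convention == "camera468":
        return DEFAULT_CAMERA468_SUBSET
    if _SYNTHETIC_RE.match(convention):
        from .synthetic import default_synthetic_subset  # local import: no cycle at module load
        return default_synthetic_subset(convention)
    raise InvalidInputError(f"no default subset for convention {convention!r}")


def select_subset(f: FacialLandmarks, spec: SubsetSpec) -> np.ndarray:
    """Flatten the selected facial points to a row vector of length 3·Nf.

    Coordinates are concatenated as (x, y, z) triplets in subset order.
    """
    if spec.convention != f.convention:
        raise InvalidInputError(
            f"subset is for {spec.convention!r} but landmarks use {f.convention!r}"
        )
    return f.points[list(spec.indices)].reshape(-1)


# ---------------------------------------------------------------------------
# affine frame conversion
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AffineTransform:
    """``y = A·x + b`` on 3D points."""

    A: np.ndarray
    b: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "A", np.asarray(self.A, dtype=float).reshape(3, 3))
        object.__setattr__(self, "b", np.asarray(self.b, dtype=float).reshape(3))

    @classmethod
    def identity(cls) -> "AffineTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, points) -> np.ndarray:
        pts = np.asarray(points, dtype=float)
        return pts @ self.A.T + self.b

    def compose(self, other: "AffineTransform") -> "AffineTransform":
        """``self ∘ other``: apply ``other`` first."""
        return AffineTransform(self.A @ other.A, self.A @ other.b + self.b)

    def inverse(self) -> "AffineTransform":
        det = np.linalg.det(self.A)
        if abs(det) < 1e-300:
            raise DegeneracyError("affine transform is singular and cannot be inverted")
        inv = np.linalg.inv(self.A)
        return AffineTransform(inv, -inv @ self.b)


def fit_view_affine(src, dst) -> AffineTransform:
    """Least-squares affine ``dst ≈ A·src + b`` from matched 3D points.

    Requires at least four non-coplanar source points; exact when an
    affine relation holds.
    """
    src = np.asarray(src, dtype=float)
    dst = np.asarray(dst, dtype=float)
    if src.shape != dst.shape or src.ndim != 2 or src.shape[1] != 3:
        raise InvalidInputError("src and dst must be matched (n, 3) arrays")
    if len(src) < 4:
        raise InvalidInputError("at least 4 point pairs are required")
    centered = src - src.mean(axis=0)
    scale = max(float(np.abs(centered).max()), 1e-300)
    if np.linalg.matrix_rank(centered, tol=1e-9 * scale) < 3:
        raise DegeneracyError("source points are coplanar; affine fit is rank deficient")
    X = np.hstack([src, np.ones((len(src), 1))])
    coef, *_ = np.linalg.lstsq(X, dst, rcond=None)
    return AffineTransform(coef[:3].T, coef[3])


def map_points(transform: AffineTransform, points) -> np.ndarray:
    """Apply an affine frame conversion to a set of 3D points."""
    return transform.apply(points)


# ---------------------------------------------------------------------------
# stacked linear head map
# ---------------------------------------------------------------------------

@dataclass
class LinearHeadMap:
    """Per-target affine regressions from facial rows to cranial points."""

    targets: dict[str, tuple[np.ndarray, np.ndarray]]
    subset: SubsetSpec
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        missing = [c for c in REGRESSED_TARGETS if c not in self.targets]
        if missing:
            raise InvalidInputError(f"head map is missing target(s): {missing}")
        clean = {}
        for c, (A, b) in self.targets.items():
            A = np.asarray(A, dtype=float)
            b = np.asarray(b, dtype=float).reshape(3)
            if A.shape != (3 * self.subset.nf, 3):
                raise InvalidInputError(
                    f"target {c}: coefficient shape {A.shape} does not match "
                    f"subset Nf={self.subset.nf}"
                )
            clean[c] = (A, b)
        self.targets = clean

    def predict_target(self, c: str, row: np.ndarray) -> np.ndarray:
        A, b = self.targets[c]
        return row @ A + b


def fit_linear_headmap(rows, subset: SubsetSpec, ridge: float = 0.0,
                       metadata: dict | None = None) -> LinearHeadMap:
    """Fit the stacked linear head map by least squares.

    ``rows`` maps each target name to a sequence of ``(facial_row, point)``
    pairs, where ``facial_row`` has length 3·Nf.  With ``ridge > 0`` a
    Tikhonov penalty ``ridge·‖A_c‖²`` (intercept unpenalized) guards
    rank-deficient designs; with ``ridge = 0`` a deficiency raises.
    """
    if ridge < 0:
        raise InvalidInputError("ridge must be >= 0")
    p = 3 * subset.nf
    targets = {}
    residuals = {}
    n_rows = None
    for c in REGRESSED_TARGETS:
        if c not in rows:
            raise InvalidInputError(f"no training rows for target {c!r}")
        pairs = list(rows[c])
        if ridge == 0 and len(pairs) < p + 1:
            raise InvalidInputError(
                f"target {c}: {len(pairs)} rows cannot determine {p + 1} coefficients"
            )
        X = np.asarray([np.asarray(r, dtype=float).reshape(-1) for r, _ in pairs])
        Y = np.asarray([np.asarray(t, dtype=float).reshape(3) for _, t in pairs])
        if X.shape[1] != p:
            raise InvalidInputError(
                f"target {c}: facial rows have length {X.shape[1]}, expected {p}"
            )
        Xa = np.hstack([X, np.ones((len(X), 1))])
        if ridge == 0:
            coef, _, rank, _ = np.linalg.lstsq(Xa, Y, rcond=None)
            if rank < p + 1:
                raise DegeneracyError(
                    f"target {c}: design matrix rank {rank} < {p + 1}; "
                    "add rows, reduce the subset, or set ridge > 0"
                )
        else:
            penalty = np.diag(np.concatenate([np.full(p, ridge), [0.0]]))
            coef = np.linalg.solve(Xa.T @ Xa + penalty, Xa.T @ Y)
        targets[c] = (coef[:p], coef[p])
        res = Xa @ coef - Y
        residuals[c] = {
            "rms_mm": float(np.sqrt(np.mean(np.sum(res**2, axis=1)))),
            "max_mm": float(np.sqrt(np.sum(res**2, axis=1)).max()) if len(res) else 0.0,
        }
        n_rows = len(pairs)
    meta = {"n_rows": n_rows, "ridge": ridge, "residuals": residuals}
    meta.update(metadata or {})
    return LinearHeadMap(targets=targets, subset=subset, metadata=meta)


def training_rows_from_records(records, subset: SubsetSpec) -> dict:
    """Convert JSON-style training records into per-target row pairs.

    Each record carries ``facial`` (full landmark list in the subset's
    convention) and ``targets`` (name → 3D point).
    """
    rows = {c: [] for c in REGRESSED_TARGETS}
    for rec in records:
        f = FacialLandmarks(np.asarray(rec["facial"], dtype=float),
                            convention=rec.get("convention", subset.convention))
        vec = select_subset(f, subset)
        for c in REGRESSED_TARGETS:
            rows[c].append((vec, np.asarray(rec["targets"][c], dtype=float)))
    return rows


def predict_cranial(hmap: LinearHeadMap, f: FacialLandmarks) -> CranialLandmarks:
    """Predict the five cranial fiducials from one facial-landmark frame.

    Iz/LPA/RPA/Cz come from the fitted regressions; Nz is the designated
    facial point copied verbatim.  The result lives in the facial frame.
    """
    if f.convention != hmap.subset.convention:
        raise InvalidInputError(
            f"map was trained on {hmap.subset.convention!r} landmarks, "
            f"got {f.convention!r}"
        )
    row = select_subset(f, hmap.subset)
    preds = {c: hmap.predict_target(c, row) for c in REGRESSED_TARGETS}
    return CranialLandmarks(f.nz, preds["Iz"], preds["LPA"], preds["RPA"],
                            preds["Cz"], frame=f.frame, method="three-point")
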