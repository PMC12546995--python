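"""Cranial fiducial construction on a head surface.

Given the nasion (Nz) and the two preauricular points (LPA/RPA) on a
triangulated scalp, the inion (Iz) and vertex (Cz) are constructed
geometrically under the three-point assumption that Nz, Iz, LPA and RPA
share a plane:

* **Iz** is the far intersection of the scalp with the ray from Nz through
  the LPA–RPA midpoint — coplanar with the three inputs by construction.
* **Cz** is the far scalp intersection of the ray cast from the LPA–RPA
  midpoint along the normal of the fiducial plane, taken as
  ``cross(Iz − Nz, RPA − LPA)``, oriented toward the side whose hit lies
  farther from the plane (the superior side on any head-like surface).

The vector normal to the fiducial plane is necessarily a cross product of
the two in-plane axes; a scalar product of those axes carries no
directional information, so the cross product is the only construction
that yields the superior axis described above.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .errors import InvalidInputError, RayMissError
from .geometry import closest_point_on_mesh, ray_mesh_intersect

FIDUCIAL_NAMES = ("Nz", "Iz", "LPA", "RPA", "Cz")

#: Coplanarity tolerance (mm) for three-point fiducial sets.
COPLANAR_TOL = 1e-6


@dataclass(frozen=True)
class CranialLandmarks:
    """The five cranial reference points with an explicit coordinate frame.

    ``frame`` is ``"head-mm"`` (surface coordinates, millimeters) or
    ``"normalized-camera"`` (detector frame, x/y in [0, 1]).  ``method``
    records whether Iz was derived under the coplanarity assumption
    (``"three-point"``) or supplied independently (``"five-point"``).
    """

    nz: np.ndarray
    iz: np.ndarray
    lpa: np.ndarray
    rpa: np.ndarray
    cz: np.ndarray
    frame: str = "head-mm"
    method: str = "three-point"

    def __post_init__(self):
        for name in ("nz", "iz", "lpa", "rpa", "cz"):
            v = np.asarray(getattr(self, name), dtype=float).reshape(3)
            object.__setattr__(self, name, v)
        if self.frame not in ("head-mm", "normalized-camera"):
            raise InvalidInputError(f"unknown frame {self.frame!r}")
        if self.method not in ("three-point", "five-point"):
            raise InvalidInputError(f"unknown method {self.method!r}")

    def as_array(self) -> np.ndarray:
        """(5, 3) array in the canonical order Nz, Iz, LPA, RPA, Cz."""
        return np.vstack([self.nz, self.iz, self.lpa, self.rpa, self.cz])

    def as_dict(self) -> dict:
        return dict(zip(FIDUCIAL_NAMES, (p.tolist() for p in self.as_array())))

    @classmethod
    def from_dict(cls, points: dict, frame: str = "head-mm",
                  method: str = "three-point") -> "CranialLandmarks":
        missing = [n for n in FIDUCIAL_NAMES if n not in points]
        if missing:
            raise InvalidInputError(f"missing cranial landmark(s): {missing}")
        return cls(points["Nz"], points["Iz"], points["LPA"], points["RPA"],
                   points["Cz"], frame=frame, method=method)

    def with_frame(self, frame: str) -> "CranialLandmarks":
        return replace(self, frame=frame)

    def coplanarity_residual(self) -> float:
        """Max |signed distance| of Nz/Iz/LPA/RPA from their best-fit plane."""
        return coplanarity_residual(np.vstack([self.nz, self.iz, self.lpa, self.rpa]))


def coplanarity_residual(points: np.ndarray) -> float:
    """Maximum distance of ``points`` from their least-squares plane (mm)."""
    pts = np.asarray(points, dtype=float)
    centered = pts - pts.mean(axis=0)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    return float(np.abs(centered @ vt[-1]).max())


def estimate_iz(mesh, nz, lpa, rpa) -> np.ndarray:
    """Inion: far scalp intersection of the ray from Nz through midpoint(LPA, RPA)."""
    nz = np.asarray(nz, dtype=float)
    mid = (np.asarray(lpa, dtype=float) + np.asarray(rpa, dtype=float)) / 2.0
    direction = mid - nz
    scale = max(float(np.abs(mesh.vertices).max()), 1.0)
    if np.linalg.norm(direction) <= 1e-12 * scale:
        raise InvalidInputError("Nz coincides with the LPA/RPA midpoint")
    return ray_mesh_intersect(mesh, nz, direction, select="farthest")


def estimate_cz(mesh, nz, iz, lpa, rpa, origin: str = "ear-midpoint") -> np.ndarray:
    """Vertex: scalp intersection along the fiducial-plane normal.

    ``origin`` selects the ray origin within the fiducial plane:
    ``"ear-midpoint"`` (LPA/RPA midpoint, default), ``"nasion-inion-midpoint"``,
    or ``"plane-centroid"`` (mean of the four fiducials).  Of the two normal
    orientations, the hit farther from the fiducial plane is kept; on a tie
    the ``cross(Iz − Nz, RPA − LPA)`` direction wins.
    """
    nz, iz = np.asarray(nz, float), np.asarray(iz, float)
    lpa, rpa = np.asarray(lpa, float), np.asarray(rpa, float)
    axis_ap = iz - nz
    axis_lr = rpa - lpa
    normal = np.cross(axis_ap, axis_lr)
    scale = max(float(np.abs(mesh.vertices).max()), 1.0)
    if (np.linalg.norm(axis_ap) <= 1e-12 * scale or np.linalg.norm(axis_lr) <= 1e-12 * scale
            or np.linalg.norm(normal) <= 1e-12 * scale**2):
        raise InvalidInputError("Nz→Iz and LPA→RPA must be nonzero and non-parallel")
    normal = normal / np.linalg.norm(normal)
    if origin == "ear-midpoint":
        o = (lpa + rpa) / 2.0
    elif origin == "nasion-inion-midpoint":
        o = (nz + iz) / 2.0
    elif origin == "plane-centroid":
        o = (nz + iz + lpa + rpa) / 4.0
    else:
        raise InvalidInputError(f"unknown Cz ray origin {origin!r}")

    hits = []
    for sign in (+1.0, -1.0):
        try:
            p = ray_mesh_intersect(mesh, o, sign * normal, select="farthest")
        except RayMissError:
            continue
        hits.append((abs(float((p - o) @ normal)), sign, p))
    if not hits:
        raise RayMissError("neither plane-normal orientation intersects the surface")
    # farther-from-plane hit wins; ties (within 1e-9·scale) prefer +normal
    hits.sort(key=lambda h: (-h[0], -h[1]))
    if len(hits) == 2 and abs(hits[0][0] - hits[1][0]) <= 1e-9 * scale:
        return next(h[2] for h in hits if h[1] > 0)
    return hits[0][2]


def build_cranial_set(mesh, nz, lpa, rpa, method: str = "three-point",
                      cz_override=None, iz_override=None,
                      on_mesh_tol: float = 1.0,
                      cz_origin: str = "ear-midpoint") -> CranialLandmarks:
    """Assemble the five-point cranial set from Nz/LPA/RPA.

    ``three-point``: Iz and Cz are constructed geometrically (overrides are
    rejected).  ``five-point``: overrides are used verbatim when given
    (checked to lie within ``on_mesh_tol`` mm of the surface) and
    constructed otherwise.
    """
    if method not in ("three-point", "five-point"):
        raise InvalidInputError(f"unknown method {method!r}")
    if method == "three-point" and (cz_override is not None or iz_override is not None):
        raise InvalidInputError("three-point method constructs Iz/Cz; overrides not allowed")
    for name, p in (("Iz", iz_override), ("Cz", cz_override)):
        if p is not None:
            _, dist = closest_point_on_mesh(mesh, [np.asarray(p, float)])
            if dist[0] > on_mesh_tol:
                raise InvalidInputError(
                    f"{name} override is {dist[0]:.3g} mm off the mesh (tol {on_mesh_tol} mm)"
                )
    iz = np.asarray(iz_override, float) if iz_override is not None \
        else estimate_iz(mesh, nz, lpa, rpa)
    cz = np.asarray(cz_override, float) if cz_override is not None \
        else estimate_cz(mesh, nz, iz, lpa, rpa, origin=cz_origin)
    return CranialLandmarks(nz, iz, lpa, rpa, cz, frame="head-mm", method=method)
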