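"""Geometric primitives on triangular head-surface meshes.

All head-frame coordinates are right-handed millimeters.  Meshes are held
as :class:`trimesh.Trimesh` objects and need not be watertight; plane cuts
are assumed to yield a single relevant contour (heads are near-convex) and
an explicit error is raised otherwise.

The ray-casting and closest-point kernels here are brute-force and
vectorized over all faces; head meshes in this package are small (a few
tens of thousands of triangles at most), for which an acceleration
structure buys nothing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import trimesh

from .errors import ContourError, InvalidInputError, RayMissError

#: Duplicate vertices closer than this (mm) are merged when stitching contours.
MERGE_TOL = 1e-9

#: Minimum ray parameter (mm) accepted as a hit, rejecting self-hits when the
#: ray origin itself lies on the surface (e.g. a ray cast from Nz).
RAY_MIN_T = 1e-9


def as_mesh(vertices, faces) -> trimesh.Trimesh:
    """Build a validated triangular mesh from raw arrays.

    Raises
    ------
    InvalidInputError
        If a face index is out of range or a face is degenerate
        (repeated vertices or near-zero area).
    """
    vertices = np.asarray(vertices, dtype=float)
    faces = np.asarray(faces, dtype=np.int64)
    if vertices.ndim != 2 or vertices.shape[1] != 3:
        raise InvalidInputError("vertices must be an (n, 3) array")
    if faces.ndim != 2 or faces.shape[1] != 3:
        raise InvalidInputError("faces must be an (m, 3) array")
    if faces.size and (faces.min() < 0 or faces.max() >= len(vertices)):
        bad = int(np.argmax((faces < 0).any(axis=1) | (faces >= len(vertices)).any(axis=1)))
        raise InvalidInputError(f"face {bad} references a vertex outside [0, {len(vertices)})")
    same = (
        (faces[:, 0] == faces[:, 1]) | (faces[:, 1] == faces[:, 2]) | (faces[:, 0] == faces[:, 2])
    )
    if same.any():
        raise InvalidInputError(f"face {int(np.argmax(same))} repeats a vertex")
    tri = vertices[faces]
    area2 = np.linalg.norm(np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0]), axis=1)
    scale = max(float(np.abs(vertices).max()), 1.0)
    if (area2 < 1e-12 * scale**2).any():
        raise InvalidInputError(f"face {int(np.argmax(area2 < 1e-12 * scale**2))} has ~zero area")
    return trimesh.Trimesh(vertices=vertices, faces=faces, process=False)


def mesh_edge_length(mesh: trimesh.Trimesh, which: str = "max") -> float:
    """Characteristic edge length of a mesh (``max`` or ``mean``)."""
    lengths = mesh.edges_unique_length
    return float(lengths.max() if which == "max" else lengths.mean())


@dataclass(frozen=True)
class PolylineArc:
    """An ordered 3D polyline with cumulative arc length.

    ``closed`` arcs store each vertex once; the closing segment from the
    last point back to the first contributes to :attr:`length` but carries
    no stored vertex.
    """

    points: np.ndarray
    closed: bool = False
    cumlen: np.ndarray = field(init=False, repr=False)

    def __post_init__(self):
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 3 or len(pts) < 2:
            raise InvalidInputError("a polyline needs at least two 3D points")
        seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        if (seg <= MERGE_TOL).any():
            raise InvalidInputError("consecutive polyline points must be distinct")
        object.__setattr__(self, "points", pts)
        object.__setattr__(self, "cumlen", np.concatenate([[0.0], np.cumsum(seg)]))

    @property
    def length(self) -> float:
        total = float(self.cumlen[-1])
        if self.closed:
            total += float(np.linalg.norm(self.points[0] - self.points[-1]))
        return total

    def reversed(self) -> "PolylineArc":
        return PolylineArc(self.points[::-1].copy(), closed=self.closed)

    # -- parametrization by arc length -----------------------------------
    def point_at(self, s: float) -> np.ndarray:
        """Point at arc-length position ``s`` (wrapping if closed)."""
        L = self.length
        if self.closed:
            s = s % L
            cum = np.concatenate([self.cumlen, [L]])
            pts = np.vstack([self.points, self.points[:1]])
        else:
            s = min(max(s, 0.0), L)
            cum, pts = self.cumlen, self.points
        i = int(np.searchsorted(cum, s, side="right")) - 1
        i = min(max(i, 0), len(pts) - 2)
        seg = cum[i + 1] - cum[i]
        t = 0.0 if seg == 0 else (s - cum[i]) / seg
        return (1 - t) * pts[i] + t * pts[i + 1]

    def locate(self, q) -> tuple[float, np.ndarray, float]:
        """Project ``q`` onto the polyline.

        Returns ``(s, point, distance)``: arc-length position of the
        closest point, the closest point itself, and the distance to it.
        """
        q = np.asarray(q, dtype=float)
        if self.closed:
            a = np.vstack([self.points, self.points[:1]])[:-1]
            b = np.vstack([self.points[1:], self.points[:1]])
            cum = np.concatenate([self.cumlen, [self.length]])[:-1]
        else:
            a, b = self.points[:-1], self.points[1:]
            cum = self.cumlen[:-1]
        d = b - a
        seg2 = np.einsum("ij,ij->i", d, d)
        t = np.clip(np.einsum("ij,ij->i", q - a, d) / seg2, 0.0, 1.0)
        proj = a + t[:, None] * d
        dist = np.linalg.norm(proj - q, axis=1)
        k = int(np.argmin(dist))
        s = float(cum[k] + t[k] * np.sqrt(seg2[k]))
        return s, proj[k], float(dist[k])


# ---------------------------------------------------------------------------
# ray casting
# ---------------------------------------------------------------------------

def ray_mesh_intersect(mesh, origin, direction, select: str = "farthest",
                       min_t: float = RAY_MIN_T) -> np.ndarray:
    """Intersect a ray with the mesh and return the nearest or farthest hit.

    Möller–Trumbore over all faces.  Hits with ray parameter ``t <= min_t``
    are rejected so that rays originating on the surface do not return
    their own origin.

    Raises
    ------
    InvalidInputError
        For a zero direction, empty mesh, or unknown ``select``.
    RayMissError
        If no face is hit.
    """
    if select not in ("nearest", "farthest"):
        raise InvalidInputError(f"select must be 'nearest' or 'farthest', got {select!r}")
    origin = np.asarray(origin, dtype=float)
    direction = np.asarray(direction, dtype=float)
    norm = np.linalg.norm(direction)
    if norm == 0:
        raise InvalidInputError("ray direction has zero norm")
    if len(mesh.faces) == 0:
        raise InvalidInputError("mesh has no faces")
    d = direction / norm

    tri = mesh.triangles
    v0 = tri[:, 0]
    e1 = tri[:, 1] - v0
    e2 = tri[:, 2] - v0
    h = np.cross(d[None, :], e2)
    a = np.einsum("ij,ij->i", e1, h)
    scale = max(float(np.abs(mesh.vertices).max()), 1.0)
    ok = np.abs(a) > 1e-14 * scale * scale
    with np.errstate(divide="ignore", invalid="ignore"):
        f = np.where(ok, 1.0 / a, 0.0)
        s = origin[None, :] - v0
        u = f * np.einsum("ij,ij->i", s, h)
        q = np.cross(s, e1)
        v = f * (q @ d)
        t = f * np.einsum("ij,ij->i", e2, q)
    eps = 1e-9
    hit = ok & (u >= -eps) & (v >= -eps) & (u + v <= 1 + eps) & (t > min_t)
    if not hit.any():
        raise RayMissError("ray misses surface")
    t_hit = t[hit]
    t_sel = t_hit.min() if select == "nearest" else t_hit.max()
    return origin + t_sel * d


# ---------------------------------------------------------------------------
# closest point on mesh
# ---------------------------------------------------------------------------

def closest_point_on_mesh(mesh, points) -> tuple[np.ndarray, np.ndarray]:
    """Closest surface points and distances for query ``points``.

    Standard point-triangle projection (Ericson), vectorized over every
    (point, face) pair; intended for small meshes and few query points.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    tri = mesh.triangles
    a, b, c = tri[:, 0][None], tri[:, 1][None], tri[:, 2][None]
    p = points[:, None, :]
    ab, ac, ap = b - a, c - a, p - a
    d1 = np.einsum("pfk,pfk->pf", ab, ap)
    d2 = np.einsum("pfk,pfk->pf", ac, ap)
    bp = p - b
    d3 = np.einsum("pfk,pfk->pf", ab, bp)
    d4 = np.einsum("pfk,pfk->pf", ac, bp)
    cp = p - c
    d5 = np.einsum("pfk,pfk->pf", ab, cp)
    d6 = np.einsum("pfk,pfk->pf", ac, cp)

    va = d3 * d6 - d5 * d4
    vb = d5 * d2 - d1 * d6
    vc = d1 * d4 - d3 * d2
    denom = va + vb + vc
    with np.errstate(divide="ignore", invalid="ignore"):
        v = np.where(denom != 0, vb / denom, 0.0)
        w = np.where(denom != 0, vc / denom, 0.0)
    cand = a + v[..., None] * ab + w[..., None] * ac  # interior projection

    # edge/vertex regions override the interior candidate
    with np.errstate(divide="ignore", invalid="ignore"):
        t_ab = np.clip(np.where(d1 - d3 != 0, d1 / (d1 - d3), 0.0), 0, 1)
        t_ac = np.clip(np.where(d2 - d6 != 0, d2 / (d2 - d6), 0.0), 0, 1)
        t_bc = np.clip(
            np.where((d4 - d3) + (d5 - d6) != 0, (d4 - d3) / ((d4 - d3) + (d5 - d6)), 0.0), 0, 1
        )
    on_ab = a + t_ab[..., None] * ab
    on_ac = a + t_ac[..., None] * ac
    on_bc = b + t_bc[..., None] * (c - b)

    cand = np.where((vc <= 0)[..., None] & (d1 >= 0)[..., None] & (d3 <= 0)[..., None], on_ab, cand)
    cand = np.where((vb <= 0)[..., None] & (d2 >= 0)[..., None] & (d6 <= 0)[..., None], on_ac, cand)
    cand = np.where(
        (va <= 0)[..., None] & ((d4 - d3) >= 0)[..., None] & ((d5 - d6) >= 0)[..., None], on_bc, cand
    )
    cand = np.where((d1 <= 0)[..., None] & (d2 <= 0)[..., None], a, cand)
    cand = np.where((d3 >= 0)[..., None] & (d4 <= d3)[..., None], b, cand)
    cand = np.where((d6 >= 0)[..., None] & (d5 <= d6)[..., None], c, cand)

    dist = np.linalg.norm(cand - p, axis=2)
    k = np.argmin(dist, axis=1)
    rows = np.arange(len(points))
    return cand[rows, k], dist[rows, k]


# ---------------------------------------------------------------------------
# plane cuts and arcs
# ---------------------------------------------------------------------------

def plane_mesh_contour(mesh, plane_point, plane_normal, anchor,
                       anchor_tol: float | None = None) -> PolylineArc:
    """Cut the mesh with a plane and return the contour nearest ``anchor``.

    Of all connected intersection components, the one with the smallest
    distance to ``anchor`` is returned (ties broken by larger total
    length).  ``anchor_tol`` defaults to 10% of the mesh bounding-box
    diagonal.
    """
    plane_normal = np.asarray(plane_normal, dtype=float)
    if np.linalg.norm(plane_normal) == 0:
        raise InvalidInputError("plane normal has zero norm")
    section = mesh.section(plane_origin=np.asarray(plane_point, float),
                           plane_normal=plane_normal / np.linalg.norm(plane_normal))
    if section is None:
        raise ContourError("plane misses mesh")
    arcs = []
    for curve in section.discrete:
        pts = np.asarray(curve, dtype=float)
        closed = len(pts) > 3 and np.linalg.norm(pts[0] - pts[-1]) <= MERGE_TOL
        if closed:
            pts = pts[:-1]
        keep = np.concatenate(
            [[True], np.linalg.norm(np.diff(pts, axis=0), axis=1) > MERGE_TOL]
        )
        pts = pts[keep]
        if len(pts) >= 2:
            arcs.append(PolylineArc(pts, closed=closed))
    if not arcs:
        raise ContourError("plane misses mesh")
    anchor = np.asarray(anchor, dtype=float)
    dists = [arc.locate(anchor)[2] for arc in arcs]
    best = min(range(len(arcs)), key=lambda i: (dists[i], -arcs[i].length))
    if anchor_tol is None:
        anchor_tol = 0.1 * float(np.linalg.norm(mesh.bounds[1] - mesh.bounds[0]))
    if dists[best] > anchor_tol:
        raise ContourError(
            f"anchor is {dists[best]:.3g} mm from the nearest contour (tol {anchor_tol:.3g})"
        )
    return arcs[best]


def _slice_closed(contour: PolylineArc, s0: float, s1: float) -> np.ndarray:
    """Vertices of the forward (increasing-s) sub-arc of a closed contour."""
    L = contour.length
    s0, s1 = s0 % L, s1 % L
    p0, p1 = contour.point_at(s0), contour.point_at(s1)
    span = (s1 - s0) % L
    # collect interior vertex positions walking forward from s0
    verts = [p0]
    vertex_s = contour.cumlen
    order = np.argsort((vertex_s - s0) % L)
    for idx in order:
        ds = (vertex_s[idx] - s0) % L
        if MERGE_TOL < ds < span - MERGE_TOL:
            verts.append(contour.points[idx])
    verts.append(p1)
    out = [verts[0]]
    for v in verts[1:]:
        if np.linalg.norm(v - out[-1]) > MERGE_TOL:
            out.append(v)
    return np.asarray(out)


def arc_between(contour: PolylineArc, start, via, end,
                tol: float | None = None) -> PolylineArc:
    """Open sub-arc of ``contour`` from ``start`` to ``end`` passing ``via``.

    ``start``/``via``/``end`` are projected onto the contour; the traversal
    direction is the one whose sub-arc passes nearest ``via``.  ``tol``
    bounds how far the three points may sit from the contour (default: 5%
    of contour length).
    """
    if tol is None:
        tol = 0.05 * contour.length
    s_a, p_a, d_a = contour.locate(start)
    s_v, p_v, d_v = contour.locate(via)
    s_b, p_b, d_b = contour.locate(end)
    for name, d in (("start", d_a), ("via", d_v), ("end", d_b)):
        if d > tol:
            raise ContourError(f"{name} point is {d:.3g} mm off the contour (tol {tol:.3g})")
    if np.linalg.norm(p_a - p_b) <= MERGE_TOL:
        raise InvalidInputError("start and end coincide on the contour (zero-length arc)")

    if contour.closed:
        L = contour.length
        fwd_span = (s_b - s_a) % L
        on_fwd = (s_v - s_a) % L <= fwd_span + MERGE_TOL
        if on_fwd:
            pts = _slice_closed(contour, s_a, s_b)
        else:
            pts = _slice_closed(contour, s_b, s_a)[::-1]
        return PolylineArc(pts, closed=False)

    lo, hi = min(s_a, s_b), max(s_a, s_b)
    if not (lo - MERGE_TOL <= s_v <= hi + MERGE_TOL):
        raise ContourError("via point does not lie between start and end on the contour")
    cum = contour.cumlen
    inner = contour.points[(cum > lo + MERGE_TOL) & (cum < hi - MERGE_TOL)]
    pts = [contour.point_at(lo)] + list(inner) + [contour.point_at(hi)]
    out = [pts[0]]
    for v in pts[1:]:
        if np.linalg.norm(v - out[-1]) > MERGE_TOL:
            out.append(v)
    arc = PolylineArc(np.asarray(out), closed=False)
    return arc if s_a <= s_b else arc.reversed()


def subdivide_arc(arc: PolylineArc, fractions) -> np.ndarray:
    """Points at cumulative arc-length ``fractions`` of ``arc``.

    Fractions must lie in [0, 1]; 0 and 1 map to the exact endpoints of an
    open arc (for a closed arc, 1 wraps to the start).  An empty fraction
    list yields an empty array.
    """
    fractions = np.asarray(list(fractions), dtype=float)
    if fractions.size == 0:
        return np.empty((0, 3))
    if (fractions < 0).any() or (fractions > 1).any():
        raise InvalidInputError("fractions must lie within [0, 1]")
    if arc.length <= 0:
        raise InvalidInputError("arc has zero length")
    out = np.empty((len(fractions), 3))
    for i, f in enumerate(fractions):
        if not arc.closed and f == 0.0:
            out[i] = arc.points[0]
        elif not arc.closed and f == 1.0:
            out[i] = arc.points[-1]
        else:
            out[i] = arc.point_at(f * arc.length)
    return out


def rotate_closed(contour: PolylineArc, anchor, orient_toward=None) -> PolylineArc:
    """Re-seam a closed contour to start at the projection of ``anchor``.

    If ``orient_toward`` is given, the traversal direction is flipped when
    needed so that the arc-length position of ``orient_toward`` falls in
    the first half of the loop.
    """
    if not contour.closed:
        raise InvalidInputError("rotate_closed requires a closed contour")
    s0, p0, _ = contour.locate(anchor)
    pts = _slice_closed(contour, s0, s0 - MERGE_TOL * 2)  # full loop from p0
    arc = PolylineArc(pts[:-1] if np.linalg.norm(pts[0] - pts[-1]) <= MERGE_TOL else pts,
                      closed=True)
    if orient_toward is not None:
        s_t, _, _ = arc.locate(orient_toward)
        if s_t > arc.length / 2:
            rev = arc.points[::-1]
            arc = PolylineArc(np.vstack([arc.points[:1], rev[:-1]]), closed=True)
    return arc
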