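"""10-20 / 10-10 / 10-5 head-landmark layouts on a triangular scalp.

The construction follows the extended 10-5 convention:

1. **Sagittal arc** — the scalp is cut by the plane through Nz, Cz and Iz;
   the open arc from Nz over Cz to Iz is subdivided at the catalogue's
   cumulative arc-length fractions (10% steps for 10-20 down to 5% steps
   for 10-5).  The 50% point *redefines Cz*: the incoming geometric Cz
   only seeds the cutting plane, because the convention defines the vertex
   by arc fractions.
2. **Coronal medial arc** — the plane through LPA, the redefined Cz and
   RPA gives the T7…C3…Cz…C4…T8 line at the same fractions.
3. **Circumferential ring** — the least-squares plane through the four
   10%-level anchors (Fpz, T7, Oz, T8) cuts a closed ring, re-seamed at
   Fpz and oriented toward T7 (the left side); lateral labels sit at fixed
   fractions of the ring circumference (odd numbers left, even right).
4. **Intermediate arcs** — e.g. F7–Fz–F8: the plane through the three
   anchors cuts an arc subdivided at quarter (10-20) or eighth (10-10)
   fractions.

The label/fraction catalogue is an editable JSON data table shipped with
the package; anterior/posterior region tags live there too, with labels on
the coronal medial line tagged ``both``.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from importlib import resources

import numpy as np

from .cranial import CranialLandmarks
from .errors import InvalidInputError, LayoutError
from .geometry import arc_between, plane_mesh_contour, rotate_closed, subdivide_arc

log = logging.getLogger(__name__)

DENSITIES = ("10-20", "10-10", "10-5")
_DENSITY_RANK = {d: i for i, d in enumerate(DENSITIES)}


def load_catalogue() -> dict:
    """The shipped label table: arcs and (label, arc, fraction, region, density)."""
    with resources.files("cranioguide.data").joinpath("ten_twenty_catalogue.json").open() as fh:
        return json.load(fh)


_CATALOGUE = None


def _catalogue() -> dict:
    global _CATALOGUE
    if _CATALOGUE is None:
        _CATALOGUE = load_catalogue()
    return _CATALOGUE


def catalogue_labels(density: str, catalogue: dict | None = None) -> list[dict]:
    """Catalogue rows included at ``density`` (densities are nested)."""
    if density not in _DENSITY_RANK:
        raise InvalidInputError(f"unknown density {density!r}")
    cat = catalogue or _catalogue()
    rank = _DENSITY_RANK[density]
    return [row for row in cat["labels"] if _DENSITY_RANK[row["min_density"]] <= rank]


@dataclass
class TenTwentyLayout:
    """Labeled scalp positions at one density, with region tags."""

    density: str
    entries: dict[str, np.ndarray]
    region: dict[str, str] = field(default_factory=dict)
    source: str = "subject"

    def __post_init__(self):
        if self.density not in DENSITIES:
            raise InvalidInputError(f"unknown density {self.density!r}")
        if self.source not in ("atlas", "subject", "predicted"):
            raise InvalidInputError(f"unknown layout source {self.source!r}")
        self.entries = {k: np.asarray(v, dtype=float).reshape(3)
                        for k, v in self.entries.items()}

    @property
    def labels(self) -> list[str]:
        return list(self.entries)

    def as_array(self, labels=None) -> np.ndarray:
        labels = list(labels) if labels is not None else self.labels
        return np.vstack([self.entries[l] for l in labels]) if labels else np.empty((0, 3))

    def with_entries(self, entries, source=None) -> "TenTwentyLayout":
        return TenTwentyLayout(self.density, dict(entries), dict(self.region),
                               source or self.source)


def _cut_arc(mesh, p1, p2, p3, name: str):
    """Open arc p1→p2→p3 along the plane through the three points."""
    normal = np.cross(np.asarray(p2, float) - p1, np.asarray(p3, float) - p1)
    if np.linalg.norm(normal) == 0:
        raise LayoutError(f"{name} arc: anchor points are collinear")
    try:
        contour = plane_mesh_contour(mesh, p1, normal, anchor=p2)
        return arc_between(contour, p1, p2, p3)
    except Exception as exc:  # noqa: BLE001 - re-raise naming the arc
        raise LayoutError(f"{name} arc construction failed: {exc}") from exc


def compute_layout(mesh, cranial: CranialLandmarks, density: str = "10-20",
                   catalogue: dict | None = None,
                   source: str = "subject") -> TenTwentyLayout:
    """Construct the labeled layout for ``density`` on ``mesh``.

    ``cranial`` must be in the head-mm frame with its five points on or
    near the mesh.
    """
    if cranial.frame != "head-mm":
        raise InvalidInputError("layout construction requires head-mm cranial landmarks")
    pts = cranial.as_array()
    for i in range(5):
        for j in range(i + 1, 5):
            if np.linalg.norm(pts[i] - pts[j]) <= 1e-9:
                raise InvalidInputError("cranial points must be pairwise distinct")
    cat = catalogue or _catalogue()
    rows = catalogue_labels(density, cat)
    by_arc: dict[str, list[dict]] = {}
    for row in rows:
        by_arc.setdefault(row["arc"], []).append(row)

    entries: dict[str, np.ndarray] = {}
    region: dict[str, str] = {}

    def place(arc, arc_rows):
        fracs = [r["fraction"] for r in arc_rows]
        pts = subdivide_arc(arc, fracs)
        for r, p in zip(arc_rows, pts):
            entries[r["label"]] = p
            region[r["label"]] = r["region"]

    # 1. sagittal arc and the fraction-defined Cz
    sag = _cut_arc(mesh, cranial.nz, cranial.cz, cranial.iz, "sagittal")
    sag_rows = by_arc.get("sagittal", [])
    place(sag, sag_rows)
    cz = subdivide_arc(sag, [0.5])[0]
    entries["Cz"] = cz
    region["Cz"] = "both"
    drift = float(np.linalg.norm(cz - cranial.cz))
    log.debug("Cz redefined at the 50%% sagittal point; moved %.3g mm from the seed", drift)

    # 2. coronal medial arc through the redefined Cz
    coronal = _cut_arc(mesh, cranial.lpa, cz, cranial.rpa, "coronal")
    place(coronal, by_arc.get("coronal", []))

    # 3. circumferential ring through the 10%-level anchors
    ring_rows = by_arc.get("ring", [])
    if ring_rows:
        t7 = subdivide_arc(coronal, [0.10])[0]
        t8 = subdivide_arc(coronal, [0.90])[0]
        fpz = subdivide_arc(sag, [0.10])[0]
        oz = subdivide_arc(sag, [0.90])[0]
        anchors = np.vstack([fpz, t7, oz, t8])
        centroid = anchors.mean(axis=0)
        _, _, vt = np.linalg.svd(anchors - centroid, full_matrices=False)
        try:
            ring_contour = plane_mesh_contour(mesh, centroid, vt[-1], anchor=fpz)
            if not ring_contour.closed:
                raise LayoutError("ring contour is not a closed loop")
            ring = rotate_closed(ring_contour, fpz, orient_toward=t7)
        except LayoutError:
            raise
        except Exception as exc:  # noqa: BLE001
            raise LayoutError(f"ring arc construction failed: {exc}") from exc
        place(ring, ring_rows)

    # 4. intermediate arcs between ring and midline anchors
    for arc_name, (left, mid, right) in cat["arcs"].items():
        arc_rows = by_arc.get(arc_name, [])
        if not arc_rows:
            continue
        for anchor in (left, mid, right):
            if anchor not in entries:
                raise LayoutError(
                    f"{arc_name} arc: anchor {anchor!r} missing at density {density}"
                )
        arc = _cut_arc(mesh, entries[left], entries[mid], entries[right], arc_name)
        place(arc, arc_rows)

    return TenTwentyLayout(density=density, entries=entries, region=region, source=source)


def region_partition(layout: TenTwentyLayout,
                     catalogue: dict | None = None) -> TenTwentyLayout:
    """Return the layout with anterior/posterior/both tags from the catalogue.

    Anterior spans the coronal medial line to Nz, posterior spans it to Iz,
    and medial-line labels belong to both regions.  Unknown labels raise.
    """
    cat = catalogue or _catalogue()
    table = {row["label"]: row["region"] for row in cat["labels"]}
    region = {}
    for label in layout.entries:
        if label not in table:
            raise InvalidInputError(f"label {label!r} is not in the layout catalogue")
        region[label] = table[label]
    return TenTwentyLayout(layout.density, dict(layout.entries), region, layout.source)


def region_labels(layout: TenTwentyLayout) -> dict[str, list[str]]:
    """Group a tagged layout's labels by region (``both`` appears in both)."""
    groups = {"anterior": [], "posterior": [], "both": []}
    for label, tag in layout.region.items():
        if tag not in groups:
            raise InvalidInputError(f"label {label!r} has unknown region tag {tag!r}")
        groups[tag].append(label)
    return groups
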