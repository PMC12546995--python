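"""File formats: meshes, landmark sets, layouts, fitted maps, streams.

JSON documents are versioned with a ``format`` field and written with
sorted keys for diff-stability.  Facial-point indexing is 0-based
everywhere (the camera convention's nasion point is index 168; beware
that 1-based tool chains would call the same point #169).  Head-frame
units are millimeters; a ``scale`` factor on mesh reads converts
meter-unit meshes.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import trimesh

from .cranial import CranialLandmarks
from .errors import InvalidInputError, SchemaError
from .geometry import as_mesh
from .mapping import FacialLandmarks, LinearHeadMap, SubsetSpec
from .tentwenty import TenTwentyLayout
from .tracking import AtlasBundle

MESH_FORMATS = (".off", ".ply", ".obj")

LANDMARKS_FORMAT = "cranioguide.landmarks/1"
LAYOUT_FORMAT = "cranioguide.layout/1"
HEADMAP_FORMAT = "cranioguide.headmap/1"
STREAM_FORMAT = "cranioguide.stream/1"


def _require(doc: dict, field: str, where: str):
    if field not in doc:
        raise SchemaError(f"{where}: missing field {field!r}")
    return doc[field]


def _no_duplicates(pairs):
    seen = {}
    for key, value in pairs:
        if key in seen:
            raise SchemaError(f"duplicate key {key!r}")
        seen[key] = value
    return seen


def _load_json(path) -> dict:
    with open(path) as fh:
        try:
            return json.load(fh, object_pairs_hook=_no_duplicates)
        except json.JSONDecodeError as exc:
            raise SchemaError(f"{path}: not valid JSON ({exc})") from exc


def _dump_json(doc: dict, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1, sort_keys=True)
        fh.write("\n")


# ---------------------------------------------------------------------------
# meshes
# ---------------------------------------------------------------------------

def read_mesh(path, scale: float = 1.0) -> trimesh.Trimesh:
    """Load an OFF/PLY/OBJ triangular mesh (geometry only), validated.

    ``scale`` multiplies vertex coordinates (e.g. 1000 for meshes stored
    in meters).
    """
    path = Path(path)
    if path.suffix.lower() not in MESH_FORMATS:
        raise InvalidInputError(f"unsupported mesh format {path.suffix!r} "
                                f"(supported: {', '.join(MESH_FORMATS)})")
    try:
        raw = trimesh.load(str(path), process=False, force="mesh")
    except Exception as exc:  # noqa: BLE001 - normalize parser errors
        raise SchemaError(f"{path}: mesh parse error ({exc})") from exc
    if not hasattr(raw, "vertices") or len(getattr(raw, "faces", [])) == 0:
        raise SchemaError(f"{path}: no triangular faces found")
    try:
        return as_mesh(np.asarray(raw.vertices, float) * float(scale), raw.faces)
    except InvalidInputError as exc:
        raise SchemaError(f"{path}: {exc}") from exc


def write_mesh(mesh: trimesh.Trimesh, path, binary: bool = False) -> None:
    """Write a mesh; ascii by default so round trips are exact."""
    path = Path(path)
    if path.suffix.lower() not in MESH_FORMATS:
        raise InvalidInputError(f"unsupported mesh format {path.suffix!r}")
    path.parent.mkdir(parents=True, exist_ok=True)
    kwargs = {}
    if path.suffix.lower() == ".ply":
        kwargs["encoding"] = "binary" if binary else "ascii"
    mesh.export(str(path), **kwargs)


# ---------------------------------------------------------------------------
# landmark sets
# ---------------------------------------------------------------------------

def write_landmarks(cranial: CranialLandmarks, path, extra: dict | None = None) -> None:
    doc = {"format": LANDMARKS_FORMAT, "frame": cranial.frame,
           "method": cranial.method, "points": cranial.as_dict()}
    doc.update(extra or {})
    _dump_json(doc, path)


def read_landmarks(path) -> CranialLandmarks:
    doc = _load_json(path)
    if doc.get("format") != LANDMARKS_FORMAT:
        raise SchemaError(f"{path}: missing or wrong 'format' "
                          f"(expected {LANDMARKS_FORMAT!r})")
    points = _require(doc, "points", str(path))
    frame = _require(doc, "frame", str(path))
    try:
        return CranialLandmarks.from_dict(points, frame=frame,
                                          method=doc.get("method", "three-point"))
    except InvalidInputError as exc:
        raise SchemaError(f"{path}: {exc}") from exc


# ---------------------------------------------------------------------------
# layouts
# ---------------------------------------------------------------------------

def write_layout(layout: TenTwentyLayout, path, extra: dict | None = None) -> None:
    doc = {"format": LAYOUT_FORMAT, "density": layout.density,
           "source": layout.source,
           "entries": {k: v.tolist() for k, v in layout.entries.items()},
           "region": dict(layout.region)}
    doc.update(extra or {})
    _dump_json(doc, path)


def read_layout(path) -> TenTwentyLayout:
    doc = _load_json(path)
    if doc.get("format") != LAYOUT_FORMAT:
        raise SchemaError(f"{path}: missing or wrong 'format' "
                          f"(expected {LAYOUT_FORMAT!r})")
    try:
        return TenTwentyLayout(density=_require(doc, "density", str(path)),
                               entries=_require(doc, "entries", str(path)),
                               region=doc.get("region", {}),
                               source=doc.get("source", "atlas"))
    except InvalidInputError as exc:
        raise SchemaError(f"{path}: {exc}") from exc


# ---------------------------------------------------------------------------
# fitted head maps
# ---------------------------------------------------------------------------

def write_map(hmap: LinearHeadMap, path) -> None:
    doc = {"format": HEADMAP_FORMAT, "subset": hmap.subset.to_dict(),
           "targets": {c: {"A": A.tolist(), "b": b.tolist()}
                       for c, (A, b) in hmap.targets.items()},
           "metadata": hmap.metadata}
    _dump_json(doc, path)


def read_map(path) -> LinearHeadMap:
    doc = _load_json(path)
    if doc.get("format") != HEADMAP_FORMAT:
        raise SchemaError(f"{path}: missing or wrong 'format' "
                          f"(expected {HEADMAP_FORMAT!r})")
    subset = SubsetSpec.from_dict(_require(doc, "subset", str(path)))
    targets = {c: (np.asarray(t["A"], float), np.asarray(t["b"], float))
               for c, t in _require(doc, "targets", str(path)).items()}
    try:
        return LinearHeadMap(targets=targets, subset=subset,
                             metadata=doc.get("metadata", {}))
    except InvalidInputError as exc:
        raise SchemaError(f"{path}: {exc}") from exc


# ---------------------------------------------------------------------------
# frame streams and training tables (JSON lines)
# ---------------------------------------------------------------------------

def write_stream(frames, path) -> None:
    """Write facial-landmark frames as JSON lines ({t, convention, points})."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for t, frame in enumerate(frames):
            rec = {"t": t, "convention": frame.convention,
                   "points": np.asarray(frame.points).tolist()}
            fh.write(json.dumps(rec, sort_keys=True) + "\n")


def read_stream(path) -> list[FacialLandmarks]:
    frames = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                rec = json.loads(line)
            except json.JSONDecodeError as exc:
                raise SchemaError(f"{path}:{lineno}: not valid JSON ({exc})") from exc
            points = _require(rec, "points", f"{path}:{lineno}")
            convention = _require(rec, "convention", f"{path}:{lineno}")
            try:
                frames.append(FacialLandmarks(np.asarray(points, dtype=float),
                                              convention=convention,
                                              frame="normalized-camera"))
            except InvalidInputError as exc:
                raise SchemaError(f"{path}:{lineno}: {exc}") from exc
    return frames


def write_training_table(records, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for rec in records:
            fh.write(json.dumps(rec, sort_keys=True) + "\n")


def read_training_table(path) -> list[dict]:
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                rec = json.loads(line)
            except json.JSONDecodeError as exc:
                raise SchemaError(f"{path}:{lineno}: not valid JSON ({exc})") from exc
            for field in ("subject", "view", "facial", "targets"):
                _require(rec, field, f"{path}:{lineno}")
            records.append(rec)
    return records


# ---------------------------------------------------------------------------
# atlas bundles
# ---------------------------------------------------------------------------

def write_atlas_bundle(bundle: AtlasBundle, directory, mesh=None) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_landmarks(bundle.cranial, directory / "cranial.json")
    for density, layout in bundle.layouts.items():
        write_layout(layout, directory / f"layout_{density}.json")
    if mesh is not None:
        write_mesh(mesh, directory / "mesh.ply")


def read_atlas_bundle(directory) -> AtlasBundle:
    directory = Path(directory)
    cranial = read_landmarks(directory / "cranial.json")
    layouts = {}
    for path in sorted(directory.glob("layout_*.json")):
        layout = read_layout(path)
        layouts[layout.density] = layout
    if not layouts:
        raise SchemaError(f"{directory}: atlas bundle has no layout_*.json files")
    return AtlasBundle(cranial=cranial, layouts=layouts)
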