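"""Atlas-to-subject registration of precomputed 10-20 layouts.

An affine transform is fitted between the atlas cranial fiducials and the
subject's predicted fiducials, then applied to the atlas layout.  The fit
runs directly across frames (atlas head-mm → subject normalized-camera):
the affine absorbs the scale change, so no separate unit conversion is
needed.

All five fiducials always enter the correspondence set.  Four coplanar
points cannot determine a 3D affine, and in three-point mode Nz/Iz/LPA/RPA
are coplanar by construction — Cz fixes the out-of-plane component.  The
``mode`` therefore records only how Iz was derived.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cranial import CranialLandmarks
from .errors import DegeneracyError, InvalidInputError
from .mapping import AffineTransform, fit_view_affine
from .tentwenty import TenTwentyLayout


@dataclass
class OverlayFrame:
    """2D pixel positions of layout labels for one camera frame."""

    layout2d: dict[str, np.ndarray]
    image_size: tuple[int, int]
    frame_index: int = 0
    out_of_frame: frozenset = field(default_factory=frozenset)

    def __post_init__(self):
        clean = {}
        for label, p in self.layout2d.items():
            p = np.asarray(p, dtype=float).reshape(2)
            if not np.isfinite(p).all():
                raise InvalidInputError(f"overlay point {label!r} is not finite")
            clean[label] = p
        self.layout2d = clean
        self.out_of_frame = frozenset(self.out_of_frame)


def fit_registration(predicted: CranialLandmarks, atlas: CranialLandmarks,
                     mode: str = "five-point") -> AffineTransform:
    """Least-squares affine taking atlas fiducials onto predicted ones.

    Raises :class:`DegeneracyError` when the atlas correspondences are
    coplanar (e.g. a cranial set whose Cz lies in the fiducial plane).
    """
    if mode not in ("three-point", "five-point"):
        raise InvalidInputError(f"unknown registration mode {mode!r}")
    src = atlas.as_array()
    dst = predicted.as_array()
    try:
        return fit_view_affine(src, dst)
    except DegeneracyError as exc:
        raise DegeneracyError(
            "atlas cranial correspondences are coplanar; a 3D affine is "
            "undetermined (is Cz in the fiducial plane?)"
        ) from exc


def transform_layout(layout: TenTwentyLayout, transform: AffineTransform) -> TenTwentyLayout:
    """Map every layout entry through ``transform``; tags are preserved."""
    if layout.source != "atlas":
        raise InvalidInputError("transform_layout expects an atlas-sourced layout")
    entries = {label: transform.apply(p) for label, p in layout.entries.items()}
    return TenTwentyLayout(layout.density, entries, dict(layout.region),
                           source="predicted")


def apply_offset(layout: TenTwentyLayout, offset) -> TenTwentyLayout:
    """Translate every entry by a manual offset vector."""
    offset = np.asarray(offset, dtype=float).reshape(3)
    entries = {label: p + offset for label, p in layout.entries.items()}
    return TenTwentyLayout(layout.density, entries, dict(layout.region),
                           source=layout.source)


def project_overlay(layout: TenTwentyLayout, image_size,
                    frame_index: int = 0) -> OverlayFrame:
    """Project a normalized-camera layout to pixel coordinates.

    ``pixel = (x·w, y·h)``; depth is dropped.  Entries outside [0, 1]²
    project outside the image and are flagged, not dropped.
    """
    w, h = int(image_size[0]), int(image_size[1])
    if w <= 0 or h <= 0:
        raise InvalidInputError("image size must be positive")
    layout2d = {}
    flagged = set()
    for label, p in layout.entries.items():
        layout2d[label] = np.array([p[0] * w, p[1] * h])
        if not (0.0 <= p[0] <= 1.0 and 0.0 <= p[1] <= 1.0):
            flagged.add(label)
    return OverlayFrame(layout2d=layout2d, image_size=(w, h),
                        frame_index=frame_index, out_of_frame=frozenset(flagged))
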