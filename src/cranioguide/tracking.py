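"""Per-frame pipeline orchestration and the moving-average stabilizer.

Detector-estimated facial landmarks fluctuate frame to frame under image
noise; a moving average over the last ``w`` frames reduces the marginal
standard deviation of i.i.d. jitter by ``1/√w`` at the cost of a ``w``
frame lag after a step change in the true landmarks.  Averaging is
applied to the facial landmarks *before* prediction (optionally to the
projected overlay positions instead via ``average="output"``).
"""

from __future__ import annotations

import logging
import time
from collections import deque
from dataclasses import dataclass, field

import numpy as np

from .cranial import CranialLandmarks
from .errors import InvalidInputError
from .mapping import FacialLandmarks, LinearHeadMap, predict_cranial
from .registration import (OverlayFrame, apply_offset, fit_registration,
                           project_overlay, transform_layout)
from .tentwenty import TenTwentyLayout

log = logging.getLogger(__name__)


class Stabilizer:
    """Coordinate-wise moving average over the last ``window`` frames.

    ``window=1`` is an identity pass-through.  Output is defined from the
    first frame on (the mean runs over ``min(seen, window)`` frames).
    """

    def __init__(self, window: int = 1):
        if int(window) < 1:
            raise InvalidInputError("window must be a positive integer")
        self.window = int(window)
        self._buffer: deque = deque(maxlen=self.window)
        self._convention: str | None = None

    def __len__(self) -> int:
        return len(self._buffer)

    def reset(self) -> None:
        self._buffer.clear()
        self._convention = None

    def update(self, frame: FacialLandmarks) -> FacialLandmarks:
        if self._convention is None:
            self._convention = frame.convention
        elif frame.convention != self._convention:
            raise InvalidInputError(
                f"landmark convention changed mid-stream "
                f"({self._convention!r} → {frame.convention!r})"
            )
        self._buffer.append(np.asarray(frame.points, dtype=float))
        mean = np.mean(np.stack(self._buffer), axis=0)
        return FacialLandmarks(mean, convention=frame.convention, frame=frame.frame)


def stabilize(state: Stabilizer, frame: FacialLandmarks) -> FacialLandmarks:
    """Functional alias for :meth:`Stabilizer.update`."""
    return state.update(frame)


@dataclass(frozen=True)
class AtlasBundle:
    """A precomputed atlas: cranial fiducials plus layouts per density."""

    cranial: CranialLandmarks
    layouts: dict[str, TenTwentyLayout]

    def layout(self, density: str) -> TenTwentyLayout:
        if density not in self.layouts:
            raise InvalidInputError(f"atlas bundle has no {density!r} layout")
        return self.layouts[density]


@dataclass
class TrackingConfig:
    """Per-stream options: density, Iz-derivation mode, stabilizer window,
    manual offset (normalized units) and the overlay image size in px."""

    density: str = "10-20"
    mode: str = "three-point"
    window: int = 1
    offset: tuple = (0.0, 0.0, 0.0)
    image_size: tuple = (640, 480)
    average: str = "facial"  #: "facial" or "output" landmark averaging
    stage_timings: dict = field(default_factory=dict)


def _frame_is_empty(frame) -> bool:
    return frame is None or len(np.atleast_2d(np.asarray(frame.points)).reshape(-1)) == 0


def process_stream(frames, hmap: LinearHeadMap, atlas: AtlasBundle,
                   config: TrackingConfig | None = None) -> list[OverlayFrame]:
    """Run the full per-frame pipeline over a recorded landmark stream.

    Per frame: stabilize → predict cranial fiducials → fit atlas
    registration → transform the atlas layout → apply the manual offset →
    project to pixels.  Frames with no detected face are skipped and leave
    the stabilizer untouched.  Stage errors are re-raised with the frame
    index attached.
    """
    config = config or TrackingConfig()
    frames = list(frames)
    if not frames:
        raise InvalidInputError("empty frame stream")
    if config.average not in ("facial", "output"):
        raise InvalidInputError(f"unknown averaging target {config.average!r}")
    stabilizer = Stabilizer(config.window)
    out_buffer: deque | None = (deque(maxlen=config.window)
                                if config.average == "output" else None)
    base_layout = atlas.layout(config.density)
    overlays = []
    timings = {"stabilize": 0.0, "predict": 0.0, "register": 0.0, "project": 0.0}
    for index, frame in enumerate(frames):
        if _frame_is_empty(frame):
            continue
        try:
            t0 = time.perf_counter()
            facial = stabilizer.update(frame) if out_buffer is None else frame
            t1 = time.perf_counter()
            predicted = predict_cranial(hmap, facial)
            t2 = time.perf_counter()
            T = fit_registration(predicted, atlas.cranial, mode=config.mode)
            layout = apply_offset(transform_layout(base_layout, T), config.offset)
            if out_buffer is not None:
                labels = layout.labels
                out_buffer.append(layout.as_array(labels))
                mean = np.mean(np.stack(out_buffer), axis=0)
                layout = layout.with_entries(dict(zip(labels, mean)))
            t3 = time.perf_counter()
            overlays.append(project_overlay(layout, config.image_size,
                                            frame_index=index))
            t4 = time.perf_counter()
        except Exception as exc:
            raise type(exc)(f"frame {index}: {exc}") from exc
        timings["stabilize"] += t1 - t0
        timings["predict"] += t2 - t1
        timings["register"] += t3 - t2
        timings["project"] += t4 - t3
    config.stage_timings = timings
    log.debug("processed %d/%d frames; stage seconds: %s",
              len(overlays), len(frames), timings)
    return overlays
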