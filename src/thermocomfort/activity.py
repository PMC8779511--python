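"""Activity-intensity features from a tracked bounding-box window.

Three features summarize how much a person moved over a window (10 s, i.e.
210 frames at 21 fps, by default):

1. ``center_spread`` — the box centers over the window form a 2-D point
   cluster; the product of the two eigenvalues of its sample covariance
   (equal to the covariance determinant) measures the area of the fitted
   ellipse, capturing general body movement.
2. ``scale_spread`` — the same statistic on the boxes' half-extents
   (w/2, h/2) after translating every box to the origin, capturing limb
   motion that changes the box size.
3. ``flow_intensity`` — mean absolute deviation from the zero-motion
   grayscale level (127) of the horizontal and vertical optical-flow
   images, pooled over the box and combined as sqrt(Ix² + Iy²), averaged
   over the window; captures subtle motion the box geometry misses.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .core import BoundingBox, PipelineConfig
from .tracking import Track

__all__ = [
    "FLOW_ZERO_LEVEL",
    "BoxTrajectory",
    "FlowField",
    "ActivityFeatures",
    "WindowNotFullError",
    "center_spread",
    "scale_spread",
    "flow_intensity_frame",
    "flow_intensity_window",
    "extract_features",
]

FLOW_ZERO_LEVEL = 127.0


class WindowNotFullError(ValueError):
    """Raised when a track has fewer frames than the activity window."""


@dataclass
class BoxTrajectory:
    """Per-frame box geometry over a window."""

    frames: list[int]
    boxes: list[BoundingBox]

    def __post_init__(self) -> None:
        if len(self.frames) != len(self.boxes):
            raise ValueError("frames and boxes must have equal length")

    @property
    def centers(self) -> np.ndarray:
        return np.array([b.center for b in self.boxes], dtype=float)

    @property
    def half_extents(self) -> np.ndarray:
        return np.array([b.half_extent for b in self.boxes], dtype=float)

    @classmethod
    def from_track(cls, track: Track, window: Optional[int] = None) -> "BoxTrajectory":
        pairs = track.trajectory if window is None else track.trajectory[-window:]
        return cls(frames=[f for f, _ in pairs], boxes=[b for _, b in pairs])


@dataclass
class FlowField:
    """A pair of 8-bit optical-flow images; grayscale 127 encodes zero motion."""

    horizontal: np.ndarray
    vertical: np.ndarray

    def __post_init__(self) -> None:
        self.horizontal = np.asarray(self.horizontal)
        self.vertical = np.asarray(self.vertical)
        if self.horizontal.shape != self.vertical.shape:
            raise ValueError("horizontal and vertical flow images must share a shape")
        for name in ("horizontal", "vertical"):
            arr = getattr(self, name)
            if arr.ndim != 2:
                raise ValueError(f"{name} flow must be a 2-D image")
            if arr.min() < 0 or arr.max() > 255:
                raise ValueError(f"{name} flow values must lie in [0, 255]")


@dataclass(frozen=True)
class ActivityFeatures:
    """The three activity-intensity features over one window."""

    center_spread: float
    scale_spread: float
    flow_intensity: float
    window_frames: int

    def as_array(self) -> np.ndarray:
        return np.array([self.center_spread, self.scale_spread, self.flow_intensity])


def _eigenvalue_product(points: np.ndarray) -> float:
    """Product of the two eigenvalues of the 2x2 sample covariance (N-1)."""
    if len(points) < 2:
        raise ValueError("need at least 2 points to estimate a covariance")
    cov = np.cov(points, rowvar=False, ddof=1)
    eig = np.linalg.eigvalsh(cov)
    # covariance is PSD; clip the tiny negatives that floating point produces
    return float(np.prod(np.clip(eig, 0.0, None)))


def center_spread(trajectory: BoxTrajectory) -> float:
    """Ellipse-area statistic of the box-center cluster (pixels²)."""
    return _eigenvalue_product(trajectory.centers)


def scale_spread(trajectory: BoxTrajectory) -> float:
    """Ellipse-area statistic of the half-extent cluster (pixels²)."""
    return _eigenvalue_product(trajectory.half_extents)


def _box_slice(box: BoundingBox, shape: tuple[int, int]) -> tuple[slice, slice]:
    rows, cols = shape
    r0 = min(max(int(np.floor(box.y)), 0), rows)
    r1 = min(max(int(np.ceil(box.y + box.h)), 0), rows)
    c0 = min(max(int(np.floor(box.x)), 0), cols)
    c1 = min(max(int(np.ceil(box.x + box.w)), 0), cols)
    return slice(r0, r1), slice(c0, c1)


def flow_intensity_frame(flow: FlowField, box: BoundingBox) -> float:
    """Optical-flow intensity Ixy within a box for one frame.

    Ix (Iy) is the mean over box pixels of |grayscale - 127| of the
    horizontal (vertical) flow image; the frame intensity is
    sqrt(Ix² + Iy²). The per-pixel sums are normalized by the number of box
    pixels so the statistic is box-size invariant.
    """
    rs, cs = _box_slice(box, flow.horizontal.shape)
    if rs.stop <= rs.start or cs.stop <= cs.start:
        raise ValueError("bounding box does not intersect the flow field")
    ix = float(np.abs(flow.horizontal[rs, cs].astype(float) - FLOW_ZERO_LEVEL).mean())
    iy = float(np.abs(flow.vertical[rs, cs].astype(float) - FLOW_ZERO_LEVEL).mean())
    return float(np.hypot(ix, iy))


def flow_intensity_window(
    flows: Sequence[FlowField], boxes: Sequence[BoundingBox]
) -> float:
    """Mean per-frame flow intensity over a window."""
    if len(flows) != len(boxes):
        raise ValueError(
            f"flows ({len(flows)}) and boxes ({len(boxes)}) must have equal length"
        )
    if not flows:
        raise ValueError("empty window")
    return float(np.mean([flow_intensity_frame(f, b) for f, b in zip(flows, boxes)]))


def extract_features(
    track: Track,
    flows: Sequence[FlowField],
    config: PipelineConfig,
    flow_frame_offset: int = 0,
) -> ActivityFeatures:
    """Bundle the three features over a track's most recent window.

    ``flows`` must be indexable by ``frame_index - flow_frame_offset``.

    Raises
    ------
    WindowNotFullError
        When the track has fewer than ``activity_window_frames`` boxes.
    """
    window = config.activity_window_frames
    pairs = track.trajectory[-window:]
    if len(pairs) < window:
        raise WindowNotFullError(
            f"track {track.track_id} has {len(pairs)} frames; "
            f"the activity window needs {window}"
        )
    traj = BoxTrajectory(frames=[f for f, _ in pairs], boxes=[b for _, b in pairs])
    window_flows = [flows[f - flow_frame_offset] for f in traj.frames]
    return ActivityFeatures(
        center_spread=center_spread(traj),
        scale_spread=scale_spread(traj),
        flow_intensity=flow_intensity_window(window_flows, traj.boxes),
        window_frames=window,
    )
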