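"""Skin / clothes region localization and temperature summarization.

The skin region Rs and clothing-covered region Rc are located from a sparse
set of body keypoints (nose, shoulders, elbows, wrists) conditioned on the
person's voted sleeve status:

* Rs always includes the nose; for short sleeves it additionally includes,
  per side, the lower-arm point (midpoint of elbow and wrist).
* Rc always includes the shoulders; for long sleeves it additionally
  includes the elbows (covered by the sleeve).
* For an occluded sleeve status only the unconditional points are used.

Keypoints below the confidence threshold (0.6 by default) are discarded
before any region rule is applied. Samples are accumulated over a window of
frames and averaged into the mean skin temperature Ts and the mean clothes
temperature Tc; the operative temperature To is the window average of the
per-frame background (non-person) mean temperature.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np

from .core import BoundingBox, Keypoint, PipelineConfig, SleeveStatus, ThermalFrame
from .tracking import Track, vote_category
from .core import decompose_category

__all__ = [
    "RegionSamples",
    "ThermalSummary",
    "InsufficientSamplesError",
    "locate_regions",
    "assign_skeleton",
    "accumulate_samples",
    "summarize",
    "background_temperature",
    "background_temperature_window",
    "keypoint_accuracy",
]


class InsufficientSamplesError(ValueError):
    """Raised when a temperature summary is requested for an empty region."""

    def __init__(self, region: str):
        self.region = region
        super().__init__(f"insufficient samples: the {region} region is empty")


@dataclass
class RegionSamples:
    """Accumulated (frame, u, v, temperature) samples for Rs and Rc."""

    skin_points: list[tuple[int, int, int, float]]
    clothes_points: list[tuple[int, int, int, float]]
    window_frames: int

    @property
    def n_skin(self) -> int:
        return len(self.skin_points)

    @property
    def n_clothes(self) -> int:
        return len(self.clothes_points)


@dataclass(frozen=True)
class ThermalSummary:
    """Mean skin, clothes and operative temperatures over a window (°C)."""

    ts: float
    tc: float
    to: float
    n_skin: int
    n_clothes: int


def locate_regions(
    keypoints: Sequence[Keypoint],
    sleeve_status: SleeveStatus,
    conf_threshold: float,
) -> tuple[set[tuple[float, float]], set[tuple[float, float]]]:
    """Locate skin (Rs) and clothes (Rc) sample points for one skeleton.

    Returns two sets of continuous ``(u, v)`` pixel coordinates. Empty sets
    are legal outputs (e.g. everything below threshold).
    """
    if not (0.0 < conf_threshold < 1.0):
        raise ValueError(f"conf_threshold must be in (0, 1), got {conf_threshold}")
    sleeve_status = SleeveStatus(sleeve_status)
    valid = {k.name: k for k in keypoints if k.score >= conf_threshold}

    skin: set[tuple[float, float]] = set()
    clothes: set[tuple[float, float]] = set()

    if "nose" in valid:
        skin.add((valid["nose"].u, valid["nose"].v))
    if sleeve_status is SleeveStatus.SHORT:
        for side in ("left", "right"):
            elbow = valid.get(f"{side}_elbow")
            wrist = valid.get(f"{side}_wrist")
            if elbow is not None and wrist is not None:
                skin.add(((elbow.u + wrist.u) / 2.0, (elbow.v + wrist.v) / 2.0))

    for side in ("left", "right"):
        shoulder = valid.get(f"{side}_shoulder")
        if shoulder is not None:
            clothes.add((shoulder.u, shoulder.v))
    if sleeve_status is SleeveStatus.LONG:
        for side in ("left", "right"):
            elbow = valid.get(f"{side}_elbow")
            if elbow is not None:
                clothes.add((elbow.u, elbow.v))

    return skin, clothes


def _skeleton_hull(skeleton: Sequence[Keypoint]) -> Optional[BoundingBox]:
    pts = [(k.u, k.v) for k in skeleton if k.score > 0.0]
    if not pts:
        return None
    us, vs = zip(*pts)
    w = max(max(us) - min(us), 1.0)
    h = max(max(vs) - min(vs), 1.0)
    return BoundingBox(min(us), min(vs), w, h)


def assign_skeleton(
    skeletons: Sequence[Sequence[Keypoint]], box: BoundingBox
) -> Optional[Sequence[Keypoint]]:
    """Pick the skeleton whose keypoint hull overlaps a track box the most.

    Returns ``None`` when no skeleton overlaps the box at all. Ties go to
    the earlier skeleton in the sequence.
    """
    best, best_overlap = None, 0.0
    for skel in skeletons:
        hull = _skeleton_hull(skel)
        if hull is None:
            continue
        ix = max(0.0, min(hull.x + hull.w, box.x + box.w) - max(hull.x, box.x))
        iy = max(0.0, min(hull.y + hull.h, box.y + box.h) - max(hull.y, box.y))
        overlap = ix * iy
        if overlap > best_overlap:
            best, best_overlap = skel, overlap
    return best


def accumulate_samples(
    track: Track,
    skeletons_by_frame: Mapping[int, Sequence[Sequence[Keypoint]]],
    thermal_frames: Mapping[int, ThermalFrame],
    config: PipelineConfig,
    frames: Optional[Sequence[int]] = None,
    sleeve_status: Optional[SleeveStatus] = None,
) -> RegionSamples:
    """Accumulate Rs / Rc temperature samples for one track over a window.

    For every frame of the window the skeleton with maximal hull overlap
    with the track's box is selected, regions are located with the track's
    voted sleeve status, and each region point is rounded to the nearest
    pixel, clamped to the frame, and sampled from that frame's thermal
    matrix.

    Parameters
    ----------
    frames
        Frame indices forming the window; defaults to all frames of the
        track's trajectory.
    sleeve_status
        Override for the voted sleeve status (useful for testing).
    """
    if frames is None:
        frames = [f for f, _ in track.trajectory]
    frames = list(frames)
    if not frames:
        raise ValueError("accumulation window must contain at least one frame")

    if sleeve_status is None:
        category = vote_category(track, window=max(len(frames), 1))
        sleeve_status, _ = decompose_category(category)

    traj = dict(track.trajectory)
    skin_samples: list[tuple[int, int, int, float]] = []
    clothes_samples: list[tuple[int, int, int, float]] = []
    for f in frames:
        box = traj.get(f)
        frame = thermal_frames.get(f)
        skeletons = skeletons_by_frame.get(f, ())
        if box is None or frame is None or not skeletons:
            continue
        skel = assign_skeleton(skeletons, box)
        if skel is None:
            continue
        skin, clothes = locate_regions(skel, sleeve_status, config.keypoint_conf_threshold)
        rows, cols = frame.shape
        for region, out in ((skin, skin_samples), (clothes, clothes_samples)):
            for u, v in sorted(region):
                ci = min(max(int(round(u)), 0), cols - 1)
                ri = min(max(int(round(v)), 0), rows - 1)
                temp = frame.temperature_at(ci, ri, patch=config.sample_patch)
                out.append((f, ci, ri, temp))

    return RegionSamples(
        skin_points=skin_samples,
        clothes_points=clothes_samples,
        window_frames=len(frames),
    )


def summarize(samples: RegionSamples, to: float) -> ThermalSummary:
    """Average accumulated samples into Ts and Tc; To is passed through."""
    if samples.n_skin < 1:
        raise InsufficientSamplesError("skin")
    if samples.n_clothes < 1:
        raise InsufficientSamplesError("clothes")
    ts = float(np.mean([t for *_, t in samples.skin_points]))
    tc = float(np.mean([t for *_, t in samples.clothes_points]))
    return ThermalSummary(ts=ts, tc=tc, to=float(to), n_skin=samples.n_skin, n_clothes=samples.n_clothes)


def background_temperature(
    frame: ThermalFrame, person_boxes: Sequence[BoundingBox]
) -> float:
    """Mean temperature of all pixels lying outside every person box."""
    rows, cols = frame.shape
    mask = np.ones((rows, cols), dtype=bool)
    for box in person_boxes:
        r0 = min(max(int(np.floor(box.y)), 0), rows)
        r1 = min(max(int(np.ceil(box.y + box.h)), 0), rows)
        c0 = min(max(int(np.floor(box.x)), 0), cols)
        c1 = min(max(int(np.ceil(box.x + box.w)), 0), cols)
        mask[r0:r1, c0:c1] = False
    if not mask.any():
        raise ValueError("person boxes cover the whole frame; no background pixels")
    return float(frame.values[mask].mean())


def background_temperature_window(
    frames: Sequence[ThermalFrame],
    boxes_by_frame: Sequence[Sequence[BoundingBox]],
) -> float:
    """Operative temperature To: unweighted mean of per-frame background means."""
    if len(frames) != len(boxes_by_frame):
        raise ValueError("frames and boxes_by_frame must have equal length")
    if not frames:
        raise ValueError("empty window")
    return float(
        np.mean([background_temperature(f, b) for f, b in zip(frames, boxes_by_frame)])
    )


def keypoint_accuracy(n_error_frames: int, n_frames: int) -> float:
    """Frame-level keypoint localization accuracy, as a percentage.

    A frame with even one wrongly localized keypoint counts as an error
    frame; accuracy = 100 * (1 - errors / frames).
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    if not (0 <= n_error_frames <= n_frames):
        raise ValueError("n_error_frames must be in [0, n_frames]")
    return 100.0 * (1.0 - n_error_frames / n_frames)
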