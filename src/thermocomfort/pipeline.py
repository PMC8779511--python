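"""End-to-end orchestration: tracking → voting → Icl branch and M branch.

For every confirmed track the pipeline emits

* one :class:`~thermocomfort.icl.IclResult` per Icl accumulation window
  (5 min by default; a trailing partial window is still emitted, flagged,
  when at least one second of frames exists), and
* one :class:`~thermocomfort.metabolic.MetabolicResult` per full activity
  window (10 s / 210 frames by default). Sitting windows use the constant
  72.5 W/m²; standing windows run the three-feature classifier.

Windows that cannot be computed (empty region, ill-conditioned Icl,
missing flow or classifier, not enough frames) are recorded as skips with
a reason rather than failing the run.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

from .activity import ActivityFeatures, BoxTrajectory, FlowField, center_spread, flow_intensity_window, scale_spread
from .core import Detection, PersonCategory, PipelineConfig, Posture, decompose_category
from .icl import IclResult, IllConditionedError, icl_from_summary
from .metabolic import ActivityClassifier, MetabolicResult, estimate_m, predict_probabilities
from .thermal_regions import (
    InsufficientSamplesError,
    ThermalFrame,
    accumulate_samples,
    background_temperature_window,
    summarize,
)
from .tracking import MultiObjectTracker, Track, TrackerConfig, vote_category

__all__ = ["WindowOutput", "TrackResult", "PipelineResult", "run_pipeline"]


@dataclass
class WindowOutput:
    start_frame: int
    end_frame: int  # inclusive
    icl: Optional[IclResult] = None
    m: Optional[MetabolicResult] = None
    voted_category: Optional[PersonCategory] = None
    skipped: Optional[str] = None


@dataclass
class TrackResult:
    track_id: int
    icl_windows: list[WindowOutput] = field(default_factory=list)
    m_windows: list[WindowOutput] = field(default_factory=list)


@dataclass
class PipelineResult:
    tracks: dict[int, TrackResult]
    n_frames: int
    record_counts: dict = field(default_factory=dict)
    notes: list[str] = field(default_factory=list)


def _chunks(frames: Sequence[int], size: int) -> list[list[int]]:
    return [list(frames[i : i + size]) for i in range(0, len(frames), size)]


def _modal_posture(track: Track, frames: Sequence[int]) -> Posture:
    fset = set(frames)
    postures = [
        decompose_category(c)[1] for f, c in track.category_history if f in fset
    ]
    if not postures:
        # fall back to the track-wide vote
        postures = [decompose_category(c)[1] for _, c in track.category_history]
    return Counter(postures).most_common(1)[0][0]


def run_pipeline(
    detections_by_frame: Sequence[Sequence[Detection]],
    keypoints_by_frame: Mapping[int, Sequence[Sequence]],
    thermal_frames: Optional[Sequence[ThermalFrame]],
    flows: Optional[Sequence[FlowField]],
    config: Optional[PipelineConfig] = None,
    tracker_config: Optional[TrackerConfig] = None,
    classifier: Optional[ActivityClassifier] = None,
) -> PipelineResult:
    """Run tracking plus both estimation branches over a frame range.

    ``detections_by_frame[f]`` must hold frame ``f``'s detections (possibly
    empty); thermal frames and flow fields, when provided, must cover the
    same range.
    """
    config = config or PipelineConfig()
    n_frames = len(detections_by_frame)
    for name, seq in (("thermal_frames", thermal_frames), ("flows", flows)):
        if seq is not None and len(seq) != n_frames:
            raise ValueError(
                f"frame-range mismatch: {n_frames} detection frames but "
                f"{len(seq)} {name}"
            )

    tracker = MultiObjectTracker(tracker_config)
    for f in range(n_frames):
        tracker.step(f, list(detections_by_frame[f]))

    thermal_by_index = (
        {f: fr for f, fr in enumerate(thermal_frames)} if thermal_frames is not None else {}
    )
    result = PipelineResult(tracks={}, n_frames=n_frames)

    confirmed = tracker.ever_confirmed_tracks
    # per-frame union of confirmed-track boxes, for background exclusion
    boxes_by_frame: dict[int, list] = {f: [] for f in range(n_frames)}
    for t in confirmed:
        for f, box in t.trajectory:
            boxes_by_frame[f].append(box)

    min_partial = max(int(round(config.fps)), 1)  # >= 1 s of frames

    for track in confirmed:
        tr = TrackResult(track_id=track.track_id)
        frames = [f for f, _ in track.trajectory]

        # ---- Icl branch -----------------------------------------------
        for window in _chunks(frames, config.icl_window_frames):
            out = WindowOutput(start_frame=window[0], end_frame=window[-1])
            partial = len(window) < config.icl_window_frames
            if partial and len(window) < min_partial:
                out.skipped = (
                    f"window not full: {len(window)} frames < {min_partial} minimum"
                )
                tr.icl_windows.append(out)
                continue
            if thermal_frames is None:
                out.skipped = "no thermal frames provided"
                tr.icl_windows.append(out)
                continue
            voted = vote_category(track, window=len(window))
            out.voted_category = voted
            try:
                samples = accumulate_samples(
                    track, keypoints_by_frame, thermal_by_index, config, frames=window
                )
                to = background_temperature_window(
                    [thermal_frames[f] for f in window],
                    [boxes_by_frame[f] for f in window],
                )
                summary = summarize(samples, to)
                out.icl = icl_from_summary(
                    summary, config, window_frames=len(window), partial_window=partial
                )
            except (InsufficientSamplesError, IllConditionedError, ValueError) as exc:
                out.skipped = str(exc)
            tr.icl_windows.append(out)

        # ---- M branch --------------------------------------------------
        for window in _chunks(frames, config.activity_window_frames):
            out = WindowOutput(start_frame=window[0], end_frame=window[-1])
            if len(window) < config.activity_window_frames:
                out.skipped = (
                    f"window not full: {len(window)} frames < "
                    f"{config.activity_window_frames}"
                )
                tr.m_windows.append(out)
                continue
            posture = _modal_posture(track, window)
            if posture is Posture.SIT:
                out.m = estimate_m(posture, None, config)
            elif flows is None:
                out.skipped = "standing window needs flow fields; none provided"
            elif classifier is None:
                out.skipped = "standing window needs a trained activity classifier"
            else:
                traj_map = dict(track.trajectory)
                boxes = [traj_map[f] for f in window]
                traj = BoxTrajectory(frames=list(window), boxes=boxes)
                features = ActivityFeatures(
                    center_spread=center_spread(traj),
                    scale_spread=scale_spread(traj),
                    flow_intensity=flow_intensity_window(
                        [flows[f] for f in window], boxes
                    ),
                    window_frames=len(window),
                )
                probs = predict_probabilities(classifier, features)
                out.m = estimate_m(posture, probs, config, features=features)
            tr.m_windows.append(out)

        result.tracks[track.track_id] = tr

    result.record_counts = {
        "frames": n_frames,
        "detections": sum(len(d) for d in detections_by_frame),
        "confirmed_tracks": len(confirmed),
        "icl_windows": sum(len(t.icl_windows) for t in result.tracks.values()),
        "m_windows": sum(len(t.m_windows) for t in result.tracks.values()),
    }
    return result
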