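"""Tracking-by-detection with a SORT-style Kalman filter and DeepSort lifecycle.

Detections are associated to tracks frame by frame with a minimum-cost
(Hungarian) assignment on ``1 - IoU`` between Kalman-predicted boxes and
detections, optionally blended with a pluggable appearance-distance hook.
Track lifecycle follows the Tentative-Track / Maximum-Age rules: a track is
confirmed only after ``n_init`` consecutive associations and a confirmed
track is deleted only after going unassociated for more than ``max_age``
frames. Each track additionally accumulates its per-frame six-way category
for majority voting.
"""

from __future__ import annotations

import enum
from collections import Counter
from dataclasses import dataclass, field
from typing import Callable, Iterable, NamedTuple, Optional, Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment

from .core import BoundingBox, Detection, PersonCategory

__all__ = [
    "TrackState",
    "TrackerConfig",
    "Track",
    "MultiObjectTracker",
    "vote_category",
    "MotCounts",
    "compute_mota",
    "LabelledBox",
    "evaluate_tracking",
]

_GATED_COST = 1e6


class TrackState(enum.Enum):
    TENTATIVE = "tentative"
    CONFIRMED = "confirmed"
    DELETED = "deleted"


@dataclass
class TrackerConfig:
    """Tracker parameters.

    ``appearance_hook(detection, track) -> distance >= 0`` lets callers plug
    in an appearance metric; when supplied, the association cost is the
    weighted sum ``(1 - appearance_weight) * (1 - IoU) + appearance_weight *
    distance``. The deep-embedding metric itself is out of scope, so the
    default hook is disabled.
    """

    max_age: int = 30
    n_init: int = 3
    iou_threshold: float = 0.3
    appearance_hook: Optional[Callable[[Detection, "Track"], float]] = None
    appearance_weight: float = 0.5

    def __post_init__(self) -> None:
        if self.max_age < 1:
            raise ValueError("max_age must be >= 1")
        if self.n_init < 1:
            raise ValueError("n_init must be >= 1")
        if not (0.0 < self.iou_threshold < 1.0):
            raise ValueError("iou_threshold must be in (0, 1)")
        if not (0.0 <= self.appearance_weight <= 1.0):
            raise ValueError("appearance_weight must be in [0, 1]")


def _box_to_z(box: BoundingBox) -> np.ndarray:
    cx, cy = box.center
    return np.array([cx, cy, box.w * box.h, box.w / box.h], dtype=float)


def _z_to_box(z: np.ndarray) -> BoundingBox:
    s, r = max(z[2], 1e-6), max(z[3], 1e-6)
    w = np.sqrt(s * r)
    h = s / w
    return BoundingBox(z[0] - w / 2.0, z[1] - h / 2.0, w, h)


class _KalmanBoxFilter:
    """Constant-velocity Kalman filter on (cx, cy, area, aspect).

    State is [cx, cy, s, r, vcx, vcy, vs]; the aspect ratio is modelled as
    constant. Noise settings follow the standard SORT configuration.
    """

    def __init__(self, box: BoundingBox):
        self.x = np.zeros(7)
        self.x[:4] = _box_to_z(box)
        self.F = np.eye(7)
        self.F[0, 4] = self.F[1, 5] = self.F[2, 6] = 1.0
        self.H = np.zeros((4, 7))
        self.H[:4, :4] = np.eye(4)
        self.R = np.diag([1.0, 1.0, 10.0, 10.0])
        self.P = np.eye(7) * 10.0
        self.P[4:, 4:] *= 1000.0
        self.Q = np.eye(7)
        self.Q[-1, -1] *= 0.01
        self.Q[4:, 4:] *= 0.01

    def predict(self) -> BoundingBox:
        if self.x[2] + self.x[6] <= 0:
            self.x[6] = 0.0
        self.x = self.F @ self.x
        self.P = self.F @ self.P @ self.F.T + self.Q
        return _z_to_box(self.x)

    def update(self, box: BoundingBox) -> None:
        z = _box_to_z(box)
        y = z - self.H @ self.x
        S = self.H @ self.P @ self.H.T + self.R
        K = self.P @ self.H.T @ np.linalg.inv(S)
        self.x = self.x + K @ y
        self.P = (np.eye(7) - K @ self.H) @ self.P

    @property
    def box(self) -> BoundingBox:
        return _z_to_box(self.x)


@dataclass
class Track:
    """A persistent identity with Kalman state and category history."""

    track_id: int
    kf: _KalmanBoxFilter
    state: TrackState = TrackState.TENTATIVE
    age_since_update: int = 0
    hit_streak: int = 1
    category_history: list[tuple[int, PersonCategory]] = field(default_factory=list)
    #: per-frame (frame_index, box) estimates over the track's lifetime
    trajectory: list[tuple[int, BoundingBox]] = field(default_factory=list)
    last_vote: Optional[PersonCategory] = None
    predicted_box: Optional[BoundingBox] = None
    ever_confirmed: bool = False

    @property
    def is_confirmed(self) -> bool:
        return self.state is TrackState.CONFIRMED

    def recent_boxes(self, window: int) -> list[tuple[int, BoundingBox]]:
        return self.trajectory[-window:]


class MultiObjectTracker:
    """Online tracker consuming per-frame detection lists.

    The caller must feed every frame consecutively, possibly with an empty
    detection list; skipping frames is rejected because the constant-velocity
    prediction and the lifecycle counters are per-frame.
    """

    def __init__(self, config: Optional[TrackerConfig] = None):
        self.config = config or TrackerConfig()
        self.tracks: list[Track] = []
        #: every track ever created, including deleted ones
        self.history: list[Track] = []
        self._next_id = 1
        self._next_frame: Optional[int] = None

    @property
    def confirmed_tracks(self) -> list[Track]:
        return [t for t in self.tracks if t.is_confirmed]

    @property
    def ever_confirmed_tracks(self) -> list[Track]:
        """All tracks that reached confirmation at some point, in id order."""
        return [t for t in self.history if t.ever_confirmed]

    def step(self, frame_index: int, detections: Sequence[Detection]) -> list[Track]:
        """Advance one frame; returns the live (non-deleted) tracks."""
        if self._next_frame is not None and frame_index != self._next_frame:
            raise ValueError(
                f"non-consecutive frame {frame_index}; expected {self._next_frame} "
                "(feed every frame, with an empty detection list if necessary)"
            )
        for det in detections:
            if det.frame_index != frame_index:
                raise ValueError(
                    f"detection frame_index {det.frame_index} != step frame {frame_index}"
                )
        self._next_frame = frame_index + 1

        live = [t for t in self.tracks if t.state is not TrackState.DELETED]
        live.sort(key=lambda t: t.track_id)
        for t in live:
            t.predicted_box = t.kf.predict()
            t.age_since_update += 1

        matches, unmatched_tracks, unmatched_dets = self._associate(live, detections)

        for t, det in matches:
            t.kf.update(det.box)
            t.age_since_update = 0
            t.hit_streak += 1
            t.category_history.append((frame_index, det.category))
            if t.state is TrackState.TENTATIVE and t.hit_streak >= self.config.n_init:
                t.state = TrackState.CONFIRMED
                t.ever_confirmed = True
            t.trajectory.append((frame_index, t.kf.box))

        for t in unmatched_tracks:
            t.hit_streak = 0
            if t.state is TrackState.TENTATIVE:
                # a tentative track misses once -> the "three continuous
                # frames" requirement can no longer be met; drop it
                t.state = TrackState.DELETED
            elif t.age_since_update > self.config.max_age:
                t.state = TrackState.DELETED
            else:
                t.trajectory.append((frame_index, t.predicted_box))

        for det in unmatched_dets:
            kf = _KalmanBoxFilter(det.box)
            t = Track(track_id=self._next_id, kf=kf)
            self._next_id += 1
            if self.config.n_init == 1:
                t.state = TrackState.CONFIRMED
                t.ever_confirmed = True
            t.category_history.append((frame_index, det.category))
            t.trajectory.append((frame_index, det.box))
            self.tracks.append(t)
            self.history.append(t)

        self.tracks = [t for t in self.tracks if t.state is not TrackState.DELETED]
        return list(self.tracks)

    def _associate(
        self, tracks: Sequence[Track], detections: Sequence[Detection]
    ) -> tuple[list[tuple[Track, Detection]], list[Track], list[Detection]]:
        if not tracks or not detections:
            return [], list(tracks), list(detections)
        cfg = self.config
        cost = np.full((len(tracks), len(detections)), _GATED_COST)
        for i, t in enumerate(tracks):
            for j, det in enumerate(detections):
                iou = t.predicted_box.iou(det.box)
                if iou < cfg.iou_threshold:
                    continue
                c = 1.0 - iou
                if cfg.appearance_hook is not None:
                    c = (1.0 - cfg.appearance_weight) * c + cfg.appearance_weight * float(
                        cfg.appearance_hook(det, t)
                    )
                cost[i, j] = c
        rows, cols = linear_sum_assignment(cost)
        matches = []
        matched_t, matched_d = set(), set()
        # rows come out sorted, so equal-cost ties resolve to the lowest
        # (track_id, detection index) pair
        for i, j in zip(rows, cols):
            if cost[i, j] >= _GATED_COST:
                continue
            matches.append((tracks[i], detections[j]))
            matched_t.add(i)
            matched_d.add(j)
        unmatched_tracks = [t for i, t in enumerate(tracks) if i not in matched_t]
        unmatched_dets = [d for j, d in enumerate(detections) if j not in matched_d]
        return matches, unmatched_tracks, unmatched_dets


def vote_category(
    track: Track, window: int, previous: Optional[PersonCategory] = None
) -> PersonCategory:
    """Modal six-way category over the last ``window`` frames of a track.

    Tie-break order: the previously voted category (``previous``, defaulting
    to the track's own last vote), then any non-Occluded candidate, then the
    lexicographically first value.
    """
    if not track.category_history:
        raise ValueError("cannot vote on an empty category history")
    if window < 1:
        raise ValueError("vote window must be >= 1")
    last_frame = track.category_history[-1][0]
    recent = [c for f, c in track.category_history if f > last_frame - window]
    counts = Counter(recent)
    top = max(counts.values())
    candidates = sorted((c for c, n in counts.items() if n == top), key=lambda c: c.value)
    if len(candidates) == 1:
        winner = candidates[0]
    else:
        prev = previous if previous is not None else track.last_vote
        if prev in candidates:
            winner = prev
        else:
            non_ocl = [c for c in candidates if "Ocl" not in c.value]
            winner = non_ocl[0] if non_ocl else candidates[0]
    track.last_vote = winner
    return winner


@dataclass(frozen=True)
class MotCounts:
    """CLEAR-MOT error counts over a sequence."""

    gt: int
    fn: int
    fp: int
    idsw: int

    def __post_init__(self) -> None:
        if min(self.gt, self.fn, self.fp, self.idsw) < 0:
            raise ValueError("MOT counts must be non-negative")
        if self.fn > self.gt:
            raise ValueError(f"fn ({self.fn}) cannot exceed gt ({self.gt})")


def compute_mota(counts: MotCounts) -> float:
    """Multiple Object Tracking Accuracy, as a percentage.

    MOTA = 100 * (1 - (FN + FP + IDSW) / GT).
    """
    if counts.gt == 0:
        raise ValueError("MOTA is undefined for gt = 0")
    return 100.0 * (1.0 - (counts.fn + counts.fp + counts.idsw) / counts.gt)


class LabelledBox(NamedTuple):
    frame_index: int
    object_id: int
    box: BoundingBox


def evaluate_tracking(
    ground_truth: Iterable[LabelledBox],
    hypotheses: Iterable[LabelledBox],
    iou_match: float = 0.5,
) -> MotCounts:
    """CLEAR-MOT counting of FN / FP / ID-switches at an IoU gate.

    Per frame, correspondences from the previous frame are kept while they
    still overlap above ``iou_match``; the remainder is matched by a
    minimum-cost assignment on ``1 - IoU``. An identity switch is counted
    when a ground-truth object is matched to a different hypothesis id than
    the one it was last matched to.
    """
    gt_by_frame: dict[int, list[LabelledBox]] = {}
    hyp_by_frame: dict[int, list[LabelledBox]] = {}
    for lb in ground_truth:
        gt_by_frame.setdefault(lb.frame_index, []).append(lb)
    for lb in hypotheses:
        hyp_by_frame.setdefault(lb.frame_index, []).append(lb)

    n_gt = n_fn = n_fp = n_idsw = 0
    last_match: dict[int, int] = {}  # gt id -> hyp id it was last matched to

    for frame in sorted(set(gt_by_frame) | set(hyp_by_frame)):
        gts = sorted(gt_by_frame.get(frame, []), key=lambda b: b.object_id)
        hyps = sorted(hyp_by_frame.get(frame, []), key=lambda b: b.object_id)
        n_gt += len(gts)

        matched_g: set[int] = set()
        matched_h: set[int] = set()
        # keep still-valid correspondences from earlier frames
        hyp_ids = {h.object_id: j for j, h in enumerate(hyps)}
        for i, g in enumerate(gts):
            prev = last_match.get(g.object_id)
            if prev is None or prev not in hyp_ids:
                continue
            j = hyp_ids[prev]
            if j not in matched_h and g.box.iou(hyps[j].box) >= iou_match:
                matched_g.add(i)
                matched_h.add(j)

        free_g = [i for i in range(len(gts)) if i not in matched_g]
        free_h = [j for j in range(len(hyps)) if j not in matched_h]
        if free_g and free_h:
            cost = np.full((len(free_g), len(free_h)), _GATED_COST)
            for a, i in enumerate(free_g):
                for b, j in enumerate(free_h):
                    iou = gts[i].box.iou(hyps[j].box)
                    if iou >= iou_match:
                        cost[a, b] = 1.0 - iou
            rows, cols = linear_sum_assignment(cost)
            for a, b in zip(rows, cols):
                if cost[a, b] >= _GATED_COST:
                    continue
                i, j = free_g[a], free_h[b]
                g, h = gts[i], hyps[j]
                prev = last_match.get(g.object_id)
                if prev is not None and prev != h.object_id:
                    n_idsw += 1
                matched_g.add(i)
                matched_h.add(j)
                last_match[g.object_id] = h.object_id

        n_fn += len(gts) - len(matched_g)
        n_fp += len(hyps) - len(matched_h)

    return MotCounts(gt=n_gt, fn=n_fn, fp=n_fp, idsw=n_idsw)
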