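"""Synthetic thermal office scenes with full ground truth.

Generates everything the pipeline consumes — thermal frames, detections,
keypoint skeletons, optical-flow fields — together with the ground truth
they were rendered from, so every stage can be tested without a camera,
detector, pose network, or flow tool.

Persons are rendered as warm elliptical blobs on a uniform background: a
torso ellipse at the clothes-surface temperature, a head disc at the skin
temperature, and forearm discs at skin temperature for short sleeves
(clothes temperature when the sleeve covers the arm). Sensor noise is
Gaussian with a sigma comparable to the radiometric quantization step
(which dithers the quantizer, so region means are unbiased), and every
pixel is quantized to the 0.08 °C step of the emulated 384x288 sensor.

Behaviour scripts drive sinusoidal box-center and box-scale kinematics and
analytic flow fields (per-frame displacement mapped to the 127-offset 8-bit
encoding). Five scripts are provided: ``still_sit``, ``still_stand``
(activity level low), ``gesture_stand`` (moderate), ``stretch_stand`` and
``walk`` (high).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import yaml

from .activity import (
    ActivityFeatures,
    BoxTrajectory,
    FlowField,
    center_spread,
    flow_intensity_window,
    scale_spread,
)
from .core import (
    BoundingBox,
    Detection,
    Keypoint,
    PersonCategory,
    Posture,
    SleeveStatus,
    ThermalFrame,
    compose_category,
)
from .icl import compute_icl

__all__ = [
    "BEHAVIORS",
    "BEHAVIOR_LEVEL",
    "PersonScript",
    "SceneScript",
    "GroundTruth",
    "SceneData",
    "generate_scene",
    "generate_activity_dataset",
]

#: (center amplitude px, scale amplitude px, flow deviation grayscale) per script
_KINEMATICS = {
    "still_sit": (0.4, 0.4, 1.2),
    "still_stand": (0.4, 0.4, 1.2),
    "gesture_stand": (2.5, 3.0, 7.0),
    "stretch_stand": (7.0, 9.0, 18.0),
    "walk": (16.0, 6.0, 22.0),
}
BEHAVIORS = tuple(_KINEMATICS)

#: activity-intensity level of each standing behaviour script
BEHAVIOR_LEVEL = {
    "still_sit": "low",
    "still_stand": "low",
    "gesture_stand": "moderate",
    "stretch_stand": "high",
    "walk": "high",
}


@dataclass
class PersonScript:
    """Behaviour and surface temperatures for one synthetic person."""

    behavior: str = "still_sit"
    sleeve_status: SleeveStatus = SleeveStatus.SHORT
    skin_temperature: float = 34.7
    clothes_temperature: float = 33.4
    center: Optional[tuple[float, float]] = None  # default: spread across the frame
    occluded_keypoints: tuple[str, ...] = ()  # these get scores below any threshold

    def __post_init__(self) -> None:
        if self.behavior not in BEHAVIORS:
            raise ValueError(f"unknown behavior {self.behavior!r}; expected one of {BEHAVIORS}")
        self.sleeve_status = SleeveStatus(self.sleeve_status)

    @property
    def posture(self) -> Posture:
        return Posture.SIT if self.behavior.endswith("_sit") else Posture.STAND

    @property
    def category(self) -> PersonCategory:
        return compose_category(self.sleeve_status, self.posture)


@dataclass
class SceneScript:
    """Full specification of a synthetic scene.

    The defaults emulate the study conditions: a 384x288 sensor at 21 fps
    with 0.08 °C radiometric resolution, an indoor (background) temperature
    of 22 °C, and the skin / clothes surface temperatures measured for a
    lightly dressed office occupant (≈34.7 / 33.4 °C).
    """

    persons: list[PersonScript] = field(default_factory=lambda: [PersonScript()])
    background_temperature: float = 22.0
    frame_shape: tuple[int, int] = (288, 384)  # rows, cols for a 384x288 sensor
    n_frames: int = 210
    fps: float = 21.0
    seed: int = 0
    sensor_noise_sigma: float = 0.08  # °C; ~NETD, also dithers the quantizer
    quantization_step: float = 0.08  # °C
    jitter_sigma: float = 0.0  # detection box jitter, px
    fp_rate: float = 0.0  # false positives per frame
    fn_rate: float = 0.0  # per-detection drop probability
    keypoint_score_mean: float = 0.9
    keypoint_score_sigma: float = 0.04
    flow_gain: float = 6.0  # grayscale units per pixel of displacement
    render_thermal: bool = True

    def __post_init__(self) -> None:
        for name in ("fp_rate", "fn_rate"):
            if not (0.0 <= getattr(self, name) <= 1.0):
                raise ValueError(f"{name} must be in [0, 1]")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SceneScript":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        persons = [PersonScript(**p) for p in raw.pop("persons", [{}])]
        if "frame_shape" in raw:
            raw["frame_shape"] = tuple(raw["frame_shape"])
        return cls(persons=persons, **raw)


@dataclass
class GroundTruth:
    """Everything the scene was rendered from."""

    boxes_by_frame: list[list[tuple[int, BoundingBox]]]  # (person_id, box)
    keypoints_by_frame: list[list[list[Keypoint]]]  # per frame, per person
    categories: dict[int, PersonCategory]
    skin_temperatures: dict[int, float]
    clothes_temperatures: dict[int, float]
    background_temperature: float
    activity_levels: dict[int, str]
    true_icl: dict[int, float]


@dataclass
class SceneData:
    script: SceneScript
    thermal_frames: list[ThermalFrame]
    detections_by_frame: list[list[Detection]]
    keypoints_by_frame: list[list[list[Keypoint]]]
    flows: list[FlowField]
    ground_truth: GroundTruth


def _base_geometry(script: SceneScript, person: PersonScript, idx: int) -> tuple[float, float, float, float]:
    rows, cols = script.frame_shape
    if person.posture is Posture.STAND:
        w0, h0 = 46.0, 110.0
        cy0 = rows * 0.52
    else:
        w0, h0 = 50.0, 82.0
        cy0 = rows * 0.60
    if person.center is not None:
        cx0, cy0 = person.center
    else:
        cx0 = cols * (idx + 1) / (len(script.persons) + 1)
    return cx0, cy0, w0, h0


def _keypoints_for_box(box: BoundingBox, scores: dict[str, float]) -> list[Keypoint]:
    cx, _ = box.center
    x, y, w, h = box.x, box.y, box.w, box.h
    layout = {
        "nose": (cx, y + 0.10 * h),
        "left_shoulder": (cx - 0.18 * w, y + 0.22 * h),
        "right_shoulder": (cx + 0.18 * w, y + 0.22 * h),
        "left_elbow": (cx - 0.26 * w, y + 0.42 * h),
        "right_elbow": (cx + 0.26 * w, y + 0.42 * h),
        "left_wrist": (cx - 0.28 * w, y + 0.60 * h),
        "right_wrist": (cx + 0.28 * w, y + 0.60 * h),
    }
    return [Keypoint(name, u, v, scores[name]) for name, (u, v) in layout.items()]


def _paint_ellipse(canvas: np.ndarray, cu: float, cv: float, au: float, av: float, value: float) -> None:
    rows, cols = canvas.shape
    r0, r1 = max(0, int(cv - av) - 1), min(rows, int(cv + av) + 2)
    c0, c1 = max(0, int(cu - au) - 1), min(cols, int(cu + au) + 2)
    if r0 >= r1 or c0 >= c1:
        return
    vv, uu = np.mgrid[r0:r1, c0:c1]
    mask = ((uu - cu) / au) ** 2 + ((vv - cv) / av) ** 2 <= 1.0
    canvas[r0:r1, c0:c1][mask] = value


def _render_frame(script: SceneScript, boxes: Sequence[tuple[PersonScript, BoundingBox]], rng: np.random.Generator) -> ThermalFrame:
    rows, cols = script.frame_shape
    canvas = np.full((rows, cols), script.background_temperature, dtype=np.float64)
    for person, box in boxes:
        cx, _ = box.center
        x, y, w, h = box.x, box.y, box.w, box.h
        # torso covers shoulders and elbows
        _paint_ellipse(canvas, cx, y + 0.45 * h, 0.30 * w, 0.32 * h, person.clothes_temperature)
        # forearms: bare skin for short sleeves, covered otherwise
        arm_temp = (
            person.skin_temperature
            if person.sleeve_status is SleeveStatus.SHORT
            else person.clothes_temperature
        )
        for sign in (-1.0, 1.0):
            _paint_ellipse(canvas, cx + sign * 0.27 * w, y + 0.51 * h, 4.0, 4.0, arm_temp)
        # head disc around the nose
        _paint_ellipse(canvas, cx, y + 0.10 * h, 0.09 * h, 0.09 * h, person.skin_temperature)
    canvas += rng.normal(0.0, script.sensor_noise_sigma, canvas.shape)
    step = script.quantization_step
    canvas = np.round(canvas / step) * step
    return ThermalFrame(canvas, quantization_step=step)


def generate_scene(script: SceneScript) -> SceneData:
    """Render a fully-labelled scene; the same seed is bit-reproducible."""
    rng = np.random.default_rng(script.seed)
    rows, cols = script.frame_shape
    n = script.n_frames

    # base geometry, with a packing check
    bases = [_base_geometry(script, p, i) for i, p in enumerate(script.persons)]
    base_boxes = [BoundingBox(cx - w / 2, cy - h / 2, w, h) for cx, cy, w, h in bases]
    for i in range(len(base_boxes)):
        for j in range(i + 1, len(base_boxes)):
            if base_boxes[i].iou(base_boxes[j]) > 0.3:
                raise ValueError(
                    f"persons {i} and {j} overlap beyond the packing limit "
                    f"(IoU > 0.3); spread their centers"
                )

    # per-person kinematic parameters (amplitudes jittered, random phases)
    t = np.arange(n, dtype=float)
    person_tracks: list[tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]] = []
    person_flow_dev: list[tuple[np.ndarray, np.ndarray]] = []
    for i, person in enumerate(script.persons):
        cx0, cy0, w0, h0 = bases[i]
        ca, sa, fd = _KINEMATICS[person.behavior]
        ca *= rng.uniform(0.7, 1.3)
        sa *= rng.uniform(0.7, 1.3)
        fd *= rng.uniform(0.7, 1.3)
        freqs = rng.uniform(0.15, 0.45, size=6)  # Hz
        phases = rng.uniform(0.0, 2.0 * np.pi, size=6)
        arg = 2.0 * np.pi * t / script.fps
        cx = cx0 + ca * np.sin(arg * freqs[0] + phases[0])
        cy = cy0 + 0.4 * ca * np.sin(arg * freqs[1] + phases[1])
        w = np.maximum(w0 + sa * np.sin(arg * freqs[2] + phases[2]), 8.0)
        h = np.maximum(h0 + 0.8 * sa * np.sin(arg * freqs[3] + phases[3]), 8.0)
        person_tracks.append((cx, cy, w, h))
        dev_h = script.flow_gain * np.diff(cx, prepend=cx[0]) + fd * np.sin(
            arg * freqs[4] + phases[4]
        )
        dev_v = script.flow_gain * np.diff(cy, prepend=cy[0]) + fd * np.sin(
            arg * freqs[5] + phases[5]
        )
        person_flow_dev.append((dev_h, dev_v))

    boxes_by_frame: list[list[tuple[int, BoundingBox]]] = []
    keypoints_by_frame: list[list[list[Keypoint]]] = []
    detections_by_frame: list[list[Detection]] = []
    flows: list[FlowField] = []
    thermal_frames: list[ThermalFrame] = []

    for f in range(n):
        frame_boxes: list[tuple[int, BoundingBox]] = []
        frame_kps: list[list[Keypoint]] = []
        frame_dets: list[Detection] = []
        flow_h = np.full((rows, cols), 127, dtype=np.uint8)
        flow_v = np.full((rows, cols), 127, dtype=np.uint8)

        for i, person in enumerate(script.persons):
            cx, cy, w, h = (arr[f] for arr in person_tracks[i])
            box = BoundingBox(cx - w / 2.0, cy - h / 2.0, w, h)
            frame_boxes.append((i + 1, box))

            scores = {}
            for name in (
                "nose", "left_shoulder", "right_shoulder",
                "left_elbow", "right_elbow", "left_wrist", "right_wrist",
            ):
                if name in person.occluded_keypoints:
                    scores[name] = 0.05
                else:
                    scores[name] = float(
                        np.clip(
                            rng.normal(script.keypoint_score_mean, script.keypoint_score_sigma),
                            0.0,
                            1.0,
                        )
                    )
            frame_kps.append(_keypoints_for_box(box, scores))

            # analytic flow inside the box
            dev_h, dev_v = person_flow_dev[i]
            rs = slice(max(0, int(box.y)), min(rows, int(box.y + box.h)))
            cs = slice(max(0, int(box.x)), min(cols, int(box.x + box.w)))
            flow_h[rs, cs] = np.uint8(np.clip(round(127.0 + dev_h[f]), 0, 255))
            flow_v[rs, cs] = np.uint8(np.clip(round(127.0 + dev_v[f]), 0, 255))

            # corrupted detection
            if rng.uniform() >= script.fn_rate:
                jx, jy = rng.normal(0.0, script.jitter_sigma, size=2) if script.jitter_sigma > 0 else (0.0, 0.0)
                det_box = BoundingBox(box.x + jx, box.y + jy, box.w, box.h)
                frame_dets.append(
                    Detection(
                        frame_index=f,
                        box=det_box,
                        category=person.category,
                        confidence=float(rng.uniform(0.85, 0.99)),
                    )
                )

        if rng.uniform() < script.fp_rate:
            fw, fh = rng.uniform(30, 60), rng.uniform(60, 120)
            fx = rng.uniform(0, cols - fw)
            fy = rng.uniform(0, rows - fh)
            frame_dets.append(
                Detection(
                    frame_index=f,
                    box=BoundingBox(fx, fy, fw, fh),
                    category=PersonCategory.OCL_STAND,
                    confidence=float(rng.uniform(0.3, 0.6)),
                )
            )

        boxes_by_frame.append(frame_boxes)
        keypoints_by_frame.append(frame_kps)
        detections_by_frame.append(frame_dets)
        flows.append(FlowField(horizontal=flow_h, vertical=flow_v))
        if script.render_thermal:
            thermal_frames.append(
                _render_frame(script, [(script.persons[pid - 1], b) for pid, b in frame_boxes], rng)
            )

    gt = GroundTruth(
        boxes_by_frame=boxes_by_frame,
        keypoints_by_frame=keypoints_by_frame,
        categories={i + 1: p.category for i, p in enumerate(script.persons)},
        skin_temperatures={i + 1: p.skin_temperature for i, p in enumerate(script.persons)},
        clothes_temperatures={i + 1: p.clothes_temperature for i, p in enumerate(script.persons)},
        background_temperature=script.background_temperature,
        activity_levels={i + 1: BEHAVIOR_LEVEL[p.behavior] for i, p in enumerate(script.persons)},
        true_icl={
            i + 1: compute_icl(
                p.skin_temperature, p.clothes_temperature, script.background_temperature
            )
            for i, p in enumerate(script.persons)
        },
    )
    return SceneData(
        script=script,
        thermal_frames=thermal_frames,
        detections_by_frame=detections_by_frame,
        keypoints_by_frame=keypoints_by_frame,
        flows=flows,
        ground_truth=gt,
    )


_LEVEL_BEHAVIORS = {
    "low": ("still_stand",),
    "moderate": ("gesture_stand",),
    "high": ("stretch_stand", "walk"),
}


def generate_activity_dataset(
    n_per_level: int, seed: int, window_frames: int = 210
) -> list[tuple[ActivityFeatures, str]]:
    """Labelled (features, level) pairs from scripted standing scenes.

    Each sample runs the feature extractor on a fresh single-person scene
    of one activity window; thermal rendering is skipped because only box
    kinematics and flow fields feed the features.
    """
    if n_per_level < 1:
        raise ValueError("n_per_level must be >= 1")
    rng = np.random.default_rng(seed)
    out: list[tuple[ActivityFeatures, str]] = []
    for level in ("low", "moderate", "high"):
        behaviors = _LEVEL_BEHAVIORS[level]
        for k in range(n_per_level):
            behavior = behaviors[k % len(behaviors)]
            scene = generate_scene(
                SceneScript(
                    persons=[PersonScript(behavior=behavior)],
                    n_frames=window_frames,
                    seed=int(rng.integers(0, 2**31 - 1)),
                    render_thermal=False,
                )
            )
            boxes = [b for [(pid, b)] in scene.ground_truth.boxes_by_frame]
            traj = BoxTrajectory(frames=list(range(window_frames)), boxes=boxes)
            feats = ActivityFeatures(
                center_spread=center_spread(traj),
                scale_spread=scale_spread(traj),
                flow_intensity=flow_intensity_window(scene.flows, boxes),
                window_frames=window_frames,
            )
            out.append((feats, level))
    return out
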