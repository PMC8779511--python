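"""Shared domain types, category taxonomy, and pipeline configuration.

Coordinate conventions used throughout the package:

* images are indexed ``(row, col)`` but points are expressed as ``(u, v)``
  pixel coordinates with ``u`` horizontal and ``v`` vertical,
* boxes are 0-based, top-left origin, half-open ``[x, x+w) x [y, y+h)``,
* keypoints live in continuous pixel coordinates and are rounded to the
  nearest integer pixel only when a temperature is sampled.
"""

from __future__ import annotations

import dataclasses
import enum
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import yaml

__all__ = [
    "SleeveStatus",
    "Posture",
    "PersonCategory",
    "BoundingBox",
    "Detection",
    "Keypoint",
    "KEYPOINT_NAMES",
    "COCO17_INDEX",
    "ThermalFrame",
    "PipelineConfig",
    "decompose_category",
    "compose_category",
    "CATEGORY_CODES",
    "CODE_TO_CATEGORY",
]


class SleeveStatus(str, enum.Enum):
    """Clothing status visible on the upper body."""

    LONG = "Long"
    SHORT = "Short"
    OCCLUDED = "Occluded"


class Posture(str, enum.Enum):
    SIT = "Sit"
    STAND = "Stand"


class PersonCategory(str, enum.Enum):
    """Six-way detector category: sleeve status x key posture."""

    LONG_SIT = "LongSit"
    SHORT_SIT = "ShortSit"
    OCL_SIT = "OclSit"
    LONG_STAND = "LongStand"
    SHORT_STAND = "ShortStand"
    OCL_STAND = "OclStand"


#: Integer codes used in the MOT-CSV ``class`` column (documented in README).
CATEGORY_CODES: Mapping[PersonCategory, int] = {
    PersonCategory.LONG_SIT: 1,
    PersonCategory.SHORT_SIT: 2,
    PersonCategory.OCL_SIT: 3,
    PersonCategory.LONG_STAND: 4,
    PersonCategory.SHORT_STAND: 5,
    PersonCategory.OCL_STAND: 6,
}
CODE_TO_CATEGORY: Mapping[int, PersonCategory] = {
    code: cat for cat, code in CATEGORY_CODES.items()
}

_DECOMPOSITION: Mapping[PersonCategory, tuple[SleeveStatus, Posture]] = {
    PersonCategory.LONG_SIT: (SleeveStatus.LONG, Posture.SIT),
    PersonCategory.SHORT_SIT: (SleeveStatus.SHORT, Posture.SIT),
    PersonCategory.OCL_SIT: (SleeveStatus.OCCLUDED, Posture.SIT),
    PersonCategory.LONG_STAND: (SleeveStatus.LONG, Posture.STAND),
    PersonCategory.SHORT_STAND: (SleeveStatus.SHORT, Posture.STAND),
    PersonCategory.OCL_STAND: (SleeveStatus.OCCLUDED, Posture.STAND),
}


def decompose_category(category: PersonCategory) -> tuple[SleeveStatus, Posture]:
    """Split a six-way person category into its (sleeve status, posture) pair."""
    try:
        category = PersonCategory(category)
    except ValueError:
        raise ValueError(f"unknown person category: {category!r}") from None
    return _DECOMPOSITION[category]


def compose_category(sleeve: SleeveStatus, posture: Posture) -> PersonCategory:
    """Inverse of :func:`decompose_category`."""
    for cat, pair in _DECOMPOSITION.items():
        if pair == (SleeveStatus(sleeve), Posture(posture)):
            return cat
    raise ValueError(f"no category for {sleeve!r}, {posture!r}")


@dataclass(frozen=True)
class BoundingBox:
    """Axis-aligned box in pixel coordinates, half-open on both axes."""

    x: float
    y: float
    w: float
    h: float

    def __post_init__(self) -> None:
        if not (self.w > 0 and self.h > 0):
            raise ValueError(f"box width/height must be positive, got w={self.w}, h={self.h}")

    @property
    def center(self) -> tuple[float, float]:
        return (self.x + self.w / 2.0, self.y + self.h / 2.0)

    @property
    def half_extent(self) -> tuple[float, float]:
        """Upper-right corner after centering the box at the origin: (w/2, h/2)."""
        return (self.w / 2.0, self.h / 2.0)

    @property
    def area(self) -> float:
        return self.w * self.h

    def iou(self, other: "BoundingBox") -> float:
        """Intersection-over-union with another box."""
        ix = max(0.0, min(self.x + self.w, other.x + other.w) - max(self.x, other.x))
        iy = max(0.0, min(self.y + self.h, other.y + other.h) - max(self.y, other.y))
        inter = ix * iy
        if inter <= 0.0:
            return 0.0
        return inter / (self.area + other.area - inter)

    def contains(self, u: float, v: float) -> bool:
        return self.x <= u < self.x + self.w and self.y <= v < self.y + self.h


@dataclass(frozen=True)
class Detection:
    """One detector output: a box plus the six-way category and a confidence."""

    frame_index: int
    box: BoundingBox
    category: PersonCategory
    confidence: float = 1.0

    def __post_init__(self) -> None:
        if self.frame_index < 0:
            raise ValueError(f"frame_index must be >= 0, got {self.frame_index}")
        if not (0.0 <= self.confidence <= 1.0):
            raise ValueError(f"confidence must be in [0, 1], got {self.confidence}")


#: The seven keypoints that influence skin/clothes region localization.
KEYPOINT_NAMES = (
    "nose",
    "left_shoulder",
    "right_shoulder",
    "left_elbow",
    "right_elbow",
    "left_wrist",
    "right_wrist",
)

#: Positions of the supported keypoints in the COCO-17 skeleton layout.
COCO17_INDEX: Mapping[str, int] = {
    "nose": 0,
    "left_shoulder": 5,
    "right_shoulder": 6,
    "left_elbow": 7,
    "right_elbow": 8,
    "left_wrist": 9,
    "right_wrist": 10,
}


@dataclass(frozen=True)
class Keypoint:
    """A named 2-D body keypoint with a detection confidence score."""

    name: str
    u: float
    v: float
    score: float

    def __post_init__(self) -> None:
        if self.name not in KEYPOINT_NAMES:
            raise ValueError(
                f"unsupported keypoint {self.name!r}; expected one of {KEYPOINT_NAMES}"
            )
        if not (0.0 <= self.score <= 1.0):
            raise ValueError(f"keypoint score must be in [0, 1], got {self.score}")


class ThermalFrame:
    """A 2-D matrix of pixel temperatures in degrees Celsius.

    Parameters
    ----------
    values
        2-D array of temperatures (°C).
    quantization_step
        Radiometric resolution of the sensor; 0.08 °C for the emulated
        Gobi-384 camera.
    """

    def __init__(self, values: np.ndarray, quantization_step: float = 0.08):
        values = np.asarray(values, dtype=np.float64)
        if values.ndim != 2:
            raise ValueError(f"thermal frame must be 2-D, got shape {values.shape}")
        if not np.all(np.isfinite(values)):
            raise ValueError("thermal frame contains non-finite temperatures")
        if quantization_step <= 0:
            raise ValueError("quantization_step must be positive")
        self.values = values
        self.quantization_step = float(quantization_step)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape  # (rows, cols) = (height, width)

    def temperature_at(self, u: float, v: float, patch: int = 1) -> float:
        """Temperature at continuous pixel coordinates ``(u, v)``.

        The point is rounded to the nearest integer pixel and clamped to the
        frame. ``patch`` (odd) averages a patch x patch neighbourhood; the
        default samples the single nearest pixel.
        """
        if patch < 1 or patch % 2 == 0:
            raise ValueError(f"patch must be a positive odd integer, got {patch}")
        rows, cols = self.values.shape
        ci = min(max(int(round(u)), 0), cols - 1)
        ri = min(max(int(round(v)), 0), rows - 1)
        if patch == 1:
            return float(self.values[ri, ci])
        half = patch // 2
        r0, r1 = max(0, ri - half), min(rows, ri + half + 1)
        c0, c1 = max(0, ci - half), min(cols, ci + half + 1)
        return float(self.values[r0:r1, c0:c1].mean())


@dataclass
class PipelineConfig:
    """Pipeline-wide parameters.

    All window lengths are in frames; the defaults derive from a 21 fps
    camera, for which a 10 s activity window is 210 frames.
    """

    fps: float = 21.0
    keypoint_conf_threshold: float = 0.6
    icl_window_frames: int = 6300  # 5 min at 21 fps
    activity_window_frames: int = 210  # 10 s at 21 fps
    vote_window_frames: int = 63  # ~3 s at 21 fps
    h_coefficient: float = 8.6  # human heat-transfer coefficient, W/(m^2 K)
    m_sitting: float = 72.5  # W/m^2
    m_levels: tuple[float, float, float] = (75.0, 125.0, 174.0)  # (Ml, Mm, Mh), W/m^2
    icl_epsilon: float = 0.1  # °C; ill-conditioning guard on (Tc - To)
    sample_patch: int = 1  # odd patch size for temperature sampling

    def __post_init__(self) -> None:
        for name in ("icl_window_frames", "activity_window_frames", "vote_window_frames"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not (0.0 < self.keypoint_conf_threshold < 1.0):
            raise ValueError("keypoint_conf_threshold must be in (0, 1)")
        ml, mm, mh = self.m_levels
        if not (ml < mm < mh):
            raise ValueError(f"m_levels must be strictly increasing, got {self.m_levels}")
        if self.h_coefficient <= 0:
            raise ValueError("h_coefficient must be positive")
        if self.fps <= 0:
            raise ValueError("fps must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        """Load a config from a flat YAML key-value file.

        Unknown keys are rejected so typos fail loudly.
        """
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise ValueError(f"config file {path} must contain a mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "m_levels" in raw:
            raw["m_levels"] = tuple(float(v) for v in raw["m_levels"])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        data = dataclasses.asdict(self)
        data["m_levels"] = list(data["m_levels"])
        Path(path).write_text(yaml.safe_dump(data, sort_keys=True))

    def resolved(self) -> dict:
        """Plain-dict view of the resolved configuration (for run manifests)."""
        data = dataclasses.asdict(self)
        data["m_levels"] = list(data["m_levels"])
        return data
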