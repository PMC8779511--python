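"""Readers and writers for the interchange formats, plus run manifests.

Formats
-------
* Detections and tracks: MOTChallenge CSV dialect
  ``frame,id,x,y,w,h,conf,class,vis`` with 1-based frame numbers in files
  (0-based internally); ``class`` is the six-way person category as an
  integer code 1-6; ``id`` is -1 for raw detections.
* Keypoints: per-frame JSON in the COCO-17 index layout (0 nose, 5/6
  shoulders, 7/8 elbows, 9/10 wrists; other indices are ignored), each
  keypoint a ``[u, v, score]`` triple.
* Thermal stacks: multi-page float32 TIFF of °C values, or an ``.npz``
  archive with a ``frames`` array. Integer-coded stacks are accepted with
  an explicit scale/offset and converted on read.
* Flow fields: per-frame pairs of 8-bit grayscale rasters
  ``flow_x_<frame>.png`` / ``flow_y_<frame>.png`` (1-based frame numbers).

All CSV output uses '.' decimals, UTF-8 and LF endings; floats are written
with ``repr`` so round-trips are lossless.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import imageio.v3 as iio
import numpy as np
import tifffile

from . import __version__
from .activity import FlowField
from .core import (
    BoundingBox,
    CATEGORY_CODES,
    CODE_TO_CATEGORY,
    COCO17_INDEX,
    Detection,
    Keypoint,
    PersonCategory,
    ThermalFrame,
)
from .tracking import LabelledBox

__all__ = [
    "read_detections",
    "write_detections",
    "TrackRow",
    "read_tracks",
    "write_tracks",
    "read_keypoints",
    "write_keypoints",
    "read_thermal_stack",
    "write_thermal_stack",
    "read_flow_fields",
    "write_flow_fields",
    "RunManifest",
]

_MOT_COLUMNS = 9


def _parse_mot_row(parts: list[str], path: Path, lineno: int):
    if len(parts) != _MOT_COLUMNS:
        raise ValueError(
            f"{path}:{lineno}: expected {_MOT_COLUMNS} comma-separated fields "
            f"(frame,id,x,y,w,h,conf,class,vis), got {len(parts)}"
        )
    try:
        frame = int(parts[0])
        obj_id = int(parts[1])
        x, y, w, h, conf = (float(v) for v in parts[2:7])
        code = int(parts[7])
        vis = float(parts[8])
    except ValueError as exc:
        raise ValueError(f"{path}:{lineno}: malformed row: {exc}") from None
    if frame < 1:
        raise ValueError(f"{path}:{lineno}: frame numbers in files are 1-based, got {frame}")
    if code not in CODE_TO_CATEGORY:
        raise ValueError(
            f"{path}:{lineno}: unknown class {code}; valid codes are 1-6 "
            f"({', '.join(f'{c}={cat.value}' for cat, c in CATEGORY_CODES.items())})"
        )
    return frame - 1, obj_id, BoundingBox(x, y, w, h), conf, CODE_TO_CATEGORY[code], vis


def read_detections(path: str | Path) -> list[Detection]:
    """Read raw detections from a MOT-dialect CSV; an empty file is legal."""
    path = Path(path)
    out: list[Detection] = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        frame, _id, box, conf, category, _vis = _parse_mot_row(
            line.split(","), path, lineno
        )
        out.append(Detection(frame_index=frame, box=box, category=category, confidence=conf))
    return out


def write_detections(detections: Sequence[Detection], path: str | Path) -> None:
    lines = []
    for d in detections:
        code = CATEGORY_CODES[d.category]
        b = d.box
        lines.append(
            f"{d.frame_index + 1},-1,{float(b.x)!r},{float(b.y)!r},{float(b.w)!r},"
            f"{float(b.h)!r},{float(d.confidence)!r},{code},1"
        )
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""), newline="\n")


@dataclass(frozen=True)
class TrackRow:
    """One confirmed-track box in a tracks CSV."""

    frame_index: int
    track_id: int
    box: BoundingBox
    category: PersonCategory
    confidence: float = 1.0


def write_tracks(rows: Sequence[TrackRow], path: str | Path) -> None:
    lines = []
    for r in sorted(rows, key=lambda r: (r.frame_index, r.track_id)):
        code = CATEGORY_CODES[r.category]
        b = r.box
        lines.append(
            f"{r.frame_index + 1},{r.track_id},{float(b.x)!r},{float(b.y)!r},"
            f"{float(b.w)!r},{float(b.h)!r},{float(r.confidence)!r},{code},1"
        )
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""), newline="\n")


def read_tracks(path: str | Path) -> list[TrackRow]:
    path = Path(path)
    out: list[TrackRow] = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        frame, obj_id, box, conf, category, _vis = _parse_mot_row(
            line.split(","), path, lineno
        )
        out.append(TrackRow(frame, obj_id, box, category, conf))
    return out


def tracks_as_labelled_boxes(rows: Sequence[TrackRow]) -> list[LabelledBox]:
    return [LabelledBox(r.frame_index, r.track_id, r.box) for r in rows]


# -- keypoints ---------------------------------------------------------------

_N_COCO = 17
_INDEX_TO_NAME = {idx: name for name, idx in COCO17_INDEX.items()}


def write_keypoints(
    keypoints_by_frame: Sequence[Sequence[Sequence[Keypoint]]], path: str | Path
) -> None:
    """Write per-frame skeletons as COCO-17 JSON (frame_index is 0-based)."""
    frames = []
    for f, skeletons in enumerate(keypoints_by_frame):
        skels = []
        for skel in skeletons:
            arr = [[0.0, 0.0, 0.0] for _ in range(_N_COCO)]
            for kp in skel:
                arr[COCO17_INDEX[kp.name]] = [kp.u, kp.v, kp.score]
            skels.append(arr)
        frames.append({"frame_index": f, "skeletons": skels})
    Path(path).write_text(
        json.dumps({"format": "coco17-keypoints/1", "frames": frames}), newline="\n"
    )


def read_keypoints(path: str | Path) -> dict[int, list[list[Keypoint]]]:
    """Read COCO-17 keypoint JSON into frame -> list of skeletons.

    Only the seven indices relevant to region localization are kept;
    zero-score entries are dropped.
    """
    path = Path(path)
    try:
        blob = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise ValueError(f"{path}: not valid JSON: {exc}") from None
    if not isinstance(blob, dict) or "frames" not in blob:
        raise ValueError(f"{path}: expected an object with a 'frames' list")
    out: dict[int, list[list[Keypoint]]] = {}
    for entry in blob["frames"]:
        f = int(entry["frame_index"])
        skeletons = []
        for arr in entry.get("skeletons", []):
            if len(arr) != _N_COCO:
                raise ValueError(
                    f"{path}: frame {f}: skeleton has {len(arr)} entries, expected {_N_COCO}"
                )
            skel = []
            for idx, (u, v, score) in enumerate(arr):
                name = _INDEX_TO_NAME.get(idx)
                if name is None or score <= 0.0:
                    continue
                skel.append(Keypoint(name, float(u), float(v), float(score)))
            skeletons.append(skel)
        out[f] = skeletons
    return out


# -- thermal stacks ----------------------------------------------------------


def write_thermal_stack(frames: Sequence[ThermalFrame], path: str | Path) -> None:
    """Write a multi-page float32 TIFF (or .npz) of °C values."""
    path = Path(path)
    stack = np.stack([f.values for f in frames]).astype(np.float32)
    if path.suffix == ".npz":
        np.savez_compressed(path, frames=stack)
    else:
        tifffile.imwrite(path, stack, photometric="minisblack")


def read_thermal_stack(
    path: str | Path,
    quantization_step: float = 0.08,
    scale: Optional[float] = None,
    offset: float = 0.0,
) -> list[ThermalFrame]:
    """Read a thermal stack; integer-coded stacks need an explicit scale.

    For an integer dtype the temperatures are ``raw * scale + offset`` (°C).
    """
    path = Path(path)
    if path.suffix == ".npz":
        with np.load(path) as npz:
            if "frames" not in npz:
                raise ValueError(f"{path}: .npz archive must contain a 'frames' array")
            stack = npz["frames"]
    else:
        stack = tifffile.imread(path)
    if stack.ndim == 2:
        stack = stack[None, :, :]
    if stack.ndim != 3:
        raise ValueError(f"{path}: expected a stack of 2-D frames, got shape {stack.shape}")
    if np.issubdtype(stack.dtype, np.integer):
        if scale is None:
            raise ValueError(
                f"{path}: integer-coded stack requires an explicit scale (°C per count)"
            )
        stack = stack.astype(np.float64) * scale + offset
    return [ThermalFrame(frame, quantization_step=quantization_step) for frame in stack]


# -- flow fields -------------------------------------------------------------


def write_flow_fields(flows: Sequence[FlowField], out_dir: str | Path) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for f, flow in enumerate(flows, start=1):
        iio.imwrite(out_dir / f"flow_x_{f:06d}.png", flow.horizontal.astype(np.uint8))
        iio.imwrite(out_dir / f"flow_y_{f:06d}.png", flow.vertical.astype(np.uint8))


def read_flow_fields(in_dir: str | Path) -> list[FlowField]:
    in_dir = Path(in_dir)
    xs = sorted(in_dir.glob("flow_x_*.png"))
    if not xs:
        raise ValueError(f"{in_dir}: no flow_x_*.png files found")
    flows = []
    for xpath in xs:
        ypath = in_dir / xpath.name.replace("flow_x_", "flow_y_")
        if not ypath.exists():
            raise ValueError(f"{in_dir}: missing vertical counterpart for {xpath.name}")
        flows.append(FlowField(horizontal=iio.imread(xpath), vertical=iio.imread(ypath)))
    return flows


# -- run manifest ------------------------------------------------------------


def _sha256(path: Path) -> str:
    digest = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            digest.update(chunk)
    return digest.hexdigest()


@dataclass
class RunManifest:
    """Provenance record emitted for every CLI run."""

    command: str
    config: dict = field(default_factory=dict)
    inputs: dict = field(default_factory=dict)  # path -> sha256
    seed: Optional[int] = None
    record_counts: dict = field(default_factory=dict)
    notes: list[str] = field(default_factory=list)
    tool_version: str = __version__

    def add_input(self, path: str | Path) -> None:
        p = Path(path)
        self.inputs[str(p)] = _sha256(p)

    def write(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True) + "\n",
            newline="\n",
        )
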