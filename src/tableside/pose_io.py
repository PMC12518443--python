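"""Pose, region and classification file formats.

Pose streams arrive as COCO-style keypoint result JSON: a list of records,
one per detected person per frame, each with a 51-value ``keypoints`` array
(17 triplets of x, y, confidence in the standard COCO keypoint order) and a
pose-level ``score``. The ``tracked`` dialect adds an integer ``track_id``.
Regions are a small JSON object mapping region names to vertex lists.
Classification output is plain CSV so it round-trips losslessly.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Optional

from .errors import FormatError, UsageError
from .geometry import Region, RegionSet

#: The 17 COCO keypoint names, in canonical order.
COCO_KEYPOINT_NAMES: tuple[str, ...] = (
    "nose",
    "left_eye", "right_eye",
    "left_ear", "right_ear",
    "left_shoulder", "right_shoulder",
    "left_elbow", "right_elbow",
    "left_wrist", "right_wrist",
    "left_hip", "right_hip",
    "left_knee", "right_knee",
    "left_ankle", "right_ankle",
)

KEYPOINT_INDEX = {name: i for i, name in enumerate(COCO_KEYPOINT_NAMES)}

#: Head keypoints: the nose, eyes and ears.
HEAD_KEYPOINTS = ("nose", "left_eye", "right_eye", "left_ear", "right_ear")
SHOULDER_KEYPOINTS = ("left_shoulder", "right_shoulder")
WRIST_KEYPOINTS = ("left_wrist", "right_wrist")


@dataclass(frozen=True)
class Keypoint:
    """One anatomical landmark on one frame.

    ``detected=False`` encodes a keypoint absent from the input (confidence
    exactly 0 or missing coordinates); its coordinates are then meaningless.
    """

    name: str
    x: float
    y: float
    confidence: float
    detected: bool = True

    def __post_init__(self) -> None:
        if self.name not in KEYPOINT_INDEX:
            raise FormatError(f"unknown keypoint name {self.name!r}")
        if self.detected and not (0.0 <= self.confidence <= 1.0):
            raise FormatError(
                f"keypoint {self.name!r}: confidence {self.confidence} outside [0, 1]"
            )

    @classmethod
    def undetected(cls, name: str) -> "Keypoint":
        return cls(name=name, x=math.nan, y=math.nan, confidence=0.0, detected=False)


@dataclass(frozen=True)
class PoseDetection:
    """All 17 keypoints of one person on one frame."""

    frame: int
    keypoints: tuple[Keypoint, ...]
    score: float = 1.0
    track_id: Optional[int] = None

    def __post_init__(self) -> None:
        if self.frame < 0:
            raise FormatError(f"negative frame index {self.frame}")
        if len(self.keypoints) != 17:
            raise FormatError(f"pose needs exactly 17 keypoints, got {len(self.keypoints)}")
        names = [k.name for k in self.keypoints]
        if names != list(COCO_KEYPOINT_NAMES):
            raise FormatError("keypoints must appear once each, in COCO order")

    def keypoint(self, name: str) -> Keypoint:
        return self.keypoints[KEYPOINT_INDEX[name]]

    def detected_keypoints(self) -> list[Keypoint]:
        return [k for k in self.keypoints if k.detected]

    def bbox_area(self) -> float:
        """Area of the tight bounding box around detected keypoints (px^2)."""
        pts = self.detected_keypoints()
        if not pts:
            return 0.0
        xs = [k.x for k in pts]
        ys = [k.y for k in pts]
        return (max(xs) - min(xs)) * (max(ys) - min(ys))


@dataclass(frozen=True)
class PoseStream:
    """All pose detections of one recording, ordered by frame."""

    detections: tuple[PoseDetection, ...]
    n_frames: int
    fps_nominal: float = 25.0

    def __post_init__(self) -> None:
        frames = [d.frame for d in self.detections]
        if any(f >= self.n_frames for f in frames):
            raise FormatError("detection frame index beyond n_frames")
        if any(a > b for a, b in zip(frames, frames[1:])):
            raise FormatError("detections must be ordered by frame")

    def __iter__(self) -> Iterator[PoseDetection]:
        return iter(self.detections)

    def __len__(self) -> int:
        return len(self.detections)

    @property
    def is_tracked(self) -> bool:
        return all(d.track_id is not None for d in self.detections)

    def by_track(self) -> dict[int, dict[int, PoseDetection]]:
        """Group a tracked stream as track_id -> {frame -> pose}."""
        if not self.is_tracked:
            raise UsageError("stream has untracked detections; run build_tracklets first")
        tracks: dict[int, dict[int, PoseDetection]] = {}
        for det in self.detections:
            tracks.setdefault(det.track_id, {})[det.frame] = det  # type: ignore[arg-type]
        return tracks


def _pose_from_record(rec: dict, index: int, dialect: str) -> PoseDetection:
    try:
        frame = int(rec.get("frame", rec.get("image_id")))
        raw = rec["keypoints"]
    except (KeyError, TypeError) as exc:
        raise FormatError(f"record {index}: missing frame/image_id or keypoints") from exc
    if len(raw) != 51:
        raise FormatError(f"record {index}: keypoint array length {len(raw)} != 51")
    kps = []
    for i, name in enumerate(COCO_KEYPOINT_NAMES):
        x, y, conf = raw[3 * i], raw[3 * i + 1], raw[3 * i + 2]
        if x is None or y is None or conf is None or float(conf) == 0.0:
            kps.append(Keypoint.undetected(name))
        else:
            kps.append(Keypoint(name, float(x), float(y), float(conf)))
    track_id = None
    if dialect == "tracked":
        if "track_id" not in rec:
            raise FormatError(f"record {index}: tracked dialect requires track_id")
        track_id = int(rec["track_id"])
    return PoseDetection(
        frame=frame,
        keypoints=tuple(kps),
        score=float(rec.get("score", 1.0)),
        track_id=track_id,
    )


def read_pose_stream(path: str | Path, dialect: str = "coco_result") -> PoseStream:
    """Read a pose stream from COCO-style keypoint JSON.

    Parameters
    ----------
    path
        JSON file: ``{"n_frames": int, "fps": float, "poses": [...]}`` or a
        bare list of pose records (n_frames then inferred as max frame + 1).
    dialect
        ``"coco_result"`` (untracked) or ``"tracked"`` (adds ``track_id``).
    """
    if dialect not in ("coco_result", "tracked"):
        raise UsageError(f"unknown pose dialect {dialect!r}")
    path = Path(path)
    try:
        payload = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise FormatError(f"{path}: malformed JSON: {exc}") from exc
    if isinstance(payload, dict):
        records = payload.get("poses", [])
        n_frames = payload.get("n_frames")
        fps = float(payload.get("fps", 25.0))
    else:
        records, n_frames, fps = payload, None, 25.0
    poses = []
    for i, rec in enumerate(records):
        try:
            poses.append(_pose_from_record(rec, i, dialect))
        except FormatError:
            raise
        except (TypeError, ValueError) as exc:
            raise FormatError(f"record {i}: {exc}") from exc
    poses.sort(key=lambda d: (d.frame, d.track_id if d.track_id is not None else -1))
    if n_frames is None:
        n_frames = (max((d.frame for d in poses), default=-1)) + 1
    return PoseStream(detections=tuple(poses), n_frames=int(n_frames), fps_nominal=fps)


def write_pose_stream(stream: PoseStream, path: str | Path) -> None:
    """Write a stream back to JSON (tracked dialect if track IDs present)."""
    records = []
    for det in stream:
        flat: list[float] = []
        for kp in det.keypoints:
            if kp.detected:
                flat.extend([kp.x, kp.y, kp.confidence])
            else:
                flat.extend([0.0, 0.0, 0.0])
        rec = {"frame": det.frame, "keypoints": flat, "score": det.score}
        if det.track_id is not None:
            rec["track_id"] = det.track_id
        records.append(rec)
    payload = {"n_frames": stream.n_frames, "fps": stream.fps_nominal, "poses": records}
    Path(path).write_text(json.dumps(payload))


def read_regions(path: str | Path) -> RegionSet:
    """Read the wrists/shoulders/head region polygons from JSON."""
    path = Path(path)
    try:
        payload = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise FormatError(f"{path}: malformed JSON: {exc}") from exc
    if not isinstance(payload, dict):
        raise FormatError(f"{path}: region file must be a JSON object")
    return RegionSet.from_dict(payload)


def write_regions(regions: RegionSet, path: str | Path) -> None:
    payload = {
        name: [list(v) for v in regions[name].vertices]
        for name in ("wrists", "shoulders", "head")
    }
    Path(path).write_text(json.dumps(payload))


# --- classification CSV -----------------------------------------------------

_BASE_COLUMNS = ("frame", "track_id", "still", "by_table", "interacting")


def write_classifications(records: Iterable, path: str | Path) -> None:
    """Write ClassificationRecords as CSV (one boolean column per subpose).

    Reading the file back with :func:`read_classifications` reproduces the
    record list exactly.
    """
    records = list(records)
    subpose_cols: list[str] = []
    if records:
        first = records[0]
        subpose_cols = [f"still_{n}" for n in first.subpose_still] + [
            f"pos_{n}" for n in first.subpose_positioned
        ]
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(list(_BASE_COLUMNS) + subpose_cols)
        for rec in records:
            row = [rec.frame, rec.track_id, rec.still, rec.by_table, rec.interacting]
            row += [rec.subpose_still[n] for n in rec.subpose_still]
            row += [rec.subpose_positioned[n] for n in rec.subpose_positioned]
            writer.writerow(row)


def read_classifications(path: str | Path) -> list:
    from .interaction_rules import ClassificationRecord

    records = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise FormatError(f"{path}: empty classification file (no header)")
        still_cols = [c for c in reader.fieldnames if c.startswith("still_")]
        pos_cols = [c for c in reader.fieldnames if c.startswith("pos_")]
        for row in reader:
            records.append(
                ClassificationRecord(
                    frame=int(row["frame"]),
                    track_id=int(row["track_id"]),
                    still=row["still"] == "True",
                    by_table=row["by_table"] == "True",
                    subpose_still={c[len("still_"):]: row[c] == "True" for c in still_cols},
                    subpose_positioned={c[len("pos_"):]: row[c] == "True" for c in pos_cols},
                )
            )
    return records


def read_interval_annotations(path: str | Path) -> list:
    """Read interval annotations (person_id,start_frame,end_frame,label CSV)."""
    from .annotations import ActivityInterval

    out = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            out.append(
                ActivityInterval(
                    person_id=str(row["person_id"]),
                    start_frame=int(row["start_frame"]),
                    end_frame=int(row["end_frame"]),
                    label=row["label"],
                )
            )
    return out


def write_interval_annotations(intervals: Iterable, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["person_id", "start_frame", "end_frame", "label"])
        for iv in intervals:
            writer.writerow([iv.person_id, iv.start_frame, iv.end_frame, iv.label])
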