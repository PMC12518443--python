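"""Rule-based classification of operating-table interaction.

A person is assumed to interact with the operating table when they are
simultaneously *still* and *by the table*:

* **Movement.** For each keypoint the displacement magnitude (px) over a
  span of ``f_motion`` frames is computed within its tracklet. A movement
  subpose (shoulders, head) is still when at least ``M_keypoint`` of its
  keypoints show displacement below ``tau_m``; keypoints that are
  undetected, below the confidence gate ``gamma_m``, or lacking a
  displacement endpoint are assumed still. A pose is still when at least
  ``M_subpose`` of its movement subposes are.

* **Position.** Three position subposes (wrists, shoulders, head — the
  head being nose, eyes and ears) are checked against the corresponding
  annotated region. A subpose is positioned when at least ``P_keypoint``
  of its keypoints lie inside the region; keypoints below the confidence
  gate ``gamma_p`` are not counted in any region. A pose is by the table
  when at least ``P_subpose`` subposes are positioned.

Constraining only subsets of subposes and keypoints compensates for
undetected keypoints; legs are excluded (worst detection rates) and arm
movement is ignored (arms legitimately move during table interaction).
All thresholds compare strictly: displacement exactly at ``tau_m`` is not
"below", confidence exactly at a gate counts as reliable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional

from .errors import UsageError
from .geometry import RegionSet
from .pose_io import (
    HEAD_KEYPOINTS,
    SHOULDER_KEYPOINTS,
    WRIST_KEYPOINTS,
    PoseDetection,
    PoseStream,
)

#: Qualitative display categories for a classified pose.
CATEGORY_INTERACTING = "interacting"
CATEGORY_POSITIONED_BUT_MOVING = "positioned-but-moving"
CATEGORY_WRONG_POSITION = "wrong-position"


@dataclass(frozen=True)
class MovementSubposeSpec:
    """One movement subpose: which keypoints, how many must be still."""

    name: str
    keypoints: tuple[str, ...]
    min_still_keypoints: int
    displacement_threshold: float  # tau_m, px over f_motion frames
    confidence_threshold: float    # gamma_m

    def __post_init__(self) -> None:
        if not (1 <= self.min_still_keypoints <= len(self.keypoints)):
            raise UsageError(
                f"subpose {self.name!r}: min_still_keypoints must be in "
                f"[1, {len(self.keypoints)}]"
            )
        if self.displacement_threshold <= 0:
            raise UsageError(f"subpose {self.name!r}: displacement threshold must be > 0")


@dataclass(frozen=True)
class PositionSubposeSpec:
    """One position subpose: which keypoints, how many must be in-region."""

    region_name: str
    keypoints: tuple[str, ...]
    min_inside_keypoints: int
    confidence_threshold: float  # gamma_p

    def __post_init__(self) -> None:
        if not (1 <= self.min_inside_keypoints <= len(self.keypoints)):
            raise UsageError(
                f"subpose {self.region_name!r}: min_inside_keypoints must be in "
                f"[1, {len(self.keypoints)}]"
            )


def _default_movement_subposes() -> tuple[MovementSubposeSpec, ...]:
    return (
        MovementSubposeSpec("shoulders", SHOULDER_KEYPOINTS, 1, 17.5, 0.3),
        MovementSubposeSpec("head", HEAD_KEYPOINTS, 1, 17.5, 0.3),
    )


def _default_position_subposes() -> tuple[PositionSubposeSpec, ...]:
    return (
        PositionSubposeSpec("wrists", WRIST_KEYPOINTS, 1, 0.3),
        PositionSubposeSpec("shoulders", SHOULDER_KEYPOINTS, 1, 0.3),
        PositionSubposeSpec("head", HEAD_KEYPOINTS, 2, 0.15),
    )


@dataclass(frozen=True)
class InteractionParams:
    """All movement and position parameters of the interaction rule.

    The no-argument instance is the published default configuration:
    f_motion = 5 frames; still when >= 1 of {shoulders, head} subposes is
    still (each needing 1 keypoint below 17.5 px at confidence gate 0.3);
    by the table when >= 2 of {wrists, shoulders, head} subposes are
    positioned (wrists/shoulders: 1 keypoint at gate 0.3; head: 2 of
    nose/eyes/ears at gate 0.15).
    """

    f_motion: int = 5
    movement_subposes: tuple[MovementSubposeSpec, ...] = field(
        default_factory=_default_movement_subposes
    )
    min_still_subposes: int = 1    # M_subpose
    position_subposes: tuple[PositionSubposeSpec, ...] = field(
        default_factory=_default_position_subposes
    )
    min_positioned_subposes: int = 2  # P_subpose

    def __post_init__(self) -> None:
        if self.f_motion < 1:
            raise UsageError("f_motion must be a positive frame span")
        if not (1 <= self.min_still_subposes <= len(self.movement_subposes)):
            raise UsageError("min_still_subposes out of range")
        if not (1 <= self.min_positioned_subposes <= len(self.position_subposes)):
            raise UsageError("min_positioned_subposes out of range")

    @classmethod
    def from_toml(cls, path) -> "InteractionParams":
        """Load parameters from a TOML file; omitted keys keep defaults.

        Recognised top-level keys: ``f_motion``, ``M_subpose``,
        ``P_subpose``; per-subpose tables ``movement.<name>`` with
        ``keypoints``, ``M_keypoint``, ``tau_m``, ``gamma_m`` and
        ``position.<region>`` with ``keypoints``, ``P_keypoint``,
        ``gamma_p``.
        """
        import tomllib

        with open(path, "rb") as fh:
            cfg = tomllib.load(fh)
        defaults = cls()
        movement = []
        for spec in defaults.movement_subposes:
            sub = cfg.get("movement", {}).get(spec.name, {})
            movement.append(MovementSubposeSpec(
                spec.name,
                tuple(sub.get("keypoints", spec.keypoints)),
                int(sub.get("M_keypoint", spec.min_still_keypoints)),
                float(sub.get("tau_m", spec.displacement_threshold)),
                float(sub.get("gamma_m", spec.confidence_threshold)),
            ))
        position = []
        for spec in defaults.position_subposes:
            sub = cfg.get("position", {}).get(spec.region_name, {})
            position.append(PositionSubposeSpec(
                spec.region_name,
                tuple(sub.get("keypoints", spec.keypoints)),
                int(sub.get("P_keypoint", spec.min_inside_keypoints)),
                float(sub.get("gamma_p", spec.confidence_threshold)),
            ))
        return cls(
            f_motion=int(cfg.get("f_motion", defaults.f_motion)),
            movement_subposes=tuple(movement),
            min_still_subposes=int(cfg.get("M_subpose", defaults.min_still_subposes)),
            position_subposes=tuple(position),
            min_positioned_subposes=int(cfg.get("P_subpose", defaults.min_positioned_subposes)),
        )


@dataclass(frozen=True)
class ClassificationRecord:
    """Audit-trail verdict for one pose detection."""

    frame: int
    track_id: int
    still: bool
    by_table: bool
    subpose_still: dict[str, bool]
    subpose_positioned: dict[str, bool]

    @property
    def interacting(self) -> bool:
        return self.still and self.by_table

    @property
    def category(self) -> str:
        if self.interacting:
            return CATEGORY_INTERACTING
        if self.by_table:
            return CATEGORY_POSITIONED_BUT_MOVING
        return CATEGORY_WRONG_POSITION


def keypoint_displacement(
    track: Mapping[int, PoseDetection],
    frame: int,
    keypoint: str,
    f_motion: int,
) -> Optional[float]:
    """Net displacement (px) of one keypoint over the f_motion span.

    Distance between the keypoint position at ``frame`` and at
    ``frame - f_motion`` within the same tracklet; ``None`` when either
    endpoint is missing (track absent there, or keypoint undetected).
    """
    if frame not in track:
        raise UsageError(f"frame {frame} not in track")
    earlier = track.get(frame - f_motion)
    if earlier is None:
        return None
    now_kp = track[frame].keypoint(keypoint)
    then_kp = earlier.keypoint(keypoint)
    if not (now_kp.detected and then_kp.detected):
        return None
    return math.hypot(now_kp.x - then_kp.x, now_kp.y - then_kp.y)


def classify_subpose_still(
    pose: PoseDetection,
    track: Mapping[int, PoseDetection],
    spec: MovementSubposeSpec,
    f_motion: int,
) -> bool:
    """Is this movement subpose still?

    A keypoint counts as still when its displacement is defined and below
    ``tau_m`` (strictly), or when it is undetected, below the confidence
    gate at the current frame, or its displacement is undefined — missing
    evidence defaults to stillness.
    """
    still_count = 0
    for name in spec.keypoints:
        kp = pose.keypoint(name)
        if not kp.detected or kp.confidence < spec.confidence_threshold:
            still_count += 1
            continue
        disp = keypoint_displacement(track, pose.frame, name, f_motion)
        if disp is None or disp < spec.displacement_threshold:
            still_count += 1
    return still_count >= spec.min_still_keypoints


def classify_pose_still(
    pose: PoseDetection,
    track: Mapping[int, PoseDetection],
    params: InteractionParams | None = None,
) -> tuple[bool, dict[str, bool]]:
    """Pose-level stillness plus the per-subpose verdicts."""
    params = params or InteractionParams()
    verdicts = {
        spec.name: classify_subpose_still(pose, track, spec, params.f_motion)
        for spec in params.movement_subposes
    }
    return sum(verdicts.values()) >= params.min_still_subposes, verdicts


def classify_subpose_position(
    pose: PoseDetection,
    regions: RegionSet,
    spec: PositionSubposeSpec,
) -> bool:
    """Is this position subpose inside its annotated region?

    A keypoint counts only when detected, at or above the confidence gate,
    and inside the region polygon (boundary-inclusive even-odd rule).
    """
    region = regions[spec.region_name]
    inside = 0
    for name in spec.keypoints:
        kp = pose.keypoint(name)
        if kp.detected and kp.confidence >= spec.confidence_threshold \
                and region.contains(kp.x, kp.y):
            inside += 1
    return inside >= spec.min_inside_keypoints


def classify_pose_position(
    pose: PoseDetection,
    regions: RegionSet,
    params: InteractionParams | None = None,
) -> tuple[bool, dict[str, bool]]:
    """Pose-level by-the-table verdict plus the per-subpose verdicts."""
    params = params or InteractionParams()
    verdicts = {
        spec.region_name: classify_subpose_position(pose, regions, spec)
        for spec in params.position_subposes
    }
    return sum(verdicts.values()) >= params.min_positioned_subposes, verdicts


def classify_interaction(
    stream: PoseStream,
    regions: RegionSet,
    params: InteractionParams | None = None,
) -> list[ClassificationRecord]:
    """Classify every detection of a tracked stream.

    Returns one record per pose detection, ordered by frame then track.
    interacting == still AND by_table; the record's ``category`` property
    exposes the three-way display category.
    """
    params = params or InteractionParams()
    tracks = stream.by_track()  # raises UsageError on untracked streams
    records = []
    for det in stream:
        track = tracks[det.track_id]
        still, m_verdicts = classify_pose_still(det, track, params)
        by_table, p_verdicts = classify_pose_position(det, regions, params)
        records.append(ClassificationRecord(
            frame=det.frame,
            track_id=det.track_id,  # type: ignore[arg-type]
            still=still,
            by_table=by_table,
            subpose_still=m_verdicts,
            subpose_positioned=p_verdicts,
        ))
    return records
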