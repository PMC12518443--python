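"""Synthetic operating-room scenes with ground-truth labels.

The recordings this package was designed around cannot be shared, so this
module generates pose streams with the same statistical structure: several
actors following scripted waypoint trajectories around a table area, some
standing still inside the annotated regions (staff at the table), some
loitering far away (spectators), with per-keypoint Gaussian jitter,
confidence sampling, keypoint dropout (occlusion, low light) and marked
low-light intervals with elevated dropout.

Each actor is a rigid upright 17-keypoint stick figure scaled by a body
scale (the shoulder width in px); gait articulation is deliberately absent
because the interaction rules read only positions and confidences of the
head, shoulders and wrists. Ground truth is defined operationally: the
interaction rules run on the noise-free scripted stream, so "truth" means
"what the rules say about perfect data", and recovery tests measure only
the effect of the noise model.

All randomness flows from one integer seed. The random draws per actor and
frame have fixed shapes regardless of the noise parameters, so raising the
dropout probability with the seed held fixed can only drop more keypoints,
never fewer (coupled sampling).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .annotations import ActivityInterval, PhaseInterval
from .errors import UsageError
from .geometry import Region, RegionSet
from .interaction_rules import ClassificationRecord, InteractionParams, classify_interaction
from .pose_io import COCO_KEYPOINT_NAMES, Keypoint, PoseDetection, PoseStream

#: Upright stick-figure template: keypoint offsets from the shoulder
#: midpoint, in units of shoulder width (x rightward, y downward).
SKELETON_TEMPLATE: dict[str, tuple[float, float]] = {
    "nose": (0.00, -0.45),
    "left_eye": (0.05, -0.52), "right_eye": (-0.05, -0.52),
    "left_ear": (0.12, -0.48), "right_ear": (-0.12, -0.48),
    "left_shoulder": (0.50, 0.00), "right_shoulder": (-0.50, 0.00),
    "left_elbow": (0.65, 0.45), "right_elbow": (-0.65, 0.45),
    "left_wrist": (0.70, 0.90), "right_wrist": (-0.70, 0.90),
    "left_hip": (0.30, 0.95), "right_hip": (-0.30, 0.95),
    "left_knee": (0.33, 1.75), "right_knee": (-0.33, 1.75),
    "left_ankle": (0.35, 2.55), "right_ankle": (-0.35, 2.55),
}

FIXTURE_NAMES = ("quiet_room", "busy_table", "spectators", "lowlight")


@dataclass(frozen=True)
class ActorScript:
    """One actor's scripted trajectory.

    The anchor point (shoulder midpoint) moves linearly between waypoints
    and holds position before the first and after the last. Still intervals
    are intent metadata only — ground truth always comes from running the
    rules on the noise-free stream, so intent and rule verdict may diverge
    (e.g. someone standing still at the table while cleaning).
    """

    actor_id: int
    waypoints: tuple[tuple[int, float, float], ...]
    still_intervals: tuple[tuple[int, int], ...] = ()
    role_tag: str = "staff"
    body_scale: float = 120.0

    def __post_init__(self) -> None:
        if not self.waypoints:
            raise UsageError(f"actor {self.actor_id}: needs at least one waypoint")
        frames = [w[0] for w in self.waypoints]
        if any(a >= b for a, b in zip(frames, frames[1:])):
            raise UsageError(f"actor {self.actor_id}: waypoints must strictly increase in frame")
        lo, hi = frames[0], frames[-1]
        for s, e in self.still_intervals:
            if s < lo or e > hi + 1:
                raise UsageError(
                    f"actor {self.actor_id}: still interval ({s}, {e}) outside "
                    f"waypoint span [{lo}, {hi}]"
                )
        if self.role_tag not in ("staff", "spectator", "patient"):
            raise UsageError(f"actor {self.actor_id}: unknown role {self.role_tag!r}")
        if self.body_scale <= 0:
            raise UsageError(f"actor {self.actor_id}: body_scale must be positive")

    def position(self, frame: int) -> tuple[float, float]:
        """Anchor position at a frame (linear interpolation, clamped ends)."""
        wps = self.waypoints
        if frame <= wps[0][0]:
            return wps[0][1], wps[0][2]
        if frame >= wps[-1][0]:
            return wps[-1][1], wps[-1][2]
        for (f0, x0, y0), (f1, x1, y1) in zip(wps, wps[1:]):
            if f0 <= frame <= f1:
                t = (frame - f0) / (f1 - f0)
                return x0 + t * (x1 - x0), y0 + t * (y1 - y0)
        raise AssertionError("unreachable")

    def keypoint_positions(self, frame: int) -> dict[str, tuple[float, float]]:
        ax, ay = self.position(frame)
        return {
            name: (ax + dx * self.body_scale, ay + dy * self.body_scale)
            for name, (dx, dy) in SKELETON_TEMPLATE.items()
        }


@dataclass(frozen=True)
class NoiseModel:
    """Observation noise applied to the scripted keypoint positions.

    Dropped keypoints are emitted as undetected (confidence exactly 0);
    surviving keypoints get confidence from a clipped normal distribution.
    Low-light intervals raise the dropout probability to
    ``lowlight_dropout_prob`` and depress the confidence mean by
    ``lowlight_conf_penalty``.
    """

    jitter_sigma: float = 2.0
    dropout_prob: float = 0.05
    confidence_mean: float = 0.85
    confidence_sigma: float = 0.10
    lowlight_intervals: tuple[tuple[int, int], ...] = ()
    lowlight_dropout_prob: float = 0.6
    lowlight_conf_penalty: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (self.dropout_prob, self.lowlight_dropout_prob):
            if not (0.0 <= p <= 1.0):
                raise UsageError(f"dropout probability {p} outside [0, 1]")
        if self.jitter_sigma < 0:
            raise UsageError("jitter_sigma must be >= 0")

    def in_lowlight(self, frame: int) -> bool:
        return any(s <= frame < e for s, e in self.lowlight_intervals)

    @classmethod
    def noiseless(cls, seed: int = 0) -> "NoiseModel":
        return cls(jitter_sigma=0.0, dropout_prob=0.0, confidence_mean=1.0,
                   confidence_sigma=0.0, seed=seed)


@dataclass(frozen=True)
class SimulationResult:
    """Everything one simulated recording produces."""

    stream: PoseStream                 # noisy, tracked by actor id
    clean_stream: PoseStream           # noise-free scripted poses
    ground_truth: list[ClassificationRecord]
    activities: list[ActivityInterval]
    phases: list[PhaseInterval]
    regions: RegionSet


def _clean_pose(script: ActorScript, frame: int) -> PoseDetection:
    pos = script.keypoint_positions(frame)
    kps = tuple(
        Keypoint(name, pos[name][0], pos[name][1], 1.0)
        for name in COCO_KEYPOINT_NAMES
    )
    return PoseDetection(frame=frame, keypoints=kps, score=1.0, track_id=script.actor_id)


def _noisy_pose(
    script: ActorScript,
    frame: int,
    noise: NoiseModel,
    u_drop: np.ndarray,
    jitter: np.ndarray,
    conf_z: np.ndarray,
) -> PoseDetection:
    pos = script.keypoint_positions(frame)
    lowlight = noise.in_lowlight(frame)
    p_drop = noise.lowlight_dropout_prob if lowlight else noise.dropout_prob
    conf_mean = noise.confidence_mean - (noise.lowlight_conf_penalty if lowlight else 0.0)
    kps = []
    for i, name in enumerate(COCO_KEYPOINT_NAMES):
        if u_drop[i] < p_drop:
            kps.append(Keypoint.undetected(name))
            continue
        x = pos[name][0] + noise.jitter_sigma * jitter[i, 0]
        y = pos[name][1] + noise.jitter_sigma * jitter[i, 1]
        conf = float(np.clip(conf_mean + noise.confidence_sigma * conf_z[i], 0.01, 1.0))
        kps.append(Keypoint(name, float(x), float(y), conf))
    score = float(np.mean([k.confidence for k in kps]))
    return PoseDetection(frame=frame, keypoints=tuple(kps), score=score, track_id=script.actor_id)


def default_phases(n_frames: int) -> list[PhaseInterval]:
    """Split a recording into the four workflow phases (15/20/45/20 %)."""
    edges = [0, int(0.15 * n_frames), int(0.35 * n_frames), int(0.80 * n_frames), n_frames]
    return [
        PhaseInterval(phase, edges[i], edges[i + 1])
        for i, phase in enumerate(("induction", "preparation", "surgery", "recovery"))
        if edges[i] < edges[i + 1]
    ]


def _script_activities(script: ActorScript, n_frames: int) -> list[ActivityInterval]:
    pid = f"actor_{script.actor_id}"
    if script.role_tag == "patient":
        return []  # annotators mark personnel activities only
    if script.role_tag == "spectator":
        return [ActivityInterval(pid, 0, n_frames, "observing", "other")]
    out = []
    cursor = 0
    for s, e in sorted(script.still_intervals):
        s, e = max(0, s), min(n_frames, e)
        if cursor < s:
            out.append(ActivityInterval(pid, cursor, s, "walking", "other"))
        if s < e:
            out.append(ActivityInterval(pid, s, e, "operating", "patient_interaction"))
        cursor = max(cursor, e)
    if cursor < n_frames:
        out.append(ActivityInterval(pid, cursor, n_frames, "walking", "other"))
    return out


def simulate(
    scripts: Sequence[ActorScript],
    regions: RegionSet,
    noise: NoiseModel,
    n_frames: int,
    params: InteractionParams | None = None,
) -> SimulationResult:
    """Render scripts into a noisy pose stream plus ground truth.

    Ground truth is ``classify_interaction`` on the noise-free stream with
    the given (default) rule parameters. Bit-identical output is
    guaranteed for identical (scripts, noise, seed, n_frames).
    """
    params = params or InteractionParams()
    ids = [s.actor_id for s in scripts]
    if len(set(ids)) != len(ids):
        raise UsageError("actor ids must be unique")

    root = np.random.SeedSequence(noise.seed)
    children = root.spawn(len(scripts))

    clean: list[PoseDetection] = []
    noisy: list[PoseDetection] = []
    for script, child in zip(scripts, children):
        rng = np.random.default_rng(child)
        # Fixed draw shapes -> dropout coupling across parameter settings.
        u_drop = rng.random((n_frames, 17))
        jitter = rng.standard_normal((n_frames, 17, 2))
        conf_z = rng.standard_normal((n_frames, 17))
        for frame in range(n_frames):
            clean.append(_clean_pose(script, frame))
            noisy.append(_noisy_pose(
                script, frame, noise, u_drop[frame], jitter[frame], conf_z[frame]
            ))

    key = lambda d: (d.frame, d.track_id)
    clean_stream = PoseStream(tuple(sorted(clean, key=key)), n_frames)
    noisy_stream = PoseStream(tuple(sorted(noisy, key=key)), n_frames)
    ground_truth = classify_interaction(clean_stream, regions, params)

    activities: list[ActivityInterval] = []
    for script in scripts:
        activities.extend(_script_activities(script, n_frames))

    return SimulationResult(
        stream=noisy_stream,
        clean_stream=clean_stream,
        ground_truth=ground_truth,
        activities=activities,
        phases=default_phases(n_frames),
        regions=regions,
    )


# --- canned fixtures --------------------------------------------------------

def _box(x0: float, y0: float, x1: float, y1: float, name: str) -> Region:
    return Region(name, ((x0, y0), (x1, y0), (x1, y1), (x0, y1)))


def table_regions(cx: float = 960.0, cy: float = 500.0, half_w: float = 320.0,
                  scale: float = 120.0) -> RegionSet:
    """Loose rectangular regions around a table for template-scaled actors.

    Margins are generous (about half a body scale) the way hand-drawn
    annotations are, so a few px of jitter never crosses a boundary.
    """
    m = 0.5 * scale
    return RegionSet(
        wrists=_box(cx - half_w, cy + 0.9 * scale - m, cx + half_w, cy + 0.9 * scale + m, "wrists"),
        shoulders=_box(cx - half_w, cy - m, cx + half_w, cy + m, "shoulders"),
        head=_box(cx - half_w, cy - 0.52 * scale - m, cx + half_w, cy - 0.40 * scale + m, "head"),
    )


def make_fixture(name: str, seed: int = 0) -> tuple[list[ActorScript], RegionSet, NoiseModel, int]:
    """Deterministic canned scenes for tests, docs and the CLI.

    quiet_room
        One staff member standing still at the table for 2000 frames.
    busy_table
        Two staff at the table (one leaves to fetch equipment mid-way) and
        one walking circulator, 3000 frames.
    spectators
        Two staff at the table plus two spectators far away; scripted
        per-detection interaction fraction 0.5.
    lowlight
        One staff at the table with a marked low-light interval of
        elevated dropout in the middle third, 2400 frames.
    """
    cy = 500.0
    table_x = 960.0
    far = (300.0, 900.0)
    if name == "quiet_room":
        n = 2000
        scripts = [ActorScript(0, ((0, table_x, cy), (n - 1, table_x, cy)),
                               still_intervals=((0, n),))]
        noise = NoiseModel(seed=seed)
    elif name == "busy_table":
        n = 3000
        scripts = [
            ActorScript(0, ((0, table_x - 150, cy), (n - 1, table_x - 150, cy)),
                        still_intervals=((0, n),)),
            # stands at table, walks to a far corner at frame 1200, returns at 2000
            ActorScript(1, (
                (0, table_x + 150, cy), (1200, table_x + 150, cy),
                (1320, far[0], far[1]), (1900, far[0], far[1]),
                (2020, table_x + 150, cy), (n - 1, table_x + 150, cy),
            ), still_intervals=((0, 1200), (2020, n))),
            # circulator pacing the room, never at the table
            ActorScript(2, (
                (0, 200.0, 200.0), (740, 1700.0, 200.0),
                (1480, 1700.0, 950.0), (2220, 200.0, 950.0), (n - 1, 220.0, 210.0),
            ), role_tag="staff"),
        ]
        noise = NoiseModel(seed=seed)
    elif name == "spectators":
        n = 2000
        scripts = [
            ActorScript(0, ((0, table_x - 150, cy), (n - 1, table_x - 150, cy)),
                        still_intervals=((0, n),)),
            ActorScript(1, ((0, table_x + 150, cy), (n - 1, table_x + 150, cy)),
                        still_intervals=((0, n),)),
            ActorScript(2, ((0, 250.0, 880.0), (n - 1, 250.0, 880.0)), role_tag="spectator"),
            ActorScript(3, ((0, 1650.0, 880.0), (n - 1, 1650.0, 880.0)), role_tag="spectator"),
        ]
        noise = NoiseModel(seed=seed)
    elif name == "lowlight":
        n = 2400
        scripts = [ActorScript(0, ((0, table_x, cy), (n - 1, table_x, cy)),
                               still_intervals=((0, n),))]
        noise = NoiseModel(seed=seed, lowlight_intervals=((n // 3, 2 * n // 3),))
    else:
        raise UsageError(f"unknown fixture {name!r}; expected one of {FIXTURE_NAMES}")
    return scripts, table_regions(), noise, n
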