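"""Frame-to-frame pose association on object keypoint similarity.

Operating-room staff dress alike, so appearance features are useless for
re-identification; association here is purely geometric. The tracker is a
deliberately simple two-stage greedy matcher in the BYTE style: confident
detections are matched to live tracks first, the remainder get a second
chance, unmatched confident detections open new tracks, and tracklets that
never span two consecutive frames are discarded (they are overwhelmingly
single-frame false positives of a low-threshold detector). There is no
motion model and a track missed on one frame terminates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .errors import UsageError
from .pose_io import COCO_KEYPOINT_NAMES, PoseDetection, PoseStream

#: Standard COCO per-keypoint falloff constants (k_i), indexed by name.
COCO_KEYPOINT_CONSTANTS: dict[str, float] = dict(zip(COCO_KEYPOINT_NAMES, (
    0.026, 0.025, 0.025, 0.035, 0.035,
    0.079, 0.079, 0.072, 0.072, 0.062, 0.062,
    0.107, 0.107, 0.087, 0.087, 0.089, 0.089,
)))


@dataclass(frozen=True)
class OksParams:
    """Parameters of the object-keypoint-similarity kernel."""

    per_keypoint_constant: dict[str, float] = field(
        default_factory=lambda: dict(COCO_KEYPOINT_CONSTANTS)
    )
    scale_mode: str = "bbox_area"

    def __post_init__(self) -> None:
        if any(k <= 0 for k in self.per_keypoint_constant.values()):
            raise UsageError("all per-keypoint constants must be positive")
        if self.scale_mode != "bbox_area":
            raise UsageError(f"unknown scale mode {self.scale_mode!r}")


@dataclass(frozen=True)
class TrackerParams:
    """Two-stage association thresholds and the tracklet-length floor."""

    high_conf_threshold: float = 0.6
    low_conf_threshold: float = 0.1
    oks_match_threshold: float = 0.3
    min_consecutive_frames: int = 2

    def __post_init__(self) -> None:
        if self.low_conf_threshold > self.high_conf_threshold:
            raise UsageError("low_conf_threshold must not exceed high_conf_threshold")
        if self.min_consecutive_frames < 2:
            raise UsageError("min_consecutive_frames must be >= 2")


def oks(a: PoseDetection, b: PoseDetection, params: OksParams | None = None) -> float:
    """Object keypoint similarity between two poses, in [0, 1].

    OKS = mean over keypoints detected in both poses of
    exp(-d_i^2 / (2 s^2 k_i^2)), with d_i the pixel distance between
    matching keypoints, s^2 the bounding-box area of ``a`` and k_i the
    per-keypoint falloff constant. Keypoints detected in only one pose are
    excluded; an empty intersection yields 0.
    """
    params = params or OksParams()
    if not a.detected_keypoints():
        raise UsageError("OKS undefined: reference pose has no detected keypoints")
    s2 = a.bbox_area()
    total, n = 0.0, 0
    for ka, kb in zip(a.keypoints, b.keypoints):
        if not (ka.detected and kb.detected):
            continue
        d2 = (ka.x - kb.x) ** 2 + (ka.y - kb.y) ** 2
        k = params.per_keypoint_constant[ka.name]
        denom = 2.0 * max(s2, 1e-12) * k * k
        total += math.exp(-d2 / denom)
        n += 1
    return total / n if n else 0.0


def associate_frame(
    active_tracks: list[tuple[int, PoseDetection]],
    detections: list[PoseDetection],
    tparams: TrackerParams | None = None,
    oparams: OksParams | None = None,
    next_track_id: int = 0,
) -> tuple[dict[int, int], list[tuple[int, int]], int]:
    """Greedy two-stage matching of one frame's detections to live tracks.

    Returns ``(matches, new_tracks, next_track_id)`` where ``matches`` maps
    detection index to track_id and ``new_tracks`` lists
    ``(detection index, new track_id)`` pairs. Stage 1 matches detections
    scoring at least ``high_conf_threshold``; stage 2 offers remaining
    tracks to detections scoring at least ``low_conf_threshold``. Pairs are
    taken in descending OKS order, ties broken by lower track_id then lower
    detection index, and accepted when OKS reaches ``oks_match_threshold``.
    Unmatched high-confidence detections start new tracks.
    """
    tparams = tparams or TrackerParams()
    oparams = oparams or OksParams()
    frames = {d.frame for d in detections}
    if len(frames) > 1:
        raise UsageError("associate_frame requires all detections on one frame")

    matches: dict[int, int] = {}
    free_tracks = dict(active_tracks)

    def run_stage(candidates: list[int]) -> None:
        pairs = []
        for di in candidates:
            det = detections[di]
            if not det.detected_keypoints():
                continue
            for tid, last in free_tracks.items():
                sim = oks(det, last, oparams)
                if sim >= tparams.oks_match_threshold:
                    pairs.append((-sim, tid, di))
        pairs.sort()
        used_d: set[int] = set()
        for _, tid, di in pairs:
            if di in used_d or tid not in free_tracks:
                continue
            matches[di] = tid
            used_d.add(di)
            del free_tracks[tid]

    high = [i for i, d in enumerate(detections) if d.score >= tparams.high_conf_threshold]
    low = [
        i for i, d in enumerate(detections)
        if tparams.low_conf_threshold <= d.score < tparams.high_conf_threshold
    ]
    run_stage(high)
    run_stage([i for i in low if i not in matches])

    new_tracks = []
    for di in high:
        if di not in matches:
            new_tracks.append((di, next_track_id))
            next_track_id += 1
    return matches, new_tracks, next_track_id


def build_tracklets(
    stream: PoseStream,
    tparams: TrackerParams | None = None,
    oparams: OksParams | None = None,
) -> PoseStream:
    """Assign track IDs to a pose stream by frame-by-frame association.

    Existing track IDs are ignored and overwritten. Tracklets whose longest
    run of consecutive frames is shorter than ``min_consecutive_frames``
    are removed from the output entirely.
    """
    tparams = tparams or TrackerParams()
    oparams = oparams or OksParams()

    by_frame: dict[int, list[PoseDetection]] = {}
    for det in stream:
        by_frame.setdefault(det.frame, []).append(det)

    active: dict[int, PoseDetection] = {}  # track_id -> last detection
    assigned: list[PoseDetection] = []
    next_id = 0
    for frame in sorted(by_frame):
        dets = by_frame[frame]
        matches, new_tracks, next_id = associate_frame(
            list(active.items()), dets, tparams, oparams, next_id
        )
        new_active: dict[int, PoseDetection] = {}
        for di, tid in matches.items():
            det = PoseDetection(dets[di].frame, dets[di].keypoints, dets[di].score, tid)
            new_active[tid] = det
            assigned.append(det)
        for di, tid in new_tracks:
            det = PoseDetection(dets[di].frame, dets[di].keypoints, dets[di].score, tid)
            new_active[tid] = det
            assigned.append(det)
        active = new_active  # unmatched tracks terminate

    keep = _tracks_meeting_length(assigned, tparams.min_consecutive_frames)
    kept = [d for d in assigned if d.track_id in keep]
    kept.sort(key=lambda d: (d.frame, d.track_id))
    return PoseStream(tuple(kept), n_frames=stream.n_frames, fps_nominal=stream.fps_nominal)


def _tracks_meeting_length(detections: list[PoseDetection], min_run: int) -> set[int]:
    frames_by_track: dict[int, list[int]] = {}
    for det in detections:
        frames_by_track.setdefault(det.track_id, []).append(det.frame)  # type: ignore[arg-type]
    keep = set()
    for tid, frames in frames_by_track.items():
        frames.sort()
        run = best = 1
        for a, b in zip(frames, frames[1:]):
            run = run + 1 if b == a + 1 else 1
            best = max(best, run)
        if best >= min_run:
            keep.add(tid)
    return keep
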