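"""Shared generators for randomized tests.

Everything is driven by explicit numpy Generators so each test seeds its
own randomness and stays reproducible.
"""

from __future__ import annotations

import math

import numpy as np
import pytest

from tableside import (
    COCO_KEYPOINT_NAMES,
    InteractionParams,
    Keypoint,
    PoseDetection,
    PoseStream,
    Region,
    RegionSet,
)


def random_pose(rng: np.random.Generator, frame: int, track_id: int | None = 0,
                center: tuple[float, float] | None = None,
                spread: float = 80.0, dropout: float = 0.2,
                low_conf_prob: float = 0.3) -> PoseDetection:
    """One pose with mixed dropout and confidence levels around a center."""
    if center is None:
        center = (float(rng.uniform(100, 1800)), float(rng.uniform(100, 1000)))
    kps = []
    for name in COCO_KEYPOINT_NAMES:
        if rng.random() < dropout:
            kps.append(Keypoint.undetected(name))
            continue
        x = center[0] + float(rng.normal(0, spread))
        y = center[1] + float(rng.normal(0, spread))
        if rng.random() < low_conf_prob:
            conf = float(rng.uniform(0.01, 0.35))
        else:
            conf = float(rng.uniform(0.35, 1.0))
        kps.append(Keypoint(name, x, y, conf))
    return PoseDetection(frame=frame, keypoints=tuple(kps), score=float(rng.uniform(0.3, 1.0)),
                         track_id=track_id)


def random_track(rng: np.random.Generator, track_id: int = 0, length: int | None = None,
                 start: int = 0, step_px: float = 8.0, **pose_kw) -> dict[int, PoseDetection]:
    """A tracklet of consecutive-frame poses following a random walk."""
    if length is None:
        length = int(rng.integers(1, 12))
    center = (float(rng.uniform(200, 1700)), float(rng.uniform(200, 900)))
    track = {}
    for i in range(length):
        frame = start + i
        track[frame] = random_pose(rng, frame, track_id, center=center, **pose_kw)
        center = (center[0] + float(rng.normal(0, step_px)),
                  center[1] + float(rng.normal(0, step_px)))
    return track


def random_convex_region(rng: np.random.Generator, name: str,
                         center: tuple[float, float] | None = None,
                         radius: float = 250.0, n_vertices: int = 6) -> Region:
    """A random convex polygon (angles sorted around a center)."""
    if center is None:
        center = (float(rng.uniform(400, 1500)), float(rng.uniform(300, 800)))
    angles = np.sort(rng.uniform(0, 2 * math.pi, n_vertices))
    radii = rng.uniform(0.5 * radius, radius, n_vertices)
    verts = tuple(
        (center[0] + r * math.cos(a), center[1] + r * math.sin(a))
        for a, r in zip(angles, radii)
    )
    return Region(name, verts)


def random_region_set(rng: np.random.Generator,
                      center: tuple[float, float] | None = None) -> RegionSet:
    if center is None:
        center = (float(rng.uniform(500, 1400)), float(rng.uniform(300, 800)))
    return RegionSet(
        wrists=random_convex_region(rng, "wrists", center),
        shoulders=random_convex_region(rng, "shoulders", center),
        head=random_convex_region(rng, "head", center),
    )


def stream_from_tracks(tracks: dict[int, dict[int, PoseDetection]],
                       n_frames: int | None = None) -> PoseStream:
    dets = sorted(
        (d for track in tracks.values() for d in track.values()),
        key=lambda d: (d.frame, d.track_id),
    )
    if n_frames is None:
        n_frames = max((d.frame for d in dets), default=-1) + 1
    return PoseStream(tuple(dets), n_frames)


@pytest.fixture
def default_params() -> InteractionParams:
    return InteractionParams()
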