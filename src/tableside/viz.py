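"""Overlay rendering of classified poses.

Each pose skeleton is drawn in one of three colours: interacting with the
table, in the right position but moving too fast to interact, or in the
wrong position. Keypoints below a confidence floor (default 0.2) are not
drawn, though the pose's track ID and detection score are always printed.
Output is file-based PNG; there is no GUI.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping, Optional

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
from matplotlib.patches import Polygon as MplPolygon

from .errors import UsageError
from .geometry import RegionSet
from .interaction_rules import (
    CATEGORY_INTERACTING,
    CATEGORY_POSITIONED_BUT_MOVING,
    CATEGORY_WRONG_POSITION,
    ClassificationRecord,
)
from .pose_io import KEYPOINT_INDEX, PoseDetection

#: Default category colours (configurable; the categories are normative,
#: the hues are not).
DEFAULT_COLORS: dict[str, str] = {
    CATEGORY_INTERACTING: "tab:green",
    CATEGORY_POSITIONED_BUT_MOVING: "tab:orange",
    CATEGORY_WRONG_POSITION: "tab:red",
}

#: Skeleton edges drawn between keypoints (COCO convention).
SKELETON_EDGES: tuple[tuple[str, str], ...] = (
    ("nose", "left_eye"), ("nose", "right_eye"),
    ("left_eye", "left_ear"), ("right_eye", "right_ear"),
    ("left_shoulder", "right_shoulder"),
    ("left_shoulder", "left_elbow"), ("left_elbow", "left_wrist"),
    ("right_shoulder", "right_elbow"), ("right_elbow", "right_wrist"),
    ("left_shoulder", "left_hip"), ("right_shoulder", "right_hip"),
    ("left_hip", "right_hip"),
    ("left_hip", "left_knee"), ("left_knee", "left_ankle"),
    ("right_hip", "right_knee"), ("right_knee", "right_ankle"),
)


def render_overlay(
    frame_size: tuple[int, int],
    poses: list[PoseDetection],
    records: list[ClassificationRecord],
    regions: Optional[RegionSet],
    path: str | Path,
    draw_confidence_min: float = 0.2,
    colors: Optional[Mapping[str, str]] = None,
) -> None:
    """Render one frame's poses, colour-coded by classification category.

    ``poses`` and ``records`` must align one-to-one (same frame and track).
    """
    if len(poses) != len(records):
        raise UsageError("poses and records must align one-to-one")
    for pose, rec in zip(poses, records):
        if pose.frame != rec.frame or pose.track_id != rec.track_id:
            raise UsageError(
                f"pose (frame {pose.frame}, track {pose.track_id}) does not match "
                f"record (frame {rec.frame}, track {rec.track_id})"
            )
    palette = dict(DEFAULT_COLORS)
    if colors:
        palette.update(colors)

    width, height = frame_size
    fig, ax = plt.subplots(figsize=(width / 100, height / 100), dpi=100)
    ax.set_xlim(0, width)
    ax.set_ylim(height, 0)  # image convention: y down
    ax.set_aspect("equal")
    ax.set_facecolor("black")

    if regions is not None:
        for rname, rcolor in (("wrists", "tab:blue"), ("shoulders", "tab:purple"),
                              ("head", "tab:olive")):
            region = regions[rname]
            ax.add_patch(MplPolygon(
                list(region.vertices), closed=True, fill=False,
                edgecolor=rcolor, linewidth=1.0, linestyle="--",
            ))

    for pose, rec in zip(poses, records):
        color = palette[rec.category]
        drawable = {
            k.name: (k.x, k.y) for k in pose.keypoints
            if k.detected and k.confidence >= draw_confidence_min
        }
        for a, b in SKELETON_EDGES:
            if a in drawable and b in drawable:
                (xa, ya), (xb, yb) = drawable[a], drawable[b]
                ax.plot([xa, xb], [ya, yb], color=color, linewidth=1.5)
        if drawable:
            xs, ys = zip(*drawable.values())
            ax.scatter(xs, ys, s=12, color=color, zorder=3)
            label_x, label_y = min(xs), min(ys) - 10
        else:
            # ID and score are printed even when nothing else is drawn
            anchor = [k for k in pose.keypoints if k.detected] or None
            if anchor:
                label_x = min(k.x for k in anchor)
                label_y = min(k.y for k in anchor) - 10
            else:
                label_x, label_y = 10, 20
        ax.text(label_x, label_y, f"id {pose.track_id}  {pose.score:.2f}",
                color=color, fontsize=8)

    ax.axis("off")
    fig.savefig(path, bbox_inches="tight", pad_inches=0)
    plt.close(fig)
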