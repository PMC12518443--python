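"""Region polygons and point containment.

Regions are hand-drawn pixel-space polygons (one each for wrists, shoulders
and head) marking where those body parts must be for a person to interact
with the operating table. Containment uses the even-odd (ray crossing) rule
and is boundary-inclusive, so it stays well defined even for accidentally
self-intersecting hand annotations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .errors import FormatError, GeometryError

logger = logging.getLogger(__name__)

REGION_NAMES = ("wrists", "shoulders", "head")


def point_in_polygon(x: float, y: float, vertices: list[tuple[float, float]]) -> bool:
    """Even-odd containment test, inclusive of the polygon boundary.

    The polygon is implicitly closed (last vertex connects back to the
    first). A point exactly on an edge or vertex counts as inside.
    """
    n = len(vertices)
    inside = False
    for i in range(n):
        x1, y1 = vertices[i]
        x2, y2 = vertices[(i + 1) % n]
        if _on_segment(x, y, x1, y1, x2, y2):
            return True
        # Half-open vertical span avoids double-counting shared vertices.
        if (y1 > y) != (y2 > y):
            x_cross = x1 + (y - y1) * (x2 - x1) / (y2 - y1)
            if x < x_cross:
                inside = not inside
    return inside


def _on_segment(px: float, py: float, x1: float, y1: float, x2: float, y2: float,
                eps: float = 1e-9) -> bool:
    cross = (x2 - x1) * (py - y1) - (y2 - y1) * (px - x1)
    seg_len2 = (x2 - x1) ** 2 + (y2 - y1) ** 2
    if cross * cross > eps * max(seg_len2, 1.0):
        return False
    dot = (px - x1) * (x2 - x1) + (py - y1) * (y2 - y1)
    return -eps <= dot <= seg_len2 + eps


def _segments_intersect(a1, a2, b1, b2) -> bool:
    def orient(p, q, r):
        v = (q[0] - p[0]) * (r[1] - p[1]) - (q[1] - p[1]) * (r[0] - p[0])
        return 0 if v == 0 else (1 if v > 0 else -1)

    o1, o2 = orient(a1, a2, b1), orient(a1, a2, b2)
    o3, o4 = orient(b1, b2, a1), orient(b1, b2, a2)
    return o1 != o2 and o3 != o4


@dataclass(frozen=True)
class Region:
    """One named polygon in image pixel coordinates."""

    name: str
    vertices: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        if len(self.vertices) < 3:
            raise GeometryError(
                f"region {self.name!r} needs at least 3 vertices, got {len(self.vertices)}"
            )
        if self.is_self_intersecting():
            logger.warning(
                "region %r is self-intersecting; even-odd containment still applies",
                self.name,
            )

    def contains(self, x: float, y: float) -> bool:
        return point_in_polygon(x, y, list(self.vertices))

    def is_self_intersecting(self) -> bool:
        n = len(self.vertices)
        edges = [(self.vertices[i], self.vertices[(i + 1) % n]) for i in range(n)]
        for i in range(n):
            for j in range(i + 1, n):
                if j == i + 1 or (i == 0 and j == n - 1):
                    continue  # adjacent edges share a vertex
                if _segments_intersect(*edges[i], *edges[j]):
                    return True
        return False


@dataclass(frozen=True)
class RegionSet:
    """The three table-interaction regions of one camera view."""

    wrists: Region
    shoulders: Region
    head: Region

    def __getitem__(self, name: str) -> Region:
        if name not in REGION_NAMES:
            raise FormatError(f"unknown region name {name!r}; expected one of {REGION_NAMES}")
        return getattr(self, name)

    @classmethod
    def from_dict(cls, polygons: dict[str, list[tuple[float, float]]]) -> "RegionSet":
        missing = [n for n in REGION_NAMES if n not in polygons]
        if missing:
            raise FormatError(f"region file is missing polygon(s): {', '.join(missing)}")
        return cls(**{
            name: Region(name, tuple((float(x), float(y)) for x, y in polygons[name]))
            for name in REGION_NAMES
        })
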