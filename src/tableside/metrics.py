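"""The interaction time-fraction metric F and its windowed variants.

F is the mean of a binary indicator r(p) over a set P of pose detections:

    F = (1 / |P|) * sum over p in P of r(p)

with r(p) = 1 when the pose interacts (or, for the movement fraction, when
it moves). Because only detected poses enter P, missed detections do not
bias F; summing over all individuals discards identity, so re-identification
errors do not either; and letting P span a time window averages out
single-frame detection errors. An empty P leaves F undefined — 0/0 must
never masquerade as "no interaction".
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Optional, Sequence

from .errors import UndefinedMetricError, UsageError
from .interaction_rules import ClassificationRecord

#: Built-in indicator predicates for :func:`fraction`.
PREDICATES: dict[str, Callable[[ClassificationRecord], bool]] = {
    "interacting": lambda r: r.interacting,
    "moving": lambda r: not r.still,
}


@dataclass(frozen=True)
class WindowSpec:
    """Sliding-window layout: length 7500 frames, starts 3750 apart.

    At a nominal 25 fps the defaults give 5-minute windows with 50 %
    overlap between adjacent windows.
    """

    length: int = 7500
    step: int = 3750

    def __post_init__(self) -> None:
        if not (0 < self.step <= self.length):
            raise UsageError("require 0 < step <= length")

    def starts(self, n_frames: int) -> list[int]:
        """Every window start below n_frames: 0, step, 2*step, ..."""
        if n_frames <= 0:
            return []
        return list(range(0, n_frames, self.step))


@dataclass(frozen=True)
class WindowSeries:
    """Per-window metric values; value is None where the window is empty."""

    starts: tuple[int, ...]
    length: int
    values: tuple[Optional[float], ...]
    n_poses: tuple[int, ...]

    def __post_init__(self) -> None:
        if not (len(self.starts) == len(self.values) == len(self.n_poses)):
            raise UsageError("starts, values and n_poses must align")
        for v, n in zip(self.values, self.n_poses):
            if (v is None) != (n == 0):
                raise UsageError("value must be None exactly when the window is empty")

    def __len__(self) -> int:
        return len(self.starts)

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["window_start", "window_length", "n_poses", "value"])
            for start, n, v in zip(self.starts, self.n_poses, self.values):
                writer.writerow([start, self.length, n, "" if v is None else repr(v)])


def _resolve(predicate: str | Callable) -> Callable[[ClassificationRecord], bool]:
    if callable(predicate):
        return predicate
    try:
        return PREDICATES[predicate]
    except KeyError:
        raise UsageError(f"unknown predicate {predicate!r}; expected {sorted(PREDICATES)}")


def fraction(records: Iterable[ClassificationRecord],
             predicate: str | Callable = "interacting") -> float:
    """F over a record set: share of records where the predicate holds."""
    records = list(records)
    if not records:
        raise UndefinedMetricError("F is undefined on an empty pose set (|P| = 0)")
    pred = _resolve(predicate)
    return sum(1 for r in records if pred(r)) / len(records)


def windowed_fraction(
    records: Iterable[ClassificationRecord],
    n_frames: int,
    spec: WindowSpec | None = None,
    predicate: str | Callable = "interacting",
) -> WindowSeries:
    """F per sliding window.

    A record with frame f contributes to every window with
    start <= f < start + length. The final windows may extend past the
    recording end and simply contain fewer frames.
    """
    spec = spec or WindowSpec()
    pred = _resolve(predicate)
    records = list(records)
    starts = spec.starts(n_frames)
    values: list[Optional[float]] = []
    counts: list[int] = []
    for start in starts:
        in_win = [r for r in records if start <= r.frame < start + spec.length]
        counts.append(len(in_win))
        if in_win:
            values.append(sum(1 for r in in_win if pred(r)) / len(in_win))
        else:
            values.append(None)
    return WindowSeries(tuple(starts), spec.length, tuple(values), tuple(counts))


def detection_ratio(
    detection_counts: Sequence[int],
    annotated_counts: Sequence[int],
) -> list[Optional[float]]:
    """Per-window detected poses divided by annotated persons.

    May exceed 1 (unannotated spectators, false positives). Undefined
    (None) where no persons are annotated.
    """
    if len(detection_counts) != len(annotated_counts):
        raise UsageError("detection and annotation windows must align")
    return [
        (d / a) if a > 0 else None
        for d, a in zip(detection_counts, annotated_counts)
    ]


def annotated_interaction_fraction(
    intervals: Iterable,
    frame_range: tuple[int, int],
    categories: Optional[dict[str, str]] = None,
) -> float:
    """Patient-interaction fraction from interval annotations.

    P is the set of per-frame per-person activity samples within
    ``frame_range`` (half-open) whose label is not 'absence'; the fraction
    is the share of P categorised as patient interaction. ``categories``
    maps labels to {'patient_interaction', 'other', 'absence'}; intervals
    carrying their own category need no mapping.
    """
    from .annotations import category_of

    lo, hi = frame_range
    n_p = 0
    n_interacting = 0
    for iv in intervals:
        overlap = min(hi, iv.end_frame) - max(lo, iv.start_frame)
        if overlap <= 0:
            continue
        cat = category_of(iv, categories)
        if cat == "absence":
            continue
        n_p += overlap
        if cat == "patient_interaction":
            n_interacting += overlap
    if n_p == 0:
        raise UndefinedMetricError(
            "patient-interaction fraction undefined: no non-absence samples in range"
        )
    return n_interacting / n_p


def write_summary(rows: list[dict], path: str | Path) -> None:
    """Write a metric summary CSV (one row per metric or per phase-metric)."""
    if not rows:
        raise UsageError("summary needs at least one row")
    fields = list(rows[0].keys())
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=fields)
        writer.writeheader()
        writer.writerows(rows)
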