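"""Interval annotations: personnel activities and workflow phases.

Human annotators mark, per person, which activity they perform on which
frame interval; activities are grouped into three categories —
``patient_interaction``, ``other`` and the reserved ``absence`` (person not
in the room). Workflow phases (induction, preparation, surgery, recovery)
partition a recording and enable per-phase summaries. The concrete activity
vocabulary is configuration, not code: the label→category mapping ships as
an editable table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from .errors import ConfigurationError, UsageError
from .interaction_rules import ClassificationRecord
from .metrics import WindowSeries

logger = logging.getLogger(__name__)

CATEGORIES = ("patient_interaction", "other", "absence")
PHASES = ("induction", "preparation", "surgery", "recovery")
UNPHASED = "unphased"

#: Example label→category mapping; real deployments supply their own.
EXAMPLE_CATEGORY_MAP: dict[str, str] = {
    "absence": "absence",
    "operating": "patient_interaction",
    "patient_positioning": "patient_interaction",
    "anaesthesia_care": "patient_interaction",
    "wound_closure": "patient_interaction",
    "documentation": "other",
    "device_setup": "other",
    "walking": "other",
    "observing": "other",
}


@dataclass(frozen=True)
class ActivityInterval:
    """One person's activity over a half-open frame interval."""

    person_id: str
    start_frame: int
    end_frame: int
    label: str
    category: Optional[str] = None

    def __post_init__(self) -> None:
        if self.start_frame >= self.end_frame:
            raise UsageError(
                f"interval for {self.person_id!r}: start {self.start_frame} "
                f">= end {self.end_frame}"
            )
        if self.category is not None and self.category not in CATEGORIES:
            raise ConfigurationError(f"unknown category {self.category!r}")


@dataclass(frozen=True)
class PhaseInterval:
    """One workflow phase over a half-open frame interval."""

    phase: str
    start_frame: int
    end_frame: int

    def __post_init__(self) -> None:
        if self.phase not in PHASES:
            raise ConfigurationError(
                f"unknown phase {self.phase!r}; expected one of {PHASES}"
            )
        if self.start_frame >= self.end_frame:
            raise UsageError(f"phase {self.phase}: start >= end")


def category_map(label: str, mapping: dict[str, str]) -> str:
    """Look up the category of an activity label; unknown labels error."""
    if label == "absence":
        return "absence"
    try:
        cat = mapping[label]
    except KeyError:
        raise ConfigurationError(
            f"activity label {label!r} has no configured category"
        ) from None
    if cat not in CATEGORIES:
        raise ConfigurationError(f"label {label!r} maps to unknown category {cat!r}")
    return cat


def category_of(interval: ActivityInterval, mapping: Optional[dict[str, str]]) -> str:
    if interval.category is not None:
        return interval.category
    if mapping is None:
        raise ConfigurationError(
            f"interval label {interval.label!r} carries no category and no mapping given"
        )
    return category_map(interval.label, mapping)


def validate_person_intervals(intervals: Sequence[ActivityInterval]) -> None:
    """Check that no person's intervals overlap."""
    by_person: dict[str, list[ActivityInterval]] = {}
    for iv in intervals:
        by_person.setdefault(iv.person_id, []).append(iv)
    for person, ivs in by_person.items():
        ivs = sorted(ivs, key=lambda i: i.start_frame)
        for a, b in zip(ivs, ivs[1:]):
            if b.start_frame < a.end_frame:
                raise UsageError(
                    f"person {person!r}: overlapping intervals at frame {b.start_frame}"
                )


def _phase_at(frame: int, phases: Sequence[PhaseInterval]) -> str:
    for ph in phases:
        if ph.start_frame <= frame < ph.end_frame:
            return ph.phase
    return UNPHASED


def stratify_records_by_phase(
    records: Iterable[ClassificationRecord],
    phases: Sequence[PhaseInterval],
) -> dict[str, list[ClassificationRecord]]:
    """Partition classification records by the phase containing their frame."""
    out: dict[str, list[ClassificationRecord]] = {}
    warned = False
    for rec in records:
        phase = _phase_at(rec.frame, phases)
        if phase == UNPHASED and not warned:
            logger.warning("records outside every phase assigned to %r", UNPHASED)
            warned = True
        out.setdefault(phase, []).append(rec)
    return out


def stratify_windows_by_phase(
    series: WindowSeries,
    phases: Sequence[PhaseInterval],
) -> dict[str, list[tuple[int, Optional[float], int]]]:
    """Partition windows by the phase containing their *start* frame.

    Windows may straddle phase boundaries; assignment by start frame keeps
    the partition deterministic. Returns phase -> list of
    (start, value, n_poses).
    """
    out: dict[str, list[tuple[int, Optional[float], int]]] = {}
    for start, value, n in zip(series.starts, series.values, series.n_poses):
        phase = _phase_at(start, phases)
        out.setdefault(phase, []).append((start, value, n))
    return out


def stratify_by_phase(values, phases: Sequence[PhaseInterval]):
    """Dispatch to the record- or window-based stratifier."""
    if isinstance(values, WindowSeries):
        return stratify_windows_by_phase(values, phases)
    return stratify_records_by_phase(values, phases)
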