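"""Gambit-of-the-group construction from detection streams.

Detections are collapsed into clock-aligned, half-open time bins (default
10 min) per receiver; every set of individuals co-detected at one receiver in
one bin is a group.  Groups are then aggregated into coarser sampling periods
(default 1 h) over which dyadic counts are later tallied.  Singleton groups
are retained: they contribute "seen alone" denominators downstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from socnet.io_telemetry import DetectionRecord, StudyWindow, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "GroupObservation",
    "SamplingPeriodTable",
    "bin_capacity",
    "bin_detections",
    "collapse_to_periods",
    "exclude_individual",
    "filter_window",
    "restrict_proximity_groups",
    "write_groups",
]


@dataclass(frozen=True)
class GroupObservation:
    """Individuals co-detected at one receiver within one time bin."""

    receiver_id: str
    bin_start: float
    members: frozenset[str]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValidationError("group must have at least one member")


@dataclass(frozen=True)
class SamplingPeriodTable:
    """Groups keyed by the clock-aligned sampling period containing them."""

    period_width: float
    periods: Mapping[float, tuple[GroupObservation, ...]]

    @property
    def n_periods(self) -> int:
        return len(self.periods)

    @property
    def n_groups(self) -> int:
        return sum(len(g) for g in self.periods.values())

    def individuals(self) -> tuple[str, ...]:
        seen: set[str] = set()
        for groups in self.periods.values():
            for g in groups:
                seen.update(g.members)
        return tuple(sorted(seen))

    def all_groups(self) -> list[GroupObservation]:
        return [g for key in sorted(self.periods) for g in self.periods[key]]


def write_groups(groups: Iterable[GroupObservation], path) -> None:
    """Optional export: receiver_id, bin_start, semicolon-joined members."""
    import csv
    from pathlib import Path

    from socnet.io_telemetry import format_time

    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["receiver_id", "bin_start", "members"])
        for g in groups:
            writer.writerow(
                [g.receiver_id, format_time(g.bin_start), ";".join(sorted(g.members))]
            )


def filter_window(
    detections: Sequence[DetectionRecord], window: StudyWindow
) -> list[DetectionRecord]:
    """Keep records with start <= time < end, preserving order."""
    return [r for r in detections if window.contains(r.time)]


def bin_detections(
    detections: Sequence[DetectionRecord],
    bin_width: float = 600.0,
    per_receiver: bool = True,
) -> list[GroupObservation]:
    """Collapse detections into one group per (receiver, bin).

    Bins are half-open intervals ``[k*width, (k+1)*width)`` aligned to the
    epoch clock.  With ``per_receiver=False`` all receivers pool into a single
    group per bin (not the default: co-detection at different receivers is not
    co-occurrence).
    """
    if bin_width <= 0:
        raise ValidationError("bin_width must be > 0")
    members: dict[tuple[str, float], set[str]] = {}
    for r in detections:
        start = (r.time // bin_width) * bin_width
        key = (r.receiver_id if per_receiver else "*", start)
        members.setdefault(key, set()).add(r.individual_id)
    return [
        GroupObservation(rid, start, frozenset(m))
        for (rid, start), m in sorted(members.items(), key=lambda kv: (kv[0][1], kv[0][0]))
    ]


def bin_capacity(bin_width: float, nominal_delay: float) -> int:
    """Guaranteed number of complete transmission intervals per bin."""
    if bin_width <= 0 or nominal_delay <= 0:
        raise ValidationError("bin_width and nominal_delay must be > 0")
    return int(bin_width // nominal_delay)


def collapse_to_periods(
    groups: Iterable[GroupObservation],
    period_width: float = 3600.0,
    bin_width: float = 600.0,
) -> SamplingPeriodTable:
    """Assign binned groups to clock-aligned sampling periods."""
    if period_width <= 0:
        raise ValidationError("period_width must be > 0")
    if period_width % bin_width != 0:
        raise ValidationError(
            f"period_width {period_width} is not an integer multiple of "
            f"bin_width {bin_width}"
        )
    table: dict[float, list[GroupObservation]] = {}
    for g in groups:
        period = (g.bin_start // period_width) * period_width
        table.setdefault(period, []).append(g)
    frozen = {k: tuple(v) for k, v in sorted(table.items())}
    return SamplingPeriodTable(period_width=period_width, periods=frozen)


def restrict_proximity_groups(
    proximity_groups: Sequence[GroupObservation],
    reference_detections: Sequence[DetectionRecord],
    tolerance: float = 600.0,
    bin_width: float = 600.0,
    member_rule: str = "any",
) -> list[GroupObservation]:
    """Keep animal-borne-logger groups whose members the reference receiver saw.

    A group spanning bin ``[b, b + bin_width)`` is kept iff members of the
    group were detected by the reference fixed receiver inside
    ``[b - tolerance, b + bin_width + tolerance)``.  ``member_rule`` selects
    whether one member suffices (``"any"``, default) or all must be seen
    (``"all"``).
    """
    if member_rule not in ("any", "all"):
        raise ValidationError(f"member_rule must be 'any' or 'all', got {member_rule!r}")
    if not reference_detections:
        logger.warning("empty reference detection stream: dropping all %d groups",
                       len(proximity_groups))
        return []
    ref_times: dict[str, list[float]] = {}
    for r in reference_detections:
        ref_times.setdefault(r.individual_id, []).append(r.time)

    def seen(individual: str, lo: float, hi: float) -> bool:
        return any(lo <= t < hi for t in ref_times.get(individual, ()))

    kept: list[GroupObservation] = []
    for g in proximity_groups:
        lo = g.bin_start - tolerance
        hi = g.bin_start + bin_width + tolerance
        hits = (seen(m, lo, hi) for m in g.members)
        if all(hits) if member_rule == "all" else any(hits):
            kept.append(g)
    return kept


def exclude_individual(
    groups: Iterable[GroupObservation], individual_id: str
) -> list[GroupObservation]:
    """Remove one individual from every group, dropping groups it empties.

    Used for the host of an animal-borne receiver, which would otherwise be a
    member of every association event it records.
    """
    out: list[GroupObservation] = []
    for g in groups:
        members = g.members - {individual_id}
        if members:
            out.append(GroupObservation(g.receiver_id, g.bin_start, members))
    return out
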