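"""Readers and writers for the tabular artifacts of a telemetry study.

All files are comma-separated UTF-8 with a header row, ISO-8601 timestamps
and ``.`` as the decimal mark.  Times are handled internally as float seconds
since the Unix epoch, always UTC: naive timestamps are taken to be UTC and
timestamps carrying a non-zero UTC offset are rejected rather than silently
converted.

Canonical dialects
------------------
``detections.csv``  : ``time,receiver_id,individual_id``
``receivers.csv``   : ``receiver_id,kind,x,y,detection_radius,host_individual``
``individuals.csv`` : ``individual_id,sex,total_length_cm``

Association matrices are square CSVs whose first row and first column hold
the individual ids.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "DetectionRecord",
    "FormatError",
    "IndividualSpec",
    "ReceiverSpec",
    "StudyWindow",
    "ValidationError",
    "format_time",
    "parse_time",
    "read_array_metadata",
    "read_association_matrix",
    "read_detections",
    "write_association_matrix",
    "write_detections",
]


class FormatError(ValueError):
    """A file could not be parsed; the message names the offending line."""


class ValidationError(ValueError):
    """Parsed content violates a domain invariant."""


def parse_time(text: str, *, line: int | None = None) -> float:
    """Parse an ISO-8601 timestamp into UTC epoch seconds.

    Naive timestamps are interpreted as UTC.  Timestamps with a non-zero UTC
    offset raise :class:`FormatError` (no silent conversion).
    """
    where = f" on line {line}" if line is not None else ""
    try:
        dt = datetime.fromisoformat(text.strip())
    except ValueError:
        raise FormatError(f"unparseable timestamp {text!r}{where}") from None
    if dt.tzinfo is None:
        dt = dt.replace(tzinfo=timezone.utc)
    elif dt.utcoffset() != timezone.utc.utcoffset(None):
        raise FormatError(
            f"timestamp {text!r}{where} carries a non-UTC offset; "
            "convert inputs to UTC first"
        )
    return dt.timestamp()


def format_time(t: float) -> str:
    """Render epoch seconds as an ISO-8601 UTC timestamp (second precision)."""
    return datetime.fromtimestamp(round(t), tz=timezone.utc).strftime(
        "%Y-%m-%dT%H:%M:%SZ"
    )


class DetectionRecord(NamedTuple):
    """One decoded ping: when, at which receiver, which individual."""

    time: float
    receiver_id: str
    individual_id: str


@dataclass(frozen=True)
class ReceiverSpec:
    """A deployed receiver: fixed at (x, y) or mobile on a host individual."""

    receiver_id: str
    kind: str  # "fixed" | "mobile"
    detection_radius: float
    x: float | None = None
    y: float | None = None
    host_individual: str | None = None

    def __post_init__(self) -> None:
        if not self.receiver_id:
            raise ValidationError("receiver_id must be non-empty")
        if self.kind not in ("fixed", "mobile"):
            raise ValidationError(f"unknown receiver kind {self.kind!r}")
        if not (self.detection_radius > 0):
            raise ValidationError(
                f"receiver {self.receiver_id}: detection_radius must be > 0"
            )
        if self.kind == "mobile":
            if not self.host_individual:
                raise ValidationError(
                    f"mobile receiver {self.receiver_id} requires host_individual"
                )
            if self.x is not None or self.y is not None:
                raise ValidationError(
                    f"mobile receiver {self.receiver_id} must not carry a fixed position"
                )
        else:
            if self.x is None or self.y is None:
                raise ValidationError(
                    f"fixed receiver {self.receiver_id} requires x and y"
                )
            if self.host_individual:
                raise ValidationError(
                    f"fixed receiver {self.receiver_id} must not carry a host"
                )


@dataclass(frozen=True)
class IndividualSpec:
    """A tagged individual; sex and length are carried as metadata only."""

    individual_id: str
    sex: str = "unknown"  # "F" | "M" | "unknown"
    total_length_cm: float | None = None

    def __post_init__(self) -> None:
        if not self.individual_id:
            raise ValidationError("individual_id must be non-empty")
        if self.sex not in ("F", "M", "unknown"):
            raise ValidationError(f"unknown sex code {self.sex!r}")


@dataclass(frozen=True)
class StudyWindow:
    """Half-open monitoring window [start, end), epoch seconds."""

    start: float
    end: float

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValidationError("window start must precede end")

    def contains(self, t: float) -> bool:
        return self.start <= t < self.end


def read_detections(path: str | Path) -> list[DetectionRecord]:
    """Read a detection log; records come back time-sorted.

    Ties in time are broken by (receiver_id, individual_id) so the ordering
    is a pure function of file content.  Exact duplicate rows are dropped
    with a log message.
    """
    path = Path(path)
    records: list[DetectionRecord] = []
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        _require_columns(reader, ("time", "receiver_id", "individual_id"), path)
        for i, row in enumerate(reader, start=2):
            t = parse_time(row["time"], line=i)
            rid = (row["receiver_id"] or "").strip()
            iid = (row["individual_id"] or "").strip()
            if not rid or not iid:
                raise FormatError(f"empty id on line {i} of {path}")
            records.append(DetectionRecord(t, rid, iid))
    n_raw = len(records)
    records = sorted(set(records), key=lambda r: (r.time, r.receiver_id, r.individual_id))
    if len(records) < n_raw:
        logger.info("dropped %d exact-duplicate detections", n_raw - len(records))
    return records


def write_detections(records: Iterable[DetectionRecord], path: str | Path) -> None:
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["time", "receiver_id", "individual_id"])
        for r in records:
            writer.writerow([format_time(r.time), r.receiver_id, r.individual_id])


def read_array_metadata(
    receiver_path: str | Path, individual_path: str | Path
) -> tuple[list[ReceiverSpec], list[IndividualSpec]]:
    """Read receiver and individual metadata, validating all invariants."""
    receivers = _read_receivers(Path(receiver_path))
    individuals = _read_individuals(Path(individual_path))
    return receivers, individuals


def _read_receivers(path: Path) -> list[ReceiverSpec]:
    specs: list[ReceiverSpec] = []
    seen: set[str] = set()
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        _require_columns(
            reader, ("receiver_id", "kind", "x", "y", "detection_radius"), path
        )
        for i, row in enumerate(reader, start=2):
            rid = row["receiver_id"].strip()
            if rid in seen:
                raise ValidationError(f"duplicate receiver_id {rid!r} (line {i})")
            seen.add(rid)
            host = (row.get("host_individual") or "").strip() or None
            specs.append(
                ReceiverSpec(
                    receiver_id=rid,
                    kind=row["kind"].strip(),
                    x=_optional_float(row["x"], i, path),
                    y=_optional_float(row["y"], i, path),
                    detection_radius=float(row["detection_radius"]),
                    host_individual=host,
                )
            )
    return specs


def _read_individuals(path: Path) -> list[IndividualSpec]:
    specs: list[IndividualSpec] = []
    seen: set[str] = set()
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        _require_columns(reader, ("individual_id",), path)
        for i, row in enumerate(reader, start=2):
            iid = row["individual_id"].strip()
            if iid in seen:
                raise ValidationError(f"duplicate individual_id {iid!r} (line {i})")
            seen.add(iid)
            sex = (row.get("sex") or "unknown").strip() or "unknown"
            tl = _optional_float(row.get("total_length_cm") or "", i, path)
            specs.append(IndividualSpec(iid, sex, tl))
    return specs


def write_array_metadata(
    receivers: Sequence[ReceiverSpec],
    individuals: Sequence[IndividualSpec],
    receiver_path: str | Path,
    individual_path: str | Path,
) -> None:
    with Path(receiver_path).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            ["receiver_id", "kind", "x", "y", "detection_radius", "host_individual"]
        )
        for r in receivers:
            writer.writerow(
                [
                    r.receiver_id,
                    r.kind,
                    "" if r.x is None else repr(r.x),
                    "" if r.y is None else repr(r.y),
                    repr(r.detection_radius),
                    r.host_individual or "",
                ]
            )
    with Path(individual_path).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["individual_id", "sex", "total_length_cm"])
        for ind in individuals:
            writer.writerow(
                [
                    ind.individual_id,
                    ind.sex,
                    "" if ind.total_length_cm is None else repr(ind.total_length_cm),
                ]
            )


def write_association_matrix(matrix, path: str | Path) -> None:
    """Write an association matrix as CSV with ids in first row and column.

    Values are written with ``repr`` so a read-back reproduces them to full
    stored precision.
    """
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["individual_id", *matrix.index])
        for i, iid in enumerate(matrix.index):
            writer.writerow([iid, *[repr(float(v)) for v in matrix.values[i]]])


def read_association_matrix(path: str | Path):
    """Read an association matrix CSV, validating symmetry and range."""
    from socnet.association import AssociationMatrix

    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        rows = list(csv.reader(fh))
    if not rows:
        raise FormatError(f"{path}: empty file")
    header = rows[0][1:]
    ids = tuple(header)
    values = np.zeros((len(ids), len(ids)))
    if len(rows) - 1 != len(ids):
        raise FormatError(f"{path}: expected {len(ids)} data rows, got {len(rows) - 1}")
    for i, row in enumerate(rows[1:], start=2):
        if row[0] != ids[i - 2]:
            raise ValidationError(
                f"{path}: row label {row[0]!r} does not match column order"
            )
        try:
            values[i - 2] = [float(v) for v in row[1:]]
        except ValueError as exc:
            raise FormatError(f"{path}: bad numeric value on line {i}: {exc}") from None
    if values.size:
        if not np.array_equal(values, values.T):
            raise ValidationError(f"{path}: matrix is not symmetric")
        if values.min() < 0.0 or values.max() > 1.0:
            raise ValidationError(f"{path}: association values must lie in [0, 1]")
        if np.any(np.diag(values) != 0.0):
            raise ValidationError(f"{path}: diagonal must be zero")
    return AssociationMatrix(index=ids, values=values)


def _require_columns(reader: csv.DictReader, names: Sequence[str], path: Path) -> None:
    missing = [c for c in names if reader.fieldnames is None or c not in reader.fieldnames]
    if missing:
        raise FormatError(f"{path}: missing column(s) {', '.join(missing)}")


def _optional_float(text: str, line: int, path: Path) -> float | None:
    text = (text or "").strip()
    if not text:
        return None
    try:
        return float(text)
    except ValueError:
        raise FormatError(f"{path}: bad numeric value {text!r} on line {line}") from None
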