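"""Data model and CSV I/O for 6-minute-walk-test pulse-oximeter records.

A subject's record is a time-ordered sequence of samples, each carrying the
oxygen saturation (SpO2, percent), pulse rate (PR, beats/min), device flags
(``IsValid``, ``Quality``, ``IsEvent``) and, when labelled, a binary
exercise-induced oxygen desaturation (EIOD) status ``IsEIOD``.

Two on-disk schemas are supported, both comma-separated with a header row:

* **raw** — six/seven columns straight off the device:
  ``Timestamp, SpO2, PR, IsValid, Quality, IsEvent[, IsEIOD]``
* **calibrated** — the four-column matrix that remains after flag-based
  filtering: ``Timestamp, SpO2, PR, IsEIOD`` (all flags implicitly true).

:func:`calibrate` performs the flag-based filtering that turns a raw record
into a calibrated one: points with ``IsValid`` or ``Quality`` false are
dropped, and a surviving point is a positive (``is_eiod = 1``) only when
``IsEvent`` is also true.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from datetime import datetime
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import NoValidSamplesError, ParseError, SchemaError, ValidationError

logger = logging.getLogger(__name__)

_TRUE = {"true", "1", "1.0", "t", "yes"}
_FALSE = {"false", "0", "0.0", "f", "no"}


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SampledPoint:
    """One pulse-oximeter sample.

    ``timestamp`` is seconds from session start; ``spo2`` is percent
    (integer-valued on real devices); ``pr`` is beats per minute.
    ``is_eiod`` is ``None`` for unlabelled data.
    """

    timestamp: float
    spo2: float
    pr: float
    is_valid: bool = True
    quality: bool = True
    is_event: bool = True
    is_eiod: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.spo2 <= 100.0:
            raise ValidationError(f"spo2 out of [0, 100]: {self.spo2}")
        if self.is_valid and self.pr <= 0:
            raise ValidationError(f"non-positive pulse rate on valid point: {self.pr}")
        if self.is_eiod not in (None, 0, 1):
            raise ValidationError(f"is_eiod must be 0/1/None, got {self.is_eiod!r}")


@dataclass
class WalkRecord:
    """One subject's time-ordered 6MWT samples."""

    subject_id: str
    points: list[SampledPoint]
    sample_interval: float = 1.0
    cohort_group: str = "unknown"  # {"copd", "normal", "unknown"}

    def __post_init__(self) -> None:
        if not self.points:
            raise ValidationError(f"record {self.subject_id!r} has no points")
        if self.sample_interval <= 0:
            raise ValidationError("sample_interval must be positive")
        ts = np.asarray([p.timestamp for p in self.points], dtype=float)
        if len(ts) > 1 and not np.all(np.diff(ts) > 0):
            bad = int(np.argmin(np.diff(ts) > 0)) + 1
            raise ValidationError(
                f"record {self.subject_id!r}: timestamps not strictly increasing "
                f"at sample {bad}"
            )
        if self.cohort_group not in ("copd", "normal", "unknown"):
            raise ValidationError(f"unknown cohort_group {self.cohort_group!r}")

    def __len__(self) -> int:
        return len(self.points)

    @property
    def timestamps(self) -> np.ndarray:
        return np.asarray([p.timestamp for p in self.points], dtype=float)

    @property
    def spo2(self) -> np.ndarray:
        return np.asarray([p.spo2 for p in self.points], dtype=float)

    @property
    def pr(self) -> np.ndarray:
        return np.asarray([p.pr for p in self.points], dtype=float)

    @property
    def labels(self) -> np.ndarray:
        """Per-point EIOD labels; -1 marks unlabelled points."""
        return np.asarray(
            [-1 if p.is_eiod is None else int(p.is_eiod) for p in self.points],
            dtype=np.int64,
        )


@dataclass
class Cohort:
    """An ordered collection of subjects' records with unique ids."""

    records: list[WalkRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [r.subject_id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate subject ids in cohort: {dupes}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def subject_ids(self) -> list[str]:
        return [r.subject_id for r in self.records]


# ---------------------------------------------------------------------------
# schema descriptors
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SchemaDescriptor:
    """Maps column names (case-insensitive) to sample-field roles.

    ``columns`` maps a header name to one of the roles ``timestamp``,
    ``spo2``, ``pr``, ``is_valid``, ``quality``, ``is_event``, ``is_eiod``.
    Missing flag roles default to ``True``; a missing ``is_eiod`` role
    leaves points unlabelled.
    """

    name: str
    columns: Mapping[str, str]

    _ROLES = ("timestamp", "spo2", "pr", "is_valid", "quality", "is_event", "is_eiod")

    def __post_init__(self) -> None:
        roles = list(self.columns.values())
        for role in roles:
            if role not in self._ROLES:
                raise SchemaError(f"schema {self.name!r}: unknown role {role!r}")
        for required in ("timestamp", "spo2", "pr"):
            if required not in roles:
                raise SchemaError(f"schema {self.name!r}: missing role {required!r}")
        if len(set(roles)) != len(roles):
            raise SchemaError(f"schema {self.name!r}: duplicate roles")

    def role_of(self, header: str) -> str | None:
        for col, role in self.columns.items():
            if col.lower() == header.strip().lower():
                return role
        return None


RAW_SCHEMA = SchemaDescriptor(
    "raw",
    {
        "Timestamp": "timestamp",
        "SpO2": "spo2",
        "PR": "pr",
        "IsValid": "is_valid",
        "Quality": "quality",
        "IsEvent": "is_event",
        "IsEIOD": "is_eiod",
    },
)

CALIBRATED_SCHEMA = SchemaDescriptor(
    "calibrated",
    {"Timestamp": "timestamp", "SpO2": "spo2", "PR": "pr", "IsEIOD": "is_eiod"},
)

_NAMED_SCHEMAS = {"raw": RAW_SCHEMA, "calibrated": CALIBRATED_SCHEMA}


def _resolve_schema(schema: str | SchemaDescriptor) -> SchemaDescriptor:
    if isinstance(schema, SchemaDescriptor):
        return schema
    try:
        return _NAMED_SCHEMAS[schema]
    except KeyError:
        raise SchemaError(
            f"unknown schema {schema!r}; expected 'raw', 'calibrated' "
            "or a SchemaDescriptor"
        ) from None


# ---------------------------------------------------------------------------
# parsing helpers
# ---------------------------------------------------------------------------

def _parse_bool(value, line: int, column: str) -> bool:
    text = str(value).strip().lower()
    if text in _TRUE:
        return True
    if text in _FALSE:
        return False
    raise ParseError(f"line {line}: cannot parse boolean {value!r} in column {column!r}")


def _parse_timestamp(value, line: int) -> float:
    """Accept plain numbers (seconds or epoch) or ISO-8601 strings."""
    text = str(value).strip()
    try:
        return float(text)
    except ValueError:
        pass
    try:
        return datetime.fromisoformat(text).timestamp()
    except ValueError:
        raise ParseError(f"line {line}: cannot parse timestamp {value!r}") from None


def _parse_float(value, line: int, column: str) -> float:
    try:
        return float(str(value).strip())
    except ValueError:
        raise ParseError(
            f"line {line}: cannot parse number {value!r} in column {column!r}"
        ) from None


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def read_raw(
    path: str | Path,
    schema: str | SchemaDescriptor = "raw",
    subject_id: str | None = None,
    sample_interval: float | None = None,
) -> WalkRecord:
    """Read a per-subject record CSV under the given schema.

    Timestamps are normalised to seconds from the first sample.  Boolean
    columns accept True/False, 1/0, true/false case-insensitively.  The
    reader does **not** filter invalid points — see :func:`calibrate`.
    """
    path = Path(path)
    desc = _resolve_schema(schema)
    try:
        frame = pd.read_csv(path, dtype=str, skipinitialspace=True)
    except pd.errors.ParserError as exc:
        raise ParseError(f"{path}: {exc}") from exc
    if frame.empty:
        raise ParseError(f"{path}: no data rows")

    role_to_col: dict[str, str] = {}
    for header in frame.columns:
        role = desc.role_of(header)
        if role is not None:
            if role in role_to_col:
                raise SchemaError(f"{path}: column role {role!r} appears twice")
            role_to_col[role] = header
    for required in ("timestamp", "spo2", "pr"):
        if required not in role_to_col:
            raise SchemaError(
                f"{path}: header {list(frame.columns)} does not match schema "
                f"{desc.name!r} (missing {required!r})"
            )

    points: list[SampledPoint] = []
    for row_idx, row in frame.iterrows():
        line = int(row_idx) + 2  # header is line 1
        ts = _parse_timestamp(row[role_to_col["timestamp"]], line)
        spo2 = _parse_float(row[role_to_col["spo2"]], line, "SpO2")
        pr = _parse_float(row[role_to_col["pr"]], line, "PR")
        flags = {}
        for role in ("is_valid", "quality", "is_event"):
            if role in role_to_col:
                flags[role] = _parse_bool(row[role_to_col[role]], line, role)
            else:
                flags[role] = True
        label: int | None = None
        if "is_eiod" in role_to_col:
            raw = row[role_to_col["is_eiod"]]
            if not (raw is None or (isinstance(raw, float) and np.isnan(raw)) or str(raw).strip() == ""):
                label = int(_parse_bool(raw, line, "IsEIOD"))
        try:
            points.append(
                SampledPoint(timestamp=ts, spo2=spo2, pr=pr, is_eiod=label, **flags)
            )
        except ValidationError as exc:
            raise ParseError(f"{path} line {line}: {exc}") from exc

    t0 = points[0].timestamp
    points = [replace(p, timestamp=p.timestamp - t0) for p in points]

    if sample_interval is None:
        diffs = np.diff([p.timestamp for p in points])
        sample_interval = float(np.median(diffs)) if len(diffs) else 1.0

    record = WalkRecord(
        subject_id=subject_id if subject_id is not None else path.stem,
        points=points,
        sample_interval=sample_interval,
    )
    logger.info("read %d points from %s (schema=%s)", len(record), path, desc.name)
    return record


def calibrate(record: WalkRecord) -> WalkRecord:
    """Flag-based validity filter: raw record -> calibrated record.

    Keeps only points with ``is_valid`` and ``quality`` true.  On retained
    points the label becomes 1 iff ``is_event`` is true *and* the raw label
    said 1; every other retained point is a valid negative (label 0).
    Order is preserved; the operation is idempotent.
    """
    kept = []
    for p in record.points:
        if not (p.is_valid and p.quality):
            continue
        label = 1 if (p.is_event and p.is_eiod == 1) else 0
        kept.append(replace(p, is_event=p.is_event, is_eiod=label))
    if not kept:
        raise NoValidSamplesError(
            f"record {record.subject_id!r}: no valid samples after calibration"
        )
    dropped = len(record) - len(kept)
    if dropped:
        logger.info(
            "calibrate %s: dropped %d/%d points", record.subject_id, dropped, len(record)
        )
    return WalkRecord(
        subject_id=record.subject_id,
        points=kept,
        sample_interval=record.sample_interval,
        cohort_group=record.cohort_group,
    )


def calibrate_cohort(cohort: Cohort) -> Cohort:
    """Apply :func:`calibrate` to every record of a cohort."""
    return Cohort([calibrate(r) for r in cohort])


def _fmt(value: float) -> str:
    """Integers print bare; reals print with full repr precision."""
    return str(int(value)) if float(value).is_integer() else repr(float(value))


def write_record(record: WalkRecord, path: str | Path, schema: str = "raw") -> Path:
    """Write a record as CSV under the raw or calibrated schema.

    Round-trip contract: ``read_raw(write_record(r), schema)`` reproduces
    the numeric fields exactly for integers and to full printed precision
    for reals.  Writing a calibrated record under the raw schema emits its
    (defaulted) flags as True.
    """
    path = Path(path)
    if not record.points:  # unreachable via WalkRecord, kept for raw dicts
        raise ValidationError("cannot write an empty record")
    rows = []
    for p in record.points:
        label = "" if p.is_eiod is None else str(int(p.is_eiod))
        if schema == "raw":
            rows.append(
                {
                    "Timestamp": _fmt(p.timestamp),
                    "SpO2": _fmt(p.spo2),
                    "PR": _fmt(p.pr),
                    "IsValid": str(p.is_valid),
                    "Quality": str(p.quality),
                    "IsEvent": str(p.is_event),
                    "IsEIOD": label,
                }
            )
        elif schema == "calibrated":
            rows.append(
                {
                    "Timestamp": _fmt(p.timestamp),
                    "SpO2": _fmt(p.spo2),
                    "PR": _fmt(p.pr),
                    "IsEIOD": label,
                }
            )
        else:
            raise SchemaError(f"unknown output schema {schema!r}")
    pd.DataFrame(rows).to_csv(path, index=False)
    logger.info("wrote %d points to %s (schema=%s)", len(rows), path, schema)
    return path
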