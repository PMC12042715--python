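"""Attempt-level record model and CSV I/O for simulation training logs.

One :class:`AttemptRecord` describes a single end-to-end anastomosis attempt:
per-stage mistake scores (stage 1 circumferential dissection, stage 2
adventitial dissection, stage 3 suturing), the total mistake score, per-stage
times and the total task-completion time in seconds.

The CSV schema is::

    attempt,date,stage1_mistakes,stage2_mistakes,stage3_mistakes,total_score,
    stage1_time,stage2_time,stage3_time,total_time

A cell rendered ``-`` or left empty means *absent* (not recorded), which is
distinct from zero: attempts aborted by a major mistake carry a recorded
``total_time`` of 0 with all stage times absent.  Times may use thousands
separators (``1,159``).
"""

from __future__ import annotations

import csv
import datetime as _dt
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import IO, Iterable, Sequence

__all__ = [
    "AttemptRecord",
    "MistakeRubric",
    "ValidationIssue",
    "ValidationReport",
    "SchemaError",
    "RecordParseError",
    "read_attempts",
    "write_attempts",
    "validate_attempts",
    "is_major",
]

CSV_COLUMNS = (
    "attempt",
    "date",
    "stage1_mistakes",
    "stage2_mistakes",
    "stage3_mistakes",
    "total_score",
    "stage1_time",
    "stage2_time",
    "stage3_time",
    "total_time",
)

#: Cell values interpreted as "absent".
ABSENT_TOKENS = frozenset({"", "-", "na", "n/a"})


class SchemaError(ValueError):
    """The CSV header does not match the attempt-log schema."""


class RecordParseError(ValueError):
    """A data cell could not be parsed; carries the 1-based row number."""

    def __init__(self, message: str, row: int):
        super().__init__(f"row {row}: {message}")
        self.row = row


@dataclass(frozen=True)
class MistakeRubric:
    """Scoring rubric: minor mistakes score 1 point, major mistakes 5;
    an attempt counts as a *major-mistake attempt* when its total score
    reaches ``major_threshold`` (default 5, i.e. a total score > 4)."""

    minor_points: int = 1
    major_points: int = 5
    major_threshold: int = 5

    def __post_init__(self) -> None:
        if not (self.major_threshold >= self.major_points >= self.minor_points >= 1):
            raise ValueError(
                "rubric must satisfy major_threshold >= major_points >= minor_points >= 1"
            )


@dataclass(frozen=True)
class AttemptRecord:
    """One attempt of the three-stage microsurgical task.

    ``stage_mistakes`` and ``stage_times`` are 3-tuples whose entries are
    ``None`` when the corresponding cell was not recorded.  ``total_time`` is
    0 for attempts aborted by a major mistake (no time was taken).
    """

    attempt_index: int
    total_score: int
    total_time: int
    stage_mistakes: tuple[int | None, int | None, int | None] = (None, None, None)
    stage_times: tuple[int | None, int | None, int | None] = (None, None, None)
    date: _dt.date | None = None

    def __post_init__(self) -> None:
        if self.attempt_index < 1:
            raise ValueError("attempt_index must be >= 1")
        if self.total_score < 0:
            raise ValueError("total_score must be non-negative")
        if self.total_time < 0:
            raise ValueError("total_time must be non-negative")
        for v in (*self.stage_mistakes, *self.stage_times):
            if v is not None and v < 0:
                raise ValueError("stage scores and times must be non-negative")

    @property
    def timed(self) -> bool:
        """Whether the attempt carries a usable completion time."""
        return self.total_time > 0


@dataclass(frozen=True)
class ValidationIssue:
    attempt_index: int
    code: str
    message: str


@dataclass(frozen=True)
class ValidationReport:
    n_records: int
    issues: tuple[ValidationIssue, ...] = field(default_factory=tuple)

    @property
    def is_clean(self) -> bool:
        return not self.issues

    def __str__(self) -> str:  # human-readable summary for CLI error paths
        if self.is_clean:
            return f"{self.n_records} records, no issues"
        lines = [f"{self.n_records} records, {len(self.issues)} issue(s):"]
        lines += [
            f"  attempt {i.attempt_index}: [{i.code}] {i.message}" for i in self.issues
        ]
        return "\n".join(lines)


def is_major(record: AttemptRecord, rubric: MistakeRubric = MistakeRubric()) -> bool:
    """True iff the attempt's total mistake score reaches the major threshold."""
    return record.total_score >= rubric.major_threshold


# ---------------------------------------------------------------------------
# parsing helpers


def _parse_int(cell: str, what: str, row: int) -> int | None:
    token = cell.strip()
    if token.lower() in ABSENT_TOKENS:
        return None
    try:
        return int(token.replace(",", ""))
    except ValueError:
        raise RecordParseError(f"non-numeric {what}: {cell!r}", row) from None


def _parse_date(cell: str) -> _dt.date | None:
    token = cell.strip()
    if token.lower() in ABSENT_TOKENS:
        return None
    for fmt in ("%Y-%m-%d", "%B %d, %Y", "%b %d, %Y", "%d/%m/%Y", "%m/%d/%Y"):
        try:
            return _dt.datetime.strptime(token, fmt).date()
        except ValueError:
            continue
    return None  # dates are informational; unparseable dates degrade to absent


def read_attempts(path: str | Path | IO[str], **dialect) -> list[AttemptRecord]:
    """Read an attempt log CSV, returning records sorted by attempt index.

    Parameters
    ----------
    path
        File path or open text handle.
    **dialect
        Extra :func:`csv.reader` dialect options (e.g. ``delimiter``).

    Raises
    ------
    SchemaError
        If a required column is missing or renamed.
    RecordParseError
        If a score or time cell is non-numeric (with the offending row).
    """
    if hasattr(path, "read"):
        return _read_handle(path, dialect)  # type: ignore[arg-type]
    with open(path, newline="", encoding="utf-8") as fh:
        return _read_handle(fh, dialect)


def _read_handle(fh: IO[str], dialect: dict) -> list[AttemptRecord]:
    reader = csv.reader(fh, **dialect)
    try:
        header = next(reader)
    except StopIteration:
        raise SchemaError("empty file: expected a header row") from None
    header = [h.strip().lower() for h in header]
    missing = [c for c in CSV_COLUMNS if c not in header]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    idx = {c: header.index(c) for c in CSV_COLUMNS}

    records: list[AttemptRecord] = []
    for rownum, row in enumerate(reader, start=2):
        if not row or all(not c.strip() for c in row):
            continue

        def cell(name: str) -> str:
            i = idx[name]
            return row[i] if i < len(row) else ""

        attempt = _parse_int(cell("attempt"), "attempt index", rownum)
        if attempt is None:
            raise RecordParseError("attempt index is absent", rownum)
        total_score = _parse_int(cell("total_score"), "total score", rownum)
        if total_score is None:
            raise RecordParseError("total score is absent", rownum)
        total_time = _parse_int(cell("total_time"), "total time", rownum)
        if total_time is None:
            raise RecordParseError("total time is absent", rownum)
        records.append(
            AttemptRecord(
                attempt_index=attempt,
                date=_parse_date(cell("date")),
                stage_mistakes=tuple(  # type: ignore[arg-type]
                    _parse_int(cell(f"stage{k}_mistakes"), f"stage {k} score", rownum)
                    for k in (1, 2, 3)
                ),
                total_score=total_score,
                stage_times=tuple(  # type: ignore[arg-type]
                    _parse_int(cell(f"stage{k}_time"), f"stage {k} time", rownum)
                    for k in (1, 2, 3)
                ),
                total_time=total_time,
            )
        )
    records.sort(key=lambda r: r.attempt_index)
    return records


def _format_cell(v: int | None) -> str:
    return "-" if v is None else str(v)


def write_attempts(records: Iterable[AttemptRecord], path: str | Path | IO[str]) -> None:
    """Write records in the attempt-log CSV schema (absent cells as ``-``).

    Round-trips with :func:`read_attempts` field for field.
    """
    if hasattr(path, "write"):
        _write_handle(records, path)  # type: ignore[arg-type]
        return
    with open(path, "w", newline="", encoding="utf-8") as fh:
        _write_handle(records, fh)


def _write_handle(records: Iterable[AttemptRecord], fh: IO[str]) -> None:
    writer = csv.writer(fh, lineterminator="\n")
    writer.writerow(CSV_COLUMNS)
    for r in records:
        writer.writerow(
            [
                r.attempt_index,
                r.date.isoformat() if r.date else "-",
                *(_format_cell(v) for v in r.stage_mistakes),
                r.total_score,
                *(_format_cell(v) for v in r.stage_times),
                r.total_time,
            ]
        )


def validate_attempts(
    records: Sequence[AttemptRecord], mode: str = "lenient"
) -> ValidationReport:
    """Check a record list against the schema invariants without mutating it.

    ``strict`` mode flags (a) total_score differing from the sum of the
    recorded stage scores, (b) total_time differing from the sum of recorded
    stage times (when all three are present), and (c) attempt indices not
    contiguous from 1.  ``lenient`` mode flags only (b) and (c) and treats
    ``total_score`` as authoritative — real logs contain rows where stage
    entries and the printed total disagree.
    """
    if mode not in ("strict", "lenient"):
        raise ValueError(f"mode must be 'strict' or 'lenient', got {mode!r}")
    if not records:
        raise ValueError("records must be non-empty")
    issues: list[ValidationIssue] = []

    indices = [r.attempt_index for r in records]
    if sorted(indices) != list(range(1, len(records) + 1)):
        seen = set(indices)
        expected = set(range(1, len(records) + 1))
        for i in sorted(seen - expected) or sorted(expected - seen):
            issues.append(
                ValidationIssue(
                    i,
                    "noncontiguous_index",
                    "attempt indices are not contiguous from 1",
                )
            )

    for r in records:
        if mode == "strict":
            # absent stage cells count as 0: a nonzero total with no stage
            # entries is itself an inconsistency
            stage_score_sum = sum(v or 0 for v in r.stage_mistakes)
            if stage_score_sum != r.total_score:
                issues.append(
                    ValidationIssue(
                        r.attempt_index,
                        "score_mismatch",
                        f"stage scores sum to {stage_score_sum} "
                        f"but total_score is {r.total_score}",
                    )
                )
        if all(v is not None for v in r.stage_times):
            stage_sum = sum(r.stage_times)  # type: ignore[arg-type]
            if stage_sum != r.total_time:
                issues.append(
                    ValidationIssue(
                        r.attempt_index,
                        "time_mismatch",
                        f"stage times sum to {stage_sum} "
                        f"but total_time is {r.total_time}",
                    )
                )
    return ValidationReport(n_records=len(records), issues=tuple(issues))


def renumber(records: Sequence[AttemptRecord]) -> list[AttemptRecord]:
    """Return a copy with attempt indices rewritten contiguously from 1,
    preserving order. Convenience for subsetting logs."""
    return [replace(r, attempt_index=i) for i, r in enumerate(records, start=1)]
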