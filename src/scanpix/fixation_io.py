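"""Reading, validating and writing fixation tables.

Eye trackers (here the Tobii/iMotions export dialect) emit one CSV row per
fixation with the screen position in pixels (``FixationX``, ``FixationY``,
origin at the top-left corner, x rightward, y downward), the fixation
duration in milliseconds (``FixationDuration``) and the subject identifier
(``Name``).  This module parses such tables into :class:`Scanpath` objects,
one per (subject, stimulus) pair, preserving the acquisition order of rows.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

#: Default mapping from logical field names to CSV column names.
DEFAULT_DIALECT: dict[str, str] = {
    "x": "FixationX",
    "y": "FixationY",
    "duration_ms": "FixationDuration",
    "subject": "Name",
    # optional columns; absent from the raw tracker export
    "stimulus": "Stimulus",
    "label": "Label",
}

MANDATORY_FIELDS = ("x", "y", "duration_ms", "subject")


class FixationTableError(ValueError):
    """A fixation table violates the expected format."""


class EmptyScanpathError(ValueError):
    """Every record of a scanpath was invalid."""


@dataclass(frozen=True)
class FixationRecord:
    """One fixation: where the gaze paused, for how long, and whose it was."""

    x: float
    y: float
    duration_ms: float
    subject: str
    stimulus: str = ""
    label: str | None = None


@dataclass
class Scanpath:
    """Ordered fixation sequence of one subject on one stimulus."""

    records: list[FixationRecord]
    screen_dims: tuple[int, int] = (1920, 1080)

    def __post_init__(self) -> None:
        subjects = {r.subject for r in self.records}
        stimuli = {r.stimulus for r in self.records}
        if len(subjects) > 1 or len(stimuli) > 1:
            raise ValueError(
                "scanpath records must share subject and stimulus; "
                f"got subjects={sorted(subjects)} stimuli={sorted(stimuli)}"
            )

    def __len__(self) -> int:
        return len(self.records)

    @property
    def subject(self) -> str:
        return self.records[0].subject if self.records else ""

    @property
    def stimulus(self) -> str:
        return self.records[0].stimulus if self.records else ""

    @property
    def label(self) -> str | None:
        return self.records[0].label if self.records else None

    def xy(self) -> list[tuple[float, float]]:
        return [(r.x, r.y) for r in self.records]

    def durations(self) -> list[float]:
        return [r.duration_ms for r in self.records]


@dataclass
class ValidationReport:
    """Rows dropped during validation, with the reason for each."""

    dropped: list[tuple[int, str]] = field(default_factory=list)

    def __bool__(self) -> bool:
        return bool(self.dropped)


def read_fixation_table(
    path: str | Path,
    dialect: Mapping[str, str] | None = None,
    *,
    delimiter: str = ",",
    screen_dims: tuple[int, int] = (1920, 1080),
) -> list[Scanpath]:
    """Read a fixation CSV and group rows into per-(subject, stimulus) scanpaths.

    The tracker export has no stimulus column: if the dialect's stimulus
    column is absent from the header, the whole file is treated as one
    stimulus identified by the file stem.  Row order within each group is
    preserved (it is the temporal order of fixations).

    Raises
    ------
    FixationTableError
        If a mandatory column is missing or a coordinate/duration cell does
        not parse as a number (the error names the column / row).
    """
    path = Path(path)
    cols = dict(DEFAULT_DIALECT)
    if dialect:
        cols.update(dialect)

    df = pd.read_csv(path, delimiter=delimiter, dtype=str, keep_default_na=False)
    for fld in MANDATORY_FIELDS:
        if cols[fld] not in df.columns:
            raise FixationTableError(
                f"{path.name}: missing mandatory column {cols[fld]!r}"
            )

    numeric: dict[str, pd.Series] = {}
    for fld in ("x", "y", "duration_ms"):
        parsed = pd.to_numeric(df[cols[fld]], errors="coerce")
        bad = parsed.isna()
        if bad.any():
            row = int(bad.idxmax()) + 2  # 1-based, plus header line
            raise FixationTableError(
                f"{path.name}: non-numeric value {df[cols[fld]][bad.idxmax()]!r} "
                f"in column {cols[fld]!r} at line {row}"
            )
        numeric[fld] = parsed

    has_stim = cols["stimulus"] in df.columns
    has_label = cols["label"] in df.columns
    stimuli = df[cols["stimulus"]] if has_stim else None

    records_by_group: dict[tuple[str, str], list[FixationRecord]] = {}
    for i in range(len(df)):
        subject = str(df[cols["subject"]].iloc[i])
        stimulus = str(stimuli.iloc[i]) if stimuli is not None else path.stem
        rec = FixationRecord(
            x=float(numeric["x"].iloc[i]),
            y=float(numeric["y"].iloc[i]),
            duration_ms=float(numeric["duration_ms"].iloc[i]),
            subject=subject,
            stimulus=stimulus,
            label=(str(df[cols["label"]].iloc[i]) or None) if has_label else None,
        )
        records_by_group.setdefault((subject, stimulus), []).append(rec)

    return [
        Scanpath(records=recs, screen_dims=screen_dims)
        for recs in records_by_group.values()
    ]


def validate_records(
    scanpath: Scanpath,
    screen_dims: tuple[int, int] | None = None,
) -> tuple[Scanpath, ValidationReport]:
    """Drop out-of-bounds or non-positive-duration fixations.

    Out-of-bounds fixations are removed rather than clamped: clamping would
    fabricate attention at the screen edges.  Survivor order is unchanged.

    Raises
    ------
    EmptyScanpathError
        If every record is dropped.
    """
    if not scanpath.records:
        raise EmptyScanpathError("scanpath has no records")
    width, height = screen_dims or scanpath.screen_dims
    report = ValidationReport()
    kept: list[FixationRecord] = []
    for i, rec in enumerate(scanpath.records):
        if not (0 <= rec.x < width):
            report.dropped.append((i, "x out of range"))
        elif not (0 <= rec.y < height):
            report.dropped.append((i, "y out of range"))
        elif not rec.duration_ms > 0:
            report.dropped.append((i, "non-positive duration"))
        else:
            kept.append(rec)
    for i, reason in report.dropped:
        logger.warning(
            "dropping fixation %d of %s/%s: %s",
            i, scanpath.subject, scanpath.stimulus, reason,
        )
    if not kept:
        raise EmptyScanpathError(
            f"all {len(scanpath)} records of {scanpath.subject}/"
            f"{scanpath.stimulus} were invalid"
        )
    return Scanpath(records=kept, screen_dims=(width, height)), report


def write_fixation_table(
    scanpaths: Sequence[Scanpath],
    path: str | Path,
    *,
    dialect: Mapping[str, str] | None = None,
    delimiter: str = ",",
) -> Path:
    """Write scanpaths to one CSV in the tracker dialect.

    Stimulus and label columns are always written so that
    :func:`read_fixation_table` reproduces the grouping (round trip).
    """
    if not scanpaths:
        raise ValueError("no scanpaths to write")
    path = Path(path)
    cols = dict(DEFAULT_DIALECT)
    if dialect:
        cols.update(dialect)
    rows = [
        {
            cols["x"]: rec.x,
            cols["y"]: rec.y,
            cols["duration_ms"]: rec.duration_ms,
            cols["subject"]: rec.subject,
            cols["stimulus"]: rec.stimulus,
            cols["label"]: rec.label if rec.label is not None else "",
        }
        for sp in scanpaths
        for rec in sp.records
    ]
    pd.DataFrame(rows).to_csv(path, sep=delimiter, index=False)
    return path
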