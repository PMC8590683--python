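"""Reading and writing the plain-text record formats used by the pipeline.

All downstream modules consume only the types defined here:

* :class:`RRISeries` — one subject's ordered R-R intervals, in seconds.
* :class:`EventAnnotation` — an apnea/hypopnea/arrhythmia episode given as
  record-relative onset and duration (seconds).
* :class:`SubjectRecord` — subject id plus apnea-hypopnea index (AHI);
  the moderate-to-severe group is defined by AHI >= 15.

File conventions: comma-separated UTF-8, an optional single header line
detected by a non-numeric first token.  RRI files carry intervals only
(column ``rri_s``); beat times are always derived as cumulative sums so
there is a single source of truth for elapsed time.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "RRISeries",
    "EventAnnotation",
    "SubjectRecord",
    "EVENT_TYPES",
    "AHI_PATIENT_CUTOFF",
    "read_rri",
    "write_rri",
    "read_annotations",
    "write_annotations",
    "read_subject_table",
    "write_subject_table",
    "write_predictions",
    "read_predictions",
]

EVENT_TYPES = frozenset({"apnea", "hypopnea", "arrhythmia"})

#: AHI (events/hour) at or above which a subject is moderate-to-severe SAS.
AHI_PATIENT_CUTOFF = 15.0


class ValidationError(ValueError):
    """Raised when an input file or record violates a domain invariant."""


@dataclass(frozen=True)
class RRISeries:
    """Ordered R-R intervals for one subject.

    Parameters
    ----------
    subject_id : str
        Opaque identifier.
    intervals : ndarray
        Positive durations in seconds, in beat order.
    origin_time : float
        Elapsed-time zero point in seconds (default 0).
    """

    subject_id: str
    intervals: np.ndarray
    origin_time: float = 0.0

    def __post_init__(self) -> None:
        arr = np.asarray(self.intervals, dtype=float)
        if arr.ndim != 1 or arr.size < 1:
            raise ValidationError("RRISeries needs at least one interval")
        if not np.all(np.isfinite(arr)):
            raise ValidationError("RRISeries contains non-finite intervals")
        if np.any(arr <= 0):
            bad = int(np.flatnonzero(arr <= 0)[0])
            raise ValidationError(
                f"RRI interval at position {bad + 1} is non-positive ({arr[bad]!r})"
            )
        object.__setattr__(self, "intervals", arr)

    def __len__(self) -> int:
        return int(self.intervals.size)

    @property
    def duration(self) -> float:
        """Total record duration in seconds (sum of intervals)."""
        return float(self.intervals.sum())

    def beat_times(self) -> np.ndarray:
        """Cumulative beat times in seconds, relative to ``origin_time``.

        The first R wave is at ``origin_time``; interval *t* separates
        beats *t* and *t+1*, so ``len(beat_times) == len(intervals) + 1``.
        """
        return self.origin_time + np.concatenate(([0.0], np.cumsum(self.intervals)))


@dataclass(frozen=True, order=True)
class EventAnnotation:
    """A scored episode: onset and duration in seconds from record start."""

    onset: float
    duration: float
    event_type: str = field(compare=False)

    def __post_init__(self) -> None:
        if self.onset < 0:
            raise ValidationError(f"event onset must be >= 0, got {self.onset}")
        if self.duration <= 0:
            raise ValidationError(f"event duration must be > 0, got {self.duration}")
        if self.event_type not in EVENT_TYPES:
            raise ValidationError(
                f"unknown event_type {self.event_type!r}; expected one of {sorted(EVENT_TYPES)}"
            )

    @property
    def offset(self) -> float:
        return self.onset + self.duration


@dataclass(frozen=True)
class SubjectRecord:
    """Subject id and AHI; ``group`` derives from the AHI >= 15 cutoff."""

    subject_id: str
    ahi: float

    def __post_init__(self) -> None:
        if self.ahi < 0 or not np.isfinite(self.ahi):
            raise ValidationError(f"AHI must be finite and >= 0, got {self.ahi}")

    @property
    def group(self) -> str:
        return "patient" if self.ahi >= AHI_PATIENT_CUTOFF else "healthy"

    @property
    def is_patient(self) -> bool:
        return self.ahi >= AHI_PATIENT_CUTOFF


def _is_number(token: str) -> bool:
    try:
        float(token)
        return True
    except ValueError:
        return False


def _read_csv_maybe_header(path: Path, names: Sequence[str]) -> pd.DataFrame:
    """Read a CSV whose single header line is optional.

    Header presence is decided by whether the first token of the first
    line parses as a number.
    """
    with open(path, "r", encoding="utf-8") as fh:
        first = fh.readline()
    if not first.strip():
        raise ValidationError(f"{path}: empty file")
    has_header = not _is_number(first.split(",")[0].strip())
    if has_header:
        return pd.read_csv(path, float_precision="round_trip")
    return pd.read_csv(path, header=None, names=list(names), float_precision="round_trip")


def read_rri(path: str | Path, subject_id: str | None = None) -> RRISeries:
    """Read an RRI CSV (one interval in seconds per row, column ``rri_s``).

    Raises
    ------
    FileNotFoundError
        If ``path`` does not exist.
    ValidationError
        On a non-numeric row or a non-positive interval; the message
        names the offending row number (1-based, data rows).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = _read_csv_maybe_header(path, ["rri_s"])
    col = "rri_s" if "rri_s" in df.columns else df.columns[0]
    raw = df[col]
    numeric = pd.to_numeric(raw, errors="coerce")
    if numeric.isna().any():
        row = int(np.flatnonzero(numeric.isna().to_numpy())[0]) + 1
        raise ValidationError(f"{path}: non-numeric RRI value at data row {row}")
    values = numeric.to_numpy(dtype=float)
    if np.any(values <= 0):
        row = int(np.flatnonzero(values <= 0)[0]) + 1
        raise ValidationError(
            f"{path}: non-positive RRI ({values[row - 1]}) at data row {row}"
        )
    sid = subject_id if subject_id is not None else path.stem
    return RRISeries(subject_id=sid, intervals=values)


def write_rri(series: RRISeries, path: str | Path) -> None:
    """Write an RRI series as CSV with header ``rri_s`` using repr precision."""
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("rri_s\n")
        for v in series.intervals:
            fh.write(f"{float(v)!r}\n")


def read_annotations(path: str | Path) -> list[EventAnnotation]:
    """Read event annotations (``onset_s,duration_s,event_type``), sorted by onset."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    required = {"onset_s", "duration_s", "event_type"}
    if not required.issubset(df.columns):
        raise ValidationError(
            f"{path}: annotation file must have columns {sorted(required)}"
        )
    events = [
        EventAnnotation(
            onset=float(r.onset_s), duration=float(r.duration_s), event_type=str(r.event_type)
        )
        for r in df.itertuples(index=False)
    ]
    events.sort(key=lambda e: (e.onset, e.duration, e.event_type))
    _check_no_within_type_overlap(events)
    return events


def _check_no_within_type_overlap(events: Iterable[EventAnnotation]) -> None:
    last_end: dict[str, float] = {}
    for ev in sorted(events, key=lambda e: e.onset):
        end = last_end.get(ev.event_type, -np.inf)
        if ev.onset < end:
            raise ValidationError(
                f"overlapping {ev.event_type} events at onset {ev.onset}"
            )
        last_end[ev.event_type] = ev.offset


def write_annotations(events: Sequence[EventAnnotation], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("onset_s,duration_s,event_type\n")
        for ev in sorted(events, key=lambda e: (e.onset, e.duration, e.event_type)):
            fh.write(f"{float(ev.onset)!r},{float(ev.duration)!r},{ev.event_type}\n")


def read_subject_table(path: str | Path) -> list[SubjectRecord]:
    """Read the subject table CSV (``subject_id,ahi``)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    if not {"subject_id", "ahi"}.issubset(df.columns):
        raise ValidationError(f"{path}: subject table needs columns subject_id,ahi")
    return [
        SubjectRecord(subject_id=str(r.subject_id), ahi=float(r.ahi))
        for r in df.itertuples(index=False)
    ]


def write_subject_table(subjects: Sequence[SubjectRecord], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("subject_id,ahi\n")
        for s in subjects:
            fh.write(f"{s.subject_id},{float(s.ahi)!r}\n")


def write_predictions(rows: pd.DataFrame, path: str | Path) -> None:
    """Write per-segment predictions.

    Expects columns ``subject_id,segment_index,start_s,end_s,pred_label``.
    """
    required = ["subject_id", "segment_index", "start_s", "end_s", "pred_label"]
    missing = [c for c in required if c not in rows.columns]
    if missing:
        raise ValidationError(f"prediction frame missing columns {missing}")
    rows[required].to_csv(path, index=False)


def read_predictions(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"subject_id", "segment_index", "start_s", "end_s", "pred_label"}
    if not required.issubset(df.columns):
        raise ValidationError(f"{path}: prediction file needs columns {sorted(required)}")
    return df
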