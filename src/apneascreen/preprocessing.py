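"""Per-subject RRI standardization and fixed-duration segmentation.

The screening pipeline standardizes a whole night's R-R intervals to zero
mean and unit variance (handling between-subject differences in resting
heart rate), then splits the standardized tachogram into windows of fixed
wall-clock duration (60 s by default, the period of cyclical variation of
heart rate during repetitive apnea).  Window membership is decided purely
by cumulative elapsed time: interval *i* with cumulative sum
``c_i = z_1 + ... + z_i`` belongs to window *n* when
``60(n-1) < c_i <= 60 n`` — i.e. an interval is assigned to the window in
which it *ends*, and an interval whose cumulative sum lands exactly on a
boundary closes the earlier window.  A trailing partial window is
discarded so every segment spans the same nominal duration.

Ground-truth labels: a segment is apnea (``"A"``) when scored
apnea/hypopnea episodes cover at least ``label_overlap_s`` seconds of the
window (default 10 s, the minimum scoreable event duration), else normal
(``"N"``).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .io import EventAnnotation, RRISeries, ValidationError

__all__ = [
    "Segment",
    "SegmentSet",
    "standardize_rri",
    "segment_rri",
    "label_segments",
    "DEFAULT_WINDOW_WIDTH_S",
    "DEFAULT_LABEL_OVERLAP_S",
]

DEFAULT_WINDOW_WIDTH_S = 60.0
DEFAULT_LABEL_OVERLAP_S = 10.0

APNEA_LABEL = "A"
NORMAL_LABEL = "N"


@dataclass(frozen=True)
class Segment:
    """One fixed-duration window of a subject's standardized RRI.

    ``values`` carry the subject-level standardization; they are never
    re-standardized per segment.  ``start_s``/``end_s`` are the nominal
    window bounds, so ``end_s - start_s`` always equals the window width.
    """

    subject_id: str
    index: int  # 1-based window number n
    values: np.ndarray
    start_s: float
    end_s: float
    first_beat: int  # k_n, 1-based interval index
    last_beat: int  # j_n, 1-based interval index
    raw_values: np.ndarray | None = None  # same beats, unstandardized seconds

    @property
    def n_beats(self) -> int:
        return int(self.values.size)


@dataclass(frozen=True)
class SegmentSet:
    """Ordered segments for one subject plus optional per-segment labels."""

    subject_id: str
    segments: tuple[Segment, ...]
    window_width_s: float
    labels: tuple[str, ...] | None = field(default=None)

    def __post_init__(self) -> None:
        if self.labels is not None and len(self.labels) != len(self.segments):
            raise ValidationError("labels must align 1:1 with segments")

    def __len__(self) -> int:
        return len(self.segments)

    def with_labels(self, labels: Sequence[str]) -> "SegmentSet":
        bad = set(labels) - {APNEA_LABEL, NORMAL_LABEL}
        if bad:
            raise ValidationError(f"labels must be in {{A, N}}, got {sorted(bad)}")
        return replace(self, labels=tuple(labels))


def standardize_rri(series: RRISeries) -> np.ndarray:
    """Standardize a subject's RRI to zero mean and unit sample variance.

    The sample (n-1) standard deviation is used.  The original series is
    untouched — raw intervals remain the time base for segmentation.

    Raises
    ------
    ValidationError
        If the series has fewer than 2 intervals or zero dispersion.
    """
    x = series.intervals
    if x.size < 2:
        raise ValidationError("standardization needs at least 2 intervals")
    mean = float(np.mean(x))
    sd = float(np.std(x, ddof=1))
    # a bitwise-constant series can yield a one-ulp nonzero sd through the
    # rounded mean; treat dispersion at rounding level as zero
    if np.ptp(x) == 0 or sd < 1e-12 * abs(mean):
        raise ValidationError("constant RRI series has zero variance")
    return (x - mean) / sd


def segment_rri(
    series: RRISeries,
    standardized: np.ndarray,
    window_width_s: float = DEFAULT_WINDOW_WIDTH_S,
) -> SegmentSet:
    """Split a standardized RRI series into fixed-duration windows.

    Window *n* (1-based) covers elapsed time ``[(n-1) w, n w)`` and
    contains the standardized intervals whose cumulative raw sum lies in
    ``((n-1) w, n w]``.  The trailing partial window is discarded.

    Parameters
    ----------
    series : RRISeries
        Raw intervals; their cumulative sum is the time base.
    standardized : ndarray
        Output of :func:`standardize_rri`, aligned with ``series``.
    window_width_s : float
        Window width *w* in seconds (default 60).

    Raises
    ------
    ValidationError
        If the record is shorter than one window, or a window captures
        no beat (an interval longer than the window).
    """
    if window_width_s <= 0:
        raise ValidationError("window width must be positive")
    z = series.intervals
    if standardized.shape != z.shape:
        raise ValidationError("standardized values must align with the raw series")
    cumsum = np.cumsum(z)
    total = float(cumsum[-1])
    n_windows = int(np.floor(total / window_width_s + 1e-12))
    if n_windows < 1:
        raise ValidationError(
            f"record ({total:.1f} s) shorter than one {window_width_s:.0f}-s window"
        )
    # interval i (1-based) -> window ceil(cumsum_i / w); exact boundary hits
    # close the earlier window.  searchsorted gives both bounds in O(log N).
    boundaries = window_width_s * np.arange(n_windows + 1)
    # index of first interval with cumsum > (n-1)w  (0-based)
    k = np.searchsorted(cumsum, boundaries[:-1], side="right")
    # index of last interval with cumsum <= nw  (0-based, inclusive)
    j = np.searchsorted(cumsum, boundaries[1:], side="right") - 1
    segments = []
    for n in range(n_windows):
        if j[n] < k[n]:
            raise ValidationError(
                f"window {n + 1} contains no beat (interval exceeds window width)"
            )
        segments.append(
            Segment(
                subject_id=series.subject_id,
                index=n + 1,
                values=standardized[k[n] : j[n] + 1],
                start_s=float(boundaries[n]),
                end_s=float(boundaries[n + 1]),
                first_beat=int(k[n]) + 1,
                last_beat=int(j[n]) + 1,
                raw_values=z[k[n] : j[n] + 1],
            )
        )
    return SegmentSet(
        subject_id=series.subject_id,
        segments=tuple(segments),
        window_width_s=float(window_width_s),
    )


def _union_overlap(events: Sequence[EventAnnotation], start: float, end: float) -> float:
    """Seconds of [start, end) covered by the union of the given events."""
    clipped = sorted(
        (max(e.onset, start), min(e.offset, end))
        for e in events
        if e.offset > start and e.onset < end
    )
    covered = 0.0
    cursor = start
    for a, b in clipped:
        if b > cursor:
            covered += b - max(a, cursor)
            cursor = b
    return covered


def label_segments(
    segset: SegmentSet,
    events: Sequence[EventAnnotation],
    label_overlap_s: float = DEFAULT_LABEL_OVERLAP_S,
) -> SegmentSet:
    """Assign ground-truth A/N labels to segments from scored episodes.

    A segment is labeled apnea when the union of apnea and hypopnea
    episodes covers at least ``label_overlap_s`` seconds of its window.
    An empty event list yields all-normal labels.  Arrhythmia annotations
    never contribute to the apnea label.
    """
    resp = [e for e in events if e.event_type in ("apnea", "hypopnea")]
    labels = [
        APNEA_LABEL
        if _union_overlap(resp, seg.start_s, seg.end_s) >= label_overlap_s
        else NORMAL_LABEL
        for seg in segset.segments
    ]
    return segset.with_labels(labels)
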