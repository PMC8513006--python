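"""Reading accelerometer/annotation CSVs, alignment, labeling and trimming.

Each annotated activity interval is trimmed by removing the first 20 s and
the last 5 s before labeling, discarding the transition noise at activity
boundaries.  Interval membership is half-open, ``start + trim_front <= t <
end − trim_back``, so boundary samples are never double-counted.  Samples
between activities (breaks) are dropped, not labeled.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import labels as _labels
from .errors import (AnnotationError, CoverageError, DataError,
                     DegenerateIntervalError, EmptyRecordingError, LabelError,
                     ParseError, RateMismatchError)
from .labels import ActivityLabel
from .simulate import AnnotationLog, TriaxialRecording

RECORDING_HEADER = ["timestamp", "x", "y", "z"]
ANNOTATION_HEADER = ["participant_id", "activity", "start", "end"]


@dataclass
class LabeledSegment:
    """A contiguous trimmed block of samples for one activity."""

    participant_id: str
    activity: ActivityLabel
    t: np.ndarray
    xyz: np.ndarray

    def __len__(self) -> int:
        return len(self.t)


def read_recording(path: str | Path, participant_id: str | None = None,
                   expected_rate: float | None = None) -> TriaxialRecording:
    """Parse a `timestamp,x,y,z` CSV into a recording.

    The sampling rate is inferred from the median timestamp spacing and, if
    ``expected_rate`` is given, checked against it with ±1% tolerance.
    """
    path = Path(path)
    if participant_id is None:
        participant_id = path.stem
    try:
        df = pd.read_csv(path, dtype=float)
    except ValueError as exc:
        # pandas reports the offending line in its message
        raise ParseError(f"{path}: {exc}") from exc
    if list(df.columns) != RECORDING_HEADER:
        raise ParseError(f"{path}: header must be "
                         f"{','.join(RECORDING_HEADER)!r}, got "
                         f"{','.join(map(str, df.columns))!r}")
    if df.isna().any().any():
        row = int(df.isna().any(axis=1).idxmax()) + 2  # header is line 1
        raise ParseError(f"{path}: malformed row at line {row}")
    if len(df) == 0:
        raise EmptyRecordingError(f"{path}: no samples")
    t = df["timestamp"].to_numpy()
    if len(t) < 2:
        raise DataError(f"{path}: need at least two samples to infer rate")
    dt = np.diff(t)
    if np.any(dt <= 0):
        at = int(np.argmax(dt <= 0)) + 2
        raise DataError(f"{path}: non-increasing timestamps at line {at + 1}")
    rate = 1.0 / float(np.median(dt))
    if expected_rate is not None and abs(rate - expected_rate) > 0.01 * expected_rate:
        raise RateMismatchError(
            f"{path}: inferred rate {rate:.3f} Hz deviates >1% from "
            f"configured {expected_rate:.3f} Hz")
    return TriaxialRecording(participant_id, rate, t,
                             df[["x", "y", "z"]].to_numpy())


def read_annotations(path: str | Path) -> AnnotationLog:
    """Parse a per-participant `participant_id,activity,start,end` CSV."""
    path = Path(path)
    df = pd.read_csv(path)
    if list(df.columns) != ANNOTATION_HEADER:
        raise ParseError(f"{path}: header must be "
                         f"{','.join(ANNOTATION_HEADER)!r}")
    if len(df) == 0:
        raise AnnotationError(f"{path}: empty annotation log")
    pids = df["participant_id"].unique()
    if len(pids) != 1:
        raise AnnotationError(f"{path}: expected one participant, got {pids}")
    entries: list[tuple[ActivityLabel, float, float]] = []
    for _, row in df.iterrows():
        name = row["activity"]
        if name not in _labels.BY_NAME:
            raise LabelError(f"{path}: unknown activity {name!r}")
        entries.append((_labels.BY_NAME[name],
                        float(row["start"]), float(row["end"])))
    entries.sort(key=lambda e: e[1])
    for (_, _, e0), (a1, s1, _) in zip(entries, entries[1:]):
        if s1 < e0:
            raise AnnotationError(
                f"{path}: interval {a1.name!r} starting at {s1} overlaps "
                f"the previous interval ending at {e0}")
    return AnnotationLog(str(pids[0]), entries)


def align_and_trim(recording: TriaxialRecording, log: AnnotationLog,
                   trim_front: float = 20.0, trim_back: float = 5.0
                   ) -> list[LabeledSegment]:
    """Label and trim: one segment per annotation, keeping samples with
    ``start + trim_front <= t < end − trim_back``.
    """
    segments: list[LabeledSegment] = []
    t = recording.t
    for label, start, end in log.entries:
        if end - start <= trim_front + trim_back:
            raise DegenerateIntervalError(
                f"{label.name!r}: interval of {end - start:g} s is shorter "
                f"than trim_front + trim_back = {trim_front + trim_back:g} s")
        if start < t[0] - 1e-9 or end > t[-1] + 1.0 / recording.sampling_rate + 1e-9:
            raise CoverageError(
                f"{label.name!r}: interval [{start:g}, {end:g}] not covered "
                f"by recording [{t[0]:g}, {t[-1]:g}]")
        lo = np.searchsorted(t, start + trim_front - 1e-9, side="left")
        hi = np.searchsorted(t, end - trim_back - 1e-9, side="left")
        segments.append(LabeledSegment(
            recording.participant_id, label,
            t[lo:hi].copy(), recording.xyz[lo:hi].copy()))
    return segments
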