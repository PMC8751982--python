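"""Frame/subsequence/bout data model and ethogram file I/O.

A *FrameSequence* is one video: an ordered stream of behavior labels, one
per frame, for a single animal in a single feed state. Arena resets (RESET
frames) split the stream into *subsequences* — the unit on which all
per-sequence statistics are computed. Within a subsequence, maximal runs
of one behavior are *bouts*; bout length is the dwell time.

Frame indexing is 0-based and bout intervals are half-open ``[start, end)``
so durations add without off-by-one corrections.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import (
    EmptyFile,
    NonContiguousFrames,
    UnknownBehaviorCode,
)
from .vocab import (
    BY_CODE,
    DEFAULT_FPS,
    INSTANTANEOUS,
    RESET,
)

TERMINATIONS = ("capture", "escape_reset", "experimenter", "timeout")


@dataclass(frozen=True)
class FrameRecord:
    """One labeled video frame."""

    frame_index: int
    behavior: str
    fps: float = DEFAULT_FPS

    @property
    def time_s(self) -> float:
        return self.frame_index / self.fps


@dataclass
class FrameSequence:
    """Per-frame behavior labels for one video (one animal x feed state)."""

    animal_id: str
    feed_state: int
    labels: np.ndarray  # 1-D array of behavior code strings
    fps: float = DEFAULT_FPS

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=object)
        if self.labels.size == 0:
            raise EmptyFile("frame sequence has no frames")
        bad = sorted({c for c in self.labels if c not in BY_CODE})
        if bad:
            raise UnknownBehaviorCode(f"unknown behavior code(s): {bad}")
        if self.feed_state not in (0, 1, 2, 3, 4):
            raise ValueError(f"feed_state must be 0..4, got {self.feed_state}")
        if self.fps <= 0:
            raise ValueError("fps must be positive")

    def __len__(self) -> int:
        return int(self.labels.size)

    @property
    def duration_s(self) -> float:
        return len(self) / self.fps

    def records(self) -> list[FrameRecord]:
        return [FrameRecord(i, c, self.fps) for i, c in enumerate(self.labels)]


@dataclass
class Subsequence:
    """Maximal run of frames between arena resets.

    ``start``/``stop`` index into the parent label stream (half-open) and
    never include a RESET frame. ``termination`` records why the run ended:
    ``capture`` (last behavior before the reset was a successful strike),
    ``escape_reset`` (escape attempt forced the reset), ``experimenter``
    (any other reset cause) or ``timeout`` (end of trial, no reset).
    """

    parent: FrameSequence
    ordinal: int  # 1-based within the video
    start: int
    stop: int
    termination: str

    def __post_init__(self) -> None:
        if self.stop <= self.start:
            raise ValueError("empty subsequence")
        if self.termination not in TERMINATIONS:
            raise ValueError(f"bad termination {self.termination!r}")

    @property
    def labels(self) -> np.ndarray:
        return self.parent.labels[self.start : self.stop]

    @property
    def n_frames(self) -> int:
        return self.stop - self.start

    @property
    def fps(self) -> float:
        return self.parent.fps

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.fps

    @property
    def animal_id(self) -> str:
        return self.parent.animal_id

    @property
    def feed_state(self) -> int:
        return self.parent.feed_state

    def __len__(self) -> int:
        return self.n_frames


@dataclass(frozen=True)
class Bout:
    """Maximal run of one behavior: half-open frame interval [start, end)."""

    behavior: str
    start_frame: int
    end_frame: int
    fps: float = DEFAULT_FPS

    def __post_init__(self) -> None:
        if self.end_frame <= self.start_frame:
            raise ValueError("bout must span at least one frame")

    @property
    def n_frames(self) -> int:
        return self.end_frame - self.start_frame

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.fps


def read_ethogram(
    path: str | Path,
    fps: float = DEFAULT_FPS,
    animal_id: str | None = None,
    feed_state: int | None = None,
) -> FrameSequence:
    """Read a frame-level ethogram CSV into a validated FrameSequence.

    Expected columns: ``frame,behavior`` with optional ``animal_id`` and
    ``feed_state`` columns that override the arguments. Behavior strings
    are matched case-insensitively against the 12-code vocabulary; ``#``
    lines are comments. Frame indices must be 0,1,2,... contiguous.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, comment="#", dtype={"frame": "Int64"})
    except pd.errors.EmptyDataError:
        raise EmptyFile(f"{path}: no data rows") from None
    if df.empty:
        raise EmptyFile(f"{path}: no data rows")
    for col in ("frame", "behavior"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")

    codes = df["behavior"].astype(str).str.strip().str.upper().to_numpy(dtype=object)
    bad_mask = np.array([c not in BY_CODE for c in codes])
    if bad_mask.any():
        row = int(np.flatnonzero(bad_mask)[0])
        raise UnknownBehaviorCode(
            f"{path}: unknown behavior {codes[row]!r} at data row {row} "
            f"(frame {df['frame'].iloc[row]})"
        )

    frames = df["frame"].to_numpy(dtype=np.int64)
    expected = np.arange(len(frames))
    if not np.array_equal(frames, expected):
        first = int(np.flatnonzero(frames != expected)[0])
        raise NonContiguousFrames(
            f"{path}: frame index {frames[first]} at row {first}, expected {expected[first]}"
        )

    if "animal_id" in df.columns:
        animal_id = str(df["animal_id"].iloc[0])
    if "feed_state" in df.columns:
        feed_state = int(df["feed_state"].iloc[0])
    if animal_id is None:
        animal_id = path.stem
    if feed_state is None:
        feed_state = 0

    _warn_long_strikes(codes, path)
    return FrameSequence(animal_id=animal_id, feed_state=feed_state, labels=codes, fps=fps)


def _warn_long_strikes(codes: np.ndarray, path: Path) -> None:
    """Strikes are instantaneous; a multi-frame strike run is one event."""
    for code, start, end in _runs(codes):
        if code in INSTANTANEOUS and end - start > 1:
            warnings.warn(
                f"{path}: {code} run of {end - start} frames at frame {start}; "
                "treated as a single instantaneous strike event",
                stacklevel=3,
            )


def write_ethogram(seq: FrameSequence, path: str | Path) -> None:
    """Write a FrameSequence to the ethogram CSV format (round-trips)."""
    df = pd.DataFrame(
        {
            "frame": np.arange(len(seq)),
            "behavior": seq.labels,
            "animal_id": seq.animal_id,
            "feed_state": seq.feed_state,
        }
    )
    df.to_csv(path, index=False)


def _runs(labels: Sequence[str]) -> list[tuple[str, int, int]]:
    """Maximal equal-label runs as (code, start, end) half-open triples."""
    arr = np.asarray(labels, dtype=object)
    if arr.size == 0:
        return []
    change = np.flatnonzero(arr[1:] != arr[:-1]) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [arr.size]))
    return [(arr[s], int(s), int(e)) for s, e in zip(starts, ends)]


def segment_subsequences(seq: FrameSequence) -> list[Subsequence]:
    """Split a video at arena resets.

    RESET frames belong to no subsequence. A subsequence followed by a
    reset is terminated by ``capture`` when its last frame is a successful
    strike, ``escape_reset`` when it is an escape attempt, otherwise
    ``experimenter``. Trailing frames after the last reset (or a video
    with no reset) form a final subsequence with ``termination='timeout'``.
    """
    labels = seq.labels
    is_reset = labels == RESET
    subs: list[Subsequence] = []
    ordinal = 1
    start = 0
    for i in range(len(labels) + 1):
        at_end = i == len(labels)
        if at_end or is_reset[i]:
            if i > start:
                if at_end:
                    term = "timeout"
                else:
                    last = labels[i - 1]
                    term = (
                        "capture"
                        if last == "SS"
                        else "escape_reset"
                        if last == "ESC"
                        else "experimenter"
                    )
                subs.append(Subsequence(seq, ordinal, start, i, term))
                ordinal += 1
            start = i + 1
    return subs


def run_length_encode(sub: Subsequence) -> list[Bout]:
    """Run-length encode a subsequence into bouts.

    Concatenating the bouts reproduces the frame labels exactly. A run of
    an instantaneous behavior (SS, MS), whatever its frame count, is a
    single bout representing one strike event.
    """
    if len(sub) == 0:
        raise ValueError("cannot encode an empty subsequence")
    fps = sub.fps
    return [
        Bout(code, sub.start + s, sub.start + e, fps)
        for code, s, e in _runs(sub.labels)
    ]


def expand_bouts(bouts: Iterable[Bout]) -> list[str]:
    """Inverse of run_length_encode: bouts back to a per-frame label list."""
    out: list[str] = []
    for b in bouts:
        out.extend([b.behavior] * b.n_frames)
    return out


BOUT_COLUMNS = [
    "animal_id",
    "feed_state",
    "subsequence",
    "behavior",
    "start_frame",
    "end_frame",
    "duration_s",
]


def bout_table(subsequences: Iterable[Subsequence]) -> pd.DataFrame:
    """Tidy table of every bout in the given subsequences."""
    rows = []
    for sub in subsequences:
        for b in run_length_encode(sub):
            rows.append(
                (
                    sub.animal_id,
                    sub.feed_state,
                    sub.ordinal,
                    b.behavior,
                    b.start_frame,
                    b.end_frame,
                    b.duration_s,
                )
            )
    return pd.DataFrame(rows, columns=BOUT_COLUMNS)


def write_bout_table(bouts: pd.DataFrame, path: str | Path) -> None:
    """Write a bout table as CSV with 6-significant-digit durations."""
    out = bouts.copy()
    out["duration_s"] = out["duration_s"].map(lambda x: float(f"{x:.6g}"))
    out.to_csv(path, index=False, columns=BOUT_COLUMNS)


def read_bout_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")[BOUT_COLUMNS]
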