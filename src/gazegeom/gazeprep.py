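"""From raw gaze samples and word events to per-trial medians and displacements.

The preprocessing deliberately does almost nothing: invalid samples (blinks,
off-screen track losses) are excluded and the median gaze position in the
500 ms window before each word onset is extracted per trial.  No filtering,
smoothing, interpolation or detrending is applied — the effects of interest
are expected at the level of raw spontaneous gaze.

Conventions: screen origin top-left, y increasing downward; the pre-onset
window is half-open, [onset - window_ms, onset), so the onset sample itself
is excluded; a transition is only formed between trials adjacent in
utterance order within the same block, and is dropped if either member is
invalid (no bridging across lost trials).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import DataError

__all__ = [
    "GazeRecording",
    "WordEvent",
    "clean_recording",
    "window_median_gaze",
    "displacement_series",
    "DEFAULT_WINDOW_MS",
    "DEFAULT_MIN_SAMPLES",
]

logger = logging.getLogger(__name__)

DEFAULT_WINDOW_MS = 500.0
#: minimum valid samples for a trial median (10 ms of data at 1 kHz)
DEFAULT_MIN_SAMPLES = 10


@dataclass
class GazeRecording:
    """Time-stamped gaze samples for one subject/block.

    time_ms must be strictly increasing; x/y are screen pixels and must be
    finite wherever valid is True.
    """

    time_ms: np.ndarray
    x_px: np.ndarray
    y_px: np.ndarray
    valid: np.ndarray

    def __post_init__(self):
        self.time_ms = np.asarray(self.time_ms, dtype=float)
        self.x_px = np.asarray(self.x_px, dtype=float)
        self.y_px = np.asarray(self.y_px, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        n = len(self.time_ms)
        if not (len(self.x_px) == len(self.y_px) == len(self.valid) == n):
            raise DataError("gaze columns have unequal lengths")
        if n > 1 and not np.all(np.diff(self.time_ms) > 0):
            raise DataError("timestamps must be strictly increasing")
        if n and not np.all(np.isfinite(
                np.c_[self.x_px, self.y_px][self.valid])):
            raise DataError("x/y must be finite where valid")

    def __len__(self) -> int:
        return len(self.time_ms)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_ms": self.time_ms, "x_px": self.x_px,
                             "y_px": self.y_px,
                             "valid": self.valid.astype(int)})

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "GazeRecording":
        return cls(df["time_ms"].to_numpy(), df["x_px"].to_numpy(),
                   df["y_px"].to_numpy(), df["valid"].to_numpy().astype(bool))

    @classmethod
    def from_tsv(cls, path: str | Path) -> "GazeRecording":
        return cls.from_frame(pd.read_csv(path, sep="\t"))


@dataclass(frozen=True)
class WordEvent:
    """One uttered word with its onset/offset (ms) within a block."""

    subject: str
    block: int
    word: str
    onset_ms: float
    offset_ms: float

    def __post_init__(self):
        if not self.onset_ms < self.offset_ms:
            raise DataError(
                f"event {self.word!r}: onset must precede offset")


def events_from_frame(df: pd.DataFrame) -> list[WordEvent]:
    """Build time-ordered WordEvents from an events table, checking overlap."""
    evs = [WordEvent(str(r.subject), int(r.block), str(r.word),
                     float(r.onset_ms), float(r.offset_ms))
           for r in df.itertuples()]
    by_block: dict = {}
    for e in evs:
        by_block.setdefault((e.subject, e.block), []).append(e)
    for key, block_evs in by_block.items():
        for a, b in zip(block_evs, block_evs[1:]):
            if b.onset_ms < a.offset_ms:
                raise DataError(f"overlapping events in block {key}: "
                                f"{a.word!r} / {b.word!r}")
    return evs


def clean_recording(rec: GazeRecording) -> GazeRecording:
    """Drop invalid samples; apply no other transformation."""
    keep = rec.valid
    return GazeRecording(rec.time_ms[keep], rec.x_px[keep], rec.y_px[keep],
                         np.ones(int(keep.sum()), dtype=bool))


def window_median_gaze(rec: GazeRecording, events: Sequence[WordEvent] | pd.DataFrame,
                       window_ms: float = DEFAULT_WINDOW_MS,
                       min_samples: int = DEFAULT_MIN_SAMPLES) -> pd.DataFrame:
    """Median gaze position in the pre-onset window of every word event.

    Returns the trial table (one row per event, in event order) with columns
    block, word, median_x_px, median_y_px, n_valid_samples, valid.  A trial
    is invalid when fewer than min_samples valid samples fall in
    [onset - window_ms, onset); events outside the recording span are marked
    invalid with a logged warning.
    """
    if window_ms <= 0:
        raise DataError("window_ms must be positive")
    if isinstance(events, pd.DataFrame):
        events = events_from_frame(events)
    t = rec.time_ms
    rows = []
    for ev in events:
        lo = np.searchsorted(t, ev.onset_ms - window_ms, "left")
        hi = np.searchsorted(t, ev.onset_ms, "left")
        if len(t) and (ev.onset_ms - window_ms > t[-1] or ev.onset_ms <= t[0]):
            logger.warning("event %r at %.0f ms lies outside the recording span",
                           ev.word, ev.onset_ms)
        sel = rec.valid[lo:hi]
        n_valid = int(sel.sum())
        ok = n_valid >= min_samples
        rows.append((ev.subject, ev.block, ev.word,
                     float(np.median(rec.x_px[lo:hi][sel])) if ok else np.nan,
                     float(np.median(rec.y_px[lo:hi][sel])) if ok else np.nan,
                     n_valid, ok))
    return pd.DataFrame(rows, columns=["subject", "block", "word", "median_x_px",
                                       "median_y_px", "n_valid_samples", "valid"])


def displacement_series(trials: pd.DataFrame) -> pd.DataFrame:
    """Trial-to-trial gaze displacements between adjacent valid trials.

    For each pair of trials adjacent in utterance order within the same
    block and both valid: dx = next.x - current.x, dy likewise, d2 = hypot.
    The returned frame carries ``transition`` (positional index of the first
    trial of the pair in the full trial table) for alignment with conceptual
    change series.
    """
    t = trials.reset_index(drop=True)
    rows = []
    for i in range(len(t) - 1):
        a, b = t.iloc[i], t.iloc[i + 1]
        if a["block"] != b["block"] or a["subject"] != b["subject"]:
            continue
        if not (a["valid"] and b["valid"]):
            continue
        dx = float(b["median_x_px"] - a["median_x_px"])
        dy = float(b["median_y_px"] - a["median_y_px"])
        rows.append((i, a["block"], dx, dy, float(np.hypot(dx, dy))))
    return pd.DataFrame(rows, columns=["transition", "block", "dx", "dy", "d2"])
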