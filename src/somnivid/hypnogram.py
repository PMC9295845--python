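"""Hypnogram container and run-length utilities.

A hypnogram is a time series of discrete behavioral-state labels at a fixed
epoch length. Two alphabets are used throughout the package:

* two-state video scoring: ``{"Wake", "Sleep"}``
* three-state EEG/EMG scoring: ``{"Wake", "NREM", "REM"}``

Per-second hypnograms are simply hypnograms with ``epoch_s == 1``. A *bout*
is a maximal run of consecutive identical labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

WAKE = "Wake"
SLEEP = "Sleep"
NREM = "NREM"
REM = "REM"

TWO_STATE = frozenset({WAKE, SLEEP})
THREE_STATE = frozenset({WAKE, NREM, REM})


@dataclass(frozen=True)
class Run:
    """A maximal run of one label: ``[start, start + length)`` in epochs."""

    label: str
    start: int
    length: int

    @property
    def stop(self) -> int:
        return self.start + self.length


def run_length_encode(labels: Sequence[str] | np.ndarray) -> list[Run]:
    """Run-length encode a label sequence into maximal same-label runs."""
    labels = np.asarray(labels)
    if labels.size == 0:
        return []
    change = np.flatnonzero(labels[1:] != labels[:-1]) + 1
    starts = np.concatenate(([0], change))
    stops = np.concatenate((change, [labels.size]))
    return [Run(str(labels[a]), int(a), int(b - a)) for a, b in zip(starts, stops)]


@dataclass
class Hypnogram:
    """State labels at fixed epoch resolution.

    Parameters
    ----------
    labels : array of str
        One state label per epoch.
    epoch_s : float
        Epoch length in seconds (1 for per-second hypnograms).
    start_time_s : float
        Recording time of the first epoch's left edge.
    zeitgeber_offset_s : float
        Recording time of lights-on (ZT0); used by the hourly summaries.
    meta : dict
        Free-form provenance (e.g. injected REM onsets from the simulator).
    """

    labels: np.ndarray
    epoch_s: float = 1.0
    start_time_s: float = 0.0
    zeitgeber_offset_s: float = 0.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype="U8")
        if self.epoch_s <= 0:
            raise ValueError(f"epoch_s must be positive, got {self.epoch_s}")
        alphabet = set(self.labels.tolist())
        if not (alphabet <= TWO_STATE or alphabet <= THREE_STATE):
            bad = alphabet - (TWO_STATE | THREE_STATE)
            raise ValueError(f"unknown state labels: {sorted(bad)}")

    # -- basic queries ----------------------------------------------------
    def __len__(self) -> int:
        return int(self.labels.size)

    def __iter__(self) -> Iterator[str]:
        return iter(self.labels.tolist())

    @property
    def duration_s(self) -> float:
        return len(self) * self.epoch_s

    @property
    def states(self) -> set[str]:
        return set(np.unique(self.labels).tolist())

    @property
    def is_three_state(self) -> bool:
        return bool(self.states & {NREM, REM})

    def runs(self) -> list[Run]:
        return run_length_encode(self.labels)

    def bout_count(self, label: str = SLEEP) -> int:
        """Number of maximal runs of ``label``."""
        return sum(1 for r in self.runs() if r.label == label)

    def time_in_state(self, label: str) -> float:
        """Total seconds spent in ``label``."""
        return float(np.count_nonzero(self.labels == label)) * self.epoch_s

    # -- transformations --------------------------------------------------
    def collapse_to_two_state(self) -> "Hypnogram":
        """Map NREM and REM onto Sleep (video scoring cannot separate them)."""
        labels = np.where(np.isin(self.labels, [NREM, REM]), SLEEP, self.labels)
        return Hypnogram(labels, self.epoch_s, self.start_time_s,
                         self.zeitgeber_offset_s, dict(self.meta))

    def replace_labels(self, labels: np.ndarray) -> "Hypnogram":
        out = Hypnogram(np.asarray(labels), self.epoch_s, self.start_time_s,
                        self.zeitgeber_offset_s, dict(self.meta))
        return out

    # -- I/O --------------------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        idx = np.arange(len(self))
        return pd.DataFrame({
            "epoch_index": idx,
            "start_s": self.start_time_s + idx * self.epoch_s,
            "label": self.labels,
        })

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, epoch_s: float | None = None) -> "Hypnogram":
        df = pd.read_csv(path)
        if epoch_s is None:
            if len(df) >= 2:
                epoch_s = float(df["start_s"].iloc[1] - df["start_s"].iloc[0])
            else:
                epoch_s = 1.0
        start = float(df["start_s"].iloc[0]) if len(df) else 0.0
        return cls(df["label"].to_numpy(dtype="U8"), epoch_s, start)
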