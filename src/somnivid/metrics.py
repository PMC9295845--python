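"""Hypnogram agreement metrics and EEG-derived analytics.

Validation of video staging against a reference hypnogram is epoch-by-epoch
with Sleep as the positive class (the characteristic failure mode of
immobility-based scoring — small movements during sleep misread as waking —
is a sensitivity loss). EEG analytics operate on per-epoch 1 Hz band-power
tables (1–30 Hz): the relative NREM delta-power ratio Σ(1–4 Hz)/Σ(1–30 Hz)
averaged over NREM epochs per hour, per-state power spectra as percentages
of total 1–30 Hz power, a rule-based three-state stager, and wake→REM
transition (narcolepsy-like episode) detection.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .hypnogram import Hypnogram, NREM, REM, SLEEP, WAKE

logger = logging.getLogger(__name__)

N_BINS = 30
BIN_COLS = [f"bin_{k}" for k in range(1, N_BINS + 1)]
DELTA_BINS = [f"bin_{k}" for k in range(1, 5)]    # 1-4 Hz inclusive
THETA_BINS = [f"bin_{k}" for k in range(6, 10)]   # 6-9 Hz inclusive


@dataclass(frozen=True)
class AgreementResult:
    """Epoch-by-epoch confusion summary; Sleep is the positive class."""

    tp: int          # sleep scored sleep
    tn: int          # wake scored wake
    fp: int          # wake scored sleep
    fn: int          # sleep scored wake
    bout_count_test: int
    bout_count_reference: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")
        if self.n_epochs == 0:
            raise ValueError("empty comparison")

    @property
    def n_epochs(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn) if (self.tp + self.fn) else float("nan")

    @property
    def specificity(self) -> float:
        return self.tn / (self.tn + self.fp) if (self.tn + self.fp) else float("nan")

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / self.n_epochs

    def to_dict(self) -> dict:
        return {
            "tp": self.tp, "tn": self.tn, "fp": self.fp, "fn": self.fn,
            "n_epochs": self.n_epochs,
            "sensitivity": self.sensitivity, "specificity": self.specificity,
            "accuracy": self.accuracy,
            "bout_count_test": self.bout_count_test,
            "bout_count_reference": self.bout_count_reference,
        }


def compare_staging(test: Hypnogram, reference: Hypnogram) -> AgreementResult:
    """Score a test hypnogram against an epoch-aligned reference.

    A three-state reference is collapsed (NREM ∪ REM → Sleep) first — video
    staging cannot separate the two sleep stages. Sleep-bout counts come
    from run-length encoding of each hypnogram.
    """
    if len(test) != len(reference):
        raise ValueError(
            f"hypnogram lengths differ: test has {len(test)} epochs, "
            f"reference has {len(reference)}")
    if not np.isclose(test.epoch_s, reference.epoch_s):
        raise ValueError(
            f"epoch lengths differ: test {test.epoch_s} s vs "
            f"reference {reference.epoch_s} s")
    t = test.collapse_to_two_state().labels
    r = reference.collapse_to_two_state().labels
    tp = int(np.count_nonzero((t == SLEEP) & (r == SLEEP)))
    tn = int(np.count_nonzero((t == WAKE) & (r == WAKE)))
    fp = int(np.count_nonzero((t == SLEEP) & (r == WAKE)))
    fn = int(np.count_nonzero((t == WAKE) & (r == SLEEP)))
    return AgreementResult(
        tp=tp, tn=tn, fp=fp, fn=fn,
        bout_count_test=int(np.count_nonzero(np.diff(np.concatenate(
            ([0], (t == SLEEP).astype(np.int8)))) == 1)),
        bout_count_reference=int(np.count_nonzero(np.diff(np.concatenate(
            ([0], (r == SLEEP).astype(np.int8)))) == 1)),
    )


def sleep_time_summary(hypnogram: Hypnogram,
                       zeitgeber_offset_s: float | None = None
                       ) -> tuple[pd.DataFrame, pd.Series]:
    """Minutes per state per zeitgeber hour, plus daily totals.

    Multi-day recordings are averaged per ZT hour (hour 0 = lights-on).
    Returns ``(hourly, daily)`` where ``hourly`` is indexed by ZT hour 0-23
    and ``daily`` holds mean minutes per state per 24 h.
    """
    if zeitgeber_offset_s is None:
        zeitgeber_offset_s = hypnogram.zeitgeber_offset_s
    if zeitgeber_offset_s is None:
        raise ValueError("hypnogram has no zeitgeber anchor")
    idx = np.arange(len(hypnogram))
    t = hypnogram.start_time_s + idx * hypnogram.epoch_s - zeitgeber_offset_s
    zt_hour = ((t // 3600.0) % 24).astype(int)
    day = (t // 86400.0).astype(int)
    df = pd.DataFrame({"zt_hour": zt_hour, "day": day, "label": hypnogram.labels,
                       "minutes": hypnogram.epoch_s / 60.0})
    per_day = (df.pivot_table(index=["day", "zt_hour"], columns="label",
                              values="minutes", aggfunc="sum", fill_value=0.0))
    hourly = per_day.groupby(level="zt_hour").mean()
    hourly = hourly.reindex(range(24), fill_value=0.0)
    hourly.columns.name = None
    daily = hourly.sum(axis=0)
    daily.name = "minutes_per_day"
    return hourly, daily


# ---------------------------------------------------------------------------
# spectral analytics
# ---------------------------------------------------------------------------

def _check_spectral(epochs: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in BIN_COLS if c not in epochs.columns]
    if missing:
        raise ValueError(f"spectral table missing bins: {missing[:3]}...")
    if (epochs[BIN_COLS].to_numpy() < 0).any():
        raise ValueError("band powers must be non-negative")
    return epochs


def delta_ratio(epochs: pd.DataFrame) -> pd.Series:
    """Per-epoch Σ(1–4 Hz) / Σ(1–30 Hz); NaN where total power is zero."""
    _check_spectral(epochs)
    total = epochs[BIN_COLS].sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = epochs[DELTA_BINS].sum(axis=1) / total
    return ratio.where(total > 0)


def theta_ratio(epochs: pd.DataFrame) -> pd.Series:
    """Per-epoch Σ(6–9 Hz) / Σ(1–30 Hz)."""
    _check_spectral(epochs)
    total = epochs[BIN_COLS].sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = epochs[THETA_BINS].sum(axis=1) / total
    return ratio.where(total > 0)


def relative_delta_power(epochs: pd.DataFrame, hypnogram: Hypnogram) -> pd.Series:
    """Hourly mean NREM delta ratio; NaN for hours with no NREM epochs.

    Zero-total-power epochs are excluded (logged). The hypnogram supplies
    the NREM labels; a two-state hypnogram's Sleep epochs are treated as
    NREM (video scoring cannot separate stages, and NREM dominates).
    """
    if len(epochs) != len(hypnogram):
        raise ValueError(
            f"{len(epochs)} spectral epochs vs {len(hypnogram)} hypnogram epochs")
    ratio = delta_ratio(epochs)
    n_bad = int(ratio.isna().sum())
    if n_bad:
        logger.warning("%d epochs excluded for zero total power", n_bad)
    is_nrem = np.isin(hypnogram.labels, [NREM, SLEEP])
    start = hypnogram.start_time_s + np.arange(len(hypnogram)) * hypnogram.epoch_s
    hour = (start // 3600.0).astype(int)
    df = pd.DataFrame({"hour": hour, "ratio": ratio, "nrem": is_nrem})
    out = (df[df["nrem"]].groupby("hour")["ratio"].mean()
           .reindex(range(int(hour.max()) + 1 if len(hour) else 0)))
    out.name = "nrem_delta_ratio"
    return out


def state_power_spectra(epochs: pd.DataFrame, hypnogram: Hypnogram) -> pd.DataFrame:
    """Mean per-bin percentage of total 1–30 Hz power, per state.

    Each epoch's bins are normalized to percent of its own total power, then
    averaged within state, so every state's 30 bins sum to 100. States with
    no epochs are omitted with a note.
    """
    if len(epochs) != len(hypnogram):
        raise ValueError(
            f"{len(epochs)} spectral epochs vs {len(hypnogram)} hypnogram epochs")
    _check_spectral(epochs)
    power = epochs[BIN_COLS].to_numpy(dtype=float)
    total = power.sum(axis=1, keepdims=True)
    ok = total[:, 0] > 0
    pct = np.divide(power, total, out=np.zeros_like(power), where=total > 0) * 100.0
    rows = {}
    for state in sorted(set(hypnogram.labels.tolist())):
        sel = (hypnogram.labels == state) & ok
        if not sel.any():
            logger.info("state %s absent from recording; omitted", state)
            continue
        rows[state] = pct[sel].mean(axis=0)
    return pd.DataFrame.from_dict(rows, orient="index", columns=BIN_COLS)


# ---------------------------------------------------------------------------
# three-state analytics
# ---------------------------------------------------------------------------

def detect_wake_to_rem(hypnogram: Hypnogram,
                       min_wake_s: float | None = None
                       ) -> tuple[int, list[float]]:
    """Count direct wake→REM transitions (narcolepsy-like episodes).

    A REM run counts as an episode when the immediately preceding run is
    Wake of duration >= ``min_wake_s`` (default: one epoch). Healthy mice
    enter REM only from NREM, so any such transition is abnormal. Returns
    ``(count, onset_times_s)`` with onsets at the REM run starts.
    """
    if not hypnogram.is_three_state:
        raise ValueError("wake→REM detection requires a three-state hypnogram")
    if min_wake_s is None:
        min_wake_s = hypnogram.epoch_s
    runs = hypnogram.runs()
    onsets = []
    for prev, cur in zip(runs, runs[1:]):
        if (cur.label == REM and prev.label == WAKE
                and prev.length * hypnogram.epoch_s >= min_wake_s):
            onsets.append(hypnogram.start_time_s + cur.start * hypnogram.epoch_s)
    return len(onsets), onsets


@dataclass
class EegCutoffs:
    """Rule-based stager cutoffs (simplified stand-in; no parity claim)."""

    delta_ratio: float = 0.4
    theta_ratio: float = 0.45
    emg_low_percentile: float = 50.0     # below -> low tonus (NREM-compatible)
    emg_atonia_percentile: float = 10.0  # below -> atonia (REM-compatible)


def rule_based_eeg_stager(epochs: pd.DataFrame,
                          cutoffs: EegCutoffs | None = None,
                          epoch_s: float = 20.0) -> Hypnogram:
    """Three-state staging from per-epoch band powers and an EMG summary.

    Rules, applied per epoch: high theta ratio with EMG atonia → REM; high
    delta ratio with low EMG tonus → NREM; otherwise Wake. EMG cutoffs are
    percentiles of the recording's own EMG distribution. Without an ``emg``
    column a two-state (Wake/NREM) fallback on the delta rule alone is
    returned with a warning.
    """
    cutoffs = cutoffs or EegCutoffs()
    d = delta_ratio(epochs).to_numpy()
    th = theta_ratio(epochs).to_numpy()
    if "emg" not in epochs.columns:
        warnings.warn("no EMG column; falling back to two-state delta-rule staging")
        labels = np.where(np.nan_to_num(d) > cutoffs.delta_ratio, NREM, WAKE)
        return Hypnogram(labels.astype("U8"), epoch_s=epoch_s)
    emg = epochs["emg"].to_numpy(dtype=float)
    emg_low = np.percentile(emg, cutoffs.emg_low_percentile)
    emg_atonia = np.percentile(emg, cutoffs.emg_atonia_percentile)
    labels = np.full(len(epochs), WAKE, dtype="U8")
    nrem = (np.nan_to_num(d) > cutoffs.delta_ratio) & (emg <= emg_low)
    rem = (np.nan_to_num(th) > cutoffs.theta_ratio) & (emg <= emg_atonia)
    labels[nrem] = NREM
    labels[rem] = REM    # atonia+theta dominates when both rules fire
    return Hypnogram(labels, epoch_s=epoch_s)
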