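"""Synthetic home-cage video with known sleep/wake ground truth.

The simulator emits the three things the staging pipeline consumes or is
validated against:

1. a ground-truth state sequence (alternating sleep/wake bouts from a
   shifted-gamma semi-Markov model, with brief movement "twitches" injected
   into sleep as a Poisson process — the artifact that a movement-merging
   filter must absorb),
2. rendered 8-bit grayscale frames: an elliptical mouse blob over a flat
   cage background with static distractor objects (food, water gel, a
   shadow) and a 12 h light / 12 h dark cycle, and
3. reference hypnograms (two-state, or three-state with REM placed either
   at sleep-bout tails or — in the narcolepsy scenario — directly after
   wake).

Everything is deterministic under a fixed seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from skimage.draw import disk as draw_disk, ellipse as draw_ellipse

from .hypnogram import Hypnogram, NREM, REM, SLEEP, WAKE, run_length_encode

LIGHT = "light"
DARK = "dark"

# Fixed 8-bit rendering palette (arbitrary but frozen so thresholds are stable).
BG_GRAY_LIGHT = 180
BG_GRAY_DARK = 40
MOUSE_GRAY = 120

#: (shape, (row, col), size_px, gray) — food hopper, water gel, wall shadow.
DEFAULT_DISTRACTORS = (
    ("disk", (0.18, 0.15), 0.9, 100),
    ("rect", (0.15, 0.85), 1.1, 150),
    ("disk", (0.85, 0.80), 1.4, 60),
)


@dataclass
class Distractor:
    shape: str                  # "disk" | "rect"
    position: tuple[int, int]   # (row, col) center, px
    size_px: int                # radius (disk) or half-side (rect)
    gray: int


@dataclass
class SimScenario:
    """Static description of the cage, camera, and lighting."""

    arena_size_px: tuple[int, int] = (576, 704)   # (rows, cols); native camera frame
    fps: float = 25.0
    duration_s: float = 3600.0
    light_cycle: list[tuple[float, float, str]] | None = None  # None -> 12 h/12 h
    mouse_radius_px: int = 30
    distractors: list[Distractor] | None = None   # None -> defaults; [] -> none
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration_s < 0:
            raise ValueError("duration_s must be >= 0")
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        if min(self.arena_size_px) < 4 * self.mouse_radius_px:
            raise ValueError(
                f"arena {self.arena_size_px} smaller than 4x mouse radius "
                f"{self.mouse_radius_px}")
        if self.distractors is None:
            h, w = self.arena_size_px
            r = self.mouse_radius_px
            self.distractors = [
                Distractor(shape, (int(fr * h), int(fc * w)), max(3, int(scale * r)), gray)
                for shape, (fr, fc), scale, gray in DEFAULT_DISTRACTORS
            ]

    @property
    def n_frames(self) -> int:
        return int(round(self.duration_s * self.fps))

    def phase_at(self, t_s: float) -> str:
        if self.light_cycle:
            for start, stop, phase in self.light_cycle:
                if start <= t_s < stop:
                    return phase
            return self.light_cycle[-1][2]
        return LIGHT if (t_s % 86400.0) < 43200.0 else DARK

    def expected_mouse_area_px(self) -> float:
        # rendered blob is an ellipse with semi-axes (r, 0.6 r)
        return float(np.pi * self.mouse_radius_px * 0.6 * self.mouse_radius_px)


@dataclass
class StateModel:
    """Semi-Markov sleep/wake bout model with sleep twitches.

    Bout durations follow a shifted gamma (shape 2, minimum ``bout_min_s``)
    so that immobility runs both shorter and longer than the 40 s sleep rule
    occur. Twitches are a Poisson process over sleep time; each twitch is a
    brief burst of movement that a naive immobility rule misreads as waking.
    """

    mean_wake_bout_s: float = 300.0
    mean_sleep_bout_s: float = 300.0
    bout_min_s: float = 20.0
    gamma_shape: float = 2.0
    twitch_rate_per_min: float = 0.0
    twitch_duration_s: tuple[float, float] = (5.0, 12.0)
    wake_speed_px_s: float = 40.0
    sleep_jitter_px: float = 0.0
    twitch_jitter_px: float = 8.0

    def __post_init__(self) -> None:
        for name in ("mean_wake_bout_s", "mean_sleep_bout_s"):
            if getattr(self, name) <= self.bout_min_s:
                raise ValueError(
                    f"{name} must exceed the minimum bout duration "
                    f"{self.bout_min_s} s, got {getattr(self, name)}")
        if self.twitch_rate_per_min < 0:
            raise ValueError("twitch_rate_per_min must be >= 0")
        lo, hi = self.twitch_duration_s
        if not (0 < lo <= hi):
            raise ValueError(f"invalid twitch_duration_s {self.twitch_duration_s}")

    def draw_bout_s(self, state: str, rng: np.random.Generator) -> int:
        mean = self.mean_sleep_bout_s if state == SLEEP else self.mean_wake_bout_s
        scale = (mean - self.bout_min_s) / self.gamma_shape
        dur = self.bout_min_s + rng.gamma(self.gamma_shape, scale)
        return max(1, int(round(dur)))


@dataclass
class GroundTruth:
    """Simulator output: the recovery target for the whole pipeline."""

    state_per_second: np.ndarray            # "Sleep"/"Wake", one per second
    twitch_intervals: list[tuple[float, float]]
    trajectory: np.ndarray                  # (n_frames, 2) centroid (row, col)
    fps: float
    arena_size_px: tuple[int, int]
    seed: int

    def __post_init__(self) -> None:
        self.state_per_second = np.asarray(self.state_per_second, dtype="U8")
        n = self.state_per_second.size
        for a, b in self.twitch_intervals:
            if not (0 <= a < b <= n):
                raise ValueError(f"twitch interval ({a}, {b}) outside recording")
            if not np.all(self.state_per_second[int(a):int(np.ceil(b))] == SLEEP):
                raise ValueError(f"twitch interval ({a}, {b}) not inside sleep")

    @property
    def duration_s(self) -> float:
        return float(self.state_per_second.size)

    def is_twitching(self, t_s: float) -> bool:
        return any(a <= t_s < b for a, b in self.twitch_intervals)

    def to_hypnogram(self) -> Hypnogram:
        return Hypnogram(self.state_per_second, epoch_s=1.0)


# ---------------------------------------------------------------------------
# state sequence
# ---------------------------------------------------------------------------

def simulate_state_sequence(model: StateModel, duration_s: float, seed: int,
                            scenario: SimScenario | None = None) -> GroundTruth:
    """Draw alternating sleep/wake bouts, twitches, and a centroid trajectory.

    The state sequence tiles ``duration_s`` exactly (the final bout is
    truncated). Twitch onsets are a Poisson process at
    ``model.twitch_rate_per_min`` over realized sleep time; twitches never
    overlap and always lie wholly inside a sleep bout.
    """
    if duration_s < 60:
        raise ValueError(f"duration_s must be >= 60, got {duration_s}")
    if scenario is None:
        scenario = SimScenario(duration_s=duration_s, seed=seed)
    rng = np.random.default_rng(seed)
    n_sec = int(round(duration_s))

    # alternate bouts, wake first
    labels = np.empty(n_sec, dtype="U8")
    t, state = 0, WAKE
    bouts: list[tuple[str, int, int]] = []
    while t < n_sec:
        dur = min(model.draw_bout_s(state, rng), n_sec - t)
        labels[t:t + dur] = state
        bouts.append((state, t, dur))
        t += dur
        state = SLEEP if state == WAKE else WAKE

    # twitches: Poisson counts per sleep bout (exposure = bout duration),
    # placed without overlap by distributing the free time as Dirichlet gaps
    # so the count statistics stay exactly Poisson up to a capacity cap
    twitches: list[tuple[float, float]] = []
    if model.twitch_rate_per_min > 0:
        lo, hi = model.twitch_duration_s
        for st, start, dur in bouts:
            if st != SLEEP:
                continue
            n_tw = int(rng.poisson(model.twitch_rate_per_min * dur / 60.0))
            if n_tw == 0:
                continue
            interior = dur - 2.0  # 1 s sleep margin at each bout edge
            tw_durs = rng.uniform(lo, hi, n_tw)
            while n_tw > 0 and tw_durs[:n_tw].sum() > interior:
                n_tw -= 1
            if n_tw == 0:
                continue
            free = interior - tw_durs[:n_tw].sum()
            gaps = rng.dirichlet(np.ones(n_tw + 1)) * free
            onset = start + 1.0
            for k in range(n_tw):
                onset += gaps[k]
                twitches.append((float(onset), float(onset + tw_durs[k])))
                onset += tw_durs[k]

    trajectory = _simulate_trajectory(labels, twitches, model, scenario, rng)
    return GroundTruth(labels, twitches, trajectory, scenario.fps,
                       scenario.arena_size_px, seed)


def _simulate_trajectory(labels: np.ndarray, twitches, model: StateModel,
                         scenario: SimScenario, rng: np.random.Generator) -> np.ndarray:
    """Per-frame centroid: persistent walk during wake, jitter during sleep."""
    h, w = scenario.arena_size_px
    margin = 1.6 * scenario.mouse_radius_px
    fps = scenario.fps
    n_frames = int(round(labels.size * fps))
    pos = np.array([h / 2.0, w / 2.0])
    heading = rng.uniform(0, 2 * np.pi)
    out = np.empty((n_frames, 2))
    step = model.wake_speed_px_s / fps

    twitch_arr = np.zeros(labels.size, dtype=bool)
    for a, b in twitches:
        twitch_arr[int(a):int(np.ceil(b))] = True

    sleep_anchor = pos.copy()
    prev_state = WAKE
    for i in range(n_frames):
        sec = min(int(i / fps), labels.size - 1)
        state = labels[sec]
        if state == WAKE:
            heading += rng.normal(0, 0.35)
            pos = pos + step * np.array([np.sin(heading), np.cos(heading)])
            # reflect off walls
            for k, lim in enumerate((h, w)):
                if pos[k] < margin:
                    pos[k] = 2 * margin - pos[k]
                    heading = -heading if k == 0 else np.pi - heading
                elif pos[k] > lim - margin:
                    pos[k] = 2 * (lim - margin) - pos[k]
                    heading = -heading if k == 0 else np.pi - heading
            pos = np.clip(pos, margin, [h - margin, w - margin])
            out[i] = pos
        else:
            if prev_state == WAKE:
                sleep_anchor = pos.copy()
            jitter = model.twitch_jitter_px if twitch_arr[sec] else model.sleep_jitter_px
            out[i] = sleep_anchor + rng.normal(0, 1, 2) * jitter if jitter > 0 \
                else sleep_anchor
            out[i] = np.clip(out[i], margin, [h - margin, w - margin])
        prev_state = state
    return out


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def render_frame(truth: GroundTruth, scenario: SimScenario,
                 frame_index: int) -> np.ndarray:
    """Render a single 8-bit grayscale frame (lazy counterpart of render_video)."""
    h, w = scenario.arena_size_px
    t_s = frame_index / scenario.fps
    bg = BG_GRAY_LIGHT if scenario.phase_at(t_s) == LIGHT else BG_GRAY_DARK
    frame = np.full((h, w), bg, dtype=np.uint8)
    for d in scenario.distractors:
        if d.shape == "disk":
            rr, cc = draw_disk(d.position, d.size_px, shape=(h, w))
        elif d.shape == "rect":
            r0 = max(0, d.position[0] - d.size_px)
            c0 = max(0, d.position[1] - d.size_px)
            rr, cc = np.mgrid[r0:min(h, d.position[0] + d.size_px),
                              c0:min(w, d.position[1] + d.size_px)]
            rr, cc = rr.ravel(), cc.ravel()
        else:
            raise ValueError(f"unknown distractor shape {d.shape!r}")
        frame[rr, cc] = d.gray

    centroid = truth.trajectory[frame_index]
    r = scenario.mouse_radius_px
    if not ((r <= centroid[0] <= h - r) and (r <= centroid[1] <= w - r)):
        raise ValueError(
            f"trajectory leaves arena at frame {frame_index}: {centroid}")
    sec = min(int(t_s), truth.state_per_second.size - 1)
    if truth.state_per_second[sec] == WAKE and frame_index > 0:
        d = truth.trajectory[frame_index] - truth.trajectory[frame_index - 1]
        angle = float(np.arctan2(d[0], d[1])) if np.any(d) else 0.0
    else:
        angle = 0.0
    rr, cc = draw_ellipse(centroid[0], centroid[1], r, 0.6 * r,
                          shape=(h, w), rotation=angle)
    frame[rr, cc] = MOUSE_GRAY
    return frame


def render_video(truth: GroundTruth, scenario: SimScenario) -> np.ndarray:
    """Render all frames eagerly: (n_frames, rows, cols) uint8 stack.

    For long recordings prefer :func:`render_frame` / ``iter_frames`` — a
    2 h stack does not fit in memory.
    """
    n = min(scenario.n_frames, truth.trajectory.shape[0])
    if n == 0:
        return np.empty((0, *scenario.arena_size_px), dtype=np.uint8)
    return np.stack([render_frame(truth, scenario, i) for i in range(n)])


def iter_frames(truth: GroundTruth, scenario: SimScenario, frame_indices=None):
    """Yield ``(frame_index, frame)`` lazily; all frames if indices is None."""
    if frame_indices is None:
        frame_indices = range(min(scenario.n_frames, truth.trajectory.shape[0]))
    for i in frame_indices:
        yield i, render_frame(truth, scenario, i)


# ---------------------------------------------------------------------------
# reference hypnograms
# ---------------------------------------------------------------------------

def emit_reference_hypnogram(truth: GroundTruth, epoch_s: float = 20.0,
                             three_state: bool = False,
                             rem_fraction: float = 0.0,
                             narcolepsy: bool = False) -> Hypnogram:
    """Epoch the ground truth by majority vote; optionally paint REM runs.

    In the three-state output a fraction ``rem_fraction`` of each sleep
    run's epochs is relabeled REM as one contiguous block at the run's tail
    (the physiological position: REM follows NREM) or, in the narcolepsy
    scenario, at the run's head so the transition is Wake→REM. Injected
    wake→REM onset times (s) are recorded in ``meta["wake_to_rem_onsets"]``.
    """
    if not (0.0 <= rem_fraction <= 1.0):
        raise ValueError(f"rem_fraction must be in [0, 1], got {rem_fraction}")
    labels = _epoch_majority(truth.state_per_second, epoch_s)
    hyp = Hypnogram(labels, epoch_s=epoch_s)
    if not three_state or rem_fraction == 0.0:
        return hyp

    out = labels.copy()
    out[out == SLEEP] = NREM
    onsets: list[float] = []
    for run in run_length_encode(labels):
        if run.label != SLEEP:
            continue
        k = int(round(rem_fraction * run.length))
        if k == 0:
            continue
        k = min(k, run.length)
        if narcolepsy:
            out[run.start:run.start + k] = REM
            if run.start > 0 and labels[run.start - 1] == WAKE:
                onsets.append(run.start * epoch_s)
        else:
            out[run.stop - k:run.stop] = REM
    return Hypnogram(out, epoch_s=epoch_s,
                     meta={"wake_to_rem_onsets": onsets})


def _epoch_majority(per_second: np.ndarray, epoch_s: float) -> np.ndarray:
    """Majority label per epoch; ties go to Wake; trailing partial dropped."""
    step = int(round(epoch_s))
    n_epochs = per_second.size // step
    if per_second.size % step:
        warnings.warn(
            f"dropping trailing partial epoch of {per_second.size % step} s",
            stacklevel=3)
    labels = np.empty(n_epochs, dtype="U8")
    for e in range(n_epochs):
        chunk = per_second[e * step:(e + 1) * step]
        n_sleep = int(np.count_nonzero(chunk == SLEEP))
        labels[e] = SLEEP if n_sleep > chunk.size - n_sleep else WAKE
    return labels


# ---------------------------------------------------------------------------
# synthetic EEG/EMG spectral epochs
# ---------------------------------------------------------------------------

def simulate_spectral_epochs(hypnogram: Hypnogram, seed: int = 0):
    """Per-epoch 1 Hz band powers (1–30 Hz) and an EMG summary matching states.

    State-typical spectra: NREM is delta-dominated (1–4 Hz) with low EMG,
    REM is theta-dominated (6–9 Hz) with muscle atonia, Wake is broadband
    with high variable EMG. Powers are arbitrary units; only ratios matter
    downstream. Returns a DataFrame with columns
    ``epoch, bin_1 … bin_30, emg, state``.
    """
    import pandas as pd

    rng = np.random.default_rng(seed)
    freqs = np.arange(1, 31, dtype=float)
    base = 1.0 / freqs  # 1/f background
    rows = np.empty((len(hypnogram), 30))
    emg = np.empty(len(hypnogram))
    for i, state in enumerate(hypnogram.labels):
        spec = base.copy()
        if state == NREM or state == SLEEP:
            spec[(freqs >= 1) & (freqs <= 4)] += rng.uniform(2.0, 3.0)
            emg[i] = rng.uniform(0.5, 1.5)
        elif state == REM:
            spec[(freqs >= 6) & (freqs <= 9)] += rng.uniform(2.0, 3.0)
            emg[i] = rng.uniform(0.0, 0.05)
        else:
            spec += rng.uniform(0.05, 0.15, size=30)
            emg[i] = rng.uniform(4.0, 8.0)
        rows[i] = spec * rng.uniform(0.8, 1.2)
    df = pd.DataFrame(rows, columns=[f"bin_{k}" for k in range(1, 31)])
    df.insert(0, "epoch", np.arange(len(hypnogram)))
    df["emg"] = emg
    df["state"] = hypnogram.labels
    return df
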