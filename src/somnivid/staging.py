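"""Immobility-defined sleep/wake staging from frame-difference features.

Stage 2 of the video pipeline. For each sampled time ``t`` the detected
mouse is compared against its neighbours within a window ``t ± m`` samples;
four difference features are computed per offset:

* ``P_i`` — change in the classifier prediction score,
* ``M_i`` — mask change, ``1 − IoU`` of the two binary masks,
* ``A_i`` — centroid displacement in pixels (Euclidean),
* ``G_i`` — change in mean gray level within the mask.

The mouse is judged *active* at ``t`` if any offset satisfies

    P_i > 0.1  or  G_i > 3  or  A_i > 5  or  (G_i/255 + M_i + P_i)/3 > 0.5

(the combined mean uses each term rescaled to [0, 1]; the per-feature
thresholds act on raw units). Sleep is then defined behaviorally as >= 40 s
of continuous immobility, and a movement-merging filter relabels runs of
<= 15 s of movement flanked by sleep as sleep — brief twitches during sleep
would otherwise fragment bouts and be misread as waking.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .hypnogram import Hypnogram, SLEEP, WAKE, run_length_encode
from .vision import MouseDetection, RoiCandidate

logger = logging.getLogger(__name__)


@dataclass
class StagingParams:
    """All staging thresholds; defaults are the published operating point."""

    fps: float = 25.0
    sample_period_s: float = 1.0
    window_half_width_m: int = 2        # compare t with t +/- 1..m samples
    thr_P: float = 0.1                  # prediction-score difference
    thr_G: float = 3.0                  # gray levels
    thr_A: float = 5.0                  # px
    thr_combined: float = 0.5           # on mean of [0,1]-scaled (G, M, P)
    immobility_min_s: float = 40.0
    merge_filter_s: float = 15.0
    epoch_s: float = 20.0

    def __post_init__(self) -> None:
        for name in ("thr_P", "thr_G", "thr_A", "thr_combined",
                     "immobility_min_s", "epoch_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.merge_filter_s < 0:
            raise ValueError("merge_filter_s must be >= 0")
        if self.merge_filter_s >= self.immobility_min_s:
            raise ValueError("merge_filter_s must be shorter than immobility_min_s")


@dataclass(frozen=True)
class FeatureDiff:
    """Differences between the detections at ``t`` and ``t + i`` samples."""

    i: int
    P_i: float
    M_i: float
    A_i: float
    G_i: float

    def __post_init__(self) -> None:
        if min(self.P_i, self.M_i, self.A_i, self.G_i) < 0:
            raise ValueError("feature differences must be non-negative")
        if not (0.0 <= self.M_i <= 1.0):
            raise ValueError(f"M_i must lie in [0,1], got {self.M_i}")


@dataclass
class ActivityTrace:
    """Per-sample binary activity with quality flags."""

    active: np.ndarray                  # bool, one per sample
    sample_period_s: float = 1.0
    low_confidence: np.ndarray | None = None   # no usable diffs at sample
    excluded: np.ndarray | None = None         # detection lost beyond gap rule

    def __post_init__(self) -> None:
        self.active = np.asarray(self.active, dtype=bool)
        if self.low_confidence is None:
            self.low_confidence = np.zeros_like(self.active)
        if self.excluded is None:
            self.excluded = np.zeros_like(self.active)

    def __len__(self) -> int:
        return int(self.active.size)

    @property
    def duration_s(self) -> float:
        return len(self) * self.sample_period_s

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "second": np.arange(len(self)) * self.sample_period_s,
            "active": self.active.astype(int),
            "low_confidence": self.low_confidence.astype(int),
            "excluded": self.excluded.astype(int),
        })

    @classmethod
    def from_frame(cls, df: pd.DataFrame, sample_period_s: float = 1.0) -> "ActivityTrace":
        return cls(df["active"].to_numpy(dtype=bool), sample_period_s,
                   df["low_confidence"].to_numpy(dtype=bool) if "low_confidence" in df else None,
                   df["excluded"].to_numpy(dtype=bool) if "excluded" in df else None)


def mask_iou(a: RoiCandidate, b: RoiCandidate) -> float:
    """Intersection-over-union of two ROI masks in frame coordinates."""
    r0 = max(a.bbox[0], b.bbox[0]); c0 = max(a.bbox[1], b.bbox[1])
    r1 = min(a.bbox[2], b.bbox[2]); c1 = min(a.bbox[3], b.bbox[3])
    inter = 0
    if r0 < r1 and c0 < c1:
        sub_a = a.mask[r0 - a.bbox[0]:r1 - a.bbox[0], c0 - a.bbox[1]:c1 - a.bbox[1]]
        sub_b = b.mask[r0 - b.bbox[0]:r1 - b.bbox[0], c0 - b.bbox[1]:c1 - b.bbox[1]]
        inter = int(np.count_nonzero(sub_a & sub_b))
    union = a.area_px + b.area_px - inter
    return inter / union if union else 0.0


def feature_diff(det_t: MouseDetection, det_i: MouseDetection, i: int) -> FeatureDiff:
    """Four-feature difference between two detections (both present)."""
    ra, rb = det_t.roi, det_i.roi
    P = abs(det_t.predict_score - det_i.predict_score)
    M = 1.0 - mask_iou(ra, rb)
    A = float(np.hypot(ra.centroid[0] - rb.centroid[0],
                       ra.centroid[1] - rb.centroid[1]))
    G = abs(ra.mean_gray - rb.mean_gray)
    return FeatureDiff(i=i, P_i=P, M_i=M, A_i=A, G_i=G)


def compute_feature_diffs(detections: list[MouseDetection], t: int,
                          params: StagingParams) -> list[FeatureDiff]:
    """Diffs between sample ``t`` and each ``t + i``, i in ±1..m.

    Window edges are truncated; offsets whose detection is absent (lost
    beyond the carry-forward gap rule) are skipped.
    """
    if not detections[t].present:
        return []
    out = []
    m = params.window_half_width_m
    for i in [*range(-m, 0), *range(1, m + 1)]:
        j = t + i
        if 0 <= j < len(detections) and detections[j].present:
            out.append(feature_diff(detections[t], detections[j], i))
    return out


def judge_active(diffs: list[FeatureDiff], params: StagingParams) -> bool:
    """Activity rule: any offset trips any of the four clauses.

    An empty diff list cannot attest movement; the caller flags it as
    low-confidence inactivity.
    """
    for d in diffs:
        if d.P_i > params.thr_P or d.G_i > params.thr_G or d.A_i > params.thr_A:
            return True
        if (d.G_i / 255.0 + d.M_i + d.P_i) / 3.0 > params.thr_combined:
            return True
    return False


def activity_from_detections(detections: list[MouseDetection],
                             params: StagingParams | None = None) -> ActivityTrace:
    """Judge activity at every sample; one sample per detection.

    Samples with no usable comparison are inactive with a low-confidence
    flag; samples whose detection was lost beyond the gap rule are marked
    excluded and treated as active (immobility cannot be attested without a
    detection).
    """
    params = params or StagingParams()
    n = len(detections)
    active = np.zeros(n, dtype=bool)
    low_conf = np.zeros(n, dtype=bool)
    excluded = np.zeros(n, dtype=bool)
    for t in range(n):
        if not detections[t].present:
            excluded[t] = True
            active[t] = True
            continue
        diffs = compute_feature_diffs(detections, t, params)
        if not diffs:
            low_conf[t] = True
            active[t] = False
        else:
            active[t] = judge_active(diffs, params)
    if excluded.any():
        logger.warning("%d samples excluded (detection lost beyond gap rule)",
                       int(excluded.sum()))
    return ActivityTrace(active, params.sample_period_s, low_conf, excluded)


# ---------------------------------------------------------------------------
# run-length staging
# ---------------------------------------------------------------------------

def stage_sleep_wake(activity: ActivityTrace,
                     params: StagingParams | None = None) -> Hypnogram:
    """Label maximal immobile runs of >= ``immobility_min_s`` as Sleep.

    Output is a per-second (per-sample) hypnogram after the movement-merging
    filter. A trace shorter than the immobility threshold is all Wake.
    """
    params = params or StagingParams()
    n = len(activity)
    min_run = int(round(params.immobility_min_s / activity.sample_period_s))
    labels = np.full(n, WAKE, dtype="U8")
    if n < min_run:
        warnings.warn(f"trace of {activity.duration_s:.0f} s shorter than the "
                      f"{params.immobility_min_s:.0f} s immobility rule; all Wake")
    else:
        for run in run_length_encode(np.where(activity.active, "act", "inact")):
            if run.label == "inact" and run.length >= min_run:
                labels[run.start:run.stop] = SLEEP
    hyp = Hypnogram(labels, epoch_s=activity.sample_period_s)
    return merge_brief_movements(hyp, params.merge_filter_s)


def merge_brief_movements(hypnogram: Hypnogram, merge_filter_s: float) -> Hypnogram:
    """Relabel Wake runs of <= ``merge_filter_s`` flanked by Sleep as Sleep.

    Applied left-to-right and re-scanned to a fixed point, so chains like
    Sleep–Wake(10)–Sleep–Wake(10)–Sleep fully coalesce. ``merge_filter_s=0``
    is the identity.
    """
    if merge_filter_s < 0:
        raise ValueError("merge_filter_s must be >= 0")
    max_run = int(round(merge_filter_s / hypnogram.epoch_s))
    labels = hypnogram.labels.copy()
    if max_run == 0:
        return hypnogram.replace_labels(labels)
    changed = True
    while changed:
        changed = False
        runs = run_length_encode(labels)
        for k, run in enumerate(runs):
            if (run.label == WAKE and run.length <= max_run
                    and 0 < k < len(runs) - 1
                    and runs[k - 1].label == SLEEP and runs[k + 1].label == SLEEP):
                labels[run.start:run.stop] = SLEEP
                changed = True
        # loop re-encodes; terminates because each pass removes >=1 Wake run
    return hypnogram.replace_labels(labels)


def epoch_hypnogram(hypnogram: Hypnogram, epoch_s: float = 20.0) -> Hypnogram:
    """Majority label per epoch; ties -> Wake; trailing partial epoch dropped."""
    if epoch_s <= 0:
        raise ValueError("epoch_s must be positive")
    per = hypnogram.labels
    step = int(round(epoch_s / hypnogram.epoch_s))
    n_epochs = per.size // step
    if per.size % step:
        logger.info("dropping trailing partial epoch of %d samples", per.size % step)
    sleepish = np.isin(per[:n_epochs * step], [SLEEP]).reshape(n_epochs, step)
    n_sleep = sleepish.sum(axis=1)
    labels = np.where(n_sleep > step - n_sleep, SLEEP, WAKE)
    return Hypnogram(labels.astype("U8"), epoch_s=epoch_s,
                     start_time_s=hypnogram.start_time_s,
                     zeitgeber_offset_s=hypnogram.zeitgeber_offset_s)


def sweep_merge_threshold(activity: ActivityTrace, reference: Hypnogram,
                          thresholds=(0, 5, 10, 15, 20, 25, 30),
                          params: StagingParams | None = None) -> pd.DataFrame:
    """Stage at each merge threshold and score agreement with the reference.

    Returns one row per threshold: sensitivity, specificity, accuracy
    (epoch-by-epoch vs the reference) and the staged sleep-bout count. The
    sweep reproduces the filter-selection experiment: with brief sleep
    twitches present, accuracy peaks and bout count stabilizes once the
    filter exceeds the twitch duration.
    """
    from .metrics import compare_staging

    params = params or StagingParams()
    rows = []
    for thr in thresholds:
        p = replace(params, merge_filter_s=float(thr))
        staged = epoch_hypnogram(stage_sleep_wake(activity, p), reference.epoch_s)
        if len(staged) != len(reference):
            raise ValueError(
                f"staged hypnogram has {len(staged)} epochs but reference has "
                f"{len(reference)}; durations misaligned")
        res = compare_staging(staged, reference)
        rows.append({
            "threshold_s": thr,
            "sensitivity": res.sensitivity,
            "specificity": res.specificity,
            "accuracy": res.accuracy,
            "bout_count": res.bout_count_test,
            "sleep_s": stage_sleep_wake(activity, p).time_in_state(SLEEP),
        })
    return pd.DataFrame(rows)
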