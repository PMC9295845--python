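"""Per-frame ROI extraction and mouse-region selection.

Stage 1 of the video pipeline: each sampled frame is Gaussian-smoothed and
foreground is taken as the union of an adaptive (local) threshold and a
global Otsu threshold, both applied to the absolute deviation from the
frame's median gray (the background estimate — the mouse is darker than the
bedding in the light phase and brighter under infrared illumination in the
dark phase, so a polarity-free rule is needed). More than one ROI may
survive — food, water gel, and shadows produce stable distractor blobs —
and a patch classifier scores each candidate; the highest-confidence ROI is
designated the mouse.

Coordinates are 0-based, row-major; bounding boxes are half-open
``(r0, c0, r1, c1)``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.filters import gaussian, threshold_local, threshold_otsu
from skimage.measure import label as cc_label, regionprops

logger = logging.getLogger(__name__)


@dataclass
class VisionParams:
    """Extraction parameters (engineering choices; all exposed here)."""

    gaussian_sigma: float = 2.0
    adaptive_block_px: int = 51          # must be odd
    adaptive_offset: float = 5.0         # foreground if deviation > local mean + offset
    min_area_fraction: float = 0.25      # of expected mouse area
    expected_mouse_area_px: float = 1700.0
    min_deviation: float = 5.0           # below this the frame is deemed empty
    max_gap_s: float = 2.0               # carry-forward limit for lost detections

    @property
    def min_area_px(self) -> float:
        return self.min_area_fraction * self.expected_mouse_area_px


@dataclass
class RoiCandidate:
    """One connected foreground component."""

    mask: np.ndarray                     # cropped boolean mask (bbox frame)
    bbox: tuple[int, int, int, int]      # (r0, c0, r1, c1), half-open
    area_px: int
    centroid: tuple[float, float]        # (row, col), sub-pixel, frame coords
    mean_gray: float
    score: float | None = None

    def __post_init__(self) -> None:
        if self.area_px != int(np.count_nonzero(self.mask)):
            raise ValueError("area_px inconsistent with mask popcount")
        r0, c0, r1, c1 = self.bbox
        if not (r0 <= self.centroid[0] <= r1 and c0 <= self.centroid[1] <= c1):
            raise ValueError("centroid outside bounding box")

    def crop(self, frame: np.ndarray, pad: int = 2) -> np.ndarray:
        r0, c0, r1, c1 = self.bbox
        h, w = frame.shape
        return frame[max(0, r0 - pad):min(h, r1 + pad),
                     max(0, c0 - pad):min(w, c1 + pad)]


@dataclass
class MouseDetection:
    """Winning ROI for one sampled frame (or a flagged miss)."""

    frame_index: int
    time_s: float
    roi: RoiCandidate | None
    carried_forward: bool = False
    candidates: int = 0

    @property
    def present(self) -> bool:
        return self.roi is not None

    @property
    def predict_score(self) -> float:
        return float(self.roi.score) if self.roi and self.roi.score is not None else 0.0

    @property
    def centroid(self) -> tuple[float, float] | None:
        return self.roi.centroid if self.roi else None

    @property
    def mean_gray(self) -> float | None:
        return self.roi.mean_gray if self.roi else None


def extract_roi_candidates(frame: np.ndarray,
                           params: VisionParams | None = None) -> list[RoiCandidate]:
    """Segment candidate mouse regions from a single grayscale frame.

    Returns one unscored candidate per connected foreground component whose
    area exceeds ``params.min_area_px``. A flat frame yields an empty list.
    """
    params = params or VisionParams()
    if frame.ndim != 2:
        raise ValueError(f"expected single-channel image, got shape {frame.shape}")
    if frame.size == 0:
        return []
    img = np.asarray(frame, dtype=float)
    smooth = gaussian(img, sigma=params.gaussian_sigma, preserve_range=True)
    deviation = np.abs(smooth - np.median(smooth))
    if deviation.max() < params.min_deviation:
        return []

    block = params.adaptive_block_px
    if block % 2 == 0:
        block += 1
    # threshold_local: T = local_gaussian_mean - offset; we want mean + offset
    adaptive_fg = deviation > threshold_local(deviation, block, offset=-params.adaptive_offset)
    global_fg = deviation > threshold_otsu(deviation)
    fg = ndi.binary_fill_holes(adaptive_fg | global_fg)

    out: list[RoiCandidate] = []
    for region in regionprops(cc_label(fg, connectivity=2), intensity_image=img):
        if region.area < params.min_area_px:
            continue
        r0, c0, r1, c1 = region.bbox
        out.append(RoiCandidate(
            mask=region.image.copy(),
            bbox=(int(r0), int(c0), int(r1), int(c1)),
            area_px=int(region.area),
            centroid=(float(region.centroid[0]), float(region.centroid[1])),
            mean_gray=float(region.intensity_mean),
            score=None,
        ))
    return out


def select_mouse(candidates: list[RoiCandidate], classifier, frame: np.ndarray,
                 frame_index: int = 0, time_s: float = 0.0) -> MouseDetection:
    """Score every candidate and designate the arg-max as the mouse.

    Ties are broken by larger area, then lower bounding-box row index
    (logged). With no candidates the detection is absent and flagged by the
    caller's gap rule.
    """
    if not candidates:
        return MouseDetection(frame_index, time_s, None, candidates=0)
    for cand in candidates:
        cand.score = float(classifier.score_patch(cand.crop(frame)))
    best = max(candidates,
               key=lambda c: (c.score, c.area_px, -c.bbox[0]))
    n_best = sum(1 for c in candidates if c.score == best.score)
    if n_best > 1:
        logger.info("frame %d: %d candidates tied at score %.3f; "
                    "broke tie by area then row", frame_index, n_best, best.score)
    return MouseDetection(frame_index, time_s, best, candidates=len(candidates))


def detect_frames(frames, classifier, params: VisionParams | None = None,
                  fps: float = 25.0) -> list[MouseDetection]:
    """Run extraction + selection over ``(frame_index, frame)`` pairs.

    Lost detections within ``params.max_gap_s`` of the last valid frame are
    carried forward (same ROI, flagged); longer gaps stay absent and are
    excluded from staging by the activity layer.
    """
    params = params or VisionParams()
    detections: list[MouseDetection] = []
    last_valid: MouseDetection | None = None
    for frame_index, frame in frames:
        t = frame_index / fps
        det = select_mouse(extract_roi_candidates(frame, params), classifier,
                          frame, frame_index, t)
        if not det.present:
            if last_valid is not None and (t - last_valid.time_s) <= params.max_gap_s:
                det = MouseDetection(frame_index, t, last_valid.roi,
                                     carried_forward=True)
            else:
                logger.warning("frame %d (t=%.1fs): no mouse ROI beyond gap rule",
                               frame_index, t)
        else:
            last_valid = det
        detections.append(det)
    return detections


def detections_to_frame(detections: list[MouseDetection]) -> pd.DataFrame:
    """Export per-frame detections as a tidy table (CSV schema)."""
    rows = []
    for d in detections:
        rows.append({
            "frame": d.frame_index,
            "time_s": d.time_s,
            "row": d.roi.centroid[0] if d.present else np.nan,
            "col": d.roi.centroid[1] if d.present else np.nan,
            "area": d.roi.area_px if d.present else 0,
            "gray": d.roi.mean_gray if d.present else np.nan,
            "score": d.roi.score if d.present and d.roi.score is not None else np.nan,
            "carried_forward": d.carried_forward,
        })
    return pd.DataFrame(rows)
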