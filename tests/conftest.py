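"""Shared fixtures: small synthetic scenarios and a trained patch classifier.

Everything is generated programmatically at test time; the heavier fixtures
are session-scoped so the render→detect tests share one simulation.
"""

from __future__ import annotations

import numpy as np
import pytest

import somnivid as sv


@pytest.fixture(scope="session")
def small_scenario() -> sv.SimScenario:
    """Reduced-resolution cage (352x288 @ 5 fps) used by vision tests."""
    return sv.SimScenario(duration_s=600.0, arena_size_px=(288, 352),
                          mouse_radius_px=15, fps=5.0, seed=11)


@pytest.fixture(scope="session")
def small_truth(small_scenario) -> sv.GroundTruth:
    model = sv.StateModel(mean_wake_bout_s=120.0, mean_sleep_bout_s=180.0,
                          twitch_rate_per_min=1.0)
    return sv.simulate_state_sequence(model, small_scenario.duration_s, 11,
                                      small_scenario)


@pytest.fixture(scope="session")
def trained_classifier(small_truth, small_scenario) -> sv.PatchClassifier:
    """Logistic patch classifier trained on crops from the simulation."""
    return sv.default_classifier_for(small_truth, small_scenario, seed=11,
                                     n_patches=60)


def make_disk_frame(shape=(128, 160), center=(60, 80), radius=12,
                    bg=180, fg=120) -> np.ndarray:
    """Single dark disk on a flat background."""
    from skimage.draw import disk

    frame = np.full(shape, bg, dtype=np.uint8)
    rr, cc = disk(center, radius, shape=shape)
    frame[rr, cc] = fg
    return frame


def make_detection(t: float, row: float, col: float, score: float = 0.9,
                   gray: float = 120.0, radius: int = 5,
                   frame_shape=(200, 200)) -> sv.MouseDetection:
    """Detection with a square mask centered at (row, col); test helper."""
    r, c = int(round(row)), int(round(col))
    bbox = (r - radius, c - radius, r + radius, c + radius)
    mask = np.ones((2 * radius, 2 * radius), dtype=bool)
    roi = sv.RoiCandidate(mask=mask, bbox=bbox, area_px=int(mask.sum()),
                          centroid=(row, col), mean_gray=gray, score=score)
    return sv.MouseDetection(frame_index=int(t), time_s=t, roi=roi)
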