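"""Unit and property tests for feature diffs, the activity rule, and staging."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import somnivid as sv
from somnivid.hypnogram import SLEEP, WAKE, Hypnogram
from somnivid.staging import feature_diff, mask_iou

from conftest import make_detection
from oracles import oracle_stage

PARAMS = sv.StagingParams()


def labels_from(spec: list[tuple[str, int]]) -> np.ndarray:
    return np.concatenate([np.full(n, lab, dtype="U8") for lab, n in spec])


# ---------------------------------------------------------------------------
# feature differences
# ---------------------------------------------------------------------------

class TestFeatureDiffs:
    def test_identical_detections_zero_diffs(self):
        a = make_detection(0, 50.0, 50.0)
        b = make_detection(1, 50.0, 50.0)
        d = feature_diff(a, b, 1)
        assert d.P_i == d.M_i == d.A_i == d.G_i == 0.0

    def test_disjoint_masks_full_mask_change(self):
        a = make_detection(0, 20.0, 20.0)
        b = make_detection(1, 100.0, 100.0)
        assert feature_diff(a, b, 1).M_i == 1.0

    def test_centroid_displacement_is_euclidean(self):
        a = make_detection(0, 50.0, 50.0)
        b = make_detection(1, 53.0, 54.0)  # (3, 4) move
        assert feature_diff(a, b, 1).A_i == pytest.approx(5.0)

    def test_identical_masks_unit_iou(self):
        a = make_detection(0, 50.0, 50.0)
        assert mask_iou(a.roi, a.roi) == 1.0

    def test_window_truncated_at_edges(self):
        dets = [make_detection(t, 10.0, 10.0) for t in range(3)]
        diffs = sv.compute_feature_diffs(dets, 0, PARAMS)
        assert sorted(d.i for d in diffs) == [1, 2]

    def test_negative_feature_rejected(self):
        with pytest.raises(ValueError):
            sv.FeatureDiff(i=1, P_i=-0.1, M_i=0.0, A_i=0.0, G_i=0.0)


class TestJudgeActive:
    @pytest.mark.parametrize("kw, expected", [
        (dict(P_i=0.0, M_i=0.0, A_i=0.0, G_i=0.0), False),
        (dict(P_i=0.0, M_i=0.0, A_i=6.0, G_i=0.0), True),    # A > 5 px
        (dict(P_i=0.2, M_i=0.0, A_i=0.0, G_i=0.0), True),    # P > 0.1
        (dict(P_i=0.0, M_i=0.0, A_i=0.0, G_i=4.0), True),    # G > 3 levels
        (dict(P_i=0.05, M_i=0.55, A_i=4.0, G_i=2.0), False), # combined 0.20
    ])
    def test_threshold_clauses(self, kw, expected):
        assert sv.judge_active([sv.FeatureDiff(i=1, **kw)], PARAMS) is expected

    def test_combined_clause_fires_alone(self):
        # raise the raw thresholds so only the (G/255 + M + P)/3 mean can trip
        params = sv.StagingParams(thr_P=10.0, thr_G=300.0, thr_A=50.0)
        d = sv.FeatureDiff(i=1, P_i=0.9, M_i=0.9, A_i=0.0, G_i=0.0)
        assert sv.judge_active([d], params)
        quiet = sv.FeatureDiff(i=1, P_i=0.3, M_i=0.3, A_i=0.0, G_i=0.0)
        assert not sv.judge_active([quiet], params)

    def test_any_offset_suffices(self):
        quiet = sv.FeatureDiff(i=-1, P_i=0.0, M_i=0.0, A_i=0.0, G_i=0.0)
        loud = sv.FeatureDiff(i=1, P_i=0.0, M_i=0.0, A_i=7.0, G_i=0.0)
        assert sv.judge_active([quiet, loud], PARAMS)

    def test_empty_diffs_inactive(self):
        assert sv.judge_active([], PARAMS) is False


# ---------------------------------------------------------------------------
# run-length staging
# ---------------------------------------------------------------------------

def trace(active: np.ndarray) -> sv.ActivityTrace:
    return sv.ActivityTrace(np.asarray(active, dtype=bool))


class TestStageSleepWake:
    def test_39s_immobility_stays_wake(self):
        act = np.ones(200, dtype=bool)
        act[50:89] = False  # 39 s
        hyp = sv.stage_sleep_wake(trace(act), PARAMS)
        assert hyp.bout_count(SLEEP) == 0

    def test_40s_immobility_one_sleep_bout(self):
        act = np.ones(200, dtype=bool)
        act[50:90] = False  # exactly 40 s
        hyp = sv.stage_sleep_wake(trace(act), PARAMS)
        runs = [r for r in hyp.runs() if r.label == SLEEP]
        assert len(runs) == 1 and runs[0].length == 40 and runs[0].start == 50

    def test_all_inactive_single_bout(self):
        hyp = sv.stage_sleep_wake(trace(np.zeros(3600, dtype=bool)), PARAMS)
        runs = hyp.runs()
        assert len(runs) == 1 and runs[0].label == SLEEP and runs[0].length == 3600

    def test_short_trace_all_wake_with_warning(self):
        with pytest.warns(UserWarning, match="shorter"):
            hyp = sv.stage_sleep_wake(trace(np.zeros(30, dtype=bool)), PARAMS)
        assert set(hyp.labels) == {WAKE}


class TestMergeBriefMovements:
    def test_merges_10s_gap(self):
        hyp = Hypnogram(labels_from([(SLEEP, 60), (WAKE, 10), (SLEEP, 60)]))
        out = sv.merge_brief_movements(hyp, 15)
        assert out.bout_count(SLEEP) == 1 and out.time_in_state(SLEEP) == 130

    def test_keeps_16s_gap(self):
        hyp = Hypnogram(labels_from([(SLEEP, 60), (WAKE, 16), (SLEEP, 60)]))
        out = sv.merge_brief_movements(hyp, 15)
        assert out.bout_count(SLEEP) == 2
        assert np.array_equal(out.labels, hyp.labels)

    def test_zero_threshold_is_identity(self):
        hyp = Hypnogram(labels_from([(SLEEP, 60), (WAKE, 1), (SLEEP, 60)]))
        assert np.array_equal(sv.merge_brief_movements(hyp, 0).labels, hyp.labels)

    def test_cascade_merges_to_fixed_point(self):
        hyp = Hypnogram(labels_from(
            [(SLEEP, 50), (WAKE, 10), (SLEEP, 50), (WAKE, 10), (SLEEP, 50)]))
        out = sv.merge_brief_movements(hyp, 15)
        assert out.bout_count(SLEEP) == 1 and out.time_in_state(SLEEP) == 170

    def test_leading_wake_not_merged(self):
        hyp = Hypnogram(labels_from([(WAKE, 5), (SLEEP, 60)]))
        out = sv.merge_brief_movements(hyp, 15)
        assert out.time_in_state(WAKE) == 5


class TestEpochHypnogram:
    def test_72h_gives_12960_epochs(self):
        hyp = Hypnogram(np.full(259200, SLEEP, dtype="U8"))
        assert len(sv.epoch_hypnogram(hyp, 20.0)) == 12960

    def test_tie_labeled_wake(self):
        hyp = Hypnogram(labels_from([(SLEEP, 10), (WAKE, 10)]))
        assert sv.epoch_hypnogram(hyp, 20.0).labels.tolist() == [WAKE]

    def test_majority_sleep(self):
        hyp = Hypnogram(labels_from([(SLEEP, 11), (WAKE, 9)]))
        assert sv.epoch_hypnogram(hyp, 20.0).labels.tolist() == [SLEEP]

    def test_trailing_partial_dropped(self):
        hyp = Hypnogram(np.full(50, SLEEP, dtype="U8"))
        assert len(sv.epoch_hypnogram(hyp, 20.0)) == 2


# ---------------------------------------------------------------------------
# properties
# ---------------------------------------------------------------------------

binary_traces = st.lists(st.booleans(), min_size=60, max_size=400).map(np.array)


@given(binary_traces)
@settings(max_examples=100, deadline=None, derandomize=True)
def test_conservation_and_oracle_agreement(active):
    """Sleep + Wake tile the trace, and staging matches the brute-force oracle."""
    hyp = sv.stage_sleep_wake(trace(active), PARAMS)
    assert hyp.time_in_state(SLEEP) + hyp.time_in_state(WAKE) == active.size
    assert np.array_equal(hyp.labels, oracle_stage(active))


@given(binary_traces, st.integers(0, 30), st.integers(0, 30))
@settings(max_examples=100, deadline=None, derandomize=True)
def test_merge_monotonicity(active, thr_a, thr_b):
    """More merging can only add sleep time and remove sleep bouts."""
    lo, hi = sorted((thr_a, thr_b))
    base = sv.stage_sleep_wake(trace(active), sv.StagingParams(merge_filter_s=0))
    h_lo = sv.merge_brief_movements(base, lo)
    h_hi = sv.merge_brief_movements(base, hi)
    assert h_hi.time_in_state(SLEEP) >= h_lo.time_in_state(SLEEP)
    assert h_hi.bout_count(SLEEP) <= h_lo.bout_count(SLEEP)


def test_sweep_twitch_free_metrics_constant():
    """With nothing to merge, every threshold gives identical metrics."""
    rng = np.random.default_rng(5)
    act = np.zeros(1200, dtype=bool)
    act[0:100] = True
    act[500:700] = True  # long wake runs only; no brief gaps
    tr = trace(act)
    ref = sv.epoch_hypnogram(sv.stage_sleep_wake(tr, PARAMS), 20.0)
    table = sv.sweep_merge_threshold(tr, ref)
    assert table["accuracy"].nunique() == 1
    assert table["bout_count"].nunique() == 1


def test_sweep_bout_count_non_increasing_with_twitches():
    rng = np.random.default_rng(6)
    act = np.zeros(3000, dtype=bool)
    for start in rng.integers(0, 2980, size=25):
        act[start:start + int(rng.integers(5, 13))] = True
    tr = trace(act)
    ref = sv.epoch_hypnogram(Hypnogram(np.full(3000, SLEEP, dtype="U8")), 20.0)
    table = sv.sweep_merge_threshold(tr, ref)
    assert (np.diff(table["bout_count"].to_numpy()) <= 0).all()
    acc = table.set_index("threshold_s")["accuracy"]
    assert acc[15] >= acc[0]


def test_excluded_samples_break_immobility():
    """Detections lost beyond the gap rule cannot contribute to sleep."""
    dets = [make_detection(t, 10.0, 10.0) for t in range(100)]
    for t in range(40, 50):
        dets[t] = sv.MouseDetection(frame_index=t, time_s=float(t), roi=None)
    activity = sv.activity_from_detections(dets, PARAMS)
    assert activity.excluded[40:50].all()
    assert activity.active[40:50].all()
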