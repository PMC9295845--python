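"""Agreement metrics, sleep-time summaries, and EEG-derived analytics."""

import numpy as np
import pandas as pd
import pytest

import somnivid as sv
from somnivid.hypnogram import NREM, REM, SLEEP, WAKE, Hypnogram
from somnivid.metrics import BIN_COLS, delta_ratio


def hyp(labels, epoch_s=20.0, **kw):
    return Hypnogram(np.asarray(labels, dtype="U8"), epoch_s=epoch_s, **kw)


def labels_from(spec):
    return np.concatenate([np.full(n, lab, dtype="U8") for lab, n in spec])


def spectral_table(bin_powers, emg=None):
    """Rows of 30 bin powers -> spectral epoch DataFrame."""
    df = pd.DataFrame(np.atleast_2d(bin_powers), columns=BIN_COLS)
    df.insert(0, "epoch", np.arange(len(df)))
    if emg is not None:
        df["emg"] = emg
    return df


class TestCompareStaging:
    def test_identical_hypnograms_perfect(self):
        h = hyp(labels_from([(SLEEP, 30), (WAKE, 70)]))
        res = sv.compare_staging(h, h)
        assert res.sensitivity == res.specificity == res.accuracy == 1.0

    def test_complementary_hypnograms_zero_accuracy(self):
        a = hyp(labels_from([(SLEEP, 50), (WAKE, 50)]))
        b = hyp(labels_from([(WAKE, 50), (SLEEP, 50)]))
        assert sv.compare_staging(a, b).accuracy == 0.0

    def test_constructed_confusion(self):
        """100 epochs, 40 true sleep, 10 sleep epochs missed, rest perfect."""
        ref = labels_from([(SLEEP, 40), (WAKE, 60)])
        test = ref.copy()
        test[:10] = WAKE
        res = sv.compare_staging(hyp(test), hyp(ref))
        assert (res.tp, res.fn, res.tn, res.fp) == (30, 10, 60, 0)
        assert res.sensitivity == pytest.approx(0.75)
        assert res.accuracy == pytest.approx(0.90)
        assert res.n_epochs == 100

    def test_three_state_reference_collapsed(self):
        ref = hyp([NREM, REM, WAKE, NREM])
        test = hyp([SLEEP, SLEEP, WAKE, SLEEP])
        assert sv.compare_staging(test, ref).accuracy == 1.0

    def test_internal_identities(self):
        res = sv.AgreementResult(tp=7, tn=5, fp=2, fn=3,
                                 bout_count_test=2, bout_count_reference=3)
        assert res.sensitivity == pytest.approx(7 / 10)
        assert res.specificity == pytest.approx(5 / 7)
        assert res.accuracy == pytest.approx(12 / 17)
        assert res.n_epochs == 17

    def test_swap_symmetry(self):
        rng = np.random.default_rng(4)
        a = hyp(np.where(rng.random(200) < 0.4, SLEEP, WAKE))
        b = hyp(np.where(rng.random(200) < 0.5, SLEEP, WAKE))
        ab, ba = sv.compare_staging(a, b), sv.compare_staging(b, a)
        assert ab.accuracy == ba.accuracy
        assert ab.tp == ba.tp and ab.tn == ba.tn
        assert ab.fp == ba.fn and ab.fn == ba.fp

    def test_length_mismatch_names_both(self):
        with pytest.raises(ValueError, match="10.*12|12.*10"):
            sv.compare_staging(hyp([WAKE] * 10), hyp([WAKE] * 12))

    def test_bout_counts_from_runs(self):
        test = hyp(labels_from([(SLEEP, 3), (WAKE, 2), (SLEEP, 4)]))
        ref = hyp(labels_from([(SLEEP, 9)]))
        res = sv.compare_staging(test, ref)
        assert res.bout_count_test == 2 and res.bout_count_reference == 1


class TestSleepTimeSummary:
    def test_all_wake_day_zero_sleep(self):
        h = hyp(np.full(4320, WAKE), epoch_s=20.0)  # 24 h
        hourly, daily = sv.sleep_time_summary(h, 0.0)
        assert SLEEP not in hourly.columns or (hourly[SLEEP] == 0).all()
        assert daily[WAKE] == pytest.approx(1440.0)

    def test_alternating_epochs_30min_per_hour(self):
        labels = np.tile([SLEEP, WAKE], 4320 // 2)
        hourly, daily = sv.sleep_time_summary(hyp(labels), 0.0)
        assert np.allclose(hourly[SLEEP], 30.0)
        assert daily[SLEEP] == pytest.approx(720.0)

    def test_matches_truth_tally(self):
        sc = sv.SimScenario(duration_s=86400.0, arena_size_px=(288, 352),
                            mouse_radius_px=15, fps=0.5, seed=8)
        truth = sv.simulate_state_sequence(sv.StateModel(), 86400.0, 8, sc)
        h = truth.to_hypnogram()
        hourly, daily = sv.sleep_time_summary(h, 0.0)
        for zt in (0, 7, 23):
            chunk = truth.state_per_second[zt * 3600:(zt + 1) * 3600]
            assert hourly.loc[zt, SLEEP] == pytest.approx(
                np.count_nonzero(chunk == SLEEP) / 60.0)
        assert daily[SLEEP] == pytest.approx(
            np.count_nonzero(truth.state_per_second == SLEEP) / 60.0)

    def test_multiday_averaged(self):
        day1 = np.full(4320, WAKE)
        day2 = np.full(4320, SLEEP)
        hourly, daily = sv.sleep_time_summary(
            hyp(np.concatenate([day1, day2])), 0.0)
        assert np.allclose(hourly[SLEEP], 30.0)  # mean of 0 and 60 min


class TestDeltaPower:
    def test_all_delta_power_ratio_one(self):
        powers = np.zeros(30)
        powers[:4] = 5.0
        h = hyp([NREM])
        series = sv.relative_delta_power(spectral_table(powers), h)
        assert series.iloc[0] == pytest.approx(1.0)

    def test_flat_spectrum_ratio_4_over_30(self):
        h = hyp([NREM])
        series = sv.relative_delta_power(spectral_table(np.ones(30)), h)
        assert series.iloc[0] == pytest.approx(4 / 30)

    def test_hour_without_nrem_missing(self):
        # two hours of epochs; NREM only in hour 0
        labels = np.array([NREM] * 180 + [WAKE] * 180)
        powers = np.ones((360, 30))
        series = sv.relative_delta_power(spectral_table(powers), hyp(labels))
        assert series.loc[0] == pytest.approx(4 / 30)
        assert np.isnan(series.loc[1])

    def test_zero_power_epoch_excluded(self):
        powers = np.ones((2, 30))
        powers[1] = 0.0
        h = hyp([NREM, NREM])
        series = sv.relative_delta_power(spectral_table(powers), h)
        assert series.iloc[0] == pytest.approx(4 / 30)  # mean over valid epoch only

    def test_ratio_bounded(self):
        rng = np.random.default_rng(3)
        powers = rng.random((50, 30))
        r = delta_ratio(spectral_table(powers))
        assert ((r >= 0) & (r <= 1)).all()


class TestStateSpectra:
    def test_single_epoch_single_bin(self):
        powers = np.zeros(30)
        powers[9] = 2.5
        out = sv.state_power_spectra(spectral_table(powers), hyp([WAKE]))
        assert out.loc[WAKE, "bin_10"] == pytest.approx(100.0)
        assert out.loc[WAKE].drop("bin_10").eq(0).all()

    def test_rows_sum_to_100(self):
        rng = np.random.default_rng(7)
        powers = rng.random((40, 30))
        labels = np.where(rng.random(40) < 0.5, NREM, WAKE)
        out = sv.state_power_spectra(spectral_table(powers), hyp(labels))
        assert np.allclose(out.sum(axis=1), 100.0, atol=1e-9)

    def test_two_epoch_mean(self):
        p1, p2 = np.zeros(30), np.zeros(30)
        p1[0] = 1.0            # 100% in bin_1
        p2[0] = 1.0; p2[1] = 1.0  # 50/50 bins 1-2
        out = sv.state_power_spectra(spectral_table([p1, p2]), hyp([NREM, NREM]))
        assert out.loc[NREM, "bin_1"] == pytest.approx(75.0)
        assert out.loc[NREM, "bin_2"] == pytest.approx(25.0)

    def test_absent_state_omitted(self):
        out = sv.state_power_spectra(spectral_table(np.ones((2, 30))),
                                     hyp([WAKE, WAKE]))
        assert list(out.index) == [WAKE]


class TestWakeToRem:
    def test_rule_example(self):
        h = hyp([WAKE, WAKE, REM, REM, WAKE, NREM, REM])
        count, onsets = sv.detect_wake_to_rem(h)
        assert count == 1
        assert onsets == [2 * 20.0]

    def test_no_rem_zero(self):
        h = hyp([WAKE, NREM, WAKE, NREM])
        assert sv.detect_wake_to_rem(h)[0] == 0

    def test_two_state_input_rejected(self):
        with pytest.raises(ValueError, match="three-state"):
            sv.detect_wake_to_rem(hyp([WAKE, SLEEP]))

    def test_min_wake_duration_filter(self):
        h = hyp([NREM, WAKE, REM, NREM, WAKE, WAKE, WAKE, REM])
        assert sv.detect_wake_to_rem(h, min_wake_s=60.0)[0] == 1  # 3-epoch wake only


class TestRuleBasedStager:
    def test_rule_table(self):
        nrem_spec = np.zeros(30); nrem_spec[:4] = 10.0     # delta-ratio 1
        rem_spec = np.zeros(30); rem_spec[5:9] = 10.0      # theta-ratio 1
        wake_spec = np.ones(30)
        df = spectral_table([nrem_spec, rem_spec, wake_spec],
                            emg=[1.0, 0.01, 8.0])
        h = sv.rule_based_eeg_stager(df)
        assert h.labels.tolist() == [NREM, REM, WAKE]

    def test_missing_emg_two_state_fallback(self):
        nrem_spec = np.zeros(30); nrem_spec[:4] = 10.0
        df = spectral_table([nrem_spec, np.ones(30)])
        with pytest.warns(UserWarning, match="EMG"):
            h = sv.rule_based_eeg_stager(df)
        assert h.states <= {NREM, WAKE}

    def test_roundtrip_on_simulated_spectra(self):
        """Stager recovers the generating states from synthetic spectra."""
        labels = np.array([NREM] * 40 + [REM] * 10 + [WAKE] * 50)
        rng = np.random.default_rng(2)
        labels = labels[rng.permutation(labels.size)]
        h = hyp(labels)
        df = sv.simulate_spectral_epochs(h, seed=2)
        staged = sv.rule_based_eeg_stager(df)
        assert (staged.labels == labels).mean() >= 0.95
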