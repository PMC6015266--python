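"""Skin-conductance filtering, peak detection, epochs and the sensor block."""

import inspect

import numpy as np
import pandas as pd
import pytest

from phenosense.containers import SensorStream
from phenosense.sensors import (
    AGGREGATES,
    BASE_FEATURES,
    EPOCH_SECONDS,
    acc_fullday_summary,
    detect_sc_peaks,
    epoch_features,
    fir_lowpass,
    normalize_sc_daily,
    range_mask,
    sensor_feature_matrix,
)
from phenosense.windows import SENSOR_WINDOWS

START = pd.Timestamp("2024-01-08")


def _stream(sc, st=None, acc=None, valid=None, fs=1.0, t0=START):
    n = len(sc)
    return SensorStream(
        participant_id="p",
        sample_rate=fs,
        t0=t0,
        sc=np.asarray(sc, dtype=float),
        st=np.full(n, 33.0) if st is None else np.asarray(st, dtype=float),
        acc=np.zeros((n, 3)) if acc is None else np.asarray(acc, dtype=float),
        valid_mask=valid,
    )


class TestFirLowpass:
    def test_unit_dc_gain(self):
        x = np.full(500, 5.0)
        assert np.allclose(fir_lowpass(x, 8.0), 5.0, atol=1e-8)

    def test_stopband_attenuation_at_2hz(self):
        t = np.arange(0, 120, 1 / 8)
        y = fir_lowpass(np.sin(2 * np.pi * 2.0 * t), 8.0)
        # > 20 dB attenuation away from the edges
        assert np.max(np.abs(y[200:-200])) < 0.1

    def test_passband_preserved(self):
        t = np.arange(0, 600, 1 / 8)
        y = fir_lowpass(np.sin(2 * np.pi * 0.05 * t), 8.0)
        assert np.max(np.abs(y[500:-500])) == pytest.approx(1.0, abs=0.05)

    def test_defaults_are_04hz_order_32(self):
        sig = inspect.signature(fir_lowpass)
        assert sig.parameters["cutoff"].default == 0.4
        assert sig.parameters["order"].default == 32

    def test_sample_rate_below_nyquist_raises(self):
        with pytest.raises(ValueError, match="sample_rate"):
            fir_lowpass(np.ones(100), 0.5)

    def test_short_series_does_not_crash(self):
        y = fir_lowpass(np.array([1.0, 2.0, 3.0]), 8.0)
        assert y.shape == (3,)


class TestRangeMask:
    def test_sc_bounds(self):
        s = _stream([0.005, 1.0, 31.0], st=[19.9, 36.5, 42.0])
        sc_ok, st_ok = range_mask(s)
        assert sc_ok.tolist() == [False, True, False]
        assert st_ok.tolist() == [False, True, True]

    def test_bounds_are_inclusive(self):
        s = _stream([0.01, 30.0], st=[20.0, 42.0])
        sc_ok, st_ok = range_mask(s)
        assert sc_ok.all() and st_ok.all()

    def test_valid_mask_is_anded_in(self):
        s = _stream([1.0, 1.0, 1.0], valid=[True, False, True])
        sc_ok, st_ok = range_mask(s)
        assert sc_ok.tolist() == [True, False, True]
        assert st_ok.tolist() == [True, False, True]


class TestPeakDetection:
    def test_single_rise_above_threshold(self):
        fs = 8.0
        x = np.concatenate([np.full(80, 2.0), 2.0 + 0.05 * np.arange(1, 17) / fs,
                            np.full(40, 2.1)])
        peaks = detect_sc_peaks(x, fs)
        assert peaks.shape == (1,)
        assert peaks[0] == 79 / fs  # onset = left sample of the first steep segment

    def test_slow_rise_is_ignored(self):
        fs = 8.0
        x = np.concatenate([np.full(80, 2.0), 2.0 + 0.01 * np.arange(1, 17) / fs])
        assert detect_sc_peaks(x, fs).size == 0

    def test_threshold_is_strict(self):
        fs = 1.0
        x = np.array([0.0, 0.02, 0.04])  # slope exactly 0.02 uS/s
        assert detect_sc_peaks(x, fs).size == 0

    def test_offset_invariance(self):
        rng = np.random.default_rng(1)
        x = np.cumsum(rng.normal(0, 0.01, 500))
        a = detect_sc_peaks(x, 8.0)
        b = detect_sc_peaks(x + 7.5, 8.0)
        assert np.array_equal(a, b)

    def test_matches_scan_oracle(self):
        def oracle(x, fs, thr=0.02):
            out, prev = [], False
            for i in range(len(x) - 1):
                above = (x[i + 1] - x[i]) * fs > thr
                if above and not prev:
                    out.append(i / fs)
                prev = above
            return np.array(out)

        rng = np.random.default_rng(11)
        for _ in range(100):
            n = int(rng.integers(10, 400))
            fs = float(rng.choice([1.0, 4.0, 8.0]))
            x = np.cumsum(rng.normal(0, 0.02, n))
            assert np.array_equal(detect_sc_peaks(x, fs), oracle(x, fs))


class TestEpochFeatures:
    def test_rectangle_auc_is_60(self):
        fs = 8.0
        n = 241  # 30 s inclusive of the next epoch boundary sample
        ep = epoch_features(np.full(n, 2.0), np.empty(0), np.zeros((n, 3)), fs)
        assert ep.auc[0] == pytest.approx(60.0)
        assert bool(ep.valid[0])
        # the lone boundary sample cannot fill epoch 1
        assert not ep.valid[1] and np.isnan(ep.auc[1])

    def test_alternating_signal_gives_29_zero_crossings(self):
        n = 30
        acc = np.zeros((n, 3))
        acc[:, 0] = np.where(np.arange(n) % 2 == 0, 1.0, -1.0)
        ep = epoch_features(np.full(n, 1.0), np.empty(0), acc, 1.0)
        assert ep.zero_crossings[0] == 29.0

    def test_still_signal_gives_zero_crossings_zero(self):
        n = 30
        ep = epoch_features(np.full(n, 1.0), np.empty(0), np.zeros((n, 3)), 1.0)
        assert ep.zero_crossings[0] == 0.0

    def test_peak_counts_land_in_onset_epoch(self):
        n = 90
        ep = epoch_features(np.full(n, 1.0), np.array([5.0, 40.0, 41.0]),
                            np.zeros((n, 3)), 1.0)
        assert ep.peak_count[0] == 1.0
        assert ep.peak_count[1] == 2.0
        assert ep.peak_count[2] == 0.0

    def test_epochs_align_to_absolute_midnight(self):
        ep = epoch_features(np.full(60, 1.0), np.empty(0), np.zeros((60, 3)),
                            1.0, start_second=50.0)
        assert ep.start_seconds[0] == 30.0
        # only 10 of 30 expected samples fall in the first epoch: invalid
        assert not ep.valid[0]
        assert bool(ep.valid[1])

    def test_masked_samples_invalidate_epochs(self):
        n = 60
        mask = np.ones(n, dtype=bool)
        mask[:20] = False  # only 10/30 valid in epoch 0
        ep = epoch_features(np.full(n, 1.0), np.empty(0), np.zeros((n, 3)), 1.0,
                            sc_mask=mask)
        assert not ep.valid[0] and np.isnan(ep.auc[0])
        assert bool(ep.valid[1])


class TestNormalizeScDaily:
    def test_min_max_per_day(self):
        sc = np.array([0.0, 5.0, 10.0, 2.0, 4.0, 6.0])
        day = np.array([0, 0, 0, 1, 1, 1])
        out = normalize_sc_daily(sc, day)
        assert np.allclose(out, [0.0, 0.5, 1.0, 0.0, 0.5, 1.0])

    def test_constant_day_maps_to_zero(self):
        out = normalize_sc_daily(np.full(5, 3.3), np.zeros(5))
        assert np.allclose(out, 0.0)

    def test_masked_outliers_do_not_set_the_range(self):
        sc = np.array([0.0, 1.0, 100.0])
        mask = np.array([True, True, False])
        out = normalize_sc_daily(sc, np.zeros(3), mask=mask)
        assert np.allclose(out, [0.0, 1.0, 1.0])  # outlier clipped to 1


class TestSensorFeatureMatrix:
    def test_columns_are_stable_and_unique(self, small_bundle, small_blocks):
        block = small_blocks["sensors"]
        expected = [
            f"{feat}__{win.label}__{agg}"
            for win in SENSOR_WINDOWS
            for feat in BASE_FEATURES
            for agg in AGGREGATES
        ]
        assert list(block.data.columns) == expected
        assert not block.data.columns.duplicated().any()
        assert list(block.meta.index) == expected
        assert set(block.meta["window"]) == {w.label for w in SENSOR_WINDOWS}

    def test_participants_with_one_day_are_excluded(self):
        n = 86400  # a single day at 1 Hz
        rng = np.random.default_rng(0)
        s = _stream(2.0 + rng.normal(0, 0.01, n), acc=rng.normal(0, 0.1, (n, 3)))
        block = sensor_feature_matrix([s])
        assert block.data.shape == (0, 204)

    def test_acc_summary_single_column(self, small_bundle):
        streams = list(small_bundle.streams.values())
        block = acc_fullday_summary(streams)
        assert list(block.data.columns) == ["acc_zero_crossings__full_day__mean"]
        assert block.data.notna().all().all()
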