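"""Phone event features and mobility."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import multivariate_normal

from phenosense.phone import (
    EVENT_FEATURES,
    MOBILITY_FEATURES,
    daily_event_features,
    daily_loglik,
    daily_mobility,
    fit_mobility_gmm,
    phone_feature_matrix,
    screen_bouts,
    sms_sessions,
)
from phenosense.windows import PHONE_WINDOWS, Window

DAY = pd.Timestamp("2024-01-08")


def _empty_calls():
    return pd.DataFrame(columns=["participant_id", "start_ts", "duration_s",
                                 "contact_hash", "direction"])


def _empty_sms():
    return pd.DataFrame(columns=["participant_id", "ts", "contact_hash", "direction"])


def _empty_screen():
    return pd.DataFrame(columns=["participant_id", "ts", "state"])


def _trace(pid, times_s, xy, day=DAY):
    return pd.DataFrame(
        {
            "participant_id": pid,
            "ts": [day + pd.Timedelta(seconds=t) for t in times_s],
            "x_m": [p[0] for p in xy],
            "y_m": [p[1] for p in xy],
        }
    )


class TestSmsSessions:
    def test_gap_rule_splits_sessions(self):
        t0 = DAY + pd.Timedelta(hours=12)
        sms = pd.DataFrame(
            {
                "participant_id": ["p"] * 3,
                "ts": [t0, t0 + pd.Timedelta(seconds=100), t0 + pd.Timedelta(seconds=400)],
                "contact_hash": ["c1"] * 3,
                "direction": ["out"] * 3,
            }
        )
        sess = sms_sessions(sms)
        assert sess.shape[0] == 2
        assert sorted(sess["duration_s"].tolist()) == [0.0, 100.0]

    def test_different_contacts_never_merge(self):
        t0 = DAY + pd.Timedelta(hours=12)
        sms = pd.DataFrame(
            {
                "participant_id": ["p", "p"],
                "ts": [t0, t0 + pd.Timedelta(seconds=10)],
                "contact_hash": ["c1", "c2"],
                "direction": ["out", "in"],
            }
        )
        assert sms_sessions(sms).shape[0] == 2


class TestScreenBouts:
    def test_on_off_pairing_across_midnight(self):
        screen = pd.DataFrame(
            {
                "participant_id": ["p"] * 2,
                "ts": [DAY + pd.Timedelta(hours=23, minutes=50),
                       DAY + pd.Timedelta(days=1, minutes=10)],
                "state": ["on", "off"],
            }
        )
        bouts = screen_bouts(screen)
        assert bouts.shape[0] == 1
        assert bouts["duration_s"].iloc[0] == 1200.0

    def test_trailing_on_closed_at_next_midnight(self):
        screen = pd.DataFrame(
            {"participant_id": ["p"], "ts": [DAY + pd.Timedelta(hours=22)],
             "state": ["on"]}
        )
        bouts = screen_bouts(screen)
        assert bouts["duration_s"].iloc[0] == 7200.0

    def test_leading_off_is_dropped(self):
        screen = pd.DataFrame(
            {"participant_id": ["p"], "ts": [DAY + pd.Timedelta(hours=9)],
             "state": ["off"]}
        )
        assert screen_bouts(screen).empty


class TestDailyEventFeatures:
    def test_two_call_arithmetic(self):
        calls = pd.DataFrame(
            {
                "participant_id": ["p", "p"],
                "start_ts": [DAY + pd.Timedelta(hours=11, minutes=58),
                             DAY + pd.Timedelta(hours=12, minutes=2)],
                "duration_s": [120.0, 120.0],
                "contact_hash": ["c1", "c2"],
                "direction": ["out", "in"],
            }
        )
        df = daily_event_features(calls, _empty_sms(), _empty_screen(), Window.FULL_DAY)
        row = df.iloc[0]
        assert row["call_count"] == 2.0
        assert row["call_total_duration"] == 240.0
        assert row["call_duration_mean"] == 120.0
        assert row["call_time_mean"] == 720.0  # noon, minutes from midnight
        assert row["call_unique_contacts"] == 2.0
        assert np.isnan(row["sms_count"])

    def test_window_membership_and_offset(self):
        calls = pd.DataFrame(
            {
                "participant_id": ["p", "p"],
                "start_ts": [DAY + pd.Timedelta(hours=1, minutes=30),
                             DAY + pd.Timedelta(hours=19)],
                "duration_s": [60.0, 60.0],
                "contact_hash": ["c1", "c1"],
                "direction": ["out", "out"],
            }
        )
        late = daily_event_features(calls, _empty_sms(), _empty_screen(), Window.LATE_NIGHT)
        night = daily_event_features(calls, _empty_sms(), _empty_screen(), Window.NIGHT)
        assert late.iloc[0]["call_count"] == 1.0
        assert late.iloc[0]["call_time_mean"] == 90.0  # minutes after 00:00
        assert night.iloc[0]["call_count"] == 1.0
        assert night.iloc[0]["call_time_mean"] == 60.0  # minutes after 18:00

    def test_matches_naive_per_day_oracle(self):
        rng = np.random.default_rng(3)
        rows = []
        for pid in ("a", "b"):
            for _ in range(40):
                t = float(rng.uniform(0, 3 * 86400))
                rows.append(
                    {
                        "participant_id": pid,
                        "start_ts": DAY + pd.Timedelta(seconds=round(t)),
                        "duration_s": float(rng.exponential(100)),
                        "contact_hash": f"c{int(rng.integers(0, 4))}",
                        "direction": "out",
                    }
                )
        calls = pd.DataFrame(rows)
        df = daily_event_features(calls, _empty_sms(), _empty_screen(), Window.FULL_DAY)
        df = df.set_index(["participant_id", "date"])

        oracle: dict = {}
        for r in rows:
            key = (r["participant_id"], r["start_ts"].normalize())
            oracle.setdefault(key, []).append(r["duration_s"])
        assert set(df.index) == set(oracle)
        for key, durs in oracle.items():
            assert df.loc[key, "call_count"] == len(durs)
            assert df.loc[key, "call_total_duration"] == pytest.approx(sum(durs))


class TestDailyMobility:
    def test_stationary_day(self):
        tr = _trace("p", [0, 600, 1200, 1800], [(10.0, 10.0)] * 4)
        row = daily_mobility(tr).iloc[0]
        assert row["total_distance_m"] == 0.0
        assert row["five_min_distance_m"] == 0.0
        assert row["radius_m"] == 0.0

    def test_two_fixes_300m(self):
        tr = _trace("p", [0, 600], [(0.0, 0.0), (300.0, 0.0)])
        row = daily_mobility(tr).iloc[0]
        assert row["total_distance_m"] == 300.0
        assert row["five_min_distance_m"] == 300.0
        assert row["radius_m"] == 150.0

    def test_square_walk(self):
        tr = _trace("p", [0, 600, 1200, 1800],
                    [(0.0, 0.0), (400.0, 0.0), (400.0, 400.0), (0.0, 400.0)])
        row = daily_mobility(tr).iloc[0]
        assert row["total_distance_m"] == pytest.approx(1200.0)
        assert row["radius_m"] == pytest.approx(200.0 * np.sqrt(2))

    def test_translation_invariance(self):
        times = [0, 600, 1200, 1800]
        pts = [(0.0, 0.0), (400.0, 0.0), (400.0, 400.0), (0.0, 400.0)]
        shifted = [(x + 1000.0, y - 500.0) for x, y in pts]
        a = daily_mobility(_trace("p", times, pts)).iloc[0]
        b = daily_mobility(_trace("p", times, shifted)).iloc[0]
        for feat in ("total_distance_m", "five_min_distance_m", "radius_m"):
            assert a[feat] == pytest.approx(b[feat])

    def test_single_fix_day_is_nan(self):
        row = daily_mobility(_trace("p", [0], [(0.0, 0.0)])).iloc[0]
        assert np.isnan(row["total_distance_m"])
        assert np.isnan(row["radius_m"])


class TestMobilityModel:
    def test_single_component_matches_closed_form(self):
        rng = np.random.default_rng(5)
        pts = rng.normal(0.0, 30.0, size=(15, 2))  # < 20 fixes forces K = 1
        model = fit_mobility_gmm(pts, "p", seed=0)
        assert model.k == 1
        assert np.allclose(model.model.means_[0], pts.mean(axis=0), atol=1e-6)
        day = rng.normal(0.0, 30.0, size=(6, 2))
        expected = multivariate_normal(
            mean=model.model.means_[0], cov=model.model.covariances_[0]
        ).logpdf(day).mean()
        assert daily_loglik(model, day) == pytest.approx(expected, abs=1e-8)

    def test_routine_days_score_higher_than_novel_days(self):
        rng = np.random.default_rng(6)
        home = rng.normal(0.0, 25.0, size=(60, 2))
        model = fit_mobility_gmm(home, "p", seed=0)
        assert daily_loglik(model, home[:10]) > daily_loglik(model, home[:10] + 10_000.0)

    def test_refit_is_deterministic(self):
        rng = np.random.default_rng(7)
        pts = np.vstack([rng.normal(0, 20, (40, 2)), rng.normal(500, 20, (40, 2))])
        a = fit_mobility_gmm(pts, "p", seed=3)
        b = fit_mobility_gmm(pts, "p", seed=3)
        assert a.k == b.k
        assert a.bic == b.bic
        assert np.array_equal(a.model.means_, b.model.means_)

    def test_too_few_fixes_raise(self):
        with pytest.raises(ValueError):
            fit_mobility_gmm(np.array([[0.0, 0.0]]))


class TestPhoneFeatureMatrix:
    def test_column_layout(self, small_blocks):
        block = small_blocks["phone"]
        expected = [
            f"{feat}__{win.label}__{agg}"
            for win in PHONE_WINDOWS
            for feat in EVENT_FEATURES
            for agg in ("mean", "median", "sd")
        ] + [f"{feat}__{agg}" for feat in MOBILITY_FEATURES
             for agg in ("mean", "median", "sd")]
        assert list(block.data.columns) == expected
        assert not block.data.columns.duplicated().any()

    def test_empty_logs_give_empty_block(self):
        block = phone_feature_matrix(_empty_calls(), _empty_sms(), _empty_screen(),
                                     pd.DataFrame(columns=["participant_id", "ts",
                                                           "x_m", "y_m"]))
        assert block.data.shape == (0, 237)
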