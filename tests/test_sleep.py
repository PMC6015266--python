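"""Sleep Regularity Index and sleep feature block."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, given, settings
from hypothesis import strategies as st

from phenosense.sleep import (
    LAG_MINUTES,
    MISSING,
    SLEEP,
    WAKE,
    SleepEpisode,
    SleepWakeVector,
    UndefinedResultError,
    bedtime_circular_minutes,
    daily_sleep_table,
    episodes_from_vector,
    sleep_feature_matrix,
    sleep_regularity_index,
    sri_from_bundle_episodes,
    vector_from_episodes,
)

START = pd.Timestamp("2024-01-08")


def _vector(states):
    return SleepWakeVector(participant_id="p", start=START, states=states)


def periodic_states(days=30, bed_hour=23, wake_hour=7):
    minutes = np.arange(days * 1440) % 1440
    asleep = (minutes >= bed_hour * 60) | (minutes < wake_hour * 60)
    return np.where(asleep, SLEEP, WAKE)


def sri_oracle(states):
    """Literal double-loop definition: P[s(t) == s(t+1440)] over valid pairs."""
    agree = total = 0
    for t in range(len(states) - LAG_MINUTES):
        a, b = states[t], states[t + LAG_MINUTES]
        if a != MISSING and b != MISSING:
            total += 1
            agree += int(a == b)
    return -100.0 + 200.0 * agree / total


class TestSleepRegularityIndex:
    def test_periodic_schedule_scores_exactly_100(self):
        assert sleep_regularity_index(_vector(periodic_states())) == 100.0

    def test_alternating_full_days_scores_exactly_minus_100(self):
        states = np.tile(np.concatenate([np.full(1440, SLEEP), np.full(1440, WAKE)]), 15)
        assert sleep_regularity_index(_vector(states)) == -100.0

    def test_random_states_score_near_zero(self):
        rng = np.random.default_rng(42)
        vals = [
            sleep_regularity_index(
                _vector(np.where(rng.random(30 * 1440) < 0.5, SLEEP, WAKE))
            )
            for _ in range(50)
        ]
        assert abs(float(np.mean(vals))) < 2.0

    def test_missing_minutes_are_excluded_pairwise(self):
        states = periodic_states()
        states[3 * 1440 : 4 * 1440] = MISSING
        assert sleep_regularity_index(_vector(states)) == 100.0

    def test_relabeling_wake_and_sleep_is_invariant(self):
        rng = np.random.default_rng(0)
        states = np.where(rng.random(3000) < 0.4, SLEEP, WAKE)
        assert sleep_regularity_index(_vector(states)) == sleep_regularity_index(
            _vector(-states)
        )

    def test_too_short_vector_raises(self):
        with pytest.raises(UndefinedResultError):
            sleep_regularity_index(_vector(np.full(1440, WAKE)))

    def test_no_valid_pair_raises(self):
        states = np.full(2000, MISSING)
        states[:100] = WAKE
        with pytest.raises(UndefinedResultError):
            sleep_regularity_index(_vector(states))

    def test_invalid_state_codes_rejected(self):
        with pytest.raises(ValueError):
            _vector(np.array([1, 2, -1]))

    def test_matches_double_loop_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            n = int(rng.integers(1500, 4000))
            states = rng.choice([SLEEP, WAKE, MISSING], size=n, p=[0.4, 0.5, 0.1])
            if not ((states[:-LAG_MINUTES] != 0) & (states[LAG_MINUTES:] != 0)).any():
                continue
            v = _vector(states)
            assert sleep_regularity_index(v) == pytest.approx(
                sri_oracle(states), abs=1e-9
            )

    @settings(derandomize=True, max_examples=30, deadline=None,
              suppress_health_check=[HealthCheck.large_base_example])
    @given(st.lists(st.sampled_from([SLEEP, WAKE]), min_size=1441, max_size=3000))
    def test_result_always_in_range(self, states):
        val = sleep_regularity_index(_vector(np.array(states)))
        assert -100.0 <= val <= 100.0


class TestVectorFromEpisodes:
    def test_no_episodes_gives_all_wake(self):
        v = vector_from_episodes([], span_minutes=2880, start=START)
        assert (v.states == WAKE).all()

    def test_episode_minutes_are_sleep(self):
        epi = SleepEpisode(bedtime=START + pd.Timedelta(hours=23),
                           waketime=START + pd.Timedelta(hours=31))
        v = vector_from_episodes([epi], span_minutes=2880, start=START)
        assert (v.states[23 * 60 : 31 * 60] == SLEEP).all()
        assert (v.states[: 23 * 60] == WAKE).all()
        assert (v.states[31 * 60 :] == WAKE).all()

    def test_efficiency_places_expected_wake_minutes(self):
        epi = SleepEpisode(bedtime=START, waketime=START + pd.Timedelta(minutes=400),
                           efficiency=0.9)
        v = vector_from_episodes([epi], span_minutes=1500, start=START, seed=3)
        inside = v.states[:400]
        assert int((inside == WAKE).sum()) == round(0.1 * 400)

    def test_overlapping_episodes_raise(self):
        a = SleepEpisode(bedtime=START, waketime=START + pd.Timedelta(hours=8))
        b = SleepEpisode(bedtime=START + pd.Timedelta(hours=7),
                         waketime=START + pd.Timedelta(hours=12))
        with pytest.raises(ValueError, match="overlap"):
            vector_from_episodes([a, b], span_minutes=1500, start=START)

    def test_round_trip_through_episode_extraction(self):
        epi = SleepEpisode(bedtime=START + pd.Timedelta(minutes=100),
                           waketime=START + pd.Timedelta(minutes=520))
        v = vector_from_episodes([epi], span_minutes=1500, start=START)
        assert episodes_from_vector(v) == [(100, 520)]

    def test_rasterization_then_sri_is_100_for_periodic_episodes(self):
        episodes = [
            SleepEpisode(bedtime=START + pd.Timedelta(days=d, hours=23),
                         waketime=START + pd.Timedelta(days=d + 1, hours=7))
            # start one night early so day 0 also has the 00:00-07:00 sleep
            # tail; episodes outside the span are clipped
            for d in range(-1, 30)
        ]
        v = vector_from_episodes(episodes, span_minutes=30 * 1440, start=START)
        assert sleep_regularity_index(v) == 100.0


class TestBedtimeCircularAxis:
    def test_reference_is_1800(self):
        assert bedtime_circular_minutes(pd.Timestamp("2024-01-08 18:00")) == 0.0

    def test_straddling_midnight_averages_to_midnight(self):
        a = bedtime_circular_minutes(pd.Timestamp("2024-01-08 23:30"))
        b = bedtime_circular_minutes(pd.Timestamp("2024-01-09 00:30"))
        assert a == 330.0 and b == 390.0
        assert (a + b) / 2 == 360.0  # i.e. 18:00 + 360 min = midnight


class TestSleepFeatureMatrix:
    def _toy_daily(self):
        episodes = pd.DataFrame(
            {
                "participant_id": ["p1"] * 3,
                "day_index": [0, 1, 2],
                "bedtime": [pd.Timestamp("2024-01-08 23:00") + pd.Timedelta(days=d)
                            for d in range(3)],
                "waketime": [pd.Timestamp("2024-01-09 07:00") + pd.Timedelta(days=d)
                             for d in range(3)],
                "efficiency": [0.9, 0.95, 1.0],
            }
        )
        diary = pd.DataFrame(
            {
                "participant_id": ["p1"] * 3,
                "date": ["2024-01-08", "2024-01-09", "2024-01-10"],
                "all_nighter": [0, 0, 0],
                "presleep_media": [1, 0, 1],
                "presleep_interaction": [0, 0, 1],
                "n_naps": [0, 1, 2],
                "nap_duration_min": [0.0, 30.0, 60.0],
            }
        )
        return daily_sleep_table(episodes, diary)

    def test_daily_table_values(self):
        daily = self._toy_daily()
        assert daily.shape[0] == 3
        assert (daily["bedtime_min"] == 300.0).all()  # 23:00 = 18:00 + 300 min
        assert (daily["sleep_duration_min"] == 480.0).all()

    def test_block_has_25_columns_and_expected_aggregates(self):
        daily = self._toy_daily()
        block = sleep_feature_matrix(daily, sri={"p1": 87.5})
        assert block.data.shape == (1, 25)
        row = block.data.loc["p1"]
        assert row["sleep_regularity_index"] == 87.5
        assert row["n_naps__mean"] == 1.0
        assert row["n_naps__median"] == 1.0
        assert row["n_naps__sd"] == 1.0
        assert row["sleep_efficiency__mean"] == pytest.approx(0.95)

    def test_short_participants_are_excluded(self):
        daily = self._toy_daily().iloc[:1]
        block = sleep_feature_matrix(daily, sri={"p1": 50.0})
        assert block.data.shape[0] == 0

    def test_sri_from_episode_table(self, small_bundle):
        sri = sri_from_bundle_episodes(
            small_bundle.sleep_episodes,
            days=small_bundle.config.days_per_participant,
            start=START,
        )
        assert set(sri.index) <= set(small_bundle.participants["participant_id"])
        assert ((sri.dropna() >= -100) & (sri.dropna() <= 100)).all()
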