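"""Sleep Regularity Index and the sleep feature block.

The Sleep Regularity Index (SRI) is the probability of being in the same
state (asleep vs awake) at any two time points 24 hours apart, at 1-minute
resolution, linearly rescaled so that a perfectly periodic sleeper scores
100 and an i.i.d.-random schedule scores 0 in expectation:

    SRI = -100 + 200 * P[s(t) = s(t + 1440 min)]

Negative values are possible (e.g. alternating 24 h of sleep and 24 h of
wake gives -100) but rarely observed.  Minutes with missing state are
excluded pairwise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import FeatureBlock

logger = logging.getLogger(__name__)

WAKE = 1
SLEEP = -1
MISSING = 0
LAG_MINUTES = 1440

#: reference hour for the circular bedtime axis: bedtimes are expressed as
#: minutes after 18:00 so typical student bedtimes (evening to noon) never
#: wrap around the axis origin
BEDTIME_REFERENCE_HOUR = 18


class UndefinedResultError(ValueError):
    """The requested statistic has no valid data to be computed from."""


@dataclass
class SleepWakeVector:
    """Minute-resolution wake(+1)/sleep(-1)/missing(0) states for one person."""

    participant_id: str
    start: pd.Timestamp
    states: np.ndarray

    def __post_init__(self):
        self.states = np.asarray(self.states, dtype=np.int8)
        bad = ~np.isin(self.states, (WAKE, SLEEP, MISSING))
        if bad.any():
            raise ValueError("states must be +1 (wake), -1 (sleep) or 0 (missing)")
        self.start = pd.Timestamp(self.start)

    @property
    def total_minutes(self) -> int:
        return self.states.shape[0]


@dataclass
class SleepEpisode:
    """One night's main sleep period plus daytime naps."""

    bedtime: pd.Timestamp
    waketime: pd.Timestamp
    efficiency: float = 1.0
    naps: list = field(default_factory=list)
    all_nighter: bool = False

    def __post_init__(self):
        self.bedtime = pd.Timestamp(self.bedtime)
        self.waketime = pd.Timestamp(self.waketime)
        if not self.all_nighter and self.waketime <= self.bedtime:
            raise ValueError("waketime must be after bedtime")
        if not 0.0 <= self.efficiency <= 1.0:
            raise ValueError("efficiency must lie in [0, 1]")


def sleep_regularity_index(v: SleepWakeVector, lag_minutes: int = LAG_MINUTES) -> float:
    """SRI in [-100, 100]; pairs with either state missing are excluded."""
    s = v.states
    if s.shape[0] <= lag_minutes:
        raise UndefinedResultError("need more than 24 h of data to form any 24-h pair")
    a, b = s[:-lag_minutes], s[lag_minutes:]
    ok = (a != MISSING) & (b != MISSING)
    if not ok.any():
        raise UndefinedResultError("no valid 24-h-apart state pair")
    agree = float(np.mean(a[ok] == b[ok]))
    return -100.0 + 200.0 * agree


def vector_from_episodes(episodes: list[SleepEpisode], span_minutes: int,
                         start: pd.Timestamp, seed: int = 0,
                         participant_id: str = "") -> SleepWakeVector:
    """Rasterize sleep episodes into a minute-resolution state vector.

    Minutes inside an episode are sleep; when an episode's efficiency is
    below 1, the implied within-episode wake minutes are placed uniformly
    at random (seeded) inside the episode.  Minutes outside all episodes
    are wake.  Episodes must not overlap.
    """
    start = pd.Timestamp(start)
    states = np.full(span_minutes, WAKE, dtype=np.int8)
    rng = np.random.default_rng(seed)
    spans = []
    for epi in episodes:
        if epi.all_nighter:
            continue
        lo = int((epi.bedtime - start).total_seconds() // 60)
        hi = int((epi.waketime - start).total_seconds() // 60)
        spans.append((lo, hi))
    spans.sort()
    for (lo, hi), (lo2, _hi2) in zip(spans, spans[1:]):
        if lo2 < hi:
            raise ValueError("sleep episodes overlap")
    for epi in episodes:
        if epi.all_nighter:
            continue
        lo = max(int((epi.bedtime - start).total_seconds() // 60), 0)
        hi = min(int((epi.waketime - start).total_seconds() // 60), span_minutes)
        if hi <= lo:
            continue
        states[lo:hi] = SLEEP
        n_wake = int(round((1.0 - epi.efficiency) * (hi - lo)))
        if n_wake > 0:
            idx = rng.choice(np.arange(lo, hi), size=n_wake, replace=False)
            states[idx] = WAKE
    return SleepWakeVector(participant_id=participant_id, start=start, states=states)


def episodes_from_vector(v: SleepWakeVector, min_minutes: int = 1) -> list[tuple[int, int]]:
    """Maximal sleep runs (start minute, end minute) of a state vector."""
    asleep = v.states == SLEEP
    edges = np.diff(asleep.astype(np.int8))
    starts = list(np.flatnonzero(edges == 1) + 1)
    ends = list(np.flatnonzero(edges == -1) + 1)
    if asleep.size and asleep[0]:
        starts.insert(0, 0)
    if asleep.size and asleep[-1]:
        ends.append(asleep.size)
    return [(s, e) for s, e in zip(starts, ends) if e - s >= min_minutes]


def bedtime_circular_minutes(bedtime: pd.Timestamp) -> float:
    """Bedtime as minutes after 18:00 on a circular axis (0..1440).

    The 18:00 reference places typical bedtimes (evening through next
    noon) on a contiguous stretch, so plain mean/SD are meaningful
    without midnight wrap-around.
    """
    t = pd.Timestamp(bedtime)
    minute_of_day = t.hour * 60 + t.minute + t.second / 60.0
    return (minute_of_day - BEDTIME_REFERENCE_HOUR * 60) % 1440.0


#: the 8 per-day quantities aggregated by mean/median/SD (plus SRI -> 25 cols)
SLEEP_DAILY_ITEMS = (
    "bedtime_min",
    "sleep_duration_min",
    "sleep_efficiency",
    "all_nighter",
    "presleep_media",
    "presleep_interaction",
    "n_naps",
    "nap_duration_min",
)


def daily_sleep_table(sleep_episodes: pd.DataFrame, diary: pd.DataFrame) -> pd.DataFrame:
    """Per-participant-day sleep quantities from episodes + diary records.

    ``sleep_episodes`` needs (participant_id, day_index, bedtime, waketime,
    efficiency); ``diary`` needs (participant_id, date-ordered rows with
    all_nighter, presleep flags, n_naps, nap_duration_min).
    """
    d = diary.sort_values(["participant_id", "date"]).copy()
    d["day_index"] = d.groupby("participant_id").cumcount()
    cols = ["participant_id", "day_index", "all_nighter", "presleep_media",
            "presleep_interaction", "n_naps", "nap_duration_min"]
    out = d[cols].merge(
        sleep_episodes[["participant_id", "day_index", "bedtime", "waketime", "efficiency"]],
        on=["participant_id", "day_index"], how="left",
    )
    out["bedtime_min"] = out["bedtime"].map(
        lambda t: np.nan if pd.isna(t) else bedtime_circular_minutes(t)
    )
    dur = (out["waketime"] - out["bedtime"]).dt.total_seconds() / 60.0
    out["sleep_duration_min"] = dur
    out["sleep_efficiency"] = out["efficiency"]
    return out


def sleep_feature_matrix(daily: pd.DataFrame, sri: pd.Series | dict,
                         min_days: int = 2) -> FeatureBlock:
    """The 25-column sleep feature block: SRI + 8 daily items x 3 aggregates.

    ``daily`` is the output of :func:`daily_sleep_table`; ``sri`` maps
    participant id to Sleep Regularity Index.
    """
    sri = pd.Series(sri)
    rows, index = [], []
    for pid, g in daily.groupby("participant_id", sort=True):
        if g.shape[0] < min_days:
            logger.warning("participant %s excluded from sleep features: <%d days", pid, min_days)
            continue
        row = {"sleep_regularity_index": float(sri.get(pid, np.nan))}
        for item in SLEEP_DAILY_ITEMS:
            vals = g[item].to_numpy(dtype=float)
            vals = vals[~np.isnan(vals)]
            if vals.size >= min_days:
                row[f"{item}__mean"] = float(np.mean(vals))
                row[f"{item}__median"] = float(np.median(vals))
                row[f"{item}__sd"] = float(np.std(vals, ddof=1))
            else:
                row[f"{item}__mean"] = np.nan
                row[f"{item}__median"] = np.nan
                row[f"{item}__sd"] = np.nan
        rows.append(row)
        index.append(pid)

    columns = ["sleep_regularity_index"] + [
        f"{item}__{agg}" for item in SLEEP_DAILY_ITEMS for agg in ("mean", "median", "sd")
    ]
    data = pd.DataFrame(rows, index=pd.Index(index, name="participant_id"), columns=columns)
    meta_rows = [{"block": "sleep", "statistic": "sleep_regularity_index",
                  "window": "study", "aggregate": ""}]
    meta_rows += [
        {"block": "sleep", "statistic": item, "window": "daily", "aggregate": agg}
        for item in SLEEP_DAILY_ITEMS for agg in ("mean", "median", "sd")
    ]
    meta = pd.DataFrame(meta_rows, index=columns)
    return FeatureBlock(data=data, meta=meta)


def sri_from_bundle_episodes(sleep_episodes: pd.DataFrame, days: int,
                             start: pd.Timestamp, seed: int = 0) -> pd.Series:
    """SRI per participant from a ground-truth episode table."""
    out = {}
    for pid, g in sleep_episodes.groupby("participant_id", sort=True):
        episodes = [
            SleepEpisode(bedtime=r["bedtime"], waketime=r["waketime"],
                         efficiency=float(r["efficiency"]))
            for _, r in g.iterrows()
        ]
        v = vector_from_episodes(episodes, span_minutes=days * 1440, start=start,
                                 seed=seed, participant_id=pid)
        try:
            out[pid] = sleep_regularity_index(v)
        except UndefinedResultError:
            out[pid] = np.nan
    return pd.Series(out, name="sleep_regularity_index")
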