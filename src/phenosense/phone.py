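"""Phone-event and mobility features.

Call, SMS and screen logs are summarised per day within three daily
windows (full day 00-24, late night 00-03, evening 18-24) into 25 per-day
quantities, then aggregated across days by mean/median/SD (225 columns).
Mobility adds four per-day quantities — total distance, 5-minute-binned
distance, radius, and the day's mean log-likelihood under a per-participant
Gaussian-mixture routine model — aggregated the same way (12 columns), for
a 237-column block.

SMS messages carry no duration of their own; bursts of messages with the
same contact separated by less than a configurable gap are grouped into
sessions whose span serves as the duration.  Screen bouts run from an
"on" event to the next "off" event; a trailing unpaired "on" is closed at
midnight.  Distances are Euclidean on planar meters; a haversine mode
exists for real latitude/longitude input.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.mixture import GaussianMixture

from .containers import FeatureBlock
from .windows import PHONE_WINDOWS, Window

logger = logging.getLogger(__name__)

SMS_SESSION_GAP_S = 300.0
AGGREGATES = ("mean", "median", "sd")

#: per-day features per event type (9 + 8 + 8 = 25 per window)
CALL_FEATURES = (
    "call_duration_mean", "call_duration_median", "call_duration_sd",
    "call_time_mean", "call_time_median", "call_time_sd",
    "call_total_duration", "call_count", "call_unique_contacts",
)
SMS_FEATURES = (
    "sms_duration_mean", "sms_duration_median", "sms_duration_sd",
    "sms_time_mean", "sms_time_median", "sms_time_sd",
    "sms_count", "sms_unique_contacts",
)
SCREEN_FEATURES = (
    "screen_bout_duration_mean", "screen_bout_duration_median", "screen_bout_duration_sd",
    "screen_bout_time_mean", "screen_bout_time_median", "screen_bout_time_sd",
    "screen_total_on_duration", "screen_cycle_count",
)
EVENT_FEATURES = CALL_FEATURES + SMS_FEATURES + SCREEN_FEATURES

MOBILITY_FEATURES = ("total_distance_m", "five_min_distance_m", "radius_m", "gmm_loglik")


@dataclass
class MobilityModel:
    """Per-participant Gaussian-mixture model of routine locations."""

    participant_id: str
    model: GaussianMixture
    k: int
    bic: float

    def __post_init__(self):
        w = self.model.weights_
        if abs(w.sum() - 1.0) > 1e-9:
            raise ValueError("mixture weights must sum to 1")


# ---------------------------------------------------------------------------
# event preprocessing


def sms_sessions(sms: pd.DataFrame, gap_s: float = SMS_SESSION_GAP_S) -> pd.DataFrame:
    """Group messages into sessions (same contact, gaps < ``gap_s``).

    Returns one row per session with ``ts`` (first message) and
    ``duration_s`` (span from first to last message).
    """
    if sms.empty:
        return pd.DataFrame(columns=["participant_id", "ts", "duration_s", "contact_hash"])
    df = sms.sort_values(["participant_id", "contact_hash", "ts"]).copy()
    gap = df.groupby(["participant_id", "contact_hash"])["ts"].diff().dt.total_seconds()
    df["session"] = ((gap.isna()) | (gap >= gap_s)).cumsum()
    out = df.groupby("session").agg(
        participant_id=("participant_id", "first"),
        contact_hash=("contact_hash", "first"),
        ts=("ts", "min"),
        last=("ts", "max"),
    )
    out["duration_s"] = (out["last"] - out["ts"]).dt.total_seconds()
    return out.drop(columns="last").reset_index(drop=True).sort_values(["participant_id", "ts"])


def screen_bouts(screen: pd.DataFrame) -> pd.DataFrame:
    """Pair screen on/off events into bouts (ts = on time, duration_s).

    A trailing "on" without a matching "off" is closed at the next local
    midnight; "off" events without a preceding "on" are dropped.
    """
    rows = []
    for pid, g in screen.sort_values("ts").groupby("participant_id", sort=True):
        on_ts = None
        for _, r in g.iterrows():
            if r["state"] == "on":
                if on_ts is None:
                    on_ts = r["ts"]
            elif on_ts is not None:
                rows.append({"participant_id": pid, "ts": on_ts,
                             "duration_s": (r["ts"] - on_ts).total_seconds()})
                on_ts = None
        if on_ts is not None:
            end = (on_ts + pd.Timedelta(days=1)).normalize()
            rows.append({"participant_id": pid, "ts": on_ts,
                         "duration_s": (end - on_ts).total_seconds()})
    return pd.DataFrame(rows, columns=["participant_id", "ts", "duration_s"])


# ---------------------------------------------------------------------------
# per-day event features


def _window_filter(df: pd.DataFrame, window: Window) -> pd.DataFrame:
    s, e = window.bounds_seconds()
    sec = (df["ts"] - df["ts"].dt.normalize()).dt.total_seconds()
    return df[(sec >= s) & (sec < e)]


def _minutes_since_window_start(ts: pd.Series, window: Window) -> pd.Series:
    s, _ = window.bounds_seconds()
    sec = (ts - ts.dt.normalize()).dt.total_seconds()
    return (sec - s) / 60.0


def _stats(vals: np.ndarray, prefix: str) -> dict:
    out = {}
    out[f"{prefix}_mean"] = float(np.mean(vals))
    out[f"{prefix}_median"] = float(np.median(vals))
    out[f"{prefix}_sd"] = float(np.std(vals, ddof=1)) if vals.size > 1 else 0.0
    return out


def daily_event_features(calls: pd.DataFrame, sms: pd.DataFrame, screen: pd.DataFrame,
                         window: Window, sms_gap_s: float = SMS_SESSION_GAP_S) -> pd.DataFrame:
    """The 25 per-day event features inside one window, for all participants.

    Days with no events of a type get NaN for that type's features (they
    are skipped by the across-day aggregation).
    """
    calls = calls.rename(columns={"start_ts": "ts"})
    sess = sms_sessions(sms, gap_s=sms_gap_s)
    bouts = screen_bouts(screen)

    frames = {}
    for name, df, durcol in [("call", calls, "duration_s"),
                             ("sms", sess, "duration_s"),
                             ("screen", bouts, "duration_s")]:
        if df.empty:
            frames[name] = {}
            continue
        sub = _window_filter(df, window).copy()
        sub["date"] = sub["ts"].dt.normalize()
        sub["tod_min"] = _minutes_since_window_start(sub["ts"], window)
        per = {}
        for (pid, date), g in sub.groupby(["participant_id", "date"]):
            durs = g[durcol].to_numpy(dtype=float)
            tods = g["tod_min"].to_numpy(dtype=float)
            if name == "call":
                row = _stats(durs, "call_duration") | _stats(tods, "call_time")
                row["call_total_duration"] = float(durs.sum())
                row["call_count"] = float(len(g))
                row["call_unique_contacts"] = float(g["contact_hash"].nunique())
            elif name == "sms":
                row = _stats(durs, "sms_duration") | _stats(tods, "sms_time")
                row["sms_count"] = float(len(g))
                row["sms_unique_contacts"] = float(g["contact_hash"].nunique())
            else:
                row = _stats(durs, "screen_bout_duration") | _stats(tods, "screen_bout_time")
                row["screen_total_on_duration"] = float(durs.sum())
                row["screen_cycle_count"] = float(len(g))
            per[(pid, date)] = row
        frames[name] = per

    keys = sorted(set().union(*[set(f) for f in frames.values()]) if frames else set())
    rows = []
    for key in keys:
        row = {"participant_id": key[0], "date": key[1]}
        for f in frames.values():
            row.update(f.get(key, {}))
        rows.append(row)
    df = pd.DataFrame(rows, columns=["participant_id", "date", *EVENT_FEATURES])
    return df


# ---------------------------------------------------------------------------
# mobility


def _dist(xy: np.ndarray, geodesic: bool = False) -> np.ndarray:
    """Consecutive displacement lengths; planar meters or haversine."""
    if xy.shape[0] < 2:
        return np.empty(0)
    if not geodesic:
        return np.hypot(*np.diff(xy, axis=0).T)
    lat, lon = np.radians(xy[:, 1]), np.radians(xy[:, 0])
    dlat, dlon = np.diff(lat), np.diff(lon)
    a = np.sin(dlat / 2) ** 2 + np.cos(lat[:-1]) * np.cos(lat[1:]) * np.sin(dlon / 2) ** 2
    return 2 * 6371000.0 * np.arcsin(np.sqrt(a))


def daily_mobility(trace: pd.DataFrame, model: MobilityModel | None = None,
                   geodesic: bool = False) -> pd.DataFrame:
    """Per-day total distance, 5-minute-binned distance, radius and routine log-likelihood.

    Total distance sums consecutive-fix displacements; the 5-minute
    distance is the mean displacement between centroids of consecutive
    occupied 5-minute bins; the radius is the maximum distance of any fix
    from the day's centroid.  Days with fewer than two fixes get NaN
    distances.  ``gmm_loglik`` is the mean per-fix log density of the
    day's fixes under the participant's routine model (NaN without one).
    """
    rows = []
    for (pid, date), g in trace.assign(date=trace["ts"].dt.normalize()).groupby(
            ["participant_id", "date"]):
        g = g.sort_values("ts")
        xy = g[["x_m", "y_m"]].to_numpy(dtype=float)
        row = {"participant_id": pid, "date": date}
        if xy.shape[0] >= 2:
            row["total_distance_m"] = float(_dist(xy, geodesic).sum())
            sec = (g["ts"] - date).dt.total_seconds().to_numpy()
            bins = (sec // 300).astype(int)
            cents = np.array([xy[bins == b].mean(axis=0) for b in np.unique(bins)])
            d5 = _dist(cents, geodesic)
            row["five_min_distance_m"] = float(d5.mean()) if d5.size else 0.0
            centroid = xy.mean(axis=0)
            if not geodesic:
                row["radius_m"] = float(np.hypot(*(xy - centroid).T).max())
            else:
                pts = np.vstack([centroid, xy])
                row["radius_m"] = float(max(_dist(np.vstack([centroid, p]), True)[0] for p in xy))
        else:
            row["total_distance_m"] = np.nan
            row["five_min_distance_m"] = np.nan
            row["radius_m"] = np.nan
        if model is not None and xy.shape[0] >= 1:
            row["gmm_loglik"] = float(model.model.score(xy))
        else:
            row["gmm_loglik"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows, columns=["participant_id", "date", *MOBILITY_FEATURES])


def fit_mobility_gmm(trace_xy: np.ndarray, participant_id: str = "",
                     max_k: int = 8, seed: int = 0) -> MobilityModel:
    """Fit the routine model on all of a participant's fixes.

    Full-covariance Gaussian mixtures with K in 1..max_k are fit (5
    restarts each, fixed seed) and the Bayesian information criterion
    selects K; fitting a given K requires at least 10*K fixes, so sparse
    traces fall back toward K=1.
    """
    xy = np.asarray(trace_xy, dtype=float)
    if xy.ndim != 2 or xy.shape[1] != 2 or xy.shape[0] < 2:
        raise ValueError("need an (n, 2) array with n >= 2 fixes")
    best = None
    k_cap = max(min(max_k, xy.shape[0] // 10), 1)
    for k in range(1, k_cap + 1):
        gm = GaussianMixture(n_components=k, covariance_type="full", n_init=5,
                             random_state=seed, reg_covar=1e-6)
        gm.fit(xy)
        bic = gm.bic(xy)
        if best is None or bic < best[1]:
            best = (gm, bic, k)
    gm, bic, k = best
    return MobilityModel(participant_id=participant_id, model=gm, k=k, bic=float(bic))


def daily_loglik(model: MobilityModel, day_xy: np.ndarray) -> float:
    """Mean per-fix log density of one day's fixes under the routine model."""
    xy = np.asarray(day_xy, dtype=float)
    if xy.ndim != 2 or xy.shape[1] != 2 or xy.shape[0] == 0:
        raise ValueError("need an (n, 2) array with n >= 1 fixes")
    return float(model.model.score(xy))


# ---------------------------------------------------------------------------
# the 237-column block


def phone_feature_matrix(calls: pd.DataFrame, sms: pd.DataFrame, screen: pd.DataFrame,
                         locations: pd.DataFrame, sms_gap_s: float = SMS_SESSION_GAP_S,
                         gmm_max_k: int = 8, seed: int = 0, min_days: int = 2,
                         geodesic: bool = False) -> FeatureBlock:
    """The full 237-column phone feature block.

    25 event features x 3 windows x 3 across-day aggregates, plus 4
    mobility features x 3 aggregates.  Participants appearing in any log
    are included; per-day missing values are skipped by the aggregation.
    """
    pids = sorted(
        set(calls.get("participant_id", pd.Series(dtype=str)))
        | set(sms.get("participant_id", pd.Series(dtype=str)))
        | set(screen.get("participant_id", pd.Series(dtype=str)))
        | set(locations.get("participant_id", pd.Series(dtype=str)))
    )

    agg_frames = []
    for window in PHONE_WINDOWS:
        daily = daily_event_features(calls, sms, screen, window, sms_gap_s=sms_gap_s)
        agg = _aggregate_daily(daily, EVENT_FEATURES, f"__{window.label}", pids, min_days)
        agg_frames.append(agg)

    models = {}
    for pid in pids:
        xy = locations.loc[locations["participant_id"] == pid, ["x_m", "y_m"]].to_numpy(dtype=float)
        if xy.shape[0] >= 2:
            try:
                models[pid] = fit_mobility_gmm(xy, pid, max_k=gmm_max_k, seed=seed)
            except ValueError:
                pass
    mob_daily = []
    for pid, g in locations.groupby("participant_id", sort=True):
        mob_daily.append(daily_mobility(g, model=models.get(pid), geodesic=geodesic))
    mob = pd.concat(mob_daily, ignore_index=True) if mob_daily else pd.DataFrame(
        columns=["participant_id", "date", *MOBILITY_FEATURES])
    agg_frames.append(_aggregate_daily(mob, MOBILITY_FEATURES, "", pids, min_days))

    data = pd.concat(agg_frames, axis=1)
    data.index.name = "participant_id"

    meta_rows, columns = [], []
    for window in PHONE_WINDOWS:
        for feat in EVENT_FEATURES:
            for agg in AGGREGATES:
                columns.append(f"{feat}__{window.label}__{agg}")
                meta_rows.append({"block": "phone", "signal": feat.split("_")[0],
                                  "statistic": feat, "window": window.label, "aggregate": agg})
    for feat in MOBILITY_FEATURES:
        for agg in AGGREGATES:
            columns.append(f"{feat}__{agg}")
            meta_rows.append({"block": "phone", "signal": "mobility", "statistic": feat,
                              "window": "full_day", "aggregate": agg})
    data = data[columns]
    meta = pd.DataFrame(meta_rows, index=columns)
    return FeatureBlock(data=data, meta=meta)


def _aggregate_daily(daily: pd.DataFrame, features: tuple, suffix: str,
                     pids: list, min_days: int) -> pd.DataFrame:
    rows = []
    grouped = dict(list(daily.groupby("participant_id"))) if not daily.empty else {}
    for pid in pids:
        g = grouped.get(pid)
        row = {}
        for feat in features:
            vals = g[feat].to_numpy(dtype=float) if g is not None else np.empty(0)
            vals = vals[~np.isnan(vals)]
            if vals.size >= min_days:
                row[f"{feat}{suffix}__mean"] = float(np.mean(vals))
                row[f"{feat}{suffix}__median"] = float(np.median(vals))
                row[f"{feat}{suffix}__sd"] = float(np.std(vals, ddof=1))
            else:
                row[f"{feat}{suffix}__mean"] = np.nan
                row[f"{feat}{suffix}__median"] = np.nan
                row[f"{feat}{suffix}__sd"] = np.nan
        rows.append(row)
    columns = [f"{feat}{suffix}__{agg}" for feat in features for agg in AGGREGATES]
    return pd.DataFrame(rows, index=pids, columns=columns)
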