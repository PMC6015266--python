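"""Wearable-signal preprocessing and the sensor feature block.

Skin conductance (SC) is low-pass filtered (0.4 Hz cutoff, 32nd-order FIR,
zero-phase), range-masked to the physiologically trustworthy 0.01-30 uS
band, and scanned for electrodermal peaks wherever the first derivative of
the filtered, non-normalized signal exceeds 0.02 uS/s.  Features are
computed per 30-second epoch, summarised per participant-day within four
daily windows (late night 00-03, sleep, day 09-18, night 18-24), and then
aggregated across days by mean / median / SD, yielding 17 base features x
4 windows x 3 aggregates = 204 columns.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps

from .containers import FeatureBlock, SensorStream
from .windows import SENSOR_WINDOWS, Window

logger = logging.getLogger(__name__)

SC_RANGE_US = (0.01, 30.0)
ST_RANGE_C = (20.0, 42.0)
EPOCH_SECONDS = 30.0

#: the 17 per-day-per-window base features, in column order
BASE_FEATURES = (
    "sc_auc",
    "sc_amp_max",
    "sc_amp_mean",
    "sc_amp_median",
    "sc_amp_sd",
    "sc_peaks_mean",
    "sc_peaks_median",
    "sc_peaks_sd",
    "sc_norm_mean",
    "sc_norm_median",
    "sc_norm_sd",
    "acc_zero_crossings",
    "st_max",
    "st_min",
    "st_mean",
    "st_median",
    "st_sd",
)

AGGREGATES = ("mean", "median", "sd")


def fir_lowpass(x: np.ndarray, sample_rate: float, cutoff: float = 0.4,
                order: int = 32) -> np.ndarray:
    """Zero-phase FIR low-pass filter (default 0.4 Hz cutoff, order 32).

    The filter is applied forward and backward (zero phase compensation),
    so the output has no group delay and unit DC gain.
    """
    if sample_rate <= 2.0 * cutoff:
        raise ValueError(
            f"sample_rate ({sample_rate} Hz) must exceed twice the cutoff ({cutoff} Hz)"
        )
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        return x.copy()
    taps = sps.firwin(order + 1, cutoff, fs=sample_rate)
    padlen = min(3 * (order + 1), x.size - 1)
    if padlen < 1:
        return x.copy()
    return sps.filtfilt(taps, [1.0], x, padlen=padlen)


def range_mask(stream: SensorStream) -> tuple[np.ndarray, np.ndarray]:
    """In-range masks for SC (0.01-30 uS) and ST (20-42 C), bounds inclusive.

    Each mask is combined with the stream's ``valid_mask`` by logical AND.
    """
    sc_ok = (stream.sc >= SC_RANGE_US[0]) & (stream.sc <= SC_RANGE_US[1])
    st_ok = (stream.st >= ST_RANGE_C[0]) & (stream.st <= ST_RANGE_C[1])
    return sc_ok & stream.valid_mask, st_ok & stream.valid_mask


def detect_sc_peaks(filtered_sc: np.ndarray, sample_rate: float,
                    slope_threshold: float = 0.02) -> np.ndarray:
    """Electrodermal peak onsets from a slope threshold on the derivative.

    One event is emitted per maximal contiguous run of first-difference
    slope strictly above ``slope_threshold`` (uS/s); the event time is the
    run onset, in seconds from the start of the series.  The input must
    already be low-pass filtered and non-normalized.
    """
    x = np.asarray(filtered_sc, dtype=float)
    if x.size < 2:
        return np.empty(0)
    slope = np.diff(x) * sample_rate
    above = slope > slope_threshold
    onset = above & ~np.concatenate(([False], above[:-1]))
    return np.flatnonzero(onset) / sample_rate


@dataclass
class EpochSeries:
    """Per-30-second-epoch summaries of one stream segment.

    ``start_seconds`` are epoch start times in absolute seconds (aligned to
    local midnight when the caller supplies a midnight-referenced offset).
    Epochs with fewer than ``min_valid_fraction`` valid samples are flagged
    invalid and their values set to NaN.
    """

    start_seconds: np.ndarray
    auc: np.ndarray
    peak_count: np.ndarray
    zero_crossings: np.ndarray
    valid: np.ndarray
    acc_valid: np.ndarray
    epoch_length: float = EPOCH_SECONDS


def epoch_features(filtered_sc: np.ndarray, peak_times: np.ndarray, acc: np.ndarray,
                   sample_rate: float, start_second: float = 0.0,
                   sc_mask: np.ndarray | None = None,
                   acc_mask: np.ndarray | None = None,
                   min_valid_fraction: float = 0.5) -> EpochSeries:
    """Per-epoch SC area under the curve, peak counts, and ACC zero crossings.

    Epochs are aligned to absolute second 0 (local midnight when
    ``start_second`` is a midnight-referenced offset).  The AUC is the
    trapezoidal integral of SC across the epoch in uS*s; each inter-sample
    trapezoid is assigned to the epoch containing its left sample.  Zero
    crossings are sign changes of per-epoch mean-removed acceleration,
    summed over the three axes.
    """
    sc = np.asarray(filtered_sc, dtype=float)
    acc = np.asarray(acc, dtype=float)
    n = sc.shape[0]
    if sc_mask is None:
        sc_mask = np.ones(n, dtype=bool)
    if acc_mask is None:
        acc_mask = np.ones(n, dtype=bool)

    abs_sec = start_second + np.arange(n) / sample_rate
    eid_abs = (abs_sec // EPOCH_SECONDS).astype(np.int64)
    e0 = eid_abs[0]
    eid = eid_abs - e0
    n_ep = int(eid[-1]) + 1 if n else 0
    expected = EPOCH_SECONDS * sample_rate

    counts_valid = np.bincount(eid[sc_mask], minlength=n_ep) if n else np.zeros(0)
    valid = counts_valid / expected >= min_valid_fraction
    counts_acc = np.bincount(eid[acc_mask], minlength=n_ep) if n else np.zeros(0)
    acc_valid = counts_acc / expected >= min_valid_fraction

    # trapezoidal AUC, skipping segments touching an invalid sample
    seg = (sc[:-1] + sc[1:]) / (2.0 * sample_rate)
    seg_ok = sc_mask[:-1] & sc_mask[1:]
    auc = np.bincount(eid[:-1][seg_ok], weights=seg[seg_ok], minlength=n_ep)
    auc = np.where(valid, auc, np.nan)

    # peak counts by onset epoch
    peak_idx = np.round(np.asarray(peak_times, dtype=float) * sample_rate).astype(np.int64)
    peak_idx = peak_idx[(peak_idx >= 0) & (peak_idx < n)]
    peak_idx = peak_idx[sc_mask[peak_idx]]
    pc = np.bincount(eid[peak_idx], minlength=n_ep).astype(float)
    pc = np.where(valid, pc, np.nan)

    # ACC zero crossings on mean-removed axes
    zc = np.zeros(n_ep)
    cnt = np.maximum(counts_acc, 1)
    pair_ok = (eid[:-1] == eid[1:]) & acc_mask[:-1] & acc_mask[1:]
    for ax in range(3):
        x = acc[:, ax]
        sums = np.bincount(eid[acc_mask], weights=x[acc_mask], minlength=n_ep)
        centered = x - (sums / cnt)[eid]
        cross = pair_ok & (centered[:-1] * centered[1:] < 0)
        zc += np.bincount(eid[:-1][cross], minlength=n_ep)
    zc = np.where(acc_valid, zc, np.nan)

    starts = (e0 + np.arange(n_ep)) * EPOCH_SECONDS
    return EpochSeries(start_seconds=starts, auc=auc, peak_count=pc,
                       zero_crossings=zc, valid=valid, acc_valid=acc_valid)


def normalize_sc_daily(sc: np.ndarray, day_index: np.ndarray,
                       mask: np.ndarray | None = None) -> np.ndarray:
    """Min-max normalize SC within each day of each individual.

    Per day, ``x -> (x - day_min) / (day_max - day_min)`` using the valid
    samples of that day; a constant (or empty) day maps to 0.  Output is
    clipped to [0, 1].
    """
    sc = np.asarray(sc, dtype=float)
    day_index = np.asarray(day_index)
    if mask is None:
        mask = np.ones(sc.shape[0], dtype=bool)
    out = np.zeros_like(sc)
    for d in np.unique(day_index):
        sel = day_index == d
        vals = sc[sel & mask]
        if vals.size == 0:
            continue
        lo, hi = vals.min(), vals.max()
        if hi > lo:
            out[sel] = np.clip((sc[sel] - lo) / (hi - lo), 0.0, 1.0)
    return out


def _nanstats(vals: np.ndarray) -> dict:
    if vals.size == 0:
        return {}
    return {
        "max": float(np.max(vals)),
        "min": float(np.min(vals)),
        "mean": float(np.mean(vals)),
        "median": float(np.median(vals)),
        "sd": float(np.std(vals, ddof=1)) if vals.size > 1 else 0.0,
    }


def _episode_day_ranges(episodes: list[tuple[pd.Timestamp, pd.Timestamp]],
                        midnight: pd.Timestamp) -> dict[int, list[tuple[float, float]]]:
    """Map day index -> list of (start, end) absolute seconds, keyed by bedtime day."""
    out: dict[int, list[tuple[float, float]]] = {}
    for start, end in episodes:
        s = (pd.Timestamp(start) - midnight).total_seconds()
        e = (pd.Timestamp(end) - midnight).total_seconds()
        if e <= s:
            continue
        out.setdefault(int(s // 86400), []).append((s, e))
    return out


def participant_sensor_features(stream: SensorStream,
                                sleep_intervals: list[tuple] | None = None,
                                min_day_fraction: float = 0.5) -> pd.DataFrame:
    """Per-day, per-window values of the 17 base sensor features.

    Returns a frame indexed by ``(day, window_label)``.  A day-window cell
    is populated only when at least ``min_day_fraction`` of its expected
    samples are valid (per signal); otherwise its features are NaN.
    """
    fs = stream.sample_rate
    n = stream.n_samples
    midnight = stream.t0.normalize()
    off = (stream.t0 - midnight).total_seconds()

    m_sc, m_st = range_mask(stream)
    m_acc = stream.valid_mask

    filt = fir_lowpass(stream.sc, fs)
    day_of_sample = ((off + np.arange(n) / fs) // 86400).astype(np.int64)
    norm = normalize_sc_daily(filt, day_of_sample, mask=m_sc)
    peak_times = detect_sc_peaks(filt, fs)

    ep = epoch_features(filt, peak_times, stream.acc, fs, start_second=off,
                        sc_mask=m_sc, acc_mask=m_acc,
                        min_valid_fraction=min_day_fraction)

    # prefix sums for O(1) valid-sample counts on index ranges
    csum_sc = np.concatenate(([0], np.cumsum(m_sc)))
    csum_st = np.concatenate(([0], np.cumsum(m_st)))
    csum_acc = np.concatenate(([0], np.cumsum(m_acc)))

    def idx_range(lo_sec: float, hi_sec: float) -> tuple[int, int]:
        lo = int(np.ceil((lo_sec - off) * fs - 1e-9))
        hi = int(np.ceil((hi_sec - off) * fs - 1e-9))
        return max(lo, 0), min(max(hi, 0), n)

    sleep_by_day = _episode_day_ranges(sleep_intervals or [], midnight)
    n_days = int(np.ceil((off + n / fs) / 86400))
    rows = []
    for d in range(n_days):
        for win in SENSOR_WINDOWS:
            if win is Window.SLEEP:
                ranges = sleep_by_day.get(d, [])
            else:
                s, e = win.bounds_seconds()
                ranges = [(d * 86400 + s, d * 86400 + e)]
            feats = _window_features(
                ranges, idx_range, fs, min_day_fraction,
                filt, norm, stream.st, m_sc, m_st,
                csum_sc, csum_st, csum_acc, ep,
            )
            feats["day"] = d
            feats["window"] = win.label
            rows.append(feats)
    df = pd.DataFrame(rows).set_index(["day", "window"])
    return df[list(BASE_FEATURES)]


def _window_features(ranges, idx_range, fs, min_frac, filt, norm, st,
                     m_sc, m_st, csum_sc, csum_st, csum_acc, ep) -> dict:
    out = {f: np.nan for f in BASE_FEATURES}
    if not ranges:
        return out
    expected = sum((hi - lo) for lo, hi in ranges) * fs
    if expected <= 0:
        return out
    bounds = [idx_range(lo, hi) for lo, hi in ranges]
    n_sc = sum(csum_sc[b] - csum_sc[a] for a, b in bounds)
    n_st = sum(csum_st[b] - csum_st[a] for a, b in bounds)
    n_acc = sum(csum_acc[b] - csum_acc[a] for a, b in bounds)

    # epoch selection: an epoch belongs to the window iff its start is inside
    ep_sel = np.zeros(ep.start_seconds.shape[0], dtype=bool)
    for lo, hi in ranges:
        ep_sel |= (ep.start_seconds >= lo) & (ep.start_seconds < hi)

    if n_sc >= min_frac * expected:
        sc_vals = np.concatenate([filt[a:b][m_sc[a:b]] for a, b in bounds]) if bounds else np.empty(0)
        s = _nanstats(sc_vals)
        if s:
            out["sc_amp_max"] = s["max"]
            out["sc_amp_mean"] = s["mean"]
            out["sc_amp_median"] = s["median"]
            out["sc_amp_sd"] = s["sd"]
        nv = np.concatenate([norm[a:b][m_sc[a:b]] for a, b in bounds]) if bounds else np.empty(0)
        s = _nanstats(nv)
        if s:
            out["sc_norm_mean"] = s["mean"]
            out["sc_norm_median"] = s["median"]
            out["sc_norm_sd"] = s["sd"]
        good = ep_sel & ep.valid
        if good.any():
            out["sc_auc"] = float(np.nanmean(ep.auc[good]))
            pc = ep.peak_count[good]
            out["sc_peaks_mean"] = float(np.nanmean(pc))
            out["sc_peaks_median"] = float(np.nanmedian(pc))
            out["sc_peaks_sd"] = float(np.nanstd(pc, ddof=1)) if pc.size > 1 else 0.0

    if n_st >= min_frac * expected:
        st_vals = np.concatenate([st[a:b][m_st[a:b]] for a, b in bounds]) if bounds else np.empty(0)
        s = _nanstats(st_vals)
        if s:
            out["st_max"] = s["max"]
            out["st_min"] = s["min"]
            out["st_mean"] = s["mean"]
            out["st_median"] = s["median"]
            out["st_sd"] = s["sd"]

    if n_acc >= min_frac * expected:
        good = ep_sel & ep.acc_valid
        if good.any():
            out["acc_zero_crossings"] = float(np.nansum(ep.zero_crossings[good]))
    return out


def _aggregate_days(per_day: pd.DataFrame, min_days: int = 2) -> dict:
    """Across-day mean/median/SD of each (feature, window) cell."""
    out = {}
    for win in SENSOR_WINDOWS:
        try:
            sub = per_day.xs(win.label, level="window")
        except KeyError:
            sub = pd.DataFrame(columns=per_day.columns)
        for feat in BASE_FEATURES:
            vals = sub[feat].to_numpy(dtype=float) if feat in sub else np.empty(0)
            vals = vals[~np.isnan(vals)]
            prefix = f"{feat}__{win.label}"
            if vals.size >= min_days:
                out[f"{prefix}__mean"] = float(np.mean(vals))
                out[f"{prefix}__median"] = float(np.median(vals))
                out[f"{prefix}__sd"] = float(np.std(vals, ddof=1))
            else:
                out[f"{prefix}__mean"] = np.nan
                out[f"{prefix}__median"] = np.nan
                out[f"{prefix}__sd"] = np.nan
    return out


def _intervals_by_pid(sleep_episodes) -> dict[str, list[tuple]]:
    if sleep_episodes is None:
        return {}
    if isinstance(sleep_episodes, dict):
        return sleep_episodes
    out: dict[str, list[tuple]] = {}
    for _, r in sleep_episodes.iterrows():
        out.setdefault(r["participant_id"], []).append((r["bedtime"], r["waketime"]))
    return out


def sensor_feature_matrix(streams, sleep_episodes=None,
                          min_day_fraction: float = 0.5) -> FeatureBlock:
    """The 204-column wearable-sensor feature block.

    Parameters
    ----------
    streams : iterable of SensorStream
    sleep_episodes : DataFrame (participant_id, bedtime, waketime) or dict
        Per-participant sleep intervals defining the SLEEP window.
    min_day_fraction : float
        Minimum valid-sample fraction for a day-window to contribute.

    Participants with fewer than two usable days are excluded with a
    logged warning.  Across-day aggregates skip missing days.
    """
    intervals = _intervals_by_pid(sleep_episodes)
    rows, index = [], []
    for stream in streams:
        per_day = participant_sensor_features(
            stream, intervals.get(stream.participant_id, []), min_day_fraction
        )
        usable = (~per_day.isna()).any(axis=1).groupby(level="day").any().sum()
        if usable < 2:
            logger.warning(
                "participant %s excluded from sensor features: only %d usable day(s)",
                stream.participant_id, usable,
            )
            continue
        rows.append(_aggregate_days(per_day))
        index.append(stream.participant_id)

    columns = [
        f"{feat}__{win.label}__{agg}"
        for win in SENSOR_WINDOWS
        for feat in BASE_FEATURES
        for agg in AGGREGATES
    ]
    data = pd.DataFrame(rows, index=pd.Index(index, name="participant_id"), columns=columns)
    meta = pd.DataFrame(
        [
            {
                "block": "sensor",
                "signal": feat.split("_")[0],
                "statistic": feat,
                "window": win.label,
                "aggregate": agg,
            }
            for win in SENSOR_WINDOWS
            for feat in BASE_FEATURES
            for agg in AGGREGATES
        ],
        index=columns,
    )
    return FeatureBlock(data=data, meta=meta)


def acc_fullday_summary(streams, min_day_fraction: float = 0.5) -> FeatureBlock:
    """Single-column movement summary: across-day mean of full-day ACC zero crossings.

    Used by the modifiable-behaviors modality, where movement contributes
    one column rather than the per-window sensor breakdown.
    """
    rows, index = [], []
    for stream in streams:
        fs = stream.sample_rate
        off = (stream.t0 - stream.t0.normalize()).total_seconds()
        filt = fir_lowpass(stream.sc, fs)
        ep = epoch_features(filt, np.empty(0), stream.acc, fs, start_second=off,
                            acc_mask=stream.valid_mask, min_valid_fraction=min_day_fraction)
        day = (ep.start_seconds // 86400).astype(int)
        per_day = pd.Series(ep.zero_crossings).groupby(day).sum(min_count=1)
        vals = per_day.to_numpy(dtype=float)
        vals = vals[~np.isnan(vals)]
        if vals.size < 2:
            logger.warning("participant %s excluded from ACC summary", stream.participant_id)
            continue
        rows.append({"acc_zero_crossings__full_day__mean": float(np.mean(vals))})
        index.append(stream.participant_id)
    data = pd.DataFrame(rows, index=pd.Index(index, name="participant_id"),
                        columns=["acc_zero_crossings__full_day__mean"])
    meta = pd.DataFrame(
        [{"block": "sensor_aux", "signal": "acc", "statistic": "acc_zero_crossings",
          "window": "full_day", "aggregate": "mean"}],
        index=data.columns,
    )
    return FeatureBlock(data=data, meta=meta)
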