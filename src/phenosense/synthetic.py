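"""Synthetic multimodal cohort generator.

Generates full study-shaped datasets — wearable streams (skin conductance,
skin temperature, 3-axis acceleration), phone event logs (calls, SMS,
screen), location traces, twice-daily diaries, and pre/post questionnaire
scores — with the statistical structure the downstream analysis assumes:

* a latent per-participant stress trait ``z ~ N(0, 1)`` drives negatively
  correlated perceived-stress (PSS) and mental-health (MCS) outcomes;
* the same trait shifts behavioural/physiological feature families
  (skin-conductance peak rate, nap frequency, mobility radius, screen
  time, bedtime jitter) by configurable standardized effect sizes;
* everything is reproducible from a single integer seed.

The generator is deliberately simple where the analysis does not look:
locations live on a plane in meters (no geodesy), circadian physiology is
a two-state (sleep/wake) caricature, and diaries agree with the
ground-truth sleep schedule unless corruption is explicitly requested.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import fftconvolve

from .containers import SensorStream

SCHEMA_VERSION = "1"

#: feature families that the latent trait can shift
EFFECT_FAMILIES = (
    "sc_peak_rate",
    "nap_rate",
    "mobility_radius",
    "screen_time",
    "bedtime_jitter",
)

#: latent-trait slope per unit effect size on the log scale of each family
_EFFECT_SLOPE = 0.35
#: trait-independent between-participant heterogeneity (log scale)
_EFFECT_RESID_SD = 0.05


class ParameterError(ValueError):
    """Invalid generator configuration; the message names the field."""


class FormatError(ValueError):
    """On-disk dataset does not match the expected schema."""


def _default_effects() -> dict[str, float]:
    # Moderate, literature-plausible defaults: higher trait stress means
    # more SC peaks, more naps, more screen time, more irregular bedtimes,
    # and a smaller mobility radius.
    return {
        "sc_peak_rate": 0.8,
        "nap_rate": 0.6,
        "mobility_radius": -0.4,
        "screen_time": 0.5,
        "bedtime_jitter": 0.5,
    }


@dataclass
class CohortConfig:
    """Configuration of one synthetic cohort draw.

    Parameters
    ----------
    n_participants : int
    n_cohorts : int
        Number of enrollment cohorts (semesters); used as cross-validation
        groups downstream.
    days_per_participant : int
        Length of each participant's recording, in civil days.
    sc_sample_rate : float
        Wearable sampling rate in Hz.
    latent_effect_sizes : dict
        Standardized effect (per 1 SD of the latent trait, on the family's
        log scale divided by :data:`_EFFECT_SLOPE`) for each feature family
        in :data:`EFFECT_FAMILIES`.
    outcome_noise_sd : float
        SD of the trait-independent noise in the standardized post-study
        PSS score; the PSS trait loading is ``sqrt(1 - sd**2)``.
    target_pss_mcs_corr : float
        Desired population Pearson correlation between post-study PSS and
        MCS, in ``[-1, 0]``.  Given the PSS loading ``b``, the MCS loading
        is chosen in closed form as ``d = |r| / b`` (with noise
        ``sqrt(1 - d**2)``), so that ``corr = -b * d = r``.
    seed : int
        Fully determines the generated bundle.
    """

    n_participants: int = 200
    n_cohorts: int = 5
    days_per_participant: int = 30
    sc_sample_rate: float = 8.0
    latent_effect_sizes: dict[str, float] = field(default_factory=_default_effects)
    outcome_noise_sd: float = 0.25
    target_pss_mcs_corr: float = -0.71
    seed: int = 0

    def validate(self) -> None:
        if self.n_participants < 1:
            raise ParameterError("n_participants must be >= 1")
        if self.n_cohorts < 2:
            raise ParameterError("n_cohorts must be >= 2")
        if self.days_per_participant < 2:
            raise ParameterError("days_per_participant must be >= 2")
        if self.sc_sample_rate <= 0:
            raise ParameterError("sc_sample_rate must be > 0")
        if not -1.0 <= self.target_pss_mcs_corr <= 0.0:
            raise ParameterError("target_pss_mcs_corr must lie in [-1, 0]")
        if not 0.0 < self.outcome_noise_sd < 1.0:
            raise ParameterError("outcome_noise_sd must lie in (0, 1)")
        unknown = set(self.latent_effect_sizes) - set(EFFECT_FAMILIES)
        if unknown:
            raise ParameterError(f"latent_effect_sizes has unknown families: {sorted(unknown)}")
        b = np.sqrt(1.0 - self.outcome_noise_sd**2)
        if abs(self.target_pss_mcs_corr) > b:
            raise ParameterError(
                "target_pss_mcs_corr is unreachable: |r| must not exceed the PSS "
                f"trait loading sqrt(1 - outcome_noise_sd**2) = {b:.3f}"
            )

    def effect(self, family: str) -> float:
        return float(self.latent_effect_sizes.get(family, 0.0))

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "CohortConfig":
        return cls(**d)


@dataclass
class ParticipantRecord:
    """Questionnaire-level description of one participant."""

    id: str
    cohort: str
    gender: str
    openness: float
    conscientiousness: float
    extraversion: float
    agreeableness: float
    neuroticism: float
    pss_pre: float
    pss_post: float
    mcs_pre: float
    mcs_post: float
    latent_trait: float  # generator-internal; hidden from the pipeline


@dataclass
class DatasetBundle:
    """Everything one cohort draw produces, in memory.

    Event tables are plain DataFrames with the documented CSV schemas;
    wearable streams are :class:`~phenosense.containers.SensorStream`.
    ``latent`` is generator-internal ground truth (never fed to the
    pipeline; kept for calibration tests).
    """

    config: CohortConfig
    participants: pd.DataFrame
    latent: pd.Series
    streams: dict[str, SensorStream]
    calls: pd.DataFrame
    sms: pd.DataFrame
    screen: pd.DataFrame
    locations: pd.DataFrame
    diary: pd.DataFrame
    sleep_episodes: pd.DataFrame

    def participant_records(self) -> list[ParticipantRecord]:
        out = []
        for _, r in self.participants.iterrows():
            out.append(
                ParticipantRecord(
                    id=r["participant_id"],
                    cohort=r["cohort"],
                    gender=r["gender"],
                    openness=r["openness"],
                    conscientiousness=r["conscientiousness"],
                    extraversion=r["extraversion"],
                    agreeableness=r["agreeableness"],
                    neuroticism=r["neuroticism"],
                    pss_pre=r["pss_pre"],
                    pss_post=r["pss_post"],
                    mcs_pre=r["mcs_pre"],
                    mcs_post=r["mcs_post"],
                    latent_trait=float(self.latent.loc[r["participant_id"]]),
                )
            )
        return out


STUDY_START = pd.Timestamp("2024-01-08")  # all cohorts share a nominal start date


def _effect_multiplier(effect: float, z: np.ndarray, eta: np.ndarray) -> np.ndarray:
    """Per-participant multiplicative shift of a feature family's base rate."""
    return np.exp(_EFFECT_SLOPE * effect * z + _EFFECT_RESID_SD * eta)


def _round_clip(x: np.ndarray, lo: float, hi: float, decimals: int | None = None) -> np.ndarray:
    if decimals is not None:
        x = np.round(x, decimals)
    return np.clip(x, lo, hi)


def generate_cohort(config: CohortConfig) -> DatasetBundle:
    """Draw one full synthetic cohort.

    Equal configs (including the seed) produce identical bundles.
    """
    config.validate()
    root = np.random.SeedSequence(config.seed)
    ss_meta, ss_streams, ss_phone, ss_diary = root.spawn(4)
    rng = np.random.default_rng(ss_meta)

    n = config.n_participants
    pids = [f"P{i:04d}" for i in range(n)]

    # --- cohorts: balanced random assignment -----------------------------
    cohort_labels = [f"C{j + 1}" for j in range(config.n_cohorts)]
    assignment = np.array([cohort_labels[i % config.n_cohorts] for i in range(n)])
    rng.shuffle(assignment)

    # --- latent trait and questionnaire outcomes -------------------------
    z = rng.standard_normal(n)
    sigma = config.outcome_noise_sd
    b_pss = np.sqrt(1.0 - sigma**2)
    r = abs(config.target_pss_mcs_corr)
    d_mcs = r / b_pss
    sigma_mcs = np.sqrt(1.0 - d_mcs**2)

    pss_post = _round_clip(17.1 + 6.5 * (b_pss * z + sigma * rng.standard_normal(n)), 0, 40, 0)
    pss_pre = _round_clip(15.0 + 6.5 * (0.6 * z + 0.8 * rng.standard_normal(n)), 0, 40, 0)
    mcs_post = _round_clip(40.4 + 9.5 * (-d_mcs * z + sigma_mcs * rng.standard_normal(n)), 5, 75, 1)
    mcs_pre = _round_clip(44.4 + 9.5 * (-0.6 * z + 0.8 * rng.standard_normal(n)), 5, 75, 1)

    gender = np.where(rng.random(n) < 0.64, "male", "female")
    big5 = {
        "openness": _round_clip(3.5 + 0.7 * rng.standard_normal(n), 1, 5, 2),
        "conscientiousness": _round_clip(3.5 + 0.7 * (-0.3 * z + 0.954 * rng.standard_normal(n)), 1, 5, 2),
        "extraversion": _round_clip(3.4 + 0.7 * rng.standard_normal(n), 1, 5, 2),
        "agreeableness": _round_clip(3.6 + 0.7 * rng.standard_normal(n), 1, 5, 2),
        "neuroticism": _round_clip(3.0 + 0.7 * (0.4 * z + 0.917 * rng.standard_normal(n)), 1, 5, 2),
    }

    participants = pd.DataFrame(
        {
            "participant_id": pids,
            "cohort": assignment,
            "gender": gender,
            **big5,
            "pss_pre": pss_pre,
            "pss_post": pss_post,
            "mcs_pre": mcs_pre,
            "mcs_post": mcs_post,
        }
    )
    latent = pd.Series(z, index=pd.Index(pids, name="participant_id"), name="latent_trait")

    # per-participant, per-family heterogeneity
    eta = {fam: rng.standard_normal(n) for fam in EFFECT_FAMILIES}
    mult = {fam: _effect_multiplier(config.effect(fam), z, eta[fam]) for fam in EFFECT_FAMILIES}

    # --- sleep schedules (shared by streams, diaries, sleep features) ----
    rng_d = np.random.default_rng(ss_diary)
    schedules = {}
    for i, pid in enumerate(pids):
        schedules[pid] = _draw_sleep_schedule(
            rng_d,
            days=config.days_per_participant,
            jitter_sd_min=30.0 * mult["bedtime_jitter"][i],
            nap_prob=float(np.clip(0.25 * mult["nap_rate"][i], 0.0, 0.9)),
        )

    # --- wearable streams -------------------------------------------------
    stream_seeds = ss_streams.spawn(n)
    streams = {}
    for i, pid in enumerate(pids):
        streams[pid] = _generate_stream(
            np.random.default_rng(stream_seeds[i]),
            pid,
            config,
            schedules[pid],
            sc_rate_mult=mult["sc_peak_rate"][i],
        )

    # --- phone logs and locations ----------------------------------------
    phone_seeds = ss_phone.spawn(n)
    calls_l, sms_l, screen_l, loc_l = [], [], [], []
    for i, pid in enumerate(pids):
        c, s, sc_ev, loc = _generate_phone(
            np.random.default_rng(phone_seeds[i]),
            pid,
            config,
            schedules[pid],
            screen_mult=mult["screen_time"][i],
            mobility_mult=mult["mobility_radius"][i],
        )
        calls_l.append(c)
        sms_l.append(s)
        screen_l.append(sc_ev)
        loc_l.append(loc)
    calls = pd.concat(calls_l, ignore_index=True)
    sms = pd.concat(sms_l, ignore_index=True)
    screen = pd.concat(screen_l, ignore_index=True)
    locations = pd.concat(loc_l, ignore_index=True)

    # --- diaries and ground-truth sleep episode table ---------------------
    diary_rows, episode_rows = [], []
    for pid in pids:
        d_rows, e_rows = _generate_diary(rng_d, pid, config, schedules[pid])
        diary_rows.extend(d_rows)
        episode_rows.extend(e_rows)
    diary = pd.DataFrame(diary_rows)
    sleep_episodes = pd.DataFrame(episode_rows)

    return DatasetBundle(
        config=config,
        participants=participants,
        latent=latent,
        streams=streams,
        calls=calls,
        sms=sms,
        screen=screen,
        locations=locations,
        diary=diary,
        sleep_episodes=sleep_episodes,
    )


# ---------------------------------------------------------------------------
# sleep schedule


def _draw_sleep_schedule(rng, days: int, jitter_sd_min: float, nap_prob: float) -> dict:
    """Bedtimes, durations, efficiencies, naps and all-nighters for one person.

    Times are minutes since the local midnight starting day 0.  The night-d
    episode starts near 00:30 of day d+1; episode windows are constrained so
    consecutive episodes can never overlap.
    """
    mean_bed = 1470.0 + rng.normal(0.0, 45.0)  # ~00:30 next day
    beds, wakes, effs, allnighters, naps = [], [], [], [], []
    for d in range(days):
        if rng.random() < 0.03:  # pulled an all-nighter
            allnighters.append(True)
            beds.append(np.nan)
            wakes.append(np.nan)
            effs.append(np.nan)
        else:
            allnighters.append(False)
            bed = d * 1440.0 + np.clip(mean_bed + rng.normal(0.0, jitter_sd_min), 1200.0, 1680.0)
            dur = np.clip(rng.normal(450.0, 40.0), 300.0, 600.0)
            beds.append(bed)
            wakes.append(bed + dur)
            effs.append(float(np.clip(rng.normal(0.93, 0.04), 0.70, 1.0)))
        if rng.random() < nap_prob:
            start = d * 1440.0 + rng.uniform(13 * 60, 18 * 60)
            naps.append((d, start, float(np.clip(rng.normal(45.0, 15.0), 10.0, 120.0))))
    return {
        "days": days,
        "bed_min": np.array(beds),
        "wake_min": np.array(wakes),
        "efficiency": np.array(effs),
        "all_nighter": np.array(allnighters, dtype=bool),
        "naps": naps,
    }


def _sleep_indicator_minutes(schedule: dict) -> np.ndarray:
    """Boolean asleep-indicator at 1-minute resolution over the full span."""
    n_min = schedule["days"] * 1440
    asleep = np.zeros(n_min, dtype=bool)
    for bed, wake in zip(schedule["bed_min"], schedule["wake_min"]):
        if np.isnan(bed):
            continue
        lo, hi = int(bed), min(int(wake), n_min)
        asleep[lo:hi] = True
    return asleep


# ---------------------------------------------------------------------------
# wearable streams


def _ou_process(rng, n: int, x0: float, mu: float, theta: float, sigma: float,
                lo: float, hi: float) -> np.ndarray:
    x = np.empty(n)
    x[0] = x0
    steps = rng.standard_normal(n - 1)
    for i in range(1, n):
        x[i] = np.clip(x[i - 1] + theta * (mu - x[i - 1]) + sigma * steps[i - 1], lo, hi)
    return x


def _scr_kernel(fs: float) -> np.ndarray:
    """Canonical rapid-rise / slow-decay skin-conductance response shape."""
    t = np.arange(0.0, 20.0, 1.0 / fs)
    k = (1.0 - np.exp(-t / 0.75)) * np.exp(-t / 4.0)
    peak = k.max()
    if peak <= 0.0:  # sub-minute sampling: kernel degenerates to a unit impulse
        return np.ones(max(t.size, 1))
    return k / peak


def _generate_stream(rng, pid: str, config: CohortConfig, schedule: dict,
                     sc_rate_mult: float) -> SensorStream:
    fs = config.sc_sample_rate
    days = config.days_per_participant
    n = int(round(days * 86400 * fs))
    n_min = days * 1440

    asleep_min = _sleep_indicator_minutes(schedule)
    minute_of_sample = np.minimum((np.arange(n) / (60.0 * fs)).astype(np.int64), n_min - 1)
    asleep = asleep_min[minute_of_sample]

    # tonic level: bounded mean-reverting walk simulated on the minute grid
    x0 = rng.uniform(1.5, 3.5)
    tonic_min = _ou_process(rng, n_min, x0=x0, mu=x0, theta=0.05, sigma=0.12, lo=0.5, hi=10.0)
    tonic = np.interp(np.arange(n) / (60.0 * fs), np.arange(n_min), tonic_min)

    # phasic peaks: Poisson events at trait-dependent rates, convolved with
    # an SCR kernel; awake rate ~4/min, asleep ~1/min at zero effect
    rate_per_sample = np.where(asleep, 1.0, 4.0) * sc_rate_mult / (60.0 * fs)
    events = rng.random(n) < rate_per_sample
    amps = np.zeros(n)
    n_ev = int(events.sum())
    if n_ev:
        amps[events] = rng.lognormal(mean=np.log(0.25), sigma=0.4, size=n_ev)
    phasic = fftconvolve(amps, _scr_kernel(fs))[:n]

    sc = np.maximum(tonic + phasic + rng.normal(0.0, 0.01, n), 0.02)

    # skin temperature: warmer during sleep, slow drift
    sleep_frac = np.convolve(asleep_min.astype(float), np.ones(31) / 31.0, mode="same")
    st_min = 31.0 + 3.0 * sleep_frac + _ou_process(rng, n_min, 0.0, 0.0, 0.02, 0.05, -1.5, 1.5)
    st = np.interp(np.arange(n) / (60.0 * fs), np.arange(n_min), st_min)
    st = np.clip(st + rng.normal(0.0, 0.05, n), 25.0, 41.5)

    # acceleration: high-variance noise awake, near-still asleep
    sd = np.where(asleep, 0.03, 0.25)
    acc = rng.normal(0.0, 1.0, (n, 3)) * sd[:, None]
    acc[:, 2] += 1.0  # gravity offset

    return SensorStream(
        participant_id=pid,
        sample_rate=fs,
        t0=STUDY_START,
        sc=sc,
        st=st,
        acc=acc,
    )


# ---------------------------------------------------------------------------
# phone


def _generate_phone(rng, pid: str, config: CohortConfig, schedule: dict,
                    screen_mult: float, mobility_mult: float):
    days = config.days_per_participant
    day0 = STUDY_START
    contacts = [f"{pid}_c{j:02d}" for j in range(12)]
    w = 1.0 / (np.arange(12) + 1.0)
    contact_p = w / w.sum()

    call_rows, sms_rows, screen_rows, loc_rows = [], [], [], []

    for d in range(days):
        base = d * 86400
        # calls
        for _ in range(rng.poisson(3.0)):
            t = base + rng.uniform(9 * 3600, 24 * 3600)
            call_rows.append(
                {
                    "participant_id": pid,
                    "start_ts": day0 + pd.Timedelta(seconds=round(t)),
                    "duration_s": float(round(rng.exponential(150.0), 1)),
                    "contact_hash": contacts[rng.choice(12, p=contact_p)],
                    "direction": "out" if rng.random() < 0.5 else "in",
                }
            )
        # SMS sessions: bursts of messages with the same contact
        for _ in range(rng.poisson(4.0)):
            t = base + rng.uniform(8 * 3600, 24 * 3600)
            contact = contacts[rng.choice(12, p=contact_p)]
            n_msg = 1 + min(int(rng.geometric(0.45)) - 1, 7)
            for _m in range(n_msg):
                sms_rows.append(
                    {
                        "participant_id": pid,
                        "ts": day0 + pd.Timedelta(seconds=round(t)),
                        "contact_hash": contact,
                        "direction": "out" if rng.random() < 0.5 else "in",
                    }
                )
                t += rng.uniform(20.0, 200.0)
        # screen bouts: sorted starts, durations truncated at the next start
        n_bouts = rng.poisson(25.0)
        starts = np.sort(rng.uniform(0, 86400 - 60, n_bouts)) + base
        target_total = 180.0 * 60.0 * screen_mult
        durs = rng.exponential(max(target_total / max(n_bouts, 1), 5.0), n_bouts)
        for j, (s, du) in enumerate(zip(starts, durs)):
            nxt = starts[j + 1] if j + 1 < n_bouts else base + 86400.0
            du = float(np.clip(du, 3.0, max(nxt - s - 1.0, 3.0)))
            screen_rows.append({"participant_id": pid, "ts": day0 + pd.Timedelta(seconds=round(s)), "state": "on"})
            screen_rows.append({"participant_id": pid, "ts": day0 + pd.Timedelta(seconds=round(s + du)), "state": "off"})

    # locations: anchor-based routine on a plane (meters)
    n_anchor = int(rng.integers(2, 5))
    anchors = np.vstack(
        [
            rng.normal(0.0, 50.0, size=2),  # home
            rng.uniform(-400.0, 400.0, size=(n_anchor - 1, 2)) * mobility_mult,
        ]
    )
    asleep_min = _sleep_indicator_minutes(schedule)
    cur = 0
    for tmin in range(0, days * 1440, 10):
        if asleep_min[min(tmin, len(asleep_min) - 1)]:
            cur = 0  # home during sleep
        elif rng.random() < 0.1:
            cur = int(rng.integers(0, n_anchor))
        pos = anchors[cur] + rng.normal(0.0, 20.0, size=2)
        loc_rows.append(
            {
                "participant_id": pid,
                "ts": day0 + pd.Timedelta(seconds=tmin * 60),
                "x_m": round(float(pos[0]), 2),
                "y_m": round(float(pos[1]), 2),
            }
        )

    cols_calls = ["participant_id", "start_ts", "duration_s", "contact_hash", "direction"]
    cols_sms = ["participant_id", "ts", "contact_hash", "direction"]
    cols_screen = ["participant_id", "ts", "state"]
    cols_loc = ["participant_id", "ts", "x_m", "y_m"]
    return (
        pd.DataFrame(call_rows, columns=cols_calls),
        pd.DataFrame(sms_rows, columns=cols_sms),
        pd.DataFrame(screen_rows, columns=cols_screen),
        pd.DataFrame(loc_rows, columns=cols_loc),
    )


# ---------------------------------------------------------------------------
# diaries and sleep episodes


DIARY_ITEMS = [
    "all_nighter",
    "presleep_media",
    "presleep_interaction",
    "n_naps",
    "nap_duration_min",
    "academic_count",
    "academic_duration_min",
    "study_duration_min",
    "extracurricular_count",
    "extracurricular_duration_min",
    "exercise_count",
    "exercise_duration_min",
    "caffeine_count",
    "positive_interaction",
    "somewhat_negative_interaction",
    "very_negative_interaction",
    "last_caffeine_time_min",
]


def _generate_diary(rng, pid: str, config: CohortConfig, schedule: dict):
    day0 = STUDY_START
    naps_by_day: dict[int, list] = {}
    for d, start, dur in schedule["naps"]:
        naps_by_day.setdefault(d, []).append((start, dur))

    diary_rows, episode_rows = [], []
    for d in range(schedule["days"]):
        naps = naps_by_day.get(d, [])
        caffeine = int(rng.poisson(1.5))
        row = {
            "participant_id": pid,
            "date": (day0 + pd.Timedelta(days=d)).date().isoformat(),
            "all_nighter": int(schedule["all_nighter"][d]),
            "presleep_media": int(rng.random() < 0.5),
            "presleep_interaction": int(rng.random() < 0.3),
            "n_naps": len(naps),
            "nap_duration_min": round(float(sum(dur for _s, dur in naps)), 1),
            "academic_count": int(rng.poisson(2.0)),
            "academic_duration_min": round(float(np.clip(rng.normal(240, 60), 0, 600)), 1),
            "study_duration_min": round(float(np.clip(rng.normal(180, 60), 0, 600)), 1),
            "extracurricular_count": int(rng.poisson(1.0)),
            "extracurricular_duration_min": round(float(np.clip(rng.normal(60, 40), 0, 300)), 1),
            "exercise_count": int(rng.random() < 0.4),
            "exercise_duration_min": round(float(np.clip(rng.normal(40, 20), 0, 180)), 1),
            "caffeine_count": caffeine,
            "positive_interaction": int(rng.random() < 0.6),
            "somewhat_negative_interaction": int(rng.random() < 0.25),
            "very_negative_interaction": int(rng.random() < 0.08),
            "last_caffeine_time_min": (
                round(float(rng.uniform(8 * 60, 22 * 60)), 0) if caffeine > 0 else np.nan
            ),
        }
        # reported bed/wake times (consistent with ground truth)
        bed, wake = schedule["bed_min"][d], schedule["wake_min"][d]
        row["reported_bedtime"] = "" if np.isnan(bed) else str(day0 + pd.Timedelta(minutes=round(bed)))
        row["reported_waketime"] = "" if np.isnan(wake) else str(day0 + pd.Timedelta(minutes=round(wake)))
        diary_rows.append(row)

        if not np.isnan(bed):
            episode_rows.append(
                {
                    "participant_id": pid,
                    "day_index": d,
                    "bedtime": day0 + pd.Timedelta(minutes=round(bed)),
                    "waketime": day0 + pd.Timedelta(minutes=round(wake)),
                    "efficiency": round(float(schedule["efficiency"][d]), 3),
                }
            )
    return diary_rows, episode_rows


# ---------------------------------------------------------------------------
# artifact injection


def inject_artifacts(stream: SensorStream, fraction: float, seed: int) -> SensorStream:
    """Replace ~``fraction`` of SC samples with out-of-range values.

    Corruption is placed in contiguous bouts (mean ~30 s), alternating
    rail-low (< 0.01 uS) and rail-high (> 30 uS) values, mimicking
    electrode detachment and saturation.  The input stream is not
    modified; a corrupted copy is returned.
    """
    if not 0.0 <= fraction < 1.0:
        raise ParameterError("fraction must lie in [0, 1)")
    out = stream.copy()
    if fraction == 0.0:
        return out
    rng = np.random.default_rng(seed)
    n = out.n_samples
    target = int(round(fraction * n))
    bad = np.zeros(n, dtype=bool)
    mean_bout = max(int(round(30.0 * out.sample_rate)), 1)
    guard = 0
    while bad.sum() < target and guard < 100 * n:
        start = int(rng.integers(0, n))
        length = max(int(rng.exponential(mean_bout)), 1)
        stop = min(start + length, n)
        high = rng.random() < 0.5
        vals = 35.0 + rng.random(stop - start) * 10.0 if high else 0.001 + rng.random(stop - start) * 0.005
        out.sc[start:stop] = vals
        bad[start:stop] = True
        guard += stop - start
    return out


# ---------------------------------------------------------------------------
# on-disk dataset


_FILES = {
    "participants": "participants.csv",
    "latent": "latent.csv",
    "streams": "streams.csv",
    "calls": "calls.csv",
    "sms": "sms.csv",
    "screen": "screen.csv",
    "locations": "locations.csv",
    "diary": "diary.csv",
    "sleep_episodes": "sleep_episodes.csv",
}


def write_dataset(bundle: DatasetBundle, directory: str | Path) -> dict:
    """Serialize a bundle to plain CSV files plus a JSON manifest.

    Returns the manifest dict.  ``read_dataset(write_dataset(b)) == b`` up
    to float round-tripping through decimal text (exact for repr output).
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)

    bundle.participants.to_csv(directory / _FILES["participants"], index=False)
    # %.17g guarantees exact float64 round-trip for the full-precision tables
    bundle.latent.rename("latent_trait").to_csv(directory / _FILES["latent"],
                                                float_format="%.17g")

    stream_frames = []
    for pid in bundle.participants["participant_id"]:
        s = bundle.streams[pid]
        ts = s.t0 + pd.to_timedelta(np.arange(s.n_samples) / s.sample_rate, unit="s")
        stream_frames.append(
            pd.DataFrame(
                {
                    "participant_id": pid,
                    "timestamp": ts,
                    "sc_uS": s.sc,
                    "st_C": s.st,
                    "acc_x": s.acc[:, 0],
                    "acc_y": s.acc[:, 1],
                    "acc_z": s.acc[:, 2],
                    "valid": s.valid_mask.astype(int),
                }
            )
        )
    pd.concat(stream_frames, ignore_index=True).to_csv(directory / _FILES["streams"],
                                                       index=False, float_format="%.17g")

    bundle.calls.to_csv(directory / _FILES["calls"], index=False)
    bundle.sms.to_csv(directory / _FILES["sms"], index=False)
    bundle.screen.to_csv(directory / _FILES["screen"], index=False)
    bundle.locations.to_csv(directory / _FILES["locations"], index=False)
    bundle.diary.to_csv(directory / _FILES["diary"], index=False)
    bundle.sleep_episodes.to_csv(directory / _FILES["sleep_episodes"], index=False)

    manifest = {
        "schema_version": SCHEMA_VERSION,
        "seed": bundle.config.seed,
        "config": bundle.config.to_dict(),
        "files": sorted(_FILES.values()),
    }
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def read_dataset(directory: str | Path) -> DatasetBundle:
    """Load a bundle previously written by :func:`write_dataset`."""
    directory = Path(directory)
    man_path = directory / "manifest.json"
    if not man_path.exists():
        raise FormatError(f"missing manifest.json in {directory}")
    manifest = json.loads(man_path.read_text())
    if manifest.get("schema_version") != SCHEMA_VERSION:
        raise FormatError(
            f"{man_path}: schema version {manifest.get('schema_version')!r} "
            f"!= supported {SCHEMA_VERSION!r}"
        )
    for fname in manifest["files"]:
        if not (directory / fname).exists():
            raise FormatError(f"missing dataset file: {directory / fname}")

    config = CohortConfig.from_dict(manifest["config"])

    def _read(name, **kw):
        path = directory / _FILES[name]
        # round_trip parsing: the default fast parser is off by 1 ulp on
        # some values, which would break exact write/read round-trips
        df = pd.read_csv(path, float_precision="round_trip", **kw)
        return df

    participants = _read("participants")
    required = {"participant_id", "cohort", "pss_post", "mcs_post"}
    if not required.issubset(participants.columns):
        raise FormatError(f"{directory / _FILES['participants']}: missing columns "
                          f"{sorted(required - set(participants.columns))} (line 1)")
    latent = _read("latent").set_index("participant_id")["latent_trait"]

    raw = _read("streams", parse_dates=["timestamp"])
    streams = {}
    for pid, g in raw.groupby("participant_id", sort=False):
        streams[pid] = SensorStream(
            participant_id=pid,
            sample_rate=config.sc_sample_rate,
            t0=g["timestamp"].iloc[0],
            sc=g["sc_uS"].to_numpy(),
            st=g["st_C"].to_numpy(),
            acc=g[["acc_x", "acc_y", "acc_z"]].to_numpy(),
            valid_mask=g["valid"].to_numpy().astype(bool),
        )

    calls = _read("calls", parse_dates=["start_ts"])
    sms = _read("sms", parse_dates=["ts"])
    screen = _read("screen", parse_dates=["ts"])
    locations = _read("locations", parse_dates=["ts"])
    diary = _read("diary")
    for col in ("reported_bedtime", "reported_waketime"):
        if col in diary.columns:  # empty strings (all-nighters) round-trip as NaN
            diary[col] = diary[col].fillna("")
    episodes = _read("sleep_episodes", parse_dates=["bedtime", "waketime"])

    return DatasetBundle(
        config=config,
        participants=participants,
        latent=latent,
        streams=streams,
        calls=calls,
        sms=sms,
        screen=screen,
        locations=locations,
        diary=diary,
        sleep_episodes=episodes,
    )


def bundles_equal(a: DatasetBundle, b: DatasetBundle, numeric_tol: float = 0.0) -> bool:
    """Structural + numeric equality of two bundles (used for round-trip tests)."""
    if a.config.to_dict() != b.config.to_dict():
        return False
    frames = ["participants", "calls", "sms", "screen", "locations", "diary", "sleep_episodes"]
    for name in frames:
        fa, fb = getattr(a, name).reset_index(drop=True), getattr(b, name).reset_index(drop=True)
        if fa.shape != fb.shape or list(fa.columns) != list(fb.columns):
            return False
        for c in fa.columns:
            xa, xb = fa[c], fb[c]
            if pd.api.types.is_float_dtype(xa) or pd.api.types.is_float_dtype(xb):
                va, vb = xa.astype(float).to_numpy(), xb.astype(float).to_numpy()
                ok = np.isclose(va, vb, atol=numeric_tol, rtol=0.0, equal_nan=True).all()
            else:
                ok = (xa.astype(str) == xb.astype(str)).all()
            if not ok:
                return False
    if not np.allclose(a.latent.to_numpy(), b.latent.to_numpy(), atol=numeric_tol, rtol=0.0):
        return False
    if set(a.streams) != set(b.streams):
        return False
    for pid in a.streams:
        sa, sb = a.streams[pid], b.streams[pid]
        if sa.t0 != sb.t0 or sa.sample_rate != sb.sample_rate:
            return False
        for arr_a, arr_b in [(sa.sc, sb.sc), (sa.st, sb.st), (sa.acc, sb.acc)]:
            if not np.allclose(arr_a, arr_b, atol=numeric_tol, rtol=0.0):
                return False
        if not np.array_equal(sa.valid_mask, sb.valid_mask):
            return False
    return True
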