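"""Diary feature block, modality assembly, and outcome group construction.

Groups are built from post-study questionnaire scores: perceived stress
(PSS, 0-40, >=16 treated as high stress) and the SF-12 mental component
summary (MCS, >=50 good mental health).  The larger class is randomly
downsampled (seeded) so both classes have equal prior probability.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import FeatureBlock, concat_blocks

logger = logging.getLogger(__name__)

#: the 17 diary items aggregated across days by mean/median/SD (51 columns)
DIARY_ITEMS = (
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
)

MODALITIES = ("all", "big5_gender", "sensors", "phone", "objective", "modifiable",
              "diary", "sleep")


class LabelingError(ValueError):
    """Group construction failed (e.g. an empty class under the cutoffs)."""


class ConfigurationError(ValueError):
    """A required feature block is missing from the assembly."""


@dataclass
class LabelSet:
    """Binary class membership for one outcome, after balancing."""

    outcome: str
    cutoff_spec: dict
    high_ids: list[str]
    low_ids: list[str]
    dropped_ids: list[str] = field(default_factory=list)
    seed: int | None = None

    def __post_init__(self):
        if set(self.high_ids) & set(self.low_ids):
            raise LabelingError("classes must be disjoint")

    @property
    def ids(self) -> list[str]:
        return list(self.high_ids) + list(self.low_ids)

    def series(self) -> pd.Series:
        """Participant id -> 1 (high) / 0 (low)."""
        return pd.Series(
            {**{i: 1 for i in self.high_ids}, **{i: 0 for i in self.low_ids}},
            name=self.outcome,
        )


def diary_feature_matrix(diary: pd.DataFrame, min_days: int = 2) -> FeatureBlock:
    """The 51-column diary block: 17 items x mean/median/SD across days.

    Binary items aggregate to a proportion (mean), median and SD.  Days
    where the last-caffeine-time item is missing (no caffeine) are
    excluded from that item's aggregates.  Participants with fewer than
    ``min_days`` diary days are excluded with a logged warning.
    """
    rows, index = [], []
    for pid, g in diary.groupby("participant_id", sort=True):
        if g.shape[0] < min_days:
            logger.warning("participant %s excluded from diary features: <%d days", pid, min_days)
            continue
        row = {}
        for item in DIARY_ITEMS:
            vals = g[item].to_numpy(dtype=float)
            vals = vals[~np.isnan(vals)]
            if vals.size >= min_days:
                row[f"diary_{item}__mean"] = float(np.mean(vals))
                row[f"diary_{item}__median"] = float(np.median(vals))
                row[f"diary_{item}__sd"] = float(np.std(vals, ddof=1))
            else:
                row[f"diary_{item}__mean"] = np.nan
                row[f"diary_{item}__median"] = np.nan
                row[f"diary_{item}__sd"] = np.nan
        rows.append(row)
        index.append(pid)
    columns = [f"diary_{item}__{agg}" for item in DIARY_ITEMS
               for agg in ("mean", "median", "sd")]
    data = pd.DataFrame(rows, index=pd.Index(index, name="participant_id"), columns=columns)
    meta = pd.DataFrame(
        [{"block": "diary", "statistic": item, "window": "daily", "aggregate": agg}
         for item in DIARY_ITEMS for agg in ("mean", "median", "sd")],
        index=columns,
    )
    return FeatureBlock(data=data, meta=meta)


def big5_gender_block(participants: pd.DataFrame) -> FeatureBlock:
    """The 6-column trait block: Big Five scores plus gender (male=1)."""
    df = participants.set_index("participant_id")
    data = df[["openness", "conscientiousness", "extraversion", "agreeableness",
               "neuroticism"]].astype(float).copy()
    data["gender_male"] = (df["gender"] == "male").astype(float)
    meta = pd.DataFrame(
        [{"block": "trait", "statistic": c, "window": "", "aggregate": ""}
         for c in data.columns],
        index=data.columns,
    )
    return FeatureBlock(data=data, meta=meta)


#: sleep-block columns reused by the modifiable-behaviors modality
_MODIFIABLE_SLEEP_COLS = (
    "sleep_regularity_index",
    "bedtime_min__mean", "bedtime_min__median", "bedtime_min__sd",
    "sleep_duration_min__mean", "sleep_duration_min__median", "sleep_duration_min__sd",
)


def assemble_modality(blocks: dict[str, FeatureBlock], modality: str) -> FeatureBlock:
    """Assemble one of the named feature modalities from its blocks.

    ``blocks`` may contain 'sensors' (204), 'phone' (237), 'diary' (51),
    'sleep' (25), 'big5_gender' (6) and 'acc_summary' (1).  Compositions:

    * objective   = sensors + phone                       (441)
    * modifiable  = SRI + bedtime/duration stats (7) + diary (51)
                    + ACC zero-crossing summary (1) + phone (237)  (296)
    * all         = big5_gender + diary + sensors + phone (498)
    """
    def need(name):
        if name not in blocks:
            raise ConfigurationError(f"modality '{modality}' requires missing block '{name}'")
        return blocks[name]

    if modality in ("sensors", "phone", "diary", "sleep", "big5_gender"):
        return need(modality)
    if modality == "objective":
        return concat_blocks([need("sensors"), need("phone")])
    if modality == "all":
        return concat_blocks([need("big5_gender"), need("diary"), need("sensors"), need("phone")])
    if modality == "modifiable":
        sleep = need("sleep")
        cols = [c for c in _MODIFIABLE_SLEEP_COLS if c in sleep.data.columns]
        if len(cols) != len(_MODIFIABLE_SLEEP_COLS):
            missing = set(_MODIFIABLE_SLEEP_COLS) - set(cols)
            raise ConfigurationError(f"sleep block lacks columns {sorted(missing)}")
        sleep_part = FeatureBlock(data=sleep.data[cols], meta=sleep.meta.loc[cols])
        return concat_blocks([sleep_part, need("diary"), need("acc_summary"), need("phone")])
    raise ConfigurationError(f"unknown modality '{modality}'")


def _balance(high: list[str], low: list[str], seed: int | None):
    rng = np.random.default_rng(seed)
    dropped: list[str] = []
    if len(high) > len(low):
        keep = sorted(rng.choice(np.array(high), size=len(low), replace=False).tolist())
        dropped = sorted(set(high) - set(keep))
        high = keep
    elif len(low) > len(high):
        keep = sorted(rng.choice(np.array(low), size=len(high), replace=False).tolist())
        dropped = sorted(set(low) - set(keep))
        low = keep
    return list(high), list(low), dropped


def label_pss(scores: pd.Series, cutoff: float = 16.0,
              balance_seed: int | None = 0) -> LabelSet:
    """High/low perceived-stress groups: high = PSS >= cutoff, then balance.

    The larger class is randomly downsampled without replacement (seeded)
    to the smaller class's size so the prior probability of each class is
    0.5.
    """
    scores = pd.Series(scores).dropna()
    if ((scores < 0) | (scores > 40)).any():
        raise LabelingError("PSS scores must lie in [0, 40]")
    high = sorted(scores.index[scores >= cutoff].tolist())
    low = sorted(scores.index[scores < cutoff].tolist())
    if not high or not low:
        raise LabelingError(f"empty class under PSS cutoff {cutoff}")
    high, low, dropped = _balance(high, low, balance_seed)
    return LabelSet(outcome="pss", cutoff_spec={"cutoff": cutoff},
                    high_ids=high, low_ids=low, dropped_ids=dropped, seed=balance_seed)


def label_mcs(scores: pd.Series, mode: str = "extremes",
              high_cutoff: float | None = 50.0, low_cutoff: float | None = 29.4,
              quantile: float | None = None,
              balance_seed: int | None = 0) -> LabelSet:
    """High/low mental-health groups from MCS scores.

    ``extremes`` mode keeps only the tails: high = MCS >= ``high_cutoff``,
    low = MCS <= ``low_cutoff`` (defaults 50 / 29.4); alternatively pass
    ``quantile`` (e.g. 0.12) to derive both cutoffs from the sample, in
    which case each tail is trimmed by score order to
    ``round(quantile * n)`` members (ties kept first, most extreme scores
    retained).  ``median`` mode splits at the sample median (high = MCS >=
    median).  Classes are then balanced as for PSS.
    """
    scores = pd.Series(scores).dropna()
    if scores.empty:
        raise LabelingError("no MCS scores")
    if mode == "median":
        med = float(scores.median())
        high = sorted(scores.index[scores >= med].tolist())
        low = sorted(scores.index[scores < med].tolist())
        spec = {"mode": "median", "median": med}
    elif mode == "extremes":
        if quantile is not None:
            n_target = int(round(quantile * scores.shape[0]))
            if n_target < 1:
                raise LabelingError("quantile too small: empty tail")
            order = scores.sort_values(kind="mergesort")
            low = sorted(order.index[:n_target].tolist())
            high = sorted(order.index[-n_target:].tolist())
            spec = {"mode": "extremes", "quantile": quantile, "n_per_tail": n_target}
        else:
            high = sorted(scores.index[scores >= high_cutoff].tolist())
            low = sorted(scores.index[scores <= low_cutoff].tolist())
            spec = {"mode": "extremes", "high_cutoff": high_cutoff, "low_cutoff": low_cutoff}
    else:
        raise LabelingError(f"unknown mode '{mode}'")
    if not high or not low:
        raise LabelingError("empty class under the chosen MCS cutoffs")
    if set(high) & set(low):
        raise LabelingError("MCS cutoffs overlap: classes are not disjoint")
    high, low, dropped = _balance(high, low, balance_seed)
    return LabelSet(outcome="mcs", cutoff_spec=spec, high_ids=high, low_ids=low,
                    dropped_ids=dropped, seed=balance_seed)
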