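"""End-to-end orchestration: simulate/ingest -> extract -> label -> evaluate -> stats -> report.

A run is driven by a single declarative config (YAML/JSON).  One global
seed expands deterministically into per-stage seeds, every output file is
declared in a manifest, and rerunning the same config reproduces all
numeric outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .containers import FeatureBlock
from .cohort_stats import group_feature_tests, results_frame
from .evaluate import ModelSpec, loco_cv
from .labels import assemble_modality, big5_gender_block, diary_feature_matrix, label_mcs, label_pss
from .phone import phone_feature_matrix
from .sensors import acc_fullday_summary, sensor_feature_matrix
from .sleep import daily_sleep_table, sleep_feature_matrix, sri_from_bundle_episodes
from .synthetic import CohortConfig, DatasetBundle, generate_cohort, read_dataset, write_dataset

logger = logging.getLogger(__name__)

_STAGES = ("simulate", "extract", "label", "evaluate", "stats", "report")


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class RunConfig:
    """Declarative description of one reproducible run."""

    dataset_path: str | None = None  # load instead of simulating
    cohort: dict = field(default_factory=dict)  # CohortConfig overrides for simulation
    modalities: list[str] = field(default_factory=lambda: ["big5_gender"])
    outcomes: list[str] = field(default_factory=lambda: ["pss"])
    models: list[str] = field(default_factory=lambda: ["svm_rbf"])
    model_spec: dict = field(default_factory=dict)  # ModelSpec overrides
    seed: int = 0
    last_week_only: bool = False
    output_dir: str = "run_output"

    def validate(self):
        from .labels import MODALITIES

        for m in self.modalities:
            if m not in MODALITIES:
                raise ValueError(f"unknown modality '{m}'")
        for o in self.outcomes:
            if o not in ("pss", "mcs"):
                raise ValueError(f"unknown outcome '{o}'")
        for fam in self.models:
            if fam not in ("svm_rbf", "svm_linear", "lasso"):
                raise ValueError(f"unknown model family '{fam}'")

    def stage_seed(self, stage: str) -> int:
        """Deterministic per-stage seed: SeedSequence(seed, stage index)."""
        return int(np.random.SeedSequence([self.seed, _STAGES.index(stage)]).generate_state(1)[0] % (2**31))

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        return cls(**d)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text)
        return cls.from_dict(data)


def slice_bundle_days(bundle: DatasetBundle, first_day: int, last_day: int) -> DatasetBundle:
    """Restrict a bundle to days ``[first_day, last_day)`` (pure input filter).

    Used for the "last week only" comparison: features computed on the
    restricted bundle flow through the unchanged pipeline.
    """
    from .containers import SensorStream
    from .synthetic import STUDY_START

    t_lo = STUDY_START + pd.Timedelta(days=first_day)
    t_hi = STUDY_START + pd.Timedelta(days=last_day)

    streams = {}
    for pid, s in bundle.streams.items():
        lo = int(max((t_lo - s.t0).total_seconds(), 0) * s.sample_rate)
        hi = int(min(max((t_hi - s.t0).total_seconds(), 0) * s.sample_rate, s.n_samples))
        streams[pid] = SensorStream(
            participant_id=pid, sample_rate=s.sample_rate,
            t0=s.t0 + pd.Timedelta(seconds=lo / s.sample_rate),
            sc=s.sc[lo:hi], st=s.st[lo:hi], acc=s.acc[lo:hi], valid_mask=s.valid_mask[lo:hi],
        )

    def _cut(df, col):
        return df[(df[col] >= t_lo) & (df[col] < t_hi)].reset_index(drop=True)

    diary = bundle.diary.copy()
    dates = pd.to_datetime(diary["date"])
    diary = diary[(dates >= t_lo) & (dates < t_hi)].reset_index(drop=True)
    episodes = bundle.sleep_episodes
    episodes = episodes[(episodes["bedtime"] >= t_lo) & (episodes["bedtime"] < t_hi)]

    cfg = CohortConfig.from_dict({**bundle.config.to_dict(),
                                  "days_per_participant": last_day - first_day})
    return DatasetBundle(
        config=cfg,
        participants=bundle.participants,
        latent=bundle.latent,
        streams=streams,
        calls=_cut(bundle.calls, "start_ts"),
        sms=_cut(bundle.sms, "ts"),
        screen=_cut(bundle.screen, "ts"),
        locations=_cut(bundle.locations, "ts"),
        diary=diary,
        sleep_episodes=episodes.reset_index(drop=True),
    )


def extract_all_blocks(bundle: DatasetBundle, seed: int = 0) -> dict[str, FeatureBlock]:
    """All feature blocks from a bundle (sensor, phone, diary, sleep, traits)."""
    streams = [bundle.streams[p] for p in bundle.participants["participant_id"]]
    blocks = {
        "sensors": sensor_feature_matrix(streams, bundle.sleep_episodes),
        "phone": phone_feature_matrix(bundle.calls, bundle.sms, bundle.screen,
                                      bundle.locations, seed=seed),
        "diary": diary_feature_matrix(bundle.diary),
        "big5_gender": big5_gender_block(bundle.participants),
        "acc_summary": acc_fullday_summary(streams),
    }
    sri = sri_from_bundle_episodes(bundle.sleep_episodes,
                                   days=bundle.config.days_per_participant,
                                   start=streams[0].t0.normalize() if streams else None,
                                   seed=seed)
    daily = daily_sleep_table(bundle.sleep_episodes, bundle.diary)
    blocks["sleep"] = sleep_feature_matrix(daily, sri)
    return blocks


def make_labels(participants: pd.DataFrame, outcome: str, seed: int,
                pss_cutoff: float = 16.0, mcs_mode: str = "extremes"):
    scores = participants.set_index("participant_id")
    if outcome == "pss":
        return label_pss(scores["pss_post"], cutoff=pss_cutoff, balance_seed=seed)
    return label_mcs(scores["mcs_post"], mode=mcs_mode, balance_seed=seed)


def run_pipeline(config: RunConfig) -> Path:
    """Execute all stages; returns the run directory.

    The run directory contains the dataset (when simulated), one CSV per
    feature block/modality, label JSONs, evaluation JSONs, group-test
    CSVs, a report table, and a manifest declaring every written file.
    """
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[str] = []

    def _declare(path: Path):
        written.append(str(path.relative_to(out)))

    # --- stage: simulate / ingest ----------------------------------------
    try:
        if config.dataset_path:
            bundle = read_dataset(config.dataset_path)
        else:
            cc = CohortConfig.from_dict({"seed": config.stage_seed("simulate"),
                                         **config.cohort})
            bundle = generate_cohort(cc)
            write_dataset(bundle, out / "dataset")
            for f in sorted((out / "dataset").iterdir()):
                _declare(f)
    except Exception as e:  # noqa: BLE001
        raise StageError(f"stage 'simulate' failed: {e}") from e

    if config.last_week_only:
        days = bundle.config.days_per_participant
        bundle = slice_bundle_days(bundle, max(days - 7, 0), days)

    # --- stage: extract ----------------------------------------------------
    try:
        blocks = extract_all_blocks(bundle, seed=config.stage_seed("extract"))
        features_dir = out / "features"
        features_dir.mkdir(exist_ok=True)
        modality_blocks = {}
        for m in config.modalities:
            fb = assemble_modality(blocks, m)
            modality_blocks[m] = fb
            p = features_dir / f"features_{m}.csv"
            fb.data.to_csv(p)
            _declare(p)
            pm = features_dir / f"feature_metadata_{m}.json"
            pm.write_text(json.dumps(fb.meta.to_dict(orient="index"), indent=2))
            _declare(pm)
    except Exception as e:  # noqa: BLE001
        raise StageError(f"stage 'extract' failed: {e}") from e

    # --- stage: label -------------------------------------------------------
    try:
        label_sets = {}
        for oc in config.outcomes:
            ls = make_labels(bundle.participants, oc, seed=config.stage_seed("label"))
            label_sets[oc] = ls
            p = out / f"labels_{oc}.json"
            p.write_text(json.dumps({
                "outcome": ls.outcome, "cutoff_spec": ls.cutoff_spec,
                "high_ids": ls.high_ids, "low_ids": ls.low_ids,
                "dropped_ids": ls.dropped_ids, "seed": ls.seed,
            }, indent=2))
            _declare(p)
    except Exception as e:  # noqa: BLE001
        raise StageError(f"stage 'label' failed: {e}") from e

    # --- stage: evaluate ----------------------------------------------------
    cohorts = bundle.participants.set_index("participant_id")["cohort"]
    report_rows = []
    try:
        for oc in config.outcomes:
            for m in config.modalities:
                for fam in config.models:
                    spec = ModelSpec(**{**config.model_spec, "family": fam,
                                        "seed": config.stage_seed("evaluate")})
                    res = loco_cv(modality_blocks[m].data, label_sets[oc], cohorts,
                                  spec, outcome=oc)
                    p = out / f"evaluation_{oc}_{m}_{fam}.json"
                    p.write_text(json.dumps(res.to_dict(), indent=2))
                    _declare(p)
                    fp = out / f"selection_frequencies_{oc}_{m}_{fam}.csv"
                    res.selection_frequency.rename_axis("feature").to_csv(fp)
                    _declare(fp)
                    report_rows.append({
                        "outcome": oc, "modality": m, "model": fam,
                        "n": res.n, "accuracy": res.accuracy,
                        "ci_low": res.accuracy_ci[0], "ci_high": res.accuracy_ci[1],
                        "f1": res.f1,
                    })
    except Exception as e:  # noqa: BLE001
        raise StageError(f"stage 'evaluate' failed: {e}") from e

    # --- stage: stats -------------------------------------------------------
    try:
        for oc in config.outcomes:
            m = config.modalities[0]
            res = group_feature_tests(modality_blocks[m].data, label_sets[oc])
            p = out / f"group_tests_{oc}_{m}.csv"
            results_frame(res).to_csv(p, index=False)
            _declare(p)
    except Exception as e:  # noqa: BLE001
        raise StageError(f"stage 'stats' failed: {e}") from e

    # --- stage: report ------------------------------------------------------
    try:
        report = pd.DataFrame(report_rows)
        p = out / "report.csv"
        report.to_csv(p, index=False)
        _declare(p)
    except Exception as e:  # noqa: BLE001
        raise StageError(f"stage 'report' failed: {e}") from e

    cfg_json = json.dumps(config.to_dict(), sort_keys=True)
    manifest = {
        "package_version": __version__,
        "config": config.to_dict(),
        "config_hash": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "stage_seeds": {s: config.stage_seed(s) for s in _STAGES},
        "files": sorted(written),
    }
    (out / "run_manifest.json").write_text(json.dumps(manifest, indent=2))
    return out
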