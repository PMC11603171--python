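"""Tabular I/O, configuration, and pipeline orchestration.

All tables are plain CSV with a header.  The block table schema is this
package's own convention (the columns of :class:`~taplearn.types.BlockRecord`
plus the participant profile columns); floats are written with full
``repr`` precision so that write -> read round-trips are exact and
repeated runs are byte-identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import yaml

from . import classifier, cohort, dynamics as dyn, plateau
from .types import (
    Arm,
    BlockRecord,
    BlockType,
    Dataset,
    ParticipantProfile,
    PipelineConfig,
    age_group_for,
)

log = logging.getLogger(__name__)

BLOCK_COLUMNS = [
    "participant_id", "day", "block_index", "block_type",
    "speed", "accuracy", "n_presses",
]
PROFILE_COLUMNS = ["participant_id", "age_years", "age_group", "arm", "dataset"]


class SchemaError(ValueError):
    """A required column is missing from an input table."""


def blocks_to_frame(records: Iterable[BlockRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        d = asdict(r)
        d["block_type"] = r.block_type.value
        rows.append(d)
    return pd.DataFrame(rows, columns=BLOCK_COLUMNS)


def profiles_to_frame(profiles: Iterable[ParticipantProfile]) -> pd.DataFrame:
    rows = []
    for p in profiles:
        rows.append(
            {
                "participant_id": p.participant_id,
                "age_years": p.age_years,
                "age_group": p.age_group.value,
                "arm": p.arm.value,
                "dataset": p.dataset.value,
            }
        )
    return pd.DataFrame(rows, columns=PROFILE_COLUMNS)


def frame_to_records(df: pd.DataFrame) -> list[BlockRecord]:
    records = []
    for i, row in df.iterrows():
        try:
            records.append(
                BlockRecord(
                    participant_id=str(row["participant_id"]),
                    day=int(row["day"]),
                    block_index=int(row["block_index"]),
                    block_type=BlockType(row["block_type"]),
                    speed=float(row["speed"]),
                    accuracy=float(row["accuracy"]),
                    n_presses=int(row.get("n_presses", 0)),
                )
            )
        except ValueError as exc:
            raise ValueError(f"row {i}: {exc}") from exc
    return records


def read_block_table(
    path: str | Path,
) -> tuple[list[BlockRecord], list[ParticipantProfile]]:
    """Read a block table CSV; validates every row and dedups profiles.

    Profile columns (age_years, arm, ...) are optional in the file; absent
    ones default to age 30 / arm none so purely behavioral tables load.
    """
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in BLOCK_COLUMNS if c not in df.columns and c != "n_presses"]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    records = frame_to_records(df)
    profiles: dict[str, ParticipantProfile] = {}
    for _, row in df.iterrows():
        pid = str(row["participant_id"])
        if pid in profiles:
            continue
        age = float(row["age_years"]) if "age_years" in df.columns else 30.0
        arm = Arm(row["arm"]) if "arm" in df.columns else Arm.NONE
        ds = Dataset(row["dataset"]) if "dataset" in df.columns else Dataset.SYNTHETIC
        profiles[pid] = ParticipantProfile(
            participant_id=pid, age_years=age, age_group=age_group_for(age),
            arm=arm, dataset=ds,
        )
    return records, list(profiles.values())


def write_block_table(
    records: Sequence[BlockRecord],
    path: str | Path,
    profiles: Sequence[ParticipantProfile] | None = None,
) -> Path:
    """Write records (optionally joined with profile columns) as CSV.

    Deterministic byte-for-byte for identical input.
    """
    path = Path(path)
    df = blocks_to_frame(records)
    if profiles is not None:
        df = df.merge(profiles_to_frame(profiles), on="participant_id", how="left")
    df.to_csv(path, index=False, float_format=None)
    return path


def load_config(path: str | Path | None = None, **overrides) -> PipelineConfig:
    """Load a YAML key-value config; unspecified keys take defaults,
    unknown keys are warned about and ignored."""
    values: dict = {}
    if path is not None:
        text = Path(path).read_text()
        loaded = yaml.safe_load(text)
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ValueError(f"{path}: config must be a key-value mapping")
        values.update(loaded)
    values.update(overrides)
    known = set(PipelineConfig.field_names())
    unknown = set(values) - known
    for key in sorted(unknown):
        log.warning("ignoring unknown config key %r", key)
        values.pop(key)
    return PipelineConfig(**values)


def run_pipeline(
    config: PipelineConfig,
    out_dir: str | Path,
    blocks_path: str | Path | None = None,
    effects: cohort.StimEffectSpec | None = None,
    cohort_spec: cohort.CohortSpec | None = None,
) -> dict[str, Path]:
    """Run the full analysis and write its report bundle.

    Without ``blocks_path`` a synthetic cohort is simulated (default
    spec, seeded from the config).  Stages: label the cohort from
    learning-curve plateaus; train the stratifier on unstimulated
    participants; predict likelihood-to-benefit, class and tier for
    everyone; compute accuracy and speed dynamics; test per-tier day-1
    verum-vs-placebo contrasts.  Outputs (CSV + a JSON run log recording
    config and seed) are byte-identical across repeated runs.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    def stage(name: str):
        class _Ctx:
            def __enter__(self):
                return None

            def __exit__(self, exc_type, exc, tb):
                if exc is not None:
                    raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
                return False

        return _Ctx()

    with stage("input"):
        if blocks_path is None:
            spec = cohort_spec if cohort_spec is not None else cohort.CohortSpec(
                n_days=config.n_days, rng_seed=config.rng_seed
            )
            profiles, records, truth = cohort.generate_cohort_blocks(
                spec, effects if effects is not None else cohort.StimEffectSpec()
            )
            truth_path = out_dir / "ground_truth.csv"
            truth.to_csv(truth_path, index=False)
            paths["ground_truth"] = truth_path
        else:
            records, profiles = read_block_table(blocks_path)
        blocks = blocks_to_frame(records)
        prof_df = profiles_to_frame(profiles)
        paths["blocks"] = out_dir / "blocks.csv"
        write_block_table(records, paths["blocks"], profiles)

    with stage("plateau_labeling"):
        labels, unlabelable = plateau.label_cohort(blocks, config)
        paths["labels"] = out_dir / "labels.csv"
        labels.to_csv(paths["labels"], index=False)
        if len(unlabelable):
            paths["unlabelable"] = out_dir / "unlabelable.csv"
            unlabelable.to_csv(paths["unlabelable"], index=False)

    with stage("stratifier_training"):
        features = classifier.extract_features(blocks, prof_df)
        unstim = prof_df[prof_df["arm"] != Arm.VERUM.value]["participant_id"]
        train_feats = features[features["participant_id"].isin(unstim)]
        model = classifier.train_stratifier(train_feats, labels, config)
        paths["model"] = out_dir / "model.json"
        paths["model"].write_text(model.to_json())

    with stage("prediction"):
        preds = classifier.predict_likelihood(model, features)
        preds = preds.merge(prof_df[["participant_id", "arm"]], on="participant_id")
        paths["predictions"] = out_dir / "predictions.csv"
        preds.to_csv(paths["predictions"], index=False)

    with stage("dynamics"):
        frames = []
        for metric in dyn.METRICS:
            d = dyn.compute_dynamics(blocks, metric, config.blocks_per_session)
            d.insert(1, "metric", metric)
            frames.append(d)
        dynamics = pd.concat(frames, ignore_index=True)
        paths["dynamics"] = out_dir / "dynamics.csv"
        dynamics.to_csv(paths["dynamics"], index=False)

    with stage("contrasts"):
        acc = dynamics[dynamics["metric"] == "accuracy"].drop(columns="metric")
        contrasts = dyn.posthoc_day1_contrasts(
            acc, preds, config.blocks_per_session
        )
        paths["contrasts"] = out_dir / "contrasts.csv"
        contrasts.to_csv(paths["contrasts"], index=False)

    run_log = {
        "config": {k: getattr(config, k) for k in config.field_names()},
        "seed": config.rng_seed,
        "n_participants": int(len(prof_df)),
        "outputs": {k: str(v.name) for k, v in paths.items()},
    }
    paths["run_log"] = out_dir / "run_log.json"
    paths["run_log"].write_text(json.dumps(run_log, indent=2, sort_keys=True))
    return paths
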