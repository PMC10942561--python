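"""Readers, writers and run configuration.

CSV schemas
-----------
Trial CSV: ``t,pos_x,pos_y,pos_z,acc_x,acc_y,acc_z`` (SI units), one file
per trial, header required.  Manifest CSV: ``subject_id,group,trial_index,
file,trigger_time,end_time,vabs_com,vabs_dl,vabs_soc``.  Derived tables
(features, statistics, CV results, importance) are written with six
significant digits; raw trial channels and event times are written at
near-full precision so re-reading does not perturb differentiation.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .classifier import ClassifierConfig, CVResult, ImportanceResult
from .errors import ConfigError
from .kinematics import (MovementUnitConfig, OnsetConfig, SignalPrepConfig)
from .synthetic import (CohortSpec, Group, GroupParams, ScoreModel,
                        TrialRecording, default_group_params)

__all__ = [
    "write_trial_csv", "read_trial_csv", "write_cohort", "read_trials",
    "write_feature_table", "read_feature_table", "write_battery",
    "write_cv_results", "write_importance", "write_run_manifest",
    "RunConfig", "load_run_config", "config_hash", "stage_seed",
]

TRIAL_COLUMNS = ("t", "pos_x", "pos_y", "pos_z", "acc_x", "acc_y", "acc_z")
MANIFEST_COLUMNS = ("subject_id", "group", "trial_index", "file",
                    "trigger_time", "end_time",
                    "vabs_com", "vabs_dl", "vabs_soc")

_RAW_FMT = "%.10g"
_DERIVED_FMT = "%.6g"

# fixed per-stage seed offsets so each stage is independently reproducible
_STAGE_OFFSETS = {"simulate": 0, "extract": 101, "stats": 202,
                  "train": 303, "importance": 404}


def stage_seed(global_seed: int, stage: str) -> int:
    return (int(global_seed) + _STAGE_OFFSETS[stage]) % (2**31)


def write_trial_csv(rec: TrialRecording, path) -> None:
    pos = rec.pos if rec.pos is not None else np.full((rec.t.size, 3), np.nan)
    acc = rec.acc if rec.acc is not None else np.full((rec.t.size, 3), np.nan)
    df = pd.DataFrame({
        "t": rec.t,
        "pos_x": pos[:, 0], "pos_y": pos[:, 1], "pos_z": pos[:, 2],
        "acc_x": acc[:, 0], "acc_y": acc[:, 1], "acc_z": acc[:, 2],
    })
    df.to_csv(path, index=False, float_format=_RAW_FMT)


def read_trial_csv(path, *, subject_id: str = "", group: Optional[str] = None,
                   trial_index: int = 0, trigger_time: float = 0.0,
                   end_time: Optional[float] = None) -> TrialRecording:
    df = pd.read_csv(path)
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise ConfigError(f"{path}: missing columns {missing}")
    t = df["t"].to_numpy(dtype=float)
    if t.size < 2 or np.any(np.diff(t) <= 0):
        raise ConfigError(f"{path}: non-monotone or too-short time column")
    pos = df[["pos_x", "pos_y", "pos_z"]].to_numpy(dtype=float)
    acc = df[["acc_x", "acc_y", "acc_z"]].to_numpy(dtype=float)
    fs = 1.0 / float(np.median(np.diff(t)))
    if end_time is None:
        end_time = float(t[-1])
    return TrialRecording(
        subject_id=subject_id, group_label=Group(group) if group else None,
        trial_index=int(trial_index), sample_rate=fs, t=t,
        pos=None if np.isnan(pos).all() else pos,
        acc=None if np.isnan(acc).all() else acc,
        trigger_time=float(trigger_time), end_time=float(end_time),
    ).validate()


def write_cohort(recordings, manifest: pd.DataFrame, out_dir) -> Path:
    """Write one CSV per trial plus the cohort manifest; returns the
    manifest path."""
    out_dir = Path(out_dir)
    trials_dir = out_dir / "trials"
    trials_dir.mkdir(parents=True, exist_ok=True)
    manifest = manifest.copy()
    files = []
    for rec in recordings:
        fname = f"trials/{rec.subject_id}_t{rec.trial_index:02d}.csv"
        write_trial_csv(rec, out_dir / fname)
        files.append(fname)
    manifest["file"] = files
    manifest = manifest[list(MANIFEST_COLUMNS)]
    path = out_dir / "manifest.csv"
    manifest.to_csv(path, index=False, float_format=_RAW_FMT)
    return path


def read_trials(manifest_path):
    """Read a cohort manifest and its trial files.

    Returns ``(recordings, manifest)``; any missing trial file or
    malformed row raises with the offending file named.
    """
    manifest_path = Path(manifest_path)
    manifest = pd.read_csv(manifest_path)
    required = [c for c in MANIFEST_COLUMNS if c not in ("vabs_com", "vabs_dl",
                                                         "vabs_soc")]
    missing = [c for c in required if c not in manifest.columns]
    if missing:
        raise ConfigError(f"{manifest_path}: manifest missing columns {missing}")
    base = manifest_path.parent
    recordings = []
    for i, row in manifest.iterrows():
        fpath = base / str(row["file"])
        if not fpath.exists():
            raise FileNotFoundError(
                f"{manifest_path} row {i}: trial file not found: {fpath}")
        try:
            rec = read_trial_csv(
                fpath, subject_id=str(row["subject_id"]), group=str(row["group"]),
                trial_index=int(row["trial_index"]),
                trigger_time=float(row["trigger_time"]),
                end_time=float(row["end_time"]))
        except ConfigError as exc:
            raise ConfigError(f"{manifest_path} row {i}: {exc}") from exc
        recordings.append(rec)
    return recordings, manifest


def write_feature_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False, float_format=_DERIVED_FMT)


def read_feature_table(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_battery(battery, out_dir) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    battery.anova.to_csv(out_dir / "anova.csv", index=False,
                         float_format=_DERIVED_FMT)
    battery.posthoc.to_csv(out_dir / "posthoc.csv", index=False,
                           float_format=_DERIVED_FMT)
    battery.correlations.to_csv(out_dir / "correlations.csv", index=False,
                                float_format=_DERIVED_FMT)


def write_cv_results(cv: CVResult, path) -> None:
    df = pd.DataFrame({
        "fold": np.arange(len(cv.fold_accuracies)),
        "accuracy": cv.fold_accuracies,
        "best_val_loss": cv.fold_val_losses,
    })
    df.to_csv(path, index=False, float_format=_DERIVED_FMT)


def write_importance(imp: ImportanceResult, path) -> None:
    order = {int(f): r for r, f in enumerate(imp.ranks)}
    df = pd.DataFrame({
        "feature": imp.feature_names,
        "mean_importance": imp.importances,
        "rank": [order[i] + 1 for i in range(len(imp.feature_names))],
    })
    df.to_csv(path, index=False, float_format=_DERIVED_FMT)


def write_run_manifest(path, *, config: dict, seed: int, extra: dict = None) -> None:
    payload = {"config_hash": config_hash(config), "seed": int(seed),
               "config": config}
    if extra:
        payload.update(extra)
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True,
                                     default=_json_default) + "\n")


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, Group):
        return obj.value
    raise TypeError(f"not JSON serializable: {type(obj)}")


def config_hash(config: dict) -> str:
    canon = yaml.safe_dump(_plain(config), sort_keys=True)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def _plain(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _plain(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {str(k): _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, Group):
        return obj.value
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj


# --------------------------------------------------------------------------
# run configuration


@dataclasses.dataclass
class RunConfig:
    """Everything one pipeline run needs: stage configs plus a global seed
    fanned out to each stage by fixed offsets."""

    cohort: CohortSpec
    signal_prep: SignalPrepConfig = dataclasses.field(default_factory=SignalPrepConfig)
    onset: OnsetConfig = dataclasses.field(default_factory=OnsetConfig)
    movement_units: MovementUnitConfig = dataclasses.field(default_factory=MovementUnitConfig)
    classifier: ClassifierConfig = dataclasses.field(default_factory=ClassifierConfig)
    stats_alpha: float = 0.05
    stats_q: float = 0.05
    seed: int = 0

    def as_dict(self) -> dict:
        return _plain(self)


def _cohort_from_dict(d: dict) -> CohortSpec:
    groups = []
    for g in d.get("groups", []):
        g = dict(g)
        label = Group(g.pop("label"))
        n = int(g.pop("n_subjects"))
        params = dataclasses.replace(default_group_params(label), **{
            k: v for k, v in g.items()})
        groups.append((params, n))
    if not groups:
        raise ConfigError("cohort config must define at least one group")
    kwargs = {k: v for k, v in d.items() if k != "groups" and k != "score_model"}
    sm = d.get("score_model")
    if sm is not None:
        kwargs["score_model"] = ScoreModel(noise_sd=float(sm.get("noise_sd", 5.0)))
    return CohortSpec(groups=groups, **kwargs)


def load_run_config(path=None, *, seed: Optional[int] = None) -> RunConfig:
    """Load a YAML run config; ``path=None`` yields the default children
    cohort configuration.  ``seed`` overrides the file's global seed."""
    from .synthetic import default_cohort_spec

    if path is None:
        data = {}
    else:
        data = yaml.safe_load(Path(path).read_text()) or {}
    g_seed = int(data.get("seed", 0) if seed is None else seed)
    cohort_d = data.get("cohort")
    if cohort_d is None:
        cohort = default_cohort_spec("full", seed=stage_seed(g_seed, "simulate"))
    else:
        cohort_d = dict(cohort_d)
        cohort_d["seed"] = stage_seed(g_seed, "simulate")
        cohort = _cohort_from_dict(cohort_d)

    def _mk(cls, key):
        return cls(**data.get(key, {}))

    clf_d = dict(data.get("classifier", {}))
    for tup_key in ("feature_set", "hidden_sizes"):
        if tup_key in clf_d:
            clf_d[tup_key] = tuple(clf_d[tup_key])
    clf = ClassifierConfig(seed=stage_seed(g_seed, "train"), **clf_d)
    return RunConfig(
        cohort=cohort,
        signal_prep=_mk(SignalPrepConfig, "signal_prep"),
        onset=_mk(OnsetConfig, "onset"),
        movement_units=_mk(MovementUnitConfig, "movement_units"),
        classifier=clf,
        stats_alpha=float(data.get("stats_alpha", 0.05)),
        stats_q=float(data.get("stats_q", 0.05)),
        seed=g_seed,
    )
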