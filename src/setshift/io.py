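"""Trial-log and metric-table IO, run configuration, and orchestration.

The interchange format is a UTF-8 CSV with a header row and '.' decimals;
object features are serialized as ``dimension=value`` pairs joined by ``|``,
objects by ``;``.  ``run_experiment`` simulates every scheduled session,
computes the metric tables, runs the dose contrasts and writes a provenance
record so identical configurations reproduce identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .agent import (
    TRIAL_LOG_COLUMNS,
    AgentParams,
    DoseMap,
    default_dose_map,
    simulate_session,
)
from .metrics import (
    compute_block_metrics,
    compute_session_metrics,
    speed_of_processing,
    vs_set_size_effects,
    vs_similarity_effects,
)
from .stats import condition_anova
from .task import ConfigurationError, TaskConfig, build_session_schedule

__all__ = [
    "RunConfig",
    "load_run_config",
    "write_trial_log",
    "read_trial_log",
    "validate_trial_log",
    "ValidationReport",
    "run_experiment",
    "contrast_report",
]

_STRING_COLUMNS = [
    "subject", "dose", "task", "load", "target_feature", "target_dimension",
    "switch_type", "objects", "chosen_features",
]
_INT_COLUMNS = ["session", "block", "trial_in_block", "set_size",
                "choice_index", "correct", "rewarded"]


@dataclass
class RunConfig:
    """A full synthetic experiment: who is simulated, how often, and how.

    The default session counts follow the within-subject design the tasks
    were built for: many vehicle determinations (40) against 7 determinations
    of each of three dose levels, per subject.
    """

    n_subjects: int = 4
    sessions_per_condition: dict[str, int] = field(
        default_factory=lambda: {"vehicle": 40, "0.3": 7, "1": 7, "3": 7}
    )
    seed: int = 0
    agent: AgentParams = field(default_factory=AgentParams)
    dose_map: DoseMap = field(default_factory=default_dose_map)
    task: TaskConfig = field(default_factory=TaskConfig)

    def __post_init__(self) -> None:
        for label in self.sessions_per_condition:
            if label not in self.dose_map.multipliers:
                raise ConfigurationError(
                    f"dose condition {label!r} is not defined in the dose map "
                    f"(known: {list(self.dose_map.multipliers)})"
                )

    def to_dict(self) -> dict:
        return {
            "n_subjects": self.n_subjects,
            "sessions_per_condition": dict(self.sessions_per_condition),
            "seed": self.seed,
            "agent": dataclasses.asdict(self.agent),
            "dose_map": {k: list(v) for k, v in self.dose_map.multipliers.items()},
            "task": {
                "n_frl_blocks": self.task.n_frl_blocks,
                "p_high_load": self.task.p_high_load,
                "reward_prob_target": self.task.reward_prob_target,
                "reward_prob_other": self.task.reward_prob_other,
                "feature_space": {
                    d: list(v)
                    for d, v in self.task.feature_space.values_per_dimension.items()
                },
            },
        }


def load_run_config(path: str | Path) -> RunConfig:
    """Load a run configuration from a YAML or JSON file."""
    from .task import FeatureSpace

    text = Path(path).read_text()
    raw = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
    raw = raw or {}
    kwargs: dict[str, Any] = {}
    for key in ("n_subjects", "seed"):
        if key in raw:
            kwargs[key] = int(raw[key])
    if "sessions_per_condition" in raw:
        kwargs["sessions_per_condition"] = {
            str(k): int(v) for k, v in raw["sessions_per_condition"].items()
        }
    if "agent" in raw:
        kwargs["agent"] = AgentParams(**raw["agent"])
    if "dose_map" in raw:
        kwargs["dose_map"] = DoseMap(
            {str(k): tuple(v) for k, v in raw["dose_map"].items()}
        )
    if "task" in raw:
        task_raw = dict(raw["task"])
        if "feature_space" in task_raw:
            task_raw["feature_space"] = FeatureSpace(
                {d: tuple(v) for d, v in task_raw["feature_space"].items()}
            )
        kwargs["task"] = TaskConfig(**task_raw)
    return RunConfig(**kwargs)


def write_trial_log(log: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    log.to_csv(path, index=False)
    return path


def read_trial_log(path: str | Path) -> pd.DataFrame:
    """Read a trial-log CSV, preserving string fields and dose labels exactly."""
    df = pd.read_csv(
        path,
        dtype={c: str for c in _STRING_COLUMNS},
        keep_default_na=False,
        na_values={"mean_shared_features": [""], "rt_ms": [""]},
    )
    for col in _INT_COLUMNS:
        df[col] = df[col].astype(int)
    for col in ("mean_shared_features", "rt_ms"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    return df[TRIAL_LOG_COLUMNS]


@dataclass
class ValidationReport:
    """Machine-readable trial-log validation outcome."""

    n_rows: int
    violations: list[dict]

    @property
    def ok(self) -> bool:
        return not self.violations

    def to_dict(self) -> dict:
        return {"n_rows": self.n_rows, "ok": self.ok, "violations": self.violations}


def validate_trial_log(log: pd.DataFrame | str | Path) -> ValidationReport:
    """Check schema, value ranges and block structure of a trial log.

    Range checks: rt >= 0, correct/rewarded binary, VS search set sizes in
    {3,6,9,12}.  Structure: FRL block lengths within [35, 60].  Violations
    are row- or block-indexed diagnostics.
    """
    if not isinstance(log, pd.DataFrame):
        log = read_trial_log(log)
    violations: list[dict] = []
    missing = [c for c in TRIAL_LOG_COLUMNS if c not in log.columns]
    if missing:
        return ValidationReport(len(log), [{"kind": "schema", "missing_columns": missing}])

    def _flag(mask: pd.Series, kind: str, detail: str) -> None:
        for idx in log.index[mask][:20]:
            violations.append({"kind": kind, "row": int(idx), "detail": detail})

    _flag(log["rt_ms"] < 0, "range", "negative response time")
    _flag(~log["correct"].isin([0, 1]), "range", "correct not in {0,1}")
    _flag(~log["rewarded"].isin([0, 1]), "range", "rewarded not in {0,1}")
    vs = log["task"] == "VS"
    _flag(vs & ~log["set_size"].isin([3, 6, 9, 12]), "range",
          "VS search set size not in {3,6,9,12}")
    frl = log[log["task"] == "FRL"]
    for (subject, session, block), grp in frl.groupby(["subject", "session", "block"]):
        n = len(grp)
        if not 35 <= n <= 60:
            violations.append(
                {
                    "kind": "structure",
                    "subject": str(subject),
                    "session": int(session),
                    "block": int(block),
                    "detail": f"FRL block length {n} outside [35, 60]",
                }
            )
        expected = np.arange(1, n + 1)
        if not np.array_equal(np.sort(grp["trial_in_block"].to_numpy()), expected):
            violations.append(
                {
                    "kind": "structure",
                    "subject": str(subject),
                    "session": int(session),
                    "block": int(block),
                    "detail": "trial_in_block is not contiguous from 1",
                }
            )
    return ValidationReport(len(log), violations)


def simulate_experiment(config: RunConfig) -> pd.DataFrame:
    """Simulate every scheduled session; returns the concatenated trial log.

    Per-session seeds are spawned deterministically from ``config.seed`` in a
    fixed subject x condition x repetition order.
    """
    root = np.random.SeedSequence(config.seed)
    logs = []
    for s in range(config.n_subjects):
        subject = f"subject_{s + 1}"
        session_index = 0
        for condition, n_sessions in config.sessions_per_condition.items():
            for _ in range(n_sessions):
                sched_seed, sim_seed = root.spawn(1)[0].generate_state(2)
                schedule = build_session_schedule(
                    config.task,
                    seed=int(sched_seed % 2**31),
                    subject_id=subject,
                    dose_condition=condition,
                    session=session_index,
                )
                logs.append(
                    simulate_session(
                        schedule, config.agent, config.dose_map,
                        seed=int(sim_seed % 2**31),
                    )
                )
                session_index += 1
    return pd.concat(logs, ignore_index=True)


#: Session-level metrics contrasted across dose conditions in the report.
CONTRAST_METRICS = [
    "median_ttc", "median_ttc_low", "median_ttc_high",
    "criterion_reached_prop", "plateau_accuracy", "mean_rt_correct",
    "persev_target", "persev_distractor",
]


def contrast_report(session_metrics: pd.DataFrame) -> tuple[pd.DataFrame, str]:
    """Dose-condition ANOVA for each session-level metric.

    Returns a tidy table (one row per metric x condition) and a text report
    in the caption style.
    """
    rows, texts = [], []
    for metric in CONTRAST_METRICS:
        if metric not in session_metrics.columns:
            continue
        sub = session_metrics.dropna(subset=[metric])
        if sub["dose"].nunique() < 2 or sub.groupby("dose")[metric].count().min() < 2:
            continue
        contrast = condition_anova(sub, metric)
        texts.append(contrast.summary())
        for cond in contrast.conditions:
            rows.append(
                {
                    "metric": metric,
                    "condition": cond,
                    "mean": contrast.means[cond],
                    "sem": contrast.sems[cond],
                    "n": contrast.ns[cond],
                    "F": contrast.f_stat,
                    "df1": contrast.df_between,
                    "df2": contrast.df_within,
                    "p": contrast.p_value,
                    "eta_squared": contrast.eta_squared,
                    "tukey_p_vs_vehicle": contrast.tukey_p_vs_vehicle.get(cond, np.nan),
                    "cohens_d_vs_vehicle": contrast.cohens_d_vs_vehicle.get(cond, np.nan),
                }
            )
    return pd.DataFrame(rows), "\n\n".join(texts)


def run_experiment(config: RunConfig, out_dir: str | Path) -> Path:
    """Simulate, analyze and contrast a full experiment into ``out_dir``.

    Writes per-session trial logs, block/session metric tables, VS summaries,
    the contrast report (CSV and text) and a provenance record (config hash,
    seed, version).
    """
    out = Path(out_dir)
    (out / "trial_logs").mkdir(parents=True, exist_ok=True)
    (out / "metrics").mkdir(exist_ok=True)

    log = simulate_experiment(config)
    for (subject, session), grp in log.groupby(["subject", "session"]):
        dose = grp["dose"].iloc[0]
        write_trial_log(
            grp.reset_index(drop=True),
            out / "trial_logs" / f"{subject}_session{int(session):03d}_{dose}.csv",
        )

    report = validate_trial_log(log)
    if not report.ok:
        raise RuntimeError(f"simulation stage produced an invalid log: {report.violations[:3]}")

    block_metrics = compute_block_metrics(log)
    session_metrics = compute_session_metrics(log)
    per_size, slopes = vs_set_size_effects(log)
    similarity = vs_similarity_effects(log)
    processing = speed_of_processing(log)
    block_metrics.to_csv(out / "metrics" / "block_metrics.csv", index=False)
    session_metrics.to_csv(out / "metrics" / "session_metrics.csv", index=False)
    per_size.to_csv(out / "metrics" / "vs_per_set_size.csv", index=False)
    slopes.to_csv(out / "metrics" / "vs_set_size_slopes.csv", index=False)
    similarity.to_csv(out / "metrics" / "vs_similarity.csv", index=False)
    processing.to_csv(out / "metrics" / "vs_speed_of_processing.csv", index=False)

    contrast_table, contrast_text = contrast_report(session_metrics)
    contrast_table.to_csv(out / "contrasts.csv", index=False)
    (out / "contrasts.txt").write_text(contrast_text + "\n")

    config_dict = config.to_dict()
    provenance = {
        "package_version": __version__,
        "seed": config.seed,
        "config": config_dict,
        "config_sha256": hashlib.sha256(
            json.dumps(config_dict, sort_keys=True).encode()
        ).hexdigest(),
        "n_sessions": int(log.groupby(["subject", "session"]).ngroups),
        "n_trials": int(len(log)),
    }
    (out / "provenance.json").write_text(json.dumps(provenance, indent=2) + "\n")
    return out
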