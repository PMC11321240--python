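"""On-disk dataset layout and the simulate/analyze/pipeline runners.

A dataset directory holds plain, diff-able text:

    config.yaml                 configuration echo (provenance)
    session.csv                 one row of trial metadata per trial
    trials/<id>_emg.csv         sample, agonist, antagonist   (EMG rate)
    trials/<id>_mocap.csv       sample, wrist_x, wrist_y, elbow_x, elbow_y

Raw signals are written with enough digits that offline onset detection
reproduces the closed-loop result exactly.
"""

from __future__ import annotations

import logging
import time
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd

from . import signals, stats, workflow
from .config import RunConfig
from .errors import SchemaError
from .protocol import PullCommand
from .synthetic import TrialRecord, iter_cohort

log = logging.getLogger(__name__)

SESSION_COLUMNS = [
    "participant", "block_index", "condition", "phase", "trial_in_block",
    "cue_time", "cue_index", "emg_rate", "mocap_rate", "rest_start", "rest_stop",
    "rest_max", "threshold", "onset_index", "true_onset_index", "missed_trigger",
    "pull_start", "pull_duration", "pull_direction", "trial_id",
]


def _trial_id(trial: TrialRecord) -> str:
    return f"{trial.participant_id}_b{trial.block_index}_t{trial.trial_in_block:02d}"


def write_dataset(config: RunConfig, out_dir: str | Path) -> Path:
    """Simulate the configured cohort and write it to out_dir."""
    out = Path(out_dir)
    trials_dir = out / "trials"
    trials_dir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")

    params = config.effective_generator()
    rows = []
    t0 = time.perf_counter()
    for _, trial in iter_cohort(params):
        tid = _trial_id(trial)
        emg = pd.DataFrame(
            {
                "sample": np.arange(trial.agonist_emg.size),
                "agonist": trial.agonist_emg,
                "antagonist": trial.antagonist_emg,
            }
        )
        emg.to_csv(trials_dir / f"{tid}_emg.csv", index=False, float_format="%.10g")
        mocap = pd.DataFrame(
            {
                "sample": np.arange(trial.wrist_xy.shape[0]),
                "wrist_x": trial.wrist_xy[:, 0],
                "wrist_y": trial.wrist_xy[:, 1],
                "elbow_x": trial.elbow_xy[:, 0],
                "elbow_y": trial.elbow_xy[:, 1],
            }
        )
        mocap.to_csv(trials_dir / f"{tid}_mocap.csv", index=False, float_format="%.10g")
        rows.append(
            {
                "participant": trial.participant_id,
                "block_index": trial.block_index,
                "condition": trial.condition,
                "phase": trial.phase,
                "trial_in_block": trial.trial_in_block,
                "cue_time": trial.cue_time,
                "cue_index": trial.cue_index,
                "emg_rate": trial.emg_rate,
                "mocap_rate": trial.mocap_rate,
                "rest_start": trial.rest_window[0],
                "rest_stop": trial.rest_window[1],
                "rest_max": trial.detection.rest_max,
                "threshold": trial.detection.threshold,
                "onset_index": trial.detection.onset_index,
                "true_onset_index": trial.true_onset_index,
                "missed_trigger": trial.missed_trigger,
                "pull_start": trial.pull.start_time if trial.pull else np.nan,
                "pull_duration": trial.pull.duration if trial.pull else np.nan,
                "pull_direction": trial.pull.direction if trial.pull else 0,
                "trial_id": _trial_id(trial),
            }
        )
    session = pd.DataFrame(rows, columns=SESSION_COLUMNS)
    session.to_csv(out / "session.csv", index=False, float_format="%.10g")
    log.info("wrote %d trials to %s in %.1f s", len(session), out, time.perf_counter() - t0)
    return out


def read_session(data_dir: str | Path) -> pd.DataFrame:
    """Load and validate session.csv."""
    path = Path(data_dir) / "session.csv"
    if not path.exists():
        raise SchemaError(f"missing session file: {path}")
    session = pd.read_csv(path)
    missing = [c for c in SESSION_COLUMNS if c not in session.columns]
    if missing:
        raise SchemaError(f"{path} is missing column(s): {missing}")
    if session.empty:
        raise SchemaError(f"{path} contains no trials")
    return session


def iter_trials(data_dir: str | Path) -> Iterator[TrialRecord]:
    """Stream TrialRecords back from a dataset directory."""
    data_dir = Path(data_dir)
    session = read_session(data_dir)
    for _, row in session.iterrows():
        emg_path = data_dir / "trials" / f"{row.trial_id}_emg.csv"
        mocap_path = data_dir / "trials" / f"{row.trial_id}_mocap.csv"
        for path, cols in (
            (emg_path, ["agonist", "antagonist"]),
            (mocap_path, ["wrist_x", "wrist_y", "elbow_x", "elbow_y"]),
        ):
            if not path.exists():
                raise SchemaError(f"missing trial file: {path}")
        emg = pd.read_csv(emg_path)
        mocap = pd.read_csv(mocap_path)
        for path, frame, cols in (
            (emg_path, emg, ["agonist", "antagonist"]),
            (mocap_path, mocap, ["wrist_x", "wrist_y", "elbow_x", "elbow_y"]),
        ):
            missing = [c for c in cols if c not in frame.columns]
            if missing:
                raise SchemaError(f"{path} is missing column(s): {missing}")
        pull = None
        if np.isfinite(row.pull_start):
            pull = PullCommand(
                start_time=float(row.pull_start),
                duration=float(row.pull_duration),
                direction=int(row.pull_direction),
            )
        yield TrialRecord(
            participant_id=str(row.participant),
            condition=str(row.condition),
            phase=str(row.phase),
            block_index=int(row.block_index),
            trial_in_block=int(row.trial_in_block),
            cue_time=float(row.cue_time),
            emg_rate=float(row.emg_rate),
            mocap_rate=float(row.mocap_rate),
            cue_index=int(row.cue_index),
            agonist_emg=emg["agonist"].to_numpy(),
            antagonist_emg=emg["antagonist"].to_numpy(),
            wrist_xy=mocap[["wrist_x", "wrist_y"]].to_numpy(),
            elbow_xy=mocap[["elbow_x", "elbow_y"]].to_numpy(),
            pull=pull,
            true_onset_index=None if pd.isna(row.true_onset_index) else int(row.true_onset_index),
            rest_window=(int(row.rest_start), int(row.rest_stop)),
            detection=signals.DetectionResult(
                rest_max=float(row.rest_max),
                threshold=float(row.threshold),
                onset_index=None if pd.isna(row.onset_index) else int(row.onset_index),
            ),
            missed_trigger=bool(row.missed_trigger),
        )


def run_simulate(config: RunConfig, out_dir: str | Path) -> Path:
    """Write the configured synthetic cohort to disk."""
    return write_dataset(config, out_dir)


def run_analyze(data_dir: str | Path, out_dir: str | Path, alpha: float = 0.05) -> dict:
    """Analyze a dataset directory: metrics, models, summary, report."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    metrics = workflow.metrics_table(iter_trials(data_dir))
    metrics.to_csv(out / "metrics.csv", index=False)
    summary = workflow.condition_summary(metrics)
    summary.to_csv(out / "condition_summary.csv", index=False)

    models = stats.analyze_outcomes(metrics)
    if models:
        workflow.recovered_effects(models).to_csv(out / "contrasts.csv", index=False)
        lrt = pd.DataFrame(
            [
                {
                    "outcome": m.outcome,
                    "lrt_chi2": m.lrt_chi2,
                    "lrt_df": m.lrt_df,
                    "lrt_p": m.lrt_p,
                    "n_participants": m.n_participants,
                }
                for m in models.values()
            ]
        )
        lrt.to_csv(out / "lrt.csv", index=False)
    (out / "report.txt").write_text(format_report(metrics, models, alpha))
    try:
        from .viz import plot_condition_summary

        plot_condition_summary(metrics, out / "condition_summary.png")
    except Exception as exc:  # plotting must never sink an analysis run
        log.warning("summary figure not written: %s", exc)
    return {"metrics": metrics, "models": models, "summary": summary, "out_dir": out}


def run_pipeline(config: RunConfig, out_dir: str | Path) -> dict:
    """Simulate then analyze, under one output directory."""
    out = Path(out_dir)
    data_dir = write_dataset(config, out / "dataset")
    return run_analyze(data_dir, out / "analysis", alpha=config.alpha)


def format_report(metrics: pd.DataFrame, models: dict, alpha: float) -> str:
    """Plain-text analysis report."""
    lines = ["emdassist analysis report", "=" * 60, ""]
    lines.append(f"trials analyzed: {len(metrics)}")
    lines.append(f"missed triggers: {int(metrics['missed_trigger'].sum())}")
    lines.append("")
    summary = workflow.condition_summary(metrics)
    lines.append("condition means (pulled-phase trials, mean +/- SD):")
    lines.append(summary.to_string(index=False, float_format=lambda v: f"{v:.3f}"))
    lines.append("")
    if not models:
        lines.append("statistics skipped: fewer than 2 conditions present")
        return "\n".join(lines) + "\n"
    for name, res in models.items():
        lines.append(f"outcome: {name}")
        lines.append(
            f"  condition LRT: chi2({res.lrt_df}, n={res.n_participants}) = "
            f"{res.lrt_chi2:.2f}, p = {res.lrt_p:.4g}"
        )
        for _, row in res.contrasts.iterrows():
            star = "*" if row.holm_p < alpha else " "
            lines.append(
                f"  {star} {row.condition_a:>15s} vs {row.condition_b:<15s} "
                f"est = {row.estimate:9.3f} (SE {row.se:.3f}), "
                f"diff = {row.percent_difference:8.2f}%, "
                f"p = {row.raw_p:.4g}, holm p = {row.holm_p:.4g}"
            )
        lines.append("")
    return "\n".join(lines) + "\n"
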