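"""End-to-end runs: cohort simulation -> tidy metrics -> mixed models.

These functions stream trials one at a time, so full-size cohorts never
hold all raw signals in memory; only the per-trial metric rows are kept.
"""

from __future__ import annotations

import logging
import time
from typing import Iterable

import numpy as np
import pandas as pd

from . import signals, stats, synthetic
from .errors import NormalizationError
from .synthetic import GeneratorParams, TrialRecord

log = logging.getLogger(__name__)


def features_table(trials: Iterable[TrialRecord]) -> pd.DataFrame:
    """Raw per-trial features (un-normalized peaks) as a tidy table."""
    return pd.DataFrame([signals.trial_features(t) for t in trials])


def metrics_table(trials: Iterable[TrialRecord]) -> pd.DataFrame:
    """Tidy per-trial metrics with control-normalized EMG peaks.

    Peaks are normalized per participant and per muscle to the mean peak
    over that participant's pulled-phase control trials.  Participants
    without usable control trials cannot be normalized and raise.
    """
    raw = features_table(trials)
    return normalize_metrics(raw)


def normalize_metrics(raw: pd.DataFrame) -> pd.DataFrame:
    """Attach normalized peak columns to a raw features table."""
    out = raw.copy()
    out["peak_agonist_norm"] = np.nan
    out["peak_antagonist_norm"] = np.nan
    for pid, grp in raw.groupby("participant"):
        control = grp[(grp["condition"] == "control") & (grp["phase"] == "pulled")]
        control = control[control["peak_agonist"].notna()]
        if control.empty:
            raise NormalizationError(f"participant {pid} has no usable control trials")
        for muscle in ("agonist", "antagonist"):
            ref = control[f"peak_{muscle}"].to_numpy()
            idx = grp.index[grp[f"peak_{muscle}"].notna()]
            out.loc[idx, f"peak_{muscle}_norm"] = signals.normalize_peaks(
                raw.loc[idx, f"peak_{muscle}"].to_numpy(), ref
            )
    return out


def cohort_metrics(params: GeneratorParams) -> pd.DataFrame:
    """Simulate a cohort and compute its tidy metrics table, streaming."""
    t0 = time.perf_counter()
    rows = []
    for _, trial in synthetic.iter_cohort(params):
        rows.append(signals.trial_features(trial))
    raw = pd.DataFrame(rows)
    out = normalize_metrics(raw)
    log.info(
        "cohort seed=%s: %d trials in %.1f s (%.1f%% missed triggers)",
        params.seed,
        len(out),
        time.perf_counter() - t0,
        100.0 * out["missed_trigger"].mean(),
    )
    return out


def cohort_models(params: GeneratorParams) -> dict[str, stats.ModelResult]:
    """Full pipeline on one synthetic cohort: metrics plus all four models."""
    return stats.analyze_outcomes(cohort_metrics(params))


def condition_summary(metrics: pd.DataFrame) -> pd.DataFrame:
    """Mean and SD per condition for each outcome, pulled-phase trials."""
    pulled = metrics[metrics["phase"] == "pulled"]
    pieces = []
    for outcome in stats.OUTCOME_COLUMNS:
        if outcome not in pulled.columns:
            continue
        g = pulled.groupby("condition", observed=True)[outcome].agg(["mean", "std", "count"])
        g.insert(0, "outcome", outcome)
        pieces.append(g.reset_index())
    return pd.concat(pieces, ignore_index=True)


def recovered_effects(models: dict[str, stats.ModelResult]) -> pd.DataFrame:
    """Percent differences and contrast estimates, one row per pair/outcome."""
    frames = []
    for outcome, res in models.items():
        tab = res.contrasts.copy()
        tab.insert(0, "outcome", outcome)
        tab["lrt_chi2"] = res.lrt_chi2
        tab["lrt_p"] = res.lrt_p
        frames.append(tab)
    return pd.concat(frames, ignore_index=True)


def contrast_value(
    models: dict[str, stats.ModelResult],
    outcome: str,
    cond_a: str,
    cond_b: str,
    column: str = "percent_difference",
) -> float:
    """Look up one contrast (cond_a vs cond_b) from a model-result set.

    Antisymmetric columns (estimate, percent difference via sign flip on
    the estimate scale) are returned with cond_a as the first member even
    if the stored row has the opposite orientation.
    """
    tab = models[outcome].contrasts
    row = tab[(tab["condition_a"] == cond_a) & (tab["condition_b"] == cond_b)]
    if len(row) == 1:
        return float(row[column].iloc[0])
    row = tab[(tab["condition_a"] == cond_b) & (tab["condition_b"] == cond_a)]
    if len(row) != 1:
        raise KeyError(f"no contrast {cond_a} vs {cond_b} for outcome {outcome}")
    if column == "estimate":
        return -float(row[column].iloc[0])
    emms = models[outcome].emms
    if column == "percent_difference":
        return stats.percent_difference(emms[cond_a], emms[cond_b])
    raise KeyError(f"cannot reorient column {column!r}")
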