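"""Summary bar figures for per-condition outcomes."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from . import stats, workflow


def plot_condition_summary(metrics, path) -> None:
    """Bar chart of mean +/- SD per condition for each outcome."""
    summary = workflow.condition_summary(metrics)
    outcomes = [o for o in stats.OUTCOME_COLUMNS if o in set(summary["outcome"])]
    fig, axes = plt.subplots(1, len(outcomes), figsize=(4 * len(outcomes), 3.5))
    if len(outcomes) == 1:
        axes = [axes]
    for ax, outcome in zip(axes, outcomes):
        sub = summary[summary["outcome"] == outcome]
        ax.bar(sub["condition"], sub["mean"], yerr=sub["std"].fillna(0.0), capsize=3)
        ax.set_title(stats.OUTCOME_COLUMNS[outcome], fontsize=9)
        ax.tick_params(axis="x", rotation=60, labelsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
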