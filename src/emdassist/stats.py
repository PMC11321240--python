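"""Mixed-model inference on per-trial outcomes.

Each outcome (normalized agonist peak, normalized antagonist peak, peak
angular velocity, reaction time) is modelled at the trial level with a
linear mixed model: fixed effects for condition (five levels, control as
reference) and for the order in which the condition block occurred
(numeric 1-5 covariate), and a participant random intercept absorbing
within-subject correlation.  The condition main effect is tested with a
likelihood-ratio test (df = 4) between maximum-likelihood fits with and
without the condition term.  All ten pairwise condition contrasts are
formed from the fitted fixed effects; their p-values are Holm-adjusted as
a family, and percent differences are reported from estimated marginal
means.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy import stats as sct
from statsmodels.stats.multitest import multipletests
from statsmodels.tools.sm_exceptions import ConvergenceWarning

from .errors import DegenerateDataError, InputError
from .protocol import NON_PASSIVE_CONDITIONS

OUTCOME_COLUMNS = {
    "peak_agonist_norm": "normalized agonist peak (% control)",
    "peak_antagonist_norm": "normalized antagonist peak (% control)",
    "peak_angular_velocity": "peak angular velocity (rad/s)",
    "reaction_time_ms": "reaction time (ms)",
}

DEFAULT_ALPHA = 0.05


def build_outcome_table(metrics: pd.DataFrame, outcome: str) -> pd.DataFrame:
    """Restrict a tidy metrics table to one outcome's analyzable rows.

    Keeps pulled-phase trials of the five non-passive conditions, drops
    missed-trigger/undefined values, and attaches the numeric order
    covariate (1-based block position).
    """
    if outcome not in metrics.columns:
        raise InputError(f"outcome column {outcome!r} missing from metrics table")
    rows = metrics[
        (metrics["phase"] == "pulled")
        & metrics["condition"].isin(NON_PASSIVE_CONDITIONS)
        & metrics[outcome].notna()
    ]
    table = pd.DataFrame(
        {
            "participant": rows["participant"],
            "condition": pd.Categorical(rows["condition"], categories=NON_PASSIVE_CONDITIONS),
            "order": rows["block_index"].astype(float) + 1.0,
            "value": rows[outcome].astype(float),
        }
    ).reset_index(drop=True)
    if table["condition"].isna().any():
        raise InputError("metrics table contains unknown condition labels")
    if table["participant"].nunique() < 2:
        raise InputError("at least 2 participants are required for a mixed model")
    return table


@dataclass
class ModelResult:
    """Per-outcome fit: likelihood-ratio test and pairwise contrast table."""

    outcome: str
    lrt_chi2: float
    lrt_df: int
    lrt_p: float
    n_participants: int
    emms: pd.Series
    contrasts: pd.DataFrame


def fit_outcome_model(table: pd.DataFrame):
    """Fit the trial-level mixed model for one outcome by ML.

    Returns (full fit, reduced fit without condition).  Zero-variance
    outcome data raise DegenerateDataError; boundary (zero random-effect
    variance) fits proceed with a warning from statsmodels suppressed, as
    the profiled likelihood remains valid for the LRT.
    """
    if np.ptp(table["value"].to_numpy()) == 0:
        raise DegenerateDataError("outcome values are all identical")
    levels = [c for c in NON_PASSIVE_CONDITIONS if c in set(table["condition"].astype(str))]
    data = table.assign(condition=pd.Categorical(table["condition"], categories=levels))
    full = _fit_ml(smf.mixedlm("value ~ C(condition) + order", data, groups=data["participant"]))
    reduced = _fit_ml(smf.mixedlm("value ~ order", data, groups=data["participant"]))
    return full, reduced


def _fit_ml(model):
    """ML fit with an optimizer cascade for stubborn likelihood surfaces."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", UserWarning)
        warnings.simplefilter("ignore", RuntimeWarning)
        result = None
        for method in (None, "lbfgs", "cg", "powell"):
            kwargs = {} if method is None else {"method": method}
            try:
                candidate = model.fit(reml=False, **kwargs)
            except Exception:
                continue
            if np.isfinite(candidate.llf):
                if result is None or candidate.llf > result.llf + 1e-9:
                    result = candidate
                if result is not None and method is None:
                    break
        if result is None:
            raise DegenerateDataError("mixed model likelihood could not be maximized")
    return result


def likelihood_ratio_test(full, reduced, df: int) -> tuple[float, float]:
    """Chi-square LRT statistic and p-value for nested ML fits."""
    stat = max(2.0 * (full.llf - reduced.llf), 0.0)
    return stat, float(sct.chi2.sf(stat, df))


def estimated_marginal_means(full, table: pd.DataFrame) -> pd.Series:
    """Model-based condition means with the order covariate at its mean."""
    levels = list(table["condition"].cat.categories)
    params = full.fe_params
    mean_order = float(table["order"].mean())
    emms = {}
    for lev in levels:
        emm = params["Intercept"] + mean_order * params.get("order", 0.0)
        key = f"C(condition)[T.{lev}]"
        if key in params:
            emm += params[key]
        emms[lev] = emm
    return pd.Series(emms, name="emm")


def percent_difference(emm_a: float, emm_b: float) -> float:
    """(EMM_A - EMM_B) / EMM_B x 100; the reference EMM must be positive."""
    if not emm_b > 0:
        raise InputError(f"reference marginal mean must be positive, got {emm_b}")
    return (emm_a - emm_b) / emm_b * 100.0


def pairwise_contrasts(full, table: pd.DataFrame) -> pd.DataFrame:
    """All pairwise condition contrasts with Holm-adjusted p-values.

    Estimates and standard errors come from the fitted fixed effects and
    their covariance; raw p-values are two-sided Wald z-tests.  The percent
    difference column uses estimated marginal means, reference = second
    member of the pair.
    """
    levels = list(table["condition"].cat.categories)
    params = full.fe_params
    cov = full.cov_params().loc[params.index, params.index]
    emms = estimated_marginal_means(full, table)

    def coef_vector(level: str) -> np.ndarray:
        v = np.zeros(len(params))
        key = f"C(condition)[T.{level}]"
        if key in params.index:
            v[params.index.get_loc(key)] = 1.0
        return v

    rows = []
    for a, b in itertools.combinations(levels, 2):
        c = coef_vector(a) - coef_vector(b)
        est = float(c @ params.to_numpy())
        se = float(np.sqrt(c @ cov.to_numpy() @ c))
        z = est / se if se > 0 else np.inf
        p = float(2.0 * sct.norm.sf(abs(z)))
        rows.append((a, b, est, se, z, p, percent_difference(emms[a], emms[b])
                     if emms[b] > 0 else np.nan))
    out = pd.DataFrame(
        rows,
        columns=["condition_a", "condition_b", "estimate", "se", "z", "raw_p", "percent_difference"],
    )
    out["holm_p"] = multipletests(out["raw_p"].to_numpy(), method="holm")[1]
    return out


def analyze_outcome(metrics: pd.DataFrame, outcome: str) -> ModelResult:
    """Model one outcome end to end: build table, fit, test, contrast."""
    table = build_outcome_table(metrics, outcome)
    full, reduced = fit_outcome_model(table)
    df = len(table["condition"].cat.categories) - 1
    stat, p = likelihood_ratio_test(full, reduced, df)
    return ModelResult(
        outcome=outcome,
        lrt_chi2=stat,
        lrt_df=df,
        lrt_p=p,
        n_participants=int(table["participant"].nunique()),
        emms=estimated_marginal_means(full, table),
        contrasts=pairwise_contrasts(full, table),
    )


def analyze_outcomes(metrics: pd.DataFrame, outcomes=tuple(OUTCOME_COLUMNS)) -> dict[str, ModelResult]:
    """Fit every outcome's model; returns {outcome: ModelResult}."""
    pulled = metrics[(metrics["phase"] == "pulled")
                     & metrics["condition"].isin(NON_PASSIVE_CONDITIONS)]
    if pulled["condition"].nunique() < 2:
        warnings.warn("fewer than 2 conditions present; statistics skipped", stacklevel=2)
        return {}
    return {outcome: analyze_outcome(metrics, outcome) for outcome in outcomes}


def simulate_null_outcome_table(
    n_participants: int = 14,
    trials_per_cell: int = 8,
    participant_sd: float = 20.0,
    residual_sd: float = 35.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Outcome table with no condition effect (mixed-model null).

    Value = 100 + participant intercept + residual noise; condition order
    is randomized per participant as in a real session.  This is the
    model-level null used for likelihood-ratio-test calibration at large
    replicate counts.
    """
    rng = np.random.default_rng(seed)
    frames = []
    for i in range(n_participants):
        b = rng.normal(0.0, participant_sd)
        order = rng.permutation(len(NON_PASSIVE_CONDITIONS)) + 1
        for c, cond in enumerate(NON_PASSIVE_CONDITIONS):
            frames.append(
                pd.DataFrame(
                    {
                        "participant": f"P{i + 1:02d}",
                        "condition": cond,
                        "order": float(order[c]),
                        "value": 100.0 + b + rng.normal(0.0, residual_sd, trials_per_cell),
                    }
                )
            )
    table = pd.concat(frames, ignore_index=True)
    table["condition"] = pd.Categorical(table["condition"], categories=NON_PASSIVE_CONDITIONS)
    return table


def lrt_type1_rate(
    n_reps: int = 1000,
    n_participants: int = 14,
    trials_per_cell: int = 8,
    alpha: float = DEFAULT_ALPHA,
    seed: int = 0,
) -> float:
    """Monte-Carlo type-I error of the condition LRT under the null."""
    rejections = 0
    for r in range(n_reps):
        table = simulate_null_outcome_table(
            n_participants=n_participants, trials_per_cell=trials_per_cell, seed=seed + r
        )
        full, reduced = fit_outcome_model(table)
        _, p = likelihood_ratio_test(full, reduced, df=4)
        rejections += p < alpha
    return rejections / n_reps
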