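"""Fit the mixed models and report Holm-adjusted pairwise contrasts.

Simulates a six-participant cohort, fits the trial-level linear mixed
model (condition + block order fixed effects, participant random
intercept) for each outcome, and prints the likelihood-ratio test and
every condition's effect against control.
"""

from emdassist import GeneratorParams, cohort_models
from emdassist.protocol import NON_PASSIVE_CONDITIONS
from emdassist.workflow import contrast_value

models = cohort_models(GeneratorParams(n_participants=6, seed=15))
for name, res in models.items():
    print(f"\n{name}: LRT chi2({res.lrt_df}, n={res.n_participants}) = "
          f"{res.lrt_chi2:.1f}, p = {res.lrt_p:.2g}")
    for cond in NON_PASSIVE_CONDITIONS[1:]:
        if name == "reaction_time_ms":
            effect = f"{contrast_value(models, name, cond, 'control', 'estimate'):+7.2f} ms"
        else:
            effect = f"{contrast_value(models, name, cond, 'control'):+7.2f}%"
        row = res.contrasts[(res.contrasts.condition_a == "control")
                            & (res.contrasts.condition_b == cond)]
        print(f"  {cond:16s} vs control: {effect}  (holm p = {row.holm_p.iloc[0]:.3g})")

# Expected pattern: rapid assistance raises agonist peaks ~69% above
# control; perturbations raise both muscles' peaks and cut peak angular
# velocity by ~40%; reaction-time shifts are a few tens of ms.
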