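# emdassist

Simulation and analysis of **robotic assistance delivered inside the
electromechanical delay** — the ~40 ms between the onset of muscle
electrical activation (surface EMG) and the onset of mechanical motion.

A cable actuator watches the triceps EMG of a person performing cued
rapid arm extensions.  The moment a raw squared EMG sample rises 1% above
the maximum squared EMG of the preceding rest period, the actuator pulls
the arm — in the extension direction ("assistance", 0.31 s) or the
flexion direction ("perturbation", 0.1 s), either immediately ("rapid",
~23 ms total trigger latency) or with a 40 ms artificial delay
("delayed").  Because the rapid pull starts before the muscle itself can
move, the arm is in motion *within* the electromechanical delay.  The
striking consequence this framework measures: rapid assistance *raises*
subsequent voluntary agonist activation by roughly 69% over unassisted
extension, where conventional robotic assistance lowers it.

The package is for researchers in rehabilitation robotics and motor
control who want a fully testable, end-to-end reimplementation of this
closed loop: protocol, trigger, synthetic cohorts with known ground
truth, signal pipeline and statistics.

## What it contains

- `emdassist.protocol` — the six experimental conditions, randomized
  session schedules (10/30/10-trial blocks, 5–15 s cues, passive last),
  and actuator pull commands (40 rad/s drum, 0.79 m/s rope).
- `emdassist.synthetic` — a closed-loop cohort generator: rest-noise +
  envelope-modulated EMG bursts, the detector running in the loop,
  triggered pulls injected into planar wrist/elbow kinematics at 200 Hz,
  and condition effects embedded as recoverable ground truth.
- `emdassist.signals` — the detection rule (threshold = 1.01 × rest
  maximum of squared EMG), the published envelope (rectify → 20 Hz
  high-pass → 10 Hz low-pass, zero-phase Butterworth), 200 ms post-onset
  peak extraction, control normalization, marker-based angular velocity,
  reaction time.
- `emdassist.stats` — trial-level linear mixed models (condition + block
  order fixed effects, participant random intercept), likelihood-ratio
  tests, and all-pairwise Holm-adjusted contrasts with percent
  differences from estimated marginal means.
- `emdassist.datasets` / CLI — plain-text dataset layout and
  `emdassist simulate|analyze|pipeline` commands.

## Worked example

Simulate one rapid-assistance trial and look at the trigger timeline
(`examples/02_closed_loop_trial.py`):

```
rest-period max squared EMG : 15.453
onset threshold (1% above)  : 15.608
true EMG onset              :   157.5 ms after cue
detected EMG onset          :   163.0 ms after cue
actuator pull start         :   183.0 ms after cue
muscle contraction expected :   197.5 ms after cue

the pull starts 14.5 ms BEFORE the muscle itself would move:
assistance is delivered inside the electromechanical delay.
```

The detector fires 5.5 ms after the burst begins; with the 20 ms
closed-loop actuation lag the pull is moving the arm 14.5 ms before the
end of the electromechanical delay.

Run the full pipeline on a six-participant synthetic cohort
(`examples/04_mixed_model_contrasts.py`):

```
peak_agonist_norm: LRT chi2(4, n=6) = 397.0, p = 1.2e-84
  rapid_assist     vs control:  +74.83%  (holm p = 1.72e-43)
  delayed_assist   vs control:  +32.41%  (holm p = 2.61e-08)
  rapid_perturb    vs control:  +92.96%  (holm p = 9.42e-60)
  delayed_perturb  vs control: +100.94%  (holm p = 2.46e-76)
...
reaction_time_ms: LRT chi2(4, n=6) = 155.6, p = 1.3e-32
  rapid_assist     vs control:  -22.56 ms  (holm p = 5.42e-11)
  delayed_perturb  vs control:  +19.88 ms  (holm p = 1.57e-08)
```

Agonist peaks under rapid assistance sit ~69–75% above control (the
generator's embedded truth is +68.97%); perturbations roughly double both
muscles' activation while cutting peak angular velocity by ~38–40%; and
rapid assistance shortens reaction time while delayed perturbation
lengthens it.  Each `examples/*.py` script is a short narrative: build a
small input, run one capability, print what the numbers mean.

A shell-level run of the same pipeline:

```
emdassist pipeline --seed 1 --out results/run1
```

writes the dataset, per-trial metrics, contrast tables and a plain-text
report under `results/run1/`.

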