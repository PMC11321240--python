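# Methods

`emdassist` simulates and analyzes a closed-loop experiment in which a
cable actuator assists or perturbs a cued rapid arm extension within the
electromechanical delay (EMD) — the ~40 ms lag between the onset of
muscle electrical activation and the onset of mechanical motion.  This
note documents the model, its parameters, the numerical choices, and what
the synthetic cohorts can and cannot show about real data.

## Experimental model

Six conditions are defined by pull direction, pull duration and trigger
timing: `control` (no pull), `rapid_assist` / `delayed_assist`
(extension-direction pulls of 0.31 s), `rapid_perturb` /
`delayed_perturb` (flexion-direction pulls of 0.1 s), and `passive`
(assistive pull with no voluntary extension).  "Rapid" pulls are released
at the system's fastest post-onset latency; "delayed" pulls add a 40 ms
artificial delay.  Every pull rotates the actuator drum at 40 rad/s
(rope retraction 0.79 m/s at the 19.75 mm drum radius).

A session is five (or six, with passive last) condition blocks of 50
trials each — 10 unpulled lead-in, 30 pulled, 10 unpulled tail — with the
non-passive block order drawn uniformly from the 5! permutations and
inter-cue intervals drawn uniformly on [5, 15] s.  The middle 30 trials of
the control block are labelled "pulled"-phase by position so that phases
are comparable across conditions.

## Onset detection

The real-time trigger squares each raw EMG sample and compares it against
a threshold set 1% above the maximum squared EMG of the preceding rest
period; the search starts at the cue.  An all-zero rest window falls back
to a machine-epsilon threshold floor.  Detection operates on raw samples
with no smoothing.  Because the rule is an extreme-value comparison, a
small fraction of trials (~2–3% at the default rest lengths) cross the
threshold in the cue-to-onset gap before the voluntary burst; these early
triggers are retained, as the physical system would also have acted on
them, and they are the main reason the latency distribution has a heavier
left tail (SD ~17 ms) than its central mode.

## Synthetic EMG

Agonist and antagonist EMG are arbitrary-unit Gaussian processes: rest is
white noise with standard deviation `rest_noise_sd` (default 1); a
voluntary burst multiplies an independent white-noise stream by the
unimodal envelope `(t/tau) exp(1 - t/tau)` starting at the true onset
(cue + reaction-time draw, N(180, 25) ms clipped at 50 ms).  The agonist
burst amplitude is `burst_amplitude` (default 10, i.e. a peak
signal-to-noise ratio of 10) times a lognormal participant scale
(sigma = 0.3) times the condition's agonist multiplier; the antagonist is
analogous at 0.8 of the agonist base amplitude (strong ballistic
co-contraction, keeping its burst well above the envelope noise floor).

The trigger latency decomposes as threshold-crossing latency plus a fixed
20 ms closed-loop actuation lag (`loop_delay_ms`) covering acquisition,
processing and cable-tension take-up.  The burst rise time
`burst_rise_tau_ms` = 80 ms was calibrated by simulation sweep
(`scripts/calibrate_burst_tau.py`) so that the mean trigger latency on
rapid-condition trials equals the 23.4 ms the hardware achieved.  Two
alternatives were tried and rejected: carrying the whole 23.4 ms in the
envelope rise requires tau ≈ 600 ms, which leaves the 200 ms peak window
on the rising flank and distorts recovered peak ratios by ~8%; and
ramping the condition multipliers in only after the pull starts injects a
spectral edge into the rectified-EMG amplitude profile that the envelope
filters convert into a multiplier-dependent bias.  Static whole-burst
multipliers with a fast rise give unbiased recovery.

Condition effects are embedded as ground truth: multiplicative factors on
agonist peak, antagonist peak and voluntary peak angular velocity, and
additive reaction-time offsets.  Defaults (control = 1/1/1/0):

| condition        | agonist | antagonist | velocity | reaction (ms) |
|------------------|--------:|-----------:|---------:|--------------:|
| rapid_assist     | 1.6897  | 1.20       | 1.38     | −22.76        |
| delayed_assist   | 1.316   | 1.20       | 1.20     | 0             |
| rapid_perturb    | 1.8191  | 2.0035     | 0.6049   | 0             |
| delayed_perturb  | 1.9211  | 1.8581     | 0.614    | +22.76        |

The single known reaction-time contrast (45.52 ms between delayed
perturbation and rapid assistance) is split symmetrically between those
two conditions because only the pairwise difference is identified.  The
passive condition has no burst; its pull is issued at the nominal trigger
time (reaction mean + 23.4 ms).

## Synthetic kinematics

Arm angular velocity is a Gaussian bell (sigma 150 ms) whose peak, 5.2
rad/s at control (a typical rapid tabletop extension), occurs 600 ms
after mechanical onset (true EMG onset + EMD); placing the voluntary peak
after the longest pull ends keeps the actuator term from contaminating
the voluntary peak.  The actuator contributes a rectangular angular-rate
pulse of rope_speed / forearm_length = 3.16 rad/s with the pull's sign
while the rope moves, which makes passive-pull peaks (~3.16 rad/s)
comparable to perturbation-condition peaks by construction.  Wrist and
elbow markers are synthesized at 200 Hz from the trapezoid-integrated
angle at a fixed 0.25 m forearm in the transverse plane, noise-free by
default (`marker_noise_sd` adds Gaussian marker noise if wanted).

## Signal pipeline

Offline EMG processing rectifies, then applies a zero-phase 4th-order
Butterworth 20 Hz high-pass, then a zero-phase 4th-order 10 Hz low-pass —
in exactly that published order, even though high-pass-after-rectification
leaves only a narrow residual band, because the analysis is ratio-based
and the attenuation cancels in normalization.  Filters run as cascaded
second-order sections; the direct (b, a) form loses ~8 significant digits
at these cutoff-to-rate ratios.  Peak activation is the envelope maximum
(negative ripple clipped at zero) in the 200 ms window after the detected
onset, truncated at the series end.  Peaks are normalized per participant
and per muscle to the mean over that participant's pulled-phase control
trials, so participant amplitude scale cancels exactly.  Angular velocity
is the central-difference derivative of the unwrapped planar wrist-elbow
angle (extension positive); its per-trial outcome is the signed maximum
over [cue, cue + 1.5 s].  Reaction time is (onset − cue) at the EMG rate,
in ms, using the closed-loop onset; an offline re-detection with the
identical rule is recorded alongside.

## Statistics

Each outcome is modelled at the trial level (pulled-phase trials of the
five non-passive conditions) with a linear mixed model fit by maximum
likelihood: fixed effects for condition and for block order (numeric 1–5
covariate — a single term, matching the design's single order effect),
and a participant random intercept.  The condition main effect is a
likelihood-ratio chi-square (df = 4) against the model without condition.
All ten pairwise contrasts are Wald z-tests on fixed-effect differences,
Holm-adjusted as a family of ten; percent differences are computed from
estimated marginal means (order held at its mean).  Fits fall back
through an optimizer cascade (default, L-BFGS, CG, Powell) when the
profiled likelihood is awkward; boundary estimates of the random-effect
variance are accepted.  Zero-variance outcomes raise an error rather than
fitting.

Type-I calibration of the LRT (1000 replicates, 14 participants) uses a
model-level null generator (participant intercept + residual noise, no
condition effect, 8 trials per cell): the full signal-level pipeline at
that replicate count would take hours without changing what is being
calibrated, which is the test's behaviour under the fitted model's null.
A smaller full-pipeline null check (all multipliers 1) runs end to end.

## Problem sizes

The recovery tests in the suite average 6 default-size cohorts
(14 participants × 250 trials); the acceptance script averages 50.  Their
tolerance is a Monte-Carlo interval (4 standard errors across cohorts,
floored at 5% of the target) — with 6 cohorts that is roughly ±2–3
percentage points.  Latency checks use 1200–2000 rapid trials.

## Limitations

- EMG realism stops at band-limited-variance Gaussian modulation: no
  motor-unit structure, no 50/60 Hz interference, no electrode artifacts.
  Real rest periods contain movement artifacts that the adaptive
  threshold was designed to survive; the synthetic rest is stationary, so
  threshold elevation occurs only through sampling extremes.
- Condition multipliers scale the whole burst, including the pre-trigger
  rise; the real effects presumably develop after the pull.  The
  simplification leaves a small amplitude-dependence in crossing latency
  (~2 ms across conditions), visible as a ≤1.5 ms bias in the recovered
  reaction-time contrast.
- Kinematics are single-joint and planar with a rectangular actuator
  velocity pulse; only peak ratios are meaningful.
- The passive condition is generated but, as in the analysis design, never
  enters the mixed models.
- Passing recovery tests show the pipeline is consistent for data shaped
  like this generator; they cannot validate the detector or filters
  against real surface EMG.
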