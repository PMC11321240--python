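"""Closed-loop synthetic cohorts: EMG, kinematics, and triggered pulls.

Each trial emulates one cued rapid arm extension.  Agonist (triceps) and
antagonist (biceps) surface EMG are band-limited-variance Gaussian noise:
at rest the signal is white noise of fixed standard deviation, and a
voluntary burst is modelled as noise amplitude-modulated by a smooth
unimodal envelope starting at cue + reaction time.  The same adaptive
threshold detector that the analysis pipeline uses runs on the agonist
stream while the trial is generated; when it fires on a pulled-phase
trial, the actuator pull it commands is injected into the simulated arm
kinematics.  Condition effects enter as multiplicative factors on burst
amplitudes and voluntary velocity and as additive reaction-time offsets,
so the downstream pipeline's job is to recover exactly these factors.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator

import numpy as np

from . import protocol, signals
from .errors import ParameterError
from .protocol import ConditionSpec, PullCommand, SessionPlan

#: Burst rise time (ms) of the voluntary-activation envelope.  Calibrated by
#: simulation sweep (scripts/calibrate_burst_tau.py) so that the mean
#: trigger latency (threshold crossing + closed-loop actuation lag) on
#: rapid-condition trials at the default signal-to-noise ratio matches the
#: 23.4 ms real-time latency of the hardware implementation.
DEFAULT_BURST_RISE_TAU_MS = 80.0

#: Fixed closed-loop actuation lag (ms) between the threshold crossing and
#: the actuator starting to move: acquisition, processing and cable tension
#: take-up.  The analysis-side EMG onset is the raw threshold crossing; this
#: lag only delays the pull.
DEFAULT_LOOP_DELAY_MS = 20.0

#: Mean rapid-condition trigger latency (ms) that the calibration targets;
#: also used as the nominal trigger latency for passive pulls, where no
#: voluntary onset exists to fire the detector.
RAPID_TRIGGER_LATENCY_MS = 23.4

#: Reaction-time draws are clipped here (ms); a draw this low is a >5 sigma
#: event at the default reaction-time distribution.
MIN_REACTION_MS = 50.0

@dataclass(frozen=True)
class ConditionEffect:
    """Ground-truth effect of one condition relative to control.

    agonist / antagonist / velocity multiply the control-level burst
    amplitudes and voluntary peak angular velocity; reaction_offset_ms adds
    to the mean reaction time.
    """

    agonist: float = 1.0
    antagonist: float = 1.0
    velocity: float = 1.0
    reaction_offset_ms: float = 0.0


def default_condition_effects() -> dict[str, ConditionEffect]:
    """Ground-truth condition effects the generator embeds by default.

    The multipliers are the study-level percent differences the analysis
    is expected to recover, expressed as levels (e.g. a 68.97% larger
    agonist peak than control is the multiplier 1.6897).  The single
    reported reaction-time contrast (45.52 ms between delayed perturbation
    and rapid assistance) is split symmetrically between those two
    conditions.  The passive condition has no voluntary burst, so its
    multipliers are inert.
    """
    return {
        "control": ConditionEffect(),
        "rapid_assist": ConditionEffect(1.6897, 1.20, 1.38, -22.76),
        "delayed_assist": ConditionEffect(1.316, 1.20, 1.20, 0.0),
        "rapid_perturb": ConditionEffect(1.8191, 2.0035, 0.6049, 0.0),
        "delayed_perturb": ConditionEffect(1.9211, 1.8581, 0.614, +22.76),
        "passive": ConditionEffect(),
    }


def null_condition_effects() -> dict[str, ConditionEffect]:
    """All multipliers 1 and offsets 0; used for type-I calibration runs."""
    return {name: ConditionEffect() for name in protocol.ALL_CONDITIONS}


@dataclass
class GeneratorParams:
    """Tunable parameters of the synthetic cohort generator.

    EMG is in arbitrary units (all analyses normalize to the control
    condition, so the units cancel).  Rates are Hz, durations seconds and
    reaction/EMD times milliseconds.
    """

    n_participants: int = 14
    emg_rate: float = 2000.0
    mocap_rate: float = 200.0
    post_cue_s: float = 3.0
    pre_cue_rest_s: float = 2.5
    reaction_mean_ms: float = 180.0
    reaction_sd_ms: float = 25.0
    emd_ms: float = 40.0
    rest_noise_sd: float = 1.0
    burst_amplitude: float = 10.0
    burst_rise_tau_ms: float = DEFAULT_BURST_RISE_TAU_MS
    loop_delay_ms: float = DEFAULT_LOOP_DELAY_MS
    antagonist_fraction: float = 0.8
    between_participant_sd: float = 0.3
    velocity_amplitude: float = 5.2
    velocity_sigma_s: float = 0.150
    velocity_peak_delay_s: float = 0.600
    velocity_participant_sd: float = 0.15
    velocity_trial_sd: float = 0.12
    forearm_length_m: float = 0.25
    marker_noise_sd: float = 0.0
    include_passive: bool = False
    condition_effects: dict[str, ConditionEffect] = field(default_factory=default_condition_effects)
    seed: int = 0

    def __post_init__(self) -> None:
        positive = [
            ("emg_rate", self.emg_rate),
            ("mocap_rate", self.mocap_rate),
            ("post_cue_s", self.post_cue_s),
            ("pre_cue_rest_s", self.pre_cue_rest_s),
            ("rest_noise_sd", self.rest_noise_sd),
            ("burst_amplitude", self.burst_amplitude),
            ("burst_rise_tau_ms", self.burst_rise_tau_ms),
            ("velocity_amplitude", self.velocity_amplitude),
            ("velocity_sigma_s", self.velocity_sigma_s),
            ("forearm_length_m", self.forearm_length_m),
        ]
        for name, value in positive:
            if not value > 0:
                raise ParameterError(f"{name} must be positive, got {value}")
        if self.n_participants < 1:
            raise ParameterError("n_participants must be at least 1")
        for cond, eff in self.condition_effects.items():
            for attr in ("agonist", "antagonist", "velocity"):
                if not getattr(eff, attr) > 0:
                    raise ParameterError(f"{cond}.{attr} multiplier must be positive")
        control = self.condition_effects.get("control")
        if control is not None and (
            control.agonist != 1 or control.antagonist != 1 or control.velocity != 1
        ):
            raise ParameterError("control multipliers must all be exactly 1")


def with_null_effects(params: GeneratorParams) -> GeneratorParams:
    """A copy of params with every condition effect removed."""
    return replace(params, condition_effects=null_condition_effects())


@dataclass
class TrialRecord:
    """One simulated arm extension with its full signal content."""

    participant_id: str
    condition: str
    phase: str
    block_index: int
    trial_in_block: int
    cue_time: float
    emg_rate: float
    mocap_rate: float
    cue_index: int
    agonist_emg: np.ndarray
    antagonist_emg: np.ndarray
    wrist_xy: np.ndarray
    elbow_xy: np.ndarray
    pull: PullCommand | None
    true_onset_index: int | None
    rest_window: tuple[int, int]
    detection: signals.DetectionResult
    missed_trigger: bool = False


def burst_envelope(t_since_onset_ms, amplitude: float, rise_tau_ms: float):
    """Unimodal voluntary-activation envelope.

    Zero before onset; (t/tau) * exp(1 - t/tau) * amplitude afterwards, so
    the peak equals amplitude and occurs at t = tau.
    """
    if not rise_tau_ms > 0:
        raise ParameterError(f"rise_tau_ms must be positive, got {rise_tau_ms}")
    t = np.asarray(t_since_onset_ms, dtype=float)
    x = t / rise_tau_ms
    env = np.where(t >= 0, x * np.exp(1.0 - x), 0.0) * amplitude
    if np.ndim(t_since_onset_ms) == 0:
        return float(env)
    return env


def generate_trial(
    params: GeneratorParams,
    spec: ConditionSpec,
    participant_scale: float,
    rng: np.random.Generator,
    *,
    phase: str = "pulled",
    rest_duration_s: float | None = None,
    participant_velocity_scale: float = 1.0,
    participant_id: str = "P01",
    block_index: int = 0,
    trial_in_block: int = 0,
    cue_time: float = 0.0,
) -> TrialRecord:
    """Simulate one trial in closed loop.

    rest_duration_s is the true quiet interval before the cue (from the
    previous trial's end to this cue); the detector threshold is computed
    over the whole interval, while the stored trace keeps only the trailing
    pre_cue_rest_s seconds, mirroring a bounded acquisition buffer.
    """
    fs = params.emg_rate
    eff = params.condition_effects.get(spec.name, ConditionEffect())
    cue_index = int(round(params.pre_cue_rest_s * fs))
    n_active = int(round(params.post_cue_s * fs))

    rest_s = max(rest_duration_s or params.pre_cue_rest_s, params.pre_cue_rest_s)
    rest_full = params.rest_noise_sd * rng.standard_normal(int(round(rest_s * fs)))
    detection = signals.compute_threshold(rest_full)
    rest_ag = rest_full[-cue_index:]
    rest_ant = params.rest_noise_sd * rng.standard_normal(cue_index)

    # Voluntary burst: amplitude-modulated Gaussian noise from the true onset.
    true_onset: int | None = None
    env = np.zeros(n_active)
    if spec.voluntary:
        rt_ms = max(
            rng.normal(params.reaction_mean_ms + eff.reaction_offset_ms, params.reaction_sd_ms),
            MIN_REACTION_MS,
        )
        onset_rel = int(round(rt_ms / 1000.0 * fs))
        true_onset = cue_index + onset_rel
        t_ms = (np.arange(n_active) - onset_rel) / fs * 1000.0
        env = burst_envelope(t_ms, 1.0, params.burst_rise_tau_ms)

    amp_ag = params.burst_amplitude * participant_scale * eff.agonist
    amp_ant = params.burst_amplitude * params.antagonist_fraction * participant_scale * eff.antagonist
    active_ag = params.rest_noise_sd * rng.standard_normal(n_active) \
        + amp_ag * env * rng.standard_normal(n_active)
    active_ant = params.rest_noise_sd * rng.standard_normal(n_active) \
        + amp_ant * env * rng.standard_normal(n_active)
    agonist = np.concatenate([rest_ag, active_ag])
    antagonist = np.concatenate([rest_ant, active_ant])

    # Closed-loop detection and actuator command.
    detection.onset_index = signals.detect_onset(agonist, detection.threshold, cue_index)
    missed = spec.voluntary and detection.onset_index is None

    pull: PullCommand | None = None
    if phase == "pulled" and spec.direction != 0:
        if detection.onset_index is not None:
            trigger_s = (detection.onset_index - cue_index) / fs + params.loop_delay_ms / 1000.0
            pull = protocol.make_pull_command(spec, trigger_s)
        elif not spec.voluntary:
            trigger_s = (params.reaction_mean_ms + RAPID_TRIGGER_LATENCY_MS) / 1000.0
            pull = protocol.make_pull_command(spec, trigger_s)

    wrist, elbow = _synthesize_markers(
        params, eff.velocity, pull, true_onset, cue_index, participant_velocity_scale, rng
    )

    return TrialRecord(
        participant_id=participant_id,
        condition=spec.name,
        phase=phase,
        block_index=block_index,
        trial_in_block=trial_in_block,
        cue_time=cue_time,
        emg_rate=fs,
        mocap_rate=params.mocap_rate,
        cue_index=cue_index,
        agonist_emg=agonist,
        antagonist_emg=antagonist,
        wrist_xy=wrist,
        elbow_xy=elbow,
        pull=pull,
        true_onset_index=true_onset,
        rest_window=(0, cue_index),
        detection=detection,
        missed_trigger=missed,
    )


def _synthesize_markers(params, vel_mult, pull, true_onset, cue_index, vel_scale, rng):
    """Wrist/elbow planar trajectories from the simulated angular velocity.

    Voluntary extension is a Gaussian angular-velocity bell starting one
    electromechanical delay after the true EMG onset; the actuator adds a
    rectangular velocity pulse of magnitude rope_speed / forearm_length
    with the pull's sign while the rope moves.
    """
    fm = params.mocap_rate
    n = int(round((params.pre_cue_rest_s + params.post_cue_s) * fm))
    t = np.arange(n) / fm - params.pre_cue_rest_s  # seconds relative to cue
    omega = np.zeros(n)

    if true_onset is not None:
        t_mech = (true_onset - cue_index) / params.emg_rate + params.emd_ms / 1000.0
        center = t_mech + params.velocity_peak_delay_s
        peak = (
            params.velocity_amplitude
            * vel_mult
            * vel_scale
            * float(np.exp(rng.normal(0.0, params.velocity_trial_sd)))
        )
        omega += peak * np.exp(-0.5 * ((t - center) / params.velocity_sigma_s) ** 2)

    if pull is not None:
        arm_omega = pull.rope_speed / params.forearm_length_m
        in_pull = (t >= pull.start_time) & (t < pull.start_time + pull.duration)
        omega += pull.direction * arm_omega * in_pull

    # integrate to angle; markers at fixed forearm length in the plane
    theta = np.concatenate([[0.0], np.cumsum((omega[1:] + omega[:-1]) / 2.0)]) / fm
    wrist = params.forearm_length_m * np.column_stack([np.cos(theta), np.sin(theta)])
    elbow = np.zeros_like(wrist)
    if params.marker_noise_sd > 0:
        wrist = wrist + rng.normal(0.0, params.marker_noise_sd, wrist.shape)
        elbow = elbow + rng.normal(0.0, params.marker_noise_sd, elbow.shape)
    return wrist, elbow


def iter_cohort(params: GeneratorParams) -> Iterator[tuple[SessionPlan, TrialRecord]]:
    """Yield (session plan, trial) pairs for a whole cohort, lazily.

    All randomness derives from params.seed: each participant gets a
    schedule seed, an EMG amplitude scale and a velocity scale (both
    lognormal), and a private trial-level stream.
    """
    master = np.random.default_rng(params.seed)
    specs = {s.name: s for s in protocol.make_condition_specs()}
    for i in range(params.n_participants):
        pid = f"P{i + 1:02d}"
        plan_seed = int(master.integers(2**31))
        emg_scale = float(np.exp(master.normal(0.0, params.between_participant_sd)))
        vel_scale = float(np.exp(master.normal(0.0, params.velocity_participant_sd)))
        trial_rng = np.random.default_rng(int(master.integers(2**31)))
        plan = protocol.schedule_session(
            include_passive=params.include_passive, seed=plan_seed, participant_id=pid
        )
        prev_cue = 0.0
        for slot in plan.trials:
            rest_s = slot.cue_time - prev_cue - (params.post_cue_s if prev_cue > 0 else 0.0)
            prev_cue = slot.cue_time
            trial = generate_trial(
                params,
                specs[slot.condition],
                emg_scale,
                trial_rng,
                phase=slot.phase,
                rest_duration_s=rest_s,
                participant_velocity_scale=vel_scale,
                participant_id=pid,
                block_index=slot.block_index,
                trial_in_block=slot.trial_in_block,
                cue_time=slot.cue_time,
            )
            yield plan, trial


@dataclass
class Cohort:
    """A fully materialized synthetic dataset."""

    params: GeneratorParams
    plans: list[SessionPlan]
    trials: list[TrialRecord]


def generate_cohort(params: GeneratorParams) -> Cohort:
    """Materialize a cohort in memory (use iter_cohort for large runs)."""
    plans: dict[str, SessionPlan] = {}
    trials: list[TrialRecord] = []
    for plan, trial in iter_cohort(params):
        plans[plan.participant_id] = plan
        trials.append(trial)
    return Cohort(params=params, plans=list(plans.values()), trials=trials)


def detector_latency_sample(
    params: GeneratorParams,
    n_trials: int,
    seed: int,
    conditions: tuple[str, ...] = ("rapid_assist", "rapid_perturb"),
) -> np.ndarray:
    """Trigger latencies (ms, detected minus true onset) on pulled trials.

    Each trial draws a fresh participant amplitude scale and a fresh
    Uniform(5, 15) s inter-cue rest, matching the cohort's marginal
    distribution.  The latency is the full trigger latency: threshold
    crossing relative to the true onset plus the closed-loop actuation
    lag.  Missed-trigger trials are excluded (they have no latency);
    occasional pre-onset threshold crossings give short latencies and are
    retained, as the real-time system would have acted on them too.
    """
    rng = np.random.default_rng(seed)
    specs = {s.name: s for s in protocol.make_condition_specs()}
    latencies = []
    for k in range(n_trials):
        spec = specs[conditions[k % len(conditions)]]
        scale = float(np.exp(rng.normal(0.0, params.between_participant_sd)))
        gap = rng.uniform(*protocol.CUE_INTERVAL_S)
        trial = generate_trial(
            params, spec, scale, rng, phase="pulled", rest_duration_s=gap - params.post_cue_s
        )
        if trial.detection.onset_index is None or trial.true_onset_index is None:
            continue
        latencies.append(
            (trial.detection.onset_index - trial.true_onset_index) / params.emg_rate * 1000.0
            + params.loop_delay_ms
        )
    return np.asarray(latencies)
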