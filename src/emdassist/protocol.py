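"""Experimental protocol: conditions, session schedules, and pull commands.

The task is a cued rapid arm extension on a tabletop.  A cable actuator can
pull the arm in the extension direction (assistance) or the flexion
direction (perturbation), released either at the earliest achievable
latency after EMG onset detection ("rapid") or with a 40 ms artificial
delay ("delayed").  Two reference conditions exist: control (no pull) and
passive (pull without voluntary extension).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Actuator drum rotation speed, identical for every pull (rad/s).
PULL_ANGULAR_SPEED = 40.0

#: Drum radius (m); 40 rad/s on this drum retracts the rope at 0.79 m/s.
DRUM_RADIUS_M = 0.01975

#: Pull durations (s) in the assistive and perturbing directions.
ASSIST_PULL_S = 0.31
PERTURB_PULL_S = 0.10

#: Extra delay (s) added on top of the fastest detection for "delayed" pulls.
ARTIFICIAL_DELAY_S = 0.040

#: Trials per block: unpulled lead-in, pulled middle, unpulled tail.
BLOCK_STRUCTURE = (10, 30, 10)
TRIALS_PER_BLOCK = sum(BLOCK_STRUCTURE)

#: Inter-cue interval range (s).
CUE_INTERVAL_S = (5.0, 15.0)

#: Names of the five conditions entering the statistical comparison, in
#: canonical order, plus the passive reference.
NON_PASSIVE_CONDITIONS = (
    "control",
    "rapid_assist",
    "delayed_assist",
    "rapid_perturb",
    "delayed_perturb",
)
ALL_CONDITIONS = NON_PASSIVE_CONDITIONS + ("passive",)

PHASES = ("pre", "pulled", "post")


@dataclass(frozen=True)
class ConditionSpec:
    """One experimental condition.

    direction is +1 for pulls in the extension (assistive) direction, -1 for
    flexion (perturbing) pulls and 0 for the unpulled control.  voluntary is
    False only for the passive condition, where the participant is
    instructed not to extend.
    """

    name: str
    direction: int
    pull_duration: float
    artificial_delay: float
    voluntary: bool = True


@dataclass(frozen=True)
class PullCommand:
    """A single actuator rotation sequence.

    start_time is expressed in seconds relative to the trial cue.
    """

    start_time: float
    duration: float
    direction: int
    angular_speed: float = PULL_ANGULAR_SPEED

    @property
    def rope_speed(self) -> float:
        """Linear rope retraction speed (m/s) at the drum surface."""
        return self.angular_speed * DRUM_RADIUS_M


@dataclass(frozen=True)
class TrialSlot:
    """One scheduled trial of a session."""

    condition: str
    phase: str
    cue_time: float
    block_index: int
    trial_in_block: int


@dataclass
class SessionPlan:
    """Ordered trial schedule for one participant."""

    participant_id: str
    trials: list[TrialSlot] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.trials)

    @property
    def condition_order(self) -> list[str]:
        seen: list[str] = []
        for t in self.trials:
            if t.condition not in seen:
                seen.append(t.condition)
        return seen

    def to_frame(self) -> pd.DataFrame:
        """Tabular form: one row per trial."""
        return pd.DataFrame(
            {
                "participant": self.participant_id,
                "block_index": [t.block_index for t in self.trials],
                "condition": [t.condition for t in self.trials],
                "phase": [t.phase for t in self.trials],
                "trial_in_block": [t.trial_in_block for t in self.trials],
                "cue_time": [t.cue_time for t in self.trials],
            }
        )


def make_condition_specs() -> list[ConditionSpec]:
    """Return the six condition definitions.

    Assistance pulls last 0.31 s in the extension direction; perturbation
    pulls last 0.1 s in the flexion direction.  Rapid conditions add no
    artificial delay; delayed conditions add 40 ms.  The passive condition
    receives an assistive pull without voluntary extension.
    """
    return [
        ConditionSpec("control", 0, 0.0, 0.0),
        ConditionSpec("rapid_assist", +1, ASSIST_PULL_S, 0.0),
        ConditionSpec("delayed_assist", +1, ASSIST_PULL_S, ARTIFICIAL_DELAY_S),
        ConditionSpec("rapid_perturb", -1, PERTURB_PULL_S, 0.0),
        ConditionSpec("delayed_perturb", -1, PERTURB_PULL_S, ARTIFICIAL_DELAY_S),
        ConditionSpec("passive", +1, ASSIST_PULL_S, 0.0, voluntary=False),
    ]


def condition_spec(name: str) -> ConditionSpec:
    """Look up a single condition by name."""
    for spec in make_condition_specs():
        if spec.name == name:
            return spec
    raise KeyError(f"unknown condition: {name!r}")


def _phase_of(trial_in_block: int) -> str:
    n_pre, n_pulled, _ = BLOCK_STRUCTURE
    if trial_in_block < n_pre:
        return "pre"
    if trial_in_block < n_pre + n_pulled:
        return "pulled"
    return "post"


def schedule_session(
    include_passive: bool = False,
    seed: int = 0,
    participant_id: str = "P01",
) -> SessionPlan:
    """Build a randomized session schedule.

    The five non-passive conditions appear in a seed-determined uniform
    random order, each as a 10/30/10 block of 50 trials; the passive block,
    if requested, always comes last.  Successive cues are separated by
    independent Uniform(5, 15) s intervals.
    """
    rng = np.random.default_rng(seed)
    order = [NON_PASSIVE_CONDITIONS[i] for i in rng.permutation(5)]
    if include_passive:
        order.append("passive")

    plan = SessionPlan(participant_id=participant_id)
    t = 0.0
    for block_index, condition in enumerate(order):
        for k in range(TRIALS_PER_BLOCK):
            t += rng.uniform(*CUE_INTERVAL_S)
            plan.trials.append(
                TrialSlot(
                    condition=condition,
                    phase=_phase_of(k),
                    cue_time=t,
                    block_index=block_index,
                    trial_in_block=k,
                )
            )
    return plan


def make_pull_command(spec: ConditionSpec, trigger_time: float) -> PullCommand | None:
    """Translate an onset trigger into an actuator command.

    Returns None for the control condition.  The pull starts at the trigger
    plus the condition's artificial delay; trigger_time and the returned
    start_time are seconds relative to the cue.
    """
    if trigger_time < 0:
        raise ValueError("trigger_time must be nonnegative")
    if spec.direction == 0:
        return None
    return PullCommand(
        start_time=trigger_time + spec.artificial_delay,
        duration=spec.pull_duration,
        direction=spec.direction,
    )


def all_condition_pairs(conditions=NON_PASSIVE_CONDITIONS) -> list[tuple[str, str]]:
    """All unordered condition pairs, in canonical order."""
    return list(itertools.combinations(conditions, 2))
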