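"""Simulate one closed-loop trial and inspect the trigger timeline.

Generates a rapid-assistance trial, shows when the voluntary EMG burst
started, when the adaptive-threshold detector fired, and when the actuator
pull began relative to the ~40 ms electromechanical delay.
"""

import numpy as np

from emdassist import GeneratorParams, generate_trial
from emdassist.protocol import condition_spec

params = GeneratorParams()
rng = np.random.default_rng(12)
trial = generate_trial(
    params, condition_spec("rapid_assist"), participant_scale=1.0, rng=rng,
    rest_duration_s=8.0,
)

fs = trial.emg_rate
onset_true_ms = (trial.true_onset_index - trial.cue_index) / fs * 1e3
onset_det_ms = (trial.detection.onset_index - trial.cue_index) / fs * 1e3
print(f"rest-period max squared EMG : {trial.detection.rest_max:.3f}")
print(f"onset threshold (1% above)  : {trial.detection.threshold:.3f}")
print(f"true EMG onset              : {onset_true_ms:7.1f} ms after cue")
print(f"detected EMG onset          : {onset_det_ms:7.1f} ms after cue")
print(f"actuator pull start         : {trial.pull.start_time * 1e3:7.1f} ms after cue")
print(f"muscle contraction expected : {onset_true_ms + params.emd_ms:7.1f} ms after cue")

lead = onset_true_ms + params.emd_ms - trial.pull.start_time * 1e3
print(f"\nthe pull starts {lead:.1f} ms BEFORE the muscle itself would move:")
print("assistance is delivered inside the electromechanical delay.")
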