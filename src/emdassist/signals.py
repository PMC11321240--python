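"""Per-trial signal processing: onset detection, EMG envelope, kinematics.

The real-time trigger compares each raw squared EMG sample against a
threshold set 1% above the maximum squared EMG observed during the rest
period preceding the cue.  Offline, EMG is rectified and filtered
(zero-phase 4th-order Butterworth, 20 Hz high-pass followed by 10 Hz
low-pass) and peak activation is read from the 200 ms window that follows
the detected onset.  Arm angular velocity comes from the planar wrist
marker angle about the elbow, differentiated centrally.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy import signal as sps

from .errors import (
    GeometryError,
    InputError,
    NormalizationError,
    OnsetOrderingError,
)

#: Fractional margin of the onset threshold above the rest maximum.
THRESHOLD_MARGIN = 1.01

#: Peak-extraction window after detected onset (s).
PEAK_WINDOW_S = 0.200

#: Window after the cue searched for the peak angular velocity (s).
VELOCITY_WINDOW_S = 1.5

#: Butterworth cutoffs (Hz) and order for the EMG envelope.
ENVELOPE_HIGHPASS_HZ = 20.0
ENVELOPE_LOWPASS_HZ = 10.0
ENVELOPE_ORDER = 4


@dataclass
class DetectionResult:
    """Adaptive-threshold detector output for one trial."""

    rest_max: float
    threshold: float
    onset_index: int | None = None


@dataclass
class TrialMetrics:
    """Per-trial outcomes entering the statistical models.

    Peaks are percentages of the participant's mean control-condition peak;
    angular velocity is rad/s with extension positive; reaction time is ms
    from cue to detected EMG onset (None for passive / missed trials).
    """

    peak_agonist_norm: float
    peak_antagonist_norm: float
    peak_angular_velocity: float
    reaction_time: float | None


def compute_threshold(rest_emg: np.ndarray) -> DetectionResult:
    """Set the onset threshold from a rest-period EMG segment.

    threshold = 1.01 x max(rest squared); an all-zero rest window falls back
    to a machine-epsilon floor so the detector still requires nonzero input.
    """
    rest_emg = np.asarray(rest_emg, dtype=float)
    if rest_emg.size == 0:
        raise InputError("rest window is empty")
    rest_max = float(np.max(rest_emg**2))
    threshold = THRESHOLD_MARGIN * rest_max if rest_max > 0 else float(np.finfo(float).eps)
    return DetectionResult(rest_max=rest_max, threshold=threshold)


def detect_onset(emg: np.ndarray, threshold: float, search_start: int) -> int | None:
    """First index at/after search_start whose squared sample exceeds threshold."""
    emg = np.asarray(emg, dtype=float)
    if not 0 <= search_start <= emg.size:
        raise InputError(f"search_start {search_start} outside series of {emg.size}")
    tail = emg[search_start:]
    hits = np.nonzero(tail * tail > threshold)[0]
    if hits.size == 0:
        return None
    return search_start + int(hits[0])


def run_detector(emg: np.ndarray, rest_window: tuple[int, int], search_start: int) -> DetectionResult:
    """Threshold from the rest window, then search from search_start."""
    lo, hi = rest_window
    result = compute_threshold(np.asarray(emg)[lo:hi])
    result.onset_index = detect_onset(emg, result.threshold, search_start)
    return result


@lru_cache(maxsize=8)
def _envelope_filters(rate: float):
    # second-order sections keep the low relative cutoffs well conditioned
    sos_hp = sps.butter(ENVELOPE_ORDER, ENVELOPE_HIGHPASS_HZ, "highpass", fs=rate, output="sos")
    sos_lp = sps.butter(ENVELOPE_ORDER, ENVELOPE_LOWPASS_HZ, "lowpass", fs=rate, output="sos")
    return sos_hp, sos_lp


def emg_envelope(raw: np.ndarray, rate: float) -> np.ndarray:
    """Rectify, then 20 Hz high-pass, then 10 Hz low-pass (zero phase).

    The high-pass-then-low-pass sequence is applied exactly in that order.
    Output has the input's length; filtering can produce small negative
    values, which are clipped at zero later, at peak extraction.
    """
    raw = np.asarray(raw, dtype=float)
    if rate <= 2 * ENVELOPE_HIGHPASS_HZ:
        raise InputError(f"sampling rate {rate} Hz too low for a {ENVELOPE_HIGHPASS_HZ} Hz high-pass")
    sos_hp, sos_lp = _envelope_filters(float(rate))
    padlen = 3 * (2 * ENVELOPE_ORDER + 1)
    if raw.size <= padlen:
        raise InputError(f"series of {raw.size} samples too short to filter (need > {padlen})")
    env = sps.sosfiltfilt(sos_hp, np.abs(raw))
    env = sps.sosfiltfilt(sos_lp, env)
    return env


def peak_activation(envelope: np.ndarray, onset_index: int, rate: float) -> float:
    """Maximum envelope value in the 200 ms window after the detected onset.

    The window is truncated at the end of the series; negative filter
    ripple is clipped at zero.
    """
    envelope = np.asarray(envelope, dtype=float)
    if not 0 <= onset_index < envelope.size:
        raise InputError(f"onset index {onset_index} outside series of {envelope.size}")
    stop = onset_index + int(round(PEAK_WINDOW_S * rate)) + 1
    window = envelope[onset_index:stop]
    return float(np.max(np.clip(window, 0.0, None)))


def normalize_peaks(peaks: np.ndarray, control_peaks: np.ndarray) -> np.ndarray:
    """Express peaks as a percentage of the mean control-condition peak.

    Intended to be applied per participant and per muscle, so that
    between-participant amplitude scale (electrode placement, physiology)
    cancels.
    """
    control_peaks = np.asarray(control_peaks, dtype=float)
    if control_peaks.size == 0:
        raise NormalizationError("no control peaks to normalize against")
    ref = float(np.mean(control_peaks))
    if not ref > 0:
        raise NormalizationError(f"control mean peak must be positive, got {ref}")
    return np.asarray(peaks, dtype=float) * 100.0 / ref


def angular_velocity(wrist_xy: np.ndarray, elbow_xy: np.ndarray, rate: float) -> np.ndarray:
    """Arm angular velocity (rad/s) from planar wrist and elbow markers.

    The forearm angle is the unwrapped planar arctangent of wrist minus
    elbow; differentiation is by central differences (one-sided at the
    ends).  Extension is positive; flexion negative.
    """
    wrist_xy = np.asarray(wrist_xy, dtype=float)
    elbow_xy = np.asarray(elbow_xy, dtype=float)
    if wrist_xy.shape != elbow_xy.shape or wrist_xy.ndim != 2 or wrist_xy.shape[1] != 2:
        raise InputError("wrist and elbow must be equal-length (n, 2) series")
    rel = wrist_xy - elbow_xy
    if np.any(np.hypot(rel[:, 0], rel[:, 1]) == 0):
        raise GeometryError("wrist and elbow markers coincide")
    theta = np.unwrap(np.arctan2(rel[:, 1], rel[:, 0]))
    return np.gradient(theta) * rate


def reaction_time(cue_index: int, onset_index: int, rate: float) -> float:
    """Cue-to-onset duration in milliseconds."""
    if onset_index <= cue_index:
        raise OnsetOrderingError(f"onset index {onset_index} not after cue index {cue_index}")
    return (onset_index - cue_index) / rate * 1000.0


def trial_features(trial) -> dict:
    """Raw (un-normalized) per-trial outcomes for one TrialRecord.

    Returns peaks in generator EMG units, the signed peak angular velocity
    over [cue, cue + 1.5 s], and the reaction time from the closed-loop
    onset.  The onset is also recomputed offline with the identical rule on
    the stored rest window, and both are reported.  Trials whose detector
    never fired (or passive trials) yield None outcomes where undefined.
    """
    onset = trial.detection.onset_index
    offline = run_detector(
        trial.agonist_emg, trial.rest_window, search_start=trial.cue_index
    ).onset_index

    out = {
        "participant": trial.participant_id,
        "condition": trial.condition,
        "phase": trial.phase,
        "block_index": trial.block_index,
        "trial_in_block": trial.trial_in_block,
        "onset_closed_loop": onset,
        "onset_offline": offline,
        "true_onset": trial.true_onset_index,
        "missed_trigger": trial.missed_trigger,
        "peak_agonist": np.nan,
        "peak_antagonist": np.nan,
        "peak_angular_velocity": np.nan,
        "reaction_time_ms": np.nan,
    }

    cue_m = int(round(trial.cue_index / trial.emg_rate * trial.mocap_rate))
    omega = angular_velocity(trial.wrist_xy, trial.elbow_xy, trial.mocap_rate)
    stop = cue_m + int(round(VELOCITY_WINDOW_S * trial.mocap_rate)) + 1
    out["peak_angular_velocity"] = float(np.max(omega[cue_m:stop]))

    if onset is None:
        return out

    env_ag = emg_envelope(trial.agonist_emg, trial.emg_rate)
    env_ant = emg_envelope(trial.antagonist_emg, trial.emg_rate)
    out["peak_agonist"] = peak_activation(env_ag, onset, trial.emg_rate)
    out["peak_antagonist"] = peak_activation(env_ant, onset, trial.emg_rate)
    if trial.true_onset_index is not None and onset > trial.cue_index:
        out["reaction_time_ms"] = reaction_time(trial.cue_index, onset, trial.emg_rate)
    return out


def trial_metrics(trial, control_means: dict) -> TrialMetrics | None:
    """Normalized outcomes for a single trial.

    control_means maps {"agonist": x, "antagonist": y} to the participant's
    mean control-condition peaks.  Returns None for metric-less trials
    (missed trigger).
    """
    feats = trial_features(trial)
    if feats["onset_closed_loop"] is None:
        return None
    return TrialMetrics(
        peak_agonist_norm=float(
            normalize_peaks([feats["peak_agonist"]], [control_means["agonist"]])[0]
        ),
        peak_antagonist_norm=float(
            normalize_peaks([feats["peak_antagonist"]], [control_means["antagonist"]])[0]
        ),
        peak_angular_velocity=feats["peak_angular_velocity"],
        reaction_time=None if np.isnan(feats["reaction_time_ms"]) else feats["reaction_time_ms"],
    )
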