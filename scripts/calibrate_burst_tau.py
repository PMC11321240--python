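"""Calibrate the default burst rise time of the synthetic EMG generator.

Sweeps burst_rise_tau_ms and measures the mean trigger latency (threshold
crossing relative to the true onset, plus the fixed closed-loop actuation
lag) on rapid-condition trials at the default signal-to-noise ratio, then
solves for the tau whose mean latency matches the 23.4 ms real-time
trigger latency of the hardware system.  The result is frozen as
emdassist.synthetic.DEFAULT_BURST_RISE_TAU_MS.

Run from the repository root:

    python scripts/calibrate_burst_tau.py [--trials 4000] [--seed 12345]
"""

import argparse
from dataclasses import replace

import numpy as np

from emdassist.synthetic import (
    DEFAULT_BURST_RISE_TAU_MS,
    RAPID_TRIGGER_LATENCY_MS,
    GeneratorParams,
    detector_latency_sample,
)


def mean_latency(tau: float, n_trials: int, seed: int) -> float:
    params = replace(GeneratorParams(), burst_rise_tau_ms=tau)
    return float(np.mean(detector_latency_sample(params, n_trials, seed=seed)))


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--trials", type=int, default=4000, help="trials per tau value")
    ap.add_argument("--seed", type=int, default=12345)
    args = ap.parse_args()

    taus = np.array([40.0, 60.0, 80.0, 100.0, 140.0, 200.0])
    means = np.array([mean_latency(t, args.trials, args.seed + i) for i, t in enumerate(taus)])
    for t, m in zip(taus, means):
        print(f"tau = {t:6.1f} ms   mean trigger latency = {m:6.2f} ms")

    # latency grows smoothly with tau; linear interpolation on the sweep
    target = RAPID_TRIGGER_LATENCY_MS
    tau_star = float(np.interp(target, means, taus))
    print(f"\ntarget latency {target} ms -> tau = {tau_star:.0f} ms")

    check = mean_latency(round(tau_star), 2 * args.trials, args.seed + 99)
    print(f"verification at tau = {round(tau_star)} ms: mean latency {check:.2f} ms")
    print(f"currently frozen default: {DEFAULT_BURST_RISE_TAU_MS} ms")


if __name__ == "__main__":
    main()
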