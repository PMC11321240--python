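import numpy as np
import pytest

import emdassist as ea
from emdassist import protocol, synthetic
from emdassist.errors import ParameterError

SPECS = {s.name: s for s in protocol.make_condition_specs()}


class TestBurstEnvelope:
    def test_causal(self):
        assert synthetic.burst_envelope(-5.0, 2.0, 100.0) == 0.0

    def test_peak_at_tau(self):
        assert synthetic.burst_envelope(100.0, 3.0, 100.0) == pytest.approx(3.0)

    def test_decay_value(self):
        # (10) * exp(1 - 10) = 10 * exp(-9)
        assert synthetic.burst_envelope(1000.0, 1.0, 100.0) == pytest.approx(
            10.0 * np.exp(-9.0), rel=1e-12
        )

    def test_vectorized_and_unimodal(self):
        t = np.linspace(-50, 2000, 500)
        env = synthetic.burst_envelope(t, 1.0, 150.0)
        assert env.max() <= 1.0 + 1e-12
        assert np.argmax(env) == np.argmin(np.abs(t - 150.0))

    def test_bad_tau_rejected(self):
        with pytest.raises(ParameterError):
            synthetic.burst_envelope(1.0, 1.0, 0.0)


class TestGeneratorParams:
    def test_defaults_valid(self):
        ea.GeneratorParams()

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"emg_rate": 0.0},
            {"burst_amplitude": -1.0},
            {"n_participants": 0},
        ],
    )
    def test_invalid_rejected(self, kwargs):
        with pytest.raises(ParameterError):
            ea.GeneratorParams(**kwargs)

    def test_non_unit_control_multiplier_rejected(self):
        effects = synthetic.default_condition_effects()
        effects["control"] = synthetic.ConditionEffect(agonist=1.1)
        with pytest.raises(ParameterError):
            ea.GeneratorParams(condition_effects=effects)


class TestGenerateTrial:
    def test_series_lengths_consistent(self, default_params):
        rng = np.random.default_rng(0)
        tr = synthetic.generate_trial(default_params, SPECS["control"], 1.0, rng)
        p = default_params
        assert tr.agonist_emg.size == int((p.pre_cue_rest_s + p.post_cue_s) * p.emg_rate)
        assert tr.antagonist_emg.size == tr.agonist_emg.size
        assert tr.wrist_xy.shape[0] == int((p.pre_cue_rest_s + p.post_cue_s) * p.mocap_rate)
        assert tr.rest_window == (0, tr.cue_index)
        assert tr.true_onset_index > tr.cue_index

    def test_control_trial_voluntary_motion_no_pull(self, default_params):
        rng = np.random.default_rng(1)
        tr = synthetic.generate_trial(default_params, SPECS["control"], 1.0, rng)
        assert tr.pull is None
        omega = ea.angular_velocity(tr.wrist_xy, tr.elbow_xy, tr.mocap_rate)
        assert omega[tr.cue_index // 10 :].max() > 0  # extension positive

    def test_passive_trial_pull_without_burst(self, default_params):
        rng = np.random.default_rng(2)
        tr = synthetic.generate_trial(default_params, SPECS["passive"], 1.0, rng)
        assert tr.true_onset_index is None
        assert tr.pull is not None and tr.pull.direction == +1
        # without a voluntary burst the post-cue EMG stays at rest level
        assert np.std(tr.agonist_emg[tr.cue_index :]) == pytest.approx(
            default_params.rest_noise_sd, rel=0.1
        )

    def test_rapid_assist_pull_within_electromechanical_delay(self, default_params):
        rng = np.random.default_rng(3)
        starts = []
        for _ in range(20):
            tr = synthetic.generate_trial(default_params, SPECS["rapid_assist"], 1.0, rng)
            if tr.pull is None:
                continue
            onset_s = (tr.true_onset_index - tr.cue_index) / tr.emg_rate
            starts.append(tr.pull.start_time - onset_s)
        # pull begins after onset but before the ~40 ms mechanical delay
        assert np.mean(starts) > 0
        assert np.mean(starts) < default_params.emd_ms / 1000.0

    def test_angular_velocity_peak_matches_actuator_profile(self, default_params):
        """Passive pulls have a known analytic peak: rope speed / forearm."""
        rng = np.random.default_rng(4)
        tr = synthetic.generate_trial(default_params, SPECS["passive"], 1.0, rng)
        omega = ea.angular_velocity(tr.wrist_xy, tr.elbow_xy, tr.mocap_rate)
        expected = tr.pull.rope_speed / default_params.forearm_length_m
        assert omega.max() == pytest.approx(expected, rel=0.05)


class TestCohort:
    def test_cohort_shape_and_determinism(self):
        params = ea.GeneratorParams(n_participants=2, seed=5)
        a = ea.generate_cohort(params)
        b = ea.generate_cohort(params)
        assert len(a.trials) == 2 * 250
        assert len(a.plans) == 2
        for ta, tb in zip(a.trials[::83], b.trials[::83]):
            assert np.array_equal(ta.agonist_emg, tb.agonist_emg)
            assert np.array_equal(ta.wrist_xy, tb.wrist_xy)
            assert ta.detection.onset_index == tb.detection.onset_index

    def test_passive_block_present_when_requested(self, tiny_cohort):
        assert len(tiny_cohort.trials) == 300
        assert all(t.condition == "passive" for t in tiny_cohort.trials[-50:])

    def test_missed_trigger_rate_below_one_percent(self, tiny_cohort):
        voluntary = [t for t in tiny_cohort.trials if t.condition != "passive"]
        rate = np.mean([t.missed_trigger for t in voluntary])
        assert rate < 0.01

    def test_reaction_time_mean_matches_generator(self, tiny_cohort):
        """Empirical true-onset reaction times agree with the 180 ms mean."""
        rts = np.array(
            [
                (t.true_onset_index - t.cue_index) / t.emg_rate * 1000.0
                for t in tiny_cohort.trials
                if t.condition == "control"
            ]
        )
        se = ea.GeneratorParams().reaction_sd_ms / np.sqrt(len(rts))
        assert abs(rts.mean() - 180.0) < 3 * se

    def test_trigger_latency_positive_and_below_emd(self, default_params):
        lat = ea.detector_latency_sample(default_params, 300, seed=8)
        assert 0 < lat.mean() < default_params.emd_ms

    def test_trial_metrics_requires_a_detected_onset(self, tiny_cohort):
        """Passive/missed trials are metric-less; voluntary trials are not."""
        control_means = {"agonist": 1.0, "antagonist": 1.0}
        passive = [t for t in tiny_cohort.trials if t.condition == "passive"]
        fired = [ea.trial_metrics(t, control_means) for t in passive]
        assert all(m is None or m.reaction_time is None for m in fired)
        voluntary = next(
            t for t in tiny_cohort.trials
            if t.condition == "control" and t.detection.onset_index is not None
        )
        m = ea.trial_metrics(voluntary, control_means)
        assert m is not None and m.reaction_time > 0 and m.peak_agonist_norm > 0
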