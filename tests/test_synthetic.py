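"""Tests of the generative two-step restart simulator against closed forms
and degenerate limits."""

import dataclasses

import numpy as np
import pytest

from selstop.synthetic import (
    FIRST_STEP_ERROR,
    NO_STOP_LABEL,
    RESTART_ERROR,
    STEP_LABELS,
    STOP_SUCCESS,
    TRIGGER_FAIL,
    EmgParams,
    RestartModelParams,
    default_params,
    sample_go_latencies,
    sample_participant_params,
    session_frame,
    simulate_session,
    simulate_stop_trial,
    synthesize_emg,
)
from selstop.task_model import (
    Effector,
    SessionConfig,
    StopVersion,
    TaskCondition,
    TrialOutcome,
)


def with_conditions(params, **overrides):
    """Clone params overriding per-condition dicts with a single value."""
    fixed = {}
    for key, value in overrides.items():
        current = getattr(params, key)
        fixed[key] = {c: value for c in current} if isinstance(current, dict) else value
    return dataclasses.replace(params, **fixed)


class TestGoLatencies:
    def test_zero_noise_gives_exact_foot_offset(self, params):
        p = dataclasses.replace(params, effector_noise_sd=0.0)
        wrist, foot = sample_go_latencies(p, np.random.default_rng(0), n=500)
        np.testing.assert_allclose(foot - wrist, p.foot_offset)

    def test_correlation_matches_variance_ratio(self):
        # shared var 6400, effector noise var 625: r = 6400/7025 ~ 0.911
        p = RestartModelParams(go_mu=400.0, go_sigma=80.0, go_tau=0.0,
                               effector_noise_sd=25.0)
        wrist, foot = sample_go_latencies(p, np.random.default_rng(1), n=100_000)
        r = np.corrcoef(wrist, foot)[0, 1]
        assert r == pytest.approx(6400 / 7025, abs=0.01)

    def test_mean_foot_lag_is_46_ms(self, params):
        wrist, foot = sample_go_latencies(params, np.random.default_rng(2), n=100_000)
        assert foot.mean() - wrist.mean() == pytest.approx(46.0, abs=1.0)


class TestStopTrial:
    def test_trigger_failure_resolves_as_race_free_go(self, params):
        p = dataclasses.replace(params, p_trigger_fail=1.0)
        go = (430.0, 480.0)
        trial = simulate_stop_trial(p, 200.0, StopVersion.STOP_WRIST,
                                    TaskCondition.MIX, np.random.default_rng(3),
                                    go_latencies=go)
        assert trial.step_label == TRIGGER_FAIL
        assert trial.latent_onset[Effector.WRIST] == go[0]
        assert trial.latent_onset[Effector.FOOT] == go[1]
        assert trial.record.outcome is TrialOutcome.ERROR

    def test_deterministic_restart_cost_is_visible(self, params):
        # stop wins outright; the moving foot restarts at ssd + stop + delay
        p = with_conditions(
            dataclasses.replace(params, p_trigger_fail=0.0, stop_sd=0.0,
                                p_wrong_effector=0.0, restart_delay_sd=0.0),
            restart_delay_mean=250.0, p_decouple_fail=0.0)
        trial = simulate_stop_trial(p, 0.0, StopVersion.STOP_WRIST,
                                    TaskCondition.MIX, np.random.default_rng(4),
                                    go_latencies=(300.0, 346.0))
        assert trial.step_label == STOP_SUCCESS
        assert trial.latent_onset[Effector.WRIST] is None
        assert trial.latent_onset[Effector.FOOT] == pytest.approx(0.0 + p.stop_mean + 250.0)
        assert trial.record.outcome is TrialOutcome.CORRECT

    def test_race_lost_on_both_effectors_keeps_go_finishes(self, params):
        p = dataclasses.replace(params, p_trigger_fail=0.0, stop_sd=0.0)
        go = (300.0, 346.0)
        trial = simulate_stop_trial(p, 400.0, StopVersion.STOP_BOTH,
                                    TaskCondition.BLOCK, np.random.default_rng(5),
                                    go_latencies=go)
        assert trial.step_label == FIRST_STEP_ERROR
        assert trial.latent_onset[Effector.WRIST] == go[0]
        assert trial.latent_onset[Effector.FOOT] == go[1]
        assert trial.record.outcome is TrialOutcome.ERROR

    def test_decouple_failure_moves_both_effectors_together(self, params):
        p = with_conditions(
            dataclasses.replace(params, p_trigger_fail=0.0, stop_sd=0.0,
                                p_wrong_effector=0.0, restart_delay_sd=0.0),
            restart_delay_mean=300.0, p_decouple_fail=1.0)
        trial = simulate_stop_trial(p, 100.0, StopVersion.STOP_WRIST,
                                    TaskCondition.MIX, np.random.default_rng(6),
                                    go_latencies=(500.0, 546.0))
        assert trial.step_label == RESTART_ERROR
        t = 100.0 + p.stop_mean + 300.0
        assert trial.latent_onset[Effector.WRIST] == pytest.approx(t)
        assert trial.latent_onset[Effector.FOOT] == pytest.approx(t)
        assert trial.latent_onset[Effector.WRIST] > trial.latent_stop_finish

    def test_negative_ssd_rejected(self, params):
        with pytest.raises(ValueError):
            simulate_stop_trial(params, -1.0, StopVersion.STOP_BOTH,
                                TaskCondition.BLOCK, np.random.default_rng(0))


class TestSession:
    def test_block_session_has_exact_design_counts(self, params):
        config = SessionConfig(n_trials=300, condition=TaskCondition.BLOCK,
                               block_version=StopVersion.STOP_BOTH, seed=8)
        frame = session_frame(simulate_session(config, params))
        assert (frame["trial_type"] == "no_stop").sum() == 210

    def test_same_seed_gives_identical_tables(self, params, tmp_path):
        from selstop.synthetic import split_tables
        from selstop.task_model import write_trial_table
        config = SessionConfig(n_trials=120, condition=TaskCondition.MIX, seed=9)
        paths = []
        for name in ("a.csv", "b.csv"):
            frame = session_frame(simulate_session(config, params))
            write_trial_table(split_tables(frame)[0], tmp_path / name)
            paths.append((tmp_path / name).read_bytes())
        assert paths[0] == paths[1]

    def test_staircase_converges_to_half_error_rate(self, mix_study):
        """After burn-in the tracked stop-error rate sits at 0.50 per version."""
        stop = mix_study[(mix_study["trial_type"] == "stop")
                         & (mix_study["stop_order"] >= 10)
                         & (mix_study["outcome"] != "aborted")]
        rates = stop.groupby("stop_version")["outcome"].apply(
            lambda s: (s == "error").mean())
        assert len(rates) == 3
        for rate in rates:
            assert rate == pytest.approx(0.50, abs=0.07)

    def test_step_labels_partition_stop_trials(self, mix_study):
        stop = mix_study[mix_study["trial_type"] == "stop"]
        assert set(stop["step_label"]) <= set(STEP_LABELS) - {NO_STOP_LABEL}
        assert stop["step_label"].notna().all()
        no_stop = mix_study[mix_study["trial_type"] == "no_stop"]
        assert (no_stop["step_label"] == NO_STOP_LABEL).all()

    def test_first_step_error_onset_equals_go_finish(self, mix_study):
        err = mix_study[(mix_study["step_label"] == FIRST_STEP_ERROR)
                        & (mix_study["stop_version"] == "stop_wrist")]
        np.testing.assert_allclose(err["wrist_mus_rt"], err["latent_go_wrist"])
        assert (err["wrist_mus_rt"] < err["latent_stop_finish"]).all()

    def test_restart_error_onset_after_stop_finish(self, mix_study):
        err = mix_study[(mix_study["step_label"] == RESTART_ERROR)
                        & (mix_study["stop_version"] == "stop_wrist")]
        assert len(err) > 0
        assert (err["wrist_mus_rt"] > err["latent_stop_finish"]).all()

    def test_participant_heterogeneity_preserves_bounds(self, params):
        rng = np.random.default_rng(10)
        for _ in range(50):
            drawn = sample_participant_params(params, rng)
            assert drawn.stop_mean >= 50.0
            assert drawn.p_trigger_fail == params.p_trigger_fail


class TestSyntheticEmg:
    def test_non_moving_effector_trace_is_stationary(self, params, rng):
        config = SessionConfig(n_trials=4, condition=TaskCondition.MIX, seed=1)
        trial = next(t for t in simulate_session(config, params)
                     if t.latent_onset[Effector.WRIST] is None
                     or t.latent_onset[Effector.FOOT] is None)
        eff = (Effector.WRIST if trial.latent_onset[Effector.WRIST] is None
               else Effector.FOOT)
        trace = synthesize_emg(trial, params.emg, rng)[eff]
        half = trace.samples.size // 2
        sd1, sd2 = trace.samples[:half].std(), trace.samples[half:].std()
        assert sd2 / sd1 == pytest.approx(1.0, abs=0.05)

    def test_zero_baseline_sd_gives_silent_pre_go(self, params, rng):
        emg = dataclasses.replace(params.emg, baseline_sd=0.0)
        config = SessionConfig(n_trials=4, condition=TaskCondition.MIX, seed=1)
        trial = simulate_session(config, params)[0]
        trace = synthesize_emg(trial, emg, rng)[Effector.WRIST]
        assert np.all(trace.samples[: trace.go_index] == 0.0)

    def test_closed_loop_onset_recovery(self, params, rng):
        from selstop.emg import detect_onset, process_trace
        config = SessionConfig(n_trials=40, condition=TaskCondition.BLOCK,
                               block_version=StopVersion.STOP_BOTH, seed=2)
        errors = []
        for trial in simulate_session(config, params):
            onset = trial.latent_onset[Effector.WRIST]
            if onset is None:
                continue
            trace = synthesize_emg(trial, params.emg, rng)[Effector.WRIST]
            detected = detect_onset(process_trace(trace))
            assert detected is not None
            errors.append(abs(detected - onset))
        assert np.median(errors) <= params.emg.burst_rise_ms + 10.0

    def test_invalid_emg_config_rejected(self):
        with pytest.raises(Exception):
            EmgParams(sampling_rate=0.0)
        with pytest.raises(Exception):
            EmgParams(burst_gain=0.5)
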