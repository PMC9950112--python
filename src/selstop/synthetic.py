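"""Generative two-step restart race model with latent ground truth.

The simulator emulates a multi-effector selective stop-signal session:

* A *shared* Go process (ex-Gaussian) drives both effectors; the foot lags
  the wrist by a fixed offset (~46 ms) and each effector adds independent
  Gaussian noise, reproducing the strong wrist-foot latency correlation of a
  common Go process.
* An independent Stop process (Normal, truncated at 0, mean ~150 ms) races
  the Go process from Stop-signal onset.  With probability
  ``p_trigger_fail`` it is never triggered and the trial resolves as a
  race-free Go.
* Selective stopping is two-step: a *global* inhibition first pauses both
  effectors (any effector whose Go finish beats the Stop finish escapes and
  moves - a first-step race loss), then the effector that must keep moving
  *restarts* after a context-dependent delay.  The restart can fail by
  keeping the two effectors coupled (both restart: ``p_decouple_fail``) or
  by reactivating the wrong effector (``p_wrong_effector``) - both produce
  Stop Errors whose muscle onsets sit *after* the Stop process finished.

Every simulated trial carries its latent truth (Go/Stop finishing times,
which process step produced the outcome, true EMG onsets) so downstream
estimators can be validated against ground truth.  Overt movement times add
a per-effector electromechanical delay (wrist ~90 ms, foot ~140 ms) with
small jitter.  ``synthesize_emg`` renders surface-EMG-like traces (quiet
Gaussian baseline, amplitude burst from the latent onset) at 6104 Hz.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .emg import EMGTrace
from .task_model import (
    NO_STOP,
    STOP,
    ConfigError,
    Effector,
    SessionConfig,
    StaircaseState,
    StopVersion,
    TaskCondition,
    TrialOutcome,
    TrialRecord,
    TRIAL_TABLE_COLUMNS,
    allocate_trials,
    classify_trial,
    next_ssd,
)

# step labels of SimulatedTrial
FIRST_STEP_ERROR = "first_step_error"
RESTART_ERROR = "restart_error"
STOP_SUCCESS = "stop_success"
TRIGGER_FAIL = "trigger_fail"
NO_STOP_LABEL = "no_stop"

STEP_LABELS = (FIRST_STEP_ERROR, RESTART_ERROR, STOP_SUCCESS, TRIGGER_FAIL, NO_STOP_LABEL)


@dataclass(frozen=True)
class EmgParams:
    """Parameters of the synthetic surface-EMG renderer.

    The burst is modelled as Gaussian noise whose standard deviation ramps
    linearly from ``baseline_sd`` to ``burst_gain * baseline_sd`` over
    ``burst_rise_ms`` starting at the latent onset, then persists.
    """

    sampling_rate: float = 6104.0
    baseline_sd: float = 1.0
    burst_gain: float = 8.0
    burst_rise_ms: float = 15.0
    trace_pre_go_ms: float = 200.0
    trace_post_go_ms: float = 1600.0

    def __post_init__(self) -> None:
        if self.sampling_rate <= 0:
            raise ConfigError("sampling_rate must be positive")
        if self.burst_gain <= 1:
            raise ConfigError("burst_gain must exceed 1")
        if self.baseline_sd < 0:
            raise ConfigError("baseline_sd must be non-negative")


@dataclass(frozen=True)
class RestartModelParams:
    """All generative parameters of the two-step restart race model.

    Defaults are calibrated to the summary statistics typical of wrist+foot
    selective stopping (mean wrist muscle onset ~450 ms with SD ~85 ms,
    foot lagging by 46 ms, wrist-foot correlation ~0.8, SSRT ~150 ms,
    electromechanical delays ~90/140 ms).  ``restart_delay_mean`` and
    ``p_decouple_fail`` are per task condition: with foreknowledge of the
    effector to stop (block) the restart is fast and rarely fails; without
    it (mix) the restart is slow and decoupling failures are common.
    These two fields are the "block"/"mix" preset bundles.
    """

    go_mu: float = 410.0
    go_sigma: float = 75.0
    go_tau: float = 40.0
    foot_offset: float = 46.0
    effector_noise_sd: float = 40.0
    stop_mean: float = 150.0
    stop_sd: float = 30.0
    p_trigger_fail: float = 0.02
    restart_delay_mean: dict[TaskCondition, float] = field(
        default_factory=lambda: {TaskCondition.BLOCK: 120.0, TaskCondition.MIX: 400.0})
    restart_delay_sd: float = 50.0
    p_decouple_fail: dict[TaskCondition, float] = field(
        default_factory=lambda: {TaskCondition.BLOCK: 0.03, TaskCondition.MIX: 0.20})
    p_wrong_effector: float = 0.03
    em_delay: dict[Effector, float] = field(
        default_factory=lambda: {Effector.WRIST: 90.0, Effector.FOOT: 140.0})
    em_jitter_sd: float = 5.0
    # cohort-level heterogeneity, applied per participant by simulate_study
    participant_go_mu_sd: float = 70.0
    participant_stop_mean_sd: float = 25.0
    emg: EmgParams = field(default_factory=EmgParams)

    def __post_init__(self) -> None:
        for p in (self.p_trigger_fail, self.p_wrong_effector,
                  *self.p_decouple_fail.values()):
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"probability {p} outside [0, 1]")
        for sd in (self.go_sigma, self.go_tau, self.effector_noise_sd, self.stop_sd,
                   self.restart_delay_sd, self.em_jitter_sd,
                   self.participant_go_mu_sd, self.participant_stop_mean_sd):
            if sd < 0:
                raise ConfigError("standard deviations must be non-negative")


def default_params() -> RestartModelParams:
    """The default parameter bundle (block and mix presets included)."""
    return RestartModelParams()


@dataclass
class SimulatedTrial:
    """One simulated trial: the observable record plus its latent truth."""

    record: TrialRecord
    latent_go_finish: dict[Effector, float]
    latent_stop_finish: Optional[float]
    step_label: str
    latent_onset: dict[Effector, Optional[float]]
    stop_order: Optional[int] = None  # position within this staircase's stop trials


def sample_participant_params(
    params: RestartModelParams, rng: np.random.Generator
) -> RestartModelParams:
    """Draw one participant's parameters from the cohort distribution.

    Only the shared Go mean and the Stop-process mean vary between
    participants; the Stop mean is kept at or above 50 ms.
    """
    go_mu = params.go_mu + rng.normal(0.0, params.participant_go_mu_sd)
    stop_mean = max(50.0, params.stop_mean + rng.normal(0.0, params.participant_stop_mean_sd))
    return replace(params, go_mu=go_mu, stop_mean=stop_mean)


def sample_go_latencies(
    params: RestartModelParams, rng: np.random.Generator, n: int = 1
) -> tuple[np.ndarray, np.ndarray]:
    """Sample per-effector latent muscle-onset latencies for ``n`` trials.

    wrist = G + e_w, foot = G + foot_offset + e_f, with G ex-Gaussian
    (mu, sigma, tau) shared between effectors and e iid Normal(0,
    effector_noise_sd).  Returns ``(wrist, foot)`` arrays of length n.
    """
    g = rng.normal(params.go_mu, params.go_sigma, n) + rng.exponential(params.go_tau, n)
    wrist = g + rng.normal(0.0, params.effector_noise_sd, n)
    foot = g + params.foot_offset + rng.normal(0.0, params.effector_noise_sd, n)
    return wrist, foot


def _positive_normal(rng: np.random.Generator, mean: float, sd: float) -> float:
    """Normal(mean, sd) truncated at 0 (rejection sampling; sd=0 clips)."""
    if sd == 0.0:
        return max(0.0, mean)
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if x >= 0.0:
            return x
    return 0.0  # pathological mean << 0


def _finish_trial(
    params: RestartModelParams,
    rng: np.random.Generator,
    config: SessionConfig,
    trial_index: int,
    version: Optional[StopVersion],
    ssd: Optional[float],
    onsets: dict[Effector, Optional[float]],
    go: dict[Effector, float],
    stop_finish: Optional[float],
    step_label: str,
    em_jitter: Optional[dict[Effector, float]] = None,
) -> SimulatedTrial:
    """Assemble the observable record from latent onsets."""
    rts: dict[Effector, Optional[float]] = {}
    for eff in Effector:
        t = onsets[eff]
        if t is None:
            rts[eff] = None
        else:
            jitter = (em_jitter[eff] if em_jitter is not None
                      else rng.normal(0.0, params.em_jitter_sd))
            rts[eff] = t + params.em_delay[eff] + jitter
    wrist_moved = onsets[Effector.WRIST] is not None
    foot_moved = onsets[Effector.FOOT] is not None
    outcome = classify_trial(
        version, wrist_moved, foot_moved,
        rts[Effector.WRIST], rts[Effector.FOOT], config, ssd=ssd)
    record = TrialRecord(
        trial_index=trial_index,
        trial_type=NO_STOP if version is None else STOP,
        condition=config.condition,
        stop_version=version,
        ssd=ssd,
        wrist_moved=wrist_moved,
        foot_moved=foot_moved,
        wrist_mus_rt=onsets[Effector.WRIST],
        foot_mus_rt=onsets[Effector.FOOT],
        wrist_rt=rts[Effector.WRIST],
        foot_rt=rts[Effector.FOOT],
        outcome=outcome,
    )
    return SimulatedTrial(
        record=record,
        latent_go_finish=dict(go),
        latent_stop_finish=stop_finish,
        step_label=step_label,
        latent_onset=dict(onsets),
    )


def simulate_stop_trial(
    params: RestartModelParams,
    ssd: float,
    version: StopVersion,
    condition: TaskCondition,
    rng: np.random.Generator,
    *,
    config: Optional[SessionConfig] = None,
    go_latencies: Optional[tuple[float, float]] = None,
    em_jitter: Optional[dict[Effector, float]] = None,
    trial_index: int = 0,
) -> SimulatedTrial:
    """Simulate one stop trial of the two-step restart race.

    Sequence of events: with probability ``p_trigger_fail`` the Stop process
    never starts and both effectors move at their Go finishes.  Otherwise the
    global first step completes at ``ssd + S`` (S ~ truncated Normal); every
    effector whose Go finish beats it escapes (a first-step error when a
    to-be-stopped effector escapes).  If the to-be-stopped effector(s) were
    held: non-selective trials end as stop successes; selective trials enter
    the restart step, where the moving effector restarts after a
    context-dependent delay unless a decoupling failure restarts both
    effectors or the wrong effector alone is reactivated (both restart
    errors).  A restarted effector responds at the later of its own Go
    finish and ``stop_finish + delay``: the pause can only cost time.
    """
    if ssd < 0:
        raise ValueError("ssd must be non-negative")
    version = StopVersion(version)
    condition = TaskCondition(condition)
    if config is None:
        config = SessionConfig(condition=condition,
                               block_version=version if condition is TaskCondition.BLOCK else None)
    if go_latencies is None:
        w, f = sample_go_latencies(params, rng)
        go = {Effector.WRIST: float(w[0]), Effector.FOOT: float(f[0])}
    else:
        go = {Effector.WRIST: float(go_latencies[0]), Effector.FOOT: float(go_latencies[1])}

    def finish(onsets, stop_finish, label):
        return _finish_trial(params, rng, config, trial_index, version, ssd,
                             onsets, go, stop_finish, label, em_jitter)

    if rng.random() < params.p_trigger_fail:
        # stop process never starts: race-free Go, both effectors respond
        onsets = {eff: go[eff] for eff in Effector}
        return finish(onsets, None, TRIGGER_FAIL)

    stop_finish = ssd + _positive_normal(rng, params.stop_mean, params.stop_sd)
    targets = ([Effector.WRIST, Effector.FOOT] if version is StopVersion.STOP_BOTH
               else [version.stopped_effector])
    escaped = [eff for eff in targets if go[eff] < stop_finish]

    onsets: dict[Effector, Optional[float]] = {eff: None for eff in Effector}
    if escaped:
        for eff in escaped:
            onsets[eff] = go[eff]
        if version.is_selective:
            mover = version.moving_effector
            if go[mover] < stop_finish:
                onsets[mover] = go[mover]
            else:
                delay = _positive_normal(
                    rng, params.restart_delay_mean[condition], params.restart_delay_sd)
                onsets[mover] = max(go[mover], stop_finish + delay)
        return finish(onsets, stop_finish, FIRST_STEP_ERROR)

    if version is StopVersion.STOP_BOTH:
        return finish(onsets, stop_finish, STOP_SUCCESS)

    mover = version.moving_effector
    stopped = version.stopped_effector
    if go[mover] < stop_finish:
        # the moving effector finished before the global pause completed:
        # nothing to restart, the stopped effector stays inhibited
        onsets[mover] = go[mover]
        return finish(onsets, stop_finish, STOP_SUCCESS)

    delay = _positive_normal(
        rng, params.restart_delay_mean[condition], params.restart_delay_sd)
    # a paused motor program cannot complete before its own Go finish, so a
    # restarted effector responds at the later of the two (pause cost >= 0)
    t_restart = stop_finish + delay
    u = rng.random()
    if u < params.p_decouple_fail[condition]:
        # decoupling failure: both effectors restart together
        onsets[mover] = max(go[mover], t_restart)
        onsets[stopped] = max(go[stopped], t_restart)
        return finish(onsets, stop_finish, RESTART_ERROR)
    if u < params.p_decouple_fail[condition] + params.p_wrong_effector:
        # the wrong effector alone is reactivated
        onsets[stopped] = max(go[stopped], t_restart)
        return finish(onsets, stop_finish, RESTART_ERROR)
    onsets[mover] = max(go[mover], t_restart)
    return finish(onsets, stop_finish, STOP_SUCCESS)


def simulate_session(
    config: SessionConfig,
    params: RestartModelParams,
    seed: Optional[int] = None,
    participant_id: str = "p0",
) -> list[SimulatedTrial]:
    """Simulate a full session: allocation, staircase tracking, outcomes.

    The trial sequence comes from :func:`allocate_trials` (seeded by
    ``config.seed``); the behavioural randomness uses ``seed`` (defaulting
    to ``config.seed``).  Each stop version runs its own SSD staircase
    (three in mix sessions) that updates after every non-aborted stop trial;
    SSDs are clipped to [0, upper_rt_limit].
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    sequence = allocate_trials(config)
    n = len(sequence)
    wrist_go, foot_go = sample_go_latencies(params, rng, n)
    jw = rng.normal(0.0, params.em_jitter_sd, n)
    jf = rng.normal(0.0, params.em_jitter_sd, n)

    versions = ([config.block_version] if config.condition is TaskCondition.BLOCK
                else list(StopVersion))
    staircases = {
        v: StaircaseState(config.staircase_start, config.staircase_step,
                          floor=0.0, ceiling=config.upper_rt_limit)
        for v in versions
    }
    stop_counts = {v: 0 for v in versions}

    trials: list[SimulatedTrial] = []
    for i, (trial_type, version) in enumerate(sequence):
        go = (float(wrist_go[i]), float(foot_go[i]))
        jitter = {Effector.WRIST: float(jw[i]), Effector.FOOT: float(jf[i])}
        if trial_type == NO_STOP:
            onsets = {Effector.WRIST: go[0], Effector.FOOT: go[1]}
            trial = _finish_trial(
                params, rng, config, i, None, None, onsets,
                {Effector.WRIST: go[0], Effector.FOOT: go[1]}, None,
                NO_STOP_LABEL, jitter)
        else:
            state = staircases[version]
            trial = simulate_stop_trial(
                params, state.current_ssd, version, config.condition, rng,
                config=config, go_latencies=go, em_jitter=jitter, trial_index=i)
            trial.stop_order = stop_counts[version]
            stop_counts[version] += 1
            if trial.record.outcome is not TrialOutcome.ABORTED:
                staircases[version] = next_ssd(state, trial.record.outcome)
        trial.record.participant_id = participant_id
        trials.append(trial)
    return trials


LATENT_COLUMNS = [
    "participant_id", "condition", "session_version", "trial_index",
    "step_label", "latent_go_wrist", "latent_go_foot", "latent_stop_finish",
    "latent_onset_wrist", "latent_onset_foot",
]


def session_frame(
    trials: Iterable[SimulatedTrial],
    session_version: str = "",
) -> pd.DataFrame:
    """Flatten simulated trials into a single analysis table.

    Contains both the observable trial-table columns and the latent-truth
    columns; :func:`split_tables` separates them for writing.
    ``session_version`` labels which block session a row came from (empty
    for mix sessions).
    """
    rows = []
    for t in trials:
        r = t.record
        rows.append((
            r.participant_id, r.condition.value, session_version, r.trial_index,
            r.trial_type, r.stop_version.value if r.stop_version else "",
            t.stop_order, r.ssd,
            r.wrist_moved, r.foot_moved,
            r.wrist_mus_rt, r.foot_mus_rt, r.wrist_rt, r.foot_rt,
            r.outcome.value if r.outcome else "",
            t.step_label,
            t.latent_go_finish[Effector.WRIST], t.latent_go_finish[Effector.FOOT],
            t.latent_stop_finish,
            t.latent_onset[Effector.WRIST], t.latent_onset[Effector.FOOT],
        ))
    columns = TRIAL_TABLE_COLUMNS + [
        "step_label", "latent_go_wrist", "latent_go_foot", "latent_stop_finish",
        "latent_onset_wrist", "latent_onset_foot",
    ]
    frame = pd.DataFrame(rows, columns=columns)
    return frame


def split_tables(frame: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split a combined session frame into (trial table, latent-truth table)."""
    trial = frame[TRIAL_TABLE_COLUMNS].copy()
    latent = frame[LATENT_COLUMNS].copy()
    return trial, latent


def simulate_study(
    n_participants: int,
    params: RestartModelParams,
    seed: int,
    conditions: Sequence[TaskCondition] = (TaskCondition.BLOCK, TaskCondition.MIX),
    block_trials: int = 300,
    mix_trials: int = 600,
) -> pd.DataFrame:
    """Simulate a cohort: per-participant parameters plus all sessions.

    Block condition runs one ``block_trials``-trial session per stop version;
    mix runs a single ``mix_trials``-trial session.  Participant-level
    heterogeneity is drawn via :func:`sample_participant_params`.
    Returns the combined analysis frame of every trial.
    """
    root = np.random.SeedSequence(seed)
    frames = []
    for p, child in enumerate(root.spawn(n_participants)):
        prng = np.random.default_rng(child)
        p_params = sample_participant_params(params, prng)
        pid = f"p{p:02d}"
        session_seeds = prng.integers(0, 2**31 - 1, size=4)
        if TaskCondition.BLOCK in conditions:
            for v_i, version in enumerate(StopVersion):
                config = SessionConfig(
                    n_trials=block_trials, condition=TaskCondition.BLOCK,
                    block_version=version, seed=int(session_seeds[v_i]))
                trials = simulate_session(config, p_params, participant_id=pid)
                frames.append(session_frame(trials, session_version=version.value))
        if TaskCondition.MIX in conditions:
            config = SessionConfig(
                n_trials=mix_trials, condition=TaskCondition.MIX,
                seed=int(session_seeds[3]))
            trials = simulate_session(config, p_params, participant_id=pid)
            frames.append(session_frame(trials, session_version=""))
    return pd.concat(frames, ignore_index=True)


def synthesize_emg(
    trial: SimulatedTrial,
    emg: Optional[EmgParams] = None,
    rng: Optional[np.random.Generator] = None,
) -> dict[Effector, EMGTrace]:
    """Render synthetic surface-EMG traces for both effectors of a trial.

    The trace is zero-mean Gaussian noise whose standard deviation is
    ``baseline_sd`` everywhere except after the effector's latent onset,
    where it ramps linearly over ``burst_rise_ms`` to
    ``burst_gain * baseline_sd`` and persists to the end of the trace.
    Non-moving effectors get a stationary baseline-only trace.  The latent
    onset is carried on the returned traces for closed-loop validation.
    """
    if emg is None:
        emg = EmgParams()
    if rng is None:
        rng = np.random.default_rng()
    rate = emg.sampling_rate
    n_pre = int(round(emg.trace_pre_go_ms * rate / 1000.0))
    n_post = int(round(emg.trace_post_go_ms * rate / 1000.0))
    n = n_pre + n_post
    rise = max(emg.burst_rise_ms * rate / 1000.0, 1.0)

    traces: dict[Effector, EMGTrace] = {}
    for eff in Effector:
        onset = trial.latent_onset[eff]
        sd = np.full(n, emg.baseline_sd)
        if onset is not None:
            i0 = n_pre + onset * rate / 1000.0
            idx = np.arange(n)
            ramp = np.clip((idx - i0) / rise, 0.0, 1.0)
            sd = emg.baseline_sd * (1.0 + (emg.burst_gain - 1.0) * ramp)
        samples = rng.normal(0.0, 1.0, n) * sd
        traces[eff] = EMGTrace(
            samples=samples,
            sampling_rate=rate,
            go_index=n_pre,
            effector=eff,
            trial_index=trial.record.trial_index,
            participant_id=trial.record.participant_id,
            latent_onset_ms=onset,
        )
    return traces
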