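# Methods

This note documents the generative model, the analysis conventions, the
default parameters and the design decisions behind `selstop`, together with
what the synthetic validation does and does not demonstrate.

## Task and trial outcomes

Each trial requires a simultaneous wrist-extension + foot-flexion response
to a Go signal. 70% of trials are No-Stop; 30% carry a Stop signal at an
adaptively tracked delay (SSD). Outcomes follow the standard rules: a
No-Stop trial is correct when both effectors move within the 1300 ms upper
RT limit and within 200 ms of each other; a non-selective (stop-both) trial
is an error when any effector moves within 1300 ms of the Stop signal; a
selective trial is an error exactly when the to-be-stopped effector moves,
correct when it holds and the other effector moves in time, and aborted
otherwise. Times are milliseconds from Go onset; the Stop signal occurs at
t = SSD.

The SSD staircase is one-up/one-down with a 50 ms step from a 50 ms start,
tracking ~50% stopping success; each stop version runs its own tracker
(three in mixed sessions). SSDs are clipped to [0, 1300] ms — the floor
keeps the Stop signal after the Go signal, the ceiling keeps it inside the
response window. Aborted trials do not advance the staircase, which is
defined on the correct/error outcomes only. Trial-type allocation uses
exact counts with largest-remainder rounding and a seeded permutation, so
the design fractions are testable exactly rather than only in expectation.

## Generative two-step restart model

Latent muscle-onset latencies come from a shared Go process
G ~ ex-Gaussian(mu, sigma, tau) with per-effector Gaussian noise:

    wrist = G + e_w,   foot = G + 46 ms + e_f.

The shared component makes wrist and foot latencies strongly correlated
(the signature of a single Go process driving both effectors); the fixed
offset reflects the larger moving mass of the foot.

On a stop trial, unless the Stop process fails to trigger (probability
`p_trigger_fail`, in which case both effectors simply respond at their Go
finishes), the global first inhibition step completes at

    stop_finish = SSD + S,   S ~ Normal(stop_mean, stop_sd) truncated at 0.

Every effector whose Go finish precedes `stop_finish` escapes and responds
at its Go finish — a first-step race loss when the escaped effector was to
be stopped. If the to-be-stopped effector(s) are held, non-selective trials
end as stop successes; selective trials enter the restart step: the mover
restarts after D ~ Normal(restart_delay_mean[condition], restart_delay_sd),
truncated at 0. With probability `p_decouple_fail` the two effectors fail
to decouple and both restart together; with probability `p_wrong_effector`
only the wrong (stopped) effector is reactivated. Both are restart errors
whose onsets necessarily follow `stop_finish`. A restarted effector
responds at `max(go_finish, stop_finish + D)`: a paused motor program
cannot complete before its own Go process would have, so the pause can only
cost time. When the mover's Go finish precedes `stop_finish` it has already
responded and there is nothing to restart; such selective trials resolve as
stop successes without a decoupling opportunity.

Observable movement times add a per-effector electromechanical delay
(wrist 90 ms, foot 140 ms) with 5 ms Gaussian jitter, constant across
conditions.

### Default parameters

| parameter | default | rationale |
|---|---|---|
| go mu, sigma, tau | 410, 75, 40 ms | mean 450 ms, SD 85 ms, moderate right skew — typical wrist MusRT summary statistics |
| foot_offset | 46 ms | observed wrist→foot onset lag |
| effector_noise_sd | 40 ms | yields wrist–foot rank correlation ≈ 0.82 |
| stop_mean, stop_sd | 150, 30 ms | non-selective SSRT in the 140–160 ms range |
| p_trigger_fail | 0.02 | small trigger-failure rate, standard in race-model fits |
| restart_delay_mean | block 120 / mix 400 ms | foreknowledge makes the restart fast; without it the restart is slow (mix stop-correct interference ≈ 350–420 ms) |
| p_decouple_fail | block 0.03 / mix 0.20 | decoupling failures are the dominant restart error without foreknowledge |
| p_wrong_effector | 0.03 | rare wrong-effector reactivation after a successful first step |
| em_delay | wrist 90 / foot 140 ms (±5 jitter) | electromechanical delay, condition-invariant |
| participant_go_mu_sd / participant_stop_mean_sd | 70 / 25 ms | cohort heterogeneity; between-participant SDs of session means are ~70–130 ms (MusRT) and ~25–40 ms (stopping latency). Identical simulated participants would make every group test unrealistically powerful. Applied only by `simulate_study`; `simulate_session` uses the parameters verbatim. |

The block/mix presets differ **only** in `restart_delay_mean` and
`p_decouple_fail`, isolating the effect of effector foreknowledge; both
live as per-condition fields of one `RestartModelParams` bundle. They are
synthetic calibrations chosen to reproduce qualitative patterns, not fitted
quantities.

### Synthetic EMG

`synthesize_emg` renders each moving effector as zero-mean Gaussian noise
whose standard deviation ramps linearly from `baseline_sd` to
`burst_gain x baseline_sd` (default gain 8, rise 15 ms) at the latent onset
and persists, sampled at 6104 Hz with 200 ms of pre-Go baseline. This
emulates the amplitude statistics that threshold onset detection relies on;
it does not model motor-unit physiology, partial bursts on successfully
stopped effectors, movement artefacts or powerline noise. Passing the
closed-loop detection tests therefore shows the detector recovers onsets
from bursts of realistic SNR and timing, not that it is robust to every
artefact of real surface EMG.

## EMG processing

MusRT detection follows the standard chain: full-wave rectification, a
centred moving average (default 10 ms — short enough to bias onsets by
< 5 ms at 6104 Hz; edges use the truncated window), then the first post-Go
sample exceeding `baseline mean + k x baseline SD` (k = 2.5, baseline =
100 ms before Go, computed on the processed signal) that stays above
threshold for `sustain_ms` (default 10 ms, rejecting single-sample spikes).
The search starts at the Go signal, so MusRT is never negative; a sustained
pre-Go crossing flags the trial as contaminated and excludes it instead.
All three tuning constants are exposed as configuration. Note that with the
sustain window equal to the smoothing window the sustain rule is a weak
guard — the smoothed signal is autocorrelated at that scale — so a small
tail (~5%) of detections fires early on baseline noise; the median absolute
onset error on high-SNR synthetic bursts stays under 2 ms.

## Race-model analysis conventions

* **Cells.** A cell is participant x condition x stop version. Block cells
  take their No-Stop reference from the same block session; mix cells share
  the mix session's No-Stop pool. The first 10 stop trials of each
  staircase are excluded from every stopping statistic (they carry the ramp
  from the fixed 50 ms start).
* **Analysed latency.** Selective cells use the *stopped* effector's MusRT.
  Non-selective independence tests pool both effectors (errors contribute
  the mean of their moved effectors' onsets). Non-selective **SSRT**
  estimation instead uses the per-trial earliest onset min(wrist, foot),
  because the stop-both race is lost as soon as the first effector escapes;
  using the pooled mean would inflate SSRT by ~25 ms.
* **Independence.** Two-tailed paired t-test across participants at
  alpha = 0.05 on (mean Stop Error MusRT, mean No-Stop MusRT). `violated`
  means a *significant reversal* (errors slower); errors faster — however
  strong — respects the race model.
* **SSRT.** The mean method (mean No-Stop MusRT − mean SSD) is primary
  because the staircase tracks 50% response probability; the integration
  method (No-Stop quantile at the realized response rate − mean SSD) is the
  cross-check. Estimates from cells with violated independence or fewer
  than 20 post-burn-in stop trials are flagged invalid and excluded from
  group averages.
* **Group SSRT comparisons** use a between-subjects one-way ANOVA across
  cells (the convention of the analyses this package mirrors); the
  repeated-measures toolkit is available where a within-subject design is
  wanted.

## Restart decomposition

Stop End = non-selective SSRT of the matching condition + the cell's mean
selective SSD, per participant. Errors with MusRT strictly below the Stop
End are Compliant; ties and later onsets are Non-Compliant (the tie rule is
fixed for determinism; ties have measure zero). Per-subset SSD means come
from the contributing trials. Wrong-effector restart errors contribute the
erroneously moved effector's onset like any other error. Participants
without a valid non-selective SSRT are skipped and logged. The z-test on
Compliant proportions between conditions pools trials across participants
by default (per-participant averaging is available via the split table).

### What the latent-truth validation shows — and a known limitation

With mix-like presets the full Stop Error set reliably violates
independence for the selective versions while stop-both never does; cutting
at the Stop End restores the error-faster direction in essentially every
replicate cohort, and the Compliant-subset SSRT is statistically
indistinguishable from the non-selective SSRT at cohort scale. Compliant-
labelled errors are ~97% genuine first-step race losses.

The Non-Compliant label, however, is impure by construction. First-step
race losses concentrate just below each trial's own `stop_finish =
SSD_i + S_i`, while the Stop End is a per-participant *average*
(mean SSD + SSRT). Whenever the staircase's trial-to-trial SSD spread (~1–2
steps) plus the stop-latency noise places `stop_finish` above the Stop End
— disproportionately the long-SSD trials where escapes are most likely —
the escaped onsets can land past the cut. Under the default conditions
~35–40% of first-step losses do, so roughly half of the Non-Compliant
subset consists of mislabelled race losses (restart errors themselves are
essentially never mislabelled, since they sit a full restart delay beyond
the stop finish). Two measurable consequences: the Compliant/Non-Compliant
SSD contrast, while positive (race losses happen at long SSDs, restart
errors at short ones), is attenuated; and the Compliant-subset SSRT retains
a residual upward bias of ~20 ms — still roughly half the bias of the naive
full-cell selective estimate. The package reports the full confusion matrix
(`compliance_fidelity`) so this asymmetry is visible rather than hidden; a
per-trial stop-finish criterion would remove it but is unobservable without
latent truth, which is exactly why the decomposition uses the average.

## Statistics toolkit

Self-contained classical implementations: two-way repeated-measures ANOVA
by direct sum-of-squares decomposition with each effect's
subject-interaction stratum as its error term and partial eta squared
SS_effect/(SS_effect+SS_error); paired t; Bonferroni (min(1, p·m));
Spearman with average-rank ties and the t-approximation p-value; a
between-subjects one-way ANOVA; and the conventional eta_p² labels
(0.01/0.06/0.14). Sphericity corrections are omitted — exact for two-level
factors, uncorrected dfs reported otherwise (noted in table metadata).
Everything is verified in the test suite against brute-force oracles
(explicit-loop SS decomposition, exact sign-flip permutation, exact
conditional hypergeometric, manual rank arithmetic) and against pingouin /
scipy as independent implementations.

## Problem sizes and numerical choices

Validation runs use the study's design sizes: 300-trial block sessions,
600-trial mix sessions, 9-participant cohorts. SSRT recovery uses one
5000-stop-trial non-selective cell; the replicate battery scores 100
independent 9-participant mix cohorts with 200 stop trials per version per
participant (2000-trial sessions), enough for every per-participant
Compliant subset to clear the 20-trial validity threshold; label-fidelity
uses a 27-participant cohort so the SSD-contrast sign is stable. Truncated
normal draws use rejection sampling (the clip at zero is negligible for all
default parameters). All randomness flows from seeded
`numpy.random.Generator` streams; identical seeds reproduce sessions, study
tables and report digests byte for byte.

## Limitations

* No proactive slowing of No-Stop responses is modelled (none was needed to
  reproduce the target patterns), and partial EMG bursts on successfully
  stopped effectors are out of scope.
* The simulator's between-participant heterogeneity is limited to the Go
  mean and Stop mean; real cohorts vary in every parameter.
* The mean-method SSRT inherits a small (+5–7 ms) positive bias from the
  right skew of the Go distribution at the 50%-tracking point; the
  integration method shares the staircase-mean convention.
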