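"""Race-model statistics: independence tests, SSRT, interference, coupling.

The horse-race model treats stopping as a race between a Go process
(triggered by the Go signal) and an independent Stop process (triggered by
the Stop signal at t = SSD).  Its context-independence assumption implies
that Stop Error responses are drawn from the fast tail of the Go
distribution and must therefore be *faster* on average than No Stop
responses; a significant reversal (errors slower) violates the model and
invalidates SSRT estimation for that cell.

SSRT estimators: because the SSD staircase tracks ~50% stopping success,
the *mean method* (mean No Stop latency minus mean SSD) is the primary
estimator; the *integration method* (Go-distribution quantile at the
response probability minus mean SSD) is provided as a cross-check.  All
latencies here are muscle reaction times (MusRT), measured from Go onset.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .stats import paired_t, spearman
from .task_model import StopVersion, TaskCondition

DEFAULT_ALPHA = 0.05
DEFAULT_BURN_IN = 10
MIN_STOP_TRIALS = 20

ERROR_FASTER = "error_faster"
ERROR_SLOWER = "error_slower"


@dataclass
class SSRTEstimate:
    """A per-participant, per-cell stopping-latency estimate.

    ``valid`` is False when the estimate should not enter group averages
    (too few trials, or the cell's independence assumption is violated).
    """

    ssrt: float
    method: str  # "mean" | "integration" | "mean/compliant"
    mean_ssd: float
    n_stop_trials: int
    valid: bool = True
    participant_id: str = ""
    condition: Optional[TaskCondition] = None
    version: Optional[StopVersion] = None


@dataclass
class IndependenceResult:
    """Group-level paired test of the race model's independence assumption."""

    stop_error_means: np.ndarray  # per participant
    no_stop_means: np.ndarray
    t_stat: float
    df: int
    p_value: float
    direction: str  # ERROR_FASTER | ERROR_SLOWER
    violated: bool
    alpha: float = DEFAULT_ALPHA
    condition: Optional[TaskCondition] = None
    version: Optional[StopVersion] = None


def mean_method_ssrt(
    no_stop_musrts: Sequence[float],
    ssds: Sequence[float],
    burn_in: int = DEFAULT_BURN_IN,
    min_trials: int = MIN_STOP_TRIALS,
    **ids,
) -> SSRTEstimate:
    """Mean-method SSRT: mean(No Stop MusRT) - mean(SSD).

    Valid because the staircase holds the response probability at 0.5, where
    the mean SSD marks the point at which Go and Stop finish together on
    average.  ``ssds`` must be in staircase order: the first ``burn_in``
    stop trials are dropped to remove the ramp from the fixed starting SSD.
    Fewer than ``min_trials`` SSDs after burn-in yields ``valid=False`` with
    a warning rather than an error.
    """
    no_stop = np.asarray(no_stop_musrts, dtype=float)
    ssds = np.asarray(ssds, dtype=float)[burn_in:]
    valid = True
    if ssds.size < min_trials:
        warnings.warn(
            f"only {ssds.size} stop trials after burn-in (< {min_trials}); "
            "SSRT flagged invalid", stacklevel=2)
        valid = False
    if ssds.size == 0 or no_stop.size == 0:
        return SSRTEstimate(float("nan"), "mean", float("nan"), 0, False, **ids)
    ssrt = float(no_stop.mean() - ssds.mean())
    return SSRTEstimate(ssrt, "mean", float(ssds.mean()), int(ssds.size), valid, **ids)


def integration_ssrt(
    no_stop_musrts: Sequence[float],
    p_respond: float,
    mean_ssd: float,
    **ids,
) -> SSRTEstimate:
    """Integration-method SSRT: Go-quantile at p(respond) minus mean SSD.

    The Stop process finishes, on average, at the point of the No Stop
    distribution that splits responders from stoppers.
    """
    if not 0.0 < p_respond < 1.0:
        raise ValueError("p_respond must lie strictly between 0 and 1")
    no_stop = np.asarray(no_stop_musrts, dtype=float)
    if no_stop.size < 2 or np.ptp(no_stop) == 0.0:
        raise ValueError("degenerate No Stop distribution")
    ssrt = float(np.quantile(no_stop, p_respond) - mean_ssd)
    return SSRTEstimate(ssrt, "integration", float(mean_ssd), no_stop.size, True, **ids)


def independence_test(
    stop_error_means: Sequence[float],
    no_stop_means: Sequence[float],
    alpha: float = DEFAULT_ALPHA,
    **ids,
) -> IndependenceResult:
    """Paired t-test of Stop Error vs No Stop mean MusRTs across participants.

    ``violated`` is True only for a *significant reversal* (errors slower
    than No Stop at the two-tailed alpha level); errors faster - however
    strongly - respects the race model.
    """
    err = np.asarray(stop_error_means, dtype=float)
    ns = np.asarray(no_stop_means, dtype=float)
    if err.size != ns.size:
        raise ValueError("paired means must align")
    if err.size < 2:
        raise ValueError("independence test needs at least 2 participants")
    t, df, p = paired_t(err, ns)
    direction = ERROR_SLOWER if err.mean() > ns.mean() else ERROR_FASTER
    violated = direction == ERROR_SLOWER and p < alpha
    return IndependenceResult(err, ns, t, df, p, direction, violated, alpha, **ids)


def interference_effect(
    stop_correct_moving_musrts: Sequence[float],
    no_stop_musrts: Sequence[float],
    version: StopVersion,
) -> float:
    """Stop-interference: delay of the moving effector in correct selective
    stop trials relative to the same effector's No Stop MusRTs (ms).

    Positive values reflect the pause cost of the global first inhibition
    step.  Only defined for selective versions (stop_both has no moving
    effector).
    """
    version = StopVersion(version)
    if not version.is_selective:
        raise ValueError("interference is defined for selective stop versions only")
    sc = np.asarray(stop_correct_moving_musrts, dtype=float)
    ns = np.asarray(no_stop_musrts, dtype=float)
    if sc.size == 0 or ns.size == 0:
        raise ValueError("empty sample")
    return float(sc.mean() - ns.mean())


def coupling_correlation(
    wrist_musrts: Sequence[float],
    foot_musrts: Sequence[float],
) -> Optional[tuple[float, float]]:
    """Spearman correlation between paired wrist and foot No Stop MusRTs.

    A strong positive correlation is the signature of a shared Go process.
    Returns (r, p) or None for constant input (undefined).
    """
    wrist = np.asarray(wrist_musrts, dtype=float)
    foot = np.asarray(foot_musrts, dtype=float)
    if wrist.size != foot.size:
        raise ValueError("paired samples must align")
    if wrist.size < 10:
        raise ValueError("need at least 10 paired trials")
    return spearman(wrist, foot)
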