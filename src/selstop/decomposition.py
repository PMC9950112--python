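"""Restart-model decomposition of selective Stop Errors.

Under the two-step restart account, selective Stop Errors are a mixture:

* *first-step* race losses - the to-be-stopped effector's Go process beat
  the global inhibition; these behave exactly as the race model demands
  (fast MusRTs, drawn from the Go distribution's left tail);
* *restart-step* errors - the global inhibition succeeded but the
  subsequent selective restart went wrong (the effectors stayed coupled, or
  the wrong effector was reactivated); their MusRTs pay the pause cost and
  land *after* the Stop process finished.

The decomposition cuts each participant's selective Stop Error MusRTs at
the **Stop End** - the estimated completion time of the first (global)
inhibition step, Stop End = non-selective SSRT + mean selective SSD - into
a *Compliant* subset (MusRT < Stop End, first-step losses) and a
*Non-Compliant* subset (MusRT >= Stop End, restart errors).  Re-testing
independence and re-estimating SSRT on the Compliant subset restores the
race model where the full error set violates it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats as sps

from .race import (
    DEFAULT_ALPHA,
    MIN_STOP_TRIALS,
    IndependenceResult,
    SSRTEstimate,
    independence_test,
)
from .task_model import StopVersion, TaskCondition

logger = logging.getLogger("selstop.decomposition")


class MissingSSRTError(ValueError):
    """The non-selective SSRT needed for the Stop End is unavailable."""


@dataclass
class ComplianceSplit:
    """A participant's selective Stop Errors partitioned at the Stop End."""

    stop_end: float
    compliant_musrts: np.ndarray
    noncompliant_musrts: np.ndarray
    compliant_ssds: np.ndarray
    noncompliant_ssds: np.ndarray
    participant_id: str = ""
    condition: Optional[TaskCondition] = None
    version: Optional[StopVersion] = None

    @property
    def n_errors(self) -> int:
        return self.compliant_musrts.size + self.noncompliant_musrts.size

    @property
    def p_compliant(self) -> float:
        return self.compliant_musrts.size / self.n_errors

    @property
    def mean_ssd_compliant(self) -> float:
        return float(self.compliant_ssds.mean()) if self.compliant_ssds.size else float("nan")

    @property
    def mean_ssd_noncompliant(self) -> float:
        return (float(self.noncompliant_ssds.mean())
                if self.noncompliant_ssds.size else float("nan"))


def compute_stop_end(
    ssrt_nonselective: SSRTEstimate | float,
    mean_ssd_selective: float,
) -> float:
    """Stop End = non-selective SSRT + mean SSD of the selective cell.

    The non-selective (stop_both) SSRT of the *matching task condition*
    estimates the duration of the global first inhibition step; adding the
    selective cell's mean SSD places its completion on the from-Go time
    axis.  An invalid non-selective estimate (independence violated or too
    few trials) raises :class:`MissingSSRTError`; callers skip and log the
    participant.
    """
    if isinstance(ssrt_nonselective, SSRTEstimate):
        if not ssrt_nonselective.valid or not np.isfinite(ssrt_nonselective.ssrt):
            raise MissingSSRTError(
                "non-selective SSRT is invalid; cannot place the Stop End")
        ssrt = ssrt_nonselective.ssrt
    else:
        ssrt = float(ssrt_nonselective)
        if not np.isfinite(ssrt):
            raise MissingSSRTError("non-selective SSRT is not finite")
    return ssrt + float(mean_ssd_selective)


def split_errors(
    error_musrts: Sequence[float],
    stop_end: float,
    ssds: Sequence[float],
    **ids,
) -> ComplianceSplit:
    """Partition Stop Error MusRTs at the Stop End (strict: ties are
    Non-Compliant, since Compliant errors are those *faster than* the Stop
    End).  ``ssds`` align with ``error_musrts`` so per-subset mean SSDs can
    be computed from the contributing trials."""
    musrts = np.asarray(error_musrts, dtype=float)
    ssds = np.asarray(ssds, dtype=float)
    if musrts.size == 0:
        raise ValueError("no Stop Error MusRTs to split")
    if musrts.size != ssds.size:
        raise ValueError("error_musrts and ssds must align")
    compliant = musrts < stop_end
    return ComplianceSplit(
        stop_end=float(stop_end),
        compliant_musrts=musrts[compliant],
        noncompliant_musrts=musrts[~compliant],
        compliant_ssds=ssds[compliant],
        noncompliant_ssds=ssds[~compliant],
        **ids,
    )


def proportion_ztest(k1: int, n1: int, k2: int, n2: int) -> tuple[float, float]:
    """Two-proportion pooled z-test; returns (z, two-tailed p).

    z = (p1 - p2) / sqrt(p(1-p)(1/n1 + 1/n2)) with p the pooled proportion.
    Degenerate pooled proportions (0 or 1) give z = 0 when the two
    proportions agree and +/-inf otherwise.
    """
    if n1 <= 0 or n2 <= 0:
        raise ValueError("sample sizes must be positive")
    if not (0 <= k1 <= n1 and 0 <= k2 <= n2):
        raise ValueError("counts must satisfy 0 <= k <= n")
    p1, p2 = k1 / n1, k2 / n2
    pooled = (k1 + k2) / (n1 + n2)
    var = pooled * (1.0 - pooled) * (1.0 / n1 + 1.0 / n2)
    if var == 0.0:
        if p1 == p2:
            return 0.0, 1.0
        return float(np.sign(p1 - p2)) * float("inf"), 0.0
    z = (p1 - p2) / np.sqrt(var)
    p = 2.0 * sps.norm.sf(abs(z))
    return float(z), float(p)


def compliant_independence_retest(
    splits: Sequence[ComplianceSplit],
    no_stop_means: Sequence[float],
    alpha: float = DEFAULT_ALPHA,
    **ids,
) -> IndependenceResult:
    """Re-test independence on the Compliant subset only.

    ``splits`` and ``no_stop_means`` align per participant; participants
    with an empty Compliant subset are excluded (and logged) before the
    paired test.
    """
    if len(splits) != len(no_stop_means):
        raise ValueError("splits and no_stop_means must align per participant")
    err_means, ns_means = [], []
    for split, ns in zip(splits, no_stop_means):
        if split.compliant_musrts.size == 0:
            logger.warning("participant %s has no Compliant Stop Errors; "
                           "excluded from the retest", split.participant_id)
            continue
        err_means.append(float(split.compliant_musrts.mean()))
        ns_means.append(float(ns))
    return independence_test(err_means, ns_means, alpha, **ids)


def compliant_ssrt(
    split: ComplianceSplit,
    no_stop_musrts: Sequence[float],
    min_trials: int = MIN_STOP_TRIALS,
) -> SSRTEstimate:
    """Mean-method SSRT restricted to Compliant-trial SSDs.

    Compliant errors are the trials where the race genuinely ran to the Go
    process's advantage, so their SSDs support a race-model SSRT for the
    selective cell.  Fewer than ``min_trials`` Compliant trials flags the
    estimate invalid.
    """
    if split.compliant_musrts.size == 0:
        raise ValueError("empty Compliant subset")
    no_stop = np.asarray(no_stop_musrts, dtype=float)
    mean_ssd = split.mean_ssd_compliant
    ssrt = float(no_stop.mean() - mean_ssd)
    return SSRTEstimate(
        ssrt=ssrt,
        method="mean/compliant",
        mean_ssd=mean_ssd,
        n_stop_trials=int(split.compliant_musrts.size),
        valid=split.compliant_musrts.size >= min_trials,
        participant_id=split.participant_id,
        condition=split.condition,
        version=split.version,
    )
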