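"""EMG processing: from raw traces to muscle reaction times (MusRT).

The muscle reaction time is the latency from the Go signal to the onset of
the EMG burst in the agonist muscle; it marks response initiation earlier in
the motor cascade than the overt movement.  The processing chain is the
standard one: full-wave rectification, moving-average smoothing, then a
threshold rule - the onset is the first post-Go time at which the processed
signal exceeds the mean of the pre-Go baseline by ``k`` baseline standard
deviations (default 2.5 SD over the 100 ms before the Go signal) and stays
above threshold for a sustain window (default 10 ms) to reject single-sample
noise spikes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .task_model import Effector, MalformedTrialError

logger = logging.getLogger("selstop.emg")

DEFAULT_SMOOTH_MS = 10.0
DEFAULT_BASELINE_MS = 100.0
DEFAULT_K = 2.5
DEFAULT_SUSTAIN_MS = 10.0


@dataclass
class EMGTrace:
    """A sampled EMG signal with its Go-signal index.

    ``latent_onset_ms`` is only ever set on synthetic traces and carries the
    generative ground truth for closed-loop validation.
    """

    samples: np.ndarray
    sampling_rate: float
    go_index: int
    effector: Effector
    trial_index: int = 0
    participant_id: str = "p0"
    latent_onset_ms: Optional[float] = None

    def __post_init__(self) -> None:
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        self.samples = np.asarray(self.samples, dtype=float)


def rectify(samples: np.ndarray) -> np.ndarray:
    """Full-wave rectification (element-wise absolute value)."""
    return np.abs(np.asarray(samples, dtype=float))


def smooth(samples: np.ndarray, window_ms: float, sampling_rate: float) -> np.ndarray:
    """Centered moving average; edges use the truncated window.

    The window is ``round(window_ms * rate / 1000)`` samples (at least 1).
    Length is preserved; near the edges the average runs over the samples
    actually available, so a constant trace stays exactly constant.
    """
    if window_ms <= 0:
        raise ValueError("window_ms must be positive")
    x = np.asarray(samples, dtype=float)
    w = max(1, int(round(window_ms * sampling_rate / 1000.0)))
    if w > x.size:
        raise ValueError(f"smoothing window ({w} samples) longer than trace ({x.size})")
    kernel = np.ones(w)
    num = np.convolve(x, kernel, mode="same")
    den = np.convolve(np.ones(x.size), kernel, mode="same")
    return num / den


def process_trace(trace: EMGTrace, window_ms: float = DEFAULT_SMOOTH_MS) -> EMGTrace:
    """Rectify and smooth a raw trace, returning a new EMGTrace."""
    processed = smooth(rectify(trace.samples), window_ms, trace.sampling_rate)
    return replace(trace, samples=processed)


def _first_sustained_crossing(above: np.ndarray, n_sustain: int) -> Optional[int]:
    """Index of the first run of >= n_sustain True values, or None."""
    if above.size < n_sustain:
        return None
    counts = np.convolve(above.astype(np.intp), np.ones(n_sustain, dtype=np.intp),
                         mode="valid")
    hits = np.flatnonzero(counts == n_sustain)
    return int(hits[0]) if hits.size else None


def detect_onset(
    trace: EMGTrace,
    baseline_ms: float = DEFAULT_BASELINE_MS,
    k: float = DEFAULT_K,
    sustain_ms: float = DEFAULT_SUSTAIN_MS,
) -> Optional[float]:
    """Detect the muscle onset (MusRT, ms from Go) on a processed trace.

    The threshold is ``mean + k * sd`` of the processed signal over the
    ``baseline_ms`` window immediately before the Go index.  The onset is
    the first post-Go sample exceeding the threshold and staying above it
    for at least ``sustain_ms``; returns None when no such crossing exists
    (never raises for a quiet trace).  The search never extends before the
    Go signal, so a detected MusRT is always non-negative.
    """
    rate = trace.sampling_rate
    n_base = int(round(baseline_ms * rate / 1000.0))
    if n_base < 1 or trace.go_index < n_base:
        raise ValueError("insufficient pre-Go samples for the baseline window")
    baseline = trace.samples[trace.go_index - n_base: trace.go_index]
    threshold = float(np.mean(baseline) + k * np.std(baseline))
    post = trace.samples[trace.go_index:]
    n_sustain = max(1, int(round(sustain_ms * rate / 1000.0)))
    idx = _first_sustained_crossing(post > threshold, n_sustain)
    if idx is None:
        return None
    return idx * 1000.0 / rate


def pre_go_contaminated(
    trace: EMGTrace,
    baseline_ms: float = DEFAULT_BASELINE_MS,
    k: float = DEFAULT_K,
    sustain_ms: float = DEFAULT_SUSTAIN_MS,
) -> bool:
    """True when the pre-Go segment (before the baseline window) already
    shows a sustained supra-threshold crossing, i.e. the muscle was active
    before the trial properly started.  Such trials are flagged for
    exclusion rather than assigned a negative MusRT."""
    rate = trace.sampling_rate
    n_base = int(round(baseline_ms * rate / 1000.0))
    if trace.go_index < n_base:
        raise ValueError("insufficient pre-Go samples for the baseline window")
    baseline = trace.samples[trace.go_index - n_base: trace.go_index]
    threshold = float(np.mean(baseline) + k * np.std(baseline))
    pre = trace.samples[: trace.go_index - n_base]
    if pre.size == 0:
        return False
    n_sustain = max(1, int(round(sustain_ms * rate / 1000.0)))
    return _first_sustained_crossing(pre > threshold, n_sustain) is not None


def write_trace(trace: EMGTrace, path) -> None:
    """Write a trace as plain text: '# key: value' header lines then one
    sample per line."""
    header = [
        f"# participant_id: {trace.participant_id}",
        f"# trial_index: {trace.trial_index}",
        f"# effector: {trace.effector.value}",
        f"# sampling_rate_hz: {trace.sampling_rate:g}",
        f"# go_index: {trace.go_index}",
    ]
    if trace.latent_onset_ms is not None:
        header.append(f"# latent_onset_ms: {trace.latent_onset_ms:.3f}")
    body = "\n".join(f"{v:.6g}" for v in trace.samples)
    with open(path, "w") as fh:
        fh.write("\n".join(header) + "\n" + body + "\n")


def read_trace(path) -> EMGTrace:
    """Read a trace written by :func:`write_trace`."""
    meta: dict[str, str] = {}
    samples: list[float] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                key, _, value = line[1:].partition(":")
                meta[key.strip()] = value.strip()
            else:
                samples.append(float(line))
    return EMGTrace(
        samples=np.asarray(samples),
        sampling_rate=float(meta["sampling_rate_hz"]),
        go_index=int(meta["go_index"]),
        effector=Effector(meta["effector"]),
        trial_index=int(meta.get("trial_index", 0)),
        participant_id=meta.get("participant_id", "p0"),
        latent_onset_ms=(float(meta["latent_onset_ms"])
                         if "latent_onset_ms" in meta else None),
    )


def build_musrt_table(
    traces: Iterable[EMGTrace],
    trial_table: pd.DataFrame,
    window_ms: float = DEFAULT_SMOOTH_MS,
    baseline_ms: float = DEFAULT_BASELINE_MS,
    k: float = DEFAULT_K,
    sustain_ms: float = DEFAULT_SUSTAIN_MS,
) -> pd.DataFrame:
    """Fill the per-effector MusRT columns of a trial table from raw traces.

    Each raw trace is rectified, smoothed and passed to the onset detector;
    results merge into the table by (participant_id, trial_index, effector).
    Moved effectors without a detectable onset (or with pre-Go contamination)
    leave the MusRT missing and set the ``excluded`` flag; a moved effector
    with *no trace at all* is an error listing the offending trial indices.
    """
    table = trial_table.copy()
    if "excluded" not in table.columns:
        table["excluded"] = False
    detected: dict[tuple[str, int, Effector], Optional[float]] = {}
    for raw in traces:
        processed = process_trace(raw, window_ms)
        if pre_go_contaminated(processed, baseline_ms, k, sustain_ms):
            onset = None
            logger.warning("pre-Go EMG contamination: participant %s trial %d (%s)",
                           raw.participant_id, raw.trial_index, raw.effector.value)
        else:
            onset = detect_onset(processed, baseline_ms, k, sustain_ms)
        detected[(raw.participant_id, raw.trial_index, Effector(raw.effector))] = onset

    missing: list[int] = []
    for row in table.itertuples():
        for eff, moved_col, col in (
            (Effector.WRIST, "wrist_moved", "wrist_mus_rt"),
            (Effector.FOOT, "foot_moved", "foot_mus_rt"),
        ):
            key = (row.participant_id, row.trial_index, eff)
            if not getattr(row, moved_col):
                continue
            if key not in detected:
                missing.append(row.trial_index)
                continue
            onset = detected[key]
            if onset is None:
                table.loc[row.Index, "excluded"] = True
                logger.warning("no EMG onset for moved effector: participant %s "
                               "trial %d (%s); trial flagged for exclusion",
                               row.participant_id, row.trial_index, eff.value)
            else:
                table.loc[row.Index, col] = onset
    if missing:
        raise MalformedTrialError(
            f"moved effectors without an EMG trace at trials {sorted(set(missing))}")
    return table
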