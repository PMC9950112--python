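"""End-to-end orchestration: cells, batteries, reports, manifests.

This module turns trial tables (simulated or ingested) into the analysis
outputs: per-cell independence tests, SSRT tables (mean and integration
methods), stop-interference and coupling measures, the Compliant /
Non-Compliant decomposition, and the replicate batteries used to validate
the whole chain against the simulator's latent ground truth.

Cell conventions
----------------
A *cell* is participant x task condition x stop version.  Block cells draw
their No Stop reference from the same block session; mix cells share the
mix session's No Stop pool.  For selective versions the analysed latency is
the *stopped* effector's MusRT; for the non-selective version the
independence comparison pools both effectors' MusRTs (errors contribute the
mean of their moved effectors) while SSRT estimation uses the per-trial
earliest onset, because the non-selective race is lost as soon as the first
effector escapes.  The first ``burn_in`` stop trials of each staircase are
excluded from every stopping statistic.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .decomposition import (
    ComplianceSplit,
    MissingSSRTError,
    compliant_independence_retest,
    compliant_ssrt,
    compute_stop_end,
    proportion_ztest,
    split_errors,
)
from .emg import build_musrt_table
from .race import (
    DEFAULT_ALPHA,
    DEFAULT_BURN_IN,
    IndependenceResult,
    SSRTEstimate,
    coupling_correlation,
    independence_test,
    integration_ssrt,
    interference_effect,
    mean_method_ssrt,
)
from .stats import oneway_anova
from .synthetic import (
    FIRST_STEP_ERROR,
    RESTART_ERROR,
    RestartModelParams,
    default_params,
    simulate_study,
    split_tables,
    synthesize_emg,
)
from .task_model import (
    Effector,
    SessionConfig,
    StopVersion,
    TaskCondition,
    TrialOutcome,
    write_trial_table,
)

logger = logging.getLogger("selstop.pipeline")


# ---------------------------------------------------------------------------
# Cell extraction
# ---------------------------------------------------------------------------

def _cond(frame: pd.DataFrame, condition: TaskCondition) -> pd.DataFrame:
    return frame[frame["condition"] == condition.value]


def no_stop_pool(
    frame: pd.DataFrame,
    participant_id: str,
    condition: TaskCondition,
    version: StopVersion,
) -> pd.DataFrame:
    """Correct No Stop trials forming the cell's Go-distribution reference."""
    sub = _cond(frame, condition)
    sub = sub[(sub["participant_id"] == participant_id)
              & (sub["trial_type"] == "no_stop")
              & (sub["outcome"] == TrialOutcome.CORRECT.value)]
    if condition is TaskCondition.BLOCK:
        sub = sub[sub["session_version"] == version.value]
    return sub


def stop_cell(
    frame: pd.DataFrame,
    participant_id: str,
    condition: TaskCondition,
    version: StopVersion,
    burn_in: int = DEFAULT_BURN_IN,
    include_aborted: bool = False,
) -> pd.DataFrame:
    """Post-burn-in stop trials of one cell, in staircase order."""
    sub = _cond(frame, condition)
    sub = sub[(sub["participant_id"] == participant_id)
              & (sub["trial_type"] == "stop")
              & (sub["stop_version"] == version.value)
              & (sub["stop_order"] >= burn_in)]
    if not include_aborted:
        sub = sub[sub["outcome"] != TrialOutcome.ABORTED.value]
    return sub.sort_values("stop_order")


def error_musrts(stop_rows: pd.DataFrame, version: StopVersion) -> np.ndarray:
    """The erroneous MusRT of each Stop Error row.

    Selective: the stopped effector's MusRT.  Non-selective: the mean of the
    moved effectors' MusRTs (matching the pooled-effector convention of the
    independence comparison).
    """
    err = stop_rows[stop_rows["outcome"] == TrialOutcome.ERROR.value]
    if version.is_selective:
        col = f"{version.stopped_effector.value}_mus_rt"
        return err[col].to_numpy(dtype=float)
    w = err["wrist_mus_rt"].to_numpy(dtype=float)
    f = err["foot_mus_rt"].to_numpy(dtype=float)
    moved_w = err["wrist_moved"].to_numpy(dtype=bool)
    moved_f = err["foot_moved"].to_numpy(dtype=bool)
    out = np.where(
        moved_w & moved_f, (w + f) / 2.0, np.where(moved_w, w, f))
    return out.astype(float)


def no_stop_reference(
    pool: pd.DataFrame, version: StopVersion, for_ssrt: bool = False
) -> np.ndarray:
    """No Stop MusRTs matching a cell's analysed latency.

    Selective cells use the stopped effector.  Non-selective cells pool both
    effectors for the independence comparison but use the per-trial earliest
    onset when ``for_ssrt`` (the race is decided by the first effector).
    """
    w = pool["wrist_mus_rt"].to_numpy(dtype=float)
    f = pool["foot_mus_rt"].to_numpy(dtype=float)
    if version.is_selective:
        return w if version.stopped_effector is Effector.WRIST else f
    if for_ssrt:
        return np.minimum(w, f)
    return np.concatenate([w, f])


def participants(frame: pd.DataFrame) -> list[str]:
    return sorted(frame["participant_id"].unique())


# ---------------------------------------------------------------------------
# Independence battery and SSRT tables
# ---------------------------------------------------------------------------

def analyze_independence(
    frame: pd.DataFrame,
    condition: TaskCondition,
    version: StopVersion,
    alpha: float = DEFAULT_ALPHA,
    burn_in: int = DEFAULT_BURN_IN,
) -> IndependenceResult:
    """Group-level independence test for one condition x version cell."""
    err_means, ns_means = [], []
    for pid in participants(frame):
        rows = stop_cell(frame, pid, condition, version, burn_in)
        errs = error_musrts(rows, version)
        pool = no_stop_pool(frame, pid, condition, version)
        if errs.size == 0 or len(pool) == 0:
            logger.warning("cell %s/%s/%s has no errors or no No Stop trials; skipped",
                           pid, condition.value, version.value)
            continue
        err_means.append(float(errs.mean()))
        ns_means.append(float(no_stop_reference(pool, version).mean()))
    return independence_test(err_means, ns_means, alpha,
                             condition=condition, version=version)


def participant_ssrts(
    frame: pd.DataFrame,
    participant_id: str,
    condition: TaskCondition,
    version: StopVersion,
    burn_in: int = DEFAULT_BURN_IN,
) -> tuple[SSRTEstimate, Optional[SSRTEstimate]]:
    """Mean-method and integration-method SSRTs for one cell."""
    rows = stop_cell(frame, participant_id, condition, version, burn_in)
    pool = no_stop_pool(frame, participant_id, condition, version)
    ref = no_stop_reference(pool, version, for_ssrt=True)
    ssds = rows["ssd"].to_numpy(dtype=float)
    ids = dict(participant_id=participant_id, condition=condition, version=version)
    mean_est = mean_method_ssrt(ref, ssds, burn_in=0, **ids)
    n_err = int((rows["outcome"] == TrialOutcome.ERROR.value).sum())
    integ_est = None
    if 0 < n_err < len(rows) and ref.size >= 2 and np.ptp(ref) > 0:
        integ_est = integration_ssrt(ref, n_err / len(rows), float(ssds.mean()), **ids)
    return mean_est, integ_est


def ssrt_table(
    frame: pd.DataFrame,
    alpha: float = DEFAULT_ALPHA,
    burn_in: int = DEFAULT_BURN_IN,
) -> pd.DataFrame:
    """All per-participant SSRT estimates, with cell validity flags.

    A cell whose group-level independence test is violated has every
    estimate flagged invalid (they are excluded from group averages).
    """
    conditions = [TaskCondition(c) for c in frame["condition"].unique()]
    rows = []
    for condition in conditions:
        for version in StopVersion:
            try:
                ind = analyze_independence(frame, condition, version, alpha, burn_in)
            except ValueError:
                continue
            for pid in participants(frame):
                mean_est, integ_est = participant_ssrts(
                    frame, pid, condition, version, burn_in)
                for est in (mean_est, integ_est):
                    if est is None:
                        continue
                    rows.append({
                        "participant_id": pid,
                        "condition": condition.value,
                        "version": version.value,
                        "method": est.method,
                        "ssrt": est.ssrt,
                        "mean_ssd": est.mean_ssd,
                        "n_stop_trials": est.n_stop_trials,
                        "valid": bool(est.valid and not ind.violated),
                        "independence_violated": bool(ind.violated),
                    })
    return pd.DataFrame(rows)


def interference_table(
    frame: pd.DataFrame, burn_in: int = DEFAULT_BURN_IN
) -> pd.DataFrame:
    """Per-participant stop-interference deltas for the selective versions."""
    conditions = [TaskCondition(c) for c in frame["condition"].unique()]
    rows = []
    for condition in conditions:
        for version in (StopVersion.STOP_WRIST, StopVersion.STOP_FOOT):
            mover = version.moving_effector
            for pid in participants(frame):
                cell = stop_cell(frame, pid, condition, version, burn_in)
                correct = cell[cell["outcome"] == TrialOutcome.CORRECT.value]
                sc = correct[f"{mover.value}_mus_rt"].dropna().to_numpy(dtype=float)
                pool = no_stop_pool(frame, pid, condition, version)
                ns = pool[f"{mover.value}_mus_rt"].to_numpy(dtype=float)
                if sc.size == 0 or ns.size == 0:
                    continue
                rows.append({
                    "participant_id": pid,
                    "condition": condition.value,
                    "version": version.value,
                    "moving_effector": mover.value,
                    "interference_ms": interference_effect(sc, ns, version),
                    "n_stop_correct": int(sc.size),
                })
    return pd.DataFrame(rows)


def coupling_table(frame: pd.DataFrame) -> pd.DataFrame:
    """Per-participant wrist-foot Spearman correlation in No Stop trials."""
    conditions = [TaskCondition(c) for c in frame["condition"].unique()]
    rows = []
    for condition in conditions:
        sub = _cond(frame, condition)
        sub = sub[(sub["trial_type"] == "no_stop")
                  & (sub["outcome"] == TrialOutcome.CORRECT.value)]
        for pid in participants(frame):
            p = sub[sub["participant_id"] == pid]
            if len(p) < 10:
                continue
            res = coupling_correlation(
                p["wrist_mus_rt"].to_numpy(dtype=float),
                p["foot_mus_rt"].to_numpy(dtype=float))
            if res is None:
                continue
            rows.append({
                "participant_id": pid,
                "condition": condition.value,
                "spearman_r": res[0],
                "p_value": res[1],
                "n_trials": len(p),
            })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Decomposition of selective Stop Errors
# ---------------------------------------------------------------------------

@dataclass
class DecompositionCell:
    """Group-level decomposition outputs for one condition x selective version."""

    condition: TaskCondition
    version: StopVersion
    splits: list[ComplianceSplit]
    no_stop_means: list[float]
    retest: Optional[IndependenceResult]
    compliant_ssrts: list[SSRTEstimate]
    mean_p_compliant: float = field(init=False)

    def __post_init__(self) -> None:
        self.mean_p_compliant = (
            float(np.mean([s.p_compliant for s in self.splits]))
            if self.splits else float("nan"))

    def pooled_counts(self) -> tuple[int, int]:
        """(compliant, total) Stop Error counts pooled over participants."""
        k = sum(s.compliant_musrts.size for s in self.splits)
        n = sum(s.n_errors for s in self.splits)
        return k, n


def decompose_cell(
    frame: pd.DataFrame,
    condition: TaskCondition,
    version: StopVersion,
    alpha: float = DEFAULT_ALPHA,
    burn_in: int = DEFAULT_BURN_IN,
) -> DecompositionCell:
    """Run the Stop End split for every participant of one selective cell.

    The Stop End uses each participant's own non-selective (stop_both) SSRT
    from the *matching* task condition plus the participant's mean selective
    SSD.  Participants whose non-selective SSRT is invalid are skipped and
    logged.
    """
    if not version.is_selective:
        raise ValueError("decomposition applies to selective stop versions only")
    splits: list[ComplianceSplit] = []
    ns_means: list[float] = []
    for pid in participants(frame):
        both_est, _ = participant_ssrts(
            frame, pid, condition, StopVersion.STOP_BOTH, burn_in)
        cell = stop_cell(frame, pid, condition, version, burn_in)
        errs = error_musrts(cell, version)
        err_rows = cell[cell["outcome"] == TrialOutcome.ERROR.value]
        pool = no_stop_pool(frame, pid, condition, version)
        if errs.size == 0 or len(pool) == 0:
            logger.warning("no Stop Errors for %s/%s/%s; skipped",
                           pid, condition.value, version.value)
            continue
        try:
            stop_end = compute_stop_end(both_est, float(cell["ssd"].mean()))
        except MissingSSRTError:
            logger.warning("invalid non-selective SSRT for %s/%s; participant "
                           "skipped in decomposition", pid, condition.value)
            continue
        split = split_errors(
            errs, stop_end, err_rows["ssd"].to_numpy(dtype=float),
            participant_id=pid, condition=condition, version=version)
        splits.append(split)
        ns_means.append(float(no_stop_reference(pool, version).mean()))
    retest = None
    if sum(s.compliant_musrts.size > 0 for s in splits) >= 2:
        retest = compliant_independence_retest(
            splits, ns_means, alpha, condition=condition, version=version)
    compliant_estimates = []
    for split, pid in zip(splits, [s.participant_id for s in splits]):
        if split.compliant_musrts.size == 0:
            continue
        pool = no_stop_pool(frame, pid, condition, version)
        compliant_estimates.append(
            compliant_ssrt(split, no_stop_reference(pool, version)))
    return DecompositionCell(condition, version, splits, ns_means,
                             retest, compliant_estimates)


def decomposition_tables(
    frame: pd.DataFrame,
    alpha: float = DEFAULT_ALPHA,
    burn_in: int = DEFAULT_BURN_IN,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """(per-participant split table, group summary) for all selective cells.

    The group summary carries the mean Compliant proportion, the pooled
    Block-vs-Mix two-proportion z-test per version (when both conditions are
    present), the Compliant-subset independence retest and the mean
    Compliant SSRT.
    """
    conditions = [TaskCondition(c) for c in frame["condition"].unique()]
    cells: dict[tuple[TaskCondition, StopVersion], DecompositionCell] = {}
    part_rows, group_rows = [], []
    for condition in conditions:
        for version in (StopVersion.STOP_WRIST, StopVersion.STOP_FOOT):
            cell = decompose_cell(frame, condition, version, alpha, burn_in)
            cells[(condition, version)] = cell
            for split in cell.splits:
                part_rows.append({
                    "participant_id": split.participant_id,
                    "condition": condition.value,
                    "version": version.value,
                    "stop_end": split.stop_end,
                    "n_errors": split.n_errors,
                    "n_compliant": int(split.compliant_musrts.size),
                    "p_compliant": split.p_compliant,
                    "mean_musrt_compliant": (float(split.compliant_musrts.mean())
                                             if split.compliant_musrts.size else np.nan),
                    "mean_musrt_noncompliant": (float(split.noncompliant_musrts.mean())
                                                if split.noncompliant_musrts.size else np.nan),
                    "mean_ssd_compliant": split.mean_ssd_compliant,
                    "mean_ssd_noncompliant": split.mean_ssd_noncompliant,
                })
            valid_ssrts = [e.ssrt for e in cell.compliant_ssrts if e.valid]
            group_rows.append({
                "condition": condition.value,
                "version": version.value,
                "mean_p_compliant": cell.mean_p_compliant,
                "retest_t": cell.retest.t_stat if cell.retest else np.nan,
                "retest_p": cell.retest.p_value if cell.retest else np.nan,
                "retest_violated": cell.retest.violated if cell.retest else np.nan,
                "mean_compliant_ssrt": (float(np.mean(valid_ssrts))
                                        if valid_ssrts else np.nan),
                "n_participants": len(cell.splits),
            })
    group = pd.DataFrame(group_rows)
    # pooled Block-vs-Mix z-test per selective version
    if {TaskCondition.BLOCK, TaskCondition.MIX} <= set(conditions):
        zrows = []
        for version in (StopVersion.STOP_WRIST, StopVersion.STOP_FOOT):
            kb, nb = cells[(TaskCondition.BLOCK, version)].pooled_counts()
            km, nm = cells[(TaskCondition.MIX, version)].pooled_counts()
            if nb and nm:
                z, p = proportion_ztest(kb, nb, km, nm)
                zrows.append({"version": version.value,
                              "p_compliant_block": kb / nb,
                              "p_compliant_mix": km / nm,
                              "z": z, "p_value": p})
        group.attrs["block_vs_mix_ztests"] = pd.DataFrame(zrows)
    return pd.DataFrame(part_rows), group


def compliance_fidelity(
    frame: pd.DataFrame,
    condition: TaskCondition = TaskCondition.MIX,
    burn_in: int = DEFAULT_BURN_IN,
) -> dict[str, float]:
    """Confusion of Compliant/Non-Compliant labels against latent step labels.

    Requires the latent columns of a simulated study.  Returns the precision
    of each label (fraction of Compliant-labelled errors that are latent
    first-step race losses, and of Non-Compliant-labelled errors that are
    latent restart errors) plus the pooled SSD contrast.
    """
    lab = {"tp_comp": 0, "n_comp": 0, "tp_noncomp": 0, "n_noncomp": 0}
    ssd_comp, ssd_noncomp = [], []
    for version in (StopVersion.STOP_WRIST, StopVersion.STOP_FOOT):
        cell = decompose_cell(frame, condition, version, burn_in=burn_in)
        for split in cell.splits:
            pid_rows = stop_cell(frame, split.participant_id, condition, version,
                                 burn_in)
            err_rows = pid_rows[pid_rows["outcome"] == TrialOutcome.ERROR.value]
            musrts = error_musrts(err_rows, version)
            labels = err_rows["step_label"].to_numpy()
            compliant = musrts < split.stop_end
            lab["n_comp"] += int(compliant.sum())
            lab["n_noncomp"] += int((~compliant).sum())
            lab["tp_comp"] += int((labels[compliant] == FIRST_STEP_ERROR).sum())
            lab["tp_noncomp"] += int((labels[~compliant] == RESTART_ERROR).sum())
            ssd_comp.extend(split.compliant_ssds)
            ssd_noncomp.extend(split.noncompliant_ssds)
    return {
        "precision_compliant": lab["tp_comp"] / lab["n_comp"] if lab["n_comp"] else np.nan,
        "precision_noncompliant": (lab["tp_noncomp"] / lab["n_noncomp"]
                                   if lab["n_noncomp"] else np.nan),
        "mean_ssd_compliant": float(np.mean(ssd_comp)) if ssd_comp else np.nan,
        "mean_ssd_noncompliant": float(np.mean(ssd_noncomp)) if ssd_noncomp else np.nan,
    }


# ---------------------------------------------------------------------------
# Replicate battery (the end-to-end qualitative reproduction)
# ---------------------------------------------------------------------------

def replicate_battery(
    n_groups: int,
    params: Optional[RestartModelParams] = None,
    seed: int = 0,
    n_participants: int = 9,
    mix_trials: int = 2000,
    alpha: float = DEFAULT_ALPHA,
) -> pd.DataFrame:
    """Simulate ``n_groups`` independent mix-condition cohorts and score the
    full logical chain on each:

    * does the full Stop Error set violate independence in the selective
      versions but not the non-selective one?
    * does the Compliant subset pass the retest?
    * is the Compliant SSRT indistinguishable from the non-selective SSRT
      (between-subjects one-way ANOVA across the three cell types)?

    One row per replicate group.
    """
    if params is None:
        params = default_params()
    root = np.random.SeedSequence(seed)
    rows = []
    for g, child in enumerate(root.spawn(n_groups)):
        gseed = int(child.generate_state(1)[0] % (2**31 - 1))
        frame = simulate_study(n_participants, params, gseed,
                               conditions=(TaskCondition.MIX,),
                               mix_trials=mix_trials)
        row: dict[str, object] = {"group": g}
        for version in StopVersion:
            ind = analyze_independence(frame, TaskCondition.MIX, version, alpha)
            row[f"violated_{version.value}"] = ind.violated
            row[f"slower_{version.value}"] = ind.direction == "error_slower"
            row[f"t_{version.value}"] = ind.t_stat
        both_ssrts = []
        for pid in participants(frame):
            est, _ = participant_ssrts(frame, pid, TaskCondition.MIX,
                                       StopVersion.STOP_BOTH)
            if est.valid:
                both_ssrts.append(est.ssrt)
        groups = [both_ssrts]
        for version in (StopVersion.STOP_WRIST, StopVersion.STOP_FOOT):
            cell = decompose_cell(frame, TaskCondition.MIX, version, alpha)
            row[f"retest_pass_{version.value}"] = bool(
                cell.retest is not None and not cell.retest.violated)
            row[f"p_compliant_{version.value}"] = cell.mean_p_compliant
            groups.append([e.ssrt for e in cell.compliant_ssrts if e.valid])
        if all(len(g_) >= 2 for g_ in groups):
            _, _, _, p_anova, _ = oneway_anova(groups)
        else:
            p_anova = np.nan
        row["ssrt_anova_p"] = p_anova
        row["mean_ssrt_both"] = float(np.mean(both_ssrts)) if both_ssrts else np.nan
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Full-study run with manifest
# ---------------------------------------------------------------------------

def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _emg_roundtrip(frame: pd.DataFrame, params: RestartModelParams,
                   seed: int) -> pd.DataFrame:
    """Re-derive every MusRT through the synthetic-EMG + onset-detection path.

    Renders traces trial by trial from the latent onsets, erases the
    simulator's MusRT columns and refills them with detected onsets.
    """
    from .synthetic import SimulatedTrial  # local to avoid cycle at import time
    from .task_model import TrialRecord

    rng = np.random.default_rng(seed)
    blanked = frame.copy()
    blanked[["wrist_mus_rt", "foot_mus_rt"]] = np.nan
    traces = []
    for row in frame.itertuples():
        onsets = {Effector.WRIST: None if pd.isna(row.latent_onset_wrist)
                  else float(row.latent_onset_wrist),
                  Effector.FOOT: None if pd.isna(row.latent_onset_foot)
                  else float(row.latent_onset_foot)}
        trial = SimulatedTrial(
            record=TrialRecord(trial_index=int(row.trial_index),
                               trial_type=row.trial_type,
                               participant_id=row.participant_id),
            latent_go_finish={Effector.WRIST: 0.0, Effector.FOOT: 0.0},
            latent_stop_finish=None, step_label=row.step_label,
            latent_onset=onsets)
        for eff, trace in synthesize_emg(trial, params.emg, rng).items():
            if onsets[eff] is not None:
                traces.append(trace)
    return build_musrt_table(traces, blanked)


def run_full_study(
    outdir: str | Path,
    seed: int = 0,
    params: Optional[RestartModelParams] = None,
    n_participants: int = 9,
    block_trials: int = 300,
    mix_trials: int = 600,
    conditions: Sequence[TaskCondition] = (TaskCondition.BLOCK, TaskCondition.MIX),
    emg: bool = False,
    alpha: float = DEFAULT_ALPHA,
) -> dict[str, Path]:
    """Simulate a cohort and run the complete analysis chain, writing all
    tables plus a manifest to ``outdir``.  With ``emg=True`` every MusRT is
    re-derived through synthetic EMG traces and the onset detector instead
    of being read from the simulator.  Returns the map of output paths."""
    if params is None:
        params = default_params()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    frame = simulate_study(n_participants, params, seed, conditions=conditions,
                           block_trials=block_trials, mix_trials=mix_trials)
    if emg:
        frame = _emg_roundtrip(frame, params, seed + 1)
        frame = frame[~frame["excluded"]].drop(columns=["excluded"])

    trial_table, latent_table = split_tables(frame)
    outputs: dict[str, Path] = {}

    def save(name: str, obj: pd.DataFrame) -> None:
        path = outdir / f"{name}.csv"
        obj.to_csv(path, index=False)
        outputs[name] = path

    write_trial_table(trial_table, outdir / "trials.csv")
    outputs["trials"] = outdir / "trials.csv"
    latent_table.to_csv(outdir / "latent.csv", index=False, float_format="%.1f")
    outputs["latent"] = outdir / "latent.csv"

    ind_rows = []
    for condition in conditions:
        for version in StopVersion:
            try:
                ind = analyze_independence(frame, condition, version, alpha)
            except ValueError:
                continue
            ind_rows.append({
                "condition": condition.value, "version": version.value,
                "stop_error_mean": float(ind.stop_error_means.mean()),
                "no_stop_mean": float(ind.no_stop_means.mean()),
                "t": ind.t_stat, "df": ind.df, "p": ind.p_value,
                "direction": ind.direction, "violated": ind.violated,
            })
    save("independence", pd.DataFrame(ind_rows))
    save("ssrt", ssrt_table(frame, alpha))
    save("interference", interference_table(frame))
    save("coupling", coupling_table(frame))
    part, group = decomposition_tables(frame, alpha)
    save("decomposition", part)
    save("decomposition_summary", group)
    ztests = group.attrs.get("block_vs_mix_ztests")
    if ztests is not None and len(ztests):
        save("compliance_ztests", ztests)
    for name, table in report_tables(frame, ssrt_table(frame, alpha), part).items():
        save(name, table)

    manifest = {
        "package": "selstop",
        "version": __version__,
        "seed": seed,
        "timestamp_utc": datetime.now(timezone.utc).isoformat(),
        "n_participants": n_participants,
        "block_trials": block_trials,
        "mix_trials": mix_trials,
        "conditions": [c.value for c in conditions],
        "emg_roundtrip": emg,
        "params": _params_dict(params),
        "outputs": {name: {"path": str(path), "sha256": _digest(path)}
                    for name, path in sorted(outputs.items())},
    }
    manifest_path = outdir / "manifest.yaml"
    manifest_path.write_text(yaml.safe_dump(manifest, sort_keys=False))
    outputs["manifest"] = manifest_path
    return outputs


def _params_dict(params: RestartModelParams) -> dict:
    out = dataclasses.asdict(params)

    def clean(obj):
        if isinstance(obj, dict):
            return {(k.value if hasattr(k, "value") else k): clean(v)
                    for k, v in obj.items()}
        if hasattr(obj, "value"):
            return obj.value
        return obj

    return clean(out)


def report_tables(
    frame: pd.DataFrame,
    ssrt: pd.DataFrame,
    decomposition: pd.DataFrame,
) -> dict[str, pd.DataFrame]:
    """Synthetic-data summary tables in the conventional per-cell
    mean (+/- SD) shapes: No Stop MusRT and electromechanical delay per
    effector, SSRT per cell, and Compliant/Non-Compliant SSDs.  All values
    derive from simulated sessions and are labelled as such."""
    conditions = [TaskCondition(c) for c in frame["condition"].unique()]

    def cell_label(condition: TaskCondition, version: StopVersion) -> str:
        return version.value if condition is TaskCondition.BLOCK else "mix"

    # Table-1 shape: No Stop MusRT and RT-MusRT delay per effector and cell
    t1_rows = []
    seen = set()
    for condition in conditions:
        for version in StopVersion:
            label = cell_label(condition, version)
            if label in seen:
                continue
            seen.add(label)
            per_part = []
            for pid in participants(frame):
                pool = no_stop_pool(frame, pid, condition, version)
                if not len(pool):
                    continue
                per_part.append({
                    "wrist_musrt": pool["wrist_mus_rt"].mean(),
                    "wrist_delay": (pool["wrist_rt"] - pool["wrist_mus_rt"]).mean(),
                    "foot_musrt": pool["foot_mus_rt"].mean(),
                    "foot_delay": (pool["foot_rt"] - pool["foot_mus_rt"]).mean(),
                })
            if not per_part:
                continue
            pp = pd.DataFrame(per_part)
            t1_rows.append({
                "task_condition": label, "source": "synthetic",
                **{f"{c}_{s}": float(getattr(pp[c], s)())
                   for c in pp.columns for s in ("mean", "std")},
            })
    t1 = pd.DataFrame(t1_rows)

    # Table-2 shape: group SSRT per cell, "not respected" when violated
    t2_rows = []
    if len(ssrt):
        mean_rows = ssrt[ssrt["method"] == "mean"]
        for (condition, version), sub in mean_rows.groupby(["condition", "version"]):
            violated = bool(sub["independence_violated"].any())
            valid = sub[sub["valid"]]
            t2_rows.append({
                "condition": condition, "version": version, "source": "synthetic",
                "ssrt_mean": float(valid["ssrt"].mean()) if len(valid) else np.nan,
                "ssrt_sd": float(valid["ssrt"].std()) if len(valid) > 1 else np.nan,
                "independence": "not respected" if violated else "respected",
            })
    t2 = pd.DataFrame(t2_rows)

    # Table-3 shape: mean SSD of Compliant vs Non-Compliant errors
    t3_rows = []
    if len(decomposition):
        for (condition, version), sub in decomposition.groupby(["condition", "version"]):
            t3_rows.append({
                "condition": condition, "version": version, "source": "synthetic",
                "ssd_compliant_mean": float(sub["mean_ssd_compliant"].mean()),
                "ssd_compliant_sd": float(sub["mean_ssd_compliant"].std()),
                "ssd_noncompliant_mean": float(sub["mean_ssd_noncompliant"].mean()),
                "ssd_noncompliant_sd": float(sub["mean_ssd_noncompliant"].std()),
            })
    t3 = pd.DataFrame(t3_rows)
    return {"table_musrt_summary": t1, "table_ssrt_summary": t2,
            "table_ssd_summary": t3}
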