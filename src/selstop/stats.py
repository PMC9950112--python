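"""Small-sample statistical battery with exact classical contracts.

Self-contained implementations of the tests used throughout the analysis:
two-way repeated-measures ANOVA with partial eta squared, paired t-tests,
Bonferroni adjustment, Spearman rank correlation, a between-subjects one-way
ANOVA, and the conventional effect-size labels for eta_p^2.  Everything is a
direct sum-of-squares / closed-form computation so each result can be
checked against brute-force oracles on tiny datasets.

Sphericity corrections are intentionally omitted: two-level factors are
exact, and uncorrected degrees of freedom are reported elsewhere (noted in
the returned tables' metadata).
"""

from __future__ import annotations

import math
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps


def paired_t(a: Sequence[float], b: Sequence[float]) -> tuple[float, int, float]:
    """Classical paired t-test; returns (t, df, two-tailed p).

    Zero-variance differences: t = 0, p = 1 when the common difference is
    zero; +/-inf with p = 0 otherwise.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    n = a.size
    if n < 2:
        raise ValueError("paired t-test needs at least 2 pairs")
    d = a - b
    df = n - 1
    sd = d.std(ddof=1)
    mean = d.mean()
    if sd == 0.0:
        if mean == 0.0:
            return 0.0, df, 1.0
        return math.copysign(math.inf, mean), df, 0.0
    t = mean / (sd / math.sqrt(n))
    p = 2.0 * sps.t.sf(abs(t), df)
    return float(t), df, float(p)


def bonferroni(p_values: Sequence[float], m: Optional[int] = None) -> np.ndarray:
    """Bonferroni adjustment: p_adj = min(1, p * m); m defaults to the count."""
    p = np.asarray(p_values, dtype=float)
    if m is None:
        m = p.size
    if m < p.size:
        raise ValueError("m must be at least the number of comparisons")
    return np.minimum(1.0, p * m)


def spearman(a: Sequence[float], b: Sequence[float]) -> Optional[tuple[float, float]]:
    """Spearman rank correlation with average ranks for ties.

    Returns (r, two-tailed p from the t approximation), or None when either
    input is constant (the correlation is undefined).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("samples must have equal length")
    n = a.size
    if n < 5:
        raise ValueError("spearman needs at least 5 pairs")
    if np.ptp(a) == 0.0 or np.ptp(b) == 0.0:
        return None
    ra = sps.rankdata(a)
    rb = sps.rankdata(b)
    ra = ra - ra.mean()
    rb = rb - rb.mean()
    denom = math.sqrt(float(ra @ ra) * float(rb @ rb))
    r = float(ra @ rb) / denom
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        return r, 0.0
    t = r * math.sqrt((n - 2) / (1.0 - r * r))
    p = 2.0 * sps.t.sf(abs(t), n - 2)
    return r, float(p)


def effect_size_label(eta_p_sq: float) -> str:
    """Conventional label for a partial eta squared.

    Thresholds (left-closed): 0.01 small, 0.06 medium, 0.14 or higher large;
    below 0.01 is reported as negligible.
    """
    if not 0.0 <= eta_p_sq <= 1.0:
        raise ValueError("eta_p_sq must lie in [0, 1]")
    if eta_p_sq >= 0.14:
        return "large"
    if eta_p_sq >= 0.06:
        return "medium"
    if eta_p_sq >= 0.01:
        return "small"
    return "negligible"


def _f_p(ss_effect: float, df_effect: int, ss_error: float, df_error: int
         ) -> tuple[float, float, float]:
    """(F, p, eta_p_sq) from an effect/error SS pair; 0/0 is reported as 0."""
    ms_effect = ss_effect / df_effect if df_effect else 0.0
    ms_error = ss_error / df_error if df_error else 0.0
    if ms_effect == 0.0:
        return 0.0, 1.0, 0.0
    if ms_error == 0.0:
        return math.inf, 0.0, 1.0
    f = ms_effect / ms_error
    p = float(sps.f.sf(f, df_effect, df_error))
    eta = ss_effect / (ss_effect + ss_error)
    return float(f), p, float(eta)


def rm_anova2(
    cells: pd.DataFrame,
    subject: str = "subject",
    factor_a: str = "factor_a",
    factor_b: str = "factor_b",
    value: str = "value",
) -> pd.DataFrame:
    """Two-way repeated-measures ANOVA on a complete crossed design.

    ``cells`` has one row per subject x factor_a x factor_b cell mean.  The
    classical decomposition uses each effect's subject-interaction stratum
    as its error term; partial eta squared is
    SS_effect / (SS_effect + SS_error_effect).  A factor with a single level
    degenerates to the one-way repeated-measures ANOVA on the other factor.
    Missing or duplicated cells raise (no imputation).
    """
    data = cells[[subject, factor_a, factor_b, value]].copy()
    subjects = data[subject].unique()
    a_levels = data[factor_a].unique()
    b_levels = data[factor_b].unique()
    n_s, n_a, n_b = len(subjects), len(a_levels), len(b_levels)
    if n_s < 2:
        raise ValueError("need at least 2 subjects")
    counts = data.groupby([subject, factor_a, factor_b], observed=True).size()
    if len(counts) != n_s * n_a * n_b or (counts != 1).any():
        raise ValueError("design must be complete with exactly one value per cell")

    y = data.pivot_table(index=subject, columns=[factor_a, factor_b], values=value)
    arr = y.to_numpy().reshape(n_s, n_a, n_b)  # pivot sorts levels; order is immaterial

    grand = arr.mean()
    m_s = arr.mean(axis=(1, 2))
    m_a = arr.mean(axis=(0, 2))
    m_b = arr.mean(axis=(0, 1))
    m_sa = arr.mean(axis=2)
    m_sb = arr.mean(axis=1)
    m_ab = arr.mean(axis=0)

    ss_a = n_s * n_b * float(((m_a - grand) ** 2).sum())
    ss_b = n_s * n_a * float(((m_b - grand) ** 2).sum())
    ss_ab = n_s * float(
        ((m_ab - m_a[:, None] - m_b[None, :] + grand) ** 2).sum())
    ss_subj = n_a * n_b * float(((m_s - grand) ** 2).sum())
    ss_as = n_b * float(
        ((m_sa - m_s[:, None] - m_a[None, :] + grand) ** 2).sum())
    ss_bs = n_a * float(
        ((m_sb - m_s[:, None] - m_b[None, :] + grand) ** 2).sum())
    ss_total = float(((arr - grand) ** 2).sum())
    ss_abs = ss_total - (ss_a + ss_b + ss_ab + ss_subj + ss_as + ss_bs)
    ss_abs = max(ss_abs, 0.0)

    rows = []
    if n_a > 1:
        f, p, eta = _f_p(ss_a, n_a - 1, ss_as, (n_a - 1) * (n_s - 1))
        rows.append((factor_a, ss_a, ss_as, f, n_a - 1, (n_a - 1) * (n_s - 1), p, eta))
    if n_b > 1:
        f, p, eta = _f_p(ss_b, n_b - 1, ss_bs, (n_b - 1) * (n_s - 1))
        rows.append((factor_b, ss_b, ss_bs, f, n_b - 1, (n_b - 1) * (n_s - 1), p, eta))
    if n_a > 1 and n_b > 1:
        df_ab = (n_a - 1) * (n_b - 1)
        f, p, eta = _f_p(ss_ab, df_ab, ss_abs, df_ab * (n_s - 1))
        rows.append((f"{factor_a}*{factor_b}", ss_ab, ss_abs, f, df_ab,
                     df_ab * (n_s - 1), p, eta))
    table = pd.DataFrame(
        rows, columns=["effect", "ss_effect", "ss_error", "F", "df_num",
                       "df_den", "p", "eta_p_sq"])
    table.attrs["ss_total"] = ss_total
    table.attrs["ss_subject"] = ss_subj
    table.attrs["sphericity_correction"] = "none"
    return table


def oneway_anova(groups: Sequence[Sequence[float]]) -> tuple[float, int, int, float, float]:
    """Between-subjects one-way ANOVA; returns (F, df_num, df_den, p, eta_p_sq).

    The group-mean comparison used for SSRT tables, where estimates from
    different cells are treated as independent group samples.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(g.size < 2 for g in groups):
        raise ValueError("need at least two groups of at least two values")
    allv = np.concatenate(groups)
    grand = allv.mean()
    ss_between = float(sum(g.size * (g.mean() - grand) ** 2 for g in groups))
    ss_within = float(sum(((g - g.mean()) ** 2).sum() for g in groups))
    df_num = len(groups) - 1
    df_den = allv.size - len(groups)
    f, p, eta = _f_p(ss_between, df_num, ss_within, df_den)
    return f, df_num, df_den, p, eta
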