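"""Group-level inference: one-way ANOVA with Tukey HSD post-hoc,
mixed-design (between-group x within-day) repeated-measures ANOVA with an
optional Greenhouse-Geisser correction, and mean +/- SEM summaries.

Implemented from sums of squares directly (the designs here are small and
complete); p-values come from scipy's F and studentized-range
distributions. Unbalanced one-way designs use the Tukey-Kramer form.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "AnovaResult",
    "PairwiseComparison",
    "RmAnovaResult",
    "GroupSummary",
    "anova_tukey",
    "rm_anova",
    "group_summary",
]


@dataclass
class PairwiseComparison:
    group_a: str
    group_b: str
    mean_diff: float  # mean(b) - mean(a)
    p_adjusted: float


@dataclass
class AnovaResult:
    F: float
    df_between: int
    df_within: int
    p: float
    group_means: Dict[str, float]
    pairwise: List[PairwiseComparison] = field(default_factory=list)


@dataclass
class RmAnovaResult:
    """Mixed-design ANOVA table: between-group, within-subject time, and
    group x time interaction effects, each (F, df_num, df_den, p)."""

    group: Tuple[float, int, int, float]
    time: Tuple[float, int, int, float]
    interaction: Tuple[float, int, int, float]
    gg_epsilon: float
    time_p_gg: float
    interaction_p_gg: float


@dataclass
class GroupSummary:
    groups: Dict[str, Tuple[float, float, int]]  # group -> (mean, sem, n)


def _split_groups(values, groups) -> Dict[str, np.ndarray]:
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    if values.size != groups.size:
        raise ValueError("values and groups must align")
    return {str(g): values[groups == g] for g in pd.unique(groups)}


def anova_tukey(values: Sequence[float], groups: Sequence) -> AnovaResult:
    """One-way fixed-effects ANOVA across groups plus all-pairs Tukey HSD.

    Requires >= 2 groups and >= 2 observations per group. Unequal group
    sizes are handled with the Tukey-Kramer standard error.
    """
    by = _split_groups(values, groups)
    if len(by) < 2:
        raise ValueError("need >= 2 groups for ANOVA")
    for g, v in by.items():
        if v.size < 2:
            raise ValueError(f"group {g!r} has {v.size} observation(s); need >= 2")
    all_vals = np.concatenate(list(by.values()))
    grand = all_vals.mean()
    k, n = len(by), all_vals.size
    ssb = sum(v.size * (v.mean() - grand) ** 2 for v in by.values())
    ssw = sum(((v - v.mean()) ** 2).sum() for v in by.values())
    df_b, df_w = k - 1, n - k
    msw = ssw / df_w
    if msw == 0:
        f_stat = 0.0 if ssb == 0 else np.inf
        p = 1.0 if ssb == 0 else 0.0
    else:
        f_stat = (ssb / df_b) / msw
        p = float(sps.f.sf(f_stat, df_b, df_w))

    names = list(by)
    pairwise = []
    for i in range(k):
        for j in range(i + 1, k):
            a, b = by[names[i]], by[names[j]]
            diff = b.mean() - a.mean()
            se = np.sqrt(msw / 2.0 * (1.0 / a.size + 1.0 / b.size))
            if se == 0:
                p_adj = 1.0 if diff == 0 else 0.0
            else:
                q = abs(diff) / se
                p_adj = float(sps.studentized_range.sf(q, k, df_w))
            pairwise.append(PairwiseComparison(names[i], names[j],
                                               float(diff), min(p_adj, 1.0)))
    return AnovaResult(F=float(f_stat), df_between=df_b, df_within=df_w, p=p,
                       group_means={g: float(v.mean()) for g, v in by.items()},
                       pairwise=pairwise)


def _complete_pivot(df: pd.DataFrame, value: str, subject: str,
                    within: str, between: str):
    wide = df.pivot_table(index=subject, columns=within, values=value,
                          aggfunc="mean", dropna=False)
    missing = [(s, t) for s in wide.index for t in wide.columns
               if pd.isna(wide.loc[s, t])]
    if missing:
        raise ValueError(f"incomplete design; missing (subject, {within}) cells: "
                         f"{missing[:10]}{'...' if len(missing) > 10 else ''}")
    grp = df.groupby(subject)[between].agg(lambda s: s.iloc[0])
    if df.groupby(subject)[between].nunique().max() > 1:
        raise ValueError("a subject appears under more than one group label")
    return wide, grp.reindex(wide.index)


def _gg_epsilon(wide: pd.DataFrame, subj_groups: pd.Series) -> float:
    """Greenhouse-Geisser epsilon from the pooled within-group covariance
    of the subject x time matrix."""
    t = wide.shape[1]
    if t < 2:
        return 1.0
    mats = []
    for g in subj_groups.unique():
        sub = wide.loc[subj_groups == g].to_numpy(dtype=float)
        mats.append(sub - sub.mean(axis=0, keepdims=True))
    x = np.vstack(mats)
    dof = x.shape[0] - subj_groups.nunique()
    if dof < 1:
        return 1.0
    s = x.T @ x / dof
    # orthonormal contrasts spanning the within-subject space
    c = np.linalg.qr(np.vstack([np.ones(t), np.eye(t)[: t - 1]]).T)[0][:, 1:].T
    m = c @ s @ c.T
    tr = np.trace(m)
    denom = (t - 1) * np.trace(m @ m)
    if denom <= 0:
        return 1.0
    return float(np.clip(tr ** 2 / denom, 1.0 / (t - 1), 1.0))


def rm_anova(df: pd.DataFrame, value: str = "value", subject: str = "well",
             within: str = "day", between: str = "group") -> RmAnovaResult:
    """Mixed-design ANOVA on a complete tidy table.

    Every subject must be observed at every level of ``within`` (missing
    cells raise, listing them). Sphericity is assumed for the reported
    p-values; Greenhouse-Geisser-corrected p-values for the within and
    interaction effects are reported alongside.
    """
    for col in (value, subject, within, between):
        if col not in df.columns:
            raise ValueError(f"missing column {col!r}")
    wide, subj_groups = _complete_pivot(df, value, subject, within, between)
    x = wide.to_numpy(dtype=float)
    n_subj, t = x.shape
    groups = subj_groups.to_numpy()
    labels = pd.unique(groups)
    k = labels.size
    if k < 2:
        raise ValueError("need >= 2 groups")

    grand = x.mean()
    subj_means = x.mean(axis=1)
    time_means = x.mean(axis=0)
    ss_total = ((x - grand) ** 2).sum()
    ss_between_subj = t * ((subj_means - grand) ** 2).sum()
    ss_group = sum(t * (groups == g).sum() * (subj_means[groups == g].mean() - grand) ** 2
                   for g in labels)
    ss_subj_within = ss_between_subj - ss_group
    ss_within_subj = ss_total - ss_between_subj
    ss_time = n_subj * ((time_means - grand) ** 2).sum()
    ss_cells = sum((groups == g).sum() * (x[groups == g].mean(axis=0) - grand) ** 2
                   for g in labels).sum()
    ss_inter = ss_cells - ss_group - ss_time
    ss_err_within = ss_within_subj - ss_time - ss_inter

    df_group, df_subj = k - 1, n_subj - k
    df_time = t - 1
    df_inter = df_group * df_time
    df_err = df_subj * df_time

    def _f(ss_eff, df_eff, ss_err, df_err_):
        if df_err_ <= 0:
            raise ValueError("not enough subjects for the error term")
        ms_err = ss_err / df_err_
        if ss_eff <= 1e-12 * max(ss_total, 1.0):
            return 0.0, 1.0
        if ms_err == 0:
            return np.inf, 0.0
        f_stat = (ss_eff / df_eff) / ms_err
        return float(f_stat), float(sps.f.sf(f_stat, df_eff, df_err_))

    f_g, p_g = _f(ss_group, df_group, ss_subj_within, df_subj)
    f_t, p_t = _f(ss_time, df_time, ss_err_within, df_err)
    f_i, p_i = _f(ss_inter, df_inter, ss_err_within, df_err)

    eps = _gg_epsilon(wide, subj_groups)
    p_t_gg = float(sps.f.sf(f_t, df_time * eps, df_err * eps)) if f_t > 0 else 1.0
    p_i_gg = float(sps.f.sf(f_i, df_inter * eps, df_err * eps)) if f_i > 0 else 1.0

    return RmAnovaResult(group=(f_g, df_group, df_subj, p_g),
                         time=(f_t, df_time, df_err, p_t),
                         interaction=(f_i, df_inter, df_err, p_i),
                         gg_epsilon=eps, time_p_gg=p_t_gg,
                         interaction_p_gg=p_i_gg)


def group_summary(values: Sequence[float], groups: Sequence) -> GroupSummary:
    """Mean, SEM (sample SD / sqrt(n)) and n per group. A singleton group
    gets SEM 0 by convention."""
    by = _split_groups(values, groups)
    out = {}
    for g, v in by.items():
        if v.size == 0:
            raise ValueError(f"group {g!r} is empty")
        sem = float(v.std(ddof=1) / np.sqrt(v.size)) if v.size > 1 else 0.0
        out[g] = (float(v.mean()), sem, int(v.size))
    return GroupSummary(groups=out)
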