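"""Variability decomposition and within-subject inferential tests.

Two complementary standard deviations summarize where measurement variability
lives:

* the **interindividual SD** (between-subject heterogeneity): average the
  trials of each subject within each condition, take the SD of those means
  across subjects separately per condition, then average across conditions;
* the **intra-individual SD** (trial-to-trial consistency): take the SD
  across trials within each subject-by-condition cell, average the cell SDs
  across conditions within each subject, then take the grand mean across
  subjects.

A tracker that works well for some subjects but poorly for others shows up in
the first number; a tracker that is uniformly noisy shows up in the second.
All SDs use the n-1 denominator, both decompositions are invariant under
adding a constant, and both scale with |k| when all values are scaled by k.

The inferential layer provides the classical repeated-measures ANOVA
(subjects as their own controls): the one-way partition
``SS_total = SS_treatment + SS_subjects + SS_error`` with
``F = MS_treatment / MS_error`` on ``(k-1, (k-1)(n-1))`` degrees of freedom
(for two levels this F equals the squared paired t), and the two-way
fully-within interaction F tested against its interaction-by-subject
residual.  No sphericity correction is applied by default;
Greenhouse-Geisser is available as an option for the one-way test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps


# ---------------------------------------------------------------------------
# variability decomposition
# ---------------------------------------------------------------------------

def interindividual_sd(
    df: pd.DataFrame,
    value: str = "value",
    subject: str = "subject",
    condition: str = "condition",
) -> float:
    """Between-subject SD, averaged over conditions (see module docstring)."""
    if df[subject].nunique() < 2:
        raise ValueError("interindividual SD needs at least 2 subjects")
    subj_means = df.groupby([condition, subject], sort=True)[value].mean()
    per_cond_sd = subj_means.groupby(level=0).std(ddof=1)
    return float(per_cond_sd.mean())


def intraindividual_sd(
    df: pd.DataFrame,
    value: str = "value",
    subject: str = "subject",
    condition: str = "condition",
) -> float:
    """Within-subject trial-to-trial SD (see module docstring).

    Subject-by-condition cells with fewer than two trials are dropped with a
    warning.
    """
    cells = df.groupby([subject, condition], sort=True)[value].agg(["std", "count"])
    short = cells["count"] < 2
    if short.any():
        warnings.warn(
            f"dropping {int(short.sum())} cell(s) with <2 trials from "
            "intra-individual SD", stacklevel=2,
        )
        cells = cells[~short]
    if cells.empty:
        raise ValueError("no cells with >=2 trials")
    per_subject = cells["std"].groupby(level=0).mean()
    return float(per_subject.mean())


def sd_decomposition(
    df: pd.DataFrame,
    value: str = "value",
    subject: str = "subject",
    condition: str = "condition",
    system: str = "system",
) -> pd.DataFrame:
    """Inter- and intra-individual SD per system, as a tidy table."""
    rows = []
    for sysname, g in df.groupby(system, sort=True):
        rows.append({
            system: sysname,
            "interindividual_sd": interindividual_sd(g, value, subject, condition),
            "intraindividual_sd": intraindividual_sd(g, value, subject, condition),
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# repeated-measures ANOVA and paired t
# ---------------------------------------------------------------------------

@dataclass
class RMAnovaResult:
    F: float
    df1: int
    df2: int
    p: float

    def __iter__(self):
        return iter((self.F, self.df1, self.df2, self.p))


def rm_anova_oneway(
    data: np.ndarray, greenhouse_geisser: bool = False
) -> RMAnovaResult:
    """One-way repeated-measures ANOVA on an (n_subjects, k_levels) table.

    Requires a balanced table (one value per subject per level, no missing
    cells).  With ``greenhouse_geisser=True`` the degrees of freedom are
    multiplied by the Greenhouse-Geisser epsilon before computing p.
    """
    data = np.asarray(data, float)
    if data.ndim != 2:
        raise ValueError("data must be a 2-D subjects x levels table")
    if np.isnan(data).any():
        raise ValueError("unbalanced table: missing cells are not supported")
    n, k = data.shape
    if n < 2 or k < 2:
        raise ValueError("need at least 2 subjects and 2 levels")
    grand = data.mean()
    level_means = data.mean(axis=0)
    subj_means = data.mean(axis=1)
    ss_total = float(((data - grand) ** 2).sum())
    ss_treat = float(n * ((level_means - grand) ** 2).sum())
    ss_subj = float(k * ((subj_means - grand) ** 2).sum())
    ss_err = ss_total - ss_treat - ss_subj
    # sums of squares below float rounding of the partition are exact zeros
    tiny = 1e-12 * max(ss_total, 1e-300)
    ss_treat = 0.0 if ss_treat <= tiny else ss_treat
    ss_err = 0.0 if ss_err <= tiny else ss_err
    df1, df2 = k - 1, (k - 1) * (n - 1)
    ms_err = ss_err / df2
    if ms_err == 0.0:
        F = 0.0 if ss_treat == 0.0 else np.inf
    else:
        F = (ss_treat / df1) / ms_err
    eps = 1.0
    if greenhouse_geisser and k > 2:
        # epsilon from the double-centered covariance of the level scores
        cov = np.cov(data.T, ddof=1)
        c = cov - cov.mean(axis=0, keepdims=True) \
            - cov.mean(axis=1, keepdims=True) + cov.mean()
        eps = float(np.trace(c) ** 2 / ((k - 1) * (c * c).sum()))
        eps = min(max(eps, 1.0 / (k - 1)), 1.0)
    p = float(sps.f.sf(F, df1 * eps, df2 * eps)) if np.isfinite(F) else 0.0
    if F == 0.0:
        p = 1.0
    return RMAnovaResult(F=float(F), df1=df1, df2=df2, p=p)


def rm_anova_interaction(data: np.ndarray) -> RMAnovaResult:
    """Condition-by-system interaction F of a fully within-subject design.

    ``data`` is a balanced (n_subjects, n_conditions, n_systems) array with
    one value per cell.  The interaction mean square is tested against the
    interaction-by-subject residual on
    ``((n_c-1)(n_k-1), (n_c-1)(n_k-1)(n_s-1))`` degrees of freedom.
    """
    data = np.asarray(data, float)
    if data.ndim != 3:
        raise ValueError("data must be (subjects, conditions, systems)")
    if np.isnan(data).any():
        raise ValueError("unbalanced table: missing cells are not supported")
    ns, nc, nk = data.shape
    if ns < 2 or nc < 2 or nk < 2:
        raise ValueError("need >=2 subjects and >=2 levels per factor")
    grand = data.mean()
    m_c = data.mean(axis=(0, 2))          # per condition
    m_k = data.mean(axis=(0, 1))          # per system
    m_s = data.mean(axis=(1, 2))          # per subject
    m_ck = data.mean(axis=0)              # condition x system
    m_sc = data.mean(axis=2)              # subject x condition
    m_sk = data.mean(axis=1)              # subject x system
    inter = m_ck - m_c[:, None] - m_k[None, :] + grand
    ss_inter = float(ns * (inter ** 2).sum())
    resid = (
        data
        - m_sc[:, :, None] - m_sk[:, None, :] - m_ck[None, :, :]
        + m_s[:, None, None] + m_c[None, :, None] + m_k[None, None, :]
        - grand
    )
    ss_resid = float((resid ** 2).sum())
    tiny = 1e-12 * max(float(((data - grand) ** 2).sum()), 1e-300)
    ss_inter = 0.0 if ss_inter <= tiny else ss_inter
    ss_resid = 0.0 if ss_resid <= tiny else ss_resid
    df1 = (nc - 1) * (nk - 1)
    df2 = (nc - 1) * (nk - 1) * (ns - 1)
    ms_resid = ss_resid / df2
    if ms_resid == 0.0:
        F = 0.0 if ss_inter == 0.0 else np.inf
    else:
        F = (ss_inter / df1) / ms_resid
    p = float(sps.f.sf(F, df1, df2)) if np.isfinite(F) else 0.0
    if F == 0.0:
        p = 1.0
    return RMAnovaResult(F=float(F), df1=df1, df2=df2, p=p)


@dataclass
class PairedTResult:
    t: float
    df: int
    p: float
    zero_variance: bool = False

    def __iter__(self):
        return iter((self.t, self.df, self.p))


def paired_t(x, y) -> PairedTResult:
    """Two-sided paired t test: ``t = mean(d) / (sd(d)/sqrt(n))``, d = x - y.

    A zero-variance difference vector yields an infinite t (sign of the mean
    difference) flagged via ``zero_variance``; if the mean is also zero the
    samples are identical and t = 0, p = 1.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D arrays")
    n = x.size
    if n < 2:
        raise ValueError("need at least 2 pairs")
    d = x - y
    md = d.mean()
    sd = d.std(ddof=1)
    df = n - 1
    if sd == 0.0:
        if md == 0.0:
            return PairedTResult(t=0.0, df=df, p=1.0, zero_variance=True)
        return PairedTResult(t=float(np.sign(md) * np.inf), df=df, p=0.0,
                             zero_variance=True)
    t = float(md / (sd / np.sqrt(n)))
    p = float(2.0 * sps.t.sf(abs(t), df))
    return PairedTResult(t=t, df=df, p=p)


__all__ = [
    "interindividual_sd",
    "intraindividual_sd",
    "sd_decomposition",
    "rm_anova_oneway",
    "rm_anova_interaction",
    "paired_t",
    "RMAnovaResult",
    "PairedTResult",
]
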