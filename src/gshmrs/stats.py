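"""Cohort-level longitudinal analysis.

Implements the study's rules: undetectable *baselines* are imputed with the
lowest measured GSH/Cr across all subjects and scans divided by two (other
missing scans are simply excluded); each level is assigned the midpoint of
its scan; per-subject differences versus baseline are formed; the time effect
is tested with a one-way repeated-measures ANOVA (general-linear-model form
with subject as a blocking factor, so unbalanced tables are usable) followed
by Holm-Sidak-adjusted comparisons of every post-dose bin against baseline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.multitest import multipletests

from .core import ParameterError, StructuralError

ALPHA = 0.05


class DataError(RuntimeError):
    """The cohort table cannot support the analysis."""


def impute_undetectable(table: pd.DataFrame) -> pd.DataFrame:
    """Assign undetectable baselines the lowest measured ratio / 2.

    Every undetectable baseline receives the same value; detectable
    measurements are never altered; non-baseline missing scans stay excluded.
    Requires at least one detectable measurement in the cohort.
    """
    df = table.copy()
    measured = df.loc[df.flag == "ok", "gsh_cr"]
    if measured.empty or not np.isfinite(measured).any():
        raise DataError("no detectable measurement anywhere in the cohort")
    imputed_value = float(np.nanmin(measured)) / 2.0
    mask = (df.scan_index == 0) & (df.flag == "undetectable")
    df.loc[mask, "gsh_cr"] = imputed_value
    df.loc[mask, "flag"] = "imputed"
    if "cr_corrected_iu" in df and "gsh_absolute_iu" in df:
        df.loc[mask, "gsh_absolute_iu"] = (imputed_value
                                           * df.loc[mask, "cr_corrected_iu"])
    return df


def assign_time_bins(table: pd.DataFrame) -> pd.DataFrame:
    """Group scans by ordinal post-dose index; baseline is bin 0.

    Adds ``time_bin`` (ordinal) and per-bin label columns ``bin_time_mean`` /
    ``bin_time_sem`` (mean and SEM of the scan midpoints in the bin).
    """
    df = table.copy()
    df["time_bin"] = df.scan_index.astype(int)
    grp = df.groupby("time_bin")["time_min"]
    df["bin_time_mean"] = df.time_bin.map(grp.mean())
    sem = grp.apply(lambda x: float(x.std(ddof=1) / np.sqrt(len(x)))
                    if len(x) > 1 else 0.0)
    df["bin_time_sem"] = df.time_bin.map(sem)
    return df


def differences_vs_baseline(table: pd.DataFrame,
                            value: str = "gsh_cr") -> pd.DataFrame:
    """Per-subject differences of each post-dose scan versus baseline."""
    usable = table[np.isfinite(table[value])]
    base = usable[usable.scan_index == 0].set_index("subject_id")[value]
    post = usable[usable.scan_index > 0].copy()
    post = post[post.subject_id.isin(base.index)]
    post["diff_vs_baseline"] = (post[value].values
                                - base.loc[post.subject_id].values)
    return post


@dataclass
class SummaryRow:
    """One row of the per-time-point summary table."""

    time_bin: int
    time_mean_min: float
    time_sem_min: float
    n: int
    mean: float
    sem: float
    min: float
    max: float
    mean_diff_vs_baseline: float | None
    sem_diff: float | None


@dataclass
class AnovaResult:
    f_statistic: float
    p_value: float
    df_num: int
    df_den: int
    comparisons: pd.DataFrame        # per post-dose bin vs baseline
    degenerate: bool = False


def rm_anova(table: pd.DataFrame, value: str = "gsh_cr",
             min_bin_n: int = 2, complete_cases: bool = False) -> AnovaResult:
    """Repeated-measures ANOVA for the time effect + Holm-Sidak comparisons.

    The omnibus test is the general-linear-model form
    ``value ~ C(subject) + C(time_bin)`` so subjects with missing cells still
    contribute; ``complete_cases=True`` restricts to subjects observed in
    every retained bin.  Bins with fewer than ``min_bin_n`` observations are
    dropped.  The multiple-comparison family is the set of post-dose bins
    versus baseline; each comparison is the model's time-bin contrast (the
    pooled-residual t-test standard for repeated-measures post-hoc
    comparisons), adjusted by the Holm-Sidak step-down procedure.
    """
    df = table[np.isfinite(table[value])].copy()
    if "time_bin" not in df:
        raise StructuralError("run assign_time_bins first")
    counts = df.groupby("time_bin")[value].count()
    keep = counts[counts >= min_bin_n].index
    df = df[df.time_bin.isin(keep)]
    bins = sorted(df.time_bin.unique())
    if len(bins) < 2 or df.subject_id.nunique() < 2:
        raise DataError("need >=2 time bins and >=2 subjects")
    if complete_cases:
        full = df.groupby("subject_id").time_bin.nunique()
        df = df[df.subject_id.isin(full[full == len(bins)].index)]

    model = smf.ols(f"{value} ~ C(subject_id) + C(time_bin)", data=df).fit()
    an = sm.stats.anova_lm(model, typ=2)
    f_stat = float(an.loc["C(time_bin)", "F"])
    p_val = float(an.loc["C(time_bin)", "PR(>F)"])
    degenerate = not np.isfinite(f_stat)

    counts = df.groupby("time_bin")[value].count()
    rows = []
    for b in bins:
        if b == 0:
            continue
        name = f"C(time_bin)[T.{b}]"
        if name not in model.params.index:
            continue
        t = float(model.tvalues[name])
        p = float(model.pvalues[name])
        rows.append(dict(time_bin=int(b), n=int(counts.get(b, 0)),
                         mean_diff=float(model.params[name]),
                         t=t, p_raw=p))
    comp = pd.DataFrame(rows)
    if not comp.empty:
        reject, p_adj, *_ = multipletests(comp.p_raw, alpha=ALPHA,
                                          method="holm-sidak")
        comp["p_adjusted"] = p_adj
        comp["significant"] = reject
    return AnovaResult(f_statistic=f_stat, p_value=p_val,
                       df_num=int(an.loc["C(time_bin)", "df"]),
                       df_den=int(an.loc["Residual", "df"]),
                       comparisons=comp, degenerate=degenerate)


def summarize(table: pd.DataFrame, value: str = "gsh_cr",
              min_bin_n: int = 2) -> pd.DataFrame:
    """Per-time-point summary rows (mean, SEM, min, max, diff vs baseline).

    Bins with fewer than ``min_bin_n`` contributing scans are omitted.
    Invariant to subject ordering.
    """
    df = table[np.isfinite(table[value])]
    if "time_bin" not in df:
        raise StructuralError("run assign_time_bins first")
    diffs = differences_vs_baseline(table, value)
    rows = []
    for b, g in df.groupby("time_bin"):
        if len(g) < min_bin_n:
            continue
        d = diffs[diffs.time_bin == b].diff_vs_baseline if b != 0 else None
        rows.append(SummaryRow(
            time_bin=int(b),
            time_mean_min=float(g.time_min.mean()),
            time_sem_min=float(g.time_min.std(ddof=1) / np.sqrt(len(g))
                               if len(g) > 1 else 0.0),
            n=len(g),
            mean=float(g[value].mean()),
            sem=float(g[value].std(ddof=1) / np.sqrt(len(g))),
            min=float(g[value].min()),
            max=float(g[value].max()),
            mean_diff_vs_baseline=(None if d is None or d.empty
                                   else float(d.mean())),
            sem_diff=(None if d is None or len(d) < 2
                      else float(d.std(ddof=1) / np.sqrt(len(d))))))
    out = pd.DataFrame([r.__dict__ for r in rows])
    return out.sort_values("time_bin").reset_index(drop=True)


def percent_change(summary: pd.DataFrame,
                   convention: str = "ratio_of_means") -> float:
    """Change from baseline to the last summarised bin, in percent.

    ``ratio_of_means`` reports ``100 * mean_final / mean_baseline`` (the
    convention consistent with the reported 269%); ``increase`` reports
    ``100 * (mean_final / mean_baseline - 1)``.
    """
    if summary.empty or 0 not in summary.time_bin.values:
        raise DataError("summary lacks a baseline row")
    m0 = float(summary.loc[summary.time_bin == 0, "mean"].iloc[0])
    mf = float(summary.loc[summary.time_bin.idxmax(), "mean"])
    if m0 == 0:
        raise DataError("zero baseline mean")
    ratio = 100.0 * mf / m0
    if convention == "ratio_of_means":
        return ratio
    if convention == "increase":
        return ratio - 100.0
    raise ParameterError(f"unknown convention {convention!r}")
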