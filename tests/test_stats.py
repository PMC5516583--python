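"""Longitudinal-statistics tests: oracles and invariants."""

import numpy as np
import pandas as pd
import pytest
import scipy.stats
from hypothesis import given
from hypothesis import strategies as st

from gshmrs import stats
from gshmrs.cohort import simulate_cohort
from gshmrs.pipeline import quantify_cohort


def _balanced_table(seed=0, n_subjects=15, n_bins=5):
    rng = np.random.default_rng(seed)
    rows = []
    subj_eff = rng.normal(0, 0.01, n_subjects)
    bin_eff = np.array([0.0, 0.009, 0.019, 0.021, 0.029])[:n_bins]
    for i in range(n_subjects):
        for b in range(n_bins):
            rows.append(dict(subject_id=f"s{i:02d}", scan_index=b,
                             time_min=12.0 * b, flag="ok",
                             gsh_cr=0.02 + subj_eff[i] + bin_eff[b]
                             + rng.normal(0, 0.005)))
    return stats.assign_time_bins(pd.DataFrame(rows))


def test_rm_anova_matches_brute_force_sums_of_squares():
    """Complete balanced data: GLM RM-ANOVA equals the textbook two-way
    (subject x time) decomposition to 1e-8 relative."""
    df = _balanced_table()
    res = stats.rm_anova(df)

    y = df.pivot(index="subject_id", columns="time_bin",
                 values="gsh_cr").values
    n, k = y.shape
    grand = y.mean()
    ss_subj = k * np.sum((y.mean(axis=1) - grand) ** 2)
    ss_time = n * np.sum((y.mean(axis=0) - grand) ** 2)
    ss_tot = np.sum((y - grand) ** 2)
    ss_res = ss_tot - ss_subj - ss_time
    df_time, df_res = k - 1, (n - 1) * (k - 1)
    f_oracle = (ss_time / df_time) / (ss_res / df_res)
    p_oracle = float(scipy.stats.f.sf(f_oracle, df_time, df_res))

    assert res.df_num == df_time and res.df_den == df_res
    assert res.f_statistic == pytest.approx(f_oracle, rel=1e-8)
    assert res.p_value == pytest.approx(p_oracle, rel=1e-8)


def test_rm_anova_comparisons_match_model_contrasts():
    """Each comparison's mean_diff is the treatment-coded time-bin effect;
    on balanced data that is the plain bin-mean difference."""
    df = _balanced_table()
    res = stats.rm_anova(df)
    means = df.groupby("time_bin").gsh_cr.mean()
    for _, row in res.comparisons.iterrows():
        assert row.mean_diff == pytest.approx(
            means[row.time_bin] - means[0], rel=1e-8)


@given(st.lists(st.floats(1e-12, 1.0), min_size=2, max_size=8))
def test_holm_sidak_adjustment_is_monotone_and_bounded(p_raw):
    """Adjusted p-values are >= raw, <= 1, and keep the raw ordering."""
    from statsmodels.stats.multitest import multipletests
    p_raw = np.asarray(p_raw)
    _, p_adj, *_ = multipletests(p_raw, method="holm-sidak")
    assert np.all(p_adj <= 1.0 + 1e-12)
    assert np.all(p_adj >= p_raw - 1e-12)
    order = np.argsort(p_raw)
    assert np.all(np.diff(p_adj[order]) >= -1e-12)


@given(st.integers(0, 2**31 - 1))
def test_imputation_never_alters_detectable_measurements(seed):
    ds = simulate_cohort(seed=seed % 1000, mode="quantified")
    table = quantify_cohort(ds)
    out = stats.impute_undetectable(table)
    ok = table.flag == "ok"
    assert np.array_equal(out.loc[ok, "gsh_cr"], table.loc[ok, "gsh_cr"])
    imputed = out.flag == "imputed"
    assert (table.loc[imputed, "flag"] == "undetectable").all()
    # every imputed baseline receives the same value: lowest measured / 2
    if imputed.any():
        expected = table.loc[ok, "gsh_cr"].min() / 2.0
        assert np.allclose(out.loc[imputed, "gsh_cr"], expected)


def test_imputation_requires_a_detectable_measurement():
    df = pd.DataFrame([dict(subject_id="a", scan_index=0, time_min=0.0,
                            gsh_cr=np.nan, flag="undetectable")])
    with pytest.raises(stats.DataError):
        stats.impute_undetectable(df)


def test_summaries_are_invariant_to_subject_ordering():
    df = _balanced_table(seed=3)
    shuffled = df.sample(frac=1.0, random_state=11).reset_index(drop=True)
    a = stats.summarize(df)
    b = stats.summarize(shuffled)
    pd.testing.assert_frame_equal(a, b)


def test_percent_change_conventions_and_guards():
    df = _balanced_table(seed=4)
    summary = stats.summarize(df)
    ratio = stats.percent_change(summary, "ratio_of_means")
    increase = stats.percent_change(summary, "increase")
    assert increase == pytest.approx(ratio - 100.0)
    with pytest.raises(Exception):
        stats.percent_change(summary, "no_such_convention")
    with pytest.raises(stats.DataError):
        stats.percent_change(summary[summary.time_bin > 0])


def test_rm_anova_complete_cases_drops_partial_subjects():
    df = _balanced_table()
    df = df[~((df.subject_id == "s00") & (df.time_bin == 2))]
    full = stats.rm_anova(df)
    cc = stats.rm_anova(df, complete_cases=True)
    assert cc.df_den < full.df_den
    assert np.isfinite(cc.p_value)


def test_rm_anova_requires_enough_structure():
    df = _balanced_table()
    with pytest.raises(stats.DataError):
        stats.rm_anova(df[df.time_bin == 0])
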