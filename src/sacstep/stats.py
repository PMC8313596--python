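"""Group-level statistics for search-step behavior.

Implements the behavioral analysis plan: a one-tailed pooled-variance
t-test on TSRT between groups (directional, because slower inhibition in
the clinical group is the standing hypothesis), a two-way mixed ANOVA on
condition RT means (trial type within subjects, group between subjects)
with Greenhouse-Geisser sphericity correction and classical eta-squared,
and Spearman rank correlations for covariates.

The mixed ANOVA is computed from sums of squares directly so the report
can carry classical eta-squared (SS_effect / SS_total) and the
GG-corrected degrees of freedom in a single table.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps


class StatsError(ValueError):
    pass


def compare_tsrt_groups(values_a: Sequence[float], values_b: Sequence[float],
                        slower: str = "a") -> tuple[float, int, float]:
    """One-tailed pooled-variance independent t-test on TSRT.

    Returns ``(t, df, p)`` with ``t`` computed for mean(a) − mean(b) and
    the one-tailed p-value for the hypothesis that group ``slower``
    ('a' or 'b') has the longer TSRT.  df = n_a + n_b − 2.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise StatsError("each group needs at least 2 subjects")
    if slower not in ("a", "b"):
        raise StatsError("slower must be 'a' or 'b'")
    alternative = "greater" if slower == "a" else "less"
    res = sps.ttest_ind(a, b, equal_var=True, alternative=alternative)
    return float(res.statistic), int(a.size + b.size - 2), float(res.pvalue)


def compare_tsrt_table(table: pd.DataFrame, slower_label: str,
                       value_col: str = "tsrt_ms",
                       group_col: str = "group") -> dict:
    """Group-table wrapper: hypothesized-slower group vs the other."""
    labels = sorted(table[group_col].unique())
    if len(labels) != 2:
        raise StatsError(f"need exactly 2 groups, found {labels}")
    if slower_label not in labels:
        raise StatsError(f"{slower_label!r} not among groups {labels}")
    other = [l for l in labels if l != slower_label][0]
    a = table.loc[table[group_col] == slower_label, value_col]
    b = table.loc[table[group_col] == other, value_col]
    t, df, p = compare_tsrt_groups(a, b, slower="a")
    return {"t": t, "df": df, "p_one_tailed": p,
            "slower_hypothesis": slower_label, "reference": other,
            "mean_slower": float(a.mean()), "mean_reference": float(b.mean())}


def greenhouse_geisser_epsilon(wide: np.ndarray) -> float:
    """GG epsilon from the subjects × conditions score matrix.

    Computed from the double-centered covariance of the condition scores;
    equals 1 under sphericity and is bounded below by 1/(k−1).
    """
    wide = np.asarray(wide, dtype=float)
    n, k = wide.shape
    if k < 2:
        raise StatsError("need at least 2 within-subject conditions")
    S = np.cov(wide, rowvar=False)
    # double-center
    S_dc = (S - S.mean(axis=0, keepdims=True) - S.mean(axis=1, keepdims=True)
            + S.mean())
    num = np.trace(S_dc) ** 2
    den = (k - 1) * np.sum(S_dc ** 2)
    if den == 0.0:     # degenerate: no condition variance, sphericity holds
        return 1.0
    return float(num / den)


def rt_mixed_anova(long_table: pd.DataFrame, dv: str = "rt_ms",
                   within: str = "condition", subject: str = "subject",
                   between: str = "group") -> pd.DataFrame:
    """Two-way mixed ANOVA (one within, one between factor).

    Expects a long table with one row per subject × condition; subjects
    missing any condition are dropped with a warning.  Returns a table
    with rows for the between-group effect, the within-subject (condition)
    effect and their interaction, carrying F, uncorrected and
    Greenhouse-Geisser-corrected dfs and p-values, epsilon, and classical
    eta-squared (SS_effect / SS_total).
    """
    df = long_table[[subject, between, within, dv]].dropna().copy()
    conditions = sorted(df[within].unique())
    k = len(conditions)
    counts = df.groupby(subject)[within].nunique()
    complete = counts[counts == k].index
    if len(complete) < len(counts):
        import warnings
        warnings.warn(f"dropping {len(counts) - len(complete)} subject(s) "
                      "with missing conditions")
        df = df[df[subject].isin(complete)]
    groups = df.groupby(subject)[between].first()
    labels = sorted(groups.unique())
    a = len(labels)
    n = len(complete)
    if n < a + 1 or a < 1:
        raise StatsError("not enough complete subjects for the mixed ANOVA")

    x = df.pivot_table(index=subject, columns=within, values=dv).loc[complete]
    wide = x.to_numpy(dtype=float)
    grp = groups.loc[complete].to_numpy()

    grand = wide.mean()
    ss_total = float(((wide - grand) ** 2).sum())

    subj_means = wide.mean(axis=1)
    cond_means = wide.mean(axis=0)                      # weighted across subjects
    group_sizes = np.array([(grp == g).sum() for g in labels])
    group_means = np.array([wide[grp == g].mean() for g in labels])
    cell_means = np.array([wide[grp == g].mean(axis=0) for g in labels])  # (a, k)

    ss_between = float(k * (group_sizes * (group_means - grand) ** 2).sum())
    ss_within_factor = float(n * ((cond_means - grand) ** 2).sum())
    # pure error around cell (group × condition) means
    resid = wide - cell_means[np.searchsorted(labels, grp)]
    ss_resall = float((resid ** 2).sum())
    ss_inter = ss_total - ss_resall - ss_within_factor - ss_between
    # split the residual into between-subject and within-subject error
    group_mean_of_subj = np.array(
        [wide[grp == g].mean() for g in labels])[np.searchsorted(labels, grp)]
    ss_res_between = float(k * ((subj_means - group_mean_of_subj) ** 2).sum())
    ss_res_within = ss_resall - ss_res_between

    df_between, df_res_between = a - 1, n - a
    df_within, df_inter = k - 1, (a - 1) * (k - 1)
    df_res_within = (n - a) * (k - 1)

    eps = greenhouse_geisser_epsilon(wide)

    def f_and_p(ss, df1, ss_err, df2):
        if df1 == 0:
            return np.nan, np.nan
        F = (ss / df1) / (ss_err / df2)
        return F, float(sps.f.sf(F, df1, df2))

    F_b, p_b = f_and_p(ss_between, df_between, ss_res_between, df_res_between)
    F_w, p_w = f_and_p(ss_within_factor, df_within, ss_res_within, df_res_within)
    F_i, p_i = f_and_p(ss_inter, df_inter, ss_res_within, df_res_within)

    rows = [
        {"source": between, "SS": ss_between, "df1": df_between,
         "df2": df_res_between, "F": F_b, "p_unc": p_b,
         "eps": np.nan, "df1_gg": df_between, "df2_gg": df_res_between,
         "p_gg": p_b, "eta2": ss_between / ss_total},
        {"source": within, "SS": ss_within_factor, "df1": df_within,
         "df2": df_res_within, "F": F_w, "p_unc": p_w, "eps": eps,
         "df1_gg": eps * df_within, "df2_gg": eps * df_res_within,
         "p_gg": (float(sps.f.sf(F_w, eps * df_within, eps * df_res_within))
                  if np.isfinite(F_w) else np.nan),
         "eta2": ss_within_factor / ss_total},
        {"source": "interaction", "SS": ss_inter, "df1": df_inter,
         "df2": df_res_within, "F": F_i, "p_unc": p_i, "eps": eps,
         "df1_gg": eps * df_inter, "df2_gg": eps * df_res_within,
         "p_gg": (float(sps.f.sf(F_i, eps * df_inter, eps * df_res_within))
                  if np.isfinite(F_i) else np.nan),
         "eta2": ss_inter / ss_total},
    ]
    return pd.DataFrame(rows)


def covariate_correlation(values_a: Sequence[float],
                          values_b: Sequence[float]) -> tuple[float, float]:
    """Spearman rank correlation (midrank ties) with its p-value."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size != b.size:
        raise StatsError("inputs must be paired")
    if a.size < 3:
        raise StatsError("need at least 3 pairs")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise StatsError("Spearman rho undefined for constant input")
    rho, p = sps.spearmanr(a, b)
    return float(rho), float(p)
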