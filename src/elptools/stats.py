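"""Group-statistics layer: two-group tests, mixed repeated-measures ANOVA,
Šidák/Dunnett posthoc adjustment, BH-FDR, and metabolomics-style scalings.

The repeated-measures ANOVA handles the standard behavioral time-course
design: one between-subjects factor (genotype/group) crossed with one
within-subjects factor (time/task/zone), complete and balanced within
subjects (every subject has every within level exactly once; group sizes may
differ).  Sphericity is not corrected; degrees of freedom are uncorrected
and noted in the output table.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ttest_unpaired",
    "mann_whitney",
    "anova2_rm",
    "sidak_adjust",
    "dunnett_adjust",
    "bh_fdr",
    "auto_scale",
    "range_scale",
]


def ttest_unpaired(a, b, welch: bool = False) -> tuple[float, float, float]:
    """Classical two-sided unpaired Student's t-test (pooled variance).

    Returns (t, df, p).  ``welch=True`` switches to the unequal-variance
    variant.  Two degenerate constant groups with equal means give
    (0, df, 1) by convention.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0:
        df = a.size + b.size - 2
        if np.mean(a) == np.mean(b):
            return 0.0, float(df), 1.0
        return float(np.inf) * np.sign(np.mean(a) - np.mean(b)), float(df), 0.0
    res = sps.ttest_ind(a, b, equal_var=not welch)
    return float(res.statistic), float(res.df), float(res.pvalue)


def mann_whitney(a, b) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test.

    Exact null distribution when the combined sample is small (n_a + n_b
    <= 12) and tie-free; otherwise the tie-corrected normal approximation
    with continuity correction.  All-tied data give p = 1.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 1 or b.size < 1:
        raise ValueError("each group needs at least 1 value")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return a.size * b.size / 2.0, 1.0
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (a.size + b.size <= 12 and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def anova2_rm(
    data: pd.DataFrame,
    dv: str = "value",
    subject: str = "subject",
    within: str = "within",
    between: str = "group",
) -> pd.DataFrame:
    """Two-way mixed (split-plot) ANOVA from tidy long-format data.

    Between-subjects factor (e.g. genotype) x within-subjects factor (e.g.
    time), subjects nested in groups.  Requires a complete balanced within
    design: exactly one value per (subject, within level).  Returns the
    ANOVA table with effects ``between``, ``within``, ``interaction`` and
    the two error strata.

    The between effect is tested against subject-within-group variation;
    within and interaction against the residual.  With a single within
    level, the between row reproduces the one-way ANOVA F.
    """
    df = data[[dv, subject, within, between]].dropna()
    counts = df.groupby([subject, within], observed=True).size()
    if (counts != 1).any():
        raise ValueError(
            "design must be complete and balanced: one value per (subject, within level)"
        )
    # subject -> group map must be unique
    gmap = df.groupby(subject, observed=True)[between].nunique()
    if (gmap != 1).any():
        raise ValueError("each subject must belong to exactly one group")
    levels_w = df[within].unique()
    b = levels_w.size
    wide = df.pivot_table(index=subject, columns=within, values=dv, observed=True)
    if wide.isna().any().any():
        raise ValueError("missing cells: every subject needs every within level")
    groups = df.drop_duplicates(subject).set_index(subject)[between]
    groups = groups.loc[wide.index]
    a = groups.nunique()
    n_total = wide.shape[0]
    grand = float(wide.values.mean())

    subj_means = wide.values.mean(axis=1)
    group_means = {g: wide.values[groups.values == g].mean() for g in groups.unique()}
    level_means = wide.values.mean(axis=0)

    n_g = {g: int((groups.values == g).sum()) for g in groups.unique()}
    ss_a = b * sum(n_g[g] * (group_means[g] - grand) ** 2 for g in n_g)
    ss_subj = b * float(np.sum((subj_means - grand) ** 2))
    ss_subj_within = ss_subj - ss_a
    ss_b = n_total * float(np.sum((level_means - grand) ** 2))
    ss_ab = 0.0
    for g in n_g:
        cell = wide.values[groups.values == g].mean(axis=0)
        ss_ab += n_g[g] * float(
            np.sum((cell - group_means[g] - level_means + grand) ** 2)
        )
    ss_total = float(np.sum((wide.values - grand) ** 2))
    ss_err = ss_total - ss_subj - ss_b - ss_ab

    df_a = a - 1
    df_subj = n_total - a
    df_b = b - 1
    df_ab = (a - 1) * (b - 1)
    df_err = (n_total - a) * (b - 1)

    def _row(name, ss, dfree, ms_err, df_err_):
        if dfree <= 0 or ms_err is None or df_err_ <= 0:
            return {"effect": name, "SS": ss, "df": max(dfree, 0), "MS": np.nan,
                    "F": np.nan, "p": np.nan}
        ms = ss / dfree
        if ms_err > 0:
            f = ms / ms_err
            p = float(sps.f.sf(f, dfree, df_err_))
        elif ms == 0:  # degenerate all-equal data: no effect by convention
            f, p = 0.0, 1.0
        else:
            f, p = np.inf, 0.0
        return {"effect": name, "SS": ss, "df": dfree, "MS": ms, "F": f, "p": p}

    ms_subj = ss_subj_within / df_subj if df_subj > 0 else None
    ms_err = ss_err / df_err if df_err > 0 else None
    table = pd.DataFrame(
        [
            _row("between", ss_a, df_a, ms_subj, df_subj),
            {
                "effect": "subject(between)",
                "SS": ss_subj_within,
                "df": df_subj,
                "MS": ms_subj if ms_subj is not None else np.nan,
                "F": np.nan,
                "p": np.nan,
            },
            _row("within", ss_b, df_b, ms_err, df_err),
            _row("interaction", ss_ab, df_ab, ms_err, df_err),
            {
                "effect": "error(within)",
                "SS": ss_err,
                "df": max(df_err, 0),
                "MS": ms_err if ms_err is not None else np.nan,
                "F": np.nan,
                "p": np.nan,
            },
        ]
    )
    table.attrs["sphericity_correction"] = "none (uncorrected df)"
    return table


def sidak_adjust(p_values, m: int | None = None) -> np.ndarray:
    """Šidák familywise adjustment: p_adj = 1 - (1 - p)^m, capped at 1."""
    p = np.atleast_1d(np.asarray(p_values, dtype=float))
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if m is None:
        m = p.size
    if m < 1:
        raise ValueError("m must be >= 1")
    # the outer maximum guards float round-off: adjustment never reduces p
    return np.minimum(np.maximum(1.0 - (1.0 - p) ** m, p), 1.0)


def dunnett_adjust(
    control,
    treatments: list,
    n_mc: int = 100_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Many-to-one (Dunnett) comparisons against a shared control group.

    Each treatment mean is compared with the control mean using the pooled
    within-group variance; the familywise-adjusted p-value is
    P(max_j |T_j| >= |t_obs|) under the joint multivariate-t null with the
    correlation structure induced by the shared control, evaluated by seeded
    Monte Carlo (``n_mc`` draws).  Returns raw p, adjusted p and the Monte
    Carlo standard error per comparison.
    """
    if len(treatments) < 1:
        raise ValueError("need at least one treatment group")
    control = np.asarray(control, dtype=float)
    groups = [np.asarray(t, dtype=float) for t in treatments]
    k = len(groups)
    all_groups = [control] + groups
    n = np.array([g.size for g in all_groups])
    if np.any(n < 2):
        raise ValueError("each group needs at least 2 values")
    big_n = int(n.sum())
    df = big_n - (k + 1)
    sse = sum(float(np.sum((g - g.mean()) ** 2)) for g in all_groups)
    ms_err = sse / df
    t_obs = np.array(
        [
            (g.mean() - control.mean()) / np.sqrt(ms_err * (1 / g.size + 1 / control.size))
            for g in groups
        ]
    )
    # T_j = (Z_j - lam_j Z_0-correlated normal) / sqrt(chi2_df / df) with
    # lam_j = sqrt(n_j / (n_j + n_0)) giving corr(T_i, T_j) = lam_i lam_j.
    lam = np.sqrt(n[1:] / (n[1:] + n[0]))
    rng = np.random.default_rng(seed)
    z0 = rng.standard_normal(n_mc)
    z = rng.standard_normal((n_mc, k))
    w = rng.chisquare(df, n_mc) / df
    t_null = (lam[None, :] * z0[:, None] + np.sqrt(1 - lam**2)[None, :] * z) / np.sqrt(
        w
    )[:, None]
    max_abs = np.max(np.abs(t_null), axis=1)
    adj = np.array([float(np.mean(max_abs >= abs(t))) for t in t_obs])
    raw = 2.0 * sps.t.sf(np.abs(t_obs), df)
    adj = np.maximum(adj, raw)  # multiplicity never reduces the p-value
    mc_se = np.sqrt(adj * (1 - adj) / n_mc)
    return pd.DataFrame(
        {
            "comparison": [f"treatment_{j + 1} - control" for j in range(k)],
            "t": t_obs,
            "df": df,
            "raw_p": raw,
            "adjusted_p": np.minimum(adj, 1.0),
            "mc_se": mc_se,
            "method": "dunnett",
        }
    )


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (monotone-enforced)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _column_scale(table: pd.DataFrame, fn) -> pd.DataFrame:
    out = table.copy().astype(float)
    for col in out.columns:
        x = out[col].to_numpy(dtype=float)
        if np.nanmax(x) == np.nanmin(x):
            out[col] = np.nan  # constant column: flagged by NaN
            continue
        out[col] = fn(x)
    return out


def auto_scale(table: pd.DataFrame) -> pd.DataFrame:
    """Per-column (x - mean)/SD; constant columns are left missing."""
    return _column_scale(table, lambda x: (x - np.nanmean(x)) / np.nanstd(x, ddof=1))


def range_scale(table: pd.DataFrame) -> pd.DataFrame:
    """Per-column (x - mean)/(max - min); constant columns are left missing."""
    return _column_scale(
        table, lambda x: (x - np.nanmean(x)) / (np.nanmax(x) - np.nanmin(x))
    )
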