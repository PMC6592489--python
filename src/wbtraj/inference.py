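"""Descriptive statistics for interpreting trajectory clusters
(pipeline Step 3).

Covers the 4 (timepoint) x 4 (cluster) mixed factorial ANOVA with the
univariate split-plot decomposition (uncorrected F degrees of freedom),
Bonferroni-corrected pairwise post-hocs, the cross-sample two-way ANOVA
on pooled assessment epochs with Type-3 sums of squares, product-moment
correlations with Fisher-z intervals, and Welch/chi-square comparisons
of included versus excluded participants.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

import statsmodels.api as sm
import statsmodels.formula.api as smf

from .cohort import Cohort, ConfigError

__all__ = [
    "AnovaTable",
    "PosthocTable",
    "CorrResult",
    "ComparisonReport",
    "mixed_anova_4x4",
    "posthoc_pairwise",
    "cross_sample_anova",
    "pearson_corr",
    "attrition_compare",
    "retention_percentage",
]


@dataclass
class AnovaTable:
    """Per-effect SS, df, F, p and eta-squared (SS_effect / SS_total)."""

    table: pd.DataFrame  # columns: effect, ss, df, F, p, eta_sq
    ss_type: int
    design: str
    ss_total: float

    def row(self, effect: str) -> pd.Series:
        match = self.table[self.table["effect"] == effect]
        if not len(match):
            raise KeyError(effect)
        return match.iloc[0]


@dataclass
class PosthocTable:
    """Pairwise comparisons with Bonferroni adjustment
    (adjusted p = min(1, raw p * family size))."""

    table: pd.DataFrame  # pair, timepoint, mean_diff, t, p_raw, p_adj, significant
    family_size: int


@dataclass
class CorrResult:
    r: float
    ci_low: float
    ci_high: float
    p: float
    n: int


@dataclass
class ComparisonReport:
    """Included-vs-excluded baseline comparison: per-outcome Welch t and
    the retention x sample chi-square."""

    outcomes: pd.DataFrame  # outcome, mean_incl, sd_incl, n_incl, mean_excl, sd_excl, n_excl, t, df, p
    chi2: float
    chi2_df: int
    chi2_p: float
    contingency: pd.DataFrame


def _f_p(ss_effect: float, df_effect: float, ss_err: float, df_err: float) -> tuple[float, float]:
    """F and p with the degenerate-variance rule: a zero-SS effect (or a
    zero error term under a zero effect) reports F=0, p=1 instead of NaN."""
    ms_err = ss_err / df_err if df_err > 0 else 0.0
    if ss_effect <= 1e-12:
        return 0.0, 1.0
    if ms_err <= 1e-12:
        return float("inf"), 0.0
    F = (ss_effect / df_effect) / ms_err
    return float(F), float(stats.f.sf(F, df_effect, df_err))


def mixed_anova_4x4(
    view: pd.DataFrame,
    labels: Mapping[str, str | int],
    timepoints: Sequence[int],
    outcome: str = "ls",
) -> AnovaTable:
    """Mixed factorial ANOVA: timepoint (within) x cluster (between).

    ``view`` is a long-format complete-case table (participant_id, day,
    outcome column); participants missing any of the ``timepoints`` are
    dropped for this analysis only (pairwise deletion).  The univariate
    split-plot decomposition is used without sphericity correction, so
    the reported dfs match (T-1, (N-G)(T-1)) for the within effects and
    (G-1, N-G) for the between effect.
    """
    timepoints = sorted(int(t) for t in timepoints)
    T = len(timepoints)
    df = view[view["day"].isin(timepoints)].dropna(subset=[outcome]).copy()
    df["cluster"] = df["participant_id"].map(labels)
    df = df.dropna(subset=["cluster"])
    counts = df.groupby("participant_id")["day"].nunique()
    complete = counts[counts == T].index
    df = df[df["participant_id"].isin(complete)]
    if not len(df):
        raise ConfigError("no complete-case participants for the mixed ANOVA")
    sizes = df.groupby("cluster")["participant_id"].nunique()
    if (sizes < 2).any():
        small = sizes[sizes < 2].index.tolist()
        raise ConfigError(f"cluster(s) {small} have fewer than 2 complete participants")

    wide = df.pivot(index="participant_id", columns="day", values=outcome)
    cluster_of = df.drop_duplicates("participant_id").set_index("participant_id")["cluster"]
    groups = cluster_of.loc[wide.index]
    y = wide.to_numpy(dtype=float)
    N = y.shape[0]
    G = groups.nunique()
    M = y.mean()
    subj_means = y.mean(axis=1)
    grp_means = pd.Series(subj_means, index=wide.index).groupby(groups).mean()
    time_means = y.mean(axis=0)
    cell_means = (
        pd.DataFrame(y, index=wide.index).groupby(groups.to_numpy()).mean()
    )  # G x T

    ss_total = float(((y - M) ** 2).sum())
    n_g = groups.value_counts()
    ss_cluster = float(T * (n_g * (grp_means - M) ** 2).sum())
    ss_subj_err = float(
        T * ((subj_means - grp_means.loc[groups].to_numpy()) ** 2).sum()
    )
    ss_time = float(N * ((time_means - M) ** 2).sum())
    inter_dev = (
        cell_means.to_numpy()
        - grp_means.loc[cell_means.index].to_numpy()[:, None]
        - time_means[None, :]
        + M
    )
    ss_inter = float((n_g.loc[cell_means.index].to_numpy()[:, None] * inter_dev**2).sum())
    ss_err = ss_total - ss_cluster - ss_subj_err - ss_time - ss_inter
    ss_err = max(ss_err, 0.0)

    df_cluster, df_subj = G - 1, N - G
    df_time = T - 1
    df_inter = (G - 1) * (T - 1)
    df_err = (N - G) * (T - 1)

    rows = []
    for effect, ss, dfe, ss_den, df_den in (
        ("cluster", ss_cluster, df_cluster, ss_subj_err, df_subj),
        ("timepoint", ss_time, df_time, ss_err, df_err),
        ("timepoint:cluster", ss_inter, df_inter, ss_err, df_err),
    ):
        F, p = _f_p(ss, dfe, ss_den, df_den)
        rows.append(
            {
                "effect": effect,
                "ss": ss,
                "df": dfe,
                "df_error": df_den,
                "F": F,
                "p": p,
                "eta_sq": ss / ss_total if ss_total > 0 else 0.0,
            }
        )
    rows.append(
        {"effect": "subjects(cluster)", "ss": ss_subj_err, "df": df_subj,
         "df_error": np.nan, "F": np.nan, "p": np.nan,
         "eta_sq": ss_subj_err / ss_total if ss_total > 0 else 0.0}
    )
    rows.append(
        {"effect": "error", "ss": ss_err, "df": df_err, "df_error": np.nan,
         "F": np.nan, "p": np.nan,
         "eta_sq": ss_err / ss_total if ss_total > 0 else 0.0}
    )
    return AnovaTable(
        table=pd.DataFrame(rows),
        ss_type=1,
        design="split-plot: timepoint within, cluster between",
        ss_total=ss_total,
    )


def posthoc_pairwise(
    view: pd.DataFrame,
    labels: Mapping[str, str | int],
    timepoint: int,
    family_size: int | None = None,
    outcome: str = "ls",
) -> PosthocTable:
    """All pairwise two-sample t tests between clusters at one timepoint,
    Bonferroni-adjusted.

    ``family_size`` defaults to the number of pairs at this timepoint;
    the pipeline passes pairs x timepoints for the full within-sample
    family.  Groups with fewer than 2 observations are skipped with a
    warning row.
    """
    df = view[view["day"] == timepoint].dropna(subset=[outcome]).copy()
    df["cluster"] = df["participant_id"].map(labels)
    df = df.dropna(subset=["cluster"])
    clusters = sorted(df["cluster"].unique(), key=str)
    if len(clusters) < 2:
        raise ConfigError("need at least 2 groups for pairwise comparisons")
    pairs = [(a, b) for i, a in enumerate(clusters) for b in clusters[i + 1:]]
    m = family_size if family_size is not None else len(pairs)
    rows = []
    for a, b in pairs:
        xa = df.loc[df["cluster"] == a, outcome].to_numpy()
        xb = df.loc[df["cluster"] == b, outcome].to_numpy()
        if len(xa) < 2 or len(xb) < 2:
            rows.append({"pair": f"{a} vs {b}", "timepoint": timepoint,
                         "mean_diff": np.nan, "t": np.nan, "p_raw": np.nan,
                         "p_adj": np.nan, "significant": False,
                         "note": "group smaller than 2; skipped"})
            continue
        if np.var(xa, ddof=1) + np.var(xb, ddof=1) <= 1e-12:
            t, p = 0.0, 1.0
        else:
            t, p = stats.ttest_ind(xa, xb, equal_var=True)
        p_adj = min(1.0, float(p) * m)
        rows.append({"pair": f"{a} vs {b}", "timepoint": timepoint,
                     "mean_diff": float(xa.mean() - xb.mean()),
                     "t": float(t), "p_raw": float(p), "p_adj": p_adj,
                     "significant": p_adj < 0.05, "note": ""})
    return PosthocTable(table=pd.DataFrame(rows), family_size=m)


def cross_sample_anova(
    view: pd.DataFrame,
    labels: Mapping[str, str | int],
    outcome: str = "ls",
) -> AnovaTable:
    """Two-way between-groups ANOVA (cluster, sample, cluster x sample)
    with Type-3 sums of squares on observations pooled within an epoch.

    ``view`` must carry participant_id, sample_id and the outcome; the
    caller pools the epoch's days beforehand.  Effect-coded (sum)
    contrasts make the Type-3 decomposition well defined.
    """
    df = view.dropna(subset=[outcome]).copy()
    df["cluster"] = df["participant_id"].map(labels).astype(str)
    df = df[df["cluster"] != "nan"]
    cell = df.groupby(["cluster", "sample_id"])[outcome].size().unstack(fill_value=0)
    empty = [(c, s) for c in cell.index for s in cell.columns if cell.loc[c, s] == 0]
    if empty:
        raise ConfigError(f"empty cluster x sample cell(s): {empty}")
    df = df.rename(columns={outcome: "y", "sample_id": "sample"})
    model = smf.ols("y ~ C(cluster, Sum) * C(sample, Sum)", data=df).fit()
    aov = sm.stats.anova_lm(model, typ=3)
    ss_total = float(((df["y"] - df["y"].mean()) ** 2).sum())
    rename = {
        "C(cluster, Sum)": "cluster",
        "C(sample, Sum)": "sample",
        "C(cluster, Sum):C(sample, Sum)": "cluster:sample",
        "Residual": "error",
    }
    rows = []
    for idx, r in aov.iterrows():
        if idx == "Intercept":
            continue
        effect = rename.get(str(idx), str(idx))
        ss = float(r["sum_sq"])
        dfe = float(r["df"])
        if effect == "error":
            F, p = np.nan, np.nan
        elif ss <= 1e-12:
            F, p = 0.0, 1.0
        else:
            F, p = float(r["F"]), float(r["PR(>F)"])
        rows.append({"effect": effect, "ss": ss, "df": dfe,
                     "df_error": float(aov.loc["Residual", "df"]),
                     "F": F, "p": p,
                     "eta_sq": ss / ss_total if ss_total > 0 else 0.0})
    return AnovaTable(
        table=pd.DataFrame(rows),
        ss_type=3,
        design="between-groups: cluster x sample, pooled epoch observations",
        ss_total=ss_total,
    )


def pearson_corr(x, y) -> CorrResult:
    """Product-moment correlation with a Fisher-z 95% CI, after pairwise
    deletion of incomplete pairs."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    n = len(x)
    if n < 3:
        raise ConfigError(f"need at least 3 complete pairs, got {n}")
    if np.var(x) <= 0 or np.var(y) <= 0:
        raise ConfigError("zero variance input to correlation")
    r, p = stats.pearsonr(x, y)
    with np.errstate(divide="ignore"):
        z = np.arctanh(min(1.0, max(-1.0, r)))
        se = 1.0 / np.sqrt(n - 3) if n > 3 else np.inf
        lo = np.tanh(z - 1.959963984540054 * se)
        hi = np.tanh(z + 1.959963984540054 * se)
    return CorrResult(r=float(r), ci_low=float(lo), ci_high=float(hi), p=float(p), n=n)


def retention_percentage(n_included: int, n_total: int) -> float:
    """Percentage of a sample retained by the inclusion rule."""
    if n_total <= 0 or not 0 <= n_included <= n_total:
        raise ConfigError("need 0 <= n_included <= n_total with n_total > 0")
    return 100.0 * n_included / n_total


def attrition_compare(
    cohort: Cohort,
    included: Iterable[str],
    excluded: Iterable[str],
    day: int = 0,
) -> ComparisonReport:
    """Compare included vs excluded participants at baseline.

    Welch two-sample t per outcome (LS, AB, CES-D) on the ``day``
    records, plus a chi-square test of independence on the retention x
    sample contingency table.
    """
    included, excluded = set(included), set(excluded)
    if not included or not excluded:
        raise ConfigError("both included and excluded sets must be non-empty")
    base = cohort.assessments[cohort.assessments["day"] == day]
    rows = []
    for outcome in ("ls", "ab", "cesd"):
        xi = base.loc[base["participant_id"].isin(included), outcome].dropna().to_numpy()
        xe = base.loc[base["participant_id"].isin(excluded), outcome].dropna().to_numpy()
        if len(xi) < 2 or len(xe) < 2:
            raise ConfigError(f"group smaller than 2 for outcome {outcome}")
        vi, ve = np.var(xi, ddof=1), np.var(xe, ddof=1)
        if vi <= 0 or ve <= 0:
            raise ConfigError(f"zero-variance group for outcome {outcome}")
        t, p = stats.ttest_ind(xi, xe, equal_var=False)
        # Welch-Satterthwaite df
        num = (vi / len(xi) + ve / len(xe)) ** 2
        den = (vi / len(xi)) ** 2 / (len(xi) - 1) + (ve / len(xe)) ** 2 / (len(xe) - 1)
        rows.append({"outcome": outcome,
                     "mean_incl": xi.mean(), "sd_incl": xi.std(ddof=1), "n_incl": len(xi),
                     "mean_excl": xe.mean(), "sd_excl": xe.std(ddof=1), "n_excl": len(xe),
                     "t": float(t), "df": float(num / den), "p": float(p)})
    samples = cohort.sample_of()
    status = pd.Series(
        ["included" if p in included else "excluded" for p in samples.index],
        index=samples.index,
    )
    contingency = pd.crosstab(status, samples)
    chi2, chi2_p, chi2_df, _ = stats.chi2_contingency(contingency, correction=False)
    return ComparisonReport(
        outcomes=pd.DataFrame(rows),
        chi2=float(chi2),
        chi2_df=int(chi2_df),
        chi2_p=float(chi2_p),
        contingency=contingency,
    )
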