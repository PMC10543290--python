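"""Group statistics: 2-SD inclusion filter, Student's t, two-way ANOVA, post hocs.

The layer is generic over any long-form metric table with columns
``(id, group_label, [factor], metric, value)`` produced upstream.  Outlier
screening follows the common animal-behaviour convention: values within two
standard deviations of their group mean are included, applied in a single
pass (mean and SD computed once on the full group, no re-iteration).
Between-genotype single-parameter comparisons use the pooled-variance
two-tailed Student's t (groups here have similar variances by construction);
factorial designs use a two-way ANOVA — plain OLS for fully between-subject
designs, or a mixed (split-plot) ANOVA when the second factor is repeated
within subject.  Post hoc adjustments: Sidak, Holm-Sidak (step-down) and
Bonferroni (Dunn's) correction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sst

from .errors import ValidationError

__all__ = [
    "ComparisonResult",
    "filter_2sd",
    "t_test",
    "two_way_anova",
    "posthoc",
]


@dataclass
class ComparisonResult:
    test: str
    statistic: float
    df: float | tuple
    p_value: float
    adjusted_p: float | None = None
    direction: str = ""  # e.g. "A>B", "A<B", ""

    def as_dict(self) -> dict:
        return {
            "test": self.test,
            "statistic": self.statistic,
            "df": str(self.df),
            "p_value": self.p_value,
            "adjusted_p": self.adjusted_p,
            "direction": self.direction,
        }


def filter_2sd(values) -> tuple[np.ndarray, pd.DataFrame]:
    """Single-pass 2-SD inclusion filter for one group of values.

    Mean and SD (ddof=1) are computed on the full group; values ``v`` with
    ``|v - mean| <= 2 SD`` are retained.  Returns (retained values, exclusion
    log with one row per excluded value).  Groups with n < 3 are passed
    through unfiltered with a warning — the filter is meaningless there.
    """
    values = np.asarray(values, dtype=float)
    log_cols = ["index", "value", "group_mean", "group_sd", "bound"]
    if len(values) < 3:
        warnings.warn("filter_2sd skipped: group has fewer than 3 values")
        return values, pd.DataFrame(columns=log_cols)
    mean = values.mean()
    sd = values.std(ddof=1)
    keep = np.abs(values - mean) <= 2 * sd
    excluded = pd.DataFrame(
        {
            "index": np.flatnonzero(~keep),
            "value": values[~keep],
            "group_mean": mean,
            "group_sd": sd,
            "bound": 2 * sd,
        },
        columns=log_cols,
    )
    return values[keep], excluded


def t_test(group_a, group_b, labels: tuple[str, str] = ("A", "B")) -> ComparisonResult:
    """Two-sample two-tailed pooled-variance Student's t-test.

    Degenerate case: zero pooled variance gives p = 1 when the means are
    equal (no evidence of difference) and p = 0 when they differ (the
    separation is infinitely many pooled-SD units).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValidationError("each group needs at least 2 values")
    df = len(a) + len(b) - 2
    direction = (
        f"{labels[0]}>{labels[1]}" if a.mean() > b.mean()
        else f"{labels[0]}<{labels[1]}" if a.mean() < b.mean()
        else ""
    )
    pooled_var = ((len(a) - 1) * a.var(ddof=1) + (len(b) - 1) * b.var(ddof=1)) / df
    if pooled_var == 0:
        if a.mean() == b.mean():
            return ComparisonResult("student_t", 0.0, df, 1.0, direction="")
        warnings.warn("zero pooled variance with unequal means: p -> 0 limit")
        stat = np.inf if a.mean() > b.mean() else -np.inf
        return ComparisonResult("student_t", stat, df, 0.0, direction=direction)
    stat, p = sst.ttest_ind(a, b, equal_var=True)
    return ComparisonResult("student_t", float(stat), df, float(p), direction=direction)


def two_way_anova(
    table: pd.DataFrame,
    value: str = "value",
    between: str = "group_label",
    within: str = "div",
    subject: str | None = None,
    repeated: bool = False,
) -> pd.DataFrame:
    """Two-factor ANOVA on a long-form table.

    ``repeated=False``: ordinary two-way OLS ANOVA (type II sums of squares)
    with both factors between-subject.  ``repeated=True``: mixed (split-plot)
    ANOVA with ``between`` as the between-subject factor and ``within``
    repeated within each ``subject``; subjects missing any within level are
    dropped (complete-case) with a warning.

    Returns one row per effect (between, within, interaction) with columns
    ``effect, F, df1, df2, p_value``.
    """
    df = table.dropna(subset=[value]).copy()
    if df.empty:
        raise ValidationError("no data for ANOVA")

    if repeated:
        if subject is None:
            raise ValidationError("repeated-measures ANOVA requires a subject column")
        import pingouin as pg

        n_levels = df[within].nunique()
        complete = df.groupby(subject)[within].nunique()
        keep = complete[complete == n_levels].index
        dropped = set(df[subject]) - set(keep)
        if dropped:
            warnings.warn(
                f"dropping {len(dropped)} subject(s) missing within-factor levels: "
                f"{sorted(map(str, dropped))}"
            )
            df = df[df[subject].isin(keep)]
        aov = pg.mixed_anova(
            data=df, dv=value, within=within, between=between, subject=subject
        )
        p_col = "p_unc" if "p_unc" in aov.columns else "p-unc"
        out = pd.DataFrame(
            {
                "effect": aov["Source"].replace({"Interaction": f"{between}:{within}"}),
                "F": aov["F"],
                "df1": aov["DF1"],
                "df2": aov["DF2"],
                "p_value": aov[p_col],
            }
        )
        return out.reset_index(drop=True)

    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    d = df.rename(columns={value: "_y", between: "_a", within: "_b"})
    if d["_b"].nunique() == 1:
        model = smf.ols("_y ~ C(_a)", data=d).fit()
        terms = {"C(_a)": between}
    else:
        model = smf.ols("_y ~ C(_a) * C(_b)", data=d).fit()
        terms = {
            "C(_a)": between,
            "C(_b)": within,
            "C(_a):C(_b)": f"{between}:{within}",
        }
    aov = sm.stats.anova_lm(model, typ=2)
    rows = []
    resid_df = aov.loc["Residual", "df"]
    for term, name in terms.items():
        rows.append(
            {
                "effect": name,
                "F": float(aov.loc[term, "F"]),
                "df1": float(aov.loc[term, "df"]),
                "df2": float(resid_df),
                "p_value": float(aov.loc[term, "PR(>F)"]),
            }
        )
    return pd.DataFrame(rows)


def posthoc(p_values, method: str = "sidak") -> np.ndarray:
    """Multiplicity adjustment for a family of pairwise raw p-values.

    sidak: 1 - (1-p)^m; bonferroni_dunn: min(1, m p); holm_sidak: step-down
    Sidak with enforced monotonicity.  Adjusted values never fall below raw.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or len(p) == 0:
        raise ValidationError("p_values must be a non-empty 1-D sequence")
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    m = len(p)
    if method == "sidak":
        return 1.0 - (1.0 - p) ** m
    if method == "bonferroni_dunn":
        return np.minimum(1.0, m * p)
    if method == "holm_sidak":
        order = np.argsort(p)
        adj_sorted = 1.0 - (1.0 - p[order]) ** (m - np.arange(m))
        adj_sorted = np.maximum.accumulate(adj_sorted)
        out = np.empty(m)
        out[order] = np.minimum(adj_sorted, 1.0)
        return out
    raise ValidationError(
        f"unknown method {method!r}; expected sidak, holm_sidak or bonferroni_dunn"
    )
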