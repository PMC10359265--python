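"""Cohort statistics: binning, group summaries, growth regression, two-way
ANOVA and per-category sex comparisons.

The analysis mirrors a typical paediatric morphometry workflow: each
measurement is regressed on the raw (unbinned) age or height covariate;
a two-way ANOVA with interaction tests the influence of the binned
covariate and sex (Type II sums of squares, appropriate for the strongly
unbalanced cohorts such data come from); and within each age/height
category the sexes are compared with two-sided Welch t-tests at an
uncorrected alpha (multiple testing across categories is a documented
caveat, not corrected away).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

AGE_CATEGORIES = tuple(range(4, 19))
HEIGHT_BIN_EDGES = np.arange(95, 200, 5)  # bins [95,100), ..., [190,195)


class BinningError(ValueError):
    """Covariate values outside the supported binning range."""


@dataclass(frozen=True)
class RegressionResult:
    """Ordinary least squares of one measurement on one covariate."""

    slope: float
    intercept: float
    R: float         # signed Pearson correlation
    p_value: float   # two-sided, from t = R sqrt((n-2)/(1-R^2)) on n-2 df
    n: int


@dataclass(frozen=True)
class SexComparison:
    """Welch t-test of female vs male values within one category."""

    category: int
    n_f: int
    n_m: int
    mean_f: float
    mean_m: float
    p_value: float   # NaN when either group has < 2 observations


@dataclass
class AnovaResult:
    """Two-way ANOVA (factor x sex, with interaction, Type II SS) plus the
    per-category sex comparisons."""

    effects: dict[str, dict[str, float]]   # name -> {ss, df, F, p}
    sex_comparisons: list[SexComparison] = field(default_factory=list)
    reduced_model: bool = False            # True if interaction was dropped


def assign_bins(table: pd.DataFrame, axis: str) -> pd.DataFrame:
    """Return a copy of the table with a ``<axis>_category`` column.

    Ages map to integer-year categories 4..18; heights to 5-cm bins
    [x, x+5) labelled by the lower bound 95, 100, ..., 190.
    """
    df = table.copy()
    if axis == "age":
        vals = df["age_years"].to_numpy()
        bad = (~np.isfinite(np.asarray(vals, float))
               | (np.asarray(vals, float) % 1 != 0)
               | (vals < 4) | (vals > 18))
        if bad.any():
            raise BinningError(
                f"age values outside integer years 4..18: {sorted(set(np.asarray(vals)[bad]))}")
        df["age_category"] = np.asarray(vals, int)
    elif axis == "height":
        vals = np.asarray(df["height_cm"].to_numpy(), float)
        bad = ~np.isfinite(vals) | (vals < 95) | (vals >= 195)
        if bad.any():
            raise BinningError(
                f"height values outside [95, 195): {sorted(set(np.round(vals[bad], 1)))}")
        df["height_category"] = (95 + 5 * ((vals - 95) // 5)).astype(int)
    else:
        raise ValueError(f"axis must be 'age' or 'height', got {axis!r}")
    return df


def group_summary(table: pd.DataFrame, measurement: str, category_col: str,
                  by_sex: bool = True) -> pd.DataFrame:
    """Per-cell n, arithmetic mean and sample SD (n-1 denominator).

    Cells with a single observation report SD as NaN (undefined); empty
    cells are omitted with a warning.
    """
    df = table[table[measurement].notna()]
    keys = [category_col, "sex"] if by_sex else [category_col]
    if df.empty:
        warnings.warn(f"group_summary: no data for {measurement!r}")
        return pd.DataFrame(columns=keys + ["n", "mean", "sd"])
    g = df.groupby(keys, observed=True)[measurement]
    out = g.agg(n="count", mean="mean", sd=lambda v: v.std(ddof=1)).reset_index()
    out.loc[out["n"] < 2, "sd"] = np.nan
    return out


def fit_growth_regression(table: pd.DataFrame, measurement: str,
                          covariate: str) -> RegressionResult:
    """OLS of a measurement on the raw age or height covariate.

    R is the signed Pearson correlation; the p-value is the two-sided test
    of zero slope (equivalently zero correlation) on n-2 df.
    """
    col = {"age": "age_years", "height": "height_cm"}.get(covariate, covariate)
    df = table[[col, measurement]].dropna()
    if len(df) < 3:
        raise ValueError(f"regression needs n >= 3, got {len(df)}")
    x = df[col].to_numpy(float)
    y = df[measurement].to_numpy(float)
    if np.var(x) == 0:
        raise ValueError("covariate has zero variance")
    res = sps.linregress(x, y)
    return RegressionResult(slope=float(res.slope), intercept=float(res.intercept),
                            R=float(res.rvalue), p_value=float(res.pvalue),
                            n=len(df))


def per_category_sex_tests(table: pd.DataFrame, measurement: str,
                           category_col: str) -> list[SexComparison]:
    """Two-sided Welch t-tests of female vs male within each category."""
    df = table[table[measurement].notna()]
    out = []
    for cat in sorted(df[category_col].unique()):
        sub = df[df[category_col] == cat]
        f = sub.loc[sub["sex"] == "F", measurement].to_numpy(float)
        m = sub.loc[sub["sex"] == "M", measurement].to_numpy(float)
        if len(f) >= 2 and len(m) >= 2:
            p = float(sps.ttest_ind(f, m, equal_var=False).pvalue)
        else:
            p = np.nan
        out.append(SexComparison(
            category=int(cat), n_f=len(f), n_m=len(m),
            mean_f=float(f.mean()) if len(f) else np.nan,
            mean_m=float(m.mean()) if len(m) else np.nan,
            p_value=p))
    return out


def two_way_anova(table: pd.DataFrame, measurement: str,
                  category_col: str) -> AnovaResult:
    """Two-way ANOVA of a measurement on a binned covariate and sex.

    Fits the linear model ``value ~ C(category) * C(sex)`` and reports Type
    II sums of squares (robust to the unbalanced cell counts of
    observational cohorts). When empty cells make the interaction
    inestimable the additive model is fitted instead, with a warning. The
    per-category sex comparisons (Welch t-tests) are attached to the result.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    df = table[table[measurement].notna()][[category_col, "sex", measurement]].copy()
    df = df.rename(columns={measurement: "value", category_col: "category"})
    for col in ("category", "sex"):
        if df[col].nunique() < 2:
            raise ValueError(f"factor {col!r} has fewer than 2 levels")

    cells = df.groupby(["category", "sex"], observed=True).size()
    full_rank = (len(cells) == df["category"].nunique() * 2
                 and (cells > 0).all())
    formula = "value ~ C(category) * C(sex)"
    reduced = False
    if not full_rank:
        warnings.warn("empty cells: interaction dropped (additive model)")
        formula = "value ~ C(category) + C(sex)"
        reduced = True
    model = smf.ols(formula, data=df).fit()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        tab = sm.stats.anova_lm(model, typ=2)

    def row(name):
        r = tab.loc[name]
        return {"ss": float(r["sum_sq"]), "df": float(r["df"]),
                "F": float(r["F"]), "p": float(r["PR(>F)"])}

    effects = {"category": row("C(category)"), "sex": row("C(sex)")}
    if not reduced:
        effects["interaction"] = row("C(category):C(sex)")
    effects["residual"] = {"ss": float(tab.loc["Residual", "sum_sq"]),
                           "df": float(tab.loc["Residual", "df"]),
                           "F": np.nan, "p": np.nan}
    comparisons = per_category_sex_tests(
        table[table[measurement].notna()], measurement, category_col)
    return AnovaResult(effects=effects, sex_comparisons=comparisons,
                       reduced_model=reduced)


def sex_divergence_age(comparisons: list[SexComparison],
                       alpha: float = 0.05):
    """Earliest category from which the sexes stay separated.

    Returns ``(category, mask)`` where ``mask`` maps each category with a
    defined p-value to its significance at ``alpha`` (no smoothing), and
    ``category`` is the first category of the maximal suffix in which every
    defined comparison is significant — i.e. the onset of a sex difference
    that persists through the oldest/tallest category. ``None`` when no such
    suffix exists.
    """
    defined = [c for c in comparisons if np.isfinite(c.p_value)]
    mask = {c.category: bool(c.p_value < alpha) for c in defined}
    onset = None
    for c in sorted(defined, key=lambda c: c.category, reverse=True):
        if mask[c.category]:
            onset = c.category
        else:
            break
    return onset, mask
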