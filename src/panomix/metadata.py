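"""Cohort characteristics table ("Table 1") with per-variable response tests.

Each metadata variable is associated with the categorical response via

* linear regression (one-way ANOVA F-test) with a global check of the
  regression assumptions on the residuals, or
* the Kruskal-Wallis rank test (nonparametric alternative), or
* a Pearson chi-square test of independence for categorical variables.

The assumption validator decomposes departure from the linear-model
assumptions into four chi-square(1) components — skewness, kurtosis,
link function, heteroscedasticity — whose sum is a global chi-square(4)
statistic.  A violated verdict does not trigger any automatic fallback;
it is reported alongside the regression row.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .data import Study

__all__ = [
    "Table1Row",
    "AssumptionReport",
    "test_continuous_regression",
    "test_continuous_kw",
    "test_categorical",
    "global_validate",
    "build_table1",
    "table1_to_frame",
    "table1_to_markdown",
]


class StatsError(ValueError):
    """Raised when a test's preconditions are not met."""


@dataclass
class AssumptionReport:
    """Four-component global validation of linear-regression assumptions.

    Components are chi-square(1) statistics on the residuals: skewness and
    kurtosis (Jarque-Bera split), a score test for link misspecification
    (residuals regressed on squared fitted values) and a Breusch-Pagan
    heteroscedasticity test.  The global statistic is their sum, referred
    to chi-square(df) where df counts the applicable components.
    """

    components: dict[str, tuple[float, float] | None]  # name -> (stat, p) or None
    global_stat: float
    global_df: int
    global_p: float
    verdict: str  # "assumptions_ok" | "violated"


@dataclass
class Table1Row:
    """One metadata variable's summary and association with the response."""

    variable: str
    kind: str  # "numerical" | "categorical"
    per_group_summary: dict[str, dict[str, float]]
    test_name: str
    statistic: float
    df: float | tuple[float, float]
    p_value: float
    assumptions: AssumptionReport | None = None
    error: str | None = None


def _split_groups(x: np.ndarray, labels: np.ndarray) -> dict[str, np.ndarray]:
    labels = np.asarray(labels).astype(str)
    return {g: x[labels == g] for g in pd.unique(labels)}


def test_continuous_regression(
    x: np.ndarray, labels: np.ndarray
) -> tuple[Table1Row, AssumptionReport]:
    """One-way OLS of x on group indicators; overall F-test + validation.

    Group summaries are mean and standard deviation (ddof=1).  Residuals
    (x minus its group mean) feed the assumption validator.
    """
    x = np.asarray(x, dtype=float)
    groups = _split_groups(x, labels)
    if len(groups) < 2:
        raise StatsError("need >= 2 response groups")
    for g, xs in groups.items():
        if len(xs) < 2:
            raise StatsError(f"group {g!r} has fewer than 2 observations")
    if np.ptp(x) == 0:
        raise StatsError("x has zero variance")

    n, g = len(x), len(groups)
    grand = x.mean()
    means = {k: v.mean() for k, v in groups.items()}
    ssb = sum(len(v) * (means[k] - grand) ** 2 for k, v in groups.items())
    ssw = sum(((v - means[k]) ** 2).sum() for k, v in groups.items())
    df1, df2 = g - 1, n - g
    if ssw == 0:
        f_stat, p = np.inf, 0.0
        if ssb == 0:  # all values identical within and between
            f_stat, p = 0.0, 1.0
    else:
        f_stat = (ssb / df1) / (ssw / df2)
        p = float(stats.f.sf(f_stat, df1, df2))

    fitted = np.concatenate([np.full(len(v), means[k]) for k, v in groups.items()])
    resid = np.concatenate([v - means[k] for k, v in groups.items()])
    # assumption validation needs a minimum sample; report None below that
    report = global_validate(resid, fitted) if n >= 8 and ssw > 0 else None

    row = Table1Row(
        variable="",
        kind="numerical",
        per_group_summary={
            k: {"mean": float(v.mean()), "sd": float(v.std(ddof=1))}
            for k, v in groups.items()
        },
        test_name="linear_regression_F",
        statistic=float(f_stat),
        df=(float(df1), float(df2)),
        p_value=float(p),
        assumptions=report,
    )
    return row, report


def global_validate(residuals: np.ndarray, fitted: np.ndarray) -> AssumptionReport:
    """Global chi-square validation of regression assumptions on residuals.

    Components (each chi-square(1)):

    * ``skewness``: n * g1^2 / 6 with g1 the third standardized moment
    * ``kurtosis``: n * (g2 - 3)^2 / 24 with g2 the fourth moment
    * ``link_function``: n * R^2 from regressing residuals on squared
      fitted values (score test for a misspecified mean function)
    * ``heteroscedasticity``: Breusch-Pagan n * R^2 of squared scaled
      residuals on fitted values

    Residuals are standardized by the maximum-likelihood scale.  When the
    fitted values are constant the last two components are undefined and
    the global degrees of freedom shrink accordingly.
    """
    r = np.asarray(residuals, dtype=float)
    f = np.asarray(fitted, dtype=float)
    n = len(r)
    if n < 8:
        raise StatsError("need >= 8 residuals for assumption validation")
    s_ml = np.sqrt(np.mean((r - r.mean()) ** 2))
    if s_ml == 0:
        raise StatsError("residuals have zero variance")
    z = (r - r.mean()) / s_ml

    g1 = float(np.mean(z**3))
    g2 = float(np.mean(z**4))
    comps: dict[str, tuple[float, float] | None] = {
        "skewness": (n * g1**2 / 6, float(stats.chi2.sf(n * g1**2 / 6, 1))),
        "kurtosis": (n * (g2 - 3) ** 2 / 24, float(stats.chi2.sf(n * (g2 - 3) ** 2 / 24, 1))),
    }

    def _aux_r2(y: np.ndarray, covariate: np.ndarray) -> float:
        X = np.column_stack([np.ones(n), covariate])
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        pred = X @ beta
        tss = float(((y - y.mean()) ** 2).sum())
        return 0.0 if tss == 0 else 1.0 - float(((y - pred) ** 2).sum()) / tss

    if np.ptp(f) == 0:
        comps["link_function"] = None
        comps["heteroscedasticity"] = None
    else:
        r2_link = _aux_r2(r, f**2)
        stat_link = n * r2_link
        comps["link_function"] = (stat_link, float(stats.chi2.sf(stat_link, 1)))
        r2_het = _aux_r2(z**2, f)
        stat_het = n * r2_het
        comps["heteroscedasticity"] = (stat_het, float(stats.chi2.sf(stat_het, 1)))

    avail = [c for c in comps.values() if c is not None]
    global_stat = float(sum(c[0] for c in avail))
    global_df = len(avail)
    global_p = float(stats.chi2.sf(global_stat, global_df))
    return AssumptionReport(
        components=comps,
        global_stat=global_stat,
        global_df=global_df,
        global_p=global_p,
        verdict="violated" if global_p < 0.05 else "assumptions_ok",
    )


def test_continuous_kw(x: np.ndarray, labels: np.ndarray) -> Table1Row:
    """Kruskal-Wallis rank test with min/median/max group summaries.

    Uses the tie-corrected H statistic referred to chi-square(g-1); no
    exact small-sample tables.
    """
    x = np.asarray(x, dtype=float)
    groups = _split_groups(x, labels)
    if len(groups) < 2 or len(x) < 3:
        raise StatsError("need >= 2 groups and total n >= 3")
    if np.ptp(x) == 0:
        raise StatsError("all values tied across all samples")
    h_stat, p = stats.kruskal(*groups.values())
    return Table1Row(
        variable="",
        kind="numerical",
        per_group_summary={
            k: {
                "min": float(v.min()),
                "median": float(np.median(v)),
                "max": float(v.max()),
            }
            for k, v in groups.items()
        },
        test_name="kruskal_wallis",
        statistic=float(h_stat),
        df=float(len(groups) - 1),
        p_value=float(p),
    )


def test_categorical(
    x: np.ndarray, labels: np.ndarray, yates_2x2: bool = True
) -> Table1Row:
    """Pearson chi-square of independence on the variable x response table.

    Yates continuity correction is applied only to 2x2 tables (and can be
    switched off).  Summaries are counts and column percentages per
    response group.
    """
    x = np.asarray(x).astype(str)
    labels = np.asarray(labels).astype(str)
    table = pd.crosstab(pd.Series(x, name="x"), pd.Series(labels, name="group"))
    if table.shape[0] < 2 or table.shape[1] < 2:
        raise StatsError(
            f"contingency table must be >= 2x2, got {table.shape[0]}x{table.shape[1]}"
        )
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise StatsError("contingency table has a zero margin")
    correction = yates_2x2 and table.shape == (2, 2)
    chi2, p, df, _ = stats.chi2_contingency(table.to_numpy(), correction=correction)
    col_tot = table.sum(axis=0)
    summary: dict[str, dict[str, float]] = {}
    for grp in table.columns:
        summary[str(grp)] = {}
        for lev in table.index:
            cnt = int(table.loc[lev, grp])
            summary[str(grp)][f"{lev}_count"] = cnt
            summary[str(grp)][f"{lev}_percent"] = 100.0 * cnt / int(col_tot[grp])
    return Table1Row(
        variable="",
        kind="categorical",
        per_group_summary=summary,
        test_name="chi_square" + ("_yates" if correction else ""),
        statistic=float(chi2),
        df=float(df),
        p_value=float(p),
    )


def build_table1(
    study: Study,
    mode: str | dict[str, str] = "regression",
    yates_2x2: bool = True,
) -> list[Table1Row]:
    """One association row per metadata variable (excluding the response).

    ``mode`` selects the continuous-variable method, either globally
    ("regression" or "nonparametric") or per variable via a dict.
    Per-variable failures are captured in the row's ``error`` field rather
    than aborting the whole table.
    """
    labels = study.response_labels
    rows: list[Table1Row] = []
    for var in study.metadata.variables():
        if var == study.response.name:
            continue
        kind = study.metadata.var_kind[var]
        var_mode = mode[var] if isinstance(mode, dict) else mode
        values = study.metadata.frame[var].to_numpy()
        try:
            if kind == "numerical":
                if var_mode == "nonparametric":
                    row = test_continuous_kw(values.astype(float), labels)
                else:
                    row, _ = test_continuous_regression(values.astype(float), labels)
            else:
                row = test_categorical(values, labels, yates_2x2=yates_2x2)
            row.variable = var
            row.kind = kind
        except StatsError as exc:
            row = Table1Row(
                variable=var,
                kind=kind,
                per_group_summary={},
                test_name="not_applicable",
                statistic=float("nan"),
                df=float("nan"),
                p_value=float("nan"),
                error=str(exc),
            )
        rows.append(row)
    return rows


def table1_to_frame(rows: list[Table1Row]) -> pd.DataFrame:
    """Flatten Table1 rows into a tidy frame (one line per variable)."""
    records = []
    for r in rows:
        rec: dict[str, object] = {
            "variable": r.variable,
            "kind": r.kind,
            "test": r.test_name,
            "statistic": r.statistic,
            "df": r.df if not isinstance(r.df, tuple) else f"{r.df[0]:g},{r.df[1]:g}",
            "p_value": r.p_value,
        }
        for grp, summ in r.per_group_summary.items():
            for k, v in summ.items():
                rec[f"{grp}:{k}"] = v
        if r.assumptions is not None:
            rec["assumption_global_p"] = r.assumptions.global_p
            rec["assumption_verdict"] = r.assumptions.verdict
        if r.error:
            rec["error"] = r.error
        records.append(rec)
    return pd.DataFrame.from_records(records)


def table1_to_markdown(rows: list[Table1Row]) -> str:
    """Markdown pipe-table rendering for the report module."""
    frame = table1_to_frame(rows)
    return frame.to_markdown(index=False, floatfmt=".4g")
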