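"""Cohort-level statistics: baseline group comparisons, improvement rates,
and the multi-predictor linear model of mGOS with collinearity diagnostics.

Baseline continuous variables are compared with the pooled-variance
two-sample t test (computable from printed group summaries alone) and
dichotomous ones with Pearson's chi-square without continuity correction —
the two conventions that reproduce the published baseline statistics from
their group summaries.  The outcome model is ordinary least squares of the
mGOS score (or the binary improvement label) on eight C-ApEn cells plus
sex, age, duration and lesion type, reporting unstandardized and
standardized coefficients, 95% CIs, and tolerance/VIF from auxiliary
regressions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .errors import CollinearityError, DegenerateTableError

#: Table-4-style predictor set: C-ApEn cells by (pair, condition), then clinical covariates.
REGRESSION_CAPEN_CELLS: list[tuple[str, str]] = [
    ("Ca-Fa", "pain_affected"),
    ("Ca-FPa", "pain_affected"),
    ("Ca-Oa", "pain_affected"),
    ("Cu-Fu", "pain_unaffected"),
    ("Cu-Pu", "pain_unaffected"),
    ("Cu-MTu", "pain_unaffected"),
    ("Cu-FPu", "pain_unaffected"),
    ("Cu-Ou", "pain_unaffected"),
]
CLINICAL_COVARIATES = ["sex", "age", "duration", "lesion"]


def pooled_t(
    mean1: float, sd1: float, n1: int, mean2: float, sd2: float, n2: int
) -> tuple[float, float]:
    """Pooled-variance two-sample t test from group summaries.

    Sign convention is group1 - group2; degrees of freedom n1 + n2 - 2.
    Returns ``(t, two-sided p)``.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs n >= 2")
    if sd1 < 0 or sd2 < 0:
        raise ValueError("standard deviations must be non-negative")
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / df
    if sp2 == 0:
        if mean1 == mean2:
            return 0.0, 1.0
        raise ValueError("zero pooled variance with unequal means: t is infinite")
    t = (mean1 - mean2) / np.sqrt(sp2 * (1 / n1 + 1 / n2))
    p = 2 * stats.t.sf(abs(t), df)
    return float(t), float(p)


def chi2_2x2(table) -> tuple[float, float]:
    """Pearson chi-square on a 2x2 table, df = 1, no continuity correction."""
    arr = np.asarray(table, dtype=float)
    if arr.shape != (2, 2):
        raise ValueError(f"expected a 2x2 table, got shape {arr.shape}")
    if np.any(arr < 0):
        raise ValueError("counts must be non-negative")
    if np.any(arr.sum(axis=0) == 0) or np.any(arr.sum(axis=1) == 0):
        raise DegenerateTableError("2x2 table has a zero margin")
    stat, p, _, _ = stats.chi2_contingency(arr, correction=False)
    return float(stat), float(p)


def improvement_rate(improved: int, total: int) -> float:
    """Percentage of improved patients, to one decimal place."""
    if total <= 0:
        raise ValueError("total must be positive")
    if not 0 <= improved <= total:
        raise ValueError(f"improved must be in [0, {total}], got {improved}")
    return round(100.0 * improved / total, 1)


@dataclass(frozen=True)
class RegressionRow:
    """One predictor's row of the outcome-model table."""

    predictor: str
    B: float
    se: float
    beta: float
    t: float
    p: float
    ci_low: float
    ci_high: float
    tolerance: float
    vif: float


def _check_rank(X: pd.DataFrame) -> None:
    mat = X.to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(mat)
    if rank < X.shape[1]:
        # identify columns linearly dependent on their predecessors via QR
        dependent = []
        for j in range(1, X.shape[1]):
            sub = mat[:, : j + 1]
            if np.linalg.matrix_rank(sub) < j + 1:
                dependent.append(X.columns[j])
        raise CollinearityError(
            f"design matrix is rank deficient (rank {rank} < {X.shape[1]}); "
            f"dependent columns: {dependent}"
        )


def mgos_regression(
    design: pd.DataFrame,
    dependent: str = "mgos",
    predictors: list[str] | None = None,
) -> list[RegressionRow]:
    """OLS of *dependent* on *predictors* with collinearity diagnostics.

    Parameters
    ----------
    design
        Complete-case data frame holding the dependent variable and all
        predictors as numeric columns (sex and lesion already 0/1 coded:
        male = 0, TBI = 0).
    dependent
        Outcome column: the mGOS score (default) or the binary improvement
        label.
    predictors
        Predictor column order; defaults to every column except *dependent*.

    Returns the intercept row followed by one :class:`RegressionRow` per
    predictor.  Tolerance is ``1 - R^2`` of the auxiliary regression of the
    predictor on the remaining predictors; VIF is its reciprocal.
    """
    if predictors is None:
        predictors = [c for c in design.columns if c != dependent]
    X = design[predictors].astype(float)
    y = design[dependent].astype(float)
    if len(design) <= len(predictors) + 1:
        raise ValueError(
            f"need n > p + 1 complete cases (n={len(design)}, p={len(predictors)})"
        )
    if X.isna().any().any() or y.isna().any():
        raise ValueError("design matrix contains missing values; complete cases required")
    _check_rank(sm.add_constant(X, has_constant="add"))

    Xc = sm.add_constant(X, has_constant="add")
    fit = sm.OLS(y, Xc).fit()
    ci = fit.conf_int(alpha=0.05)
    sd_y = y.std(ddof=1)

    rows = [
        RegressionRow(
            predictor="(Constant)",
            B=float(fit.params["const"]),
            se=float(fit.bse["const"]),
            beta=float("nan"),
            t=float(fit.tvalues["const"]),
            p=float(fit.pvalues["const"]),
            ci_low=float(ci.loc["const", 0]),
            ci_high=float(ci.loc["const", 1]),
            tolerance=float("nan"),
            vif=float("nan"),
        )
    ]
    for name in predictors:
        others = [c for c in predictors if c != name]
        if others:
            aux = sm.OLS(X[name], sm.add_constant(X[others], has_constant="add")).fit()
            tol = float(1.0 - aux.rsquared)
        else:
            tol = 1.0
        rows.append(
            RegressionRow(
                predictor=name,
                B=float(fit.params[name]),
                se=float(fit.bse[name]),
                beta=float(fit.params[name] * X[name].std(ddof=1) / sd_y),
                t=float(fit.tvalues[name]),
                p=float(fit.pvalues[name]),
                ci_low=float(ci.loc[name, 0]),
                ci_high=float(ci.loc[name, 1]),
                tolerance=tol,
                vif=float(1.0 / tol) if tol > 0 else float("inf"),
            )
        )
    return rows


def regression_frame(rows: list[RegressionRow]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in rows])


def baseline_table(cohort: pd.DataFrame) -> pd.DataFrame:
    """Table-2-style between-group baseline comparison of a cohort frame.

    Continuous rows (age, duration, CRS-R) report group mean +/- SD and the
    pooled t; dichotomous rows (sex, lesion) report counts and the Pearson
    chi-square.
    """
    ctrl = cohort[cohort["group"] == "control"]
    tdcs = cohort[cohort["group"] == "tDCS"]
    rows = []
    for name, col in (("age", "age"), ("duration", "duration_days"), ("crsr", "crsr")):
        m1, s1, n1 = ctrl[col].mean(), ctrl[col].std(ddof=1), len(ctrl)
        m2, s2, n2 = tdcs[col].mean(), tdcs[col].std(ddof=1), len(tdcs)
        t, p = pooled_t(m1, s1, n1, m2, s2, n2)
        rows.append(
            {"variable": name, "control": f"{m1:.2f} ± {s1:.2f}",
             "tdcs": f"{m2:.2f} ± {s2:.2f}", "statistic": t, "p": p, "test": "pooled t"}
        )
    for name, col, level in (("sex_male", "sex", "male"), ("lesion_tbi", "lesion", "TBI")):
        a, b = int((ctrl[col] == level).sum()), int((ctrl[col] != level).sum())
        c, d = int((tdcs[col] == level).sum()), int((tdcs[col] != level).sum())
        stat, p = chi2_2x2([[a, b], [c, d]])
        rows.append(
            {"variable": name, "control": f"{a}/{a + b}", "tdcs": f"{c}/{c + d}",
             "statistic": stat, "p": p, "test": "chi-square"}
        )
    return pd.DataFrame(rows)


def improvement_table(cohort: pd.DataFrame) -> pd.DataFrame:
    """Table-3-style improvement rates per group."""
    rows = []
    for group, sub in cohort.groupby("group"):
        improved = int(sub["improved"].sum())
        rows.append(
            {"group": group, "improved": improved, "total": len(sub),
             "rate_pct": improvement_rate(improved, len(sub))}
        )
    return pd.DataFrame(rows)
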