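"""Cross-cohort statistics: fold changes, chi-squared prevalence tests,
degree regression with mean-shift outliers, block enrichment, and
per-patient diagnosis-count summaries.

The degree regression fits case-cohort significant-correlation counts per
code on the control-cohort counts by OLS; codes deviating from the shared
trend are flagged by the mean-shift outlier test (externally studentized
residuals, two-sided t, Bonferroni-corrected across codes) — equivalently,
the t-test on a per-point indicator regressor.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .config import AnalysisConfig
from .records import BlockMap, CohortMatrix, block_membership

__all__ = [
    "fold_change",
    "chi_square_prevalence",
    "DegreeRegression",
    "degree_regression",
    "mean_shift_outliers",
    "block_enrichment",
    "diagnosis_count_summary",
    "per_code_comparison",
]


def fold_change(prev_case: float, prev_control: float) -> float:
    """Case prevalence divided by control prevalence (unrounded).

    Display rounding to 2 decimals is applied by report writers only; all
    downstream logic uses the unrounded ratio.  Zero control prevalence is
    undefined (NaN) and excluded from fold tables.
    """
    if prev_control < 0 or prev_case < 0:
        raise ValueError("prevalences must be non-negative")
    if prev_control == 0:
        return float("nan")
    return prev_case / prev_control


def chi_square_prevalence(
    count_case: int,
    n_case: int,
    count_control: int,
    n_control: int,
    correction: bool = True,
) -> tuple[float, float]:
    """Pearson chi-squared test on the 2x2 affected/unaffected x cohort table.

    Continuity (Yates) correction on by default; disable to recover the
    closed-form statistic n(ad-bc)^2 / ((a+b)(c+d)(a+c)(b+d)).
    Returns (nan, nan) when a table margin is zero.
    """
    if count_case > n_case or count_control > n_control:
        raise ValueError("counts cannot exceed cohort sizes")
    table = np.array(
        [
            [count_case, n_case - count_case],
            [count_control, n_control - count_control],
        ]
    )
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        return float("nan"), float("nan")
    res = stats.chi2_contingency(table, correction=correction)
    return float(res.statistic), float(res.pvalue)


@dataclass
class DegreeRegression:
    """OLS fit of case degrees on control degrees, per code."""

    slope: float
    intercept: float
    r_squared: float
    slope_p: float
    intercept_p: float
    residuals: pd.DataFrame = field(repr=False)  # control, case, fitted, resid, studentized, p, p_bonf
    outliers: list[str] = field(default_factory=list)

    def summary_dict(self) -> dict:
        return {
            "slope": self.slope,
            "intercept": self.intercept,
            "r_squared": self.r_squared,
            "slope_p": self.slope_p,
            "intercept_p": self.intercept_p,
            "outliers": list(self.outliers),
        }


def degree_regression(degrees: pd.DataFrame) -> tuple[DegreeRegression, sm.regression.linear_model.RegressionResultsWrapper]:
    """Regress per-code case degree on control degree.

    ``degrees`` must have columns ``control`` and ``case`` indexed by code,
    with at least 3 rows and a non-constant predictor.
    """
    if len(degrees) < 3:
        raise ValueError("need at least 3 codes for the regression")
    x = degrees["control"].astype(float)
    if x.nunique() == 1:
        raise ValueError("control degrees are constant; slope is unidentifiable")
    y = degrees["case"].astype(float)
    fit = sm.OLS(y, sm.add_constant(x)).fit()
    resid = pd.DataFrame(
        {
            "control": x,
            "case": y,
            "fitted": fit.fittedvalues,
            "resid": fit.resid,
        }
    )
    reg = DegreeRegression(
        slope=float(fit.params["control"]),
        intercept=float(fit.params["const"]),
        r_squared=float(fit.rsquared),
        slope_p=float(fit.pvalues["control"]),
        intercept_p=float(fit.pvalues["const"]),
        residuals=resid,
    )
    return reg, fit


def mean_shift_outliers(
    fit: sm.regression.linear_model.RegressionResultsWrapper,
    reg: DegreeRegression,
    level: float = 0.05,
) -> list[str]:
    """Flag regression points whose mean-shift (studentized residual) test
    survives Bonferroni correction.

    For each point the externally studentized residual is referred to a
    two-sided Student-t with m - k - 1 df; p-values are multiplied by the
    number of points m (capped at 1).  Mutates ``reg`` with the residual
    table columns and the outlier list.
    """
    m = int(fit.nobs)
    k = len(fit.params)
    if m - k - 1 < 1:
        raise ValueError("too few points for the mean-shift test")
    test = fit.outlier_test(method="bonf")  # student_resid, unadj_p, bonf(p)
    reg.residuals["studentized"] = test["student_resid"]
    reg.residuals["p"] = test["unadj_p"]
    reg.residuals["p_bonf"] = test["bonf(p)"]
    outliers = sorted(reg.residuals.index[reg.residuals["p_bonf"] < level])
    reg.outliers = [str(c) for c in outliers]
    return reg.outliers


def per_code_comparison(
    prev_case: pd.DataFrame,
    prev_control: pd.DataFrame,
    n_case: int,
    n_control: int,
    correction: bool = True,
) -> pd.DataFrame:
    """Per-code prevalences, fold change and chi-squared test, both cohorts.

    Rows cover the codes of ``prev_case`` (typically the case-cohort
    candidate codes); control counts default to zero for codes absent from
    the control table.  Fold-change display values (``fold_change_2dp``)
    are rounded to 2 decimals; logic elsewhere uses the unrounded column.
    """
    codes = sorted(prev_case.index)
    rows = []
    for code in codes:
        cc = int(prev_case.loc[code, "count"]) if code in prev_case.index else 0
        kc = int(prev_control.loc[code, "count"]) if code in prev_control.index else 0
        pc, pk = cc / n_case, kc / n_control
        fc = fold_change(pc, pk)
        stat, p = chi_square_prevalence(cc, n_case, kc, n_control, correction=correction)
        rows.append(
            {
                "code": code,
                "prev_case": pc,
                "prev_control": pk,
                "fold_change": fc,
                "fold_change_2dp": round(fc, 2) if math.isfinite(fc) else fc,
                "chi2": stat,
                "p": p,
            }
        )
    return pd.DataFrame(rows).set_index("code")


def block_enrichment(
    matrix_case: CohortMatrix,
    matrix_control: CohortMatrix,
    blocks: BlockMap,
    config: AnalysisConfig,
) -> pd.DataFrame:
    """Block-level prevalences with the enrichment flag.

    A patient counts once per block regardless of how many member codes
    they carry.  A block is enriched when its case prevalence is strictly
    above ``block_min_prev``, its fold change at least ``block_min_fold``,
    and the chi-squared p below 0.05.
    """
    mem_case = block_membership(matrix_case, blocks)
    mem_control = block_membership(matrix_control, blocks)
    block_ids = sorted(set(mem_case.columns) | set(mem_control.columns))
    rows = []
    for bid in block_ids:
        cc = int(mem_case[bid].sum()) if bid in mem_case.columns else 0
        kc = int(mem_control[bid].sum()) if bid in mem_control.columns else 0
        pc = cc / matrix_case.n
        pk = kc / matrix_control.n
        fc = fold_change(pc, pk)
        stat, p = chi_square_prevalence(
            cc, matrix_case.n, kc, matrix_control.n, correction=config.chi2_correction
        )
        enriched = bool(
            pc > config.block_min_prev
            and math.isfinite(fc)
            and fc >= config.block_min_fold
            and math.isfinite(p)
            and p < 0.05
        )
        rows.append(
            {
                "block_id": bid,
                "block_name": blocks.block_name(bid),
                "prev_case": pc,
                "prev_control": pk,
                "fold_change": fc,
                "chi2": stat,
                "p": p,
                "enriched": enriched,
            }
        )
    return pd.DataFrame(rows).set_index("block_id")


def diagnosis_count_summary(matrix: CohortMatrix) -> dict:
    """Distribution of distinct three-character codes per patient."""
    counts = matrix.incidence.sum(axis=1).astype(int)
    histogram = pd.Series(counts).value_counts().sort_index()
    return {
        "counts": counts,
        "histogram": histogram,
        "median": float(np.median(counts)),
        "mean": float(np.mean(counts)),
        "monodiagnosis_fraction": float(np.mean(counts == 1)),
    }
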