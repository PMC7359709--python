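"""Validation and correlation statistics.

Two regressions back the method's validation:

* a straight line constrained through the origin for comparing a measured
  quantity with its physical reference (image-derived graft length vs
  caliper length); the goodness of fit uses the *uncentered* R^2,
  ``1 - SS_res / sum(y^2)``, the natural coefficient for a forced-origin
  fit (the centered form can be negative there);
* ordinary least squares with intercept for correlating average luminal
  cross-sectional area with platelet or fibrin accumulation endpoints,
  with the single-predictor regression ANOVA F-test
  ``F = R^2 (n-2) / (1 - R^2)`` on (1, n-2) degrees of freedom deciding
  significance.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from scipy import stats as sps

__all__ = [
    "FitResult",
    "fit_through_origin",
    "correlate_group",
    "correlation_table",
    "significance_flag",
    "f_from_r_squared",
    "implied_sample_size",
    "load_accumulation_csv",
]

#: Columns of an accumulation-endpoint table.
ACCUMULATION_COLUMNS = (
    "sample_id",
    "material_group",
    "platelets_per_mm",
    "fibrin",
    "average_luminal_area",
)


@dataclass(frozen=True)
class FitResult:
    """A fitted line with its regression ANOVA summary."""

    slope: float
    intercept: float | None
    r_squared: float
    f_statistic: float
    p_value: float
    n: int

    def to_dict(self) -> dict:
        return asdict(self)


def fit_through_origin(x, y) -> FitResult:
    """Least-squares line constrained to a y-intercept of (0, 0).

    slope = sum(xy)/sum(x^2); R^2 is the uncentered coefficient
    1 - SS_res/sum(y^2); the F statistic tests the single slope on
    (1, n-1) degrees of freedom.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1D arrays of equal length")
    n = x.size
    if n < 2:
        raise ValueError("need at least two points")
    sxx = float(np.sum(x * x))
    if sxx == 0.0:
        raise ValueError("all-zero x: slope undefined")
    slope = float(np.sum(x * y)) / sxx
    resid = y - slope * x
    ss_res = float(np.sum(resid * resid))
    ss_tot = float(np.sum(y * y))
    if ss_tot == 0.0:
        r2 = 1.0 if ss_res == 0.0 else 0.0
    else:
        r2 = 1.0 - ss_res / ss_tot
    df_resid = n - 1
    if ss_res == 0.0:
        f_stat, p = float("inf"), 0.0
    else:
        f_stat = (ss_tot - ss_res) / (ss_res / df_resid)
        p = float(sps.f.sf(f_stat, 1, df_resid))
    return FitResult(slope, None, r2, float(f_stat), p, n)


def correlate_group(records, predictor: str) -> FitResult:
    """OLS (with intercept) of average luminal area on one endpoint.

    ``records`` is a DataFrame (or record list) with the accumulation-table
    columns; ``predictor`` is ``"platelets"`` or ``"fibrin"``.  The expected
    physical direction is a negative slope: more accumulation, less open
    lumen.
    """
    import pandas as pd
    import statsmodels.api as sm

    df = pd.DataFrame(records)
    col = {"platelets": "platelets_per_mm", "fibrin": "fibrin"}.get(predictor, predictor)
    if col not in df.columns:
        raise KeyError(f"predictor column {col!r} not in records")
    x = df[col].to_numpy(dtype=float)
    y = df["average_luminal_area"].to_numpy(dtype=float)
    n = x.size
    if n < 3:
        raise ValueError(f"need at least 3 samples per group, got {n}")
    if np.var(x) == 0.0:
        raise ValueError("zero predictor variance")
    model = sm.OLS(y, sm.add_constant(x)).fit()
    return FitResult(
        slope=float(model.params[1]),
        intercept=float(model.params[0]),
        r_squared=float(model.rsquared),
        f_statistic=float(model.fvalue),
        p_value=float(model.f_pvalue),
        n=n,
    )


def correlation_table(records, predictors=("platelets", "fibrin"), alpha: float = 0.05):
    """Tidy per-group, per-predictor regression summary.

    Returns a DataFrame with columns
    (material_group, predictor, n, slope, r_squared, f_statistic, p_value,
    significant).
    """
    import pandas as pd

    df = pd.DataFrame(records)
    rows = []
    for group, sub in df.groupby("material_group", sort=True):
        for pred in predictors:
            fit = correlate_group(sub, pred)
            rows.append(
                {
                    "material_group": group,
                    "predictor": pred,
                    "n": fit.n,
                    "slope": fit.slope,
                    "r_squared": fit.r_squared,
                    "f_statistic": fit.f_statistic,
                    "p_value": fit.p_value,
                    "significant": significance_flag(fit, alpha),
                }
            )
    return pd.DataFrame(rows)


def significance_flag(fit: FitResult, alpha: float = 0.05) -> bool:
    """True when p < alpha (strict inequality at the boundary)."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    return bool(fit.p_value < alpha)


def f_from_r_squared(r_squared: float, n: int) -> float:
    """Single-predictor regression ANOVA identity F = R^2 (n-2) / (1 - R^2)."""
    if not 0 <= r_squared < 1:
        raise ValueError("r_squared must lie in [0, 1)")
    return r_squared * (n - 2) / (1.0 - r_squared)


def implied_sample_size(r_squared: float, f_statistic: float) -> float:
    """Sample size implied by a reported (R^2, F) pair under the F identity.

    Inverts F = R^2 (n-2)/(1-R^2); useful for checking that a published
    (R^2, F, n) triple is internally consistent.
    """
    if not 0 < r_squared < 1:
        raise ValueError("r_squared must lie in (0, 1)")
    return 2.0 + f_statistic * (1.0 - r_squared) / r_squared


def load_accumulation_csv(path):
    """Read an accumulation-endpoint table, checking the expected columns."""
    import pandas as pd

    df = pd.read_csv(path)
    missing = set(ACCUMULATION_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"accumulation table missing columns {sorted(missing)}")
    return df
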