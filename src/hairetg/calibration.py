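"""Calibration fitting and linearity diagnostics.

The working curve regresses the response ratio (analyte peak area / internal
standard peak area) on nominal concentration by unweighted ordinary least
squares — homoscedasticity is checked first with an F-test on the replicate
variances at the extreme levels, and only an unweighted fit is offered.
Linearity is then judged by two complementary F-tests at α = 0.05:

* lack-of-fit — splits the residual sum of squares into pure error (within
  replicated levels) and lack-of-fit, F = (SS_lof/(k−2)) / (SS_pe/(n−k));
* Mandel — compares the straight-line fit with a quadratic alternative,
  F = (SSE_linear − SSE_quadratic) / (SSE_quadratic/(n−3)).

Concentrations are back-calculated from the fitted line with dilution and
sample-mass scaling (50 mg reference aliquot), and a dual-range rule routes
estimates above the low curve's top (60 pg/mg) onto a high curve
(60–300 pg/mg) or flags them for extract dilution.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.stats as st
import statsmodels.api as sm

from .errors import ConfigurationError, InsufficientDataError
from .util import round_half_up

REFERENCE_SAMPLE_MASS_MG = 50.0
LOW_RANGE = (6.0, 60.0)  # pg/mg
HIGH_RANGE = (60.0, 300.0)  # pg/mg

REQUIRED_COLUMNS = ("nominal_pg_per_mg", "response_ratio")


@dataclass
class CalibrationFit:
    """OLS line and the summary statistics downstream tests need."""

    slope: float  # ratio per pg/mg
    intercept: float  # ratio
    residual_sd: float  # s_y/x, ratio units
    n: int
    mean_x: float  # pg/mg
    sxx: float  # (pg/mg)^2
    r_squared: float
    range: tuple[float, float] = LOW_RANGE  # pg/mg

    def predict(self, x):
        return self.intercept + self.slope * np.asarray(x, dtype=float)


@dataclass
class LinearityVerdict:
    fisher_F: float
    fisher_pass: bool
    lof_F: float
    lof_df: tuple[int, int]
    lof_pass: bool
    mandel_F: float
    mandel_df: tuple[int, int]
    mandel_pass: bool
    alpha: float

    @property
    def linear(self) -> bool:
        return self.lof_pass and self.mandel_pass


@dataclass
class BackCalcResult:
    concentration: float  # pg/mg (may be negative; see flag)
    below_zero: bool


@dataclass
class RangeSelection:
    decision: str  # low | high | dilution_required
    fit: CalibrationFit | None
    rationale: str


def _validate_table(table: pd.DataFrame) -> pd.DataFrame:
    for col in REQUIRED_COLUMNS:
        if col not in table.columns:
            raise ValueError(f"calibration table missing column {col!r}")
    if (table["response_ratio"] < 0).any():
        raise ValueError("response ratios must be non-negative")
    return table


def fit_calibration(
    table: pd.DataFrame,
    cal_range: tuple[float, float] = LOW_RANGE,
) -> CalibrationFit:
    """Unweighted OLS of response ratio on nominal concentration."""
    table = _validate_table(table)
    x = table["nominal_pg_per_mg"].to_numpy(dtype=float)
    y = table["response_ratio"].to_numpy(dtype=float)
    n = len(x)
    if len(np.unique(x)) < 3:
        raise InsufficientDataError("calibration requires >= 3 distinct levels")
    sxx = float(np.sum((x - x.mean()) ** 2))
    if sxx <= 0:
        raise InsufficientDataError("zero concentration variance")

    model = sm.OLS(y, sm.add_constant(x)).fit()
    intercept, slope = model.params
    resid_sd = float(np.sqrt(model.ssr / (n - 2))) if n > 2 else 0.0
    tss = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if tss == 0 else 1.0 - model.ssr / tss
    return CalibrationFit(
        slope=float(slope),
        intercept=float(intercept),
        residual_sd=resid_sd,
        n=n,
        mean_x=float(x.mean()),
        sxx=sxx,
        r_squared=float(r2),
        range=cal_range,
    )


def fisher_homoscedasticity_test(
    table: pd.DataFrame, alpha: float = 0.01
) -> tuple[float, bool]:
    """Variance-ratio F-test between the extreme calibration levels.

    F is the larger over the smaller replicate variance at the lowest and
    highest levels; homoscedasticity is accepted (pass) iff F does not exceed
    the upper critical value. Passing justifies the unweighted fit.
    """
    table = _validate_table(table)
    levels = np.sort(table["nominal_pg_per_mg"].unique())
    lo, hi = levels[0], levels[-1]
    y_lo = table.loc[table["nominal_pg_per_mg"] == lo, "response_ratio"].to_numpy()
    y_hi = table.loc[table["nominal_pg_per_mg"] == hi, "response_ratio"].to_numpy()
    if len(y_lo) < 2 or len(y_hi) < 2:
        raise InsufficientDataError(
            "need >= 2 replicates at the lowest and highest levels"
        )
    v_lo, v_hi = np.var(y_lo, ddof=1), np.var(y_hi, ddof=1)
    if min(v_lo, v_hi) == 0:
        big = max(v_lo, v_hi)
        F = np.inf if big > 0 else 1.0
        df_num = (len(y_hi) if v_hi >= v_lo else len(y_lo)) - 1
        df_den = (len(y_lo) if v_hi >= v_lo else len(y_hi)) - 1
    elif v_hi >= v_lo:
        F = v_hi / v_lo
        df_num, df_den = len(y_hi) - 1, len(y_lo) - 1
    else:
        F = v_lo / v_hi
        df_num, df_den = len(y_lo) - 1, len(y_hi) - 1
    crit = st.f.ppf(1 - alpha, df_num, df_den)
    return float(F), bool(F <= crit)


def lack_of_fit_test(
    table: pd.DataFrame,
    fit: CalibrationFit,
    alpha: float = 0.05,
) -> tuple[float, tuple[int, int], bool]:
    """Lack-of-fit F-test against pure error from replicated levels."""
    table = _validate_table(table)
    x = table["nominal_pg_per_mg"].to_numpy(dtype=float)
    y = table["response_ratio"].to_numpy(dtype=float)
    levels = np.unique(x)
    k = len(levels)
    n = len(x)
    if k < 3:
        raise InsufficientDataError("lack-of-fit requires >= 3 levels")
    if n == k:
        raise InsufficientDataError("no replication anywhere: pure error undefined")

    ss_pe = 0.0
    for lev in levels:
        yy = y[x == lev]
        ss_pe += float(np.sum((yy - yy.mean()) ** 2))
    resid = y - fit.predict(x)
    ss_resid = float(np.sum(resid**2))
    ss_lof = max(0.0, ss_resid - ss_pe)

    df_lof, df_pe = k - 2, n - k
    # an exact fit leaves only rounding dust in both SS terms; their ratio is
    # then meaningless, so report F = 0
    tiny = n * np.finfo(float).eps ** 2 * max(1.0, float(np.sum(y**2)))
    if ss_resid <= tiny:
        F = 0.0
    elif ss_pe == 0:
        F = np.inf
    else:
        F = (ss_lof / df_lof) / (ss_pe / df_pe)
    crit = st.f.ppf(1 - alpha, df_lof, df_pe)
    return float(F), (df_lof, df_pe), bool(F <= crit)


def mandel_test(
    table: pd.DataFrame, alpha: float = 0.05
) -> tuple[float, tuple[int, int], bool]:
    """Mandel's fitting test: does a quadratic term significantly improve on
    the straight line? Pass means linearity is accepted."""
    table = _validate_table(table)
    x = table["nominal_pg_per_mg"].to_numpy(dtype=float)
    y = table["response_ratio"].to_numpy(dtype=float)
    n = len(x)
    if n < 4:
        raise InsufficientDataError("Mandel test requires >= 4 points")
    sse_lin = float(np.sum((y - np.polyval(np.polyfit(x, y, 1), x)) ** 2))
    sse_quad = float(np.sum((y - np.polyval(np.polyfit(x, y, 2), x)) ** 2))
    df = (1, n - 3)
    tiny = n * np.finfo(float).eps ** 2 * max(1.0, float(np.sum(y**2)))
    if sse_lin <= tiny:
        F = 0.0
    elif sse_quad <= tiny:
        F = np.inf
    else:
        F = (sse_lin - sse_quad) / (sse_quad / (n - 3))
        F = max(0.0, F)
    crit = st.f.ppf(1 - alpha, *df)
    return float(F), df, bool(F <= crit)


def back_calculate(
    fit: CalibrationFit,
    response_ratio: float,
    dilution_factor: float = 1.0,
    sample_mass_mg: float = REFERENCE_SAMPLE_MASS_MG,
    reference_mass_mg: float = REFERENCE_SAMPLE_MASS_MG,
) -> BackCalcResult:
    """Invert the calibration line to a concentration in pg/mg.

    concentration = dilution · (ratio − intercept)/slope · (ref mass / mass).
    Negative back-calculations are flagged, not clamped — censoring semantics
    belong to the interpretation layer.
    """
    if fit.slope <= 0:
        raise ConfigurationError("calibration slope must be positive")
    if sample_mass_mg <= 0:
        raise ConfigurationError("sample mass must be positive")
    conc = (
        dilution_factor
        * (response_ratio - fit.intercept)
        / fit.slope
        * (reference_mass_mg / sample_mass_mg)
    )
    return BackCalcResult(concentration=float(conc), below_zero=conc < 0)


def select_range(
    concentration_estimate: float,
    low_curve: CalibrationFit,
    high_curve: CalibrationFit,
) -> RangeSelection:
    """Dual-range rule: low curve up to its top, high curve above it, extract
    dilution beyond the high curve's top."""
    low_top = low_curve.range[1]
    high_top = high_curve.range[1]
    if concentration_estimate <= low_top:
        return RangeSelection("low", low_curve, f"estimate <= {low_top:g} pg/mg")
    if concentration_estimate <= high_top:
        return RangeSelection(
            "high", high_curve, f"{low_top:g} < estimate <= {high_top:g} pg/mg"
        )
    return RangeSelection(
        "dilution_required", None, f"estimate > {high_top:g} pg/mg: dilute extract"
    )


def determine_loq(
    levels: Sequence[tuple[float, float, float]],
    threshold_percent: float = 20.0,
) -> float | None:
    """Lowest level whose intra-assay CV% and |bias|% are both within the
    threshold; ``None`` when no level qualifies (undefined LOQ).

    ``levels`` is a sequence of (concentration pg/mg, cv_percent, bias_percent),
    sorted ascending by concentration.
    """
    if not levels:
        raise ValueError("levels must be nonempty")
    concs = [lv[0] for lv in levels]
    if concs != sorted(concs):
        raise ValueError("levels must be sorted ascending by concentration")
    for conc, cv, bias in levels:
        if cv <= threshold_percent and abs(bias) <= threshold_percent:
            return float(conc)
    return None


class CalibrationModel:
    """Calibration curve model in the fit/Results idiom.

    Construct from a table of (nominal concentration, response ratio)
    observations, then ``fit()`` to obtain a :class:`CalibrationResults`
    carrying the line, its diagnostics and the linearity verdict.
    """

    def __init__(
        self,
        table: pd.DataFrame,
        cal_range: tuple[float, float] = LOW_RANGE,
        alpha_linearity: float = 0.05,
        alpha_fisher: float = 0.01,
    ):
        self.table = _validate_table(table).copy()
        self.cal_range = cal_range
        self.alpha_linearity = alpha_linearity
        self.alpha_fisher = alpha_fisher

    @classmethod
    def from_dataframe(cls, table: pd.DataFrame, **kwargs) -> "CalibrationModel":
        return cls(table, **kwargs)

    def fit(self) -> "CalibrationResults":
        cal_fit = fit_calibration(self.table, self.cal_range)
        fisher_F, fisher_ok = fisher_homoscedasticity_test(self.table, self.alpha_fisher)
        lof_F, lof_df, lof_ok = lack_of_fit_test(self.table, cal_fit, self.alpha_linearity)
        man_F, man_df, man_ok = mandel_test(self.table, self.alpha_linearity)
        verdict = LinearityVerdict(
            fisher_F=fisher_F,
            fisher_pass=fisher_ok,
            lof_F=lof_F,
            lof_df=lof_df,
            lof_pass=lof_ok,
            mandel_F=man_F,
            mandel_df=man_df,
            mandel_pass=man_ok,
            alpha=self.alpha_linearity,
        )
        return CalibrationResults(self, cal_fit, verdict)


class CalibrationResults:
    """Fitted calibration line plus diagnostics."""

    def __init__(self, model: CalibrationModel, fit: CalibrationFit, verdict: LinearityVerdict):
        self.model = model
        self.calibration = fit
        self.linearity = verdict

    @property
    def slope(self) -> float:
        return self.calibration.slope

    @property
    def intercept(self) -> float:
        return self.calibration.intercept

    def back_calculate(self, response_ratio: float, **kwargs) -> BackCalcResult:
        return back_calculate(self.calibration, response_ratio, **kwargs)

    def summary(self) -> str:
        c, v = self.calibration, self.linearity
        lines = [
            "Calibration curve (unweighted OLS)",
            "=" * 48,
            f"range            {c.range[0]:g}-{c.range[1]:g} pg/mg   n = {c.n}",
            f"slope            {c.slope:.6g} ratio/(pg/mg)",
            f"intercept        {c.intercept:.6g} ratio",
            f"s_y/x            {c.residual_sd:.6g}   R^2 = {c.r_squared:.5f}",
            "-" * 48,
            f"Fisher F         {v.fisher_F:.4g}   homoscedastic: {'yes' if v.fisher_pass else 'NO'}",
            f"lack-of-fit F    {v.lof_F:.4g} (df {v.lof_df[0]},{v.lof_df[1]})"
            f"   linear: {'yes' if v.lof_pass else 'NO'}",
            f"Mandel F         {v.mandel_F:.4g} (df {v.mandel_df[0]},{v.mandel_df[1]})"
            f"   linear: {'yes' if v.mandel_pass else 'NO'}",
            f"alpha            {v.alpha:g}",
        ]
        return "\n".join(lines)


def rounded_cv_bias(mean: float, sd: float, nominal: float) -> tuple[float, float]:
    """Report-layer rounding: CV% to integer, bias% to one decimal, half-up."""
    cv = 100.0 * sd / mean
    bias = 100.0 * (mean - nominal) / nominal
    return round_half_up(cv, 0), round_half_up(bias, 1)
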