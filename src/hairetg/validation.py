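"""Precision/trueness computation and validation-report assembly.

Precision is the relative standard deviation (RSD% = 100·SD/mean, sample SD
with n−1 denominator) and trueness the signed percentage deviation of the
mean from nominal (bias% = 100·(mean − nominal)/nominal). Intra-day figures
use a single day's replicates; inter-day figures pool every measurement
across days into one sample. Values are kept unrounded in the objects —
half-up rounding to the conventional printed precision (integer RSD, one
decimal bias) happens only at the report layer.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .calibration import CalibrationFit, LinearityVerdict, back_calculate
from .errors import HairEtgError, InsufficientDataError
from .limits import LodResult
from .signal import SRMTrace, integrate_peak
from .util import round_half_up

SCOPE_INTRA_DAY = "intra_day"
SCOPE_INTER_DAY = "inter_day"

DEFAULT_RSD_LIMIT = 15.0  # percent
DEFAULT_BIAS_LIMIT = 20.0  # percent


@dataclass
class QCSeries:
    """Replicated QC measurements at one nominal level."""

    nominal: float  # pg/mg
    measurements: Sequence[tuple[float, str, str]]  # (value pg/mg, day, operator)

    def __post_init__(self):
        if self.nominal <= 0:
            raise ValueError("nominal must be positive")
        if len(self.measurements) < 2:
            raise ValueError("need >= 2 measurements")
        if any(v <= 0 for v, _, _ in self.measurements):
            raise ValueError("measurements must be positive")


@dataclass
class PrecisionResult:
    nominal: float
    scope: str
    mean: float
    sd: float
    rsd_percent: float  # unrounded
    bias_percent: float  # unrounded, signed
    n: int

    def printed(self) -> dict:
        """Half-up rounding to conventional printed precision; bias magnitude."""
        return {
            "nominal_pg_per_mg": self.nominal,
            "scope": self.scope,
            "mean_pg_per_mg": round_half_up(self.mean, 1),
            "sd_pg_per_mg": round_half_up(self.sd, 1),
            "rsd_percent": round_half_up(self.rsd_percent, 0),
            "bias_percent": round_half_up(abs(self.bias_percent), 1),
            "n": self.n,
        }


def precision_trueness(series: QCSeries, scope: str, day: str | None = None) -> PrecisionResult:
    """Mean, SD, RSD% and bias% for one QC level.

    ``intra_day`` restricts to a single day's measurements (the given ``day``,
    or the only day present); ``inter_day`` pools everything and requires at
    least two distinct days.
    """
    if scope == SCOPE_INTRA_DAY:
        days = sorted({d for _, d, _ in series.measurements})
        if day is None:
            if len(days) != 1:
                raise InsufficientDataError(
                    f"intra-day scope needs a single day; found {days}; pass day="
                )
            day = days[0]
        values = [v for v, d, _ in series.measurements if d == day]
        if len(values) < 3:
            raise InsufficientDataError("intra-day precision needs >= 3 replicates")
    elif scope == SCOPE_INTER_DAY:
        days = {d for _, d, _ in series.measurements}
        if len(days) < 2:
            raise InsufficientDataError("inter-day precision needs >= 2 distinct days")
        values = [v for v, _, _ in series.measurements]
    else:
        raise ValueError(f"unknown scope {scope!r}")

    arr = np.asarray(values, dtype=float)
    mean = float(arr.mean())
    sd = float(arr.std(ddof=1))
    return PrecisionResult(
        nominal=series.nominal,
        scope=scope,
        mean=mean,
        sd=sd,
        rsd_percent=100.0 * sd / mean,
        bias_percent=100.0 * (mean - series.nominal) / series.nominal,
        n=len(values),
    )


@dataclass
class InterferenceVerdict:
    passed: bool
    apparent_concentrations: list[float]
    warnings: list[str] = field(default_factory=list)


def interference_check(
    blank_runs: Sequence[Mapping[str, SRMTrace]],
    fit: CalibrationFit,
    lod: float,
    quantifier_id: str,
    internal_standard_id: str,
    window: tuple[float, float],
    qualifier_ids: Sequence[str] = (),
) -> InterferenceVerdict:
    """Selectivity check on blank (teetotaler) hair runs.

    Pass iff every blank's back-calculated apparent concentration in the
    quantifier retention window stays below the LOD. Signal in a qualifier
    window alone does not fail quantitation but is recorded as a warning —
    the known pulverisation interference affects only the 405→331 qualifier.
    """
    apparent = []
    warnings: list[str] = []
    for i, run in enumerate(blank_runs):
        if quantifier_id not in run:
            raise HairEtgError(f"blank run {i}: missing quantifier trace {quantifier_id!r}")
        q_peak = integrate_peak(run[quantifier_id], window)
        if q_peak.area <= 0:
            apparent.append(0.0)
        else:
            if internal_standard_id not in run:
                raise HairEtgError(
                    f"blank run {i}: missing internal-standard trace {internal_standard_id!r}"
                )
            is_peak = integrate_peak(run[internal_standard_id], window)
            if is_peak.area <= 0:
                raise HairEtgError(f"blank run {i}: internal-standard peak area is zero")
            ratio = q_peak.area / is_peak.area
            result = back_calculate(fit, ratio)
            apparent.append(max(0.0, result.concentration))
        for qual in qualifier_ids:
            if qual in run and integrate_peak(run[qual], window).height > 0:
                warnings.append(f"blank run {i}: signal on qualifier {qual!r}")
    return InterferenceVerdict(
        passed=all(c < lod for c in apparent),
        apparent_concentrations=apparent,
        warnings=warnings,
    )


@dataclass
class ValidationReport:
    """Full method-validation report, JSON-serialisable."""

    calibration: CalibrationFit
    linearity: LinearityVerdict
    lod_results: list[LodResult]
    loq: float | None
    qc: list[PrecisionResult]
    interference: InterferenceVerdict | None
    rsd_limit: float
    bias_limit: float
    overall_pass: bool
    reasons: list[str]

    def to_dict(self) -> dict:
        return {
            "calibration": {
                "slope": self.calibration.slope,
                "intercept": self.calibration.intercept,
                "residual_sd": self.calibration.residual_sd,
                "n": self.calibration.n,
                "r_squared": self.calibration.r_squared,
                "range_pg_per_mg": list(self.calibration.range),
            },
            "linearity": {
                "fisher_F": self.linearity.fisher_F,
                "fisher_pass": self.linearity.fisher_pass,
                "lack_of_fit_F": self.linearity.lof_F,
                "lack_of_fit_df": list(self.linearity.lof_df),
                "lack_of_fit_pass": self.linearity.lof_pass,
                "mandel_F": None if np.isinf(self.linearity.mandel_F) else self.linearity.mandel_F,
                "mandel_df": list(self.linearity.mandel_df),
                "mandel_pass": self.linearity.mandel_pass,
                "alpha": self.linearity.alpha,
            },
            "lod": [
                {
                    "method": r.method,
                    "lod_pg_per_mg": r.lod,
                    "decision_limit_pg_per_mg": r.decision_limit,
                    "alpha": r.alpha,
                    "beta": r.beta,
                }
                for r in self.lod_results
            ],
            "loq_pg_per_mg": self.loq,
            "qc": [r.printed() for r in self.qc],
            "interference": None
            if self.interference is None
            else {
                "passed": self.interference.passed,
                "apparent_concentrations_pg_per_mg": self.interference.apparent_concentrations,
                "warnings": self.interference.warnings,
            },
            "limits": {"rsd_percent": self.rsd_limit, "bias_percent": self.bias_limit},
            "overall_pass": self.overall_pass,
            "reasons": self.reasons,
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), indent=2, **kwargs)

    def summary(self) -> str:
        d = self.to_dict()
        lines = [
            "Method validation report",
            "=" * 52,
            f"calibration slope {d['calibration']['slope']:.6g}, "
            f"intercept {d['calibration']['intercept']:.6g}, R^2 {d['calibration']['r_squared']:.5f}",
            f"linearity: lack-of-fit {'pass' if self.linearity.lof_pass else 'FAIL'}, "
            f"Mandel {'pass' if self.linearity.mandel_pass else 'FAIL'} "
            f"(alpha {self.linearity.alpha:g})",
        ]
        for r in self.lod_results:
            lines.append(f"LOD ({r.method}): {r.lod if r.lod is not None else 'undetermined'} pg/mg")
        lines.append(f"LOQ: {self.loq if self.loq is not None else 'undefined'} pg/mg")
        for q in self.qc:
            p = q.printed()
            lines.append(
                f"QC {p['nominal_pg_per_mg']:g} pg/mg ({q.scope}, n={q.n}): "
                f"mean {p['mean_pg_per_mg']}, RSD {p['rsd_percent']:g}%, bias {p['bias_percent']:g}%"
            )
        lines.append(f"overall: {'PASS' if self.overall_pass else 'FAIL'}")
        for reason in self.reasons:
            lines.append(f"  - {reason}")
        return "\n".join(lines)


def assemble_report(
    calibration: CalibrationFit | None = None,
    linearity: LinearityVerdict | None = None,
    lod_results: Sequence[LodResult] = (),
    loq: float | None = None,
    qc: Sequence[PrecisionResult] = (),
    interference: InterferenceVerdict | None = None,
    rsd_limit: float = DEFAULT_RSD_LIMIT,
    bias_limit: float = DEFAULT_BIAS_LIMIT,
) -> ValidationReport:
    """Assemble components into one report with an overall verdict.

    Overall pass requires: linearity accepted by both tests, a defined LOQ,
    every QC level within the RSD and |bias| limits, and (when supplied) a
    passing interference check. Missing mandatory components raise an error
    naming them.
    """
    if calibration is None:
        raise HairEtgError("missing mandatory component: calibration")
    if linearity is None:
        raise HairEtgError("missing mandatory component: linearity")

    reasons = []
    if not (linearity.lof_pass and linearity.mandel_pass):
        reasons.append("linearity rejected")
    if loq is None:
        reasons.append("LOQ undefined")
    for r in qc:
        if r.rsd_percent > rsd_limit:
            reasons.append(f"QC {r.nominal:g} pg/mg ({r.scope}): RSD {r.rsd_percent:.1f}% > {rsd_limit:g}%")
        if abs(r.bias_percent) > bias_limit:
            reasons.append(
                f"QC {r.nominal:g} pg/mg ({r.scope}): |bias| {abs(r.bias_percent):.1f}% > {bias_limit:g}%"
            )
    if interference is not None and not interference.passed:
        reasons.append("interference check failed")

    return ValidationReport(
        calibration=calibration,
        linearity=linearity,
        lod_results=list(lod_results),
        loq=loq,
        qc=list(qc),
        interference=interference,
        rsd_limit=rsd_limit,
        bias_limit=bias_limit,
        overall_pass=not reasons,
        reasons=reasons,
    )
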