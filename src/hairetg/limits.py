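"""Limit-of-detection estimation by two routes.

1. Signal-to-noise: the LOD is the lowest measured concentration whose
   quantifier peak exceeds three times the RMS baseline noise (S/N > 3); no
   interpolation below the lowest qualifying measured level is performed.

2. Hubaux–Vos: from the calibration line's one-sided prediction bands. The
   decision limit x_C is the concentration whose mean response equals the
   upper (1−α) prediction bound of a blank,

       y_C = a + t_{1−α, n−2} · s_{y/x} · sqrt(1 + 1/n + x̄²/S_xx),
       x_C = (y_C − a) / b,

   and the detection limit x_D is the smallest concentration whose lower
   (1−β) prediction bound clears y_C — found by bisection, since x enters the
   band width through (x − x̄)². α controls false positives on blanks, β false
   negatives at the detection limit; with β ≥ α, x_D ≥ x_C ≥ 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import math

import scipy.stats as st

from .calibration import CalibrationFit
from .errors import ConfigurationError, InsufficientDataError

METHOD_SNR = "snr"
METHOD_HUBAUX_VOS = "hubaux_vos"

SNR_THRESHOLD_DEFAULT = 3.0


@dataclass
class LodResult:
    method: str
    lod: float | None  # pg/mg; None = undetermined
    decision_limit: float | None = None  # pg/mg, Hubaux–Vos only
    alpha: float | None = None
    beta: float | None = None
    supporting: object = None

    def __post_init__(self):
        if self.lod is not None and self.lod < 0:
            raise ValueError("lod must be >= 0")
        if (
            self.lod is not None
            and self.decision_limit is not None
            and not self.lod >= self.decision_limit >= 0
        ):
            raise ValueError("require lod >= decision_limit >= 0")

    @property
    def undetermined(self) -> bool:
        return self.lod is None


def lod_from_snr(
    series: Sequence[tuple[float, float]],
    threshold: float = SNR_THRESHOLD_DEFAULT,
) -> LodResult:
    """LOD as the lowest measured concentration with S/N strictly above the
    threshold; undetermined when no level qualifies."""
    if not series:
        raise ValueError("S/N series must be nonempty")
    if any(c <= 0 for c, _ in series):
        raise ValueError("concentrations must be positive")
    qualifying = [c for c, snr in series if snr > threshold]
    lod = min(qualifying) if qualifying else None
    return LodResult(method=METHOD_SNR, lod=lod, supporting=list(series))


def lod_hubaux_vos(
    fit: CalibrationFit,
    alpha: float = 0.05,
    beta: float = 0.05,
    tol: float = 1e-6,
) -> LodResult:
    """Hubaux–Vos decision and detection limits from a fitted calibration line."""
    if not (0 < alpha < 1 and 0 < beta < 1):
        raise ConfigurationError("alpha and beta must be in (0, 1)")
    if fit.slope <= 0:
        raise ConfigurationError("calibration slope must be positive")
    if fit.n < 4:
        raise InsufficientDataError("Hubaux-Vos requires n >= 4 calibration points")
    if fit.residual_sd is None or not math.isfinite(fit.residual_sd):
        raise ConfigurationError("residual SD undefined")

    s = fit.residual_sd
    if s == 0:
        return LodResult(
            method=METHOD_HUBAUX_VOS, lod=0.0, decision_limit=0.0, alpha=alpha, beta=beta
        )

    n, a, b = fit.n, fit.intercept, fit.slope
    t_a = st.t.ppf(1 - alpha, n - 2)
    t_b = st.t.ppf(1 - beta, n - 2)

    def band(x: float) -> float:
        return s * math.sqrt(1.0 + 1.0 / n + (x - fit.mean_x) ** 2 / fit.sxx)

    y_c = a + t_a * band(0.0)
    x_c = (y_c - a) / b

    # lower (1-beta) prediction bound at x must clear y_C
    def clears(x: float) -> bool:
        return a + b * x - t_b * band(x) >= y_c

    lo, hi = x_c, max(2.0 * x_c, 1.0)
    while not clears(hi):
        hi *= 2.0
        if hi > 1e12:
            raise ConfigurationError("detection-limit search failed to bracket")
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if clears(mid):
            hi = mid
        else:
            lo = mid
    x_d = 0.5 * (lo + hi)
    return LodResult(
        method=METHOD_HUBAUX_VOS,
        lod=float(x_d),
        decision_limit=float(x_c),
        alpha=alpha,
        beta=beta,
        supporting=fit,
    )
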