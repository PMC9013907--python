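"""SRM chromatogram processing.

Selected-reaction-monitoring (SRM) acquisition records one intensity trace per
precursor→product transition. Quantitation of hair EtG uses the ratio of the
analyte quantifier peak area (m/z 405→359 for the TMS derivative) to the
deuterated internal-standard area (410→359), while the 405→331 and 405→287
qualifier transitions confirm analyte identity through their area ratios to
the quantifier.

This module integrates peaks over caller-supplied retention windows, estimates
baseline noise as detrended RMS, and checks qualifier ion ratios against
reference ratios within a relative tolerance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .errors import (
    ContaminationError,
    HairEtgError,
    ResolutionError,
    WindowError,
)

ROLE_QUANTIFIER = "quantifier"
ROLE_QUALIFIER = "qualifier"
ROLE_INTERNAL_STANDARD = "internal_standard"

_VALID_ROLES = {ROLE_QUANTIFIER, ROLE_QUALIFIER, ROLE_INTERNAL_STANDARD}


@dataclass(frozen=True)
class Transition:
    """A single SRM transition (precursor → product, in thomson)."""

    precursor_mz: float
    product_mz: float
    collision_energy: float
    role: str

    def __post_init__(self):
        if self.product_mz >= self.precursor_mz:
            raise ValueError(
                f"product m/z {self.product_mz} must be below precursor "
                f"m/z {self.precursor_mz}"
            )
        if self.collision_energy <= 0:
            raise ValueError("collision energy must be positive")
        if self.role not in _VALID_ROLES:
            raise ValueError(f"unknown transition role {self.role!r}")

    @property
    def label(self) -> str:
        return f"{self.precursor_mz:g}->{self.product_mz:g}"


@dataclass(frozen=True)
class SRMMethod:
    """An acquisition method: one quantifier, one internal standard, ≥1 qualifier."""

    transitions: tuple[Transition, ...]

    def __post_init__(self):
        roles = [t.role for t in self.transitions]
        if roles.count(ROLE_QUANTIFIER) != 1:
            raise ValueError("method requires exactly one quantifier transition")
        if roles.count(ROLE_INTERNAL_STANDARD) != 1:
            raise ValueError("method requires exactly one internal-standard transition")
        if roles.count(ROLE_QUALIFIER) < 1:
            raise ValueError("method requires at least one qualifier transition")

    @property
    def quantifier(self) -> Transition:
        return next(t for t in self.transitions if t.role == ROLE_QUANTIFIER)

    @property
    def internal_standard(self) -> Transition:
        return next(t for t in self.transitions if t.role == ROLE_INTERNAL_STANDARD)

    @property
    def qualifiers(self) -> tuple[Transition, ...]:
        return tuple(t for t in self.transitions if t.role == ROLE_QUALIFIER)


def etg_tms_method() -> SRMMethod:
    """The EtG-TMS / EtG-D5-TMS method: 405→359 (quant), 410→359 (IS),
    405→331 and 405→287 (qualifiers), all at 10 V collision energy."""
    return SRMMethod(
        transitions=(
            Transition(405.0, 359.0, 10.0, ROLE_QUANTIFIER),
            Transition(410.0, 359.0, 10.0, ROLE_INTERNAL_STANDARD),
            Transition(405.0, 331.0, 10.0, ROLE_QUALIFIER),
            Transition(405.0, 287.0, 10.0, ROLE_QUALIFIER),
        )
    )


@dataclass
class SRMTrace:
    """One transition's intensity-vs-time trace.

    ``transition`` may be a :class:`Transition` or a plain identifier string
    (simulated traces carry the id they were generated under).
    """

    transition: Transition | str
    times: np.ndarray
    intensities: np.ndarray

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.times.shape != self.intensities.shape:
            raise ValueError("times and intensities must have equal length")
        if self.times.size >= 2 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")

    def window_mask(self, t_start: float, t_end: float) -> np.ndarray:
        return (self.times >= t_start) & (self.times <= t_end)


@dataclass
class PeakResult:
    """Integrated peak: height/area above an interpolated local baseline."""

    retention_time: float
    height: float
    area: float
    noise_rms: float | None = None
    snr: float | None = None


@dataclass
class IonRatioVerdict:
    qualifier: str
    observed_ratio: float | None
    reference_ratio: float
    compliant: bool
    reason: str = ""


@dataclass
class IonRatioReport:
    per_qualifier: dict[str, IonRatioVerdict] = field(default_factory=dict)

    @property
    def compliant(self) -> bool:
        return all(v.compliant for v in self.per_qualifier.values())


def integrate_peak(
    trace: SRMTrace,
    window: tuple[float, float],
    noise_rms: float | None = None,
    baseline: str | float = "edges",
) -> PeakResult:
    """Integrate the peak inside ``window`` = (t_start, t_end).

    By default the local baseline is the straight line joining the medians of
    the first and last few samples of the window ("edges"); pass a float to
    use a known constant baseline instead (e.g. when integrating a half
    window whose edge sits on the peak itself). Height is the maximum of the
    baseline-subtracted signal and area its trapezoidal integral (floored at
    zero). Supplying ``noise_rms`` also populates the S/N ratio.
    """
    t_start, t_end = window
    if t_start < trace.times[0] or t_end > trace.times[-1] or t_start >= t_end:
        raise WindowError(
            f"window ({t_start}, {t_end}) outside trace range "
            f"({trace.times[0]}, {trace.times[-1]})"
        )
    mask = trace.window_mask(t_start, t_end)
    n = int(mask.sum())
    if n < 5:
        raise ResolutionError(f"window contains {n} samples; at least 5 required")

    t = trace.times[mask]
    y = trace.intensities[mask]
    if baseline == "edges":
        edge = max(1, min(5, n // 5))
        left = float(np.median(y[:edge]))
        right = float(np.median(y[-edge:]))
        base = np.interp(t, [t[0], t[-1]], [left, right])
    elif isinstance(baseline, (int, float)):
        base = np.full(n, float(baseline))
    else:
        raise ValueError(f"unknown baseline mode {baseline!r}")
    corrected = y - base

    i_max = int(np.argmax(corrected))
    height = max(0.0, float(corrected[i_max]))
    area = max(0.0, float(np.trapezoid(corrected, t)))
    snr = None
    if noise_rms is not None and noise_rms > 0:
        snr = height / noise_rms
    return PeakResult(
        retention_time=float(t[i_max]),
        height=height,
        area=area,
        noise_rms=noise_rms,
        snr=snr,
    )


def estimate_noise_rms(
    trace: SRMTrace,
    region: tuple[float, float],
    peak_windows: Sequence[tuple[float, float]] = (),
) -> float:
    """RMS baseline noise over a peak-free region.

    A linear trend is removed first so slow baseline drift does not inflate
    the estimate; the result is the root-mean-square of the residuals, the
    reproducible analogue of vendor auto-RMS noise readouts.
    """
    t_start, t_end = region
    if t_start < trace.times[0] or t_end > trace.times[-1] or t_start >= t_end:
        raise WindowError(f"noise region ({t_start}, {t_end}) outside trace range")
    for w0, w1 in peak_windows:
        if t_start < w1 and w0 < t_end:
            raise ContaminationError(
                f"noise region ({t_start}, {t_end}) overlaps peak window ({w0}, {w1})"
            )
    mask = trace.window_mask(t_start, t_end)
    n = int(mask.sum())
    if n < 20:
        raise ResolutionError(f"noise region contains {n} samples; at least 20 required")
    t = trace.times[mask]
    y = trace.intensities[mask]
    coef = np.polyfit(t, y, 1)
    resid = y - np.polyval(coef, t)
    return float(math.sqrt(np.mean(resid**2)))


def check_ion_ratios(
    peaks: Mapping[str, PeakResult],
    quantifier: str,
    reference_ratios: Mapping[str, float],
    tolerance: float = 0.20,
) -> IonRatioReport:
    """Check qualifier/quantifier area ratios against reference ratios.

    A qualifier is compliant iff |observed − reference| ≤ tolerance·reference.
    A missing qualifier peak is reported non-compliant with reason "absent".
    """
    if quantifier not in peaks:
        raise HairEtgError(f"quantifier peak {quantifier!r} missing")
    quant_area = peaks[quantifier].area
    if quant_area <= 0:
        raise HairEtgError("quantifier peak area must be positive")
    if tolerance <= 0:
        raise ValueError("tolerance must be positive")

    report = IonRatioReport()
    for qual, ref in reference_ratios.items():
        if qual not in peaks:
            report.per_qualifier[qual] = IonRatioVerdict(
                qualifier=qual,
                observed_ratio=None,
                reference_ratio=ref,
                compliant=False,
                reason="absent",
            )
            continue
        observed = peaks[qual].area / quant_area
        ok = abs(observed - ref) <= tolerance * ref
        report.per_qualifier[qual] = IonRatioVerdict(
            qualifier=qual,
            observed_ratio=observed,
            reference_ratio=ref,
            compliant=ok,
            reason="" if ok else "ratio outside tolerance",
        )
    return report


def learn_reference_ratios(
    standard_peaks: Sequence[Mapping[str, PeakResult]],
    quantifier: str,
    qualifiers: Sequence[str],
) -> dict[str, float]:
    """Mean qualifier/quantifier area ratio across calibration standards."""
    ratios: dict[str, list[float]] = {q: [] for q in qualifiers}
    for run in standard_peaks:
        if quantifier not in run or run[quantifier].area <= 0:
            continue
        qa = run[quantifier].area
        for q in qualifiers:
            if q in run:
                ratios[q].append(run[q].area / qa)
    out = {}
    for q, vals in ratios.items():
        if not vals:
            raise HairEtgError(f"no standards contain qualifier {q!r}")
        out[q] = float(np.mean(vals))
    return out
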