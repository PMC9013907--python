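"""Synthetic-data generators with the statistical structure the analysis assumes.

Four generators cover the pipeline's inputs:

* SRM chromatogram traces — Gaussian peaks over i.i.d. Gaussian baseline
  noise, with an optional interfering peak on a qualifier transition (the
  failure mode ball-mill pulverisation induces on the 405→331 channel of real
  hair extracts).
* Calibration tables — response ratio linear (optionally quadratic) in
  concentration with constant-SD or proportional-CV noise; defaults mirror
  the working curve (6, 10, 20, 30, 60 pg/mg, three replicates).
* Replicated 2^k factorial response tables in standard Yates run order with
  specified true effects.
* Drinking-category-labelled cohorts with log-normal per-class concentrations
  and LOD/LOQ left-censoring.

All generators are deterministic given their seed; with zero noise each is
exactly its mean model.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cohort import BELOW_LOD, CohortRecord, DRINKING_CLASSES, EtgResult, censor
from .errors import InvalidSpecError
from .signal import SRMTrace

DEFAULT_CAL_LEVELS = (6.0, 10.0, 20.0, 30.0, 60.0)  # pg/mg, low working curve


def yates_labels(k: int) -> list[str]:
    """Standard Yates run order for a 2^k design: 0, a, b, ab, c, ac, bc, abc, …"""
    letters = "abcdefgh"[:k]
    labels = []
    for i in range(2**k):
        lab = "".join(letters[j] for j in range(k) if i >> j & 1)
        labels.append(lab or "0")
    return labels


def effect_labels(k: int, max_order: int | None = None) -> list[str]:
    """All nonempty factor subsets (a, b, ab, …) up to ``max_order``, in
    Yates order."""
    max_order = k if max_order is None else max_order
    letters = "abcdefgh"[:k]
    out = []
    for lab in yates_labels(k)[1:]:
        if len(lab) <= max_order:
            out.append(lab)
    return out


@dataclass(frozen=True)
class GaussianPeak:
    transition: str
    retention_time: float  # s
    height: float  # counts above baseline
    sigma: float  # s


@dataclass
class TraceSpec:
    """Specification of a set of simulated SRM traces (one per transition)."""

    transitions: Sequence[str]
    duration: float = 60.0  # s
    sampling_interval: float = 0.1  # s
    peaks: Sequence[GaussianPeak] = ()
    baseline_level: float = 100.0  # counts
    noise_sd: float = 0.0  # counts
    interference: GaussianPeak | None = None
    seed: int = 0

    def __post_init__(self):
        self.peaks = tuple(
            p if isinstance(p, GaussianPeak) else GaussianPeak(*p) for p in self.peaks
        )
        if self.interference is not None and not isinstance(self.interference, GaussianPeak):
            self.interference = GaussianPeak(*self.interference)
        if not self.transitions:
            raise InvalidSpecError("transitions", "must be nonempty")
        if self.sampling_interval <= 0:
            raise InvalidSpecError("sampling_interval", "must be > 0")
        if self.duration <= 0:
            raise InvalidSpecError("duration", "must be > 0")
        if self.noise_sd < 0:
            raise InvalidSpecError("noise_sd", "must be >= 0")
        for p in self.peaks:
            if p.height < 0:
                raise InvalidSpecError("peaks", f"peak height {p.height} < 0")
            if not 0 <= p.retention_time <= self.duration:
                raise InvalidSpecError(
                    "peaks", f"retention time {p.retention_time} outside [0, duration]"
                )
            if p.transition not in self.transitions:
                raise InvalidSpecError("peaks", f"unknown transition {p.transition!r}")


def simulate_traces(spec: TraceSpec) -> dict[str, SRMTrace]:
    """Generate one trace per transition: baseline + Gaussian peaks + noise.

    The optional interference peak is added to its transition on top of any
    declared analyte peaks.
    """
    rng = np.random.default_rng(spec.seed)
    n = int(np.floor(spec.duration / spec.sampling_interval)) + 1
    times = np.arange(n) * spec.sampling_interval
    traces = {}
    for tid in spec.transitions:
        signal = np.full(n, float(spec.baseline_level))
        for p in spec.peaks:
            if p.transition == tid:
                signal += p.height * np.exp(-0.5 * ((times - p.retention_time) / p.sigma) ** 2)
        if spec.interference is not None and spec.interference.transition == tid:
            p = spec.interference
            signal += p.height * np.exp(-0.5 * ((times - p.retention_time) / p.sigma) ** 2)
        if spec.noise_sd > 0:
            signal = signal + rng.normal(0.0, spec.noise_sd, size=n)
        traces[tid] = SRMTrace(transition=tid, times=times, intensities=signal)
    return traces


NOISE_CONSTANT_SD = "constant_sd"
NOISE_PROPORTIONAL_CV = "proportional_cv"


@dataclass
class CalibrationSimSpec:
    """Specification of a simulated calibration response table."""

    levels: Sequence[float] = DEFAULT_CAL_LEVELS  # pg/mg
    replicates_per_level: int = 3
    slope: float = 0.01  # response ratio per pg/mg
    intercept: float = 0.0
    noise_model: str = NOISE_CONSTANT_SD
    noise_param: float = 0.0  # SD (ratio units) or CV (fraction)
    curvature: float = 0.0  # ratio per (pg/mg)^2
    seed: int = 0

    def __post_init__(self):
        levels = tuple(float(x) for x in self.levels)
        if not levels or any(x <= 0 for x in levels):
            raise InvalidSpecError("levels", "must be strictly positive")
        if any(b <= a for a, b in zip(levels, levels[1:])):
            raise InvalidSpecError("levels", "must be strictly increasing")
        self.levels = levels
        if self.replicates_per_level < 1:
            raise InvalidSpecError("replicates_per_level", "must be >= 1")
        if self.noise_param < 0:
            raise InvalidSpecError("noise_param", "must be >= 0")
        if self.noise_model not in (NOISE_CONSTANT_SD, NOISE_PROPORTIONAL_CV):
            raise InvalidSpecError("noise_model", f"unknown model {self.noise_model!r}")


def simulate_calibration(spec: CalibrationSimSpec) -> pd.DataFrame:
    """Calibration table with columns nominal_pg_per_mg, response_ratio, replicate.

    The mean response at level x is intercept + slope·x + curvature·x²; noise
    is Gaussian with constant SD or with SD proportional to the mean (CV).
    """
    rng = np.random.default_rng(spec.seed)
    rows = []
    for x in spec.levels:
        mu = spec.intercept + spec.slope * x + spec.curvature * x * x
        for rep in range(spec.replicates_per_level):
            if spec.noise_param == 0:
                y = mu
            elif spec.noise_model == NOISE_CONSTANT_SD:
                y = mu + rng.normal(0.0, spec.noise_param)
            else:
                y = mu + rng.normal(0.0, abs(mu) * spec.noise_param)
            rows.append({"nominal_pg_per_mg": x, "response_ratio": y, "replicate": rep})
    return pd.DataFrame(rows)


@dataclass
class FactorialSimSpec:
    """Specification of a replicated 2^k factorial response table."""

    k: int = 3
    true_effects: Mapping[str, float] = field(default_factory=dict)  # pg/mg
    grand_mean: float = 150.0  # pg/mg
    replicate_blocks: int = 1
    noise_sd: float = 0.0  # pg/mg
    seed: int = 0

    def __post_init__(self):
        if self.k < 2:
            raise InvalidSpecError("k", "must be >= 2")
        if self.noise_sd < 0:
            raise InvalidSpecError("noise_sd", "must be >= 0")
        if self.replicate_blocks < 1:
            raise InvalidSpecError("replicate_blocks", "must be >= 1")
        valid = set(effect_labels(self.k))
        for label in self.true_effects:
            if label not in valid:
                raise InvalidSpecError(
                    "true_effects", f"unknown effect label {label!r} for k={self.k}"
                )


def coded_levels(k: int) -> pd.DataFrame:
    """Coded ±1 design matrix for a 2^k design in Yates run order."""
    letters = "abcdefgh"[:k]
    labels = yates_labels(k)
    data = {
        letter: [1 if letter in lab else -1 for lab in labels] for letter in letters
    }
    return pd.DataFrame(data, index=pd.Index(labels, name="run_label"))


def simulate_factorial(spec: FactorialSimSpec) -> pd.DataFrame:
    """DoE table in Yates order: block, run_label, coded factors, response.

    Each run's mean is grand_mean + Σ (effect/2)·Π coded levels, so the
    downstream contrast estimator (mean-high minus mean-low) recovers the
    specified effect sizes exactly at zero noise.
    """
    rng = np.random.default_rng(spec.seed)
    design = coded_levels(spec.k)
    rows = []
    for block in range(spec.replicate_blocks):
        for label, codes in design.iterrows():
            mu = spec.grand_mean
            for eff_label, eff in spec.true_effects.items():
                mu += (eff / 2.0) * np.prod([codes[f] for f in eff_label])
            y = mu + (rng.normal(0.0, spec.noise_sd) if spec.noise_sd > 0 else 0.0)
            row = {"block": block, "run_label": label}
            row.update({f: int(codes[f]) for f in design.columns})
            row["response_pg_per_mg"] = y
            rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class CohortSimSpec:
    """Specification of a simulated cohort of censored EtG results."""

    category_sizes: Mapping[str, int] = field(
        default_factory=lambda: {"Teetotal": 6, "Light": 6, "Social": 4, "Moderate": 6, "Heavy": 3}
    )
    lognormal_params: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {
            # (median pg/mg, geometric SD); medians follow the observed class
            # centres: teetotalers ≈1 pg/mg, heavy drinkers ≈120 pg/mg
            "Teetotal": (1.0, 1.5),
            "Light": (3.0, 1.8),
            "Social": (15.0, 1.6),
            "Moderate": (45.0, 2.2),
            "Heavy": (120.0, 1.6),
        }
    )
    lod: float = 4.0  # pg/mg
    loq: float = 6.0  # pg/mg
    seed: int = 0

    def __post_init__(self):
        if not (0 < self.lod <= self.loq):
            raise InvalidSpecError("lod", f"require 0 < lod <= loq, got {self.lod}, {self.loq}")
        for cls, n in self.category_sizes.items():
            if cls not in DRINKING_CLASSES:
                raise InvalidSpecError("category_sizes", f"unknown class {cls!r}")
            if n < 0:
                raise InvalidSpecError("category_sizes", "counts must be >= 0")
        for cls, (med, gsd) in self.lognormal_params.items():
            if med < 0:
                raise InvalidSpecError("lognormal_params", f"median {med} < 0")
            if med > 0 and gsd < 1:
                raise InvalidSpecError("lognormal_params", "geometric SD must be >= 1")


def simulate_cohort(spec: CohortSimSpec) -> list[CohortRecord]:
    """Cohort records with log-normal per-class concentrations and censoring.

    A class median of zero yields all-censored records (below LOD). Subject
    metadata (age, sex, hair length) is filled with plausible draws; it is
    carried through reporting but never enters the numbers.
    """
    rng = np.random.default_rng(spec.seed)
    records = []
    counter = itertools.count(1)
    for cls, n in spec.category_sizes.items():
        med, gsd = spec.lognormal_params.get(cls, (0.0, 1.0))
        for _ in range(n):
            if med <= 0:
                etg = EtgResult(BELOW_LOD)
            else:
                conc = float(rng.lognormal(mean=np.log(med), sigma=np.log(gsd)))
                etg = censor(conc, spec.lod, spec.loq)
            records.append(
                CohortRecord(
                    subject_id=f"S{next(counter):03d}",
                    age=int(rng.integers(18, 70)),
                    sex=str(rng.choice(["M", "F"])),
                    hair_length_cm=float(rng.uniform(3, 6)),
                    hair_color=str(rng.choice(["Brown", "Black", "Blond", "Grizzled"])),
                    cosmetic_treatment=bool(rng.random() < 0.2),
                    declared_class=cls,
                    etg=etg,
                )
            )
    return records


@dataclass
class QCSimSpec:
    """Replicated QC measurements at a nominal level with known CV and bias."""

    nominal: float  # pg/mg
    cv: float = 0.10  # fractional
    bias: float = 0.0  # fractional, signed
    n_days: int = 3
    replicates_per_day: int = 3
    seed: int = 0

    def __post_init__(self):
        if self.nominal <= 0:
            raise InvalidSpecError("nominal", "must be > 0")
        if self.cv < 0:
            raise InvalidSpecError("cv", "must be >= 0")


def simulate_qc(spec: QCSimSpec) -> pd.DataFrame:
    """QC table with columns nominal_pg_per_mg, value_pg_per_mg, day, operator."""
    rng = np.random.default_rng(spec.seed)
    mu = spec.nominal * (1.0 + spec.bias)
    rows = []
    for day in range(spec.n_days):
        for _ in range(spec.replicates_per_day):
            v = mu * (1.0 + rng.normal(0.0, spec.cv)) if spec.cv > 0 else mu
            rows.append(
                {
                    "nominal_pg_per_mg": spec.nominal,
                    "value_pg_per_mg": v,
                    "day": day,
                    "operator": f"op{day}",
                }
            )
    return pd.DataFrame(rows)
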