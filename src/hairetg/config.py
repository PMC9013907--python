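"""Pipeline configuration.

One object houses every tunable the stages share: test significance levels,
the ion-ratio identification tolerance, QC acceptance limits, the SoHT
cut-off, the calibration ranges, and the reference hair aliquot mass.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import yaml

from .errors import ConfigurationError


@dataclass
class PipelineConfig:
    alpha_fisher: float = 0.01
    alpha_linearity: float = 0.05
    alpha_hubaux_vos: float = 0.05
    beta_hubaux_vos: float = 0.05
    ion_ratio_tolerance: float = 0.20  # relative fraction
    rsd_limit_percent: float = 15.0
    bias_limit_percent: float = 20.0
    cutoff_pg_per_mg: float = 30.0  # SoHT chronic-excessive-drinking cut-off
    lod_pg_per_mg: float | None = None  # override; default: estimated
    loq_pg_per_mg: float | None = None
    low_range: tuple[float, float] = (6.0, 60.0)
    high_range: tuple[float, float] = (60.0, 300.0)
    reference_mass_mg: float = 50.0
    effect_threshold_pg_per_mg: float = 19.71
    seed: int = 0

    def __post_init__(self):
        for name in ("alpha_fisher", "alpha_linearity", "alpha_hubaux_vos", "beta_hubaux_vos"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ConfigurationError(f"{name} must be in (0, 1), got {v}")
        for name in (
            "ion_ratio_tolerance",
            "rsd_limit_percent",
            "bias_limit_percent",
            "cutoff_pg_per_mg",
            "reference_mass_mg",
            "effect_threshold_pg_per_mg",
        ):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        self.low_range = tuple(self.low_range)
        self.high_range = tuple(self.high_range)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigurationError("config file must contain a mapping")
        return cls.from_dict(data)
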