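"""Censoring-aware interpretation of cohort EtG results.

Hair EtG is reported against the Society of Hair Testing (SoHT) cut-off of
30 pg/mg for chronic excessive drinking. Results below the limit of detection
or quantification are reported only as "<LOD" / "<LOQ" — they are never
imputed with LOD/2-style substitutes. Class summaries therefore compute order
statistics on quantified values only, while censored records still count
toward class sizes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .errors import ConfigurationError

BELOW_LOD = "below_lod"
BELOW_LOQ = "below_loq"
QUANTIFIED = "quantified"

#: declared drinking classes, ordered by weekly alcohol units
DRINKING_CLASSES = ("Teetotal", "Light", "Social", "Moderate", "Heavy")

EXCEEDS_CUTOFF = "exceeds_cutoff"
BELOW_CUTOFF = "below_cutoff"
NOT_ASSESSABLE_ABSTINENCE = "not_assessable_abstinence"

#: abstinence assessment requires a method LOQ at or below this (pg/mg)
ABSTINENCE_LOQ_REQUIREMENT = 5.0


@dataclass(frozen=True)
class EtgResult:
    """A possibly left-censored concentration (pg/mg)."""

    kind: str  # quantified | below_loq | below_lod
    value: float | None = None

    def __post_init__(self):
        if self.kind not in (QUANTIFIED, BELOW_LOQ, BELOW_LOD):
            raise ValueError(f"unknown result kind {self.kind!r}")
        if self.kind == QUANTIFIED and (self.value is None or self.value < 0):
            raise ValueError("quantified result requires a non-negative value")

    @property
    def censored(self) -> bool:
        return self.kind != QUANTIFIED

    def __str__(self) -> str:
        if self.kind == BELOW_LOD:
            return "<LOD"
        if self.kind == BELOW_LOQ:
            return "<LOQ"
        return f"{self.value:g}"


@dataclass
class CohortRecord:
    subject_id: str
    age: int
    sex: str
    hair_length_cm: float
    hair_color: str
    cosmetic_treatment: bool
    declared_class: str
    etg: EtgResult

    def __post_init__(self):
        if self.declared_class not in DRINKING_CLASSES:
            raise ValueError(f"unknown drinking class {self.declared_class!r}")
        if self.hair_length_cm <= 0:
            raise ValueError("hair length must be positive")


@dataclass
class ClassSummary:
    drinking_class: str
    n: int
    n_quantified: int
    minimum: float | None
    median: float | None
    maximum: float | None
    n_above_cutoff: int


def censor(
    concentration: float | None,
    lod: float,
    loq: float,
    below_zero: bool = False,
) -> EtgResult:
    """Map a back-calculated concentration onto the reporting bands.

    Values below the LOD (including negative back-calculations, flagged via
    ``below_zero``) report as <LOD; values in [LOD, LOQ) as <LOQ; the rest are
    quantified.
    """
    if not (0 < lod <= loq):
        raise ConfigurationError(f"require 0 < lod <= loq, got lod={lod}, loq={loq}")
    if below_zero or concentration is None or concentration < lod:
        return EtgResult(BELOW_LOD)
    if concentration < loq:
        return EtgResult(BELOW_LOQ)
    return EtgResult(QUANTIFIED, float(concentration))


def classify_vs_cutoff(
    record: CohortRecord,
    cutoff: float = 30.0,
    method_loq: float | None = None,
    abstinence_query: bool = False,
) -> str:
    """Classify one subject against the SoHT chronic-excessive-drinking cut-off.

    A quantified value at or above the cut-off exceeds it; censored results and
    quantified values below it do not. An abstinence assessment is only
    meaningful when the method LOQ is at or below 5 pg/mg; otherwise it is
    reported as not assessable regardless of the measured value.
    """
    if cutoff <= 0:
        raise ConfigurationError("cutoff must be positive")
    if abstinence_query:
        if method_loq is None or method_loq > ABSTINENCE_LOQ_REQUIREMENT:
            return NOT_ASSESSABLE_ABSTINENCE
    if record.etg.kind == QUANTIFIED and record.etg.value >= cutoff:
        return EXCEEDS_CUTOFF
    return BELOW_CUTOFF


def summarize_by_class(
    records: Sequence[CohortRecord],
    cutoff: float = 30.0,
) -> list[ClassSummary]:
    """Per-class counts and quantified-only order statistics.

    Censored records contribute to ``n`` but not to min/median/max, matching
    the reporting convention for left-censored biomarker panels. Classes are
    returned in increasing declared-consumption order.
    """
    if not records:
        raise ValueError("records must be nonempty")
    if cutoff <= 0:
        raise ConfigurationError("cutoff must be positive")
    out = []
    for cls in DRINKING_CLASSES:
        members = [r for r in records if r.declared_class == cls]
        if not members:
            continue
        quantified = [r.etg.value for r in members if r.etg.kind == QUANTIFIED]
        above = sum(1 for v in quantified if v >= cutoff)
        if quantified:
            out.append(
                ClassSummary(
                    drinking_class=cls,
                    n=len(members),
                    n_quantified=len(quantified),
                    minimum=float(min(quantified)),
                    median=float(np.median(quantified)),
                    maximum=float(max(quantified)),
                    n_above_cutoff=above,
                )
            )
        else:
            out.append(
                ClassSummary(
                    drinking_class=cls,
                    n=len(members),
                    n_quantified=0,
                    minimum=None,
                    median=None,
                    maximum=None,
                    n_above_cutoff=0,
                )
            )
    return out


def list_anomalies(records: Iterable[CohortRecord]) -> list[str]:
    """Subjects whose declared consumption (Moderate or above) is discordant
    with a censored result. Reported as a listed anomaly only — self-declared
    consumption is known to be unreliable, so no numeric adjustment follows."""
    threshold = DRINKING_CLASSES.index("Moderate")
    return [
        r.subject_id
        for r in records
        if DRINKING_CLASSES.index(r.declared_class) >= threshold and r.etg.censored
    ]


def plot_class_boxes(records: Sequence[CohortRecord], cutoff: float = 30.0, path=None):
    """Box plot of quantified EtG per declared class with the cut-off line.

    Returns the matplotlib figure; writes to ``path`` when given.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    classes = [c for c in DRINKING_CLASSES if any(r.declared_class == c for r in records)]
    data = [
        [r.etg.value for r in records if r.declared_class == c and not r.etg.censored]
        for c in classes
    ]
    fig, ax = plt.subplots()
    ax.boxplot(data, tick_labels=[f"{c} (n={sum(1 for r in records if r.declared_class == c)})" for c in classes])
    ax.axhline(cutoff, linestyle="--", color="grey")
    ax.set_ylabel("EtG (pg/mg)")
    if path is not None:
        fig.savefig(path)
    return fig
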