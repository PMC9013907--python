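"""2^k full-factorial design-of-experiments analysis.

The hair-pretreatment optimisation varies three two-level factors —
(a) washing rigour, (b) incubation/extraction conditions, (c) shredding
(scissor-cut vs ball-mill pulverisation) — in a full 2³ design on aliquots of
the same hair. An effect is the Montgomery-convention contrast,

    effect(S) = mean(response | Π coded = +1) − mean(response | Π coded = −1)
              = contrast / 2^(k−1),

i.e. contrast/4 for k = 3. Significance can be flagged three ways: against a
fixed pg/mg threshold, by a paired t-test across replicate blocks, or by
Lenth's pseudo-standard-error method for unreplicated designs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats as st

from .errors import ConfigurationError, DesignError
from .simulate import coded_levels, effect_labels, yates_labels
from .util import round_half_up

MODE_FIXED_THRESHOLD = "fixed_threshold"
MODE_REPLICATE_T = "replicate_t"
MODE_LENTH = "lenth"

#: pg/mg significance threshold used for the packaged pretreatment study
DEFAULT_EFFECT_THRESHOLD = 19.71

FACTOR_DESCRIPTIONS = {
    "a": "washing procedure (mild vortex wash vs quadruple wash)",
    "b": "incubation (2 h sonication at 50 degC vs overnight at 60 degC)",
    "c": "shredding (scissor cut vs ball-mill pulverisation)",
}


@dataclass
class DoETable:
    """A replicated 2^k design table, validated and held in Yates run order.

    ``data`` columns: block, run_label, one ±1 column per factor letter,
    response_pg_per_mg.
    """

    data: pd.DataFrame
    factors: tuple[str, ...] = ("a", "b", "c")

    def __post_init__(self):
        required = {"block", "run_label", "response_pg_per_mg", *self.factors}
        missing = required - set(self.data.columns)
        if missing:
            raise DesignError(f"DoE table missing columns {sorted(missing)}")
        k = len(self.factors)
        expected = set(yates_labels(k))
        design = coded_levels(k)
        for block, grp in self.data.groupby("block"):
            labels = set(grp["run_label"])
            absent = expected - labels
            if absent:
                raise DesignError(
                    f"block {block!r} missing runs {sorted(absent)}"
                )
            if len(grp) != 2**k:
                raise DesignError(f"block {block!r} must have exactly {2**k} runs")
            for _, row in grp.iterrows():
                want = design.loc[row["run_label"]]
                for f in self.factors:
                    if int(row[f]) != int(want[f]):
                        raise DesignError(
                            f"run {row['run_label']!r} has coded level {row[f]} "
                            f"for factor {f!r}; label implies {want[f]}"
                        )
        # canonical Yates ordering within blocks
        order = {lab: i for i, lab in enumerate(yates_labels(k))}
        self.data = (
            self.data.assign(_o=self.data["run_label"].map(order))
            .sort_values(["block", "_o"])
            .drop(columns="_o")
            .reset_index(drop=True)
        )

    @property
    def k(self) -> int:
        return len(self.factors)

    @property
    def n_blocks(self) -> int:
        return self.data["block"].nunique()

    def block_responses(self) -> pd.DataFrame:
        """Responses as a (block × run_label) matrix in Yates column order."""
        wide = self.data.pivot(index="block", columns="run_label", values="response_pg_per_mg")
        return wide[yates_labels(self.k)]

    def mean_responses(self) -> pd.Series:
        return self.block_responses().mean(axis=0)


@dataclass
class EffectEstimate:
    label: str
    value: float  # pg/mg
    significant: bool | None = None
    threshold: float | None = None
    test_meta: dict = field(default_factory=dict)


def _as_table(table: DoETable | pd.DataFrame) -> DoETable:
    if isinstance(table, DoETable):
        return table
    factors = tuple(c for c in "abcdefgh" if c in table.columns)
    return DoETable(table, factors=factors)


def estimate_effects(
    table: DoETable | pd.DataFrame,
    max_order: int | None = None,
) -> list[EffectEstimate]:
    """Contrast-based effect estimates from block-averaged responses.

    effect(S) = (1/2^(k−1)) Σ_runs response · Π_{f∈S} coded_level_f, for every
    nonempty factor subset S up to ``max_order`` (default: all orders).
    """
    t = _as_table(table)
    design = coded_levels(t.k)
    means = t.mean_responses()
    estimates = []
    for label in effect_labels(t.k, max_order):
        signs = np.ones(len(design))
        for f in label:
            signs = signs * design[f].to_numpy()
        contrast = float(np.dot(signs, means.to_numpy()))
        estimates.append(EffectEstimate(label=label, value=contrast / 2 ** (t.k - 1)))
    return estimates


def _per_block_effects(t: DoETable, labels: Sequence[str]) -> pd.DataFrame:
    design = coded_levels(t.k)
    wide = t.block_responses()
    out = {}
    for label in labels:
        signs = np.ones(len(design))
        for f in label:
            signs = signs * design[f].to_numpy()
        out[label] = wide.to_numpy() @ signs / 2 ** (t.k - 1)
    return pd.DataFrame(out, index=wide.index)


def flag_significance(
    effects: Sequence[EffectEstimate],
    mode: str = MODE_FIXED_THRESHOLD,
    threshold: float | None = None,
    table: DoETable | pd.DataFrame | None = None,
    alpha: float = 0.05,
) -> list[EffectEstimate]:
    """Set significance flags on effect estimates.

    * ``fixed_threshold`` — significant iff |effect| > threshold (pg/mg).
    * ``replicate_t`` — per-effect one-sample t across replicate blocks
      (requires the table with ≥2 blocks).
    * ``lenth`` — Lenth's pseudo-standard-error margin for unreplicated
      designs (requires ≥7 effect estimates).

    Returns new estimates; inputs are not mutated.
    """
    effects = list(effects)
    if mode == MODE_FIXED_THRESHOLD:
        if threshold is None:
            raise ConfigurationError("fixed_threshold mode requires a threshold")
        return [
            EffectEstimate(
                e.label,
                e.value,
                significant=abs(e.value) > threshold,
                threshold=threshold,
                test_meta={"mode": mode},
            )
            for e in effects
        ]

    if mode == MODE_REPLICATE_T:
        if table is None:
            raise ConfigurationError("replicate_t mode requires the DoE table")
        t = _as_table(table)
        if t.n_blocks < 2:
            raise ConfigurationError("replicate_t requires >= 2 replicate blocks")
        per_block = _per_block_effects(t, [e.label for e in effects])
        b = t.n_blocks
        t_crit = st.t.ppf(1 - alpha / 2, b - 1)
        out = []
        for e in effects:
            vals = per_block[e.label].to_numpy()
            sd = float(np.std(vals, ddof=1))
            tstat = np.inf if sd == 0 and vals.mean() != 0 else (
                0.0 if sd == 0 else float(vals.mean() / (sd / np.sqrt(b)))
            )
            out.append(
                EffectEstimate(
                    e.label,
                    e.value,
                    significant=abs(tstat) > t_crit,
                    threshold=None,
                    test_meta={"mode": mode, "t": tstat, "df": b - 1, "alpha": alpha},
                )
            )
        return out

    if mode == MODE_LENTH:
        if len(effects) < 7:
            raise ConfigurationError("Lenth's method requires >= 7 effect estimates")
        vals = np.array([e.value for e in effects])
        s0 = 1.5 * float(np.median(np.abs(vals)))
        trimmed = np.abs(vals)[np.abs(vals) < 2.5 * s0]
        pse = 1.5 * float(np.median(trimmed)) if trimmed.size else s0
        df = len(vals) / 3.0
        margin = st.t.ppf(1 - alpha / 2, df) * pse
        return [
            EffectEstimate(
                e.label,
                e.value,
                significant=abs(e.value) > margin,
                threshold=float(margin),
                test_meta={"mode": mode, "pse": pse, "alpha": alpha},
            )
            for e in effects
        ]

    raise ConfigurationError(f"unknown significance mode {mode!r}")


def yield_deficit(
    table: DoETable | pd.DataFrame,
    pairs: Sequence[tuple],
) -> list[float]:
    """Percent yield deficits between run conditions.

    Each pair is (numerator, denominator); either element may be a single run
    label or a sequence of labels, in which case block-averaged responses are
    averaged across the listed runs. deficit = 100·(1 − num/den), rounded
    half-up to integer percent.
    """
    t = _as_table(table)
    means = t.mean_responses()

    def resolve(item) -> float:
        labels = [item] if isinstance(item, str) else list(item)
        for lab in labels:
            if lab not in means.index:
                raise DesignError(f"unknown run label {lab!r}")
        return float(np.mean([means[lab] for lab in labels]))

    out = []
    for num, den in pairs:
        d = resolve(den)
        if d <= 0:
            raise ValueError(f"denominator response for {den!r} is non-positive")
        out.append(round_half_up(100.0 * (1.0 - resolve(num) / d), 0))
    return out


class FactorialModel:
    """Factorial effect model in the fit/Results idiom.

    By default effects are reported up to second order (main effects and
    two-factor interactions) — the conventional reporting surface for a 2³
    screening design, where the three-factor interaction serves as a noise
    proxy. Pass ``max_order=None`` for every order.
    """

    def __init__(self, table: DoETable | pd.DataFrame, max_order: int | None = 2):
        self.table = _as_table(table)
        self.max_order = max_order

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kwargs) -> "FactorialModel":
        return cls(df, **kwargs)

    def fit(
        self,
        mode: str = MODE_FIXED_THRESHOLD,
        threshold: float | None = DEFAULT_EFFECT_THRESHOLD,
        alpha: float = 0.05,
    ) -> "FactorialResults":
        effects = estimate_effects(self.table, self.max_order)
        flagged = flag_significance(
            effects, mode=mode, threshold=threshold, table=self.table, alpha=alpha
        )
        return FactorialResults(self, flagged)


class FactorialResults:
    def __init__(self, model: FactorialModel, effects: list[EffectEstimate]):
        self.model = model
        self.effects = effects

    def effect(self, label: str) -> EffectEstimate:
        for e in self.effects:
            if e.label == label:
                return e
        raise KeyError(label)

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "effect": e.label,
                    "value_pg_per_mg": e.value,
                    "significant": e.significant,
                    "threshold": e.threshold,
                }
                for e in self.effects
            ]
        )

    def summary(self) -> str:
        t = self.model.table
        lines = [
            f"2^{t.k} factorial effects ({t.n_blocks} block(s))",
            "=" * 44,
            f"{'effect':<8}{'value (pg/mg)':>16}{'significant':>14}",
        ]
        for e in self.effects:
            sig = {True: "Yes", False: "No", None: "-"}[e.significant]
            lines.append(f"{e.label:<8}{e.value:>16.2f}{sig:>14}")
        return "\n".join(lines)
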