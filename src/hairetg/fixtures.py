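"""Packaged reference tables from the pretreatment-optimisation and
validation study.

Four small fixtures ship with the package:

* ``doe_table3`` — the eight 2³ factorial pretreatment runs on one heavy
  drinker's hair, in Yates run order (the source prints runs by label;
  labels are authoritative and the order is canonicalised on load);
* ``validation_table4`` — intra-/inter-day precision and trueness summaries
  at 20, 30 and 60 pg/mg plus the LOQ-level (6 pg/mg) repeatability row;
* ``cohort_table5`` — the 25-subject cohort with declared drinking classes
  and possibly-censored EtG results (hair lengths printed as ranges are
  stored as midpoints);
* ``srm_method`` — the four-transition SRM acquisition scheme.

The study's t-test significance threshold for factorial effects (printed with
a European decimal comma as "(19,71)") is normalised once here as 19.71 pg/mg.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .cohort import BELOW_LOD, BELOW_LOQ, CohortRecord, EtgResult, QUANTIFIED
from .doe import DoETable
from .errors import FixtureError
from .signal import SRMMethod, Transition

#: fixed effect-significance threshold quoted with the factorial table (pg/mg)
TABLE3_SIGNIFICANCE_THRESHOLD = 19.71

#: printed significance flags for the six estimable effects of the fixture
TABLE3_PRINTED_SIGNIFICANCE = {
    "a": False,
    "b": True,
    "c": True,
    "ab": False,
    "ac": False,
    "bc": True,
}

#: LOD / LOQ of the validated method (pg/mg)
METHOD_LOD = 4.0
METHOD_LOQ = 6.0

FIXTURES = ("doe_table3", "validation_table4", "cohort_table5", "srm_method")


def _read(name: str) -> pd.DataFrame:
    path = resources.files("hairetg.data").joinpath(f"{name}.csv")
    with resources.as_file(path) as p:
        return pd.read_csv(p)


def load_fixture(name: str) -> pd.DataFrame:
    """Load a packaged fixture by name as a DataFrame.

    Raises :class:`FixtureError` listing the available names otherwise.
    """
    if name not in FIXTURES:
        raise FixtureError(f"unknown fixture {name!r}; available: {', '.join(FIXTURES)}")
    return _read(name)


def load_doe_table() -> DoETable:
    """The factorial pretreatment table as a validated :class:`DoETable`."""
    return DoETable(load_fixture("doe_table3"))


def load_srm_method() -> SRMMethod:
    """The packaged SRM acquisition method as an :class:`SRMMethod`."""
    df = load_fixture("srm_method")
    return SRMMethod(
        transitions=tuple(
            Transition(
                precursor_mz=float(r.precursor_mz),
                product_mz=float(r.product_mz),
                collision_energy=float(r.collision_energy_v),
                role=str(r.role),
            )
            for r in df.itertuples()
        )
    )


def _parse_etg(raw: str) -> EtgResult:
    raw = str(raw).strip()
    if raw == "<LOD":
        return EtgResult(BELOW_LOD)
    if raw == "<LOQ":
        return EtgResult(BELOW_LOQ)
    return EtgResult(QUANTIFIED, float(raw))


def load_cohort_records() -> list[CohortRecord]:
    """The 25-subject cohort as :class:`CohortRecord` objects."""
    df = load_fixture("cohort_table5")
    return [
        CohortRecord(
            subject_id=str(r.subject_id),
            age=int(r.age),
            sex=str(r.sex),
            hair_length_cm=float(r.hair_length_cm),
            hair_color=str(r.hair_color),
            cosmetic_treatment=str(r.cosmetic_treatment).strip().lower() == "yes",
            declared_class=str(r.declared_class),
            etg=_parse_etg(r.etg),
        )
        for r in df.itertuples()
    ]


def cohort_records_to_frame(records) -> pd.DataFrame:
    """Serialise cohort records back to the fixture's CSV schema."""
    return pd.DataFrame(
        [
            {
                "subject_id": r.subject_id,
                "age": r.age,
                "sex": r.sex,
                "hair_length_cm": r.hair_length_cm,
                "hair_color": r.hair_color,
                "cosmetic_treatment": "Yes" if r.cosmetic_treatment else "No",
                "declared_class": r.declared_class,
                "etg": str(r.etg),
            }
            for r in records
        ]
    )
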