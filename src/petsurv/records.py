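"""Per-patient record: covariates, PET parameters, and endpoints.

Times are in months; the two endpoints are freedom from distant metastases
(FFDM) and overall survival (OS).  Missing categorical values (notably HPV
status, known for only part of a typical cohort) use the sentinel ``"n/a"``;
missing PET parameters are NaN and handled by complete-case analysis per
parameter.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict, fields

import pandas as pd

from .errors import CohortValidationError

NA = "n/a"

#: Canonical cohort-table column order (the CSV schema).
COHORT_COLUMNS = [
    "patient_id",
    "sex",
    "age",
    "t_stage",
    "n_stage",
    "uicc_stage",
    "chemo",
    "hpv",
    "suv_prim",
    "mtv_prim",
    "tlg_prim",
    "suv_all",
    "mtv_all",
    "tlg_all",
    "ffdm_time",
    "ffdm_event",
    "os_time",
    "os_event",
]

PET_PARAMS = ["suv_prim", "mtv_prim", "tlg_prim", "suv_all", "mtv_all", "tlg_all"]

ENDPOINTS = ("ffdm", "os")


@dataclass
class PatientRecord:
    patient_id: str
    sex: str = NA          # male | female
    age: float = math.nan  # years
    t_stage: str = NA      # Tx, T1..T4
    n_stage: str = NA      # N0..N3
    uicc_stage: str = NA   # I..IV
    chemo: str = NA        # yes | no
    hpv: str = NA          # positive | negative | n/a
    suv_prim: float = math.nan
    mtv_prim: float = math.nan   # ml
    tlg_prim: float = math.nan   # ml (MTV x SUV_mean)
    suv_all: float = math.nan
    mtv_all: float = math.nan
    tlg_all: float = math.nan
    ffdm_time: float = math.nan  # months
    ffdm_event: int = 0
    os_time: float = math.nan
    os_event: int = 0

    def endpoint(self, name: str) -> tuple[float, int]:
        if name == "ffdm":
            return self.ffdm_time, self.ffdm_event
        if name == "os":
            return self.os_time, self.os_event
        raise ValueError(f"unknown endpoint {name!r}")

    def validate(self, row: int | None = None) -> None:
        for ep in ENDPOINTS:
            t, e = self.endpoint(ep)
            if not (t > 0):
                raise CohortValidationError(
                    f"{ep}_time must be > 0 (got {t})", row=row
                )
            if e not in (0, 1):
                raise CohortValidationError(
                    f"{ep}_event must be 0 or 1 (got {e})", row=row
                )


def cohort_frame(records: list[PatientRecord]) -> pd.DataFrame:
    """Cohort as a DataFrame in canonical column order."""
    df = pd.DataFrame([asdict(r) for r in records])
    if df.empty:
        df = pd.DataFrame(columns=COHORT_COLUMNS)
    return df[COHORT_COLUMNS]


def records_from_frame(df: pd.DataFrame) -> list[PatientRecord]:
    field_names = {f.name for f in fields(PatientRecord)}
    recs = []
    for _, row in df.iterrows():
        kwargs = {k: row[k] for k in df.columns if k in field_names}
        kwargs["patient_id"] = str(kwargs["patient_id"])
        for k in ("ffdm_event", "os_event"):
            if k in kwargs:
                kwargs[k] = int(kwargs[k])
        recs.append(PatientRecord(**kwargs))
    return recs
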