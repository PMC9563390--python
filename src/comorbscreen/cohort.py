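"""Pre-index exposure ascertainment from patient-level visit records.

Each patient contributes a binary exposure vector over three-character
ICD-10 groups: 1 if any emergency-department or acute-care visit inside
the observation window carried a code in the group.  The window runs
from ``lookback_years`` before the patient's index date up to
``washout_days`` before it, both edges inclusive; the washout excludes
visits in the run-up to the index event (for cases, the injury-related
cluster around the index admission) from the pre-index phase.

Profiles and visits arrive as pandas DataFrames with the column layout
documented in :func:`build_exposures`; :mod:`comorbscreen.io` reads the
delimited-text dialect into that layout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .codes import truncate_to_group

__all__ = ["WindowSpec", "ExposureMatrix", "build_exposures",
           "PROFILE_COLUMNS", "VISIT_COLUMNS"]

PROFILE_COLUMNS = ["patient_id", "cohort", "sex", "age_years",
                   "income_quintile", "rurality", "index_date"]
VISIT_COLUMNS = ["patient_id", "visit_date", "icd10_code"]


@dataclass(frozen=True)
class WindowSpec:
    """Pre-index observation window.

    ``lookback_years`` (default 5) sets how far before the index date
    visits count; ``washout_days`` (default 30) excludes the interval
    immediately before the index date.  A lookback year is 365.25 days.
    """

    lookback_years: float = 5.0
    washout_days: int = 30

    def __post_init__(self):
        if self.lookback_years <= 0:
            raise ValueError("lookback_years must be positive")
        if self.washout_days < 0:
            raise ValueError("washout_days must be non-negative")
        if self.lookback_days <= self.washout_days:
            raise ValueError("lookback window must be longer than the washout")

    @property
    def lookback_days(self) -> int:
        return round(self.lookback_years * 365.25)


@dataclass(frozen=True)
class ExposureMatrix:
    """Patients x code-groups binary indicator matrix.

    ``data`` is a DataFrame indexed by patient_id with one uint8 column
    per code group observed in at least one qualifying visit.
    """

    data: pd.DataFrame

    @property
    def patients(self) -> list:
        return list(self.data.index)

    @property
    def code_groups(self) -> list[str]:
        return list(self.data.columns)

    def vector(self, patient_id) -> np.ndarray:
        return self.data.loc[patient_id].to_numpy()


def _parse_dates(series: pd.Series, what: str) -> pd.Series:
    parsed = pd.to_datetime(series, format="%Y-%m-%d", errors="coerce")
    bad = parsed.isna() & series.notna()
    if bad.any():
        rows = (np.where(bad)[0] + 1).tolist()[:10]
        raise ValueError(f"unparseable {what} (expected YYYY-MM-DD) at row(s) {rows}")
    if parsed.isna().any():
        rows = (np.where(parsed.isna())[0] + 1).tolist()[:10]
        raise ValueError(f"missing {what} at row(s) {rows}")
    return parsed


def build_exposures(profiles: pd.DataFrame, visits: pd.DataFrame,
                    window: WindowSpec = WindowSpec()) -> ExposureMatrix:
    """Binary pre-index exposure matrix over code groups.

    Parameters
    ----------
    profiles
        One row per patient with columns including ``patient_id`` and
        ``index_date`` (ISO dates).  Every patient appears in the output
        even with no qualifying visits.
    visits
        One row per recorded diagnosis with columns ``patient_id``,
        ``visit_date``, ``icd10_code``.  Every visit must reference a
        profiled patient.
    window
        Observation window; a visit qualifies when
        ``index - lookback <= visit <= index - washout`` (inclusive).

    Exposure is presence/absence: repeated qualifying visits in a group
    still give 1.  Groups never observed in a qualifying visit are
    omitted from the column list.
    """
    for col in ("patient_id", "index_date"):
        if col not in profiles.columns:
            raise ValueError(f"profiles missing required column {col!r}")
    for col in VISIT_COLUMNS:
        if col not in visits.columns:
            raise ValueError(f"visits missing required column {col!r}")
    if profiles["patient_id"].duplicated().any():
        dup = profiles.loc[profiles["patient_id"].duplicated(), "patient_id"].tolist()
        raise ValueError(f"duplicate patient ids in profiles: {dup[:10]}")

    known = set(profiles["patient_id"])
    orphan = sorted(set(visits["patient_id"]) - known)
    if orphan:
        raise ValueError(f"visits reference unknown patient id(s): {orphan[:10]}")

    index_dates = pd.Series(
        _parse_dates(profiles["index_date"], "index_date").to_numpy(),
        index=profiles["patient_id"].to_numpy(),
    )
    patients = list(profiles["patient_id"])

    if len(visits) == 0:
        return ExposureMatrix(pd.DataFrame(index=pd.Index(patients, name="patient_id"),
                                           dtype=np.uint8))

    v = visits[VISIT_COLUMNS].copy()
    v["visit_date"] = _parse_dates(v["visit_date"], "visit_date")
    v["group"] = [truncate_to_group(c) for c in v["icd10_code"]]
    idx = v["patient_id"].map(index_dates)
    delta = (idx - v["visit_date"]).dt.days
    inside = (delta >= window.washout_days) & (delta <= window.lookback_days)
    v = v[inside]

    mat = (
        pd.crosstab(v["patient_id"], v["group"])
        .gt(0)
        .astype(np.uint8)
        .reindex(index=patients, fill_value=0)
        .sort_index(axis=1)
    )
    mat.index.name = "patient_id"
    mat.columns.name = None
    return ExposureMatrix(mat)
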