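"""Registry preprocessing and matched case-control cohort construction.

The registry is held as two pandas DataFrames:

``patients``
    one row per person: ``patient_id, sex, birth_date, status_code,
    death_date`` (dates as datetime64, missing death as NaT).
``events``
    one row per coded diagnosis: ``patient_id, event_code, admission_date,
    discharge_date, diagnosis_type, encounter_id``.

Preprocessing keeps only active residents (status "01") and deceased
residents (status "90"), and drops referral/temporary diagnoses (types H
and M) so that analyses rest on confirmed, medically relevant codes.

Cases are patients with a pancreatic-cancer code (C25) confirmed by an
external cancer-registry identifier set; their index date is the first C25
admission.  Each case is matched to ``ratio`` controls sharing sex, birth
year and index (diagnosis) year; a control's index date is its earliest
hospital contact within the matched year.  The symptom history window is
half-open, ``[index - years, index)``: events on the diagnosis day belong
to the diagnosis itself, not to the prior history.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .lexicons import CANCER_CODE

DAYS_PER_YEAR = 365.25

#: status codes retained by preprocessing: active resident / deceased
ACTIVE_STATUS_CODES = frozenset({"01", "90"})

#: referral (H) and temporary (M) diagnosis types, excluded from analyses
EXCLUDED_DIAGNOSIS_TYPES = frozenset({"H", "M"})

PATIENT_COLUMNS = ["patient_id", "sex", "birth_date", "status_code", "death_date"]
EVENT_COLUMNS = [
    "patient_id",
    "event_code",
    "admission_date",
    "discharge_date",
    "diagnosis_type",
    "encounter_id",
]


class StratumExhaustedError(RuntimeError):
    """Raised when a matching stratum cannot supply the requested controls."""

    def __init__(self, key: "MatchKey", needed: int, available: int):
        self.key = key
        self.needed = needed
        self.available = available
        super().__init__(
            f"stratum {key} has {available} eligible controls, {needed} required"
        )


@dataclass(frozen=True)
class MatchKey:
    """Control-matching stratum: sex, birth year, age at index, index year."""

    sex: str
    birth_year: int
    age_at_index: int
    index_year: int


@dataclass(frozen=True)
class DiagnosisEvent:
    code: str
    admission_date: pd.Timestamp
    discharge_date: pd.Timestamp
    diagnosis_type: str
    encounter_id: str


@dataclass
class Registry:
    """A registry extract: patient attributes plus their diagnosis events."""

    patients: pd.DataFrame
    events: pd.DataFrame
    confirmed_case_ids: frozenset = frozenset()
    end_of_data: pd.Timestamp | None = None
    meta: dict = field(default_factory=dict)

    def copy(self) -> "Registry":
        return Registry(
            self.patients.copy(),
            self.events.copy(),
            frozenset(self.confirmed_case_ids),
            self.end_of_data,
            dict(self.meta),
        )


def patient_age(birth_date, on) -> int:
    """Completed years of age on a given date (day resolution)."""
    return int((pd.Timestamp(on) - pd.Timestamp(birth_date)).days // DAYS_PER_YEAR)


def match_key(sex: str, birth_date, index_date) -> MatchKey:
    bd, ix = pd.Timestamp(birth_date), pd.Timestamp(index_date)
    return MatchKey(sex, bd.year, patient_age(bd, ix), ix.year)


def filter_active(patients: pd.DataFrame) -> pd.DataFrame:
    """Keep active residents ("01") and deceased residents ("90"), in order."""
    return patients[patients["status_code"].isin(ACTIVE_STATUS_CODES)]


def filter_diagnosis_types(events: pd.DataFrame) -> pd.DataFrame:
    """Drop referral (H) and temporary (M) diagnoses."""
    return events[~events["diagnosis_type"].isin(EXCLUDED_DIAGNOSIS_TYPES)]


def select_cases(
    patients: pd.DataFrame,
    events: pd.DataFrame,
    confirmed_ids,
    cancer_code: str = CANCER_CODE,
) -> pd.DataFrame:
    """Cases: patients with a confirmed cancer code; index = first such admission.

    Returns a DataFrame with columns ``patient_id, index_date`` sorted by
    patient id.  ``confirmed_ids`` plays the role of the national cancer
    registry: a C25 code alone does not qualify.
    """
    confirmed = set(confirmed_ids)
    cancer = events[events["event_code"] == cancer_code]
    first = cancer.groupby("patient_id")["admission_date"].min()
    keep = [
        pid for pid in first.index if pid in confirmed and pid in set(patients["patient_id"])
    ]
    out = first.loc[keep].rename("index_date").reset_index()
    return out.sort_values("patient_id", ignore_index=True)


def lookback_events(
    events: pd.DataFrame, index_date, years: float = 5
) -> pd.DataFrame:
    """Events in the half-open window ``[index - years, index)``, sorted.

    The window is measured in days with 1 year = 365.25 days.  Events on
    the index day itself are excluded.
    """
    if years <= 0:
        raise ValueError("lookback years must be positive")
    ix = pd.Timestamp(index_date)
    lo = ix - pd.Timedelta(days=years * DAYS_PER_YEAR)
    mask = (events["admission_date"] >= lo) & (events["admission_date"] < ix)
    return events[mask].sort_values("admission_date", kind="stable", ignore_index=True)


def dedup_per_encounter(events: pd.DataFrame) -> pd.DataFrame:
    """At most one record per (encounter, code); the earliest admission is kept."""
    out = events.sort_values("admission_date", kind="stable")
    out = out.drop_duplicates(subset=["encounter_id", "event_code"], keep="first")
    return out.reset_index(drop=True)


def _contact_index(patients: pd.DataFrame, events: pd.DataFrame) -> pd.DataFrame:
    """Earliest hospital contact per (patient, calendar year), with stratum keys."""
    ev = events.merge(patients[["patient_id", "sex", "birth_date"]], on="patient_id")
    ev = ev.assign(year=ev["admission_date"].dt.year)
    grp = (
        ev.groupby(["patient_id", "sex", "year"], as_index=False)
        .agg(first_contact=("admission_date", "min"), birth_date=("birth_date", "first"))
    )
    grp["birth_year"] = grp["birth_date"].dt.year
    return grp


def sample_controls(
    cases: pd.DataFrame,
    patients: pd.DataFrame,
    events: pd.DataFrame,
    ratio: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Sample ``ratio`` matched controls per case, without replacement per case.

    Matching is exact on sex, birth year and index year; the control's index
    date is its earliest hospital contact in the matched year.  Controls may
    be reused across cases but never within one case's list, and a case is
    never its own control.  Deterministic under ``seed``.

    Parameters
    ----------
    cases : DataFrame with ``patient_id, index_date`` (from :func:`select_cases`).
    patients, events : the preprocessed registry restricted to the control pool
        plus (possibly) the cases; case ids are excluded from eligibility.
    ratio : controls per case (the study design uses 10).

    Returns
    -------
    DataFrame ``case_id, control_id, control_index_date``.

    Raises
    ------
    StratumExhaustedError
        naming the match stratum, when fewer than ``ratio`` eligible
        controls exist for some case.
    """
    if ratio < 1:
        raise ValueError("ratio must be >= 1")
    rng = np.random.default_rng(seed)
    case_ids = set(cases["patient_id"])
    contacts = _contact_index(patients, events)
    contacts = contacts[~contacts["patient_id"].isin(case_ids)]
    by_key: dict[tuple, pd.DataFrame] = {
        k: g.sort_values("patient_id", ignore_index=True)
        for k, g in contacts.groupby(["sex", "birth_year", "year"])
    }
    case_attrs = cases[["patient_id", "index_date"]].merge(
        patients[["patient_id", "sex", "birth_date"]], on="patient_id"
    ).sort_values("patient_id", ignore_index=True)

    rows = []
    for rec in case_attrs.itertuples():
        key = match_key(rec.sex, rec.birth_date, rec.index_date)
        pool = by_key.get((key.sex, key.birth_year, key.index_year))
        n_avail = 0 if pool is None else len(pool)
        if n_avail < ratio:
            raise StratumExhaustedError(key, ratio, n_avail)
        pick = rng.choice(n_avail, size=ratio, replace=False)
        for j in np.sort(pick):
            rows.append(
                (rec.patient_id, pool.at[j, "patient_id"], pool.at[j, "first_contact"])
            )
    return pd.DataFrame(rows, columns=["case_id", "control_id", "control_index_date"])


def first_occurrences(
    events: pd.DataFrame,
    code_col: str = "event_code",
    date_col: str = "admission_date",
) -> pd.Series:
    """First occurrence date per (patient, code) as a MultiIndex Series."""
    if events.empty:
        idx = pd.MultiIndex.from_arrays([[], []], names=["patient_id", code_col])
        return pd.Series([], index=idx, dtype="datetime64[ns]", name=date_col)
    return events.groupby(["patient_id", code_col])[date_col].min()


def windowed_case_events(
    cases: pd.DataFrame, events: pd.DataFrame, years: float = 5
) -> pd.DataFrame:
    """Per-case lookback window + per-encounter dedup, concatenated.

    Convenience used by the model layer; equivalent to applying
    :func:`lookback_events` then :func:`dedup_per_encounter` per patient.
    """
    ev = events.merge(cases.rename(columns={"patient_id": "pid"}),
                      left_on="patient_id", right_on="pid")
    lo = ev["index_date"] - pd.Timedelta(days=years * DAYS_PER_YEAR)
    ev = ev[(ev["admission_date"] >= lo) & (ev["admission_date"] < ev["index_date"])]
    return dedup_per_encounter(ev[EVENT_COLUMNS])
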