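"""Cohort extraction: follow-up, incident sepsis, look-back linkage, strata.

Definitions follow standard EHR cohort conventions for this analysis:

* Follow-up starts at the latest of one year after registration, the
  practice's up-to-standard date and the study start; it ends at the
  earliest of deregistration, death and the study end. Person-time uses the
  half-open convention ``[start, end)`` with days/365.25 person-years.
* The incident sepsis case is the chronologically first sepsis-coded event
  inside the follow-up interval; recurrences are not analysed. Events
  outside follow-up are ignored entirely — by default an earlier
  out-of-interval code does not suppress a later in-interval one
  (``suppress_prevalent`` switches this).
* Look-back linkage searches the window before the sepsis date for the most
  recent infection consultation. Both endpoints are excluded: a
  consultation on the sepsis date itself, or exactly ``window_days``
  before, does not qualify (lags 1..window_days-1). Antibiotic exposure is
  a prescription on the linked consultation's date; prescriptions elsewhere
  in the window are recorded separately and do not set ``ab_same_date``.
* Ages are completed years at January 1 of the event's calendar year, the
  same convention the simulator uses for stratum bookkeeping.
"""
from __future__ import annotations

from typing import Iterable, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .bands import ANALYSIS_BANDS, Band, assign_band, validate_bands
from .errors import ConfigurationError, DataError

_DAY = pd.Timedelta(days=1)
DAYS_PER_YEAR = 365.25


def _record_end(patients: pd.DataFrame) -> pd.Series:
    return patients["registration_end"].where(
        patients["death_date"].isna()
        | (patients["death_date"] >= patients["registration_end"]),
        patients["death_date"],
    )


def compute_follow_up(
    patients: pd.DataFrame, study_start, study_end
) -> pd.DataFrame:
    """Follow-up interval and person-years per patient.

    Zero-length (or negative) intervals are returned explicitly with
    ``person_years = 0``, not dropped.
    """
    study_start = pd.Timestamp(study_start)
    study_end = pd.Timestamp(study_end)
    if (patients["registration_end"] < patients["registration_start"]).any():
        bad = patients.loc[
            patients["registration_end"] < patients["registration_start"], "patient_id"
        ].iloc[0]
        raise DataError(f"registration_end precedes registration_start for patient {bad}")

    start = np.maximum.reduce(
        [
            (patients["registration_start"] + pd.DateOffset(years=1)).values,
            patients["up_to_standard_date"].values,
            np.full(len(patients), study_start.to_datetime64()),
        ]
    )
    end = np.minimum(
        _record_end(patients).values, np.full(len(patients), study_end.to_datetime64())
    )
    days = ((end - start) / np.timedelta64(1, "D")).astype(float)
    days = np.clip(days, 0.0, None)
    out = pd.DataFrame(
        {
            "patient_id": patients["patient_id"].values,
            "start": start,
            "end": end,
            "person_years": days / DAYS_PER_YEAR,
        }
    )
    return out


def person_year_segments(
    patients: pd.DataFrame,
    follow_up: pd.DataFrame,
    bands: Sequence[Band] = ANALYSIS_BANDS,
    censor_dates: Optional[pd.Series] = None,
) -> pd.DataFrame:
    """Split follow-up into patient x calendar-year rows with age bands.

    ``censor_dates`` (indexed by patient_id) truncates a patient's time at
    risk the day after that date — used to censor at the incident sepsis
    event so the incidence denominator matches a first-event analysis.
    """
    validate_bands(tuple(bands))
    fu = follow_up.merge(
        patients[["patient_id", "gender", "birth_date"]], on="patient_id"
    )
    end = fu["end"].copy()
    if censor_dates is not None:
        cens = fu["patient_id"].map(censor_dates)
        end = np.minimum(end.values, (cens + _DAY).fillna(pd.Timestamp.max).values)
        end = pd.Series(end)
    start = fu["start"]
    ok = end > start
    fu = fu[ok].reset_index(drop=True)
    start = start[ok].reset_index(drop=True)
    end = end[ok].reset_index(drop=True)

    y0 = pd.DatetimeIndex(start).year.values
    y1 = pd.DatetimeIndex(end - _DAY).year.values
    n_years = y1 - y0 + 1
    rows = np.repeat(np.arange(len(fu)), n_years)
    year = y0[rows] + (np.arange(n_years.sum()) - np.repeat(np.cumsum(n_years) - n_years, n_years))
    jan1 = pd.to_datetime({"year": year, "month": 1, "day": 1}).values
    jan1_next = pd.to_datetime({"year": year + 1, "month": 1, "day": 1}).values
    seg_start = np.maximum(jan1, start.values[rows])
    seg_end = np.minimum(jan1_next, end.values[rows])
    days = ((seg_end - seg_start) / np.timedelta64(1, "D")).astype(float)
    age = np.floor(
        (jan1 - fu["birth_date"].values[rows]) / np.timedelta64(1, "D") / DAYS_PER_YEAR
    ).astype(int)
    age = np.clip(age, 0, None)
    segs = pd.DataFrame(
        {
            "patient_id": fu["patient_id"].values[rows],
            "gender": fu["gender"].values[rows],
            "year": year,
            "days": days,
            "age": age,
        }
    )
    segs = segs[segs["days"] > 0].reset_index(drop=True)
    segs["age_band"] = assign_band(segs["age"].values, tuple(bands))
    segs["person_years"] = segs["days"] / DAYS_PER_YEAR
    return segs


def ascertain_incident_sepsis(
    events: pd.DataFrame,
    follow_up: pd.DataFrame,
    suppress_prevalent: bool = False,
) -> pd.DataFrame:
    """First in-interval sepsis event per patient.

    With ``suppress_prevalent=True`` a patient whose earliest sepsis code
    predates follow-up start contributes no case at all.
    """
    sep = events[events["category"] == "sepsis"]
    sep = sep.merge(follow_up[["patient_id", "start", "end"]], on="patient_id")
    inside = (sep["event_date"] >= sep["start"]) & (sep["event_date"] < sep["end"])
    if suppress_prevalent:
        prevalent = sep.loc[sep["event_date"] < sep["start"], "patient_id"].unique()
        inside &= ~sep["patient_id"].isin(prevalent)
    sep = sep[inside]
    if sep.empty:
        return pd.DataFrame(columns=["patient_id", "sepsis_date"])
    first = (
        sep.sort_values(["patient_id", "event_date"])
        .groupby("patient_id", as_index=False)
        .first()
    )
    return first[["patient_id", "event_date"]].rename(columns={"event_date": "sepsis_date"})


def link_lookback(
    cases: pd.DataFrame,
    consultations: pd.DataFrame,
    prescriptions: pd.DataFrame,
    window_days: int = 30,
    exposure_rule: str = "most_recent",
) -> pd.DataFrame:
    """Attach look-back exposure to each sepsis case.

    Adds ``linked_date``, ``infection_type`` (NaN when unlinked),
    ``ab_same_date`` (prescription on the linked consultation's date),
    ``ab_other_date_in_window`` (a prescription in the window on some other
    date), and ``n_window_consultations``.

    ``exposure_rule='any_ab'`` instead sets ``ab_same_date`` when *any*
    consultation in the window had a same-day prescription.
    """
    if window_days not in (30, 60):
        raise ConfigurationError(f"window_days: must be 30 or 60, got {window_days}")
    if exposure_rule not in ("most_recent", "any_ab"):
        raise ConfigurationError(f"exposure_rule: unknown rule {exposure_rule!r}")

    infect = consultations[
        consultations["category"].isin(("rti", "skin", "uti"))
    ][["patient_id", "event_date", "category"]].copy()
    rx_days = prescriptions[["patient_id", "prescription_date"]].drop_duplicates()
    infect = infect.merge(
        rx_days.rename(columns={"prescription_date": "event_date"}).assign(ab=True),
        on=["patient_id", "event_date"],
        how="left",
    )
    infect["ab"] = infect["ab"].to_numpy() == True  # noqa: E712
    infect = infect.sort_values(["event_date", "patient_id"], kind="stable")

    out = cases.copy().sort_values(["sepsis_date", "patient_id"], kind="stable")
    tol = pd.Timedelta(days=window_days - 1)
    linked = pd.merge_asof(
        out,
        infect.rename(columns={"event_date": "linked_date", "category": "infection_type"}),
        left_on="sepsis_date",
        right_on="linked_date",
        by="patient_id",
        direction="backward",
        allow_exact_matches=False,
        tolerance=tol,
    )

    # counts and any-AB within the window, via interval join
    lo = linked["sepsis_date"] - pd.Timedelta(days=window_days - 1)
    keys = linked[["patient_id", "sepsis_date"]].assign(lo=lo)
    win = keys.merge(infect, on="patient_id", how="left")
    in_win = (win["event_date"] >= win["lo"]) & (win["event_date"] < win["sepsis_date"])
    win = win[in_win]
    n_win = win.groupby(["patient_id", "sepsis_date"]).size()
    any_ab = win.groupby(["patient_id", "sepsis_date"])["ab"].any()

    idx = pd.MultiIndex.from_frame(linked[["patient_id", "sepsis_date"]])
    linked["n_window_consultations"] = n_win.reindex(idx, fill_value=0).values
    linked_any_ab = any_ab.reindex(idx, fill_value=False).values

    # prescriptions in window on a non-linked date
    rxw = keys.merge(rx_days, on="patient_id", how="left")
    rx_in = (rxw["prescription_date"] >= rxw["lo"]) & (
        rxw["prescription_date"] < rxw["sepsis_date"]
    )
    rxw = rxw[rx_in].merge(
        linked[["patient_id", "sepsis_date", "linked_date"]],
        on=["patient_id", "sepsis_date"],
    )
    rx_other = (
        rxw[rxw["prescription_date"] != rxw["linked_date"]]
        .groupby(["patient_id", "sepsis_date"])
        .size()
    )
    linked["ab_other_date_in_window"] = rx_other.reindex(idx, fill_value=0).values > 0

    has_link = linked["linked_date"].notna()
    if exposure_rule == "most_recent":
        linked["ab_same_date"] = linked["ab"].to_numpy() == True  # noqa: E712
    else:
        linked["ab_same_date"] = np.asarray(linked_any_ab) & has_link.values
    linked = linked.drop(columns=["ab"])
    return linked.reset_index(drop=True)


def merge_event_sources(
    primary: pd.DataFrame,
    hospital: Optional[pd.DataFrame] = None,
    mortality: Optional[pd.DataFrame] = None,
) -> pd.DataFrame:
    """Union of sepsis event streams across sources.

    Same-day multi-source records deduplicate with source priority
    primary_care > hospital > mortality. The first event across sources
    then defines the incident date downstream.
    """
    prio = {"primary_care": 0, "hospital": 1, "mortality": 2}
    parts = [primary]
    if hospital is not None:
        parts.append(hospital)
    if mortality is not None:
        parts.append(mortality)
    allev = pd.concat(parts, ignore_index=True)
    allev = allev[allev["category"] == "sepsis"].copy()
    allev["_prio"] = allev["source"].map(prio).fillna(9)
    allev = (
        allev.sort_values(["patient_id", "event_date", "_prio"], kind="stable")
        .drop_duplicates(subset=["patient_id", "event_date"], keep="first")
        .drop(columns="_prio")
        .reset_index(drop=True)
    )
    return allev


def age_at_event(birth_date: pd.Series, event_date: pd.Series) -> np.ndarray:
    """Completed years at January 1 of the event's calendar year."""
    jan1 = pd.to_datetime(
        {"year": pd.DatetimeIndex(event_date).year, "month": 1, "day": 1}
    ).values
    age = np.floor(
        (jan1 - pd.DatetimeIndex(birth_date).values.astype("datetime64[ns]"))
        / np.timedelta64(1, "D")
        / DAYS_PER_YEAR
    ).astype(int)
    return np.clip(age, 0, None)


def tabulate_strata(
    cases: pd.DataFrame,
    patients: pd.DataFrame,
    follow_up: pd.DataFrame,
    bands: Sequence[Band] = ANALYSIS_BANDS,
    extra_case_keys: Iterable[str] = (),
    period_years: Optional[int] = None,
    censor_at_sepsis: bool = True,
) -> pd.DataFrame:
    """Sufficient statistics per stratum.

    Strata are gender x age band, optionally crossed with a calendar period
    of ``period_years`` years and with extra case-level keys (e.g.
    ``frailty_category`` or ``infection_type``). Each row carries
    ``n_sepsis``, ``n_prior_infection``, ``n_same_date_ab`` and
    ``person_years``; person-years for extra case keys are the stratum
    margin (those keys partition cases, not person-time).
    """
    validate_bands(tuple(bands))
    cases = cases.merge(patients[["patient_id", "birth_date"]], on="patient_id")
    if "gender" not in cases.columns:
        cases = cases.merge(patients[["patient_id", "gender"]], on="patient_id")
    cases["age"] = age_at_event(cases["birth_date"], cases["sepsis_date"])
    cases["age_band"] = assign_band(cases["age"].values, tuple(bands))

    censor = None
    if censor_at_sepsis and len(cases):
        censor = cases.set_index("patient_id")["sepsis_date"]
    segs = person_year_segments(patients, follow_up, bands, censor_dates=censor)

    keys = ["gender", "age_band"]
    if period_years:
        case_years = pd.DatetimeIndex(cases["sepsis_date"]).year
        candidates = [int(segs["year"].min())] if len(segs) else []
        if len(case_years):
            candidates.append(int(case_years.min()))
        y0 = min(candidates) if candidates else 0
        cases["period"] = _period_label(case_years, y0, period_years)
        segs["period"] = _period_label(segs["year"], y0, period_years)
        keys.append("period")
    keys += list(extra_case_keys)

    has_link = (
        cases["linked_date"].notna()
        if "linked_date" in cases.columns
        else pd.Series(False, index=cases.index)
    )
    ab = (
        (cases["ab_same_date"].to_numpy() == True)  # noqa: E712
        if "ab_same_date" in cases.columns
        else pd.Series(False, index=cases.index)
    )
    grp = cases.assign(_link=has_link.values, _ab=(has_link & ab).values).groupby(
        keys, dropna=False, observed=True
    )
    counts = grp.agg(
        n_sepsis=("patient_id", "size"),
        n_prior_infection=("_link", "sum"),
        n_same_date_ab=("_ab", "sum"),
    ).reset_index()

    py_keys = ["gender", "age_band"] + (["period"] if period_years else [])
    py = segs.groupby(py_keys, observed=True)["person_years"].sum().reset_index()

    out = counts.merge(py, on=py_keys, how="outer")
    for c in ("n_sepsis", "n_prior_infection", "n_same_date_ab"):
        out[c] = out[c].fillna(0).astype(int)
    out["person_years"] = out["person_years"].fillna(0.0)
    sort_keys = [k for k in keys if k in out.columns]
    return out.sort_values(sort_keys).reset_index(drop=True)


def _period_label(years, origin: int, width: int):
    years = np.asarray(years)
    k = (years - origin) // width
    lo = origin + k * width
    return np.array([f"{a}-{a + width - 1}" for a in lo], dtype=object)
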