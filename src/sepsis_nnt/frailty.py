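"""Electronic frailty index: 36-deficit accumulation, categories, allocation.

The index for a patient-year is the number of distinct deficits ever
recorded up to that year divided by 36. Deficits are cumulative: once
recorded, a deficit counts in every later year. Categories follow the
published e-FI convention — nonfrail (index <= 0.12), mild (0.12, 0.24],
moderate (0.24, 0.36], severe (> 0.36) — and are configurable via
``cuts``. By convention the index is only evaluated from age 55 upward;
younger patients are rarely beyond mild frailty.
"""
from __future__ import annotations

import re
import warnings
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DataError, DomainError

CATEGORIES = ("nonfrail", "mild", "moderate", "severe")
DEFAULT_CUTS = (0.12, 0.24, 0.36)
N_DEFICITS = 36
MIN_FRAILTY_AGE = 55

_DEFAULT_CODE_RE = re.compile(r"^EFI(\d{2})$")


def default_slot_map(codes) -> pd.Series:
    """Map generator-style deficit codes ('EFI00'..'EFI35') to slots."""
    slots = []
    for c in codes:
        m = _DEFAULT_CODE_RE.match(str(c))
        slots.append(int(m.group(1)) if m else -1)
    return pd.Series(slots, index=pd.Index(codes), dtype=int)


def load_slot_map(path) -> dict:
    """Read a deficit-map config file (YAML: slot number -> list of codes)
    into the code -> slot mapping :func:`compute_annual_frailty` expects."""
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh)
    mapping = {}
    for slot, codes in raw.items():
        slot = int(slot)
        if not 0 <= slot < N_DEFICITS:
            raise ConfigurationError(f"slot_map: slot {slot} outside 0..{N_DEFICITS - 1}")
        for code in codes:
            mapping[str(code)] = slot
    return mapping


def categorize(index_value, cuts: Sequence[float] = DEFAULT_CUTS):
    """Frailty category from index value(s); left-closed at each cut's
    upper edge (a value exactly at a cut belongs to the lower category)."""
    arr = np.asarray(index_value, dtype=float)
    if np.any((arr < 0) | (arr > 1)):
        raise DomainError(f"index_value: must be in [0,1], got {arr[(arr < 0) | (arr > 1)][0]}")
    idx = np.searchsorted(np.asarray(cuts, float), arr, side="left")
    labels = np.asarray(CATEGORIES, dtype=object)
    if arr.ndim == 0:
        return str(labels[int(idx)])
    return labels[idx]


def compute_annual_frailty(
    deficit_events: pd.DataFrame,
    years: Sequence[int],
    slot_map: Optional[Mapping[str, int]] = None,
    strict: bool = False,
    n_deficits: int = N_DEFICITS,
    cuts: Sequence[float] = DEFAULT_CUTS,
    patient_ids: Optional[Sequence] = None,
) -> pd.DataFrame:
    """One frailty assessment per patient per requested year.

    ``deficit_events`` are coded clinical events (category
    ``frailty_deficit``); codes map to deficit slots via ``slot_map``
    (default: the generator's 'EFInn' codes). Unknown codes warn and are
    ignored, or raise under ``strict=True``. A deficit recorded in year y
    counts in all years >= y. ``patient_ids``, when given, forces an
    assessment row (index 0, nonfrail) even for patients with no recorded
    deficits.
    """
    years = sorted(int(y) for y in years)
    ev = deficit_events
    if "category" in ev.columns:
        ev = ev[ev["category"] == "frailty_deficit"]
    ev = ev[["patient_id", "event_date", "code"]].copy()

    codes = ev["code"].unique()
    if slot_map is None:
        mapping = default_slot_map(codes)
    else:
        mapping = pd.Series(
            [slot_map.get(c, -1) for c in codes], index=pd.Index(codes), dtype=int
        )
    unknown = mapping.index[mapping.values < 0]
    if len(unknown):
        msg = f"{len(unknown)} deficit code(s) not in the {n_deficits}-slot map: {list(unknown)[:5]}"
        if strict:
            raise DataError(msg)
        warnings.warn(msg)
    ev["slot"] = ev["code"].map(mapping)
    ev = ev[ev["slot"] >= 0]
    if (ev["slot"] >= n_deficits).any():
        raise DataError("deficit slot outside the configured slot count")

    ev["year"] = pd.DatetimeIndex(ev["event_date"]).year
    first_year = (
        ev.groupby(["patient_id", "slot"])["year"].min().reset_index()
    )
    out_rows = []
    new_per_year = (
        first_year.groupby(["patient_id", "year"]).size().unstack(fill_value=0)
    )
    if patient_ids is not None:
        new_per_year = new_per_year.reindex(
            pd.Index(patient_ids).unique(), fill_value=0
        )
        if new_per_year.shape[1] == 0 and years:
            new_per_year[years[0]] = 0
    # counts before/at each requested year: cumulative over recorded years
    all_years = sorted(set(new_per_year.columns) | set(years))
    cum = new_per_year.reindex(columns=all_years, fill_value=0).cumsum(axis=1)
    cum = cum[years]
    for y in years:
        cnt = cum[y]
        out_rows.append(
            pd.DataFrame(
                {
                    "patient_id": cum.index.values,
                    "calendar_year": y,
                    "deficit_count": cnt.values,
                }
            )
        )
    out = pd.concat(out_rows, ignore_index=True) if out_rows else pd.DataFrame(
        columns=["patient_id", "calendar_year", "deficit_count"]
    )
    out["deficit_count"] = out["deficit_count"].astype(int).clip(upper=n_deficits)
    out["index_value"] = out["deficit_count"] / n_deficits
    out["category"] = categorize(out["index_value"].values, cuts)
    return out.sort_values(["patient_id", "calendar_year"]).reset_index(drop=True)


def attach_index_year_frailty(
    cases: pd.DataFrame, assessments: pd.DataFrame
) -> pd.DataFrame:
    """Attach each case's frailty category for its sepsis index year.

    Patients with no recorded deficits are nonfrail (index 0).
    """
    cases = cases.copy()
    year = pd.DatetimeIndex(cases["sepsis_date"]).year
    key = pd.MultiIndex.from_arrays([cases["patient_id"], year])
    lut = assessments.set_index(["patient_id", "calendar_year"])["category"]
    cases["frailty_category"] = lut.reindex(key).fillna("nonfrail").values
    return cases


def allocate_person_years(
    totals: pd.Series, proportions: pd.DataFrame, tol: float = 1e-9
) -> pd.DataFrame:
    """Allocate stratum person-year totals across frailty categories.

    ``totals`` is indexed by stratum; ``proportions`` has the same index and
    one column per category, each row summing to 1 within ``tol``. The
    allocation is ``total * proportion`` with any floating-point residue
    added to the largest cell, so row sums equal the totals exactly.
    """
    props = proportions.loc[totals.index]
    bad = (props.sum(axis=1) - 1.0).abs() > tol
    if bad.any():
        raise DataError(
            f"proportions must sum to 1 per stratum; offending strata: {list(props.index[bad])[:5]}"
        )
    alloc = props.mul(totals, axis=0)
    residue = totals - alloc.sum(axis=1)
    argmax = alloc.idxmax(axis=1)
    for stratum, col in argmax.items():
        alloc.loc[stratum, col] += residue.loc[stratum]
    return alloc


def frailty_person_year_proportions(
    assessments: pd.DataFrame,
    segments: pd.DataFrame,
    min_age: int = MIN_FRAILTY_AGE,
) -> pd.DataFrame:
    """Observed person-year share per frailty category, by gender x age band.

    ``segments`` are patient-year rows from
    :func:`sepsis_nnt.cohort.person_year_segments` (the sampled cohort);
    each patient-year's person-time goes to its assessed category for that
    year. Restricted to ages >= ``min_age`` by default.
    """
    seg = segments[segments["age"] >= min_age].copy()
    lut = assessments.set_index(["patient_id", "calendar_year"])["category"]
    key = pd.MultiIndex.from_arrays([seg["patient_id"], seg["year"]])
    seg["category"] = lut.reindex(key).fillna("nonfrail").values
    py = (
        seg.groupby(["gender", "age_band", "category"], observed=True)["person_years"]
        .sum()
        .unstack(fill_value=0.0)
        .reindex(columns=list(CATEGORIES), fill_value=0.0)
    )
    return py.div(py.sum(axis=1), axis=0)
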