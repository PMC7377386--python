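"""Stratified random sampling for consultation-rate estimation.

Consultation rates per 30 days and the proportion of consultations with a
same-day antibiotic are estimated from a stratified random sample rather
than the whole database: in each study year, up to ``per_stratum_n``
patients are drawn without replacement per year x practice x gender x
5-year age band stratum. A patient sampled in year y contributes that
calendar year's person-time and consultations, so every age-specific rate
is estimated with similar precision regardless of how common the stratum
is.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .bands import (
    ANALYSIS_BANDS,
    FIVE_YEAR_BANDS,
    Band,
    assign_band,
    validate_bands,
)
from .cohort import DAYS_PER_YEAR, person_year_segments
from .errors import ConfigurationError

logger = logging.getLogger(__name__)

DAYS_PER_30D_UNIT = 30.0


@dataclass
class SampleDesign:
    per_stratum_n: int = 10
    bands: Sequence[Band] = field(default_factory=lambda: tuple(FIVE_YEAR_BANDS))
    rng_seed: int = 0

    def validate(self) -> None:
        if self.per_stratum_n < 1:
            raise ConfigurationError(
                f"per_stratum_n: must be >= 1, got {self.per_stratum_n}"
            )
        validate_bands(tuple(self.bands))


def draw_sample(
    patients: pd.DataFrame,
    follow_up: pd.DataFrame,
    design: SampleDesign,
) -> pd.DataFrame:
    """Sampled (year, patient) pairs.

    Eligibility in a year is any follow-up time during that calendar year.
    Within each year x practice x gender x band stratum,
    ``min(per_stratum_n, stratum size)`` patients are drawn without
    replacement; empty strata yield zero draws (logged at debug level).
    Reproducible given ``design.rng_seed``.
    """
    design.validate()
    segs = person_year_segments(patients, follow_up, design.bands)
    segs = segs.merge(patients[["patient_id", "practice_id"]], on="patient_id")
    elig = segs[["patient_id", "year", "practice_id", "gender", "age_band"]].drop_duplicates()
    if elig.empty:
        logger.debug("no eligible patient-years to sample")
        return elig.assign(sampled=True).iloc[:0]
    rng = np.random.default_rng(design.rng_seed)
    elig = elig.sort_values(["year", "practice_id", "gender", "age_band", "patient_id"])
    elig = elig.reset_index(drop=True)
    elig["_key"] = rng.random(len(elig))
    took = (
        elig.sort_values("_key")
        .groupby(["year", "practice_id", "gender", "age_band"], observed=True)
        .head(design.per_stratum_n)
    )
    return (
        took.drop(columns="_key")
        .sort_values(["year", "patient_id"])
        .reset_index(drop=True)
    )


def estimate_rates(
    sample: pd.DataFrame,
    consultations: pd.DataFrame,
    prescriptions: pd.DataFrame,
    patients: pd.DataFrame,
    follow_up: pd.DataFrame,
    bands: Sequence[Band] = ANALYSIS_BANDS,
    by_infection_type: bool = False,
    equal_year_weights: bool = False,
) -> pd.DataFrame:
    """Consultation rate per 30 days and same-day antibiotic proportion.

    ``sample`` holds (year, patient_id) pairs from :func:`draw_sample`
    (pass all patient-years to use the full population). Rates pool events
    and person-time over years by default; ``equal_year_weights`` instead
    averages yearly rates, giving each study year equal weight. Strata with
    zero person-time get ``rate_per_30d = NaN`` and ``undefined = True``
    rather than a silent zero.
    """
    validate_bands(tuple(bands))
    segs = person_year_segments(patients, follow_up, bands)
    segs = segs.merge(sample[["patient_id", "year"]], on=["patient_id", "year"])

    infect = consultations[consultations["category"].isin(("rti", "skin", "uti"))][
        ["patient_id", "event_date", "category"]
    ].copy()
    rx_days = prescriptions[["patient_id", "prescription_date"]].drop_duplicates()
    infect = infect.merge(
        rx_days.rename(columns={"prescription_date": "event_date"}).assign(ab=True),
        on=["patient_id", "event_date"],
        how="left",
    )
    infect["ab"] = infect["ab"].to_numpy() == True  # noqa: E712
    infect["year"] = pd.DatetimeIndex(infect["event_date"]).year
    # keep only consultations inside a sampled patient-year's follow-up
    infect = infect.merge(
        segs[["patient_id", "year", "gender", "age_band"]],
        on=["patient_id", "year"],
    )

    keys = ["gender", "age_band"] + (["infection_type"] if by_infection_type else [])
    if by_infection_type:
        infect = infect.rename(columns={"category": "infection_type"})
    ykeys = keys + ["year"]

    ev = (
        infect.groupby(ykeys, observed=True)
        .agg(events=("patient_id", "size"), ab_numerator=("ab", "sum"))
        .reset_index()
    )
    py = (
        segs.groupby(["gender", "age_band", "year"], observed=True)["days"]
        .sum()
        .reset_index()
    )
    tab = ev.merge(py, on=["gender", "age_band", "year"], how="outer")
    for c in ("events", "ab_numerator"):
        tab[c] = tab[c].fillna(0).astype(int)
    tab["days"] = tab["days"].fillna(0.0)
    if by_infection_type:
        tab = tab.dropna(subset=["infection_type"])

    tab["person_time_30d"] = tab["days"] / DAYS_PER_30D_UNIT
    if equal_year_weights:
        tab["rate_y"] = np.where(
            tab["person_time_30d"] > 0, tab["events"] / tab["person_time_30d"], np.nan
        )
        out = (
            tab.groupby(keys, observed=True)
            .agg(
                events=("events", "sum"),
                person_time_30d=("person_time_30d", "sum"),
                rate_per_30d=("rate_y", "mean"),
                ab_numerator=("ab_numerator", "sum"),
            )
            .reset_index()
        )
    else:
        out = (
            tab.groupby(keys, observed=True)
            .agg(
                events=("events", "sum"),
                person_time_30d=("person_time_30d", "sum"),
                ab_numerator=("ab_numerator", "sum"),
            )
            .reset_index()
        )
        out["rate_per_30d"] = np.where(
            out["person_time_30d"] > 0, out["events"] / out["person_time_30d"], np.nan
        )
    out["ab_denominator"] = out["events"]
    out["ab_proportion"] = np.where(
        out["events"] > 0, out["ab_numerator"] / out["events"], np.nan
    )
    out["undefined"] = out["person_time_30d"] <= 0
    cols = keys + [
        "events", "person_time_30d", "rate_per_30d",
        "ab_numerator", "ab_denominator", "ab_proportion", "undefined",
    ]
    return out[cols].sort_values(keys).reset_index(drop=True)


def age_standardise(
    rates: pd.DataFrame, weights: Optional[pd.Series] = None
) -> pd.DataFrame:
    """Age-standardised rate and antibiotic proportion per gender.

    Bands receive equal weight unless ``weights`` (indexed by band label)
    says otherwise. Undefined band rates are excluded with their weight.
    """
    def _agg(g: pd.DataFrame) -> pd.Series:
        w = (
            pd.Series(1.0, index=g["age_band"])
            if weights is None
            else weights.reindex(g["age_band"]).fillna(0.0)
        )
        w = w.values
        ok = ~g["rate_per_30d"].isna().values & (w > 0)
        rate = float(np.average(g["rate_per_30d"].values[ok], weights=w[ok])) if ok.any() else np.nan
        okp = ~g["ab_proportion"].isna().values & (w > 0)
        prop = float(np.average(g["ab_proportion"].values[okp], weights=w[okp])) if okp.any() else np.nan
        return pd.Series({"rate_per_30d": rate, "ab_proportion": prop})

    keys = [c for c in ("gender", "infection_type") if c in rates.columns]
    return rates.groupby(keys, observed=True).apply(_agg, include_groups=False).reset_index()
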