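"""Shared fixtures: all test data is generated programmatically."""
from __future__ import annotations

import datetime as dt

import numpy as np
import pandas as pd
import pytest

from sepsis_nnt import calibrate_simulation, synthetic_ehr
from sepsis_nnt.config import SimulationConfig, StratumParams
from sepsis_nnt.bands import ANALYSIS_BANDS, band_labels

STUDY_START = dt.date(2002, 1, 1)
STUDY_END = dt.date(2017, 12, 31)


def uniform_config(
    n_patients: int,
    rate_30d: float = 0.04,
    ab_prob: float = 0.6,
    hazard_30d: float = 0.0004,
    mult_no_ab: float = 10.0,
    mult_ab: float = 2.0,
    seed: int = 0,
    **overrides,
) -> SimulationConfig:
    """Config with identical dynamics in every gender x age-band stratum."""
    strata = {
        (g, b): StratumParams(
            consult_rate_30d={"rti": 0.6 * rate_30d, "skin": 0.25 * rate_30d, "uti": 0.15 * rate_30d},
            ab_prob=ab_prob,
            sepsis_hazard_30d=hazard_30d,
            mult_no_ab=mult_no_ab,
            mult_ab=mult_ab,
        )
        for g in ("male", "female")
        for b in band_labels(ANALYSIS_BANDS)
    }
    cfg = SimulationConfig(n_patients=n_patients, strata=strata, rng_seed=seed, **overrides)
    cfg.validate()
    return cfg


def make_patients(rows):
    """Hand-crafted patients table from (pid, gender, birth, reg_start,
    reg_end, death) tuples; up-to-standard defaults to reg_start."""
    recs = []
    for pid, gender, birth, reg_start, reg_end, death in rows:
        recs.append(
            {
                "patient_id": pid,
                "gender": gender,
                "birth_date": pd.Timestamp(birth),
                "registration_start": pd.Timestamp(reg_start),
                "up_to_standard_date": pd.Timestamp(reg_start),
                "registration_end": pd.Timestamp(reg_end),
                "death_date": pd.Timestamp(death) if death else pd.NaT,
                "practice_id": 0,
            }
        )
    return pd.DataFrame(recs)


def make_events(rows):
    """Clinical-event rows from (pid, date, category[, source]) tuples."""
    recs = []
    for row in rows:
        pid, date, cat = row[:3]
        src = row[3] if len(row) > 3 else "primary_care"
        recs.append(
            {
                "patient_id": pid,
                "event_date": pd.Timestamp(date),
                "category": cat,
                "code": cat.upper(),
                "source": src,
            }
        )
    return pd.DataFrame(
        recs, columns=["patient_id", "event_date", "category", "code", "source"]
    )


def make_prescriptions(rows):
    return pd.DataFrame(
        [
            {
                "patient_id": pid,
                "prescription_date": pd.Timestamp(date),
                "product_class": "antibiotic",
            }
            for pid, date in rows
        ],
        columns=["patient_id", "prescription_date", "product_class"],
    )


@pytest.fixture(scope="session")
def calibrated_config():
    return calibrate_simulation(n_patients=3000, rng_seed=1234)


@pytest.fixture(scope="session")
def sim_tables(calibrated_config):
    return synthetic_ehr.simulate(calibrated_config)
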