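"""End-to-end orchestration: simulate -> extract -> estimate -> report."""
from __future__ import annotations

import datetime as dt
from typing import Dict, Optional, Tuple

import pandas as pd

from . import cohort, decision_model, sampling, synthetic_ehr
from .bands import ANALYSIS_BANDS
from .config import SimulationConfig
from .report import RunManifest

DEFAULT_STUDY_START = dt.date(2002, 1, 1)
DEFAULT_STUDY_END = dt.date(2017, 12, 31)


def extract_cohort(
    tables: Dict[str, pd.DataFrame],
    study_start=DEFAULT_STUDY_START,
    study_end=DEFAULT_STUDY_END,
    window_days: int = 30,
    bands=ANALYSIS_BANDS,
    censor_at_sepsis: bool = True,
) -> Tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Follow-up, linked incident cases and stratum counts from event tables."""
    patients = tables["patients"]
    events = tables["clinical_events"]
    fu = cohort.compute_follow_up(patients, study_start, study_end)
    cases = cohort.ascertain_incident_sepsis(events, fu)
    cases = cohort.link_lookback(
        cases, events, tables["prescriptions"], window_days=window_days
    )
    counts = cohort.tabulate_strata(
        cases, patients, fu, bands=bands, censor_at_sepsis=censor_at_sepsis
    )
    return fu, cases, counts


def estimate_from_tables(
    stratum_counts: pd.DataFrame,
    rates: pd.DataFrame,
    n_draws: int = decision_model.DEFAULT_N_DRAWS,
    seed: int = 0,
    prior: str = "jeffreys",
):
    """Probability sets and risk estimates per (gender, age band) stratum."""
    rates_idx = rates.set_index(["gender", "age_band"])
    prob_sets = {}
    for row in stratum_counts.itertuples(index=False):
        key = (row.gender, row.age_band)
        if key not in rates_idx.index:
            continue
        rrow = rates_idx.loc[key]
        if row.n_sepsis == 0 or row.n_prior_infection == 0 or rrow["events"] == 0:
            continue  # stratum too sparse for the chain
        prob_sets[key] = decision_model.build_probability_set(
            row._asdict(), rrow
        )
    ests = decision_model.estimate_all_strata(prob_sets, n_draws=n_draws, seed=seed, prior=prior)
    return prob_sets, ests


def run_pipeline(
    config: SimulationConfig,
    study_start=DEFAULT_STUDY_START,
    study_end=DEFAULT_STUDY_END,
    window_days: int = 30,
    n_draws: int = decision_model.DEFAULT_N_DRAWS,
    estimate_seed: int = 0,
    sample_design: Optional[sampling.SampleDesign] = None,
    use_full_population_rates: bool = False,
) -> dict:
    """Simulate a cohort and run the whole analysis on it.

    Returns a dict with the simulated tables, follow-up, cases, stratum
    counts, rates, probability sets, risk estimates and a RunManifest.
    """
    tables = synthetic_ehr.simulate(config)
    fu, cases, counts = extract_cohort(
        tables, study_start, study_end, window_days=window_days,
        bands=tuple(config.analysis_bands),
    )
    if use_full_population_rates:
        segs = cohort.person_year_segments(
            tables["patients"], fu, tuple(config.analysis_bands)
        )
        sample = segs[["patient_id", "year"]].drop_duplicates()
    else:
        design = sample_design or sampling.SampleDesign(rng_seed=config.rng_seed)
        sample = sampling.draw_sample(tables["patients"], fu, design)
    rates = sampling.estimate_rates(
        sample, tables["clinical_events"], tables["prescriptions"],
        tables["patients"], fu, bands=tuple(config.analysis_bands),
    )
    prob_sets, estimates = estimate_from_tables(
        counts, rates, n_draws=n_draws, seed=estimate_seed
    )
    manifest = RunManifest(
        config=config.to_dict(),
        seeds={"simulation": config.rng_seed, "estimation": estimate_seed},
    )
    return {
        "tables": tables,
        "follow_up": fu,
        "cases": cases,
        "stratum_counts": counts,
        "rates": rates,
        "probability_sets": prob_sets,
        "estimates": estimates,
        "manifest": manifest,
    }
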