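"""Synthetic EHR generator with known ground truth.

Generates a primary-care-like database: a registered population with
demographic and registration-interval fields, dated coded consultations for
respiratory, skin and urinary infections, same-day antibiotic prescriptions,
sepsis events, and accumulating frailty deficits.

Generative model (discrete days, piecewise-constant hazards):

* Infection consultations arise as a Poisson process at the configured
  per-30-day rate during registered time, with rates depending on the
  patient's gender and age band (ages fixed at the start of each calendar
  year).
* Each consultation independently receives a same-day antibiotic
  prescription with the stratum's probability.
* The daily sepsis hazard is the stratum baseline ``h0/30``; on the 30 days
  following the most recent consultation it is multiplied by ``mult_ab`` or
  ``mult_no_ab`` according to that consultation's prescription status.
  Sepsis events are simulated by thinning a dominating Poisson process, so
  the event-time law is exact.
* Frailty deficits accumulate with age: a per-deficit presence probability
  at cohort entry plus an annual Poisson accrual, both increasing with age,
  applied to a per-patient random acquisition order over the 36 deficit
  slots.

Because the lag since the most recent consultation is geometric in the
stationary regime, every probability of the downstream decision chain has a
closed form; :func:`ground_truth` returns these implied values together with
the closed-form exposed-window risks and the implied number needed to treat,
for use as a parameter-recovery reference.
"""
from __future__ import annotations

import math
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd

from .bands import assign_band, band_labels
from .config import (
    EXPOSURE_WINDOW_DAYS,
    INFECTION_TYPES,
    SimulationConfig,
    StratumParams,
)
from .errors import ConfigurationError
from .tableio import write_table

_DAY = pd.Timedelta(days=1)

PATIENT_COLUMNS = [
    "patient_id", "gender", "birth_date", "registration_start",
    "up_to_standard_date", "registration_end", "death_date", "practice_id",
]
EVENT_COLUMNS = ["patient_id", "event_date", "category", "code", "source"]
PRESCRIPTION_COLUMNS = ["patient_id", "prescription_date", "product_class"]


def _streams(config: SimulationConfig) -> Dict[str, np.random.Generator]:
    root = np.random.SeedSequence(config.rng_seed)
    pop, ev, fr = root.spawn(3)
    return {
        "population": np.random.default_rng(pop),
        "events": np.random.default_rng(ev),
        "frailty": np.random.default_rng(fr),
    }


# ---------------------------------------------------------------------------
# population
# ---------------------------------------------------------------------------

def generate_population(
    config: SimulationConfig, rng: Optional[np.random.Generator] = None
) -> pd.DataFrame:
    """Generate the registered population as a patients table."""
    config.validate()
    if rng is None:
        rng = _streams(config)["population"]
    n = config.n_patients
    start = pd.Timestamp(config.calendar_start)
    end = pd.Timestamp(config.calendar_end)
    if n == 0:
        return pd.DataFrame(columns=PATIENT_COLUMNS)

    gender = np.where(rng.random(n) < config.female_fraction, "female", "male")

    from .bands import FIVE_YEAR_BANDS, band_label

    if config.age_weights:
        labels = list(config.age_weights)
        weights = np.array([config.age_weights[k] for k in labels], float)
        lo_by_label = {band_label(b): b[0] for b in FIVE_YEAR_BANDS}
        hi_by_label = {band_label(b): (b[1] if b[1] is not None else b[0] + 4) for b in FIVE_YEAR_BANDS}
        try:
            lows = np.array([lo_by_label[l] for l in labels], float)
            highs = np.array([hi_by_label[l] for l in labels], float)
        except KeyError as e:  # pragma: no cover - validated upstream
            raise ConfigurationError(f"age_weights: unknown band label {e}")
    else:
        lows = np.array([b[0] for b in FIVE_YEAR_BANDS], float)
        highs = np.array([b[1] for b in FIVE_YEAR_BANDS], float)
        weights = np.ones(len(lows))
    weights = weights / weights.sum()
    band_idx = rng.choice(len(weights), size=n, p=weights)
    age = lows[band_idx] + rng.random(n) * (highs[band_idx] - lows[band_idx] + 1.0)
    birth_date = start - pd.to_timedelta(np.round(age * 365.25).astype(int), unit="D")

    late = rng.random(n) < config.late_registration_frac
    pre_days = (rng.random(n) * config.max_preregistration_years * 365.25).astype(int)
    span_days = (end - start).days
    late_offset = (rng.random(n) * max(span_days - 30, 1)).astype(int)
    reg_start = np.where(
        late,
        (start + pd.to_timedelta(late_offset, unit="D")).values,
        (start - pd.to_timedelta(pre_days, unit="D")).values,
    )
    reg_start = pd.DatetimeIndex(reg_start)

    trunc = rng.random(n) < config.truncation_frac
    u_t = rng.random(n)
    is_death = trunc & (rng.random(n) < 0.5)
    avail = np.maximum((end - reg_start).days.values, 1)
    t_date = reg_start + pd.to_timedelta((u_t * avail).astype(int), unit="D")
    reg_end = pd.DatetimeIndex(np.where(trunc & ~is_death, t_date.values, end.to_datetime64()))
    death_date = pd.DatetimeIndex(np.where(is_death, t_date.values, np.datetime64("NaT")))

    return pd.DataFrame(
        {
            "patient_id": np.arange(n, dtype=np.int64),
            "gender": gender,
            "birth_date": birth_date,
            "registration_start": reg_start,
            "up_to_standard_date": reg_start,
            "registration_end": reg_end,
            "death_date": death_date,
            "practice_id": rng.integers(0, config.n_practices, size=n),
        }
    )


# ---------------------------------------------------------------------------
# patient-year segments
# ---------------------------------------------------------------------------

def year_segments(patients: pd.DataFrame, config: SimulationConfig) -> pd.DataFrame:
    """Split each patient's active registration into calendar-year segments.

    The active interval is the registration interval clipped to the
    simulation calendar and to the death date. Ages (and hence strata) are
    fixed at January 1 of each year. Returns one row per patient-year with
    ``seg_start`` and the number of active ``days`` (inclusive convention:
    the last registered day is active).
    """
    cal_start = pd.Timestamp(config.calendar_start)
    cal_end = pd.Timestamp(config.calendar_end)
    if patients.empty:
        return pd.DataFrame(
            columns=["patient_id", "gender", "year", "seg_start", "days", "age", "age_band"]
        )
    rec_end = patients["registration_end"].where(
        patients["death_date"].isna()
        | (patients["death_date"] >= patients["registration_end"]),
        patients["death_date"],
    )
    active_start = patients["registration_start"].clip(lower=cal_start)
    active_end = rec_end.clip(upper=cal_end)
    ok = active_end >= active_start
    p = patients.loc[ok].reset_index(drop=True)
    a_start = active_start[ok].reset_index(drop=True)
    a_end = active_end[ok].reset_index(drop=True)

    y0 = a_start.dt.year.values
    y1 = a_end.dt.year.values
    n_years = y1 - y0 + 1
    rows = np.repeat(np.arange(len(p)), n_years)
    year = y0[rows] + (np.arange(n_years.sum()) - np.repeat(np.cumsum(n_years) - n_years, n_years))

    jan1 = pd.to_datetime({"year": year, "month": 1, "day": 1})
    jan1_next = pd.to_datetime({"year": year + 1, "month": 1, "day": 1})
    seg_start = np.maximum(jan1.values, a_start.values[rows])
    seg_end_excl = np.minimum(jan1_next.values, (a_end + _DAY).values[rows])
    days = ((seg_end_excl - seg_start) / np.timedelta64(1, "D")).astype(int)

    birth = p["birth_date"].values[rows]
    age = np.floor((jan1.values - birth) / np.timedelta64(1, "D") / 365.25).astype(int)
    age = np.clip(age, 0, None)

    segs = pd.DataFrame(
        {
            "patient_id": p["patient_id"].values[rows],
            "gender": p["gender"].values[rows],
            "year": year,
            "seg_start": seg_start,
            "days": days,
            "age": age,
        }
    )
    segs = segs[segs["days"] > 0].reset_index(drop=True)
    segs["age_band"] = assign_band(segs["age"].values, tuple(config.analysis_bands))
    return segs


def _stratum_frame(config: SimulationConfig) -> pd.DataFrame:
    rows = []
    for (gender, band), p in config.strata.items():
        row = {"gender": gender, "age_band": band, "ab_prob": p.ab_prob,
               "h0": p.sepsis_hazard_30d, "m1": p.mult_no_ab, "m2": p.mult_ab}
        for t in INFECTION_TYPES:
            row[f"rate_{t}"] = p.consult_rate_30d.get(t, 0.0)
        rows.append(row)
    cols = ["gender", "age_band", "ab_prob", "h0", "m1", "m2"] + [
        f"rate_{t}" for t in INFECTION_TYPES
    ]
    return pd.DataFrame(rows, columns=cols)


def _expand(rng: np.random.Generator, counts: np.ndarray, seg_start, days):
    """Scatter Poisson counts uniformly over their segments; returns row
    indices and event dates."""
    total = int(counts.sum())
    rows = np.repeat(np.arange(len(counts)), counts)
    offs = np.floor(rng.random(total) * days[rows]).astype(int)
    dates = seg_start[rows] + offs * np.timedelta64(1, "D")
    return rows, dates


# ---------------------------------------------------------------------------
# events
# ---------------------------------------------------------------------------

def generate_events(
    patients: pd.DataFrame,
    config: SimulationConfig,
    rng: Optional[np.random.Generator] = None,
    frailty_rng: Optional[np.random.Generator] = None,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Generate (clinical events, prescriptions) for a population.

    The clinical-event stream contains consultation rows (categories
    ``rti``/``skin``/``uti``), ``sepsis`` rows and ``frailty_deficit`` rows,
    all with ``source='primary_care'``. Prescriptions are same-day
    antibiotic rows, one logical prescription per patient-day.
    """
    config.validate()
    if patients.empty:
        raise ConfigurationError("population: must be nonempty")
    if rng is None or frailty_rng is None:
        streams = _streams(config)
        rng = rng or streams["events"]
        frailty_rng = frailty_rng or streams["frailty"]

    segs = year_segments(patients, config)
    params = _stratum_frame(config)
    segs = segs.merge(params, on=["gender", "age_band"], how="left")
    for c in ["ab_prob", "h0", "m1", "m2"] + [f"rate_{t}" for t in INFECTION_TYPES]:
        segs[c] = segs[c].fillna(1.0 if c in ("m1", "m2") else 0.0)

    seg_start = segs["seg_start"].values
    days = segs["days"].values.astype(float)

    # consultations, per infection type in fixed order
    consult_parts = []
    for t in INFECTION_TYPES:
        lam = segs[f"rate_{t}"].values / 30.0 * days
        rows, dates = _expand(rng, rng.poisson(lam), seg_start, segs["days"].values)
        ab = rng.random(len(rows)) < segs["ab_prob"].values[rows]
        consult_parts.append(
            pd.DataFrame(
                {
                    "patient_id": segs["patient_id"].values[rows],
                    "event_date": dates,
                    "category": t,
                    "code": f"{t.upper()}-C",
                    "ab": ab,
                }
            )
        )
    consults = pd.concat(consult_parts, ignore_index=True)
    consults = consults.sort_values(["event_date", "patient_id"], kind="stable").reset_index(drop=True)

    prescriptions = (
        consults.loc[consults["ab"], ["patient_id", "event_date"]]
        .drop_duplicates()
        .rename(columns={"event_date": "prescription_date"})
        .assign(product_class="antibiotic")
        .sort_values(["patient_id", "prescription_date"])
        .reset_index(drop=True)
    )

    # sepsis by thinning a dominating process
    m_global = 1.0
    for p in config.strata.values():
        m_global = max(m_global, p.mult_no_ab, p.mult_ab)
    lam = segs["h0"].values / 30.0 * m_global * days
    cand_rows, cand_dates = _expand(rng, rng.poisson(lam), seg_start, segs["days"].values)
    cand = pd.DataFrame(
        {
            "patient_id": segs["patient_id"].values[cand_rows],
            "event_date": cand_dates,
            "m1": segs["m1"].values[cand_rows],
            "m2": segs["m2"].values[cand_rows],
        }
    ).sort_values(["event_date", "patient_id"], kind="stable").reset_index(drop=True)
    if len(cand):
        linked = pd.merge_asof(
            cand,
            consults[["event_date", "patient_id", "ab"]].rename(columns={"event_date": "c_date"}),
            left_on="event_date",
            right_on="c_date",
            by="patient_id",
            direction="backward",
            allow_exact_matches=False,
            tolerance=pd.Timedelta(days=EXPOSURE_WINDOW_DAYS),
        )
        mult = np.ones(len(cand))
        has = linked["c_date"].notna().values
        ab = linked["ab"].to_numpy() == True  # noqa: E712 - object col with NaN
        mult[has & ab] = cand["m2"].values[has & ab]
        mult[has & ~ab] = cand["m1"].values[has & ~ab]
        accept = rng.random(len(cand)) < mult / m_global
        sepsis = cand.loc[accept, ["patient_id", "event_date"]].copy()
    else:
        rng.random(0)
        sepsis = cand[["patient_id", "event_date"]].copy()
    sepsis["category"] = "sepsis"
    sepsis["code"] = "SEPSIS"

    deficits = _generate_deficits(patients, segs, config, frailty_rng)

    consult_ev = consults[["patient_id", "event_date", "category", "code"]]
    events = pd.concat([consult_ev, sepsis, deficits], ignore_index=True)
    events["source"] = "primary_care"
    events = events.sort_values(
        ["patient_id", "event_date", "category"], kind="stable"
    ).reset_index(drop=True)
    return events[EVENT_COLUMNS], prescriptions[PRESCRIPTION_COLUMNS]


def _generate_deficits(
    patients: pd.DataFrame,
    segs: pd.DataFrame,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Frailty-deficit events: baseline presence at entry + annual accrual.

    Each patient has a fixed random acquisition order over the deficit
    slots; deficits are taken from that order, so histories are cumulative
    by construction.
    """
    fp = config.frailty
    n = len(patients)
    nd = fp.n_deficits
    order = np.argsort(rng.random((n, nd)), axis=1)
    pid = patients["patient_id"].values

    first_seg = segs.groupby("patient_id", sort=True).first()
    active = first_seg.index.values  # patients with any active time
    pos = pd.Index(pid).get_indexer(active)
    entry_date = first_seg["seg_start"].values
    entry_age = first_seg["age"].values.astype(float)

    p0 = np.clip(
        fp.initial_base + fp.initial_slope * np.maximum(0.0, entry_age - fp.pivot_age),
        0.0, 0.95,
    )
    count = np.zeros(n, dtype=int)
    out_pid, out_date, out_slot = [], [], []

    def emit(idx_local, new_counts, dates):
        """idx_local indexes `patients`; emits slots order[c_old:c_new)."""
        add = new_counts - count[idx_local]
        keep = add > 0
        idx_k = idx_local[keep]
        add_k = add[keep]
        if len(idx_k):
            rows = np.repeat(idx_k, add_k)
            base = np.repeat(count[idx_k], add_k)
            within = np.arange(add_k.sum()) - np.repeat(np.cumsum(add_k) - add_k, add_k)
            slots = order[rows, base + within]
            out_pid.append(pid[rows])
            out_date.append(np.repeat(dates[keep], add_k))
            out_slot.append(slots)
        count[idx_local] = new_counts

    n0 = rng.binomial(nd, p0)
    emit(pos, n0, entry_date)

    for year in np.sort(segs["year"].unique()):
        sy = segs[segs["year"] == year]
        idx_local = pd.Index(pid).get_indexer(sy["patient_id"].values)
        lam = (
            fp.annual_base
            + fp.annual_slope * np.maximum(0.0, sy["age"].values - fp.pivot_age)
        ) * (sy["days"].values / 365.25)
        k = rng.poisson(lam)
        new = np.minimum(nd, count[idx_local] + k)
        emit(idx_local, new, sy["seg_start"].values)

    if not out_pid:
        return pd.DataFrame(columns=["patient_id", "event_date", "category", "code"])
    df = pd.DataFrame(
        {
            "patient_id": np.concatenate(out_pid),
            "event_date": np.concatenate(out_date),
            "category": "frailty_deficit",
            "code": [f"EFI{s:02d}" for s in np.concatenate(out_slot)],
        }
    )
    return df


# ---------------------------------------------------------------------------
# ground truth
# ---------------------------------------------------------------------------

def implied_quantities(
    params: StratumParams, window_days: int = 30
) -> Dict[str, float]:
    """Exact stationary values of the decision-chain inputs for one stratum.

    ``p_infection`` is the consultation rate per 30 days (what the sampling
    estimator measures); ``p_sepsis`` is the marginal sepsis hazard per 30
    days; ``p_infection_given_sepsis`` uses the half-open look-back window
    (lags 1..window_days-1), matching the cohort linkage rule.
    """
    r = params.total_rate_30d
    lam = r / 30.0
    q = math.exp(-lam)
    q_exp = q ** EXPOSURE_WINDOW_DAYS
    s_exp = 1.0 - q_exp
    s_link = 1.0 - q ** (window_days - 1)
    a = params.ab_prob
    m1, m2 = params.mult_no_ab, params.mult_ab
    m_bar = a * m2 + (1.0 - a) * m1
    denom = q_exp + m_bar * s_exp
    h_day = params.sepsis_hazard_30d / 30.0 * denom
    p_is = (m_bar * s_link / denom) if denom > 0 else 0.0
    f = a * m2 / m_bar if m_bar > 0 else 0.0
    return {
        "p_infection": r,
        "p_sepsis": 30.0 * h_day,
        "p_infection_given_sepsis": p_is,
        "p_ab_given_infection": a,
        "frac_ab_among_linked": f,
    }


def ground_truth(config: SimulationConfig, window_days: int = 30) -> pd.DataFrame:
    """Analytically implied chain inputs and risks per configured stratum.

    Columns include both the closed-form exposed-window risks
    (``exposed_p_sepsis_no_ab = h0 * mult_no_ab`` etc., with
    ``nnt = 1 / (h0 * (mult_no_ab - mult_ab))``) and the values the
    decision chain converges to when fed the pipeline's estimators
    (``chain_*`` columns). The two differ by window-edge factors of order
    ``window/30``. A zero risk difference is reported as an infinite NNT
    with ``nnt_effect='none'`` (harm as negative difference,
    ``nnt_effect='harm'``).
    """
    from .decision_model import nnt as _nnt

    config.validate()
    rows = []
    for (gender, band), p in sorted(config.strata.items()):
        q = implied_quantities(p, window_days=window_days)
        h0 = p.sepsis_hazard_30d
        psi = (
            q["p_infection_given_sepsis"] * q["p_sepsis"] / q["p_infection"]
            if q["p_infection"] > 0
            else float("nan")
        )
        a, f = q["p_ab_given_infection"], q["frac_ab_among_linked"]
        chain_no_ab = (1.0 - f) * psi / (1.0 - a) if 0 < a < 1 else float("nan")
        chain_ab = f * psi / a if 0 < a < 1 else float("nan")
        res = _nnt(h0 * p.mult_no_ab, h0 * p.mult_ab)
        rows.append(
            {
                "gender": gender,
                "age_band": band,
                **q,
                "chain_p_sepsis_given_infection": psi,
                "chain_p_sepsis_no_ab": chain_no_ab,
                "chain_p_sepsis_ab": chain_ab,
                "exposed_p_sepsis_no_ab": h0 * p.mult_no_ab,
                "exposed_p_sepsis_ab": h0 * p.mult_ab,
                "risk_difference": res.risk_difference,
                "nnt": res.value,
                "nnt_effect": res.effect,
            }
        )
    return pd.DataFrame(rows)


def ground_truth_probability_sets(
    config: SimulationConfig, window_days: int = 30
) -> Dict[tuple, "object"]:
    """The implied chain inputs per stratum as ProbabilitySet objects
    (no counts — these are exact values, not estimates)."""
    from .decision_model import ProbabilitySet

    gt = ground_truth(config, window_days=window_days)
    out = {}
    for row in gt.itertuples(index=False):
        out[(row.gender, row.age_band)] = ProbabilitySet(
            p_infection=row.p_infection,
            p_sepsis=row.p_sepsis,
            p_infection_given_sepsis=row.p_infection_given_sepsis,
            p_ab_given_infection=row.p_ab_given_infection,
            p_ab_given_infection_and_sepsis=row.frac_ab_among_linked,
        )
    return out


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

def simulate(config: SimulationConfig) -> Dict[str, pd.DataFrame]:
    """Run the full generator; returns patients, clinical_events,
    prescriptions and the deficit rows as a separate view."""
    streams = _streams(config)
    patients = generate_population(config, streams["population"])
    if patients.empty:
        events = pd.DataFrame(columns=EVENT_COLUMNS)
        rx = pd.DataFrame(columns=PRESCRIPTION_COLUMNS)
    else:
        events, rx = generate_events(
            patients, config, streams["events"], streams["frailty"]
        )
    deficits = events[events["category"] == "frailty_deficit"].reset_index(drop=True)
    return {
        "patients": patients,
        "clinical_events": events,
        "prescriptions": rx,
        "deficits": deficits,
    }


def write_tables(tables: Dict[str, pd.DataFrame], outdir, manifest_digest=None) -> None:
    for name in ("patients", "clinical_events", "prescriptions", "deficits"):
        write_table(tables[name], f"{outdir}/{name}.csv", manifest_digest)
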