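"""Default calibration targets and config construction.

``REFERENCE_STRATA`` holds published stratified estimates for a UK
primary-care population observed 2002–2017: per gender and age band, the
probability of an infection consultation per 30 days, the probability of a
first sepsis event per 30 days, the proportion of sepsis cases with an
infection consultation in the preceding 30 days, the proportion of
consultations with a same-day antibiotic, the derived sepsis probabilities
in the no-antibiotic and antibiotic arms with the published
number-needed-to-treat and its 95% uncertainty interval, and the underlying
case counts (sepsis events, events with a preceding consultation, events
whose linked consultation had a same-day antibiotic prescription).

:func:`calibrate_simulation` inverts the generator's stationary model so
that a simulation run with the returned config has these values as its
implied chain inputs (see :func:`sepsis_nnt.synthetic_ehr.ground_truth`).
"""
from __future__ import annotations

import math
from typing import Optional, Sequence

import pandas as pd

from .bands import ANALYSIS_BANDS, band_labels
from .config import (
    FrailtyParams,
    SimulationConfig,
    StratumParams,
)
from .errors import ConfigurationError

_COLUMNS = [
    "gender", "age_band", "p_infection", "p_sepsis", "p_infection_given_sepsis",
    "p_ab_given_infection", "p_sepsis_no_ab", "p_sepsis_ab",
    "nnt", "nnt_lo", "nnt_hi", "n_sepsis", "n_prior_infection", "n_same_date_ab",
]

_ROWS = [
    ("male", "0-4", 0.08, 0.000014, 0.23, 0.43, 0.000054, 0.000020, 29773, 18458, 71091, 224, 51, 11),
    ("male", "5-14", 0.04, 0.000006, 0.16, 0.48, 0.000047, 0.000008, 25606, 17962, 40817, 303, 48, 6),
    ("male", "15-24", 0.02, 0.000008, 0.17, 0.58, 0.000101, 0.000041, 16921, 10285, 39551, 360, 59, 21),
    ("male", "25-34", 0.02, 0.000009, 0.17, 0.60, 0.000193, 0.000039, 6517, 4779, 9522, 449, 78, 18),
    ("male", "35-44", 0.02, 0.000013, 0.15, 0.62, 0.000239, 0.000039, 5035, 3980, 6610, 791, 117, 24),
    ("male", "45-54", 0.02, 0.000022, 0.18, 0.62, 0.000472, 0.000071, 2497, 2121, 2999, 1342, 241, 47),
    ("male", "55-64", 0.02, 0.000048, 0.19, 0.63, 0.000825, 0.000135, 1449, 1282, 1652, 2466, 472, 102),
    ("male", "65-74", 0.03, 0.000105, 0.18, 0.64, 0.001305, 0.000202, 907, 823, 1007, 3933, 724, 155),
    ("male", "75-84", 0.04, 0.000219, 0.23, 0.63, 0.002700, 0.000478, 450, 413, 492, 4752, 1089, 256),
    ("male", "85+", 0.05, 0.000416, 0.26, 0.61, 0.004647, 0.000833, 262, 236, 293, 2738, 713, 158),
    ("female", "0-4", 0.08, 0.000014, 0.27, 0.43, 0.000060, 0.000023, 27014, 16739, 65709, 204, 55, 12),
    ("female", "5-14", 0.04, 0.000005, 0.14, 0.51, 0.000025, 0.000010, 65522, 35239, 240067, 238, 32, 9),
    ("female", "15-24", 0.04, 0.000012, 0.15, 0.61, 0.000080, 0.000024, 18120, 12472, 30241, 500, 76, 24),
    ("female", "25-34", 0.04, 0.000016, 0.14, 0.63, 0.000105, 0.000033, 13926, 10044, 21273, 806, 110, 38),
    ("female", "35-44", 0.04, 0.000018, 0.16, 0.66, 0.000184, 0.000030, 6513, 5349, 8194, 1095, 175, 41),
    ("female", "45-54", 0.03, 0.000028, 0.16, 0.66, 0.000278, 0.000054, 4463, 3756, 5421, 1631, 267, 72),
    ("female", "55-64", 0.04, 0.000048, 0.18, 0.67, 0.000490, 0.000088, 2486, 2179, 2876, 2443, 445, 119),
    ("female", "65-74", 0.04, 0.000080, 0.20, 0.67, 0.000793, 0.000151, 1557, 1388, 1758, 3215, 646, 180),
    ("female", "75-84", 0.05, 0.000138, 0.22, 0.66, 0.001525, 0.000231, 773, 705, 847, 3982, 890, 204),
    ("female", "85+", 0.05, 0.000271, 0.26, 0.64, 0.003110, 0.000509, 385, 352, 421, 3772, 984, 222),
]

#: default split of the total consultation rate across infection types;
#: respiratory infections dominate primary-care antibiotic workload, urinary
#: infections are the least frequent of the three.
DEFAULT_TYPE_SPLIT = {"rti": 0.60, "skin": 0.25, "uti": 0.15}

#: stylised age structure (weights over 5-year bands at simulation start)
_AGE_TAPER = {
    "65-69": 0.8, "70-74": 0.6, "75-79": 0.45, "80-84": 0.3,
    "85-89": 0.18, "90-94": 0.1, "95-99": 0.05, "100-104": 0.02,
}


def reference_strata() -> pd.DataFrame:
    """The reference calibration table, one row per gender x age band."""
    return pd.DataFrame(_ROWS, columns=_COLUMNS)


def default_age_weights() -> dict:
    from .bands import FIVE_YEAR_BANDS, band_label

    return {
        band_label(b): _AGE_TAPER.get(band_label(b), 1.0) for b in FIVE_YEAR_BANDS
    }


def invert_stratum(
    p_infection: float,
    p_sepsis: float,
    p_infection_given_sepsis: float,
    p_ab_given_infection: float,
    frac_ab_among_linked: float,
    window_days: int = 30,
    type_split: Optional[dict] = None,
) -> StratumParams:
    """Solve for generator parameters whose implied chain inputs match targets.

    Under the generator, consultations are Poisson at daily rate
    ``lam = p_infection/30`` and the lag since the most recent consultation is
    geometric, so the stationary fraction of days with lag in 1..k is
    ``1 - exp(-k*lam)``. Given the target exposure odds this pins the
    AB-averaged hazard multiplier, the baseline hazard, and the two arm
    multipliers. Raises :class:`ConfigurationError` when the targets are not
    attainable (e.g. linkage proportion larger than the exposure window can
    produce).
    """
    split = dict(type_split or DEFAULT_TYPE_SPLIT)
    if abs(sum(split.values()) - 1.0) > 1e-9:
        raise ConfigurationError("type_split: fractions must sum to 1")
    lam = p_infection / 30.0
    q = math.exp(-lam)
    q30 = q ** 30
    s_exp = 1.0 - q30
    s_link = 1.0 - q ** (window_days - 1)
    denom = s_link - p_infection_given_sepsis * s_exp
    if denom <= 0:
        raise ConfigurationError(
            "p_infection_given_sepsis: not attainable with this consultation rate"
        )
    m_bar = p_infection_given_sepsis * q30 / denom
    h0 = p_sepsis / (q30 + m_bar * s_exp)
    a = p_ab_given_infection
    f = frac_ab_among_linked
    if not 0.0 < a < 1.0:
        raise ConfigurationError("p_ab_given_infection: must be in (0,1)")
    return StratumParams(
        consult_rate_30d={t: p_infection * w for t, w in split.items()},
        ab_prob=a,
        sepsis_hazard_30d=h0,
        mult_no_ab=(1.0 - f) * m_bar / (1.0 - a),
        mult_ab=f * m_bar / a,
    )


def calibrate_simulation(
    n_patients: int = 20000,
    rng_seed: int = 0,
    genders: Sequence[str] = ("male", "female"),
    age_bands: Optional[Sequence[str]] = None,
    window_days: int = 30,
    **overrides,
) -> SimulationConfig:
    """Build a :class:`SimulationConfig` calibrated to the reference strata.

    ``age_bands`` restricts calibration to a subset of analysis-band labels
    (all strata still get parameters; unlisted strata reuse the reference
    values too — the subset only matters for bespoke overrides upstream).
    Additional keyword arguments override :class:`SimulationConfig` fields.
    """
    ref = reference_strata()
    strata = {}
    for row in ref.itertuples(index=False):
        if row.gender not in genders:
            continue
        if age_bands is not None and row.age_band not in age_bands:
            continue
        f = row.n_same_date_ab / row.n_prior_infection
        p_is = row.n_prior_infection / row.n_sepsis
        strata[(row.gender, row.age_band)] = invert_stratum(
            row.p_infection, row.p_sepsis, p_is, row.p_ab_given_infection,
            f, window_days=window_days,
        )
    cfg = SimulationConfig(
        n_patients=n_patients,
        age_weights=default_age_weights(),
        strata=strata,
        analysis_bands=ANALYSIS_BANDS,
        frailty=FrailtyParams(),
        rng_seed=rng_seed,
        **overrides,
    )
    cfg.validate()
    return cfg
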