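"""Simulation configuration for the synthetic EHR generator.

The generator emulates a UK primary-care database: registered patients with
registration intervals, dated coded consultations for common infections
(respiratory tract, skin, urinary tract), same-day antibiotic prescriptions,
sepsis events, and accumulating frailty deficits. All behaviour is driven by
a :class:`SimulationConfig`, which can be round-tripped through YAML.

Per-stratum event dynamics are held in :class:`StratumParams`, one per
(gender, analysis age band):

* ``consult_rate_30d`` — infection consultation rate per 30 days, split by
  infection type; consultations arise as a Poisson process during registered
  time.
* ``ab_prob`` — probability that a consultation receives a same-day
  antibiotic prescription.
* ``sepsis_hazard_30d`` — baseline (unexposed) sepsis hazard per 30 days.
* ``mult_no_ab`` / ``mult_ab`` — relative sepsis hazard during the 30 days
  following a consultation without / with a same-day antibiotic.
"""
from __future__ import annotations

import dataclasses
import datetime as dt
from dataclasses import dataclass, field
from typing import Dict, Mapping, Optional, Sequence, Tuple

import yaml

from .bands import ANALYSIS_BANDS, Band, band_labels, validate_bands
from .errors import ConfigurationError

GENDERS = ("male", "female")
INFECTION_TYPES = ("rti", "skin", "uti")
EVENT_SOURCES = ("primary_care", "hospital", "mortality")

#: days of elevated sepsis hazard after a consultation
EXPOSURE_WINDOW_DAYS = 30


@dataclass
class StratumParams:
    consult_rate_30d: Dict[str, float]
    ab_prob: float
    sepsis_hazard_30d: float
    mult_no_ab: float = 1.0
    mult_ab: float = 1.0

    @property
    def total_rate_30d(self) -> float:
        return float(sum(self.consult_rate_30d.values()))

    def validate(self, where: str) -> None:
        for t, r in self.consult_rate_30d.items():
            if t not in INFECTION_TYPES:
                raise ConfigurationError(
                    f"{where}.consult_rate_30d: unknown infection type {t!r}"
                )
            if not r >= 0:
                raise ConfigurationError(f"{where}.consult_rate_30d[{t}]: rate must be >= 0, got {r}")
        if not 0.0 <= self.ab_prob <= 1.0:
            raise ConfigurationError(f"{where}.ab_prob: probability must be in [0,1], got {self.ab_prob}")
        if not self.sepsis_hazard_30d >= 0:
            raise ConfigurationError(f"{where}.sepsis_hazard_30d: rate must be >= 0, got {self.sepsis_hazard_30d}")
        if not self.mult_no_ab > 0:
            raise ConfigurationError(f"{where}.mult_no_ab: multiplier must be > 0, got {self.mult_no_ab}")
        if not self.mult_ab > 0:
            raise ConfigurationError(f"{where}.mult_ab: multiplier must be > 0, got {self.mult_ab}")


@dataclass
class FrailtyParams:
    """Deficit-accumulation intensities for the 36-deficit frailty index.

    The probability that any given deficit is already present at cohort
    entry is ``initial_base + initial_slope * max(0, age - pivot_age)``;
    thereafter new deficits accrue as Poisson with annual rate
    ``annual_base + annual_slope * max(0, age - pivot_age)``. Both are
    clipped so probabilities stay in [0, 0.95]. Defaults make moderate and
    severe frailty common only at older ages.
    """

    n_deficits: int = 36
    pivot_age: float = 40.0
    initial_base: float = 0.03
    initial_slope: float = 0.0035
    annual_base: float = 0.01
    annual_slope: float = 0.002

    def validate(self) -> None:
        if self.n_deficits < 1:
            raise ConfigurationError(f"frailty.n_deficits: must be >= 1, got {self.n_deficits}")
        for name in ("initial_base", "initial_slope", "annual_base", "annual_slope"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"frailty.{name}: must be >= 0")


@dataclass
class SimulationConfig:
    n_patients: int = 1000
    calendar_start: dt.date = dt.date(2001, 1, 1)
    calendar_end: dt.date = dt.date(2017, 12, 31)
    #: weights over 5-year age bands (labels "0-4" .. "100-104"); need not
    #: be normalised. Ages are drawn at calendar_start.
    age_weights: Dict[str, float] = field(default_factory=dict)
    #: (gender, band label) -> StratumParams
    strata: Dict[Tuple[str, str], StratumParams] = field(default_factory=dict)
    analysis_bands: Sequence[Band] = ANALYSIS_BANDS
    female_fraction: float = 0.5
    n_practices: int = 20
    #: fraction of patients whose registration interval is truncated before
    #: calendar_end (half by death, half by deregistration)
    truncation_frac: float = 0.15
    #: fraction registering after calendar_start instead of before it
    late_registration_frac: float = 0.1
    #: maximum years of registration history before calendar_start
    max_preregistration_years: float = 10.0
    frailty: FrailtyParams = field(default_factory=FrailtyParams)
    rng_seed: int = 0

    def validate(self) -> None:
        if self.n_patients < 0:
            raise ConfigurationError(f"n_patients: must be >= 0, got {self.n_patients}")
        if not self.calendar_start < self.calendar_end:
            raise ConfigurationError("calendar_start: must precede calendar_end")
        validate_bands(tuple(self.analysis_bands))
        labels = set(band_labels(tuple(self.analysis_bands)))
        for w_name in ("female_fraction", "truncation_frac", "late_registration_frac"):
            v = getattr(self, w_name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{w_name}: probability must be in [0,1], got {v}")
        if self.n_practices < 1:
            raise ConfigurationError(f"n_practices: must be >= 1, got {self.n_practices}")
        for lab, w in self.age_weights.items():
            if w < 0:
                raise ConfigurationError(f"age_weights[{lab}]: must be >= 0, got {w}")
        if self.age_weights and sum(self.age_weights.values()) <= 0:
            raise ConfigurationError("age_weights: weights sum to zero")
        for (gender, band), params in self.strata.items():
            if gender not in GENDERS:
                raise ConfigurationError(f"strata[{gender},{band}]: unknown gender {gender!r}")
            if band not in labels:
                raise ConfigurationError(f"strata[{gender},{band}]: band {band!r} not in analysis_bands")
            params.validate(f"strata[{gender},{band}]")
        self.frailty.validate()

    # -- YAML round-trip ---------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["calendar_start"] = self.calendar_start.isoformat()
        d["calendar_end"] = self.calendar_end.isoformat()
        d["analysis_bands"] = [list(b) for b in self.analysis_bands]
        d["strata"] = {
            f"{g}|{b}": dataclasses.asdict(p) for (g, b), p in self.strata.items()
        }
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimulationConfig":
        d = dict(d)
        d["calendar_start"] = dt.date.fromisoformat(d["calendar_start"])
        d["calendar_end"] = dt.date.fromisoformat(d["calendar_end"])
        d["analysis_bands"] = tuple(
            (lo, None if hi is None else int(hi)) for lo, hi in d["analysis_bands"]
        )
        d["strata"] = {
            tuple(k.split("|")): StratumParams(**v) for k, v in d["strata"].items()
        }
        d["frailty"] = FrailtyParams(**d.get("frailty", {}))
        cfg = cls(**d)
        cfg.validate()
        return cfg

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))
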