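"""Bayesian decision tree for sepsis risk after an infection consultation.

Five input probabilities describe one population stratum:

* ``p_infection`` — P(Infection): probability of an infection consultation
  in a 30-day period (from the sampled consultation rate).
* ``p_sepsis`` — P(Sepsis): probability of a first sepsis event in a
  30-day period (from whole-cohort incidence).
* ``p_infection_given_sepsis`` — P(Infection|Sepsis): proportion of sepsis
  cases with an infection consultation in the look-back window.
* ``p_ab_given_infection`` — P(AB|Infection): proportion of consultations
  with a same-day antibiotic prescription.
* ``p_ab_given_infection_and_sepsis`` — P([AB|Infection]|Sepsis): among
  linked sepsis cases, the proportion whose consultation had a same-day
  antibiotic.

Bayes' theorem chains these into the probability of sepsis in the 30 days
after a consultation, split by prescribing arm::

    P(Sepsis|Infection)        = P(Infection|Sepsis) P(Sepsis) / P(Infection)
    P(Sepsis|[AB|Infection])   = P([AB|Inf]|Sepsis)  P(Sepsis|Inf) / P(AB|Inf)
    P(Sepsis|[NoAB|Infection]) = P([NoAB|Inf]|Sepsis) P(Sepsis|Inf) / P(NoAB|Inf)
    NNT = 1 / (P(Sepsis|NoAB) - P(Sepsis|AB))

Uncertainty is propagated by Monte Carlo: each input probability with
observed counts (k successes of n trials) is drawn from its beta posterior
(Jeffreys Beta(k+1/2, n-k+1/2) by default, uniform-prior Beta(k+1, n-k+1)
optionally), the chain is evaluated per draw, and central estimates
(medians) with 2.5th–97.5th percentile uncertainty intervals are reported.
Draws with a non-positive risk difference propagate to the NNT distribution
as censored at infinity, and their fraction is reported.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Mapping, Optional, Tuple

import numpy as np

from .errors import ConfigurationError, DomainError

DEFAULT_N_DRAWS = 10_000
_PRIORS = {"jeffreys": 0.5, "uniform": 1.0}

_INPUT_NAMES = (
    "p_infection",
    "p_sepsis",
    "p_infection_given_sepsis",
    "p_ab_given_infection",
    "p_ab_given_infection_and_sepsis",
)


@dataclass
class ProbabilitySet:
    """The five input probabilities for one stratum, with optional counts.

    ``counts`` maps input names to ``(numerator, denominator)`` pairs; a
    denominator may be non-integer (person-time in 30-day units).
    """

    p_infection: float
    p_sepsis: float
    p_infection_given_sepsis: float
    p_ab_given_infection: float
    p_ab_given_infection_and_sepsis: float
    counts: Dict[str, Tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in _INPUT_NAMES:
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name}: probability must be in [0,1], got {v}")
        for name, (k, n) in self.counts.items():
            if name not in _INPUT_NAMES:
                raise ConfigurationError(f"counts: unknown input {name!r}")
            if not (0 <= k <= n) or n <= 0:
                raise ConfigurationError(
                    f"counts[{name}]: need 0 <= numerator <= denominator, got ({k}, {n})"
                )

    @classmethod
    def from_counts(cls, counts: Mapping[str, Tuple[float, float]]) -> "ProbabilitySet":
        missing = [n for n in _INPUT_NAMES if n not in counts]
        if missing:
            raise ConfigurationError(f"counts: missing inputs {missing}")
        vals = {n: counts[n][0] / counts[n][1] for n in _INPUT_NAMES}
        return cls(**vals, counts=dict(counts))


@dataclass
class NNTResult:
    """Number needed to treat, or a sentinel for no effect / harm.

    ``value`` is finite for a beneficial risk difference, ``inf`` when the
    difference is exactly zero, and the (negative) number needed to harm
    when the difference is negative; ``effect`` distinguishes the cases and
    ``risk_difference`` carries the raw difference.
    """

    value: float
    risk_difference: float
    effect: str  # 'benefit' | 'none' | 'harm'


@dataclass
class RiskEstimate:
    """Derived quantities for one stratum: plug-in values, medians and
    95% uncertainty intervals (NaN bounds when no draws were made)."""

    p_sepsis_given_infection: float
    p_sepsis_no_ab: float
    p_sepsis_ab: float
    nnt: NNTResult
    median: Dict[str, float] = field(default_factory=dict)
    ui_low: Dict[str, float] = field(default_factory=dict)
    ui_high: Dict[str, float] = field(default_factory=dict)
    n_draws: int = 0
    rng_seed: Optional[int] = None
    frac_nonpositive_diff: float = 0.0
    stratum: Optional[tuple] = None
    draws: Optional[Dict[str, np.ndarray]] = None


# ---------------------------------------------------------------------------
# deterministic chain
# ---------------------------------------------------------------------------

def sepsis_given_infection(p: ProbabilitySet) -> float:
    """P(Sepsis|Infection) via the Bayes quotient."""
    if p.p_infection == 0:
        raise DomainError("p_infection is zero; P(Sepsis|Infection) undefined")
    v = p.p_infection_given_sepsis * p.p_sepsis / p.p_infection
    if v > 1.0:
        raise DomainError(f"P(Sepsis|Infection) = {v} exceeds 1; inputs inconsistent")
    return v


def sepsis_given_ab_arm(p: ProbabilitySet, arm: str) -> float:
    """P(Sepsis | consulted and was (not) prescribed), ``arm`` in
    {'ab', 'no_ab'}."""
    psi = sepsis_given_infection(p)
    a = p.p_ab_given_infection
    f = p.p_ab_given_infection_and_sepsis
    if arm == "ab":
        if a == 0:
            raise DomainError("p_ab_given_infection is zero; AB arm undefined")
        v = f * psi / a
    elif arm == "no_ab":
        if a == 1:
            raise DomainError("p_ab_given_infection is one; no-AB arm undefined")
        v = (1.0 - f) * psi / (1.0 - a)
    else:
        raise ConfigurationError(f"arm: must be 'ab' or 'no_ab', got {arm!r}")
    if v > 1.0:
        raise DomainError(f"P(Sepsis|{arm} arm) = {v} exceeds 1; inputs inconsistent")
    return v


def nnt(p_no_ab: float, p_ab: float) -> NNTResult:
    """Antibiotic prescriptions needed to prevent one sepsis event."""
    for name, v in (("p_no_ab", p_no_ab), ("p_ab", p_ab)):
        if not 0.0 <= v <= 1.0:
            raise DomainError(f"{name}: probability must be in [0,1], got {v}")
    diff = p_no_ab - p_ab
    if diff > 0:
        return NNTResult(1.0 / diff, diff, "benefit")
    if diff == 0:
        return NNTResult(float("inf"), 0.0, "none")
    return NNTResult(1.0 / diff, diff, "harm")


def chain(p: ProbabilitySet) -> Dict[str, float]:
    """Evaluate the full deterministic chain; returns the derived values."""
    psi = sepsis_given_infection(p)
    p_no = sepsis_given_ab_arm(p, "no_ab")
    p_ab = sepsis_given_ab_arm(p, "ab")
    res = nnt(p_no, p_ab)
    return {
        "p_sepsis_given_infection": psi,
        "p_sepsis_no_ab": p_no,
        "p_sepsis_ab": p_ab,
        "nnt": res.value,
        "risk_difference": res.risk_difference,
    }


# ---------------------------------------------------------------------------
# Monte Carlo uncertainty
# ---------------------------------------------------------------------------

def draw_uncertainty(
    p: ProbabilitySet,
    n_draws: int = DEFAULT_N_DRAWS,
    seed=None,
    prior: str = "jeffreys",
    return_draws: bool = False,
) -> RiskEstimate:
    """Propagate count uncertainty through the chain by beta Monte Carlo.

    All five inputs must carry counts. Draws across inputs are independent.
    Medians and (2.5%, 97.5%) percentiles are reported for every derived
    quantity; NNT draws with a non-positive risk difference are censored at
    +infinity (so a heavily censored stratum has an infinite upper bound).
    """
    if prior not in _PRIORS:
        raise ConfigurationError(f"prior: must be one of {sorted(_PRIORS)}, got {prior!r}")
    missing = [n for n in _INPUT_NAMES if n not in p.counts]
    if missing:
        raise ConfigurationError(f"counts missing for inputs {missing}")
    if n_draws < 100:
        warnings.warn(f"n_draws={n_draws} is small; uncertainty intervals will be noisy")

    c = _PRIORS[prior]
    rng = np.random.default_rng(seed)
    draws = {}
    for name in _INPUT_NAMES:
        k, n = p.counts[name]
        draws[name] = rng.beta(k + c, n - k + c, size=n_draws)

    psi = draws["p_infection_given_sepsis"] * draws["p_sepsis"] / draws["p_infection"]
    a = draws["p_ab_given_infection"]
    f = draws["p_ab_given_infection_and_sepsis"]
    p_no = (1.0 - f) * psi / (1.0 - a)
    p_ab = f * psi / a
    diff = p_no - p_ab
    nonpos = diff <= 0
    with np.errstate(divide="ignore"):
        nnt_draws = np.where(nonpos, np.inf, 1.0 / np.where(nonpos, 1.0, diff))

    plug = chain(p)
    q = {"p_sepsis_given_infection": psi, "p_sepsis_no_ab": p_no, "p_sepsis_ab": p_ab, "nnt": nnt_draws}

    def _pct(v, level):
        # linear interpolation breaks on censored-at-infinity draws
        method = "nearest" if np.isinf(v).any() else "linear"
        return float(np.percentile(v, level, method=method))

    med = {k_: _pct(v, 50) for k_, v in q.items()}
    lo = {k_: _pct(v, 2.5) for k_, v in q.items()}
    hi = {k_: _pct(v, 97.5) for k_, v in q.items()}
    return RiskEstimate(
        p_sepsis_given_infection=plug["p_sepsis_given_infection"],
        p_sepsis_no_ab=plug["p_sepsis_no_ab"],
        p_sepsis_ab=plug["p_sepsis_ab"],
        nnt=nnt(plug["p_sepsis_no_ab"], plug["p_sepsis_ab"]),
        median=med,
        ui_low=lo,
        ui_high=hi,
        n_draws=n_draws,
        rng_seed=seed if isinstance(seed, int) else None,
        frac_nonpositive_diff=float(nonpos.mean()),
        draws={**draws, **q} if return_draws else None,
    )


def estimate_all_strata(
    prob_sets: Mapping[tuple, ProbabilitySet],
    n_draws: int = DEFAULT_N_DRAWS,
    seed: int = 0,
    prior: str = "jeffreys",
) -> Dict[tuple, RiskEstimate]:
    """One :class:`RiskEstimate` per stratum, with per-stratum substreams.

    Substreams are spawned from a shared seed in sorted stratum order, so
    identical strata receive identical draws and results are reproducible
    regardless of mapping order. Per-stratum errors are recorded on the
    result (``stratum`` -> Exception) rather than aborting the batch.
    """
    keys = sorted(prob_sets)
    seqs = np.random.SeedSequence(seed).spawn(len(keys))
    out: Dict[tuple, RiskEstimate] = {}
    for key, seq in zip(keys, seqs):
        try:
            est = draw_uncertainty(prob_sets[key], n_draws=n_draws, seed=seq, prior=prior)
            est.stratum = key
            out[key] = est
        except (ConfigurationError, DomainError) as e:
            out[key] = e  # type: ignore[assignment]
    return out


def build_probability_set(stratum_counts, rate_row) -> ProbabilitySet:
    """Assemble a ProbabilitySet from one stratum-counts row and one
    rates row (as produced by cohort.tabulate_strata / sampling.estimate_rates).
    """
    units = stratum_counts["person_years"] * (365.25 / 30.0)
    counts = {
        "p_sepsis": (stratum_counts["n_sepsis"], units),
        "p_infection_given_sepsis": (
            stratum_counts["n_prior_infection"],
            stratum_counts["n_sepsis"],
        ),
        "p_ab_given_infection_and_sepsis": (
            stratum_counts["n_same_date_ab"],
            stratum_counts["n_prior_infection"],
        ),
        "p_infection": (rate_row["events"], rate_row["person_time_30d"]),
        "p_ab_given_infection": (rate_row["ab_numerator"], rate_row["ab_denominator"]),
    }
    return ProbabilitySet.from_counts(counts)
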