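# Methods

## The estimation problem

The package estimates, per population stratum (gender × age band,
optionally × frailty category × infection type × calendar period), the
probability of a first sepsis event in the 30 days after a primary-care
infection consultation, separately for consultations with and without a
same-day antibiotic prescription, and the number of prescriptions per
prevented sepsis event (NNT). Because neither arm is randomised, the
estimates are associational: prescribers treat sicker patients, so the
no-antibiotic risk is likely understated and the NNT overstated relative
to a trial.

The estimation is indirect. Sepsis is rare, so its incidence and the
exposure status of cases are taken from a whole cohort, while consultation
and prescribing rates come from a stratified patient sample; Bayes'
theorem combines the two sources (see README for the chain). This mirrors
how such analyses are run against large primary-care databases, where
downloading every consultation for millions of patients is infeasible but
rare outcomes can be ascertained population-wide.

## Cohort definitions

* **Follow-up** runs from the latest of (registration + 1 year,
  practice up-to-standard date, study start) to the earliest of
  (deregistration, death, study end). Person-time uses the half-open
  convention `[start, end)` at day resolution, divided by 365.25; a
  registration interval spanning the whole 2002–2017 study therefore
  yields 16.0 person-years to within a day.
* **Incident sepsis** is the first sepsis-coded event inside follow-up;
  recurrences are ignored. An earlier code *outside* follow-up does not
  suppress a later in-interval event by default — EHR codes often restate
  historical problems, and the alternative (prevalent-case suppression) is
  a flag on `ascertain_incident_sepsis`.
* **Look-back linkage**: the most recent infection consultation with lag
  1..W−1 days before the sepsis date (W = 30, sensitivity 60). Both
  endpoints are excluded: a consultation on the sepsis date itself is
  ambiguous coding of the same encounter, and "the preceding W days"
  is read strictly. When several consultations fall in the window the most
  recent is the clinically proximate exposure and defines the infection
  type and antibiotic status; `exposure_rule="any_ab"` switches to
  counting any same-day-prescribed consultation in the window.
* **Ages** are completed years at January 1 of the event's calendar year,
  the same convention the simulator uses, so every case falls in exactly
  one band and annual bookkeeping is exact.
* **Incidence denominators** are censored at the incident sepsis date by
  default (`censor_at_sepsis`), making first-events / person-time a
  consistent hazard estimator; switching censoring off changes incidence
  by well under 1% at realistic event rates but matters for exact
  parameter-recovery checks.

## Frailty

The 36-deficit electronic frailty index is computed per patient per
calendar year as (distinct deficits recorded in any year ≤ y) / 36;
deficits are cumulative by definition. Category cut-points follow the
published convention: ≤ 0.12 nonfrail, (0.12, 0.24] mild, (0.24, 0.36]
moderate, > 0.36 severe; they are configurable. The index is evaluated
from age 55 by default — younger patients rarely exceed mild frailty.
Deficit code lists are an abstract 36-slot map (real code dictionaries are
licensed); the simulator emits codes `EFI00`–`EFI35`. Whole-cohort
person-years are allocated across frailty categories using the
person-year proportions observed in the sampled cohort, with the
floating-point residue of the multiplication added to the largest cell so
totals are conserved exactly.

## Sampling design

Per study year, practice, gender and 5-year age band (to 104), up to 10
patients (configurable) are drawn without replacement; a patient sampled
in year y contributes that year's person-time and consultations. This
equalises precision across age bands and gives each practice and year
equal weight; practice-size weighting is deliberately out of scope. Rates
are pooled counts / person-time by default (equal-year-weight averaging is
an option), and P(Infection) per 30 days is rate × 30 days — valid for
the small rates involved (≤ 0.08), and stated here because rate and
probability are conflated in the field's reporting convention.

## Uncertainty propagation

Each input probability with observed counts (k of n; n may be non-integer
person-time units) is drawn from Beta(k+½, n−k+½) — the Jeffreys
posterior, which is well-behaved at small k — with Beta(k+1, n−k+1)
(uniform prior) as an option. 10,000 draws by default; draws across the
five inputs are independent (no correlation structure is identifiable
from published marginals). Central estimates are medians; intervals are
the 2.5th–97.5th percentiles. Draws with a non-positive risk difference
are censored at +∞ in the NNT distribution and their fraction is
reported; percentiles over censored draws use nearest-order statistics
(linear interpolation is undefined between infinities). The deterministic
plug-in chain is reported alongside the medians. Per-stratum substreams
are spawned from one seed in sorted stratum order, so batch results are
reproducible and independent of dictionary order.

## Synthetic EHR generator

No generative model is published for this setting; the simulator adopts
the simplest mechanism under which every estimand above is well defined
and recoverable:

* discrete days; consultations per infection type are Poisson at the
  stratum's per-30-day rate during registered time (default type split
  60% respiratory / 25% skin / 15% urinary, reflecting primary-care
  antibiotic workload);
* each consultation independently receives a same-day prescription with
  the stratum's probability; same-day duplicates collapse to one logical
  prescription;
* the daily sepsis hazard is the stratum baseline h₀/30, multiplied on
  the 30 days after the most recent consultation by `mult_no_ab` or
  `mult_ab` according to that consultation's prescription status. Events
  are generated by thinning a dominating Poisson process, so event times
  are exact, and recurrences are generated (the cohort stage takes the
  first);
* frailty deficits: a per-deficit presence probability at entry plus
  annual Poisson accrual, both increasing linearly with age over 40,
  applied to a fixed per-patient random acquisition order — so histories
  are cumulative by construction and older strata are more often
  moderately or severely frail;
* ages are fixed at January 1 of each calendar year (no mid-year band
  migration), calendar granularity is days, dates are ISO-8601.

Because the lag since the most recent consultation is geometric at
stationarity, the model has closed forms for everything the pipeline
estimates. `ground_truth()` reports both:

* the **exposed-window risks** h₀·mult per arm, with
  NNT = 1/(h₀·(mult_no_ab − mult_ab)) — the generator's native effect
  size; and
* the **implied chain values** — the exact stationary values of the five
  chain inputs under the half-open look-back window, and the arm risks
  the Bayes chain converges to when fed consistent estimators.

The two differ by window-edge factors of order (W−1)/30 (≈ 3% at W=30);
parameter-recovery tests compare pipeline output to the implied values,
which is the estimand the analysis actually targets.

Default parameters are calibrated by inverting the stationary model
against published stratified estimates for UK primary care 2002–2017
(bundled in `sepsis_nnt.calibration`): consultation probabilities
0.02–0.08 per 30 days, same-day antibiotic proportions 0.43–0.67, sepsis
probabilities 6×10⁻⁶ to 4×10⁻⁴ per 30 days, and linked-case proportions
14–27%, per gender and age band. Where the published record is silent —
stratum person-time denominators, the population age structure, practice
count, truncation rates — the defaults are one-time choices of plausible
magnitude (a stylised tapering age pyramid, 20 practices, 15% truncated
registrations) and are not tuned to any output.

### What the simulator does not emulate

Antibiotic class and dose, regional variation, out-of-hours prescribing,
secular trends (beyond an optional period stratification of the
analysis), miscoded or missing consultations, prescribing-by-severity
confounding, and hospital-acquired sepsis. Passing recovery tests
therefore show the *pipeline* is consistent for its estimands under the
stated mechanism — not that the estimates are unconfounded in real data,
where prescribing is anything but random.

## Validation scales

The deterministic published-table checks run in milliseconds. The
end-to-end parameter-recovery check simulates one heavy stratum
(men 85+, 40,000 patients, ≈ 5.5×10⁵ person-years, ≈ 2,700 sepsis events)
and requires both arm probabilities within |z| < 3 of the implied values
(delta-method SEs). Interval coverage is assessed over 200 replicates of
the stratum's sufficient statistics at that scale with 1,000 draws each,
requiring ≥ 90% coverage for nominal 95% intervals. The published
men-85+ NNT interval (236–293) is used as a bracketing check on the
10,000-draw median with denominators of plausible magnitude; exact
reproduction of published intervals is impossible because per-stratum
denominators were never published.

## Known limitations

* The Bayes-chain estimator inherits the ~3% window-edge factor relative
  to the generator's native exposed-window risk; both are reported by
  `ground_truth()` so the discrepancy is visible rather than hidden.
* The bundled published inputs are rounded to 2 significant figures for
  rates and probabilities; chains recomputed from them reproduce
  published derived values only to within ~10% for most strata (the
  women 15–24 row, recomputed from the underlying counts, is exact at the
  printed precision).
* NNT uncertainty intervals assume independent inputs; any real
  correlation between, e.g., consultation rates and prescribing
  proportions would change interval widths.
* Frailty below 55 and per-practice weighting are intentionally not
  modelled.
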