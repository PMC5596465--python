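# Methods

## Model

`physupply` simulates physician supply as a deterministic, discrete-time
stock-flow system with an annual step, reported on a 5-year grid.
Stocks are expected (real-valued) headcounts; there is no randomness
anywhere in the engine, and rounding to integers happens only in
report tables. The model is linear in headcounts: doubling all initial
stocks and quota intakes doubles every stock at every time.

Within one year, in order:

1. **Intake.** `general_quota` and `regional_quota` entrants (absolute
   counts per calendar year) enter first-year medicine; student cohorts
   advance one program year (`school_duration`, default 6 years).
2. **Licensing exam.** The final-year cohort passes with `pass_rate`;
   failures exit the clinical pipeline (booked to cumulative exits —
   retake behaviour is not modelled because it is unidentifiable from
   aggregate data, and attrition explicitly includes drop-out).
3. **Pre-matching branches.** Passers enter graduate school with
   `grad_school_rate` and choose non-clinical careers with
   `nonclinical_rate`, in that order. By default graduate-school
   entrants do not return to clinical practice (conservative);
   `grad_school_return=True` re-inserts them into the practising flow
   after `grad_school_delay` years (default 4).
4. **Residency matching.** The remainder matches with `match_rate`;
   unmatched passers are routed to the external pool (they train and
   practise outside the prefecture). Residents advance
   (`residency_duration`, default 2 years).
5. **Location choice.** Residency completers stay in the prefecture
   with a quota-specific stay rate (`stay_rate_general` 0.453,
   `stay_rate_regional` 0.833 by default — the reported retention gap
   between regional-quota graduates and their peers); the complement
   moves to the external pool. The parameter table also carries an
   informational `other_pref_rate`; the engine uses the complement of
   the stay rate so that the headcount ledger always closes. Stayers
   are allocated across sub-regions by the `smsa_option_rates` vector
   (fractions summing to 1).
6. **Migration.** `inflow_rate` × external pool enters the prefecture
   (allocated by the option rates); an exogenous absolute inflow
   series can replace the rate-based inflow. `outflow_rate` × each
   region's stock moves to the external pool.
7. **Exits.** `retirement_rate` + `other_rates` (mortality, drop-out,
   emigration) remove headcount from each region into cumulative
   exits. The age–sex-pyramid detail behind real retirement schedules
   is deliberately simplified to a scalar (or per-year) rate; the rate
   is applied to the regional pools, not to the external aggregate.

**Conservation invariant.** At every step the change in total
headcount — all pipeline stocks plus the external pool plus cumulative
exits — equals the quota intake (tested to 1e-6, exact in floating
point up to summation order). Rates in [0, 1] guarantee non-negative
stocks; a parameter combination that would drive a stock negative
(e.g. retirement + other attrition above 1) raises an error instead of
silently clipping.

Time-varying parameters are defined per calendar year; years past the
last defined row are extended piecewise-constant with a logged
warning, while years before the first row are an error naming the
year.

## Validation

Backcasting runs the same engine over a historical window.
`validate` computes, per comparison year, the relative error
e_t = |ŷ_t − y_t| / y_t and gates on RMSE = √(Σ e_t²/n) < 0.1 (strict
inequality; threshold configurable). The default comparison years are
the biennial survey years within the window. Errors are kept at full
precision; rounding is display-only.

`estimate_retirement_rate` recovers an annual exit rate from trend
data as the window average of r_t = 1 − (P_{t+1} − entries_t) / P_t;
an implied rate outside [0, 1] is a warning (clamping is opt-in)
because it usually signals mis-specified entry accounting rather than
a legitimate rate.

## Indicators

* **Density** = physicians / population × 100 000.
* **Sufficiency** = forecast / required × correction coefficient.
  The required numbers come from hospital-administrator surveys and
  exclude clinics, while the forecast counts all practising
  physicians; the default correction is therefore the *hospital share*
  hospital/(hospital+clinic), scaling the forecast to its comparable
  hospital component. The literal quotient hospital/clinic is
  available (`mode="hospital_to_clinic"`) because the defining
  sentence in the source literature is ambiguous; the share reading is
  the default since a forecast × (hospital/clinic) quotient has no
  consistent units interpretation.
* **Classification** is inclusive at the boundary: sufficiency ≥ 1 is
  `sufficient`, otherwise `shortage`.
* **Gini** over regional densities uses the unweighted pairwise form
  G = (1/2n²μ) ΣΣ|yᵢ − yⱼ|: each SMSA counts once regardless of
  population, so G measures inequality *between areas*, bounded by
  (n−1)/n. It is computed via the sorted-rank identity (O(n log n)),
  which the test suite checks against a brute-force double sum. An
  all-zero density vector returns 0 with a warning (degenerate case).
  A population-weighted variant was considered and rejected as the
  default because the between-area reading matches the indicator's
  planning use.
* **Prefecture rows** use the prefecture-level required number, not
  the sum of the regional requirements (the two surveys need not
  add up).
* Report-time rounding only: headcounts to integers (half-to-even),
  density and sufficiency to two decimals, Gini to three, percent
  change to one.

## Synthetic data

The generator emulates the shape of the real inputs — ministry survey
aggregates that are not openly redistributable — with known ground
truth, at magnitudes chosen once for realism:

* ~5.5 M residents and 12 019 physicians at baseline across 20 SMSAs,
  45% of both concentrated in one dominant urban region; peripheral
  regions depopulate 2–6% per 5-year period while the core holds.
* Physicians-per-capita outside the core carry a seeded lognormal
  dispersion (sd 0.25), producing a baseline between-area Gini near
  0.14 — the order observed for real prefecture-level physician
  densities. Option rates equal baseline physician shares (new
  physicians settle where practices already are).
* Intakes: 270 general + up to 30 regional entrants/year (three
  medical schools' scale; the regional quota ramps from its 1997
  introduction). Rates: pass 0.90, match 0.95, graduate school 0.05,
  non-clinical 0.02, stay 0.453/0.833, inflow 0.002 of a
  rest-of-country pool set to 24× the prefecture stock, outflow 0.01,
  retirement 0.03 plus 0.005 other attrition.
* Required numbers are *constructed*: the k = round(shortage_fraction
  × n) lowest-density regions sit at baseline sufficiency 0.90, the
  rest at 1.15, and the prefecture at 0.88 — so classification tests
  have exact expected counts.
* Historic series are **self-consistent**: with `noise_sd = 0` the
  "observed" series is the engine's own backcast, so validation round
  trips give RMSE exactly 0 (the generator and the validator sum
  region headcounts in the same floating-point order to keep this
  bit-exact). `noise_sd > 0` applies multiplicative exp(N(0, sd))
  noise, which never produces negative headcounts.
* Geometries are toy rectangular tiles on a lon-lat grid (labelled
  synthetic stand-ins, not administrative boundaries).

Every generator draws from `default_rng([seed, stream])` with a
distinct stream per function — no global state, and outputs are
identical for identical (profile, seed).

**What passing tests do and do not show.** The synthetic prefecture
exercises every code path with exact ground truth, but it is
noiseless and structurally simple: real survey series carry
measurement error, real career-path rates drift with policy, and real
required numbers change over time (held fixed here). A validation
pass on self-consistent data demonstrates the engine's internal
consistency, not forecast accuracy on real data; the noise modes give
a first sense of robustness only.

## Numerical choices

* CSV loaders use round-trip float parsing so a written fixture
  reloads bit-exactly; determinism tests compare artifacts byte for
  byte.
* Percent change from a zero start value (e.g. the Gini of a
  single-region run) is reported as missing rather than an error at
  report level; the underlying function still raises.
* The exam/branch/matching order (fail → graduate school →
  non-clinical → match) fixes one consistent reading of the career
  path; with aggregate-only data the alternative orderings are
  observationally close and all conserve headcount.
* Problem sizes in tests and the acceptance script: 20 regions,
  21 simulated years, six validation years, 200 recovery replicates —
  small enough to run the whole suite in seconds while exercising
  every contract.

## Known limitations

* Supply side only: required numbers are static inputs; demand
  dynamics are out of scope.
* No uncertainty quantification — the engine is a deterministic
  expected-value model, so scenario comparison (not prediction
  intervals) is the intended use.
* Specialty mix, age–sex-resolved retirement, and within-region
  allocation below the SMSA level are not modelled.
* The external pool is a single aggregate; inflow composition
  (career stage of in-migrating physicians) is ignored.
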