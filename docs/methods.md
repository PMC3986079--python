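# Methods

This note documents the model implemented by `pgxcea`, its conventions and
numerical choices, and what the synthetic components do and do not establish.

## Model structure

Two strategies for a closed cohort (default *N* = 1,000, age 30) starting
urate-lowering therapy:

* **usual care** — all patients start allopurinol and face the marginal
  SJS/TEN incidence *I<sub>a</sub>*;
* **genetic testing** — all patients are genotyped for HLA-B\*5801 first.
  Positives (probability `S·P + (1−Sp)(1−P)`) receive probenecid, assumed to
  carry zero SJS/TEN risk; false negatives face the carrier incidence *I₁*
  and true negatives the non-carrier incidence *I₀*.

SJS/TEN is confined to the first cycle (consistent with reaction onset at
treatment initiation; no late-onset hazard is modelled). A fraction
`case_fatality` of cases die; `prob_des` of survivors develop permanent dry
eye syndrome. The Markov stage then runs three states — alive without DES,
alive with DES (absorbing until death), dead — in annual cycles over the
fixed life-expectancy horizon. All quantities are cohort expectations;
the base case involves no randomness.

## Genotype-conditional incidence: two association forms

The association between carriage and SJS/TEN enters as a single parameter
(point 348.33, 95% CI 19.15–6336.88). Two readings are implemented:

* `odds_ratio` — the exact two-constraint system (marginal incidence +
  odds-ratio identity), solved by bracketed Brent root-finding on *I₀* in
  `(0, min(1, Ia/(1−P)))` to machine tolerance. At the base case it gives
  *I₁* = 0.0104941, *I₀* = 3.0446e-5.
* `risk_ratio` (pipeline default) — the closed form
  `I0 = Ia/((1−P)+P·R)`, `I1 = R·I0`, giving *I₁* = 0.0104959,
  *I₀* = 3.0132e-5 and the downstream testing-arm incidence 0.0256 per
  1,000.

The two differ by ~1% at the base case (the odds→risk correction
`1/(1+(OR−1)·I0)` is no longer negligible when `OR·Ia` is appreciable); they
converge for rarer events. The reference results this package reproduces are
internally consistent only with the risk-ratio algebra, which is why it is
the default; the exact odds solver is retained for methodological use and is
cross-checked in the tests by forward-substituting its solution into both
defining equations. Full-precision values are always carried downstream —
printed roundings are display-only.

## Discounting

Costs and QALYs are discounted at `r = 0.03`/year over the horizon
`T = 42.7` years. The annuity factor under the end-of-year convention is the
closed form `(1−(1+r)^−T)/r`, decomposed into per-cycle weights
`w_t = (v^(t−1) − v^min(t,T))/r` (so the fractional terminal year carries an
exact fractional weight, not a truncated one). Alternative conventions shift
the within-year valuation point by `δ` years before year-end, multiplying by
`(1+r)^δ`:

| convention | δ | A(3%, 42.7 y) |
|---|---|---|
| `end_of_year` | 0 | 23.8986 |
| `calibrated` (default) | 0.04481 | 23.9303 |
| `midyear` | 0.5 | 24.2548 |
| `beginning_of_year` | 1 | 24.6156 |

The default offset is a calibration: the reference cost accounting this
model reproduces implies a base-case factor of 23.9303 (annual drug flow of
411.99 THB/person accumulating to 9,859,037 THB over the 1,000-patient
cohort), i.e. flows valued ~16 days before year-end. The convention
generalises smoothly to every discount rate (0–6% in one-way analysis) and
horizon, and reduces to `A = T` at `r = 0`.

## Accrual conventions

* One-time items — the genotyping fee, SJS/TEN management (15,440.275 THB),
  and SJS/TEN patient/relative transport and food (1,561.46 THB) — are paid
  in cycle 1 undiscounted; fatal cases still incur them.
* Deaths forfeit all recurring cost and QALY accrual (death is effectively
  at cycle start). Survivors accrue annual flows — drug, gout management
  (7,512 THB/y), gout visiting (1,634.69 THB/y), and for DES cases also DES
  management (4,043.90 THB/y) and DES visiting (831.58 THB/y) — over the
  full annuity.
* QALYs: `u_gout · A` per event-free survivor; DES cases lose
  `(u_gout − u_gout_des) · A`; the dead accrue nothing.
* Drug cost has two modes. `replicate_paper` (default) prices every patient
  at allopurinol (411.99 THB/y) regardless of test result, with SJS/TEN
  survivors switching to the probenecid price (1,277.50 THB/y) from cycle 2
  — this is the only accounting consistent with the reference cost table,
  where the testing arm's drug bill is a flat allopurinol annuity.
  `truthful` additionally charges test-positives the probenecid price for
  life; it raises the testing arm's drug bill by ~3.1 M THB and is the
  appropriate mode for prospective budgeting. The switch is symmetric across
  arms: any SJS/TEN survivor who started allopurinol moves to the
  alternative drug. (An asymmetric variant — switching usual-care survivors
  only — was rejected because it breaks the structural identity that at
  zero allele prevalence the strategies differ by exactly the cost of
  testing.)
* Indirect/productivity costs are excluded (double-counting with utilities);
  no renal-function stratification — the alternative drug's identity enters
  only through its annual price (scenario analysis).
* `run_cohort` accepts an optional constant background-mortality rate that
  decays event-free survival (an exploratory life-table-style mode; the
  calibrated default keeps the fixed-horizon annuity, which is what the
  reference totals are consistent with).

Consistency is enforced two ways: cohort QALYs recomputed from the per-cycle
occupancy trace must match the closed form to 1e-6, and a patient-level
microsimulation with identical conventions must agree within Monte Carlo
error (below).

## Sensitivity analysis

**One-way / tornado.** Each ranged parameter is set to its range ends with
everything else fixed and the full pipeline re-run; bars are sorted by
`|ICER_high − ICER_low|`. The gout-management cost range (149–474,254 THB/y)
dominates the tornado.

**Scenarios.** Arbitrary overrides re-run the pipeline; overriding the
starting age requires an explicit matching life expectancy (the model has no
internal life table).

**PSA.** Each of the 21 uncertain parameters is sampled independently per
iteration: beta for probabilities and utilities, gamma for costs, lognormal
for the association (log-location at the point estimate, i.e. median
348.33). Ranges are read as central 95% intervals, so `sd = (max−min)/3.92`;
beta and gamma are moment-matched to the point value and that sd (an
infeasible beta sd is clipped to the maximal feasible variance with a
warning). Held fixed: discount rate (a policy convention), cohort size,
starting age, life expectancy, the threshold (varied only along the CEAC
grid), and sensitivity/specificity (no stated uncertainty). Draws are taken
from a single `numpy` Generator in sorted parameter-name order; infeasible
combinations are rejected and resampled with a logged count. Defaults:
10,000 iterations, seed 20140414, λ grid 0–500,000 THB in 5,000 THB steps;
10,000 iterations stabilise the CEAC to roughly ±1 percentage point. Ties at
NMB = 0 count as not cost-effective (strict inequality; arbitrary but fixed).

Two caveats are worth stating. The gout-management and SJS/TEN-management
cost ranges are extremely wide relative to their means (cv ≈ 16 and 2.1), so
the moment-matched gammas are heavily skewed: most gout-cost draws are far
below the point value and rare draws exceed the stated maximum severalfold.
Consequently (i) the probability of cost-effectiveness at the threshold is
reproducible only to within the distribution-interpretation and Monte Carlo
tolerance (±a few percentage points), and (ii) roughly 1 iteration in 10,000
lands at ΔCost ≤ 0 through an extreme SJS/TEN-management draw, so "testing
increases costs in every iteration" holds only almost surely, not surely,
under this parameterisation.

## Synthetic components

`simulate_patients` realises the decision tree per patient (draw order:
genotype, test result, SJS/TEN event, death, DES; one seeded stream) with
the same accrual rules and drug-cost mode as the cohort model. It emulates
first-order (sampling) variation only: no parameter uncertainty, no
between-patient heterogeneity beyond genotype, no secular trends — so
agreement with the cohort model (each mean within 3 standard errors at
n = 10⁶) validates the implementation's internal consistency, not the
model's fidelity to real Thai patients. `generate_parameter_sets` perturbs
every ranged parameter uniformly within its range (scaled toward the point
value), yielding valid parameter sets by construction for property-based
testing.

## Numerical and degenerate-input choices

* Root-finding: Brent with machine-precision tolerances on a guaranteed
  bracket; the solution is verified by forward evaluation, not by iteration
  count.
* `ia = 0` yields a zero incidence split; `p = 0` puts the whole marginal
  risk in non-carriers (the carrier incidence is then a counterfactual,
  capped at 1 in the risk-ratio form).
* PPV/NPV with zero-probability denominators return `None`, never a number.
* Dominance: ΔQ > 0 > ΔC is `dominant`, ΔQ < 0 < ΔC `dominated`; ΔQ = 0
  with ΔC ≠ 0 leaves the ICER `undefined`; NMB is always reported. A free
  test makes screening dominant at the base case.
* Monetary outputs are displayed at 2 dp (THB) with a fixed 31 THB/USD
  display conversion; incidences at 4 dp; internal arithmetic is full double
  precision throughout.

## Problem sizes

The shipped tests and the acceptance script use the study-scale settings
throughout: the 1,000-patient cohort for all deterministic stages, 10,000
PSA iterations, and 10⁶ simulated patients per strategy for the
oracle-equivalence check (a few seconds of CPU). Property-based tests use
100-example Hypothesis sweeps over the valid parameter domain.

## Known limitations

* The fixed life-expectancy annuity ignores age-specific background
  mortality; the optional background-mortality argument is a constant-rate
  approximation, not a life table.
* No correlation structure in the PSA (none is specified for these inputs).
* The alternative drug is assumed reaction-free and therapeutically
  equivalent; benzbromarone/febuxostat enter only as price scenarios.
* No value-of-information analysis; exports are plain data (CSV/JSON), not
  figures.
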