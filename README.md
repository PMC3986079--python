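# pgxcea

Cost-utility model for **pharmacogenetic screening before allopurinol**: should
Thai patients starting urate-lowering therapy be genotyped for **HLA-B\*5801**
— the allele strongly associated with allopurinol-induced Stevens-Johnson
syndrome / toxic epidermal necrolysis (SJS/TEN) — so that carriers can receive
probenecid instead?

The package is aimed at health-economic modellers and methods researchers: it
implements the full decision-analytic pipeline as a tested, scriptable Python
library with a CLI, rather than as a spreadsheet.

## The model

A decision tree feeds a lifetime Markov cohort model (states: gout without
complications, gout with permanent dry eye syndrome (DES), dead) for a
hypothetical cohort of *N* = 1,000 patients aged 30, societal perspective,
costs in 2013 THB, 3%/year discounting of costs and outcomes.

**Genotype-conditional risk.** From the marginal incidence *I<sub>a</sub>* of
allopurinol-induced SJS/TEN, allele prevalence *P*, and association strength
*OR*, the carrier and non-carrier incidences (*I₁*, *I₀*) solve

```
Ia = P·I1 + (1−P)·I0          OR = [I1/(1−I1)] / [I0/(1−I0)]
```

(`split_incidence_by_genotype`, bracketed root-finding), or the risk-ratio
closed form `I0 = Ia / ((1−P) + P·R)`, `I1 = R·I0`
(`split_incidence_risk_ratio`, the pipeline default — see
`docs/methods.md`). Test positives (PPV/NPV from Bayes' rule; the assay has
sensitivity = specificity = 1) receive probenecid, which carries no SJS/TEN
risk.

**Accounting.** SJS/TEN occurs in cycle 1; a fraction 0.1134 of cases die and
37.6% of survivors develop permanent DES (utility 0.48 vs 0.71 for
uncomplicated gout). Survivors accrue annual costs and utilities over a
discounted annuity across the 42.7-year life expectancy; one-time costs (test,
SJS/TEN management and visiting) are undiscounted in cycle 1. Strategies are
compared by ΔCost, ΔQALY, the ICER, and net monetary benefit at the Thai
willingness-to-pay threshold λ = 160,000 THB/QALY.

**Uncertainty.** One-way sweeps over every tabulated parameter range (tornado
ordering), scenario overrides, and a probabilistic sensitivity analysis
(beta for probabilities/utilities, gamma for costs, lognormal for the
association; ranges read as central 95% intervals) with CE-plane points,
NMB per iteration, and the cost-effectiveness acceptability curve.

A patient-level microsimulation (`simulate_patients`) realises the identical
tree stochastically and serves as an independent oracle for the cohort
expectations.

## Worked example

```python
from pgxcea import default_parameters, run_base_case

res = run_base_case(default_parameters())
ce = res["ce"]
print(f"cases prevented /1000: {ce.cases_prevented_per_1000:.4f}")
print(f"deaths prevented /1000: {ce.deaths_prevented_per_1000:.4f}")
print(f"dCost {ce.delta_cost:,.2f} THB  dQALY {ce.delta_qaly:.4f}")
print(f"ICER {ce.icer:,.2f} THB/QALY  NMB@160k {ce.nmb:,.2f} THB")
```

prints

```
cases prevented /1000: 1.5744
deaths prevented /1000: 0.1785
dCost 925,101.01 THB  dQALY 5.9221
ICER 156,211.33 THB/QALY  NMB@160k 22,436.93 THB
```

Screening prevents ~1.57 SJS/TEN cases and ~0.18 deaths per 1,000 patients
(a ~98.4% relative reduction), costs ~0.93 M THB more for the 1,000-patient
cohort (the 1 M THB of tests, minus averted SJS/TEN, DES and drug costs, plus
the gout-care costs of the extra survivors), and gains ~5.9 QALYs — an ICER
just under the 160,000 THB/QALY threshold, hence borderline cost-effective
(positive NMB). The same numbers, organised as the standard outcome table,
come from the CLI:

```sh
pgxcea basecase --outdir out/          # outcome table CSV + JSON + manifest
pgxcea risk                            # incidence split and PPV/NPV
pgxcea oneway                          # tornado-sorted one-way sweep
pgxcea scenario --override cost_test=2000
pgxcea psa --iterations 10000 --seed 20140414
pgxcea microsim --n 1000000 --strategy usual_care
```

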