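# coxcut

Survival analysis for administrative-claims cohorts in which a treatment's
hazard ratio changes over follow-up: new-user / active-comparator cohort
construction, detection of the change point by bootstrap-maximized Cox
partial likelihood, two-period hazard-ratio estimation, Mantel–Haenszel
adjusted event rates, and an inverse-probability-weighted (IPW)
propensity-score sensitivity analysis.

## The scientific problem

Diabetic patients at high cardiovascular risk should, per guidelines,
receive a statin as first-line lipid-lowering therapy, yet fibrate
monotherapy remains common in primary care.  Comparing initiators of the
two drugs in claims data raises two methodological problems this package
addresses:

1. **Cohort validity.**  Prevalent-user and indication biases are limited
   by a new-user design (a 30-month washout free of any lipid-lowering
   drug before the first of ≥2 consecutive GP reimbursements) with an
   active comparator, disease definitions from reimbursement density
   (≥3 reimbursements of oral antidiabetics / antihypertensives within a
   one-year span), and exclusion of anyone with a prior cardiovascular
   hospitalization.

2. **Non-proportional hazards.**  The effect of fibrate vs statin on the
   composite endpoint (all-cause death, ischemic stroke, MI, above-ankle
   amputation) is not constant over follow-up.  The treatment indicator X
   is therefore decomposed into interval copies,

   X = Σₖ Xₖ(t),  Xₖ(t) = X for t ∈ Pₖ and 0 otherwise,

   so each interval Pₖ of follow-up gets its own hazard ratio
   HRₖ = exp(βₖ) in the Cox model λ(t|Z) = λ₀(t)·exp(Σₖ βₖXₖ(t) + γ'Z).
   The cut-off between intervals is chosen by profiling the maximized log
   partial likelihood over monthly candidate cut-offs and, for robustness
   to the realized event times, taking the candidate that maximizes the
   **median of 500 bootstrap log-likelihoods** (resamples stratified by
   arm) subject to proportional hazards holding inside each interval
   (Schoenfeld score test).

Since the national claims databases this design targets (SNIIRAM/PMSI) are
access-restricted, the package includes a synthetic claims generator with
known ground truth — confounded treatment choice and a piecewise-constant
treatment hazard ratio — so the full pipeline is testable end to end.
See `docs/methods.md` for the model details and design choices.

## Worked example

```python
from coxcut import (GeneratorConfig, generate_analysis_table,
                    bootstrap_select, fit_final_models, mh_adjusted_rates)

cfg = GeneratorConfig(n_subjects=20_000, seed=3)   # truth: HR 0.95 before
ana, truth = generate_analysis_table(cfg)          # day 540, 1.73 after

search = bootstrap_select(ana, B=100, seed=5)
print("selected cut-off:", search.selected, search.verdict)

models = fit_final_models(ana, search.selected,
                          ["insulin", "depression", "clopidogrel"])
full = models["full"]
print(full.summary().head(2).round(3).to_string(index=False))

mh = mh_adjusted_rates(ana)
print(f"adjusted rates /100py: statin {mh.rates[0]:.2f}, "
      f"fibrate {mh.rates[1]:.2f}")
```

Output:

```
selected cut-off: (510,) ok
     covariate   coef    se    hr  hr_ci_low  hr_ci_high     p
arm_fibrate_p1 -0.055 0.132 0.947      0.731       1.226 0.679
arm_fibrate_p2  0.618 0.189 1.854      1.279       2.688 0.001
adjusted rates /100py: statin 2.11, fibrate 2.34
```

The selected cut-off lands a month from the generating change point at
day 540; the per-period hazard ratios 0.95 / 1.85 bracket the generating
values 0.95 / 1.73 (a null effect early whose CI covers 1, a significant
harmful association late), and the age/sex-adjusted annual event rates are
~2%/year in both arms.

The same workflow runs from a shell, starting from raw claims tables:

```bash
coxcut simulate --n-subjects 20000 --seed 7 --out data/
coxcut build-cohort --claims data/claims.csv \
    --demographics data/demographics.csv --rule itt --out analysis.csv
coxcut find-cutoff --analysis analysis.csv --B 500 --seed 7 --out profile.csv
coxcut estimate --analysis analysis.csv --cutoff 540 --out results/
coxcut run-all --seed 7 --out run/          # everything + manifest + report
```

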