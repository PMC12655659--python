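# radpk — population pharmacokinetics of radotinib

Radotinib is an oral second-generation BCR-ABL1 tyrosine-kinase inhibitor
used to treat chronic-phase chronic myeloid leukemia (CML-CP).  Its approved
regimen (300 mg twice daily, fasting) raises tolerability and adherence
concerns, which makes a quantitative population pharmacokinetic (PK) model —
and the dosing simulations it enables — clinically useful.  `radpk` is a
Python implementation of that analysis for pharmacometricians: the
nonlinear mixed-effects model, its estimation and diagnostics, and Monte
Carlo exploration of alternative regimens.

## The model

Concentration-time data from healthy volunteers (single 400 mg dose) and
CML-CP patients (300 mg q12h, Days 1 and 14) are described by a
two-compartment disposition model with transit-compartment oral absorption,
first-order elimination with a circadian cosine on clearance, a disease
effect on CL/F and an age effect on Vc/F:

    CL/F_i = 23.0 · [1 + 0.646 · (1 − CML_i)] · [1 + 0.683 · cos(2π (TIME − 7)/24)] · e^η
    Vc/F_i = 383 · [1 − 0.0129 · (AGE_i − 31)] · e^η_IOV
    Q/F = 132 L/h,  Vp/F = 519 · e^η_IOV L,  ka = 1.59 h⁻¹,
    MTT = 1.88 · e^η h,  N = 6.58 · e^η

with log-normal interindividual variability (ω_CL 0.389; ω_MTT 0.316 and
ω_N 0.447 fixed), one interoccasion eta (ω 0.698) shared by the volumes,
and 20% proportional residual error.  Transit absorption uses the analytic
gamma-density input with ktr = (N+1)/MTT.  Healthy subjects clear the drug
~39% faster than patients, giving terminal half-lives of 18.2 h versus
28.8 h.

The package provides:

* `datamodel` — NONMEM-style event tables (ID/TIME/AMT/EVID/DV/MDV/OCC +
  covariates), CSV I/O, LLOQ policies (5 ng/mL), dosing regimens;
* `structural` / `population` — the deterministic model and the
  random-effects layer;
* `engine` — compiled RK4 integration, exact periodic steady state,
  exposure metrics, Monte Carlo virtual populations;
* `estimation` — FOCE with interaction, empirical Bayes etas, OFV, RSEs,
  CWRES;
* `covariates` — linear/power/exponential/proportional/additive covariate
  forms, Mosteller BSA, Cockcroft–Gault, stepwise covariate modelling
  (ΔOFV 3.84 forward / 6.63 backward);
* `diagnostics` — occasion-stratified VPC, cohort-stratified nonparametric
  bootstrap, GOF tables;
* `synthetic` — a generator reproducing the two-cohort study design, so
  every component is testable without any external data.

## Worked example

```python
import numpy as np
from radpk import (CovariateSampler, CovariateSet, final_theta, final_variance,
                   monte_carlo_exposures)
from radpk.structural import secondary_params, typical_params

theta, variance = final_theta(), final_variance()

patient = typical_params(theta, CovariateSet(age=31, cml=1))
sec = secondary_params(patient)
print(f"typical patient: CL/F {patient.cl:.1f} L/h, Vc/F {patient.vc:.0f} L, "
      f"terminal t1/2 {sec.t_half_beta:.1f} h, total V/F {sec.v_total:.0f} L")

summary = monte_carlo_exposures(theta, variance, CovariateSampler().patient,
                                (300.0, 12.0), 500, seed=42, use_periodic_ss=True)
print(summary.summary.round(1))
```

prints

```
typical patient: CL/F 23.0 L/h, Vc/F 383 L, terminal t1/2 28.8 h, total V/F 902 L
           median      q25      q75      p05      p95
auc_0_24  27177.1  21048.9  35935.0  14792.6  52269.0
cmax       1457.4   1181.3   1814.4    809.2   2513.7
ctrough    1075.1    810.6   1442.2    572.9   2134.7
tmax          3.2      2.8      3.8      2.2      4.8
```

The first line is the typical CML-CP patient at the reference age: apparent
clearance 23 L/h, central volume 383 L, the slow-phase half-life of 28.8 h
that motivates once-daily dosing, and 902 L total apparent volume.  The
table summarizes steady-state exposure (AUC₀₋₂₄ₕ in ng·h/mL, Cmax/Ctrough in
ng/mL, tmax in h) across 500 virtual patients on 300 mg twice daily: median
trough ~1000 ng/mL, peak ~1450 ng/mL about 3 h post-dose, with wide spread
driven mostly by the clearance variability.

A CLI mirrors the library (`radpk generate|simulate|fit|scm|vpc|bootstrap`,
each with `--seed/--out`), e.g.

```bash
radpk generate --seed 7 --out study.csv
radpk fit --data study.csv --out fit.yaml
radpk simulate --regimen 400x1 --n 2400 --seed 1 --out sim.csv
```

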