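# ffrcea

A mixed trial- and model-based cost-effectiveness analysis of fractional
flow reserve (FFR)-guided versus standard angiography-guided management of
non-ST-elevation myocardial infarction (NSTEMI), from a UK NHS payer
perspective.

FFR is a pressure-wire-derived index of coronary stenosis severity
(FFR ≤ 0.80 indicates inducible ischaemia). Measuring it changes the
subsequent management decision — medical therapy (MT), percutaneous coronary
intervention (PCI) or bypass surgery (CABG) — and therefore downstream
costs, major adverse cardiovascular events (MACE) and quality-adjusted
life-years (QALYs). This package implements the full analysis pipeline as a
reusable, tested library plus a sequence of narrative analysis scripts:

1. **Synthetic trial generator** (`ffrcea.synthetic`) — seeded
   individual-level two-arm data with the published arm-level structure:
   treatment-decision mixes (23/71/6% vs 13/80/7% for MT/PCI/CABG),
   MACE driven by the decision through odds ratios on a 9% MT baseline,
   correlated EQ-5D trajectories at 0/6/12 months with 17%/24% follow-up
   missingness, and resource use calibrated so each of the eight cost
   categories hits its published arm mean.
2. **Costing** (`ffrcea.costing`) — per-patient index-year costs as
   resource use × unit costs (2014 GBP), protocol-wire stripping in the
   angiography arm, and bootstrap category summaries.
3. **Outcomes** (`ffrcea.outcomes`) — QALYs as the area under the utility
   curve (linear decline to 0 at death), the arm × missingness chi-squared
   test, chained-equation multiple imputation and Rubin's-rules pooling.
4. **Regression** (`ffrcea.regression`) — GLMs for costs/QALYs with
   modified Park and Hosmer–Lemeshow family/link checks, covariate
   screening (univariable p < 0.25, prevalence > 10%), partial analysis of
   deviance for the model structure, logistic MACE regression, and marginal
   (covariate-standardised) prediction.
5. **Decision model** (`ffrcea.decision_model`) — the decision tree over
   (decision × MACE) cells with the odds-to-risk conversion
   risk′ = OR·odds/(1 + OR·odds), and the lifetime extension: life
   expectancy conditioned on index-year MACE, a £423/year cost tariff, an
   age-declining utility with a −0.05 MACE decrement, discounted at 3.5%.
6. **PSA** (`ffrcea.psa`) — moment-matched beta/gamma/lognormal/Dirichlet
   distributions, parameter-only or bootstrap-refit propagation, ICERs
   (ΔC/ΔE), the cost-effectiveness plane and acceptability curves
   (probability that λ·ΔE − ΔC > 0 over a willingness-to-pay grid).

The real trial's individual-level records are not public; the bundled
calibration (`src/ffrcea/data/*.yaml`) encodes the published arm-level
summaries, and the generator is the package's stand-in for the raw data.

## Worked example

```bash
python analysis/01_simulate.py      # 176 patients/arm, seeded
python analysis/02_costs.py
python analysis/03_outcomes.py
python analysis/05_decision_model.py
python analysis/06_psa.py
```

`05_decision_model.py` evaluates the tree at the published point values and
prints:

```
standard trial £8445 / 0.801 QALYs | lifetime £10838 / 5.35 QALYs (P(MACE) 0.103)
ffr      trial £8440 / 0.820 QALYs | lifetime £10831 / 5.36 QALYs (P(MACE) 0.102)
increments: trial £-5 / 0.019; lifetime £-8 / 0.015
ICER: trial dominant, lifetime dominant
```

i.e. at these point values FFR is slightly cheaper and slightly more
effective; the PSA (`06_psa.py`, 10,000 draws) quantifies how uncertain that
is — incremental costs of roughly −£450 to +£450 around a near-zero mean,
incremental QALYs of about −0.03 to +0.07, and a 69–79% probability of
cost-effectiveness in the £20,000–£30,000/QALY band. `04_fit_models.py`
refits the statistical models on generated data and reproduces the
qualitative findings: the decision × MACE structure is strongly supported
for costs (partial deviance p ≈ 10⁻¹²) but not for QALYs, the modified Park
test selects a gamma family, and the CABG odds ratio is near its published
point value.

Each stage is also exposed as a CLI: `ffrcea simulate|costs|fit|model|psa`
(see `--help`).

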