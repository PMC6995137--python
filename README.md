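# graftce

Cost-effectiveness and value-of-information analysis of a low-friction
bedding environment for patients recovering from burn skin-graft surgery.

## The problem

After a skin graft for a burn injury, a fraction of grafts fail to attach and
the patient needs a repeat graft — an expensive re-admission with a painful
recovery. Friction between the wound and ordinary bedsheets is one suspected
cause, and low-friction (smooth, slippery) bedding has been proposed to
reduce graft loss. The comparative evidence comes from a small,
non-randomised before/after feasibility study, so both the effect and its
economic consequences are uncertain. This package implements the decision
analysis that question calls for, aimed at health economists and trial
methodologists deciding whether a definitive randomised trial would be worth
running:

* a two-arm, 28-day **probabilistic decision tree** (standard vs low-friction
  bedding, re-graft vs no re-graft pathways);
* **probabilistic sensitivity analysis** (PSA): Monte-Carlo propagation of
  the joint parameter uncertainty into costs, QALYs and net benefit;
* **cost-effectiveness acceptability curves** (CEAC);
* **expected value of perfect information** (EVPI) and regression-based
  single-parameter **EVPPI**, per person and scaled to a discounted
  population;
* a **bias-scenario sweep** placing multiplicative lognormal bias on the
  observational relative risk;
* a **synthetic before/after study generator** with estimators that recover
  model inputs from patient-level records (the parameter-recovery test
  surface).

## The model

Each arm is a chance node. With re-graft probability *p*, re-graft /
no-re-graft costs *c_re*, *c_no*, and utilities *u* measured at surgery and
day 28:

```
cost(arm)  = c_int·1[arm = low-friction] + p·c_re + (1 − p)·c_no
QALY(arm)  = p·A(u_base, u_re) + (1 − p)·A(u_base, u_no)
A(u0, u1)  = (u0 + u1)/2 · 28/365.25          (trapezoid accrual)
```

The low-friction arm samples *p* directly (beta); the standard arm derives
it through the relative risk RR (low-friction vs standard) as
`p_std = min(1, p_lf / RR)`. Everything is put on a monetary scale with the
net-benefit framework at willingness-to-pay λ:

```
NB = λ·QALY − cost        INB = NB(low-friction) − NB(standard)
EVPI = E[max_arm NB] − max_arm E[NB]
EVPPI(θ) = E[max(g(θ), 0)] − max(E[g(θ)], 0),  g(θ) = E[INB | θ]
```

with *g* estimated by cubic-spline regression of INB on the draws of θ.

## Worked example

```python
from graftce import DecisionTreeModel, PopulationConfig, discounted_population

model = DecisionTreeModel.from_config()      # packaged base-case inputs
results = model.fit(n_iter=50_000, seed=1)
print(results.summary())
```

```
Probabilistic sensitivity analysis summary
  iterations: 50000    willingness-to-pay: £20,000/QALY

                         mean      ci_lo      ci_hi
qaly_standard        0.033266   0.010946   0.059808
qaly_low_friction    0.033135   0.010482   0.059945
qaly_incremental  -0.00013076 -0.0007368 0.00033479
cost_standard          10,563    8,764.4     12,766
cost_low_friction      10,409    8,723.2     12,346
cost_incremental      -154.32    -814.49     137.96
nb_standard            -9,898    -12,150   -8,025.2
nb_low_friction      -9,746.3    -11,748   -7,981.1
inb                    151.71    -140.48     809.08

  P(low-friction cost-effective at £20,000) = 0.704
```

Low-friction bedding costs about £154 less per patient on average (the £115
sheet cost is more than offset by avoided re-grafts) at a negligible QALY
difference, giving a mean incremental net benefit of roughly £152 — weakly in
its favour, with a 70% probability of being cost-effective at £20,000/QALY
but a credible interval spanning zero.

```python
print(results.evpi())                                  # 20.24  (£/person)
print(discounted_population(PopulationConfig()))       # 8607.7 patients over 10y
print(results.evppi_all(n_samples=10_000).round(2))
# c_regraft       16.10
# p_regraft_lf     1.91
# rr               0.00  ... (others 0)
```

Perfect information is worth ~£20 per patient (~£174,000 over a 10-year,
1000-patient/year horizon discounted at 3.5%). Almost all of it is
attributable to the **cost of re-grafting** (~£16/person, ~£139,000
population) — information obtainable from a costing audit — while the
relative risk alone carries essentially no value, so a randomised trial of
the bedding itself is unlikely to be worthwhile. The bias-scenario sweep
(`graftce scenarios`, or `BiasScenarioAnalysis`) shows these conclusions are
robust to substantial bias in the observational relative risk.

The same pipeline is available from the shell:

```bash
graftce --n-iter 50000 --seed 1 --out outputs run-all
graftce psa · ceac · voi · scenarios · simulate-study · estimate
```

Inputs are a YAML file (see `graftce/data/base_case.yaml`) with blocks
`parameters`, `model`, `population`, `scenarios`, `study`; any omitted block
falls back to the packaged base case.

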