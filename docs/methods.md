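# Methods

## Decision problem and model structure

Patients with burn injuries who have undergone skin-graft surgery are nursed
on either standard or low-friction bedding. Within a 28-day horizon a graft
either takes or is lost, in which case the patient is re-grafted. The model
is a two-arm decision tree: one chance node per arm with branches re-graft /
no re-graft. The horizon covers the period of graft "take" while the patient
is hospitalised, so no discounting is applied within it; costs are in GBP
and outcomes in QALYs.

Expected values per arm, for one joint draw of the parameters:

* cost = intervention cost (low-friction arm only) + p·c_re + (1−p)·c_no
* QALY = p·A(u_base, u_re) + (1−p)·A(u_base, u_no)

where A is trapezoid accrual between the utility at surgery and the
status-stratified day-28 utility: A(u0, u1) = (u0+u1)/2 × horizon/365.25.
The accrual rule between the two measurement points is a modelling choice;
linear interpolation is the least-assuming one, and 365.25 days/year is used
(365 is configurable and indistinguishable at this horizon's precision).

The re-graft probability is parameterised on the low-friction arm (where it
was measured prospectively) and transferred to the standard arm through the
relative risk (low-friction vs standard): p_std = min(1, p_lf / RR). The cap
guards against protective-RR draws pushing the implied probability above 1;
in the base case it binds with negligible probability. The intervention cost
(£115) is applied once per admission, independent of re-graft status.

Decision quantities use the net-benefit framework: NB = λ·QALY − cost at
willingness-to-pay λ (£20,000/QALY by default), INB = NB_lf − NB_std, and
the probability cost-effective is P(INB > 0) (ties, reachable only in
degenerate configurations, count against the intervention).

## Parameter distributions

Eight uncertain inputs, sampled mutually independently (no correlation
structure is available to inform a joint prior):

| name | family | default | units |
|---|---|---|---|
| rr | lognormal, median 0.574, 95% CI (0.52, 0.63) | sdlog ≈ 0.049 | ratio |
| p_regraft_lf | Beta(4.96, 125.04) | mean 0.038 | probability |
| c_intervention | point 115 | — | GBP |
| c_regraft | Lognormal(9.81, 0.35) | mean ≈ 19,350 | GBP |
| c_no_regraft | Lognormal(9.20, 0.09) | mean ≈ 9,940 | GBP |
| u_baseline | Beta(0.77, 1.41) | mean 0.353 | utility |
| u_no_regraft | Beta(2.26, 2.19) | mean 0.508 | utility |
| u_regraft | Beta(179.95, 106.82) | mean 0.627 | utility |

Two deliberate quirks are retained. First, the relative risk is
reconstructed from its median and 95% interval rather than from a reported
log-scale dispersion, because the two published summaries are mutually
inconsistent and only the narrow interval is consistent with the rest of the
reported analysis (a wide variant can still be expressed in the
configuration by giving `meanlog`/`sdlog` directly). Second, the day-28
utility after graft loss (0.627) exceeds the utility with an intact graft
(0.508); this is what the source data show, and it is what produces the
slightly negative incremental QALY.

`lognormal_from_median_ci` symmetrises the interval on the log scale:
meanlog = ln(median), sdlog = (ln hi − ln lo)/(2·z) with z = 1.959964 (the
normal 97.5th percentile to six decimals, not the rounded 1.96). Equal-tailed
95% intervals are used everywhere ("credible interval" below always means
the 2.5–97.5 percentile interval, sampled or analytic).

## Sampling and reproducibility

Monte-Carlo sampling uses numpy's PCG64 with one sub-stream per parameter,
keyed by (global seed, stable hash of the parameter name). Draws are
bit-reproducible given the seed, and adding a parameter (e.g. a bias term)
never perturbs the other parameters' columns — which makes the face-value
bias scenario reproduce the base case exactly. The default PSA size is
50,000 iterations; at that size the Monte-Carlo standard error of mean INB
is below £2.

## Value of information

EVPI per person is the exact sample identity E[max_arm NB] − max_arm E[NB].

Single-parameter EVPPI uses the regression shortcut: the conditional
expectation g(θ) = E[INB | θ] is estimated by ordinary least squares on a
cubic B-spline basis in θ (quantile-spaced knots, ~6 basis functions by
default — `basis_df` is configurable and estimates are stable across 4–8),
and EVPPI = mean(max(g, 0)) − max(mean(g), 0), floored at zero since the
estimand is non-negative while the regression estimate can dip below by
noise. EVPPI is computed on the first 10,000 PSA iterations; the smoother is
stable well before that size and the estimate carries ~£1 of regression
noise, which is the tolerance used when asserting EVPPI ≤ EVPI. Richer
estimators for parameter subsets (Gaussian-process or INLA-based) are out of
scope.

Population values multiply the per-person value by the discounted number of
patients facing the decision over the technology's relevance horizon: 1,000
skin grafts per year for 10 years at a 3.5% annual discount rate, with the
first cohort undiscounted (annuity-due). That convention gives a discounted
population of 8,607.7 ≈ 8,608; discounting the first cohort as well would
give 8,317 and is available via `first_year_discounted`.

## Bias scenarios

Because the relative risk comes from a non-randomised before/after
comparison, a multiplicative lognormal bias term b is placed on it:
RR_used = RR × b per iteration. Scenarios specify b by median (1.0 no bias,
0.8 favouring low-friction, 1.2 against) and a 95% interval (high or low
uncertainty), inverted to lognormal parameters exactly like the relative
risk itself. The analytic distribution of the adjusted RR is the lognormal
with summed meanlogs and root-sum-square sdlogs; it is used for the scenario
table's adjusted-RR column and is verified against per-iteration product
sampling.

The bias term is sampled as a parameter in its own right, so its EVPPI is
estimable; the per-scenario "RR" EVPPI refers to the bias-adjusted relative
risk actually driving the decision (in the face-value scenario the two
coincide and the bias EVPPI is exactly zero). Each scenario runs with seed
= base seed + scenario index, so any row of the sweep can be regenerated in
isolation.

A known limitation: published scenario summaries of this kind sometimes
print adjusted-RR intervals that are not log-symmetric, and no
multiplicative lognormal bias can then match every scenario statistic
simultaneously — widening the bias raises the mean INB but necessarily
lowers the probability of cost-effectiveness and raises EVPI. The
low-uncertainty scenarios and all qualitative orderings (EVPI maximal under
adverse uncertain bias, minimal under favourable certain bias; probability
decreasing in the bias median within an uncertainty class) are insensitive
to this.

## Synthetic study generator

The generator emulates the two-period study design behind the inputs: 131
retrospective standard-bedding patients and 90 prospective low-friction
patients by default; Bernoulli re-graft indicators at period-specific rates;
lognormal inpatient costs stratified by re-graft status (generated directly
as totals — the bed-day × length-of-stay decomposition behind real costing
is not modelled); beta utilities at baseline and day 28 (day-28 stratified
by re-graft status), observed only for a completely-at-random completing
subset (≈44%) of the prospective period. It does not emulate informative
missingness, negative (worse-than-dead) EQ-5D index values, seasonal/history
effects in the before/after contrast, or registry-linked costing — so
recovery tests demonstrate statistical correctness of the estimators under
the model's own assumptions, not robustness to those real-data features.

Estimators are deliberately standard and transparent: Jeffreys-prior
conjugate beta for proportions; delta-method lognormal for the relative
risk (log-RR SE √(1/a − 1/n_a + 1/b − 1/n_b), erroring with advice to apply
a continuity correction when a period has zero events); log-moment fits for
costs (pooling periods, matching the assumption that cost structure is
common to the arms); method-of-moments beta fits for utilities (boundary
values nudged inward by 1e-6 with a warning; variance ≥ m(1−m) raises as
beta-infeasible). They are validated by parameter recovery on synthetic
truth — at 10,000 patients per period the relative-risk median, cost scales
and the propagated incremental net benefit all return to the base case —
not by reproducing any particular published α/β pair, whose derivation is
not documented.

## Numerical and reporting conventions

* CSV outputs round currency to the pound, probabilities to 3 decimals and
  QALYs to 5 decimals; full precision is kept in memory.
* CEAC default grid: £0–£50,000 in £1,000 steps.
* The CE-plane scatter is emitted as data (ΔQALY, ΔCost per iteration);
  no plotting code is load-bearing.
* Runs below 1,000 iterations warn that value-of-information estimates are
  unstable.
* The test suite and the acceptance script use 50,000-iteration analyses
  (10,000 for EVPPI), the sizes at which the analysis is designed to be
  quoted; the whole pipeline runs in seconds.
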