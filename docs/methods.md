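# Methods

## Model structure

The model compares two first-line strategies for advanced NSCLC —
toripalimab plus platinum-doublet chemotherapy (TC) and
placebo plus chemotherapy — with three mutually exclusive states:
progression free (PFS), progressed disease (PD) and death. It is a
partitioned survival model: state membership at each cycle start is read
directly from the arm's PFS and OS curves rather than from estimated
transition probabilities,

- `p_PFS(t) = min(S_PFS(t), S_OS(t))`,
- `p_dead(t) = 1 − S_OS(t)`,
- `p_PD(t)` is the remainder.

Cycle length is 21 days (one treatment cycle); the horizon is 10 years,
realised as 174 cycle starts (`floor(10·365.25/21)` full cycles plus
cycle 0). Occupancy, costs and utilities are evaluated at cycle starts
with **no half-cycle correction**, matching the source model's
convention that expenses fall at the beginning of each cycle. Costs and
QALYs are discounted at 5% per year, `(1+r)^(−t)`, with `t` in years at
the cycle start.

**PFS-exit split.** Two survival curves do not identify how the mass
leaving PFS in a cycle divides between progression and death. Deaths in
a cycle are allocated to PFS in proportion to the PFS share of the
surviving cohort at the previous cycle start, capped by the actual PFS
decline; the rest of the PFS decline counts as new progressions. The
split only affects the one-off per-progression cost (a docetaxel
course), a small component, and is isolated in one function
(`engine.state_occupancy`).

## Survival inputs

The four base-case distributions are taken verbatim from the published
parameter table: TC PFS log-normal (meanlog 2.262, sdlog 0.950), TC OS
log-logistic (shape 1.510, scale 25.348), chemotherapy PFS log-logistic
(shape 2.489, scale 6.089), chemotherapy OS log-normal (meanlog 2.897,
sdlog 0.791); times in months. Parameterisations for all six supported
families are documented in `distributions.py` (Gompertz uses
`H(t) = (b/a)(e^{at} − 1)`; Weibull and log-logistic use shape/scale
with `S = exp(−(t/b)^k)` and `S = 1/(1+(t/b)^a)`).

These imply median PFS of 9.60 months (TC) and 6.09 months
(chemotherapy) and median OS of 25.35 and 18.12 months. The trial
medians echoed in the publication (8.4 / 5.6 months PFS; ~17.1 months
chemotherapy OS) differ slightly from what its own printed distribution
parameters imply; the package uses the printed parameters and does not
attempt to reconcile the two.

**Fitting route.** The original analysis digitised the trial's KM
curves and fitted distributions without naming a likelihood. Here a
digitised step curve is converted to pseudo individual patient data by
inverse-CDF interpolation at stratified quantiles `(j−½)/n` with an
assumed sample size `n` (the mass below the curve's final level is
right-censored at the last knot); the stratified grid reproduces the
curve at its knots to within 1/n. The six families are then fitted by
right-censored maximum likelihood (L-BFGS-B on log-scale parameters,
moment-based starts), with standard errors from the finite-difference
observed information, and ranked by AIC or BIC
(`AIC = 2k − 2ℓ`, `BIC = k ln n − 2ℓ`; ties broken by the fixed family
order). Non-convergence is flagged on the result, never silent. Fits for
the families lifelines also covers (exponential, Weibull, log-normal,
log-logistic) are cross-checked against lifelines in the test suite.

**Background mortality.** Model survival is floored by general-population
survival via a pointwise maximum of cumulative hazards, with annual
life-table probabilities `q` converted to constant hazards
`−ln(1−q)` within each age year and integrated from the cohort starting
age (default 61 years, a typical advanced-NSCLC trial median — an
assumption, as the publication reports no age). No national life table
ships with the package; the default is a **synthetic** Gompertz schedule
`q(a) = min(1, 3·10⁻⁵·e^{0.095a})`, which tracks US adult mortality to
roughly the right magnitude (q ≈ 0.010 at 61, 0.026 at 71). Because the
disease-specific cumulative hazard dominates at almost all cycle starts,
the floor has only a small effect; any real life table can be supplied
in the configuration. The floor is applied to both OS and PFS so the
adjusted curves remain ordered.

## Valuation rules

Each unit cost in the parameter table maps to exactly one booking rule:

| item | rule |
|---|---|
| first-line drugs | per PFS cycle; induction (4 cycles) carries carboplatin + pemetrexed (non-squamous) or carboplatin + nab-paclitaxel (squamous); maintenance carries pemetrexed (non-squamous) and/or toripalimab; histology-weighted for the pooled cohort |
| toripalimab | TC arm only, while cycle start < 2 years (34 cycle starts) |
| administration bundle | per PFS cycle: one day each of physician, IV, care and bed, plus blood test, biochemistry and urinalysis ($63.67) |
| CT examination | every 2nd PFS cycle (tumour evaluation every 6 weeks) |
| grade ≥3 adverse events | one-off expected cost and one-cycle utility decrement at cycle 0; each patient counted once per event type |
| subsequent docetaxel | one-off per new progression: mix share × 4 cycles × (docetaxel + administration bundle) |
| crossover toripalimab | chemotherapy arm: mix share × toripalimab price per PD cycle while within the crossover window of progression (rolling sum of recent progressions, capped by current PD occupancy) |
| best supportive care | mix share × $122.18 per PD cycle |
| follow-up visit | $77.01 per PD cycle |
| terminal care | $2,241.18 per death, at the death cycle |

QALYs accrue as `cycle_years × (0.80·p_PFS + 0.32·p_PD)` per cycle minus
the adverse-event decrement. Utilities of 0.80/0.32/0 are annual
weights. Body surface area (1.72 m²) and creatinine clearance
(70 mL/min) are carried as demography metadata only: the table's drug
prices are already per cycle, so rescaling by dose would double-count.
Induction is fixed at 4 cycles (the stated base-case assumption, though
the trial allowed 4–6). Squamous maintenance is toripalimab only (TC)
or nothing (chemotherapy). Administration costs during PD beyond the
follow-up visit, BSC and the docetaxel course are not billed; the
publication does not state the original convention, and this choice is
explicit in the rules above.

## Calibrated inputs

Two quantities the publication uses but never reports:

1. **Histology cost weight** of the pooled cohort (the squamous share of
   per-cycle drug cost). The trial enrolled both histologies; the pooled
   survival curves are given but the costing mix is not.
2. **Crossover toripalimab duration** in the chemotherapy arm (the
   crossover proportion is printed; how long those patients receive
   toripalimab is not).

Both were calibrated once, by least squares against the published pooled
base-case summaries (arm totals and incremental cost), constrained to
preserve the published qualitative ranking of one-way sensitivity
drivers (PFS utility, crossover proportion, pemetrexed price, discount
rate as the top four). The result — squamous weight 0.243, crossover
window 24 cycles (≈ 16.6 months) — is frozen in the shipped
configuration and was not revisited afterwards. Both are ordinary
configuration fields (schema defaults 0.5 and 34 cycles for
user-written configs), and the calibrated weight should be read as an
effective cost weight absorbing unmodelled regimen detail (dose
intensity, early discontinuation), not as the trial's histology
distribution. With these inputs the shipped base case lands within a few
percent of all published pooled figures; the residual gap is the price
of the under-specified booking rules and is why the acceptance tests use
±10% cost tolerances.

## Sensitivity analysis

**One-way (tornado).** Each uncertain parameter is set to its printed
low and high bound alone (costs and utilities ±20%, discount rate 0–8%,
toripalimab price slide 300–375), the model rerun, and rows ranked by
ICER span. Post-progression shares are varied independently without
renormalising the arm's mix: the parameter table gives each share —
including the "estimated" BSC remainder — its own distribution and
range, so the original model treated them as free parameters. Parameters
fixed in the PSA still appear in the tornado when they have a printed
range.

**Probabilistic.** 1,000 draws; beta for proportions, utilities and
disutilities, gamma for costs, truncated normal (at zero) for body
surface area; toripalimab price and discount rate fixed; survival
parameters fixed (their table rows carry no distribution). Hyperparameters
are moment matched reading the printed min–max as a central 95% interval:
`sd = (max − min)/(2·1.96)`, beta via the standard mean/variance
solution (variance clipped below `m(1−m)` with a warning if infeasible),
gamma via `shape = m²/v`, `scale = v/m`. One printed range (leukopenia
disutility, 0.112–0.168 around a point of 0.20) does not bracket its
point estimate; it is stored verbatim, flagged with a warning, and
sampled around the point with the range-implied sd. Because survival and
discounting are fixed, the occupancy traces are computed once and
re-valued per draw. The CEAC reports the share of draws with positive
net monetary benefit `WTP·ΔE − ΔC` on a 0–60,000 USD/QALY grid in steps
of 250 (configurable); the 50% crossing is linearly interpolated between
grid points. Body surface area is sampled but inert by construction (see
valuation rules).

**Subgroups.** Squamous and non-squamous runs force the histology weight
to 1 or 0 and use the matching regimen; the published subgroup survival
parameters live in supplementary material that is not shipped, so
subgroup behaviour is verified by structural properties (occupancy
conservation, ICER definition, price monotonicity, absence of
pemetrexed cost from squamous runs) on synthetic subgroup
configurations rather than against the printed subgroup ICERs.

## Synthetic data

The generator reproduces the *shape* of the real inputs: event times by
inverse-CDF from any supported family, uniform or administrative
censoring, per-subject coupling of progression and death (progression
clipped at death, common latent rank) so the implied curves satisfy
S_PFS ≤ S_OS, product-limit curves via lifelines, Gaussian digitisation
jitter repaired by isotonic projection, and Gompertz or constant-hazard
life tables. It does not emulate patient covariates, informative
censoring, non-proportional digitisation error (which in practice grows
near the curve tail), or numbers-at-risk reporting. Pipeline tests built
on it therefore demonstrate internal consistency — that fitting,
selection and valuation recover known truth — not fidelity to the
specific trial's patient-level data.

## Numerical choices

- Medians: closed form for five families; gamma via the inverse
  regularised incomplete gamma function. The median property
  `S(median) = 0.5` is tested to 1e-9 across families.
- Gamma survival is clipped at 1e-320 before logs to keep the cumulative
  hazard finite in the extreme tail.
- MLE: L-BFGS-B on log parameters (meanlog on the natural scale);
  standard errors by delta method from the finite-difference Hessian
  (step 1e-4); a non-invertible information matrix marks the fit
  non-converged.
- Information-criterion ties break deterministically by family order
  (exponential, Weibull, gamma, Gompertz, log-normal, log-logistic).
- Occupancy clamps `S_PFS ≤ S_OS`; conservation holds to 1e-9 by
  construction and is property-tested.
- Configuration round-trips are bit-exact: YAML serialisation uses
  shortest-repr floats.

## Limitations

- The pooled base case is a single-cohort model with histology entering
  only through the drug-cost weight; it cannot exactly reproduce a
  pooled result that averages two subgroup models with their own curves.
- The crossover window, administration bundle composition and PD-phase
  billing conventions are assumptions (documented above); crossover
  duration is a known top-tier sensitivity driver, hence exposed in the
  configuration.
- Grade 1–2 adverse events and repeated events are excluded, as in the
  source analysis.
- Extrapolation rests on the parametric families; no spline or
  mixture-cure alternatives are implemented.
- The default life table is synthetic; analyses intended for publication
  should supply a real national table.
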