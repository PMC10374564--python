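# Methods

`lrc-healthspan` quantifies how a person's family history of longevity
relates to their own healthspan — the years lived before a first chronic
age-related disease — using three-generation pedigrees, cohort lifetables,
and survival models that respect mid-life study entry.

## The LRC score

The Longevity Relatives Count for person *i* is

    LRC_i = Σ_k w_k · I(P_k ≥ 0.9) / Σ_k w_k ,

a weighted proportion in [0, 1] over the person's ancestral blood
relatives *k*: the parents, the parents' full siblings (aunts/uncles) and
the grandparents for index persons (IPs), and the parents only for IPs'
partners.  `P_k` is the ancestor's survival percentile within their own
sex- and birth-year-specific cohort lifetable, `I(P_k ≥ 0.9)` marks
membership of the top 10% survivors (the boundary is inclusive), and the
weights are relationship coefficients — by default the expected genetic
relatedness: parent 0.5, aunt/uncle 0.25, grandparent 0.25.  The weights
are configurable; the score is invariant to rescaling them uniformly.

Because the percentile is cohort- and sex-specific, the indicator is
comparable across ancestors born decades apart, which is the point of the
construction: secular mortality decline and the female survival advantage
are absorbed by the reference lifetable.

Censoring policies for ancestors who are not (yet) dead, selectable per
cohort:

* `exclude_alive` — drop alive ancestors from numerator and denominator
  (used for IPs in questionnaire cohorts with living aunts/uncles);
* `impute_alive` — replace the unknown death age by censor age plus the
  lifetable's remaining life expectancy (single imputation; used for
  partners' parents, known only up to a reported last-observation age);
* `require_extinct` — any alive ancestor is an error (register cohorts
  restricted to extinct birth cohorts).

Ancestors with missing ages are always excluded from both sides of the
ratio, with counts reported.  A person whose ancestor set is empty after
the policy has an undefined score and is dropped with a logged reason.

Analysis groups over the score: IPs with LRC ≥ 0.60 (g1), IPs with
0.1 ≤ LRC < 0.60 (g2), partners with LRC > 0 (g3) and partners with
LRC = 0 (g4, the reference).  IPs below 0.1 are excluded and logged
rather than forced into a group; in the motivating designs every IP has
a long-lived parent, so that stratum is normally empty.

## Lifetables

A cohort lifetable holds yearly hazards `h_x` for integer ages 0..ω
(ω ≥ 99).  Derived quantities:

* cumulative hazard `H(x) = Σ_{k<⌊x⌋} h_k + frac(x)·h_⌊x⌋` (piecewise
  constant hazard, hence linear interpolation of `H` within a year);
* survival `S(x) = exp(−H(x))`;
* percentile `P = 1 − S(age at death)`, the fraction of the cohort dead
  before that age — so "top 3% survivor" means `S = 0.03`;
* remaining life expectancy `e_x = Σ_{k≥1} S(x+k)/S(x) + ½`, with the
  half-year continuity correction for deaths occurring mid-interval (the
  correction is a parameter of the method, default 0.5);
* imputed death age `x + e_x` for a person alive at `x`.

Beyond ω the final hazard is held constant.  Percentile queries are
capped at age 120; the `e_x` tail beyond the table is a geometric series
under the constant-hazard closure and is summed in closed form, so a
constant-hazard table reproduces `e_x = e^{−h}/(1−e^{−h}) + ½` exactly.
Percentiles use exact (fractional) death ages by default; tables supplied
as death probabilities `q_x` convert via `h = −log(1−q)`.  Sexes are
modelled strictly separately — there is no unisex fallback — and a lookup
for a missing (sex, birth year) is an error, never a silent substitution.

## Event datasets

ICD-10 diagnoses are classified by longest-prefix match into *metabolic*
and *malignant*; *age-related* is always their union.  The default map —
malignant: C00–C97 and D00–D48; metabolic: chapters E and I — is a
declared approximation chosen to pair with the ATC-A/B/C medication
classes, and is fully overridable via a YAML prefix list (the map used is
recorded in provenance).  Three risk-set constructions:

* **first disease** — persons with any categorized diagnosis at or before
  inclusion are excluded; entry is the inclusion age, exit the first
  post-entry event of the target category or the censoring age;
* **two diseases** — exit at the second post-entry event of the category;
  persons with exactly one event by end of follow-up are excluded
  outright, so the censored set contains only persons with zero events;
* **first → second disease** — entry at the age of the first event of the
  index category, which may pre-date inclusion (one disease before the
  start of follow-up is allowed); exit at the next distinct event of the
  target category.

Ties (a second diagnosis recorded at the same age as the first) are
shifted forward by one day (1/365.25 yr) to preserve entry < exit.
Diagnosis years without dates convert to ages mid-year (+0.5).  Death
during follow-up censors disease time at the death age; competing risks
are deliberately not modelled.  Every builder reports a conservation
tally: retained + excluded = input, with per-reason counts.

Medication tables reduce to per-person indicators for ATC classes A, B
and C by first-letter prefix.  A person on the collection roster with no
rows is a genuine "no use"; a person absent from the roster is missing,
not false.

## Estimation

**Left-truncated Kaplan–Meier.**  Product-limit estimation on the age
scale with delayed-entry risk sets `R(t) = {j : entry_j < t ≤ exit_j}`
(delegated to lifelines).  The median onset age is the smallest age with
`S ≤ 0.5`, flagged undefined when the curve never crosses; group delays
are differences of medians.

**Shared gamma-frailty Cox.**  The hazard of person *j* in family *i* is
`u_i λ₀(t) exp(β'z_ij)` with `u_i ~ Gamma(mean 1, variance θ)` shared by
the family (families are IP sibships; a partner belongs to their IP's
family).  Estimation is EM:

* E-step: posterior frailty means `û_i = (1/θ + D_i)/(1/θ + Λ_i)` from
  the family's event count and accumulated cumulative hazard;
* M-step: Newton–Raphson on the Breslow partial likelihood with
  `log û_i` as offset, plus a Breslow baseline update;
* θ: outer maximisation of the gamma-integrated marginal likelihood on
  the log scale (bounded search, lower bound 10⁻⁸, estimates below
  2·10⁻⁸ reported as 0).

Convergence requires max|Δβ| < 10⁻⁶ and a relative marginal-log-likelihood
change below 10⁻⁸.  Ties use Breslow throughout — the simplest rule
consistent with delayed entry.  Standard errors for β come from the
penalized joint observed information in (β, log u): the frailty block,
carrying the gamma penalty curvature `û_i/θ`, is profiled out by a Schur
complement, so frailty-estimation uncertainty propagates into the Wald
CIs (the same construction penalized partial-likelihood frailty software
uses; at θ = 0 it reduces to the plain Cox information).  Inference is
Wald throughout.  A diverging coefficient (monotone likelihood) is
flagged as non-convergence with NaN standard errors, never silently
returned.  Martingale residuals
`r_j = δ_j − û_i exp(β'z_j)(Λ̂₀(exit_j) − Λ̂₀(entry_j))` sum to zero by the
baseline estimating equation and serve as the linearity diagnostic for
the continuous score.

The fit was validated against R `survival::coxph` with `frailty.gamma`
(coefficients agree to ~10⁻⁵ at fixed θ; the profiled θ agrees to ~10⁻³)
and against lifelines' left-truncated Cox model in the θ = 0 limit; those
frozen oracle values live in the test suite.

**Random-intercept logistic regression.**  `logit P(Y=1) = β'x + u_i`
with normal intercepts, fitted by maximising the exact marginal
likelihood with adaptive Gauss–Hermite quadrature (15 nodes by default,
recentred at each family's posterior mode with scale from the local
curvature; all families are processed vectorised).  σ is profiled on
[0, 3]; a flat profile — e.g. one member per family, where σ² is
unidentifiable — is resolved to the σ = 0 boundary, where the fit
coincides with plain logistic regression and the 2×2 odds ratio is exact.
Fixed-effect SEs come from a central-difference Hessian of the marginal
log-likelihood.  Validated against `lme4::glmer` (nAGQ = 15): estimates,
SEs, σ² and log-likelihood agree to ~10⁻³ on a frozen reference dataset.

**Random-intercept linear regression.**  REML via statsmodels `MixedLM`.
Degenerate checks: one-member families reproduce OLS exactly; balanced
layouts reproduce the one-way ANOVA method-of-moments variance
decomposition.

## Synthetic cohorts

The generator builds the structure the analysis assumes, with defaults
chosen once to emulate a questionnaire-style longevity cohort:

* **families** — four grandparents; a parental sibship per side with mean
  size 2.8 (1 + Poisson), the first child being the parent; an IP sibship
  with mean 2.58 (register-style variant: 1.67); 45% of IPs get a partner
  with two own parents (0% in the register variant).  Birth windows:
  grandparents 1870–94, parents 1900–25, IPs placed so that inclusion
  (2002, register variant 1990) falls at ages 55–65.
* **mortality** — Gompertz–Makeham hazards `a·e^{bx} + c` per sex
  (females a = 7·10⁻⁵, males 1.1·10⁻⁴, b = 0.092, c = 1.5·10⁻³) with the
  level *a* declining 0.4%/birth-year from 1900, giving realistic adult
  modal ages near 80 and a female advantage; the same parameters generate
  the cohort lifetables the scorer consumes, so simulated percentiles are
  exactly calibrated.  Lifespans are multiplied through a gamma family
  frailty (mean 1, variance θ_m = 0.2 — modest familial clustering, in
  line with the low heritability of lifespan); blood relatives share one
  draw, a partner's household another.  Study participants' lifespans are
  drawn conditional on survival to their inclusion age; ancestors are
  censored at the register closing year.
* **disease** — per base category, first-onset ages from Weibull
  baselines (metabolic shape 6, scale 82 yr; malignant 6.5, 96 yr —
  roughly 30–40% cumulative incidence over a 16-year mid-life follow-up)
  multiplied by `exp(β_d·LRC)` and a shared gamma disease frailty
  (variance θ_d = 0.2); second events add a Weibull gap (shape 1.4, scale
  9 yr) under the same multiplier.  The effect is injected through the
  *computed* LRC of each person — scores are calculated from the
  generated ancestors first, then drive the disease hazards — so the
  log-hazard coefficient has a defined truth value (default log 0.6 per
  unit LRC, matching an HR of ≈0.95 per 0.1) and recovery tests close the
  loop end to end.
* **medication / score** — class-specific logistic intercepts (A −1.4,
  B −2.2, C −0.7), an LRC coefficient of −0.6 and a family intercept
  (σ = 0.5); the continuous health score gets group shifts (g1 −0.098,
  g2 −0.032, g3 −0.016 — the magnitudes the score contrast is expected to
  recover), family σ = 0.10 and residual σ = 0.25.

Determinism: every stream (pedigree structure, mortality, disease,
medication, score, missingness) draws from
`SeedSequence(master_seed, spawn_key=(k,))` with a fixed index *k*, so
the same seed yields byte-identical files and adding a stream never
perturbs the others.

What the generator does *not* emulate: the ascertainment of IPs through
long-lived relatives (simulated LRC distributions are population-like
rather than enriched, so IP-vs-partner contrasts are weaker than in a
selected cohort), assortative mating, secular morbidity trends,
competing-risk structure, and realistic marriage/fertility demography.
Passing recovery tests therefore demonstrate that the estimators return
the parameters the generative model encodes — not that real cohort
effect sizes are reproduced.

## Pipeline and outputs

`run_pipeline` executes: read inputs → percentiles → LRC scores and
groups → per-analysis survival records → fits.  Survival fits adjust for
sex, with age handled by left truncation; medication models additionally
adjust for age at inclusion; the score model for sex, age at inclusion
and any-medication use.  The reference level is always the partner /
LRC-g4 group.  Each analysis is independently skippable; register-style
runs drop the partner-based analyses and add death as an outcome.  Every
estimate is emitted with its 95% CI, p-value and N/event counts; all
exclusions are tallied in a provenance record together with the seed and
a hash of the analytic configuration (file paths excluded, so the same
analysis hashes identically from any directory).  Output CSVs use fixed
float formatting, making equal bundles byte-identical on disk.

## Problem sizes used in the checks

The bundled checks run at sizes that keep the full suite within a few
minutes on one core: oracle equivalence on 50 datasets of ≤30 subjects;
effect recovery on 1,000 simulated families (≈3,000 scored persons);
null-coverage over 50 replicates of 120 families; determinism on 80
families end to end.

## Known limitations

* The frailty model supports a single shared gamma frailty per family; no
  nested or correlated random effects, time-varying covariates,
  stratified baselines or Efron ties.
* The ICD-10 category map is an approximation standing in for a
  study-specific disease list; results on real data depend on supplying
  the intended map.
* `e_x` beyond the table relies on the constant-hazard closure; for
  tables ending at 99 this is the dominant approximation in imputed death
  ages of long-lived censored ancestors.
* The metabolomics-based health score is consumed as a precomputed
  column; its derivation is out of scope.
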