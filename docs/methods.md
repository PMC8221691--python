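# Methods

`carebench` benchmarks home-care organizations on the 6-month societal cost
per client. This note documents the model and its assumptions, the defaults
and why they were chosen, what the synthetic-data generator does and does not
emulate, and the numerical choices that pin down otherwise ambiguous
behaviour.

## Costing model

Resource use is recorded per client per assessment wave with item-specific
recall windows: 90 days for hospitalization, emergency-room and physician
visits, 7 days for regular home care and therapist visits, 3 days for
informal care. Supportive-service and other-healthcare units are event-like
and use the 90-day recall (the instrument convention leaves these
unspecified; the choice is fixed here and configurable nowhere — it is part
of the data model). Each quantity is scaled to a 91-day quarter
(`q × 91 / recall`) and valued with a uniform standard price, so that cost
differences between care models reflect utilization, not national price
levels. Hospital nights are `events × country mean length of stay`, except
in the one configured recorded-days country, where the registered number of
admission days is used directly. Informal-care minutes are converted to
hours and valued at the wage rate of a legally employed cleaner (proxy-good
method).

Costs accumulate into seven categories — hospital admissions,
emergency/physician visits, other healthcare services, supportive care
services, institutional care, home care (incl. therapists), informal care.
The *societal* total is their sum; the *healthcare* total excludes informal
care. The shipped price table is illustrative: its values are synthetic
stand-ins on the scale of published standard-cost manuals, and category
membership of items is configuration, not hard-coded fact. Multiple named
price tables can be loaded side by side for price-swap sensitivity analyses.

### Six-month interpolation and the halfway-transition rule

The 6-month cost interpolates the two quarterly assessments with weights
(0.5, 1.5): the first quarter is the average of the two assessments, the
second is the month-6 assessment alone.

For clients who die or are institutionalized between assessments the event
is assumed to occur halfway through the 182-day window (day 91). The
semantics is pinned by a day-by-day accrual oracle: community costs accrue
at the *baseline* rate for days 0–90 and zero afterwards; institutionalized
clients additionally accrue the facility per-diem for each post-midpoint
day. `apply_transition_rules` encodes this as an *effective* month-6
quarterly cost — `carry × (1 − w₁)/w₂` for community categories (= carry/3
at the default weights) and `per-diem × 91/w₂` for the institutional
category — chosen so that the 0.5/1.5 interpolation identity holds exactly
for every client, transition or not. A 1,000-fixture randomized test checks
agreement with the literal day-by-day simulation.

Discharged and lost-to-follow-up clients have genuinely missing month-6
costs; whether the study extrapolated or imputed these is not stated
anywhere, so this package declares them missing and hands them to the
imputation stage.

## Care-model classification

Organizations score three core elements — patient-centred care (6 items),
availability of specialized professionals (5 items), monitoring of care
performance (4 items) — as plain item means. Dichotomizing each element
gives a pattern that maps to care models: (H,H,H)→CM1, (H,L,H)→CM2,
(L,L,H)→CM3, (H,H,L)→CM4. The original dichotomization rule is not
available; the default threshold is the scale midpoint, overridable per
element, with ties counting as high (a fixed, documented tie-break). The
four analyzable patterns map to CM1–CM4 for *every* threshold choice — this
contract is tested over a threshold grid. Residual patterns are assigned by
a fixed rule — low PCC with high ASP → CM5, the remaining low-MCP patterns
→ CM6 — and flagged; flagged organizations are excluded from analysis by
default, mirroring the exclusion of those two small models.

## Synthetic cohorts

The generator's defaults are the study conditions: 6/3/9 organizations in
CM1–CM3 with ≈222/104/46 clients each (≈2,060 in total), country mixes per
model, case-mix distributions calibrated to the published per-model means
(ordinal scales as binomials with matching expectations, age as a floored
normal), transition probabilities 3% institutionalized / 2% deceased /
0.7% discharged / 2.6% lost per six months, and a wave-2 item MCAR rate of
0.037, which implies ≈29% of clients with at least one missing resource
item over the nine items. Between-model effects default to €0 / +2,230 /
−321 for CM1/CM2/CM3 (CM4: +3,644, a magnitude anchor taken from the
healthcare-perspective difference since no societal value exists for it).

Cost control works through quantities, not money: the expected valued
6-month societal cost of a client equals
`base + effect[model] + Σ βᵥ (xᵥ − centerᵥ)`, with the model-level
expectation distributed over categories by per-model shares (informal care
dominating CM1 at 60%, home care dominating CM3 at 54%, CM2 set so the
informal:home ratio is 2:1) and the client-level case-mix deviation loading
on the hands-on-care categories. Event counts are Poisson, minutes and days
are gamma with shape 0.8 (the families are a modelling convenience — the
study characterizes its cost distribution only as skewed — and are
scenario-configurable). Expectations are exact by construction, which is
what the marginal-control test checks at n = 5,000 within 3 Monte-Carlo
standard errors. An infeasible configuration (negative expected category
cost) raises rather than clips, so expectations can never silently drift.

The base cost (€14,100) is set so the reference model's implied mean is
≈ €18.8k. The betas are moderate (e.g. €900 per ADLH point, €600 per CHESS
point); they produce material confounding — unadjusted contrasts are biased,
adjusted ones recover the injected effect — but they do **not** reproduce
the published inversion in which the model with the highest *adjusted* costs
had the lowest *unadjusted* mean; that would need implausibly large case-mix
coefficients under these distributions, and nothing downstream depends on
it.

What passing tests on these cohorts does *not* show about real data:
real assessments have measurement error and item-specific (likely MNAR)
missingness patterns, organizations carry unmodelled random effects
(clients here are independent given the care model), wave-2 utilization
equals wave-1 in expectation (no trend), and transition timing is uniform
in neither reality nor the generator (it is simply unobserved).

Deaths and institutionalizations are recorded by the generator only as a
wave-2 status — translating status into costs is the costing engine's job,
exactly as with the real instrument. Informal care is not assessed in the
recorded-days country, mirroring the instrument's coverage gap; societal
analyses should exclude such organizations (the default scenarios contain
none), while healthcare-perspective runs may include them with
`allow_missing=("informal_care",)`.

## Imputation

Missing quarterly cost cells are imputed by chained equations with
predictive mean matching: type-1 PMM with a donor pool of 5 nearest
predicted means and a uniform donor draw, 5 sweeps over target columns in
their declared order, predictors = the eight case-mix covariates plus
care-model dummies. Imputation operates on *wave-level category costs*,
before transition rules and interpolation, so the interpolation identity
holds in every completed dataset (the level at which the original analysis
imputed is not stated; this choice is declared, not inferred). Cells fixed
by the halfway-transition rule are masked out of the imputation. The
coefficient vector is perturbed by a posterior draw before predicting the
missing cases so between-imputation variance is non-degenerate. Ten
datasets by default.

PMM imputes only observed donor values (the support property, tested), which
is what makes it suitable for right-skewed costs. One caveat: donor
selection compares floating-point distances, so it is scale-invariant only
up to ties; the price-homogeneity test therefore isolates the costing and
regression chain on complete-follow-up data.

## Adjusted comparison and intervals

Costs are compared between care models by OLS with care-model dummies
(reference omitted) plus the case-mix covariates age, sex, living-alone
status, CPS, DRS, ADLH, iADL and CHESS; a dummy coefficient is the adjusted
mean difference versus the reference. Covariates are screened with Spearman
correlations (|ρ| > 0.4 flags a pair, the lower-priority member is dropped,
constants are degenerate and dropped). Living status enters as the binary
living-alone indicator; country of residence is available as an optional
covariate but off by default.

Confidence intervals are BCa bootstrap: clients resampled with replacement
(resample size n, the client being the unit of analysis), z₀ from the
fraction of resample statistics strictly below the point estimate (clipped
to [0.5/B, 1 − 0.5/B] to keep it finite), acceleration from jackknife
third/second moments (0 when the jackknife is flat), endpoints as linearly
interpolated empirical quantiles at the adjusted levels. A constant
resample distribution returns the point value as both bounds with a
warning. Resamples in which a care model vanishes are redrawn (stratified
guard). For throughput, bootstrap refits solve batched weighted normal
equations (algebraically identical to refitting on resampled rows, asserted
at 1e-8) and the jackknife uses the exact leave-one-out downdate. An
exhaustive-enumeration mode replaces Monte-Carlo draws by all nⁿ resamples
for tiny n, which the oracle tests use.

### Composition with multiple imputation

The study prescribes both multiple imputation and BCa bootstrapping but not
their composition. This package bootstraps *within* each completed dataset,
pools the per-dataset point estimates by Rubin's rules (with the bootstrap
variance as the within-dataset variance), averages the per-imputation BCa
bounds, and widens the averaged interval about the pooled estimate by
√(T/W) — Rubin's total-to-within variance ratio. The widening exists
because a plain average of per-imputation bounds reflects only
within-dataset sampling variation and therefore under-covers whenever
imputations disagree; in the null-scenario study the plain average inflated
the type-I error visibly, while the widened interval sits near the nominal
level. The rule reduces to the plain average when all imputations coincide.
The composition lives in one function (`pooled_contrast`) so the
bootstrap-then-impute alternative can be swapped in.

`compare_models` reports every pairwise contrast oriented against the
cheaper model, with the lowest-cost model as the global reference. The
operating-characteristic studies instead fix the contrast (CM2 − CM1) in
advance: under a null, selecting the observed-lowest model as reference is
a post-hoc selection that inflates rejection by construction.

Clustering of clients within organizations is ignored in the variance
machinery, matching the original analysis; with a true organization-level
random effect the intervals would be anticonservative. This is a known
limitation, not an accident.

## Operating characteristics and problem sizes

Two repeated-simulation studies characterize the full chain, at a scale
chosen to run in minutes on one CPU: 200 cohorts of 600 clients, B = 500
bootstrap replications, m = 5 imputations (the headline analysis itself
defaults to m = 10, B = 5,000).

* **Type-I error** (null scenario, three models, all effects zero,
  confounding active, 10% MCAR on month-6 items): fraction of 95% intervals
  for the adjusted CM2 − CM1 difference excluding zero; expected ≈ 0.05
  within binomial Monte-Carlo error.
* **Coverage** (two models, injected adjusted difference €2,230, skewed
  costs, complete follow-up): percent of intervals containing the truth;
  expected in the low-to-mid 90s.

`scripts/acceptance.py` recomputes both from scratch under a caller-supplied
seed. Residual sources of mild miscalibration at this scale are the B = 500
endpoint noise of BCa and the heavy cost skew at n = 600 per cohort; both
shrink at the headline settings.

## Numerical conventions

* Scale scores are ordinal integers; non-integer input is rejected, never
  rounded. Missing quantities stay missing — no silent zeros.
* No premature rounding anywhere in the costing chain; money is rounded to
  whole units only in the human-readable report tables, with full precision
  in the machine-readable output.
* Quantiles use linear interpolation (`numpy.quantile` default) throughout.
* One master seed per run; per-imputation and per-bootstrap substreams are
  spawned deterministically, so results are reproducible and the generator
  is byte-identical under a fixed scenario + seed.
* Currency is a label; there is no exchange-rate conversion, discounting,
  or friction-cost informal-care valuation.
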