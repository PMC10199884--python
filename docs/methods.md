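# Methods

This note documents the models behind `dermclaims`: what the synthetic
cohort emulates and how its parameters were derived, the matching and
statistical conventions, the cost-effectiveness model, and the numerical
choices made where the design was genuinely open.

## The study design being modelled

The pipeline reproduces a retrospective matched-cohort design: a large
insured adult population is offered a free CNN-based skin-check app;
everyone who completes at least one successful assessment ("users") is
matched 1:3 to non-users, and dermatological claims in the following year
are compared at person level. Effectiveness for the cost-effectiveness
model is proxied by unique persons with at least one claim for a
premalignant or malignant skin lesion.

## Synthetic cohort generator

The generator is first-class, tested code, not a fixture. Its defaults
encode the evaluated cohort's published aggregates; everything not
published is an explicit modelling choice, listed here.

**Population.** 2,213,212 insurees, uptake 18,960/2,213,212 ≈ 0.86%.
Ages are a truncated normal (mean 48.4, SD 14.0, support ≥ 17.5, rounded
to integers ≥ 18) whose location is solved numerically so the *truncated*
mean equals 48.4. Sex (53.2% female), SES (23.0/42.6/33.2% renormalised,
1.1% missing), (pre)malignancy history (4.7%) and region are independent
draws. Comorbidity counts (unique drug-class proxy) are Poisson(0.25)
capped at 5, giving median 0 (IQR 0–0) as observed. Regions: 2,500
uniform codes, emulating anonymised GP-practice codes; this count was
chosen so the tier-1 match fraction lands near the observed 88.3% (at
seed 1 the pipeline yields 87.7%). Control-pool covariates default to the
user distributions so exact matches exist; `control_age_shift` introduces
covariate shift to exercise matching fallback and failure paths.

**Assessments.** Counts per user are zero-truncated negative binomial
with truncated mean 64,128/18,960 ≈ 3.38 and dispersion `nb_size = 1`;
the underlying NB mean is solved numerically. Only the total count was
published, so the distribution shape is ours. Each photo is CNN-rated
low / low-with-symptoms / high / failed with marginal probabilities
0.585 / 0.132 / 0.235 / 0.048. "Low with symptoms" is a sub-label of low
with identical downstream handling. Teledermatologists upgrade CNN-low
photos to high with probability 0.028 and downgrade CNN-high photos with
probability 0.338. A photo counts as *high risk* when either the CNN or
the teledermatologist assigned high risk — a downgraded CNN-high photo
therefore still counts high for the subgroup split.

Independent per-photo outcomes cannot reconcile the observed marginals:
with a 23.5% CNN-high rate, a ~25.5% combined-high rate per photo, and
3.38 photos per user, the share of users with ≥ 1 high-risk assessment
would be 49–59% for *any* assessment-count dispersion, against the
observed 37.1%. High-risk outcomes evidently cluster within users (people
re-photograph the same lesion), so each user draws a high-risk propensity
`h ~ Beta(p_high·c, (1−p_high)·c)`; photos are CNN-high with probability
`h`. The mean keeps the assessment-level marginal at 23.5% exactly, and
the concentration `c` is calibrated (Gauss–Legendre quadrature over the
beta, NB probability generating function over counts, Brent root find) so
the user-level high-risk share equals 0.371. Calibration raises an error
when the target is unattainable at the configured marginals. Users whose
draws are all "failed" are redrawn (bounded retries), since the design
includes only users with ≥ 1 successful assessment.

**Claims.** Per category, a person is a claimant with a probability
conditional on arm and, for users, on their risk subgroup, taken from the
published person-level percentages (controls: 1.58 / 3.14 / 1.17 / 0.49 /
4.92%; high-risk users: 2.95 / 6.28 / 9.87 (nevi+benign) / 6.04%;
low-risk users: 1.54 / 2.78 / 3.52 / 4.83%). The pooled nevi+benign
subgroup rates are split by the overall 850:267 nevus:benign claimant
ratio. Because the subgroup mix is calibrated to 0.371, the user-arm
marginals reproduce the published overall percentages by construction.
Control claim rates are *not* conditioned on the matched user's subgroup;
the real data show such dependence (high-risk users' controls claim
slightly more), which this generator does not emulate — subgroup control
percentages are therefore not a reproduction target.

Claimants file `1 + Poisson(λ)` claims (λ per category: 1.0 / 0.2 / 1.5 /
1.0 / 2.5), each with an intervention label (GP biopsy/excision, GP
teledermatology, Mohs, hospital excision benign/(pre)malignant, or none)
drawn from per-arm-per-category mixes tuned so intervention claim volumes
per 1000 persons land near the published table. Care setting follows from
the intervention. Costs per claim are log-normal (σ = 0.8) with
arithmetic means derived from the published per-person annual costs:
holding the malignant per-claim means at the published €613.36 (users) /
€520.05 (controls), the remaining per-claim means solve
`per-person anchor = P(claimant) · (1+λ) · mean-per-claim`. The
benign-tumor per-person anchors are residuals of the published total
(€64.97/€43.09) against the published components and are labelled
derived. One consequence: the premalignant per-claim mean for users comes
out *below* the control value (the combined (pre)malignancy anchor is
nearly exhausted by malignant claims), so the synthetic premalignant cost
delta is slightly negative — a calibration artefact, not a claim about
the real cohort.

Claims are generated for a single study year; history flags are drawn
directly as booleans rather than via four years of simulated pre-study
claims, since the flag is all the analysis consumes.

**What passing tests do and do not show.** The generator has independent
covariates, no residual confounding, no correlation between matched
controls' outcomes and their user's behaviour, and exact exchangeability
between arms apart from the configured claim-probability differences.
Tests passing on it validate the *pipeline arithmetic and inference
machinery*, not the causal interpretation of any real-world estimate.

## Matching

Age bands are anchored at 18–29, then decades to 80+ (the convention is
configurable; only "10-year intervals" is fixed by the design). Matching
is exact on (age band, sex, SES, region, history, comorbidity count),
without replacement, missing SES to missing SES. Tie-breaks among
eligible controls are uniform at random behind a single seed; the pool is
canonicalised by person id before the seeded shuffle, so input row order
cannot change the selection. Users processed in id order consume
candidates; tier 2 (region dropped) only fills slots tier 1 could not.
Users with 1–2 controls are kept with their partial sets and logged
(person-count tables imply unweighted counts, so no weighting is
applied); users with none are excluded and counted. The comorbidity count
is matched exactly, optionally capped to keep exact matching feasible in
small pools. Balance is reported as standardised mean differences
(categoricals expanded to indicators, pooled-variance denominator,
defined as 0 for degenerate zero-variance agreement).

## Association statistics

Odds ratios are sample cross-product ratios; CIs are Woolf log-normal.
The published CIs are within ±0.02 of Woolf but occasionally differ in
the last digit (e.g. 1.16–1.49 printed vs 1.17–1.48 Woolf for the
premalignant row), suggesting an exact/conditional CI variant; tests
compare CI bounds at ±0.02 and point estimates at 2 decimals, where the
published values reproduce exactly. A zero cell triggers the
Haldane–Anscombe 0.5 correction with a flag. Fisher tests are two-sided
("sum of small p") via scipy, checked in tests against exhaustive
hypergeometric enumeration. The two-proportion z-test uses pooled
variance without continuity correction (a corrected variant is a config
switch). BH adjustment (via statsmodels, checked against a quadratic
reference) is applied per results table: main table, intervention table,
and each subgroup stratum as separate families — the family layout is a
package convention, as the design does not define one.

Claim-volume comparisons report claims per 1000 persons
(`1000·claims/persons`), which reconcile exactly with published counts,
and each intervention's share of the arm's total claim volume. The
published percentage column for interventions cannot be reconciled with
its stated denominators (e.g. 1913/15,404 ≠ 12.99%) and is treated as
non-reproducible; rates per 1000 are the supported volume metric.

Rounding for reported tables is round-half-even to 2 decimals; all
assertions on published values compare at that precision.

## Costs

Per-person annual means divide total category cost by the *full* arm size
(zeros included), per the "average annual cost per person" definition.
Differences use Welch t-tests with Welch-degrees-of-freedom CIs (Student
variant configurable). Per-claim means average over claims. Categories
are disjoint by construction, so per-category means sum to the
all-category mean exactly (asserted as a conservation property).

## Cost-effectiveness model

The ICER definition with component costs is stated in the source design
with a numerator whose benign and (pre)malignancy terms cancel
algebraically; consistent with the accompanying prose ("which also
includes the treatment of the additionally detected (pre)malignancies"),
it is implemented as the arm difference: intervention-arm costs (app +
benign + (pre)malignancy) minus control-arm costs. The cascade
calibration absorbs adherence into the identifiable products `vπα` and
`v(1−π)α`, solved so the model's per-user increments equal the observed
ones at (sens₀, spec₀) = (0.87, 0.70); unit costs per incremental
claimant come from observed incremental per-person costs. By
construction the surface reproduces the observed-data ICER at the
calibration point to machine precision (asserted at 1e-9 relative).

The app subscription price is not public. The default €16.26 per
user-year is reverse-engineered so that, with the published cohort
aggregates, the calibrated ICER at (0.87, 0.70) is ≈ €2,567 — a
demonstration value, clearly not an observed one. Consequently the euro
ICERs of the original evaluation are not desk-reproducible and are
treated as property targets only: both surfaces are strictly decreasing
in sensitivity and specificity (full surface strictly in sensitivity
whenever the app cost is positive), the benign-only surface never exceeds
the full surface, the minimum sits at (1, 1), and with zero app cost the
observed-data ICER from published counts and the published €21.88 cost
delta evaluates to ≈ €1,535. Overlap between app-triggered and
background detection is 0 by default (additivity). The default grid is
sens, spec ∈ {0.50, 0.55, …, 1.00}.

## Numerical and testing conventions

- All randomness flows through one `numpy.random.Generator` per run;
  identical config + seed yields byte-identical output tables.
- Root finds (truncated-normal location, zero-truncated NB mean, beta
  concentration) use Brent's method with tight tolerances and are
  LRU-cached.
- Costs are written to CSV as two-decimal strings so round trips are
  exact.
- Problem sizes: the test suite exercises the generator at 20k–400k
  population (study-default rates) and the full pipeline at study scale
  in the acceptance script (2.2M population, ~19k users). Odds-ratio
  recovery uses 100 replicates at study-scale arm sizes (75,840
  population at 25% uptake, i.e. ~18,960 users matched 1:3), checking
  that configured ORs of 1.3/2.9/4.0 fall inside their own 95% CIs in at
  least 90% of replicates.

## Known limitations

- Covariates are mutually independent and identically distributed across
  arms; there is no self-selection of app users, so the synthetic data
  cannot exhibit the residual confounding expected in the real cohort.
- Matched controls' claim probabilities ignore their user's risk
  subgroup; subgroup control rates are structurally flatter than
  observed.
- Cost calibration reproduces published per-person means, not the full
  (unpublished) cost distribution; per-claim means for premalignant
  lesions are derived residuals.
- The cascade model is linear in accuracy with constant unit costs; it
  ignores capacity constraints, repeat-visit dynamics and any long-term
  effect of earlier detection (the time horizon is 12 months).
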