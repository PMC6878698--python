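# Methods

## The model

`phsmoke` estimates, for each public housing development (PHD), how many
residents smoke cigarettes, given only (a) an individual-level national
health survey with smoking status and demographics, and (b) each
development's aggregate demographic marginals. The individual model is a
logistic regression

    logit P(smoke_i) = β₀ + β_tax·tax_i + Σ_c Σ_{ℓ≠ref(c)} β_{cℓ}·1[x_ic = ℓ]

over six closed categorical covariates — residential environment (3
levels), race/ethnicity (6), age bin (5), household income bin (4), a
composite gender/marital/children variable (6), and a composite
age/disability variable (4) — plus the state cigarette excise tax in USD
per 20-pack as the single numeric covariate. Dummy coding uses one
reference level per covariate (default: the first level of each list in
`phsmoke.categories`; configurable). An explicit intercept is always
included: without one a logistic model cannot match prevalence, so the
model treats the tax term as slope-plus-intercept rather than a lone
leading coefficient.

Fitting is unpenalized maximum likelihood (statsmodels `Logit`, Newton),
with Wald standard errors and p-values. The two age-bearing covariates
(age bin and age/disability) overlap by construction; they are not
perfectly collinear (the 60–79 bin straddles the 65-year cut), but the
fitter checks matrix rank up front and refuses to fit — naming the
offending columns — rather than silently dropping anything, and reports
the design condition number. Single-class outcomes and separation raise
errors with diagnostics.

## Harmonization conventions

Raw survey records use BRFSS-like codes; harmonization maps them onto the
closed scheme with the following fixed conventions, each unit-tested
against an independently written truth table:

- **Disability proxy**: disabled iff employment status is "unable to work"
  OR the blindness item is positive. Both routes are equivalent for the
  model; the proxy exists because the housing data reports disability, not
  employment.
- **Gender/marital/children composite**: marriage dominates sex — both
  sexes map to the two "Two spouses/married" levels; unmarried respondents
  split by sex and presence of children. Any non-married status
  (never married, divorced, widowed, separated, unmarried couple) counts
  as "not married".
- **Age 65**: the composite age/disability variable splits at 65 with 65
  itself assigned to the under-65 arm. The printed category labels leave
  65 unassigned; some fixed convention is required and this one is applied
  consistently everywhere (including the age ranges the synthetic
  generator draws from).
- **Income bins**: caps at $10,000 / $15,000 / $20,000 inclusive, lower
  bounds exclusive of the previous cap ($10,000 → "<$10k", $10,001 →
  "$10,001–$15k").
- **Race/ethnicity**: Hispanic ethnicity takes precedence over any race
  code; Asian and Native Hawaiian/Pacific Islander are merged; remaining
  codes map through a documented table with "other"/"multiracial"
  collapsing to one level.
- Records with missing fields are dropped with a logged count (no
  imputation); survey weights are not used.

## Threshold calibration

The model is used as a classifier, so a cut-off is needed. Rather than the
conventional 0.5, the threshold is chosen so the classified prevalence in
a national reference sample matches an external target — by default 0.33,
the approximate smoking prevalence among public-housing adults. The search
is exact over the finite set of observed scores: the returned threshold t
minimizes |mean(score ≥ t) − target|, with ties broken toward the larger
t, and the ≥ convention is used identically at classification time. By
construction the classified prevalence then matches the best attainable
value within 1/n. Calibration operates on the probability scale by
default; a log-odds-scale switch is provided and yields the identical
classification (the logistic function is monotone), so the choice is
cosmetic for classification purposes.

Model quality is reported by repeated random-split cross-validation
(default 75% train / 25% test, 100 repeats): per repeat the model is
refitted on the train split, its threshold recalibrated on that split,
and AUC (Mann–Whitney formulation, ties counted half) plus
sensitivity/specificity/false-positive rate at the threshold are measured
on the test split. Splits losing a class are redrawn and counted.
`train_fraction=1, repeats=1` degenerates to in-sample metrics, which the
tests use as a consistency check.

## Small-area estimation

For a development with n residents and marginal vectors per covariate, the
estimator:

1. simulates a roster of n individual residents, sampling each covariate
   independently from the development's marginals — the aggregate data
   carry no joint structure to respect — except that the stand-alone age
   bin is drawn conditionally on the age side of the age/disability draw
   (under-65 levels only with bins 18–24 … 60–79; over-65 only with 60–79
   or 80+), so the two age-bearing covariates never contradict each other.
   The conditional law is the development's age marginal restricted to the
   allowed bins and renormalized (an explicit 80+ fraction can override
   the over-65 split). The development's state fixes the tax covariate.
2. classifies every simulated resident at the calibrated threshold;
3. draws 50 bootstrap resamples of the roster (with replacement, size n)
   and records each resample's classified smoker count.

The reported estimate is the mean of the 50 bootstrap counts, with their
standard deviation and 2.5–97.5 percentile interval as uncertainty. Two
documented alternatives sit behind flags: redrawing 50 independent rosters
instead of resampling one (`roster_mode="redraw"`), and summing predicted
probabilities instead of hard classifications (`count_mode="probability"`).
The bootstrap resamples residents only; it does not refit the regression,
so coefficient uncertainty is not propagated into the interval. County
estimates are sums of PHD-level means over the county's developments
(sorted by FIPS), and conserve the PHD-level total exactly.

**A finding worth knowing before trusting per-area hard counts.** The
threshold is calibrated to match prevalence *nationally*. Any covariate
that is constant within an area but varies across areas — here the state
tax — shifts an area's whole score distribution relative to the cut, so
the classified fraction P(score ≥ t | area) can differ systematically from
the area's true mean probability even when the regression is exactly
right. On the synthetic study (6 states spanning $0.37–$4.35 excise tax)
this produces state-level biases of up to ~15 percentage points in the
hard-count estimates, while the soft-count variant tracks the hidden truth
to ~1 percentage point. The acceptance script reports both
(`sae_mae_pct` vs `sae_mae_softcount_pct`). Hard classification remains
the default because it is the method as described; users estimating across
heterogeneous tax regimes should compare both modes.

## Economics

Post-intervention smoker counts use the expected-value formulation
`after = before × (1 − participation × effectiveness)` (a flag for
re-simulation with reduced probabilities is deliberately out of scope of
the defaults). ROI is (averted annual medical cost) / (annual intervention
cost) with medical costs taken from a societal perspective; ROI > 1 flags
averted costs exceeding the intervention's cost. Cross-sector savings add
housing-system costs avoided:

    (before − after) × (eviction_rate×eviction_cost + fire_rate×fire_cost)
    + turnover_rate × n_units × (before − after)/n_residents
      × (turnover_cost_smoking − turnover_cost_nonsmoking)

with n_residents defaulting to n_units when unit counts are not tracked
separately. All economic parameters are config inputs; the shipped
defaults ($2,000/smoker/year medical cost, $50–$300 interventions with
5–20% quit rates at 50% participation, $1,000 evictions at 1%/smoker/yr,
$10,000 fires at 0.1%/smoker/yr, $2,000 turnover differential at 10%/yr)
are illustrative placeholders for exercising the pipeline, not published
estimates, and every analysis should substitute its own. The horizon is a
single year, point-in-time: no discounting, relapse, or phase-in.

## The synthetic data generator

The generator emulates the two real inputs with one known logistic
data-generating process. Its defaults are the package's study conditions:

- covariate marginals representative of adult public-housing residents
  (70% city, 40% Black and 18% Hispanic, 40% household income under $10k,
  55% of households female-headed without a spouse, 30% with a
  disability);
- six states carrying their actual 2015 cigarette excise taxes
  ($0.37–$4.35), uniform state mix;
- true coefficients of realistic sign and size (tax slope −0.12/USD,
  i.e. roughly a 2–3 point prevalence drop per dollar of tax; elevated
  odds for unmarried men, rural residents, and under-65 adults with a
  disability; reduced odds for the 80+ and higher-income groups);
- the intercept solved numerically — exact enumeration of the joint
  categorical law plus Brent root-finding — so the true national mean
  smoking probability equals 0.33;
- 30 developments of 500–2,500 residents (the mid-to-large urban
  developments such a tool targets), each assigned one state/county and
  jittered coordinates.

Covariates are sampled independently across variables (the same
independence the estimator later assumes), with the conditional age-bin
rule above. Raw survey codes are then "de-harmonized" from the sampled
categories (ages uniform within the admissible range, incomes uniform
within bins, a raw code drawn per race level, 80% of disability expressed
through employment status and 20% through blindness); the tests verify
that harmonizing the generated raw records reproduces the generator's
per-individual probabilities exactly, so the full raw-to-model path is
exercised. Development marginals are the *exact* empirical marginals of a
hidden roster, and each hidden roster's realized Bernoulli smoker count is
retained as the truth the estimator is scored against — a realizable
quantity, not an expectation.

What the generator does not emulate: joint dependence between covariates
beyond the age rule (real populations correlate income, age, race and
household structure), survey nonresponse and weighting, within-development
clustering, geographic covariate gradients within a state, and any
misreporting of smoking status. Passing validation here therefore shows
the estimator is correct *under its own assumptions*; it does not bound
errors caused by real-world joint structure the aggregate data cannot see.

All randomness flows from one seed: stream [seed, 0] generates the survey,
[seed, 1] the developments, each with a documented draw order, so both
artifacts regenerate independently and bit-identically.

## Numerical and reproducibility choices

- Newton MLE, maxiter 100; non-convergence, separation, and non-finite
  standard errors are hard errors, never silent.
- Threshold search is over observed scores (no bisection on a continuum):
  exact, deterministic, tie-broken toward the larger threshold.
- Bootstrap counts keep full precision; no rounding below the display
  layer. Percentiles use numpy's default (linear) interpolation.
- Pipeline RNG streams are derived as [seed, 2] (cross-validation) and
  [seed, 3, i] (i-th development in file order); reruns with identical
  config and seed are byte-identical, verified by SHA-256 in the manifest.
- Degenerate inputs are defined behaviour: point-mass marginals produce
  identical residents and zero bootstrap variance; a resident-count filter
  that removes every development yields empty but schema-valid outputs.
- Problem sizes used by the test suite and acceptance script — n = 50,000
  survey records, 50 replicate fits for coverage, 100 cross-validation
  repeats, 30 developments, 50 bootstrap applications — match the study
  conditions above; smaller fixtures (a few thousand records) are used
  where only plumbing is exercised.

## Known limitations

- The per-area bias of nationally-calibrated hard classification described
  above; soft counts are provided for comparison.
- Bootstrap intervals reflect roster resampling only, not regression
  uncertainty.
- Independence across covariate marginals is an assumption of both the
  generator and the estimator; real joint structure is invisible at the
  aggregate level and unmodelled.
- Economic outputs are crude single-year estimates with placeholder
  default parameters.
- County features carry FIPS codes and properties only; polygon geometry
  must be joined externally for rendering.
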