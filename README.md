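# phsmoke

Small-area estimation of cigarette smoking in U.S. public housing
developments (PHDs), with economic benefit estimation for cessation
interventions.

About one in three adults living in public housing smokes cigarettes, but
housing agencies only know their residents in aggregate: each development
is described by marginal demographic fractions, never by individual
records. `phsmoke` bridges that gap for public-health planners with a
two-part regression-and-simulation model:

1. **Individual model.** A logistic regression of smoking status fitted to
   an individual-level national survey (BRFSS-like schema), on covariates
   harmonized to the housing data's categories:

   ```
   logit P(smoke) = β₀ + β_tax·tax + β_res·x_res + β_race·x_race
                    + β_age·x_age + β_inc·x_$ + β_gmc·x_GenMaCh + β_dis·x_dis
   ```

   where `tax` is the state cigarette excise tax (USD per 20-pack) and the
   categorical blocks are residential environment, race/ethnicity, age bin,
   household income bin, a composite gender/marital-status/children
   variable, and a composite age/disability variable (the last two exist
   because the housing data reports those combinations as single fields).
   The classification threshold is not 0.5: it is calibrated so that the
   classified national prevalence matches an external target (default 33%).

2. **Microsimulation.** For each development, simulate an individual
   resident roster consistent with its aggregate marginals, classify every
   simulated resident with the fitted model, and average the classified
   smoker counts of 50 bootstrap resamples of the roster. Estimates roll up
   to county level for choropleth mapping (GeoJSON export keyed by FIPS).

On top of the smoker estimates, the economics module prices cessation
interventions: return on investment from averted smoking-related medical
costs, `ROI = (cost_no_intervention − cost_with_intervention) /
intervention_cost`, plus cross-sector housing savings (fewer evictions,
smoking-related fires, and cheaper unit turnover).

Because the real survey and housing extracts require downloads, the package
ships a known-truth synthetic generator (`phsmoke.synthetic`) that emulates
both inputs from a single logistic data-generating process, including
hidden individual rosters behind every development — so the whole pipeline,
and the accuracy of the estimator itself, can be validated offline.

## Worked example

```python
import numpy as np
from phsmoke import (
    default_population_spec, generate_survey, generate_phd_aggregates,
    harmonize_survey, SmokingModel, estimate_phd_smokers,
    compute_roi, InterventionSpec, CostModel,
)

spec = default_population_spec(n_individuals=20_000, n_phds=5, rng_seed=7)
raw, truth = generate_survey(spec)
harm = harmonize_survey(raw, spec.tax_by_state)

results = SmokingModel.from_dataframe(harm).fit()
results.calibrate_threshold(harm, target_prevalence=0.33)
print(f"threshold = {results.threshold:.4f}")
print(f"classified national prevalence = {results.classify(harm).mean():.4f}")
print(f"tax coefficient = {results.params['tax']:.4f} (se {results.bse['tax']:.4f})")

phds, phd_truth = generate_phd_aggregates(spec)
phd = phds[0]
est = estimate_phd_smokers(phd, results, spec.tax_by_state,
                           rng=np.random.default_rng(1))
print(f"{phd.phd_id} ({phd.state}, {phd.n_residents} residents): "
      f"estimated smokers = {est.estimated_smokers_mean:.1f} "
      f"[{est.percentile_interval[0]:.0f}, {est.percentile_interval[1]:.0f}], "
      f"true = {phd_truth.true_smoker_count_by_phd[phd.phd_id]}")

roi = compute_roi(est.estimated_smokers_mean,
                  InterventionSpec("counseling plus NRT", 300.0, 0.20, 1.0),
                  CostModel(medical_cost_per_smoker=2000.0))
print(f"ROI = {roi.roi:.2f} (breakeven exceeded: {roi.exceeds_breakeven})")
```

Output:

```
threshold = 0.3869
classified national prevalence = 0.3298
tax coefficient = -0.1371 (se 0.0110)
PHD0001 (CA, 2241 residents): estimated smokers = 805.9 [764, 852], true = 806
ROI = 1.33 (breakeven exceeded: True)
```

Reading: the cut-off 0.387 classifies 33.0% of the survey as smokers
(matching the one-third target); the fitted tax coefficient recovers the
generator's −0.12/USD within one standard error; the bootstrap estimate for
the first development (805.9 smokers, 95% percentile interval [764, 852])
brackets the hidden roster's realized truth of 806; and a $300/participant
intervention with a 20% quit rate returns $1.33 in averted medical costs
per dollar spent.

The same pipeline runs from the shell:

```sh
phsmoke simulate --out fixtures --n-individuals 20000 --n-phds 5 --seed 7
phsmoke run --survey fixtures/survey.csv --phds fixtures/phds.csv \
    --tax fixtures/tax.csv --economics fixtures/economics.yaml \
    --out results_dir --seed 7
```

writing per-PHD and county CSVs, the ROI table, the fitted model, a
cross-validation report, a GeoJSON map layer, and a manifest; reruns with
the same config and seed are byte-identical.

## Layout

- `phsmoke.categories` / `phsmoke.harmonize` — closed covariate scheme,
  survey harmonization (composite variables, disability proxy, binning,
  tax join), design-matrix construction
- `phsmoke.model` — `SmokingModel` / `SmokingModelResults`, threshold
  calibration, Mann–Whitney AUC, repeated cross-validation
- `phsmoke.microsim` — roster simulation, bootstrap smoker estimates,
  county aggregation
- `phsmoke.economics` — ROI and cross-sector savings
- `phsmoke.synthetic` — known-truth data generator
- `phsmoke.io` / `phsmoke.pipeline` / `phsmoke.cli` — file formats,
  end-to-end orchestration, command line

See `docs/methods.md` for the modelling assumptions, parameter choices, and
known limitations.
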