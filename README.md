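# foodaccess

Culturally appropriate food-access measures and spatially explicit
regression of area-level diabetes rates.

Many food-environment studies measure access only through supermarket
proximity (food-desert maps such as the USDA Food Access Research Atlas).
For racial and ethnic minorities — here Asian Americans and Native Hawaiians
or Pacific Islanders (AAPI) — that misses the ethnic restaurants and
groceries that actually supply culturally appropriate food. `foodaccess`
implements, as a tested and reusable pipeline, an ecological analysis of how
both kinds of access measure relate to area-level AAPI diabetes rates:

1. **Outlet classification** — rule-based coding of a business registry
   (name, point location, category list) into five mutually exclusive
   groups: AAPI / non-AAPI restaurants, AAPI / non-AAPI groceries, and
   neither; content-ambiguous categories ("grocery", "herbs & spices") are
   resolved through an explicit, auditable resolution file.
2. **Access measures** per census tract: AAPI-to-non-AAPI outlet ratios,
   AAPI outlets per AAPI resident, tract shares of the county AAPI outlet
   total, and the percent of (total and AAPI) population beyond a ½-mile
   straight-line distance of the nearest supermarket.
3. **Rate downscaling** — subregional-area (SRA) annual case counts,
   censored by small-cell suppression, are averaged over years, the county
   residual is reallocated to suppressed SRAs in proportion to their AAPI
   populations, and cases are apportioned to tracts by AAPI share, giving
   tract rates per 100 000 AAPI population.
4. **Spatial statistics and regression** — queen-contiguity and k-nearest-
   neighbour weights, global Moran's *I* (permutation or analytic-normal
   inference), Spearman collinearity screening, and covariate-adjusted OLS
   plus maximum-likelihood **spatial lag regression**

   y = ρWy + Xβ + ε,

   fitted by concentrating the Gaussian log-likelihood in ρ (log-determinant
   via the eigenvalues of W) with Wald inference from the observed
   information matrix. Exposures and covariates are z-scored, so
   coefficients read as rate change per one standard deviation.
5. **Synthetic county generator** — a grid county (tracts nested in SRA
   blocks, clustered demographic surfaces, population-driven outlet point
   processes, a spatial-lag disease process with known ρ and β, small-cell
   suppression) so every stage is testable against ground truth without any
   external data.

## Worked example

```python
from foodaccess import (
    CountyConfig, Lexicon, classify_outlets, access_measure_table,
    downscale_rates, generate_county, morans_i, SpatialLagModel,
)

config = CountyConfig(seed=7)          # 24x24 tracts, 36 SRAs, 7 years
county = generate_county(config)

classified, counts = classify_outlets(
    county.outlets, Lexicon.default(), county.resolutions
)
print("outlet groups:", counts)

measures = access_measure_table(
    classified, county.tracts, county.pop_points, county.supermarkets
)
rates = downscale_rates(
    county.cases.records, county.tracts,
    county.cases.county_mean_annual_cases,
)
data = (
    county.tracts.drop(columns="geometry")
    .merge(measures, on="tract_id")
    .merge(rates[["tract_id", "rate_per_100k"]], on="tract_id")
)

print(morans_i(data["rate_per_100k"].to_numpy(), county.weights,
               method="permutation", n_permutations=999, seed=7))

slr = SpatialLagModel.from_dataframe(
    data, outcome="rate_per_100k", weights=county.weights,
    exposure="rest_per_aapi",
).fit()
print(slr.summary())
```

which prints:

```
outlet groups: {'aapi_restaurants': 2003, 'non_aapi_restaurants': 4083, 'aapi_groceries': 538, 'non_aapi_groceries': 1058, 'neither': 2596, 'excluded': 319}
MoranResult(I=0.8567, E[I]=-0.0017, z=37.927, p=0.001, method='permutation', n=576)
Spatial lag model (maximum likelihood)
n = 576, rho = 0.9365 (se 0.0145, p 0)
loglik = -2565.414, AIC = 5144.828
                 coef     se  ci_low  ci_high      p
intercept     10.7408 2.5671  5.7093  15.7723 0.0000
rest_per_aapi -0.6365 0.8053 -2.2148   0.9417 0.4292
pop_density    3.0262 0.8570  1.3465   4.7059 0.0004
pct_obese      1.4835 0.7971 -0.0787   3.0458 0.0627
pct_over65     1.1035 0.7868 -0.4386   2.6457 0.1608
```

Reading the output: the classifier partitioned 10 278 retained outlets into
the five groups (319 non-food outlets excluded); tract diabetes rates show
very strong positive spatial autocorrelation (Moran's *I* = 0.86 against a
null expectation of −0.002, permutation p = 0.001), driven by the
constant-rate-within-SRA downscaling plus the spatial-lag process; and the
spatial-lag fit attributes most of that structure to the lag term
(ρ = 0.94), with AAPI restaurants per AAPI resident showing a negative but
non-significant adjusted association in this particular synthetic county.

The same pipeline runs from the shell:

```sh
foodaccess run --out results_dir --seed 7     # full pipeline, all artifacts
foodaccess synth --out county_dir --seed 7    # inputs only
foodaccess classify --outlets county_dir/outlets.csv \
    --resolutions county_dir/resolutions.csv --out classified.csv
```

Real data enter the same way: tracts as a projected (metre-unit) GeoJSON
FeatureCollection, outlets/supermarkets/population points as CSV, case
counts as a long CSV with blank cells for suppressed SRAs.

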