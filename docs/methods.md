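# Methods

This note documents the models, procedures and design choices behind
`foodaccess`: what each stage computes, the assumptions it makes, which
parameters matter, and what the synthetic-data tests do and do not
establish about real data.

## Outlet classification

Outlets carry an ordered list of controlled-vocabulary category strings.
Classification is two-dimensional and strictly rule-based:

* **Type** with precedence excluded > restaurant > grocery > neither.
  Excluded categories mark non-food businesses (bookstores) or businesses
  without a fixed storefront (delivery services). Restaurant matching is
  exact string equality against the restaurant category list; grocery
  matching is substring containment of any grocery keyword (at minimum
  "grocery", "farmer's market", "food market", "health market"), so
  "asian grocery store" types as a grocery. Exact matching suffices because
  registries of this kind use a controlled category vocabulary; after
  lowercasing and whitespace collapse there is nothing fuzzy left to match.
  When an outlet carries both restaurant and grocery categories the
  restaurant label wins — type is decided from the restaurant list first.
* **Content** with precedence aapi > ambiguous > non_aapi. One clearly AAPI
  category (a specific Asia-Pacific identifier such as "chinese" or
  "hawaiian", or a food of Asia-Pacific origin such as "poke" or "bubble
  tea") makes the outlet AAPI regardless of co-occurring general terms: the
  label means *majority-AAPI food*, and a specific category is stronger
  evidence than a generic one. Generic terms that may or may not cover AAPI
  food ("grocery", "herbs & spices") are ambiguous and must be resolved
  per outlet through a resolution map — an input file, so that what would
  otherwise be an undocumented manual web review becomes reproducible and
  auditable. Every non-excluded ambiguous outlet must have an entry;
  missing entries raise an error listing the offending outlet ids.

The five terminal groups (AAPI/non-AAPI × restaurant/grocery, plus
neither) partition the non-excluded outlets for any lexicon — a property
the tests exercise over randomized lexicons and category lists. The shipped
default lexicon covers common category vocabulary and is meant to be
extended for real registries; it is a starting point, not a census of any
platform's category tree.

## Access measures

All measures are per census tract, computed from point-in-polygon outlet
counts (boundary points go to the covering tract with the smallest id;
outlets outside every tract are dropped and logged).

* `rest_ratio`, `groc_ratio` — AAPI / non-AAPI outlet counts of each kind.
* `rest_per_aapi`, `groc_per_aapi` — AAPI outlets per AAPI resident,
  stored per person (the CLI also prints the per-1 000 reading).
* `rest_intensity`, `groc_intensity` — tract share of the county total of
  AAPI outlets; sums to 1 over tracts whenever the county total is
  positive.
* `fara_ct`, `fara_aapi` — percent of the tract's total and AAPI
  population beyond a distance threshold (default ½ mile = 804.672 m) from
  the nearest supermarket, computed from weighted within-tract population
  points and straight-line distance. This is a population-point
  approximation to atlas-style precomputed grid shares; straight-line
  distance is the convention for such atlases at this spatial scale, and no
  travel-time or network variant is attempted.

Zero-denominator cases are deliberate: a ratio or per-capita value with a
zero denominator and a positive numerator is *missing* (flagged), not 0 and
not infinite, because 0 would conflate "no AAPI outlets here" with "no
comparison outlets here". Both counts zero gives 0. Zero-population tracts
have missing distance shares.

## Rate downscaling

Inputs are SRA-level yearly case counts with a suppression flag, SRA AAPI
populations, and a county total on the unsuppressed scale. The order of
operations is fixed: average the yearly counts first (one mean annual count
per SRA), then form rates. The county residual — county total minus the sum
of reported SRA means — is allocated to the suppressed SRAs in proportion to
their AAPI populations; a negative residual, or a positive residual with no
suppressed SRA to receive it, is a data-consistency error.

Cases, not rate values, are then apportioned to tracts in proportion to
tract AAPI population. This choice matters: apportioning cases makes every
positive-AAPI tract inherit exactly its SRA's rate, which is the
constant-rate-within-SRA assumption the downscaling relies on, and it
conserves case totals exactly. Fractional cases are retained (rounding
would break conservation); tracts with zero AAPI population get rate 0 with
a `zero_pop` provenance flag, and all tract rows carry a provenance flag
(`reported` | `reallocated` | `zero_pop`). Reallocation operates on the
mean-annual scale; performing it on summed multi-year totals instead would
scale the residual by the number of years but leave all rates identical,
since the same factor cancels in the rate division.

No age/sex standardization is attempted: the rates are annual discharge
counts per 100 000 AAPI population, nothing more.

## Spatial weights and Moran's I

Queen contiguity (any shared boundary point, corners included) gives
symmetric binary weights; islands are allowed with a warning but are
rejected by the lag model. k-nearest-neighbour weights (default k = 8) are
directed, with distance ties broken toward the smaller tract id, and
symmetry is intentionally not enforced — kNN weights serve only descriptive
statistics and residual diagnostics, never the likelihood. Row
standardization divides each nonempty row by its sum and is idempotent.

Global Moran's I uses the standard cross-product form with expectation
−1/(n−1) under the null. Default inference is a random-permutation test
(999 draws, explicit seed, pseudo p-value with the observed statistic
counted among the draws); the analytic normal approximation is available
where speed matters, e.g. inside large simulation loops. Missing values are
removed listwise with the weights subset and re-standardized over the
surviving units; correlations, by contrast, use pairwise-complete
observations.

Collinearity screening computes Spearman rank correlations and greedily
scans pairs in input column order, dropping the later column when |ρ|
exceeds the threshold (default 0.90). The greedy rule is order-dependent by
construction; the scan order therefore encodes which variant of a
correlated pair is kept (the AAPI-specific distance share over the total
one, the per-capita count over the intensity). Constant columns have
undefined correlations and never trigger a drop.

## Regression

`OLSModel` fits by least squares with t-based two-sided inference, and
reports the Gaussian maximum-likelihood log-likelihood and
AIC = 2(k+1) − 2·loglik (the +1 counts the error variance) so OLS and lag
models are comparable. Rank-deficient designs fail with the collinear
columns named.

`SpatialLagModel` fits y = ρWy + Xβ + ε by maximum likelihood. The
log-likelihood is concentrated in ρ; the Jacobian term log|I − ρW| is
evaluated through the eigenvalues of W, computed once per weights object
and cached (at a few hundred units the dense eigendecomposition is cheap;
sparse log-determinant updates would only pay off at much larger n and are
not implemented). ρ is maximized by bounded Brent search to 10⁻⁸ on the
open interval (1/λ_min, 1), where λ_min is the most negative eigenvalue of
the row-standardized W — the interval on which every 1 − ρλ stays positive.
β and σ² then follow in closed form. Standard errors come from the observed
information matrix: a central-difference Hessian of the full log-likelihood
at (β̂, ρ̂, σ̂²) with per-coordinate step 10⁻⁵·max(1, |θ|). p-values are
two-sided Wald (normal approximation); AIC = 2(k+2) − 2·loglik counts β, ρ
and σ². At ρ = 0 the concentrated likelihood equals the OLS Gaussian
log-likelihood, so the fitted lag model never scores below OLS — an
invariant the tests assert.

Exposure and covariates (default: population density, percent obese,
percent over 65) are z-scored; the outcome stays on its natural scale, so a
coefficient is the rate change per one standard deviation of the exposure.
The model battery runs one OLS and one lag model per surviving exposure,
attaches residual Moran diagnostics under both queen and kNN weights, sorts
by lag-model AIC, and reports (rather than propagates) per-exposure
failures. Significance is judged two-sided at α = 0.05 throughout. A Welch
two-sample t-test utility is provided for comparing tract groups (e.g.
tracts with and without distance-share data); the unequal-variance form is
an assumption, chosen as the safer default.

## Synthetic county generator

The generator emulates the study conditions the analysis assumes, with
every stage drawing from a named substream of one seed (outputs are
byte-identical given the config):

* **Geometry** — an n_rows × n_cols grid of square tracts (default 24×24 =
  576 tracts of 1 km side, near the ~600 tracts of a mid-sized county),
  nested in square SRA blocks (default 4×4, giving 36 SRAs). The grid is
  the simplest geometry that still exercises queen contiguity's corner
  cases and SRA nesting; real tract polygons load through the same GeoJSON
  reader.
* **Demographics** — every surface (total population, AAPI share, percent
  over 65, percent obese, percent in poverty) is a smoothed Gaussian random
  field mapped through its marginal quantile function: marginals are
  exactly the configured log-normal/Beta distributions while neighbouring
  tracts are correlated, the way real demographic maps behave. Defaults:
  log-normal populations with mean ≈ 5 000; Beta(2, 16.4) AAPI share
  (mean ≈ 0.11); Beta marginals for the covariate percentages with means
  ≈ 14 %, 23 % and 30 %. Clustering the AAPI share concentrates the AAPI
  population in a subset of SRAs, which is what makes small-cell
  suppression bite realistically.
* **Outlets** — per-tract Poisson counts with mean rate 3.7 per 1 000
  residents (a registry-scale density), uniform locations within the
  tract, and archetype category lists. The probability of AAPI categories
  is 0.25·(1 + affinity·AAPI share), clipped to [0.02, 0.9], affinity
  default 3 — so at zero affinity AAPI content is independent of tract
  composition (tested by chi-square), and at the default a high-AAPI tract
  roughly doubles its AAPI-outlet probability. A few percent of outlets are
  deliberately content-ambiguous or non-food; ambiguous outlets get a
  synthetic resolution drawn with the same tract probability, standing in
  for a manual review.
* **Supermarkets** — Poisson, 0.6 per 10 000 residents, tuned so that an
  appreciable share of population points falls beyond ½ mile.
* **Population points** — default 25 per tract on a jittered sub-grid with
  equal weights summing exactly to the tract populations; they approximate
  within-tract population placement for the distance-share measure.
* **Cases** — latent tract rates y = (I − ρW)⁻¹(Xβ + ε) with X the
  z-scored covariates, queen W row-standardized, defaults ρ = 0.5,
  β = (36, 24, 18), σ_ε = 24 (rate units per 100 000). The draw is shifted
  by |min| + 0.01 so rates are nonnegative before Poisson sampling —
  the linear model does not itself forbid negative rates, the shift is the
  minimal intervention that does. Expected annual tract cases are
  y·pop_AAPI/10⁵; yearly counts are Poisson over 7 years (a typical
  multi-year discharge window); SRA counts are exact tract sums. SRAs whose
  mean annual count falls below the suppression threshold (default 11, a
  common public-health small-cell rule) are flagged and their counts
  withheld, while the county total is retained on the unsuppressed scale.
  Under the defaults roughly a third to a half of SRAs are suppressed,
  matching the regime the reallocation step is designed for. The effect
  and noise scales were set so that SRA counts straddle the suppression
  threshold; they are larger than typical published per-sd effect sizes,
  which sit on much smaller rate scales.

**What the generator does not emulate**: real street networks or
travel-time access, irregular tract shapes, multi-platform outlet
registries with misspelled or free-text categories, age/sex structure in
cases, and measurement error in the covariates. Passing tests therefore
show that the estimators and bookkeeping are correct under the stated
model, not that the substantive associations estimated from any real county
are unbiased — in particular, downscaled rates inherit the
constant-rate-within-SRA assumption, which no test can validate against
tract-level truth that real data do not contain.

## Numerical and degenerate-input conventions

* Moran's I and correlations are undefined (error) for constant inputs;
  constant columns never trigger a screening drop.
* Permutation p-values are bounded below by 1/(n_permutations+1) and are
  deterministic given the seed.
* ρ̂ is strictly interior to its feasible interval (the optimizer bounds
  are offset by 10⁻⁹); SLR refuses islands and rank-deficient designs with
  actionable messages.
* Conservation checks use 10⁻⁹ relative tolerance; oracle equivalences are
  asserted at 10⁻¹² (Moran), 10⁻¹⁰ (OLS) and 10⁻³ (ρ vs a 10⁻⁴-step grid).
* Simulation-based checks run at 400 tracts (20×20) with 100 seeds for
  coverage, 1 000 for OLS type-I error and 500 for residual-Moran
  calibration — sizes at which the binomial noise of the estimated rates is
  a fraction of a percentage point, while a full run stays around a minute.

## Known limitations

* The greedy screening result depends on column order; the order is
  documented configuration, not an inference.
* Wald p-values for the lag model can be optimistic near the boundary of
  the ρ interval; a likelihood-ratio comparison against the ρ = 0 fit is
  available via the reported log-likelihoods.
* The dense eigenvalue route for log|I − ρW| scales as O(n³) and is the
  right choice only up to a few thousand units.
* The default lexicon is illustrative; real registries need a fuller
  category assignment and a genuine ambiguity review.
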