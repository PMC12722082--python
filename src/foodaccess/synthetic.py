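"""Synthetic county generator.

Builds a fully synthetic study region with the statistical structure the
downstream analysis assumes: a rectangular grid of square census tracts
nested in block-shaped subregional areas (SRAs), log-normal tract
populations with a Beta-distributed AAPI share, food outlets placed by a
population-driven Poisson process whose AAPI-category probability rises with
the tract's AAPI share, supermarkets, representative within-tract population
points, and disease case counts drawn from a spatial-lag rate process with
known spatial coefficient and covariate effects, aggregated to SRA level and
small-cell suppressed.

Every stage draws from a named substream of the config seed, so outputs are
reproducible individually and jointly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import sparse
from scipy import stats as sps
from scipy.ndimage import gaussian_filter
from scipy.sparse.linalg import spsolve
from shapely.geometry import Point, box

from .classify import Lexicon, assign_content
from .config import ConfigurationError, CountyConfig
from .weights import SpatialWeights, queen_weights

# fixed substream keys so stage outputs do not depend on call order
_STREAM = {
    "tracts": 1,
    "outlets": 2,
    "supermarkets": 3,
    "pop_points": 4,
    "cases": 5,
    "resolutions": 6,
}

_RATE_SHIFT_EPS = 0.01  # per 100 000; keeps shifted latent rates positive


def _rng(config: CountyConfig, stage: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=config.seed, spawn_key=(_STREAM[stage],))
    )


def generate_tracts(config: CountyConfig) -> pd.DataFrame:
    """Square tracts tiling an ``n_rows x n_cols`` grid, with SRA ids
    assigned by ``sra_block`` blocks and demographics drawn from the
    configured distributions.

    Returns a DataFrame with one row per tract: id, SRA id, shapely polygon
    geometry (metre units), populations, covariate percentages and
    population density (persons per km**2 of residential land).
    """
    rng = _rng(config, "tracts")
    n = config.n_tracts
    side = config.tract_side
    rows, cols = np.divmod(np.arange(n), config.n_cols)
    geoms = [
        box(c * side, r * side, (c + 1) * side, (r + 1) * side)
        for r, c in zip(rows, cols)
    ]
    blocks_per_row = config.n_cols // config.sra_block
    sra_idx = (rows // config.sra_block) * blocks_per_row + (cols // config.sra_block)

    def clustered_uniform(sigma: float) -> np.ndarray:
        # smooth a Gaussian field over the grid and probability-transform it:
        # marginals stay exactly as requested while neighbouring tracts get
        # correlated values, the way real demographic surfaces behave
        g = gaussian_filter(
            rng.normal(size=(config.n_rows, config.n_cols)),
            sigma=sigma, mode="reflect",
        )
        g = (g - g.mean()) / g.std()
        return sps.norm.cdf(g).ravel()

    pop_total = np.round(
        sps.lognorm.ppf(
            clustered_uniform(2.0), s=config.pop_log_sd,
            scale=np.exp(config.pop_log_mean),
        )
    ).astype(int)
    # clustering the AAPI share concentrates the AAPI population in some
    # SRAs, which is what makes small-cell suppression hit a realistic
    # subset of SRAs downstream
    aapi_share = sps.beta.ppf(
        clustered_uniform(2.0), config.aapi_beta_a, config.aapi_beta_b
    )
    pop_aapi = np.minimum(np.round(pop_total * aapi_share).astype(int), pop_total)
    pct_over65 = 100 * sps.beta.ppf(clustered_uniform(1.5), 8.0, 47.5)
    pct_obese = 100 * sps.beta.ppf(clustered_uniform(1.5), 10.0, 32.9)
    pct_below_200fpl = 100 * sps.beta.ppf(clustered_uniform(1.5), 6.0, 14.0)
    residential_frac = rng.uniform(0.2, 0.8, n)
    area_km2 = (side / 1000.0) ** 2
    pop_density = pop_total / (residential_frac * area_km2)

    return pd.DataFrame(
        {
            "tract_id": [f"CT{i:04d}" for i in range(n)],
            "sra_id": [f"SRA{i:03d}" for i in sra_idx],
            "geometry": geoms,
            "pop_total": pop_total,
            "pop_aapi": pop_aapi,
            "pct_over65": pct_over65,
            "pct_obese": pct_obese,
            "pct_below_200fpl": pct_below_200fpl,
            "pop_density": pop_density,
        }
    )


def generate_population_points(
    config: CountyConfig, tracts: pd.DataFrame
) -> pd.DataFrame:
    """Representative population points on a jittered sub-grid inside each
    tract, with equal per-point weights that sum to the tract populations."""
    rng = _rng(config, "pop_points")
    k = config.pop_points_per_tract
    g = int(np.ceil(np.sqrt(k)))
    recs = []
    for t in tracts.itertuples():
        minx, miny, maxx, maxy = t.geometry.bounds
        cell_w, cell_h = (maxx - minx) / g, (maxy - miny) / g
        # first k cells of the g x g sub-grid, jittered within their cell
        cells = np.arange(g * g)[:k]
        cr, cc = np.divmod(cells, g)
        xs = minx + (cc + rng.uniform(0.05, 0.95, k)) * cell_w
        ys = miny + (cr + rng.uniform(0.05, 0.95, k)) * cell_h
        wt = t.pop_total / k
        wa = t.pop_aapi / k
        for x, y in zip(xs, ys):
            recs.append((t.tract_id, x, y, wt, wa))
    return pd.DataFrame(
        recs, columns=["tract_id", "x", "y", "weight_total", "weight_aapi"]
    )


# category-list templates per outlet archetype; drawn from the default lexicon
_AAPI_REST = [
    ["chinese"], ["japanese", "sushi bars"], ["korean"], ["vietnamese"],
    ["thai"], ["filipino"], ["hawaiian", "poke"], ["asian fusion"],
    ["ramen", "japanese"], ["bubble tea"], ["dim sum", "chinese"], ["indian"],
]
_NONAAPI_REST = [
    ["mexican"], ["traditional american"], ["italian", "pizza"], ["burgers"],
    ["sandwiches"], ["mediterranean"], ["soul food"], ["fast food"],
    ["breakfast & brunch"], ["french"], ["barbeque"], ["beer bar"],
]
_AAPI_GROC = [
    ["asian grocery store"], ["japanese grocery"], ["korean grocery"],
    ["chinese grocery"], ["filipino grocery"], ["pan asian food market"],
]
_NONAAPI_GROC = [
    ["mexican grocery"], ["italian grocery"], ["european food market"],
    ["organic health market"],
]
_AMBIGUOUS = [
    ["grocery"], ["food market"], ["farmer's market"], ["health market"],
    ["international grocery"], ["herbs & spices"], ["seafood markets"],
    ["tea rooms"], ["specialty food"], ["imported food"],
]
_NEITHER = [
    ["convenience stores"], ["butcher"], ["bakeries"], ["candy stores"],
    ["coffee & tea"],
]
_EXCLUDED = [["bookstores"], ["food delivery services"], ["florists"]]

# archetype mixture: restaurants dominate a review-site food registry
_KIND_P = {"restaurant": 0.58, "grocery": 0.12, "neither": 0.22,
           "ambiguous": 0.05, "excluded": 0.03}

_BASE_AAPI_P = 0.25  # AAPI-category probability at zero affinity


def aapi_category_probability(config: CountyConfig, aapi_share) -> np.ndarray:
    """Probability that an outlet in a tract carries AAPI categories:
    base probability scaled up with the tract AAPI share through the
    affinity multiplier, clipped to [0.02, 0.9]."""
    p = _BASE_AAPI_P * (1.0 + config.aapi_outlet_affinity * np.asarray(aapi_share))
    return np.clip(p, 0.02, 0.9)


def generate_outlets(config: CountyConfig, tracts: pd.DataFrame) -> pd.DataFrame:
    """Food outlets from a per-tract Poisson process with mean
    ``outlet_rate_per_1k * pop_total / 1000``, uniform locations inside the
    tract, and category lists sampled from archetype templates. The share of
    AAPI-category outlets increases with the tract AAPI share via
    ``aapi_outlet_affinity``; some outlets are deliberately content-ambiguous
    or non-food."""
    if tracts.empty:
        raise ConfigurationError("tracts must be nonempty")
    rng = _rng(config, "outlets")
    kinds = list(_KIND_P)
    kind_p = np.array([_KIND_P[k] for k in kinds])
    recs = []
    oid = 0
    for t in tracts.itertuples():
        lam = config.outlet_rate_per_1k * t.pop_total / 1000.0
        n_out = rng.poisson(lam)
        if n_out == 0:
            continue
        p_aapi = aapi_category_probability(
            config, t.pop_aapi / max(t.pop_total, 1)
        )
        minx, miny, maxx, maxy = t.geometry.bounds
        xs = rng.uniform(minx, maxx, n_out)
        ys = rng.uniform(miny, maxy, n_out)
        kind_draw = rng.choice(len(kinds), size=n_out, p=kind_p)
        aapi_draw = rng.random(n_out) < p_aapi
        for j in range(n_out):
            kind = kinds[kind_draw[j]]
            if kind == "restaurant":
                pool = _AAPI_REST if aapi_draw[j] else _NONAAPI_REST
            elif kind == "grocery":
                pool = _AAPI_GROC if aapi_draw[j] else _NONAAPI_GROC
            elif kind == "ambiguous":
                pool = _AMBIGUOUS
            elif kind == "neither":
                pool = _NEITHER
            else:
                pool = _EXCLUDED
            cats = list(pool[rng.integers(len(pool))])
            recs.append(
                (
                    f"O{oid:06d}",
                    f"Outlet {oid}",
                    t.tract_id,
                    xs[j],
                    ys[j],
                    "|".join(cats),
                )
            )
            oid += 1
    return pd.DataFrame(
        recs, columns=["outlet_id", "name", "true_tract_id", "x", "y", "categories"]
    )


def generate_supermarkets(config: CountyConfig, tracts: pd.DataFrame) -> pd.DataFrame:
    """Supermarket points: per-tract Poisson with mean
    ``supermarket_rate_per_10k * pop_total / 10000``, uniform locations."""
    rng = _rng(config, "supermarkets")
    recs = []
    sid = 0
    for t in tracts.itertuples():
        lam = config.supermarket_rate_per_10k * t.pop_total / 10000.0
        for _ in range(rng.poisson(lam)):
            minx, miny, maxx, maxy = t.geometry.bounds
            recs.append(
                (f"S{sid:04d}", rng.uniform(minx, maxx), rng.uniform(miny, maxy))
            )
            sid += 1
    return pd.DataFrame(recs, columns=["supermarket_id", "x", "y"])


def generate_resolutions(
    config: CountyConfig, tracts: pd.DataFrame, outlets: pd.DataFrame,
    lexicon: Lexicon | None = None,
) -> dict:
    """Synthetic stand-in for the manual review of content-ambiguous
    outlets: each is resolved to 'aapi' with the tract's AAPI-category
    probability, deterministically given the seed."""
    lexicon = lexicon or Lexicon.default()
    rng = _rng(config, "resolutions")
    share = (
        tracts.set_index("tract_id")["pop_aapi"]
        / tracts.set_index("tract_id")["pop_total"].clip(lower=1)
    )
    res = {}
    for o in outlets.itertuples():
        cats = o.categories.split("|")
        if assign_content(cats, lexicon) == "ambiguous":
            p = float(aapi_category_probability(config, share[o.true_tract_id]))
            res[o.outlet_id] = "aapi" if rng.random() < p else "non_aapi"
    return res


@dataclass
class CaseData:
    """Output of :func:`generate_cases`."""

    records: pd.DataFrame  # one row per SRA: sra_id, pop_aapi, suppressed, yearly
    county_mean_annual_cases: float  # unsuppressed-scale county total
    true_rates: pd.DataFrame  # tract_id, true_rate (per 100k), expected_cases
    tract_counts: pd.DataFrame  # tract x year Poisson draws (ground truth)


def generate_cases(
    config: CountyConfig,
    tracts: pd.DataFrame,
    weights: SpatialWeights,
    covariate_cols: Sequence[str] | None = None,
    true_beta: Sequence[float] | None = None,
) -> CaseData:
    """Disease cases from a spatial-lag rate process.

    Latent tract rates (per 100 000 AAPI population) follow
    ``y = (I - rho*W)^-1 (X beta + eps)`` with X the z-scored covariates,
    shifted by ``|min| + eps`` so rates are nonnegative. Expected annual
    tract cases are ``y * pop_aapi / 100000``; yearly counts are Poisson,
    summed to SRA level. SRAs whose mean annual count falls below the
    suppression threshold are flagged and their yearly counts withheld; the
    county total is retained on the unsuppressed scale.
    """
    if not abs(config.true_rho) < 1:
        raise ConfigurationError("true_rho must satisfy |true_rho| < 1")
    if weights.style != "row_standardized":
        raise ConfigurationError("weights must be row-standardized")
    if tuple(weights.ids) != tuple(tracts["tract_id"]):
        raise ConfigurationError("weights not aligned with tracts")
    covariate_cols = list(covariate_cols or config.covariate_cols)
    beta = np.asarray(
        true_beta if true_beta is not None else config.true_beta, dtype=float
    )
    if len(beta) != len(covariate_cols):
        raise ConfigurationError("true_beta length must match covariate_cols")

    rng = _rng(config, "cases")
    X = tracts[covariate_cols].to_numpy(dtype=float)
    sd = X.std(axis=0, ddof=1)
    if np.any(sd == 0):
        raise ConfigurationError("constant covariate column cannot be z-scored")
    Xz = (X - X.mean(axis=0)) / sd
    n = len(tracts)
    eps = rng.normal(0.0, config.noise_sd, n)
    eta = Xz @ beta + eps
    A = sparse.identity(n, format="csc") - config.true_rho * weights.sparse().tocsc()
    y = spsolve(A, eta)
    y = y + abs(y.min()) + _RATE_SHIFT_EPS

    lam = y * tracts["pop_aapi"].to_numpy() / 1e5
    counts = rng.poisson(lam[:, None], size=(n, config.n_years))
    tract_counts = pd.DataFrame(
        counts,
        index=tracts["tract_id"],
        columns=[f"year_{i+1}" for i in range(config.n_years)],
    )

    sra_pop = tracts.groupby("sra_id")["pop_aapi"].sum()
    sra_counts = tract_counts.groupby(tracts.set_index("tract_id")["sra_id"]).sum()
    sra_mean = sra_counts.mean(axis=1)
    suppressed = sra_mean < config.suppression_threshold
    records = pd.DataFrame(
        {
            "sra_id": sra_counts.index,
            "pop_aapi": sra_pop.reindex(sra_counts.index).to_numpy(),
            "suppressed": suppressed.to_numpy(),
            "yearly_cases": [
                None if s else list(map(int, row))
                for s, row in zip(suppressed, sra_counts.to_numpy())
            ],
        }
    ).reset_index(drop=True)

    true_rates = pd.DataFrame(
        {
            "tract_id": tracts["tract_id"].to_numpy(),
            "true_rate": y,
            "expected_cases": lam,
        }
    )
    return CaseData(
        records=records,
        county_mean_annual_cases=float(sra_mean.sum()),
        true_rates=true_rates,
        tract_counts=tract_counts,
    )


@dataclass
class SyntheticCounty:
    config: CountyConfig
    tracts: pd.DataFrame
    outlets: pd.DataFrame
    supermarkets: pd.DataFrame
    pop_points: pd.DataFrame
    resolutions: dict
    weights: SpatialWeights  # queen, row-standardized
    cases: CaseData


def generate_county(
    config: CountyConfig, lexicon: Lexicon | None = None
) -> SyntheticCounty:
    """Generate every input the pipeline consumes, deterministically."""
    tracts = generate_tracts(config)
    outlets = generate_outlets(config, tracts)
    supermarkets = generate_supermarkets(config, tracts)
    pop_points = generate_population_points(config, tracts)
    resolutions = generate_resolutions(config, tracts, outlets, lexicon)
    w = queen_weights(tracts["tract_id"], tracts["geometry"]).row_standardize()
    cases = generate_cases(config, tracts, w)
    return SyntheticCounty(
        config=config,
        tracts=tracts,
        outlets=outlets,
        supermarkets=supermarkets,
        pop_points=pop_points,
        resolutions=resolutions,
        weights=w,
        cases=cases,
    )
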