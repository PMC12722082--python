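"""Tract-level food-access measures.

Six ethnic-store variables summarise three aspects of culturally
appropriate food access from classified outlet counts:

* relative food environment — ratio of AAPI to non-AAPI outlets of each kind
  within the tract (``rest_ratio``, ``groc_ratio``);
* outlets per capita — AAPI outlets per AAPI resident (``rest_per_aapi``,
  ``groc_per_aapi``), stored per person (multiply by 1 000 for the per-1 000
  reading);
* outlet intensity — the tract's share of the county total of AAPI outlets
  of each kind (``rest_intensity``, ``groc_intensity``).

A supermarket-distance analog of the USDA Food Access Research Atlas adds
the share of the tract's total and AAPI population living beyond a straight-
line distance threshold (default half a mile) from the nearest supermarket
(``fara_ct``, ``fara_aapi``).

Zero-denominator ratios and per-capita values are reported as missing (NaN)
with a flag rather than 0 or infinity: 0 would conflate "no AAPI outlets"
with "no comparison outlets".
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from shapely.geometry import Point
from shapely.strtree import STRtree

HALF_MILE_M = 804.672  # half a US survey-free mile, metres

logger = logging.getLogger(__name__)

MEASURE_COLUMNS = [
    "fara_ct",
    "fara_aapi",
    "rest_ratio",
    "groc_ratio",
    "rest_per_aapi",
    "groc_per_aapi",
    "rest_intensity",
    "groc_intensity",
]


def count_outlets_by_tract(
    classified: pd.DataFrame, tracts: pd.DataFrame
) -> pd.DataFrame:
    """Point-in-polygon counts of classified outlets per tract and group.

    Boundary points are assigned to the covering tract with the
    lexicographically smallest id; outlets falling outside every tract are
    dropped (logged). Expects ``classified`` to carry ``group`` labels and
    planar x/y in the tracts' coordinate system.
    """
    order = np.argsort(tracts["tract_id"].to_numpy())
    geoms = tracts["geometry"].to_numpy()[order]
    ids_sorted = tracts["tract_id"].to_numpy()[order]
    tree = STRtree(list(geoms))

    counts = pd.DataFrame(
        0,
        index=pd.Index(tracts["tract_id"], name="tract_id"),
        columns=["n_aapi_rest", "n_nonaapi_rest", "n_aapi_groc", "n_nonaapi_groc"],
    )
    col_of = {
        "aapi_restaurants": "n_aapi_rest",
        "non_aapi_restaurants": "n_nonaapi_rest",
        "aapi_groceries": "n_aapi_groc",
        "non_aapi_groceries": "n_nonaapi_groc",
    }
    n_outside = 0
    relevant = classified[classified["group"].isin(col_of)]
    for o in relevant.itertuples():
        pt = Point(o.x, o.y)
        hits = tree.query(pt, predicate="intersects")
        if len(hits) == 0:
            n_outside += 1
            continue
        tid = ids_sorted[min(hits)]  # geoms sorted by id: min index = smallest id
        counts.loc[tid, col_of[o.group]] += 1
    if n_outside:
        logger.info("dropped %d outlet(s) outside all tracts", n_outside)
    return counts.reset_index()


def relative_environment(counts: pd.DataFrame) -> pd.DataFrame:
    """AAPI-to-non-AAPI outlet ratios per tract and kind.

    Both counts zero -> 0; AAPI outlets present but no non-AAPI comparison
    -> missing, flagged."""
    out = pd.DataFrame({"tract_id": counts["tract_id"]})
    for kind, num, den in (
        ("rest", "n_aapi_rest", "n_nonaapi_rest"),
        ("groc", "n_aapi_groc", "n_nonaapi_groc"),
    ):
        a = counts[num].to_numpy(dtype=float)
        b = counts[den].to_numpy(dtype=float)
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(b > 0, a / np.where(b > 0, b, 1), np.nan)
        ratio = np.where((b == 0) & (a == 0), 0.0, ratio)
        out[f"{kind}_ratio"] = ratio
        out[f"{kind}_ratio_missing"] = (b == 0) & (a > 0)
    return out


def per_capita(counts: pd.DataFrame, pop_aapi) -> pd.DataFrame:
    """AAPI outlets per AAPI resident. Zero population with zero outlets
    -> 0; zero population with outlets present -> missing, flagged."""
    pop = np.asarray(pop_aapi, dtype=float)
    if np.any(pop < 0):
        raise ValueError("pop_aapi must be nonnegative")
    out = pd.DataFrame({"tract_id": counts["tract_id"]})
    for kind, num in (("rest", "n_aapi_rest"), ("groc", "n_aapi_groc")):
        a = counts[num].to_numpy(dtype=float)
        val = np.where(pop > 0, a / np.where(pop > 0, pop, 1), np.nan)
        val = np.where((pop == 0) & (a == 0), 0.0, val)
        out[f"{kind}_per_aapi"] = val
        out[f"{kind}_per_aapi_missing"] = (pop == 0) & (a > 0)
    return out


def intensity(counts: pd.DataFrame) -> pd.DataFrame:
    """Tract share of the county total of AAPI outlets of each kind.
    Sums to 1 over tracts when the county total is positive; an all-zero
    county yields all-zero intensities with a warning."""
    out = pd.DataFrame({"tract_id": counts["tract_id"]})
    for kind, num in (("rest", "n_aapi_rest"), ("groc", "n_aapi_groc")):
        a = counts[num].to_numpy(dtype=float)
        total = a.sum()
        if total == 0:
            warnings.warn(f"county total of AAPI {kind} outlets is zero")
            out[f"{kind}_intensity"] = np.zeros_like(a)
        else:
            out[f"{kind}_intensity"] = a / total
    return out


def share_beyond(
    tracts: pd.DataFrame,
    pop_points: pd.DataFrame,
    supermarkets: pd.DataFrame,
    threshold: float = HALF_MILE_M,
) -> pd.DataFrame:
    """Percent of tract population beyond ``threshold`` (straight-line
    metres) of the nearest supermarket, for the total and the AAPI
    population. No supermarkets -> 100 for every tract with positive
    population; zero-population tracts -> missing."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    pts = pop_points.copy()
    if supermarkets.empty:
        pts["beyond"] = True
    else:
        tree = cKDTree(supermarkets[["x", "y"]].to_numpy(dtype=float))
        d, _ = tree.query(pts[["x", "y"]].to_numpy(dtype=float))
        pts["beyond"] = d > threshold

    grp = pts.groupby("tract_id")
    tot = grp["weight_total"].sum()
    tot_beyond = grp.apply(
        lambda g: g.loc[g["beyond"], "weight_total"].sum(), include_groups=False
    )
    aapi = grp["weight_aapi"].sum()
    aapi_beyond = grp.apply(
        lambda g: g.loc[g["beyond"], "weight_aapi"].sum(), include_groups=False
    )

    out = pd.DataFrame({"tract_id": tracts["tract_id"]})
    tot = tot.reindex(out["tract_id"]).to_numpy()
    tot_beyond = tot_beyond.reindex(out["tract_id"]).to_numpy()
    aapi = aapi.reindex(out["tract_id"]).to_numpy()
    aapi_beyond = aapi_beyond.reindex(out["tract_id"]).to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        out["fara_ct"] = np.where(tot > 0, 100.0 * tot_beyond / tot, np.nan)
        out["fara_aapi"] = np.where(aapi > 0, 100.0 * aapi_beyond / aapi, np.nan)
    return out


def access_measure_table(
    classified: pd.DataFrame,
    tracts: pd.DataFrame,
    pop_points: pd.DataFrame,
    supermarkets: pd.DataFrame,
    threshold: float = HALF_MILE_M,
) -> pd.DataFrame:
    """All eight access measures (plus missingness flags) per tract."""
    counts = count_outlets_by_tract(classified, tracts)
    parts = [
        counts,
        relative_environment(counts).drop(columns="tract_id"),
        per_capita(counts, tracts["pop_aapi"].to_numpy()).drop(columns="tract_id"),
        intensity(counts).drop(columns="tract_id"),
        share_beyond(tracts, pop_points, supermarkets, threshold).drop(
            columns="tract_id"
        ),
    ]
    return pd.concat(parts, axis=1)
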