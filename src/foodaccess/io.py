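"""Readers and writers for the pipeline's on-disk formats.

Tracts travel as a GeoJSON FeatureCollection (one polygon feature per tract,
demographics as properties); outlets, supermarkets, population points and
case records as CSV; configs as JSON or YAML. Coordinates are planar metres
throughout — real shapefile-derived data should be projected before entry.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
import yaml
from shapely.geometry import mapping, shape

from .config import CountyConfig

_TRACT_PROPS = [
    "tract_id",
    "sra_id",
    "pop_total",
    "pop_aapi",
    "pct_over65",
    "pct_obese",
    "pct_below_200fpl",
    "pop_density",
]


def write_tracts_geojson(tracts: pd.DataFrame, path) -> None:
    features = []
    for t in tracts.itertuples():
        props = {p: getattr(t, p) for p in _TRACT_PROPS if hasattr(t, p)}
        for k, v in props.items():
            if hasattr(v, "item"):
                props[k] = v.item()
        features.append(
            {
                "type": "Feature",
                "geometry": mapping(t.geometry),
                "properties": props,
            }
        )
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)


def read_tracts_geojson(path) -> pd.DataFrame:
    with open(path) as fh:
        fc = json.load(fh)
    rows = []
    for feat in fc["features"]:
        row = dict(feat["properties"])
        row["geometry"] = shape(feat["geometry"])
        rows.append(row)
    df = pd.DataFrame(rows)
    cols = [c for c in _TRACT_PROPS if c in df.columns] + ["geometry"]
    return df[cols + [c for c in df.columns if c not in cols]]


def write_cases_csv(records: pd.DataFrame, cases_path, pops_path) -> None:
    """Long-form cases CSV (sra_id, year, cases; blank cases = suppressed)
    plus an SRA population CSV."""
    rows = []
    for rec in records.itertuples():
        if rec.suppressed:
            rows.append({"sra_id": rec.sra_id, "year": "", "cases": ""})
        else:
            for i, c in enumerate(rec.yearly_cases, start=1):
                rows.append({"sra_id": rec.sra_id, "year": i, "cases": c})
    pd.DataFrame(rows).to_csv(cases_path, index=False)
    records[["sra_id", "pop_aapi"]].to_csv(pops_path, index=False)


def read_cases_csv(cases_path, pops_path) -> pd.DataFrame:
    cases = pd.read_csv(cases_path, dtype={"sra_id": str})
    pops = pd.read_csv(pops_path, dtype={"sra_id": str}).set_index("sra_id")
    recs = []
    for sra, grp in cases.groupby("sra_id", sort=True):
        suppressed = grp["cases"].isna().all()
        yearly = (
            None
            if suppressed
            else [int(c) for _, c in sorted(zip(grp["year"], grp["cases"]))]
        )
        recs.append(
            {
                "sra_id": sra,
                "pop_aapi": float(pops.loc[sra, "pop_aapi"]),
                "suppressed": bool(suppressed),
                "yearly_cases": yearly,
            }
        )
    return pd.DataFrame(recs)


def write_config(config: CountyConfig, path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        if path.suffix in (".yaml", ".yml"):
            yaml.safe_dump(config.to_dict(), fh)
        else:
            json.dump(config.to_dict(), fh, indent=2)


def read_config(path) -> CountyConfig:
    path = Path(path)
    with open(path) as fh:
        d = yaml.safe_load(fh) if path.suffix in (".yaml", ".yml") else json.load(fh)
    return CountyConfig.from_dict(d)


def write_weights(weights, triplet_path, neighbors_json_path=None) -> None:
    pd.DataFrame(weights.to_triplets(), columns=["i", "j", "w"]).to_csv(
        triplet_path, index=False
    )
    if neighbors_json_path:
        obj = {
            "ids": list(weights.ids),
            "scheme": weights.scheme,
            "style": weights.style,
            "k": weights.k,
            "neighbors": {
                weights.ids[i]: [weights.ids[j] for j in nb]
                for i, nb in enumerate(weights.neighbors)
            },
        }
        with open(neighbors_json_path, "w") as fh:
            json.dump(obj, fh)
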