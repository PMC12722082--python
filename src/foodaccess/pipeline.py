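"""End-to-end pipeline: generate or load a county, classify outlets,
compute access measures, downscale rates, screen variables, run the model
battery, and write all artifacts plus a run manifest."""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .classify import Lexicon, classify_outlets, read_resolutions
from .config import CountyConfig
from .downscale import downscale_rates
from .io import (
    read_cases_csv,
    read_tracts_geojson,
    write_cases_csv,
    write_config,
    write_tracts_geojson,
    write_weights,
)
from .measures import HALF_MILE_M, MEASURE_COLUMNS, access_measure_table
from .regression import run_model_battery
from .stats import morans_i, spearman_screen
from .synthetic import generate_county
from .weights import knn_weights, queen_weights

logger = logging.getLogger(__name__)

# scan order for the greedy collinearity screen: the AAPI-specific and
# per-capita variants take precedence over their highly correlated partners
EXPOSURE_CANDIDATES = [
    "fara_aapi",
    "fara_ct",
    "rest_ratio",
    "rest_per_aapi",
    "rest_intensity",
    "groc_ratio",
    "groc_per_aapi",
    "groc_intensity",
]


@dataclass
class PipelineConfig:
    mode: str = "synthetic"  # "synthetic" | "files"
    county: CountyConfig = field(default_factory=CountyConfig)
    tracts_path: str | None = None
    outlets_path: str | None = None
    supermarkets_path: str | None = None
    pop_points_path: str | None = None
    cases_path: str | None = None
    sra_pops_path: str | None = None
    lexicon_path: str | None = None
    resolutions_path: str | None = None
    county_total_mean_cases: float | None = None  # files mode, unsuppressed scale
    distance_threshold: float = HALF_MILE_M
    knn_k: int = 8
    permutations: int = 999
    screen_threshold: float = 0.90
    seed: int = 0
    out_dir: str = "pipeline_out"

    def __post_init__(self):
        if self.mode not in ("synthetic", "files"):
            raise ValueError("mode must be 'synthetic' or 'files'")
        if self.distance_threshold <= 0 or self.screen_threshold <= 0:
            raise ValueError("thresholds must be positive")


def _load_files(cfg: PipelineConfig):
    tracts = read_tracts_geojson(cfg.tracts_path)
    outlets = pd.read_csv(cfg.outlets_path, dtype={"outlet_id": str})
    supermarkets = pd.read_csv(cfg.supermarkets_path)
    pop_points = pd.read_csv(cfg.pop_points_path, dtype={"tract_id": str})
    records = read_cases_csv(cfg.cases_path, cfg.sra_pops_path)
    resolutions = (
        read_resolutions(cfg.resolutions_path) if cfg.resolutions_path else {}
    )
    county_total = cfg.county_total_mean_cases
    if county_total is None:
        # without an external county figure the reported SRAs define the
        # total, so suppressed SRAs receive zero reallocated cases
        county_total = float(
            sum(
                np.mean(y)
                for y in records.loc[~records["suppressed"], "yearly_cases"]
            )
        )
    return tracts, outlets, supermarkets, pop_points, records, resolutions, county_total


def run_pipeline(cfg: PipelineConfig) -> Path:
    """Run every stage and write artifacts to the output directory.
    Returns the artifact directory; raises on the first failing stage with a
    stage-tagged message (partial artifacts are retained)."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    lexicon = (
        Lexicon.from_json(cfg.lexicon_path) if cfg.lexicon_path else Lexicon.default()
    )
    stage = "inputs"
    try:
        if cfg.mode == "synthetic":
            county = generate_county(cfg.county, lexicon)
            tracts = county.tracts
            outlets = county.outlets
            supermarkets = county.supermarkets
            pop_points = county.pop_points
            resolutions = county.resolutions
            records = county.cases.records
            county_total = county.cases.county_mean_annual_cases
            write_tracts_geojson(tracts, out / "tracts.geojson")
            outlets.to_csv(out / "outlets.csv", index=False)
            supermarkets.to_csv(out / "supermarkets.csv", index=False)
            pop_points.to_csv(out / "pop_points.csv", index=False)
            write_cases_csv(records, out / "cases.csv", out / "sra_pops.csv")
            write_config(cfg.county, out / "county_config.json")
        else:
            (tracts, outlets, supermarkets, pop_points, records, resolutions,
             county_total) = _load_files(cfg)

        stage = "classify"
        classified, counts = classify_outlets(outlets, lexicon, resolutions)
        logger.info("outlet group counts: %s", counts)
        classified.to_csv(out / "classified_outlets.csv", index=False)

        stage = "measures"
        measures = access_measure_table(
            classified, tracts, pop_points, supermarkets, cfg.distance_threshold
        )
        measures.to_csv(out / "measures.csv", index=False)

        stage = "downscale"
        rates = downscale_rates(records, tracts, county_total)
        rates.to_csv(out / "rates.csv", index=False)

        stage = "weights"
        wq = queen_weights(tracts["tract_id"], tracts["geometry"])
        wq_std = wq.row_standardize()
        centroids = [g.centroid for g in tracts["geometry"]]
        wk = knn_weights(tracts["tract_id"], centroids, cfg.knn_k)
        write_weights(wq, out / "weights_queen.csv", out / "weights_queen.json")
        write_weights(wk, out / "weights_knn.csv", out / "weights_knn.json")

        stage = "stats"
        data = tracts.drop(columns="geometry").merge(measures, on="tract_id")
        data = data.merge(
            rates[["tract_id", "rate_per_100k"]], on="tract_id"
        )
        moran_rows = []
        for col in MEASURE_COLUMNS + ["rate_per_100k"]:
            try:
                m = morans_i(
                    data[col].to_numpy(), wk,
                    method="permutation",
                    n_permutations=cfg.permutations, seed=cfg.seed,
                )
                moran_rows.append(
                    {"variable": col, "I": m.I, "expected": m.expected,
                     "p": m.p_value, "n": m.n}
                )
            except Exception as exc:
                moran_rows.append({"variable": col, "error": str(exc)})
        pd.DataFrame(moran_rows).to_csv(out / "moran_report.csv", index=False)

        corr, dropped = spearman_screen(
            data[EXPOSURE_CANDIDATES], cfg.screen_threshold
        )
        corr.to_csv(out / "spearman_matrix.csv")
        pd.DataFrame(
            dropped, columns=["dropped", "kept", "rho"]
        ).to_csv(out / "screening.csv", index=False)
        surviving = [
            c for c in EXPOSURE_CANDIDATES if c not in {d[0] for d in dropped}
        ]

        stage = "model"
        report = run_model_battery(
            data,
            exposures=surviving,
            outcome="rate_per_100k",
            weights=wq_std,
            knn_weights_obj=wk,
            n_permutations=cfg.permutations,
            seed=cfg.seed,
        )
        report.to_csv(out / "model_battery.csv", index=False)
        report.to_json(out / "model_battery.json", orient="records", indent=2)

        stage = "manifest"
        manifest = {
            "version": __version__,
            "seed": cfg.seed,
            "mode": cfg.mode,
            "config_hash": hashlib.sha256(
                json.dumps(
                    {k: v for k, v in vars(cfg).items() if k != "county"},
                    sort_keys=True, default=str,
                ).encode()
                + json.dumps(cfg.county.to_dict(), sort_keys=True).encode()
            ).hexdigest(),
            "counts": {
                "outlets_in": int(len(outlets)),
                "outlet_groups": counts,
                "ambiguous_resolved": int(len(resolutions)),
                "tracts": int(len(tracts)),
                "sras_total": int(len(records)),
                "sras_suppressed": int(records["suppressed"].sum()),
                "tracts_missing_measures": int(
                    measures[MEASURE_COLUMNS].isna().any(axis=1).sum()
                ),
                "exposures_dropped": [d[0] for d in dropped],
                "python": sys.version.split()[0],
            },
        }
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
    except Exception as exc:
        raise RuntimeError(f"[stage: {stage}] {exc}") from exc
    return out
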