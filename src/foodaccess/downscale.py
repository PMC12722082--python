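"""Suppression-aware downscaling of subregional (SRA) case counts to
tract-level annual rates per 100 000 AAPI population.

The procedure: average each SRA's yearly counts to one mean annual count;
divide by SRA AAPI population for the SRA rate; reallocate the county
residual (county total minus the sum reported in unsuppressed SRAs) to the
suppressed SRAs in proportion to their AAPI populations; then apportion SRA
cases to tracts in proportion to tract AAPI population. Cases — not rate
values — are apportioned, which satisfies the constant-rate-within-SRA
assumption exactly: every tract with positive AAPI population inherits its
SRA's rate. Fractional cases are retained so that aggregation conserves
totals to floating-point precision. Zero-AAPI tracts are assigned rate 0.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

_REL_TOL = 1e-9


class DataConsistencyError(ValueError):
    pass


def mean_annual_cases(yearly_cases) -> float:
    """Arithmetic mean of the yearly counts."""
    arr = np.asarray(list(yearly_cases), dtype=float)
    if arr.size == 0:
        raise ValueError("yearly_cases must be nonempty")
    if np.any(arr < 0):
        raise ValueError("case counts must be nonnegative")
    return float(arr.mean())


def rate_per_100k(cases: float, pop_aapi: float) -> float:
    """Annual rate per 100 000 population; zero population yields 0."""
    if cases < 0 or pop_aapi < 0:
        raise ValueError("cases and pop_aapi must be nonnegative")
    if pop_aapi == 0:
        return 0.0
    return 1e5 * cases / pop_aapi


def reallocate_suppressed(
    county_total_mean_cases: float, records: pd.DataFrame
) -> dict:
    """Distribute the county residual over suppressed SRAs by AAPI share.

    ``records`` needs columns sra_id, pop_aapi, suppressed, yearly_cases
    (None when suppressed). Returns sra_id -> mean annual cases for each
    suppressed SRA. The residual is the county total minus the summed means
    of the reported SRAs; it must be nonnegative, and zero (to tolerance)
    when nothing is suppressed.
    """
    reported = records.loc[~records["suppressed"]]
    reported_sum = float(
        sum(mean_annual_cases(y) for y in reported["yearly_cases"])
    )
    residual = county_total_mean_cases - reported_sum
    scale = max(abs(county_total_mean_cases), 1.0)
    if residual < -_REL_TOL * scale:
        raise DataConsistencyError(
            f"reported SRA cases ({reported_sum}) exceed the county total "
            f"({county_total_mean_cases})"
        )
    suppressed = records.loc[records["suppressed"]]
    if suppressed.empty:
        if residual > _REL_TOL * scale:
            raise DataConsistencyError(
                f"residual {residual} cases but no suppressed SRA to receive them"
            )
        return {}
    pops = suppressed["pop_aapi"].to_numpy(dtype=float)
    if pops.sum() == 0:
        raise DataConsistencyError(
            "suppressed SRAs have zero total AAPI population"
        )
    shares = pops / pops.sum()
    residual = max(residual, 0.0)
    return dict(zip(suppressed["sra_id"], residual * shares))


def apportion_to_tracts(
    sra_cases: float, sra_pop_aapi: float, tracts_in_sra: pd.DataFrame
) -> pd.DataFrame:
    """Split one SRA's mean annual cases over its tracts by AAPI share.

    Every tract with positive AAPI population receives the SRA rate; tracts
    with zero AAPI population get cases 0 and rate 0. An SRA with zero AAPI
    population yields all-zero rows flagged ``zero_pop``.
    """
    tract_pop = tracts_in_sra["pop_aapi"].to_numpy(dtype=float)
    if sra_pop_aapi > 0:
        rel = abs(tract_pop.sum() - sra_pop_aapi) / sra_pop_aapi
        if rel > 1e-6:
            raise DataConsistencyError(
                f"tract AAPI populations sum to {tract_pop.sum()}, "
                f"SRA population is {sra_pop_aapi}"
            )
        cases = sra_cases * tract_pop / sra_pop_aapi
        rates = np.where(tract_pop > 0, np.divide(
            1e5 * cases, tract_pop, out=np.zeros_like(cases),
            where=tract_pop > 0), 0.0)
        flag = np.where(tract_pop > 0, "apportioned", "zero_pop")
    else:
        if tract_pop.sum() > 0:
            raise DataConsistencyError(
                "SRA AAPI population is zero but tract populations are not"
            )
        cases = np.zeros_like(tract_pop)
        rates = np.zeros_like(tract_pop)
        flag = np.full(len(tract_pop), "zero_pop", dtype=object)
    return pd.DataFrame(
        {
            "tract_id": tracts_in_sra["tract_id"].to_numpy(),
            "apportioned_cases": cases,
            "rate_per_100k": rates,
            "provenance": flag,
        }
    )


def downscale_rates(
    records: pd.DataFrame,
    tracts: pd.DataFrame,
    county_total_mean_cases: float | None = None,
) -> pd.DataFrame:
    """Full SRA-to-tract downscaling with suppression reallocation.

    Returns one row per tract: apportioned mean annual cases, annual rate
    per 100 000 AAPI population, and a provenance flag
    (reported | reallocated | zero_pop). When ``county_total_mean_cases`` is
    omitted, the reported SRAs' total is used (valid only if nothing is
    suppressed).
    """
    if county_total_mean_cases is None:
        if records["suppressed"].any():
            raise DataConsistencyError(
                "county_total_mean_cases required when SRAs are suppressed"
            )
        county_total_mean_cases = float(
            sum(mean_annual_cases(y) for y in records["yearly_cases"])
        )
    realloc = reallocate_suppressed(county_total_mean_cases, records)
    pieces = []
    for rec in records.itertuples():
        sub = tracts.loc[tracts["sra_id"] == rec.sra_id]
        if rec.suppressed:
            cases, source = realloc[rec.sra_id], "reallocated"
        else:
            cases, source = mean_annual_cases(rec.yearly_cases), "reported"
        part = apportion_to_tracts(cases, rec.pop_aapi, sub)
        part.loc[part["provenance"] == "apportioned", "provenance"] = source
        pieces.append(part)
    out = pd.concat(pieces, ignore_index=True)
    order = tracts["tract_id"].to_numpy()
    return out.set_index("tract_id").loc[order].reset_index()
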