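"""Global spatial autocorrelation (Moran's I) and correlation screening.

Moran's I for values x aligned with a spatial weights object W:

    I = (n / S0) * (sum_ij w_ij z_i z_j) / (sum_i z_i^2),   z = x - mean(x)

with expectation E[I] = -1/(n-1) under the no-autocorrelation null.
Inference is available analytically under the normality assumption or by
random permutation of the values over the units (the default here, 999
draws with an explicit seed). Missing values are removed listwise, with the
weights subset (and re-standardized) accordingly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .weights import SpatialWeights


class UndefinedStatisticError(ValueError):
    pass


@dataclass(frozen=True)
class MoranResult:
    I: float
    expected: float
    variance: float
    z: float
    p_value: float
    method: str
    n: int
    n_permutations: int = 0
    seed: int | None = None

    def __repr__(self):
        return (
            f"MoranResult(I={self.I:.4f}, E[I]={self.expected:.4f}, "
            f"z={self.z:.3f}, p={self.p_value:.4g}, method={self.method!r}, "
            f"n={self.n})"
        )


def _moran_statistic(z: np.ndarray, W) -> float:
    num = float(z @ (W @ z))
    return num


def morans_i(
    x,
    weights: SpatialWeights,
    method: str = "permutation",
    n_permutations: int = 999,
    seed: int = 0,
) -> MoranResult:
    """Global Moran's I with permutation (default) or analytic-normal
    inference. NaNs are dropped listwise with the weights subset to the
    observed units."""
    x = np.asarray(x, dtype=float)
    if x.shape[0] != weights.n:
        raise ValueError("x not aligned with weights")
    mask = ~np.isnan(x)
    if not mask.all():
        x = x[mask]
        weights = weights.subset(mask)
    n = x.size
    if n < 3:
        raise UndefinedStatisticError("need at least 3 observations")
    if np.var(x) == 0:
        raise UndefinedStatisticError("Moran's I undefined for constant input")

    W = weights.sparse()
    s0 = weights.s0
    z = x - x.mean()
    denom = float(z @ z)
    I_obs = (n / s0) * _moran_statistic(z, W) / denom
    expected = -1.0 / (n - 1)

    if method == "normal":
        # moments of I under the normality assumption
        Wd = W.toarray()
        s1 = 0.5 * np.sum((Wd + Wd.T) ** 2)
        s2 = np.sum((Wd.sum(axis=0) + Wd.sum(axis=1)) ** 2)
        var = (
            (n**2 * s1 - n * s2 + 3 * s0**2) / ((n**2 - 1) * s0**2)
            - expected**2
        )
        zscore = (I_obs - expected) / np.sqrt(var)
        p = 2 * sps.norm.sf(abs(zscore))
        return MoranResult(I_obs, expected, var, zscore, p, "normal", n)
    if method == "permutation":
        rng = np.random.default_rng(seed)
        scale = (n / s0) / denom
        perm_I = np.empty(n_permutations)
        for b in range(n_permutations):
            zp = rng.permutation(z)
            perm_I[b] = scale * _moran_statistic(zp, W)
        extreme = np.abs(perm_I - expected) >= abs(I_obs - expected) - 1e-14
        p = (1 + int(extreme.sum())) / (n_permutations + 1)
        var = float(perm_I.var(ddof=1))
        zscore = (I_obs - expected) / np.sqrt(var) if var > 0 else np.inf
        return MoranResult(
            I_obs, expected, var, zscore, p, "permutation", n, n_permutations, seed
        )
    raise ValueError(f"unknown method {method!r}")


def zscore(x) -> np.ndarray:
    """Standardize to mean 0 and sample sd 1 (n-1 denominator); NaNs
    propagate without affecting the moments."""
    x = np.asarray(x, dtype=float)
    mask = ~np.isnan(x)
    if mask.sum() < 2 or np.nanstd(x) == 0:
        raise UndefinedStatisticError("zscore undefined for constant input")
    mu = x[mask].mean()
    sd = x[mask].std(ddof=1)
    return (x - mu) / sd


def pearson_r(x, y) -> tuple[float, float]:
    """Product-moment correlation with t-based two-sided p (n-2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    mask = ~(np.isnan(x) | np.isnan(y))
    x, y = x[mask], y[mask]
    if x.size < 3:
        raise UndefinedStatisticError("need at least 3 paired observations")
    if np.var(x) == 0 or np.var(y) == 0:
        raise UndefinedStatisticError("correlation undefined for constant input")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)


def spearman_screen(
    table: pd.DataFrame, threshold: float = 0.90
) -> tuple[pd.DataFrame, list]:
    """Spearman rank correlations with greedy collinearity screening.

    Pairs are scanned in input column order; when |rho| exceeds the
    threshold the *later* column is dropped (order-dependence is inherent to
    the greedy rule). Constant columns have undefined correlations and never
    trigger a drop. Returns the full correlation matrix and a list of
    ``(dropped_column, kept_column, rho)`` records.
    """
    cols = list(table.columns)
    if len(cols) < 2:
        raise ValueError("need at least two variables to screen")
    corr = pd.DataFrame(np.nan, index=cols, columns=cols, dtype=float)
    np.fill_diagonal(corr.values, 1.0)
    for i, a in enumerate(cols):
        for b in cols[i + 1:]:
            pair = table[[a, b]].dropna()
            if len(pair) < 3 or pair[a].nunique() < 2 or pair[b].nunique() < 2:
                continue  # undefined; stays NaN
            rho = sps.spearmanr(pair[a], pair[b]).statistic
            corr.loc[a, b] = corr.loc[b, a] = rho
    dropped: list = []
    alive = set(cols)
    for i, a in enumerate(cols):
        if a not in alive:
            continue
        for b in cols[i + 1:]:
            if b not in alive:
                continue
            rho = corr.loc[a, b]
            if np.isfinite(rho) and abs(rho) > threshold:
                alive.discard(b)
                dropped.append((b, a, float(rho)))
    return corr, dropped


def welch_t(x, y) -> tuple[float, float]:
    """Welch two-sample t-test (unequal variances), two-sided."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    res = sps.ttest_ind(x[~np.isnan(x)], y[~np.isnan(y)], equal_var=False)
    return float(res.statistic), float(res.pvalue)
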