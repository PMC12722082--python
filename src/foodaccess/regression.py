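"""Covariate-adjusted OLS and maximum-likelihood spatial-lag regression.

The spatial lag model (SLR) is

    y = rho * W y + X beta + eps,    eps ~ N(0, sigma^2 I)

with W a row-standardized spatial weights matrix. It is fitted by maximum
likelihood: the log-likelihood is concentrated in rho,

    l(rho) = const - (n/2) log(sigma^2(rho)) + log|I - rho W|,

with sigma^2(rho) = e(rho)'e(rho)/n and e(rho) = e0 - rho*e1 formed from two
auxiliary OLS fits (y on X, and Wy on X). The log-determinant uses the
eigenvalues of W, computed once; rho is optimized on the open interval
(1/lambda_min, 1) by bounded Brent search, then beta and sigma^2 follow in
closed form. Standard errors come from the observed information matrix
(numerical Hessian of the full log-likelihood at the optimum).

Models follow the Model/Results convention: build a model from arrays or a
DataFrame, call ``fit()``, read estimates and diagnostics off the results
object or print ``summary()``. Exposure and covariates are z-scored by
default so coefficients read as outcome change per one standard deviation;
the outcome stays on its natural scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize
from scipy import stats as sps

from .stats import MoranResult, morans_i, zscore
from .weights import SpatialWeights

logger = logging.getLogger(__name__)

DEFAULT_COVARIATES = ("pop_density", "pct_obese", "pct_over65")


class SingularDesignError(ValueError):
    pass


@lru_cache(maxsize=8)
def weights_eigenvalues(weights: SpatialWeights) -> np.ndarray:
    """Eigenvalues of the weights matrix, computed once per weights object
    (cached: the log-determinant term reuses them across repeated fits on
    the same geometry, e.g. in a model battery)."""
    ev = np.linalg.eigvals(weights.dense())
    if np.abs(ev.imag).max() > 1e-8:
        # row-standardized contiguity is similar to a symmetric matrix, so
        # eigenvalues are real up to numerical noise
        logger.warning(
            "discarding imaginary eigenvalue parts (max %.2e)",
            np.abs(ev.imag).max(),
        )
    ev = ev.real
    ev.setflags(write=False)
    return ev


class ConvergenceError(RuntimeError):
    pass


def _check_design(X: np.ndarray, names: Sequence[str]) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # name the columns involved via small QR diagonal entries
        _, R = np.linalg.qr(X)
        diag = np.abs(np.diag(R))
        bad = [names[i] for i in np.where(diag < 1e-8 * diag.max())[0]]
        raise SingularDesignError(
            f"design matrix is rank deficient (rank {rank} of {X.shape[1]}); "
            f"collinear columns: {bad or names}"
        )


def _prepare(
    data: pd.DataFrame,
    outcome: str,
    exposure: str | None,
    covariates: Sequence[str],
    standardize: bool,
):
    cols = [outcome] + ([exposure] if exposure else []) + list(covariates)
    if exposure is not None and exposure in covariates:
        raise ValueError("exposure must not appear among covariates")
    sub = data[cols]
    mask = ~sub.isna().any(axis=1).to_numpy()
    n_dropped = int((~mask).sum())
    if n_dropped:
        logger.info("listwise deletion removed %d row(s)", n_dropped)
    sub = sub.loc[mask]
    y = sub[outcome].to_numpy(dtype=float)
    rhs = [c for c in cols[1:]]
    Xcols = [np.ones(len(sub))]
    for c in rhs:
        v = sub[c].to_numpy(dtype=float)
        Xcols.append(zscore(v) if standardize else v)
    X = np.column_stack(Xcols)
    names = ["intercept"] + rhs
    return y, X, names, mask


@dataclass
class OLSResults:
    """Least-squares estimates with t-based inference and Gaussian
    likelihood quantities for model comparison."""

    params: np.ndarray
    bse: np.ndarray
    names: list
    resid: np.ndarray
    sigma2: float  # ML error variance (RSS/n)
    llf: float
    aic: float
    nobs: int
    df_resid: int

    @property
    def tvalues(self) -> np.ndarray:
        return self.params / self.bse

    @property
    def pvalues(self) -> np.ndarray:
        return 2 * sps.t.sf(np.abs(self.tvalues), self.df_resid)

    def conf_int(self, alpha: float = 0.05) -> np.ndarray:
        q = sps.t.ppf(1 - alpha / 2, self.df_resid)
        return np.column_stack(
            [self.params - q * self.bse, self.params + q * self.bse]
        )

    def to_frame(self) -> pd.DataFrame:
        ci = self.conf_int()
        return pd.DataFrame(
            {
                "coef": self.params,
                "se": self.bse,
                "ci_low": ci[:, 0],
                "ci_high": ci[:, 1],
                "p": self.pvalues,
            },
            index=self.names,
        )

    def summary(self) -> str:
        lines = [
            "Ordinary least squares",
            f"n = {self.nobs}, loglik = {self.llf:.3f}, AIC = {self.aic:.3f}",
            self.to_frame().to_string(float_format=lambda v: f"{v:.4f}"),
        ]
        return "\n".join(lines)


class OLSModel:
    """OLS of an outcome on an exposure plus covariates (intercept always
    included). ``from_dataframe`` z-scores the right-hand side by default."""

    def __init__(self, endog, exog, names: Sequence[str] | None = None):
        self.endog = np.asarray(endog, dtype=float)
        self.exog = np.asarray(exog, dtype=float)
        if self.exog.ndim != 2 or len(self.endog) != self.exog.shape[0]:
            raise ValueError("endog/exog shape mismatch")
        self.names = list(names or [f"x{i}" for i in range(self.exog.shape[1])])
        if self.exog.shape[0] <= self.exog.shape[1]:
            raise ValueError("need more observations than parameters")
        _check_design(self.exog, self.names)

    @classmethod
    def from_dataframe(
        cls,
        data: pd.DataFrame,
        outcome: str,
        exposure: str | None = None,
        covariates: Sequence[str] = DEFAULT_COVARIATES,
        standardize: bool = True,
    ) -> "OLSModel":
        y, X, names, _ = _prepare(data, outcome, exposure, covariates, standardize)
        return cls(y, X, names)

    def fit(self) -> OLSResults:
        y, X = self.endog, self.exog
        n, k = X.shape
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        rss = float(resid @ resid)
        df = n - k
        s2_df = rss / df
        XtX_inv = np.linalg.inv(X.T @ X)
        bse = np.sqrt(np.diag(XtX_inv) * s2_df)
        sigma2_ml = rss / n
        llf = -0.5 * n * (np.log(2 * np.pi * sigma2_ml) + 1)
        aic = 2 * (k + 1) - 2 * llf  # +1 counts the error variance
        return OLSResults(
            params=beta,
            bse=bse,
            names=self.names,
            resid=resid,
            sigma2=sigma2_ml,
            llf=llf,
            aic=aic,
            nobs=n,
            df_resid=df,
        )


def residual_moran(
    resid: np.ndarray,
    weights: SpatialWeights,
    method: str = "permutation",
    n_permutations: int = 999,
    seed: int = 0,
) -> MoranResult:
    """Moran's I of model residuals under the given weights."""
    return morans_i(resid, weights, method, n_permutations, seed)


@dataclass
class SpatialLagResults:
    """ML estimates for the spatial lag model, with Wald inference."""

    rho: float
    rho_se: float
    params: np.ndarray
    bse: np.ndarray
    names: list
    sigma2: float
    llf: float
    aic: float
    nobs: int
    converged: bool
    rho_interval: tuple
    resid: np.ndarray  # eps residuals: y - rho*Wy - X beta

    @property
    def zvalues(self) -> np.ndarray:
        return self.params / self.bse

    @property
    def pvalues(self) -> np.ndarray:
        return 2 * sps.norm.sf(np.abs(self.zvalues))

    @property
    def rho_pvalue(self) -> float:
        return float(2 * sps.norm.sf(abs(self.rho / self.rho_se)))

    def conf_int(self, alpha: float = 0.05) -> np.ndarray:
        q = sps.norm.ppf(1 - alpha / 2)
        return np.column_stack(
            [self.params - q * self.bse, self.params + q * self.bse]
        )

    def residual_moran(self, weights, **kw) -> MoranResult:
        return residual_moran(self.resid, weights, **kw)

    def to_frame(self) -> pd.DataFrame:
        ci = self.conf_int()
        return pd.DataFrame(
            {
                "coef": self.params,
                "se": self.bse,
                "ci_low": ci[:, 0],
                "ci_high": ci[:, 1],
                "p": self.pvalues,
            },
            index=self.names,
        )

    def summary(self) -> str:
        lines = [
            "Spatial lag model (maximum likelihood)",
            f"n = {self.nobs}, rho = {self.rho:.4f} "
            f"(se {self.rho_se:.4f}, p {self.rho_pvalue:.4g})",
            f"loglik = {self.llf:.3f}, AIC = {self.aic:.3f}",
            self.to_frame().to_string(float_format=lambda v: f"{v:.4f}"),
        ]
        return "\n".join(lines)


class SpatialLagModel:
    """Spatial lag regression fitted by maximum likelihood over a
    row-standardized weights matrix (no islands permitted)."""

    def __init__(self, endog, exog, weights: SpatialWeights,
                 names: Sequence[str] | None = None):
        self.endog = np.asarray(endog, dtype=float)
        self.exog = np.asarray(exog, dtype=float)
        self.names = list(names or [f"x{i}" for i in range(self.exog.shape[1])])
        if weights.n != len(self.endog):
            raise ValueError("weights not aligned with data")
        if any(len(nb) == 0 for nb in weights.neighbors):
            raise ValueError(
                "weights contain island units; subset the data to connected "
                "units before fitting"
            )
        if weights.style != "row_standardized":
            weights = weights.row_standardize()
        self.weights = weights
        _check_design(self.exog, self.names)

    @classmethod
    def from_dataframe(
        cls,
        data: pd.DataFrame,
        outcome: str,
        weights: SpatialWeights,
        exposure: str | None = None,
        covariates: Sequence[str] = DEFAULT_COVARIATES,
        standardize: bool = True,
    ) -> "SpatialLagModel":
        y, X, names, mask = _prepare(
            data, outcome, exposure, covariates, standardize
        )
        if not mask.all():
            weights = weights.subset(mask)
        return cls(y, X, weights, names)

    # -- likelihood pieces -------------------------------------------------
    def _eigs(self) -> np.ndarray:
        return weights_eigenvalues(self.weights)

    def loglike(self, beta: np.ndarray, rho: float, sigma2: float,
                eigs: np.ndarray | None = None) -> float:
        """Full log-likelihood at (beta, rho, sigma2)."""
        eigs = self._eigs() if eigs is None else eigs
        n = len(self.endog)
        Wy = self.weights.sparse() @ self.endog
        e = self.endog - rho * Wy - self.exog @ beta
        terms = 1.0 - rho * eigs
        if np.any(terms <= 0):
            return -np.inf
        return float(
            -0.5 * n * np.log(2 * np.pi * sigma2)
            - (e @ e) / (2 * sigma2)
            + np.log(terms).sum()
        )

    def concentrated_loglike(self, rho: float) -> float:
        if not hasattr(self, "_parts"):
            self._parts = self._concentration_parts()
        e0, e1, eigs = self._parts
        n = len(self.endog)
        e = e0 - rho * e1
        s2 = float(e @ e) / n
        terms = 1.0 - rho * eigs
        if np.any(terms <= 0) or s2 <= 0:
            return -np.inf
        return float(
            -0.5 * n * (np.log(2 * np.pi * s2) + 1) + np.log(terms).sum()
        )

    def _concentration_parts(self):
        X, y = self.exog, self.endog
        Wy = self.weights.sparse() @ y
        b0, *_ = np.linalg.lstsq(X, y, rcond=None)
        b1, *_ = np.linalg.lstsq(X, Wy, rcond=None)
        return y - X @ b0, Wy - X @ b1, self._eigs()

    def fit(self, rho_tol: float = 1e-8) -> SpatialLagResults:
        X, y = self.exog, self.endog
        n, k = X.shape
        Wy = self.weights.sparse() @ y
        if not hasattr(self, "_parts"):
            self._parts = self._concentration_parts()
        e0, e1, eigs = self._parts
        lam_min = eigs.min()
        lo = 1.0 / lam_min if lam_min < 0 else -1.0 + 1e-9
        bound = (lo + 1e-9, 1.0 - 1e-9)

        def neg_cll(rho):
            e = e0 - rho * e1
            s2 = float(e @ e) / n
            terms = 1.0 - rho * eigs
            if np.any(terms <= 0) or s2 <= 0:
                return np.inf
            return 0.5 * n * (np.log(2 * np.pi * s2) + 1) - np.log(terms).sum()

        res = optimize.minimize_scalar(
            neg_cll, bounds=bound, method="bounded",
            options={"xatol": rho_tol},
        )
        if not res.success:
            raise ConvergenceError(
                f"rho optimization failed: {res.message}; "
                f"f({res.x})={res.fun}"
            )
        rho = float(res.x)
        b0, *_ = np.linalg.lstsq(X, y, rcond=None)
        b1, *_ = np.linalg.lstsq(X, Wy, rcond=None)
        beta = b0 - rho * b1
        e = y - rho * Wy - X @ beta
        sigma2 = float(e @ e) / n
        llf = self.loglike(beta, rho, sigma2, eigs)
        aic = 2 * (k + 2) - 2 * llf  # + rho + sigma^2

        # observed information: numerical Hessian of -loglik at the optimum
        theta = np.concatenate([beta, [rho, sigma2]])

        def nll(t):
            return -self.loglike(t[:k], t[k], t[k + 1], eigs)

        H = _numeric_hessian(nll, theta)
        try:
            cov = np.linalg.inv(H)
        except np.linalg.LinAlgError as exc:  # pragma: no cover
            raise ConvergenceError(f"singular information matrix: {exc}")
        diag = np.diag(cov)
        if np.any(diag[: k + 1] <= 0):
            raise ConvergenceError(
                "non-positive variance estimates from the information matrix"
            )
        se = np.sqrt(diag)
        return SpatialLagResults(
            rho=rho,
            rho_se=float(se[k]),
            params=beta,
            bse=se[:k],
            names=self.names,
            sigma2=sigma2,
            llf=llf,
            aic=aic,
            nobs=n,
            converged=bool(res.success),
            rho_interval=bound,
            resid=e,
        )


def _numeric_hessian(f, x0: np.ndarray) -> np.ndarray:
    """Central-difference Hessian with per-coordinate step
    1e-5 * max(1, |x_i|)."""
    p = len(x0)
    h = 1e-5 * np.maximum(1.0, np.abs(x0))
    H = np.empty((p, p))
    for i in range(p):
        for j in range(i, p):
            if i == j:
                xp, xm = x0.copy(), x0.copy()
                xp[i] += h[i]
                xm[i] -= h[i]
                H[i, i] = (f(xp) - 2 * f(x0) + f(xm)) / h[i] ** 2
            else:
                xpp, xpm, xmp, xmm = (x0.copy() for _ in range(4))
                xpp[[i, j]] += [h[i], h[j]]
                xpm[i] += h[i]
                xpm[j] -= h[j]
                xmp[i] -= h[i]
                xmp[j] += h[j]
                xmm[[i, j]] -= [h[i], h[j]]
                H[i, j] = H[j, i] = (
                    f(xpp) - f(xpm) - f(xmp) + f(xmm)
                ) / (4 * h[i] * h[j])
    return H


def run_model_battery(
    data: pd.DataFrame,
    exposures: Sequence[str],
    outcome: str,
    weights: SpatialWeights,
    covariates: Sequence[str] = DEFAULT_COVARIATES,
    knn_weights_obj: SpatialWeights | None = None,
    moran_method: str = "permutation",
    n_permutations: int = 999,
    seed: int = 0,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """One OLS and one SLR per exposure, with residual spatial diagnostics.

    Returns a table with, per exposure, the OLS coefficient / 95% CI / p,
    residual Moran's I and p under the queen weights (and kNN weights when
    supplied), and the SLR coefficient, p, rho, AIC and log-likelihood,
    sorted with the AIC-best SLR first. A failing exposure contributes an
    error row instead of aborting the battery.
    """
    rows = []
    for ex in exposures:
        row: dict = {"exposure": ex}
        try:
            ols = OLSModel.from_dataframe(
                data, outcome, ex, covariates
            ).fit()
            i_ex = ols.names.index(ex)
            ci = ols.conf_int()
            row.update(
                ols_coef=ols.params[i_ex],
                ols_ci_low=ci[i_ex, 0],
                ols_ci_high=ci[i_ex, 1],
                ols_p=ols.pvalues[i_ex],
                ols_aic=ols.aic,
            )
            sub_mask = ~data[[outcome, ex, *covariates]].isna().any(axis=1)
            w_sub = weights.subset(sub_mask.to_numpy()) if not sub_mask.all() else weights
            mq = residual_moran(
                ols.resid, w_sub, moran_method, n_permutations, seed
            )
            row.update(resid_moran_queen_I=mq.I, resid_moran_queen_p=mq.p_value)
            if knn_weights_obj is not None:
                w_knn = (
                    knn_weights_obj.subset(sub_mask.to_numpy())
                    if not sub_mask.all()
                    else knn_weights_obj
                )
                mk = residual_moran(
                    ols.resid, w_knn, moran_method, n_permutations, seed
                )
                row.update(resid_moran_knn_I=mk.I, resid_moran_knn_p=mk.p_value)
            row["resid_dependence"] = row["resid_moran_queen_p"] < alpha
            slr = SpatialLagModel.from_dataframe(
                data, outcome, weights, ex, covariates
            ).fit()
            j_ex = slr.names.index(ex)
            row.update(
                slr_coef=slr.params[j_ex],
                slr_p=slr.pvalues[j_ex],
                rho=slr.rho,
                rho_p=slr.rho_pvalue,
                slr_aic=slr.aic,
                slr_loglik=slr.llf,
            )
        except Exception as exc:  # keep the battery going
            row["error"] = f"{type(exc).__name__}: {exc}"
            logger.warning("exposure %s failed: %s", ex, exc)
        rows.append(row)
    report = pd.DataFrame(rows)
    if "slr_aic" in report:
        report = report.sort_values(
            "slr_aic", na_position="last", kind="mergesort"
        ).reset_index(drop=True)
    return report
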