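"""OLS and spatial-lag regression: oracles, reduction properties,
inference calibration and the model battery."""

import numpy as np
import pandas as pd
import pytest

from foodaccess.config import CountyConfig
from foodaccess.regression import (
    OLSModel,
    SingularDesignError,
    SpatialLagModel,
    residual_moran,
    run_model_battery,
)
from foodaccess.stats import morans_i
from foodaccess.synthetic import generate_cases, generate_tracts
from foodaccess.weights import queen_weights
from conftest import make_grid_tracts


def _grid_weights(n_rows, n_cols):
    t = make_grid_tracts(n_rows, n_cols, side=1000.0)
    return queen_weights(t["tract_id"], t["geometry"]).row_standardize()


class TestOLS:
    def test_exact_linear_data_interpolated(self):
        x = np.arange(10.0)
        y = 1 + 2 * x
        m = OLSModel(y, np.column_stack([np.ones(10), x]), ["intercept", "x"])
        r = m.fit()
        np.testing.assert_allclose(r.params, [1.0, 2.0], atol=1e-12)
        np.testing.assert_allclose(r.resid, 0.0, atol=1e-10)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(5)
        X = np.column_stack([np.ones(80), rng.normal(size=(80, 3))])
        y = rng.normal(size=80)
        r = OLSModel(y, X).fit()
        beta_oracle = np.linalg.solve(X.T @ X, X.T @ y)
        np.testing.assert_allclose(r.params, beta_oracle, atol=1e-10)

    def test_matches_statsmodels(self):
        sm = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(8)
        X = np.column_stack([np.ones(60), rng.normal(size=(60, 2))])
        y = X @ [1.0, 0.5, -2.0] + rng.normal(size=60)
        ours = OLSModel(y, X).fit()
        ref = sm.OLS(y, X).fit()
        np.testing.assert_allclose(ours.params, ref.params, atol=1e-10)
        np.testing.assert_allclose(ours.bse, ref.bse, atol=1e-10)
        np.testing.assert_allclose(ours.pvalues, ref.pvalues, atol=1e-10)
        np.testing.assert_allclose(ours.llf, ref.llf, atol=1e-8)

    def test_rank_deficiency_names_columns(self):
        x = np.arange(12.0)
        X = np.column_stack([np.ones(12), x, 2 * x])
        with pytest.raises(SingularDesignError, match="x2"):
            OLSModel(np.zeros(12), X)

    def test_standardized_exposure_coefficient_invariance(self, small_county):
        """Rescaling the exposure changes the raw coefficient but not the
        standardized (per-sd) one."""
        df = small_county.tracts.drop(columns="geometry").copy()
        rng = np.random.default_rng(0)
        df["exposure"] = rng.normal(size=len(df))
        df["outcome"] = 2.0 * df["exposure"] + rng.normal(size=len(df))
        r1 = OLSModel.from_dataframe(
            df, "outcome", "exposure", ["pct_obese"], standardize=True
        ).fit()
        df2 = df.assign(exposure=df["exposure"] * 10)
        r2 = OLSModel.from_dataframe(
            df2, "outcome", "exposure", ["pct_obese"], standardize=True
        ).fit()
        i = r1.names.index("exposure")
        assert r1.params[i] == pytest.approx(r2.params[i], rel=1e-10)
        raw1 = OLSModel.from_dataframe(
            df, "outcome", "exposure", ["pct_obese"], standardize=False
        ).fit()
        raw2 = OLSModel.from_dataframe(
            df2, "outcome", "exposure", ["pct_obese"], standardize=False
        ).fit()
        assert raw1.params[i] == pytest.approx(10 * raw2.params[i], rel=1e-8)


class TestResidualMoran:
    def test_delegates_to_morans_i(self, small_county):
        df = small_county.tracts.drop(columns="geometry").merge(
            small_county.cases.true_rates, on="tract_id"
        )
        r = OLSModel.from_dataframe(
            df, "true_rate", covariates=("pop_density", "pct_obese")
        ).fit()
        w = small_county.weights
        a = residual_moran(r.resid, w, "permutation", 99, seed=3)
        b = morans_i(r.resid, w, "permutation", 99, seed=3)
        assert a.I == b.I and a.p_value == b.p_value

    def test_power_under_strong_lag(self):
        """OLS residuals from a rho=0.7 process show dependence at n=225."""
        w = _grid_weights(15, 15)
        hits = 0
        n_seeds = 100
        for seed in range(n_seeds):
            cfg = CountyConfig(
                seed=seed, n_rows=15, n_cols=15, sra_block=5, true_rho=0.7
            )
            tr = generate_tracts(cfg)
            cases = generate_cases(cfg, tr, w)
            df = tr.drop(columns="geometry").merge(
                cases.true_rates, on="tract_id"
            )
            ols = OLSModel.from_dataframe(
                df, "true_rate", covariates=cfg.covariate_cols
            ).fit()
            if residual_moran(ols.resid, w, method="normal").p_value < 0.01:
                hits += 1
        assert hits >= 0.95 * n_seeds


class TestSLR:
    def test_rho_zero_data_recovers_ols(self):
        """With true rho=0 the SLR stays near 0 and beta tracks OLS."""
        w = _grid_weights(20, 20)
        rhos, beta_gaps = [], []
        for seed in range(20):
            cfg = CountyConfig(
                seed=seed, n_rows=20, n_cols=20, sra_block=5, true_rho=0.0
            )
            tr = generate_tracts(cfg)
            cases = generate_cases(cfg, tr, w)
            df = tr.drop(columns="geometry").merge(
                cases.true_rates, on="tract_id"
            )
            slr = SpatialLagModel.from_dataframe(
                df, "true_rate", w, covariates=cfg.covariate_cols
            ).fit()
            ols = OLSModel.from_dataframe(
                df, "true_rate", covariates=cfg.covariate_cols
            ).fit()
            rhos.append(slr.rho)
            beta_gaps.append(
                np.abs(
                    (slr.params[1:] - ols.params[1:]) / ols.params[1:]
                ).max()
            )
        assert abs(np.median(rhos)) < 0.05
        assert np.median(beta_gaps) < 0.05  # within 5% of the OLS estimates

    def test_brent_matches_grid_search_oracle(self, small_county):
        df = small_county.tracts.drop(columns="geometry").merge(
            small_county.cases.true_rates, on="tract_id"
        )
        model = SpatialLagModel.from_dataframe(
            df, "true_rate", small_county.weights,
            covariates=small_county.config.covariate_cols,
        )
        res = model.fit()
        lo, hi = res.rho_interval
        grid = np.arange(lo + 1e-4, hi, 1e-4)
        lls = np.array([model.concentrated_loglike(r) for r in grid])
        rho_grid = grid[np.argmax(lls)]
        assert res.rho == pytest.approx(rho_grid, abs=1e-3)

    def test_loglik_dominates_ols(self, small_county):
        """l(rho_hat) >= l(0), which equals the OLS Gaussian loglik."""
        df = small_county.tracts.drop(columns="geometry").merge(
            small_county.cases.true_rates, on="tract_id"
        )
        model = SpatialLagModel.from_dataframe(
            df, "true_rate", small_county.weights,
            covariates=small_county.config.covariate_cols,
        )
        slr = model.fit()
        ols = OLSModel.from_dataframe(
            df, "true_rate", covariates=small_county.config.covariate_cols
        ).fit()
        assert slr.llf >= ols.llf - 1e-9
        assert model.concentrated_loglike(0.0) == pytest.approx(ols.llf, abs=1e-8)

    def test_rho_strictly_inside_interval(self, small_county):
        df = small_county.tracts.drop(columns="geometry").merge(
            small_county.cases.true_rates, on="tract_id"
        )
        r = SpatialLagModel.from_dataframe(
            df, "true_rate", small_county.weights,
            covariates=small_county.config.covariate_cols,
        ).fit()
        lo, hi = r.rho_interval
        assert lo < r.rho < hi

    def test_aic_convention(self, small_county):
        df = small_county.tracts.drop(columns="geometry").merge(
            small_county.cases.true_rates, on="tract_id"
        )
        r = SpatialLagModel.from_dataframe(
            df, "true_rate", small_county.weights,
            covariates=small_county.config.covariate_cols,
        ).fit()
        k = len(r.params)
        assert r.aic == pytest.approx(2 * (k + 2) - 2 * r.llf)

    def test_island_weights_rejected(self):
        from foodaccess.weights import SpatialWeights

        w = SpatialWeights(
            ids=("a", "b", "c"),
            neighbors=((1,), (0,), ()),
            values=((1.0,), (1.0,), ()),
            scheme="custom",
        ).row_standardize()
        with pytest.raises(ValueError, match="island"):
            SpatialLagModel(np.zeros(3), np.ones((3, 1)), w)


class TestBattery:
    def _planted_county(self, seed):
        """County whose rate process includes a true negative effect of one
        access measure (AAPI restaurants per AAPI)."""
        from foodaccess.classify import Lexicon, classify_outlets
        from foodaccess.measures import access_measure_table
        from foodaccess.synthetic import (
            generate_county,
            generate_cases,
        )

        cfg = CountyConfig(seed=seed, n_rows=12, n_cols=12, sra_block=4)
        county = generate_county(cfg)
        classified, _ = classify_outlets(
            county.outlets, Lexicon.default(), county.resolutions
        )
        measures = access_measure_table(
            classified, county.tracts, county.pop_points, county.supermarkets
        )
        df = county.tracts.drop(columns="geometry").merge(
            measures, on="tract_id"
        )
        from foodaccess.measures import MEASURE_COLUMNS

        df = df.fillna({c: 0.0 for c in MEASURE_COLUMNS})
        cases = generate_cases(
            cfg,
            df,
            county.weights,
            covariate_cols=list(cfg.covariate_cols) + ["rest_per_aapi"],
            true_beta=list(cfg.true_beta) + [-30.0],
        )
        df = df.merge(cases.true_rates, on="tract_id")
        return df, county.weights

    def test_battery_shape_and_planted_signal(self):
        exposures = [
            "fara_aapi", "rest_ratio", "rest_per_aapi",
            "groc_ratio", "groc_per_aapi", "groc_intensity",
        ]
        wins = 0
        n_seeds = 50
        for seed in range(n_seeds):
            df, w = self._planted_county(seed)
            report = run_model_battery(
                df, exposures, "true_rate", w,
                moran_method="normal", seed=seed,
            )
            assert len(report) == len(exposures)  # 6 OLS + 6 SLR rows
            ok = report[report.get("error").isna()] if "error" in report else report
            if ok.iloc[0]["exposure"] == "rest_per_aapi":
                wins += 1
        assert wins >= 0.80 * n_seeds

    def test_report_deterministic(self, small_county):
        df = small_county.tracts.drop(columns="geometry").merge(
            small_county.cases.true_rates, on="tract_id"
        )
        kw = dict(
            data=df, exposures=["pct_below_200fpl"], outcome="true_rate",
            weights=small_county.weights, moran_method="permutation",
            n_permutations=99, seed=17,
        )
        a = run_model_battery(**kw)
        b = run_model_battery(**kw)
        pd.testing.assert_frame_equal(a, b)

    def test_failing_exposure_reported_not_fatal(self, small_county):
        df = small_county.tracts.drop(columns="geometry").merge(
            small_county.cases.true_rates, on="tract_id"
        )
        df["all_nan"] = np.nan
        report = run_model_battery(
            df, ["pct_below_200fpl", "all_nan"], "true_rate",
            small_county.weights, moran_method="normal",
        )
        assert len(report) == 2
        bad = report.loc[report["exposure"] == "all_nan"].iloc[0]
        assert isinstance(bad["error"], str)
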