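"""Density surface model: VIF screening, GAM fitting, prediction, CVs,
and the coverage-normalised fallback."""

import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest

from seasens import dsm, geo_io


@pytest.fixture(scope="module")
def flat_grid():
    return geo_io.grid_to_frame(
        geo_io.make_grid((0, 0, 30000, 30000), 3000, None))


def _constant_segments(n=200, density=5.0, seed=0, area=0.9):
    rng = np.random.default_rng(seed)
    x = rng.uniform(0, 30000, n)
    y = rng.uniform(0, 30000, n)
    counts = rng.poisson(density * area, n).astype(float)
    return pd.DataFrame({"x": x, "y": y, "n_hat": counts,
                         "covered_area_km2": area,
                         "cdist_km": x / 1000.0})


class TestVIF:
    def test_orthogonal_pair(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame({"a": rng.normal(size=500)})
        df["b"] = rng.normal(size=500)
        vifs = dsm.compute_vif(df)
        assert vifs["a"] == pytest.approx(1.0, abs=0.05)
        assert vifs["b"] == pytest.approx(1.0, abs=0.05)

    def test_perfect_collinearity_sentinel(self):
        x = np.arange(50, dtype=float)
        df = pd.DataFrame({"a": x, "b": 2 * x})
        vifs = dsm.compute_vif(df)
        assert np.isinf(vifs["a"]) and np.isinf(vifs["b"])

    def test_r09_closed_form(self):
        # correlation r ⇒ VIF = 1/(1−r²); r=0.9 ⇒ 5.26
        rng = np.random.default_rng(3)
        n = 200000
        a = rng.normal(size=n)
        b = 0.9 * a + np.sqrt(1 - 0.81) * rng.normal(size=n)
        vifs = dsm.compute_vif(pd.DataFrame({"a": a, "b": b}))
        assert vifs["a"] == pytest.approx(1 / (1 - 0.81), rel=0.02)

    def test_choose_covariates_prefers_higher_power(self):
        rng = np.random.default_rng(4)
        depth = rng.normal(size=300)
        cdist = depth + 0.1 * rng.normal(size=300)   # heavily confounded
        df = pd.DataFrame({"depth": depth, "cdist": cdist})
        kept = dsm.choose_covariates(df, {"depth": 0.2, "cdist": 0.4})
        assert kept == ["cdist"]

    def test_choose_covariates_keeps_all_below_threshold(self):
        rng = np.random.default_rng(5)
        df = pd.DataFrame(rng.normal(size=(300, 3)), columns=list("abc"))
        assert dsm.choose_covariates(df, {}) == ["a", "b", "c"]

    def test_three_way_greedy_matches_oracle(self):
        rng = np.random.default_rng(6)
        a = rng.normal(size=400)
        b = a + 0.05 * rng.normal(size=400)
        c = a + b + 0.05 * rng.normal(size=400)
        df = pd.DataFrame({"a": a, "b": b, "c": c})
        power = {"a": 0.5, "b": 0.3, "c": 0.1}
        kept = dsm.choose_covariates(df, power)
        # oracle: drop lowest-power offender repeatedly
        names = ["a", "b", "c"]
        while len(names) >= 2:
            vifs = dsm.compute_vif(df[names])
            off = [n for n in names if vifs[n] > 5.0]
            if not off:
                break
            names.remove(min(off, key=lambda n: power[n]))
        assert kept == names


class TestFit:
    def test_constant_truth_recovery(self, flat_grid):
        seg = _constant_segments(seed=7)
        model = dsm.fit_dsm(seg, smooths=[dsm.SmoothSpec(("x", "y"), 30)],
                            domain={"x": (0, 30000), "y": (0, 30000)})
        surf = dsm.predict_grid(model, flat_grid)
        d = surf.table["density"]
        assert d.mean() == pytest.approx(5.0, rel=0.15)
        # smoothness: residual spatial wiggle stays within the REML
        # optimum's band (cross-checked against mgcv on identical data)
        assert d.min() > 3.0 and d.max() < 8.0

    def test_all_zero_response(self, flat_grid):
        seg = _constant_segments(seed=8)
        seg["n_hat"] = 0.0
        model = dsm.fit_dsm(seg, smooths=[dsm.SmoothSpec(("x", "y"), 30)],
                            profile_theta=False, theta=1.0)
        surf = dsm.predict_grid(model, flat_grid)
        assert np.nanmax(surf.table["density"]) < 1e-4

    def test_poisson_limit_sum_balance(self):
        # with θ → large the NB score equation forces Σ fitted = Σ observed
        seg = _constant_segments(seed=9)
        model = dsm.fit_dsm(seg, smooths=[dsm.SmoothSpec(("x", "y"), 30)],
                            profile_theta=False, theta=1e6)
        mu = np.exp(model.linear_predictor(seg)
                    + np.log(seg["covered_area_km2"]))
        assert mu.sum() == pytest.approx(seg["n_hat"].sum(), rel=0.005)

    def test_translation_invariance(self, flat_grid):
        seg = _constant_segments(seed=10, n=150)
        shift = 250000.0
        seg2 = seg.copy()
        seg2["x"] += shift
        m1 = dsm.fit_dsm(seg, smooths=[dsm.SmoothSpec(("x", "y"), 30)],
                         profile_theta=False, theta=5.0)
        m2 = dsm.fit_dsm(seg2, smooths=[dsm.SmoothSpec(("x", "y"), 30)],
                         profile_theta=False, theta=5.0)
        g2 = flat_grid.copy()
        g2["x"] += shift
        p1 = dsm.predict_grid(m1, flat_grid).table["density"]
        p2 = dsm.predict_grid(m2, g2).table["density"]
        np.testing.assert_allclose(p1, p2, rtol=1e-6)

    def test_roughness_decreases_on_lambda_ladder(self):
        # drive the smooth toward its null space by raising λ directly
        seg = _constant_segments(seed=11)
        from seasens.dsm import (NegativeBinomial, _assemble_penalties,
                                 _build_term, _pirls, SmoothSpec)
        shifts = {"x": seg["x"].mean(), "y": seg["y"].mean()}
        term = _build_term(SmoothSpec(("x", "y"), 30), seg, shifts,
                           None, select=False)
        S_list, p = _assemble_penalties([term])
        X = np.hstack([np.ones((len(seg), 1)), term.design(seg, shifts)])
        y = seg["n_hat"].to_numpy()
        off = np.log(seg["covered_area_km2"].to_numpy())
        fam = NegativeBinomial(10.0)
        rough = []
        for lam in (1e-2, 1e0, 1e2, 1e4, 1e6):
            beta, *_ = _pirls(X, y, off, fam, S_list,
                              np.full(len(S_list), lam))
            eta = X @ beta
            rough.append(np.var(eta))
        assert all(a >= b - 1e-10 for a, b in zip(rough, rough[1:]))

    def test_tweedie_family_fits(self, flat_grid):
        seg = _constant_segments(seed=12)
        model = dsm.fit_dsm(seg, family="tweedie",
                            smooths=[dsm.SmoothSpec(("x", "y"), 30)])
        surf = dsm.predict_grid(model, flat_grid)
        assert np.nanmean(surf.table["density"]) == pytest.approx(5.0,
                                                                  rel=0.2)

    def test_negative_response_rejected(self):
        seg = _constant_segments(seed=13)
        seg.loc[0, "n_hat"] = -1.0
        with pytest.raises(ValueError):
            dsm.fit_dsm(seg, smooths=[dsm.SmoothSpec(("x", "y"), 30)])


class TestPrediction:
    def test_intercept_only_closed_form(self, flat_grid):
        model = dsm.DensityModel(
            terms=[], beta=np.array([np.log(5.0)]), Vb=np.zeros((1, 1)),
            lambdas=np.array([]), family=dsm.NegativeBinomial(1.0),
            scale=1.0, shifts={}, region="main", deviance=0.0,
            null_deviance=0.0, edf=1.0, reml=0.0)
        surf = dsm.predict_grid(model, flat_grid)
        np.testing.assert_allclose(surf.table["density"], 5.0)

    def test_coastal_cell_abundance_scales_with_area(self, flat_grid):
        g = flat_grid.copy()
        g.loc[0, "area_km2"] = 4.5
        model = dsm.DensityModel(
            terms=[], beta=np.array([np.log(2.0)]), Vb=np.zeros((1, 1)),
            lambdas=np.array([]), family=dsm.NegativeBinomial(1.0),
            scale=1.0, shifts={}, region="main", deviance=0.0,
            null_deviance=0.0, edf=1.0, reml=0.0)
        surf = dsm.predict_grid(model, g)
        assert surf.table.loc[0, "abundance"] == pytest.approx(2.0 * 4.5)

    def test_land_cells_are_missing_not_zero(self):
        from shapely.geometry import Polygon
        land = Polygon([(-10000, -10000), (4000, -10000), (4000, 40000),
                        (-10000, 40000)])
        grid = geo_io.grid_to_frame(
            geo_io.make_grid((0, 0, 30000, 30000), 3000, land))
        seg = _constant_segments(seed=14)
        seg = seg[seg["x"] > 5000]
        model = dsm.fit_dsm(seg, smooths=[dsm.SmoothSpec(("x", "y"), 30)],
                            profile_theta=False, theta=5.0)
        surf = dsm.predict_grid(model, grid)
        land_rows = ~grid["is_sea"]
        assert land_rows.any()
        assert surf.table.loc[land_rows, "density"].isna().all()


class TestCellCV:
    def _intercept_model(self, var=0.04):
        return dsm.DensityModel(
            terms=[], beta=np.array([np.log(5.0)]),
            Vb=np.array([[var]]), lambdas=np.array([]),
            family=dsm.NegativeBinomial(1.0), scale=1.0, shifts={},
            region="main", deviance=0.0, null_deviance=0.0, edf=1.0,
            reml=0.0)

    def test_deterministic_model_zero_cv(self, flat_grid):
        model = self._intercept_model(var=0.0)
        cv = dsm.cell_cv(model, flat_grid, detection_cv=0.0, n_draws=100)
        np.testing.assert_allclose(cv, 0.0)

    def test_three_four_five_combination(self, flat_grid):
        model = self._intercept_model(var=0.0)
        # CV_gam = 0 here, so feed cv_gam=0.3 analytically via detection 0.4:
        cv = dsm.cell_cv(model, flat_grid, detection_cv=0.4, n_draws=10)
        np.testing.assert_allclose(cv, 0.4)
        # and the quadrature rule itself:
        assert np.hypot(0.3, 0.4) == pytest.approx(0.5)

    def test_draws_match_analytic_lognormal_cv(self, flat_grid):
        # intercept-only: density is lognormal, CV = sqrt(exp(v) − 1)
        v = 0.04
        model = self._intercept_model(var=v)
        cv = dsm.cell_cv(model, flat_grid, detection_cv=0.0, n_draws=2000,
                         seed=5)
        analytic = np.sqrt(np.exp(v) - 1.0)
        assert np.nanmedian(cv) == pytest.approx(analytic, rel=0.10)


class TestFallback:
    def test_single_segment_arithmetic(self, flat_grid):
        seg = pd.DataFrame({"x": [1500.0], "y": [1500.0], "n_hat": [20.0],
                            "covered_area_km2": [0.6]})
        surf = dsm.relative_density_fallback(seg, flat_grid)
        t = surf.table.set_index("cell_id")
        assert t.loc[0, "density"] == pytest.approx(20.0 / 0.6)

    def test_no_effort_cells_missing(self, flat_grid):
        seg = pd.DataFrame({"x": [1500.0], "y": [1500.0], "n_hat": [5.0],
                            "covered_area_km2": [0.9]})
        surf = dsm.relative_density_fallback(seg, flat_grid)
        assert surf.table["density"].isna().sum() == len(flat_grid) - 1

    def test_uniform_simulation_recovery(self, flat_grid):
        from seasens import detection, synthetic as syn
        from seasens.pipeline import corrected_segment_abundance
        truth = syn.make_truth(flat_grid, base=10.0, frac_flying=0.0)
        scen = syn.ScenarioConfig(seed=19, transect_spacing_m=1500,
                                  sigma_m=120.0)
        segs, obs = syn.simulate_survey(truth, scen)
        m = detection.fit_best(
            distances=obs["perp_distance_m"].dropna().to_numpy(), w=300.0)
        seg = corrected_segment_abundance(segs, obs, m)
        surf = dsm.relative_density_fallback(seg, flat_grid)
        d = surf.table["density"].dropna()
        se = d.std() / np.sqrt(len(d))
        assert abs(d.mean() - 10.0) < 3 * max(se, 0.3)


@pytest.mark.skipif(shutil.which("Rscript") is None,
                    reason="Rscript not available")
def test_fit_agrees_with_mgcv_oracle(tmp_path):
    """Dual-route check: our penalized-REML GAM vs mgcv on identical data."""
    rng = np.random.default_rng(21)
    n = 250
    x = rng.uniform(0, 10, n)
    mu = np.exp(1.0 + 0.8 * np.sin(x))
    y = rng.poisson(mu).astype(float)
    seg = pd.DataFrame({"x": x * 3000, "y": np.zeros(n), "n_hat": y,
                        "covered_area_km2": 1.0, "cdist_km": x})
    model = dsm.fit_dsm(seg, smooths=[dsm.SmoothSpec(("cdist_km",), 10)],
                        profile_theta=False, theta=1e6, select=False)
    fitted = np.exp(model.linear_predictor(seg))
    df = pd.DataFrame({"x": x, "y": y})
    df.to_csv(tmp_path / "d.csv", index=False)
    rcode = f"""
    suppressMessages(library(mgcv))
    d <- read.csv("{tmp_path}/d.csv")
    m <- gam(y ~ s(x, bs="ps", k=10), family=poisson, data=d, method="REML")
    write.csv(data.frame(mu=fitted(m)), "{tmp_path}/fit.csv", row.names=FALSE)
    """
    subprocess.run(["Rscript", "-e", rcode], check=True, capture_output=True)
    ref = pd.read_csv(tmp_path / "fit.csv")["mu"].to_numpy()
    assert np.corrcoef(fitted, ref)[0, 1] > 0.99
    assert np.mean(np.abs(fitted - ref) / ref) < 0.05


def test_peninsula_far_side_flagged_extrapolated():
    """Cells beyond a land barrier from all effort must be flagged as
    extrapolated, not confidently predicted."""
    from shapely.geometry import Polygon
    # peninsula jutting east across the middle of the area
    land = Polygon([(0, 13000), (20000, 13000), (20000, 17000), (0, 17000)])
    grid = geo_io.grid_to_frame(
        geo_io.make_grid((0, 0, 30000, 30000), 3000, land))
    seg = _constant_segments(seed=15)
    seg = seg[seg["y"] < 12000]            # effort south of the peninsula only
    model = dsm.fit_dsm(seg, smooths=[dsm.SmoothSpec(("x", "y"), 30)],
                        profile_theta=False, theta=5.0)
    surf = dsm.predict_grid(model, grid)
    north = (grid["y"] > 18000) & grid["is_sea"] & (grid["x"] < 18000)
    assert north.any()
    assert surf.table.loc[north, "extrapolated"].all()


def test_two_region_models_fit_independently(flat_grid):
    """A small region fitted separately shows higher posterior CVs than the
    large region, mirroring geographic model separation."""
    rng = np.random.default_rng(30)
    def region_segments(n, x0, x1):
        x = rng.uniform(x0, x1, n)
        y = rng.uniform(0, 30000, n)
        return pd.DataFrame({"x": x, "y": y,
                             "n_hat": rng.poisson(4.5, n).astype(float),
                             "covered_area_km2": 0.9})
    big = region_segments(260, 0, 30000)
    small = region_segments(35, 0, 30000)
    m_big = dsm.fit_dsm(big, smooths=[dsm.SmoothSpec(("x", "y"), 30)],
                        profile_theta=False, theta=5.0, region="main")
    m_small = dsm.fit_dsm(small, smooths=[dsm.SmoothSpec(("x", "y"), 30)],
                          profile_theta=False, theta=5.0, region="bay")
    assert m_big.region == "main" and m_small.region == "bay"
    cv_big = dsm.cell_cv(m_big, flat_grid, n_draws=300, seed=1)
    cv_small = dsm.cell_cv(m_small, flat_grid, n_draws=300, seed=1)
    assert np.nanmedian(cv_small) > np.nanmedian(cv_big)
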