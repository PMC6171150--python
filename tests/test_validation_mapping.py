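import numpy as np
import pandas as pd
import pytest
from scipy.stats import rankdata, spearmanr

from ptarmigan_rsf import covariates as cov
from ptarmigan_rsf import synthetic as syn
from ptarmigan_rsf.rasters import Grid, LandscapeStack
from ptarmigan_rsf.rsf import BinAssignment, ModelSpec, quantile_bin
from ptarmigan_rsf.validation import (
    BinnedMap,
    area_adjusted_validation,
    cv_boyce,
    kfold_split,
    map_rsf,
    spatial_block_cv,
    summarize_bin_coverage,
)

SPEC = ModelSpec(timberline="quadratic", slope="quadratic")


def rank_pearson(a, b):
    """Brute-force Spearman oracle: average ranks, then Pearson."""
    ra, rb = rankdata(a), rankdata(b)
    return float(np.corrcoef(ra, rb)[0, 1])


class TestSpearmanOracle:
    def test_scipy_matches_rank_then_pearson(self, rng):
        for _ in range(20):
            n = rng.integers(4, 21)
            a = rng.integers(0, 6, n).astype(float)  # ties likely
            b = rng.normal(size=n)
            if np.unique(a).size < 2:
                continue
            rho, _ = spearmanr(a, b)
            assert rho == pytest.approx(rank_pearson(a, b), abs=1e-12)

    def test_perfectly_ordered_counts(self):
        assert spearmanr(np.arange(1, 11), np.arange(1, 11))[0] == pytest.approx(1.0)
        assert spearmanr(np.arange(1, 11), np.arange(10, 0, -1))[0] == pytest.approx(-1.0)


class TestKfoldSplit:
    def test_even_split(self):
        plan = kfold_split(np.arange(100), k=5, seed=1)
        sizes = np.bincount(plan.fold)[1:]
        assert list(sizes) == [20] * 5

    def test_uneven_split_within_one(self):
        plan = kfold_split(np.arange(101), k=5, seed=1)
        sizes = sorted(np.bincount(plan.fold)[1:])
        assert sizes == [20, 20, 20, 20, 21]

    def test_deterministic_given_seed(self):
        a = kfold_split(np.arange(50), k=5, seed=7)
        b = kfold_split(np.arange(50), k=5, seed=7)
        assert np.array_equal(a.fold, b.fold)

    def test_stratified_folds_balance_the_response(self, rng):
        strata = np.r_[np.ones(200), np.zeros(600)]
        plan = kfold_split(np.arange(800), k=5, seed=3, strata=strata)
        for f in range(1, 6):
            share = strata[plan.fold == f].mean()
            assert share == pytest.approx(0.25, abs=0.025)

    def test_k_larger_than_n_rejected(self):
        with pytest.raises(ValueError):
            kfold_split(np.arange(3), k=5, seed=0)


@pytest.fixture(scope="module")
def sim_data():
    cfg = syn.RecoveryConfig(rows=256, cols=256, n_areas=6,
                             expected_candidates_per_km=3.0)
    data, params, truth, extras = syn.simulate_modelling_data(cfg, seed=42)
    return data


class TestCvBoyce:
    def test_well_specified_model_is_predictive(self, sim_data):
        res = cv_boyce(sim_data, SPEC, k=5, seed=2)
        assert len(res.per_fold) == 5
        assert (res.per_fold["rho"] > 0.6).all()
        assert res.bin_counts.to_numpy().sum() == res.per_fold["n_used"].sum()

    def test_region_label_permutation_invariance(self, sim_data):
        regions = sim_data["area_id"].str.slice(0, 2).replace(
            {"A0": "south", "A1": "north"}
        )
        # group areas into two regions two ways that induce the same split
        r1 = np.where(sim_data["area_id"].isin(["A01", "A02", "A03"]), "x", "y")
        r2 = np.where(sim_data["area_id"].isin(["A01", "A02", "A03"]), "p", "q")
        a = spatial_block_cv(sim_data, r1, SPEC)
        b = spatial_block_cv(sim_data, r2, SPEC)
        np.testing.assert_allclose(
            sorted(a.per_fold["rho"]), sorted(b.per_fold["rho"]), atol=1e-12
        )


class TestAreaAdjustedValidation:
    def _map(self):
        grid = Grid(xll=0, yll=0, cell_size=10.0, nrows=40, ncols=40)
        bins = np.repeat(np.arange(1, 11), 160).reshape(40, 40)
        return BinnedMap(rsf=np.ones((40, 40)), bins=bins, grid=grid)

    def test_uniform_points_give_flat_adjusted_counts(self, rng):
        bmap = self._map()
        pts = pd.DataFrame(
            {"x": rng.uniform(0, 400, 4000), "y": rng.uniform(0, 400, 4000)}
        )
        rho, p, detail = area_adjusted_validation(pts, bmap)
        cv_spread = detail["adjusted_count"].std() / detail["adjusted_count"].mean()
        assert cv_spread < 0.2
        assert p > 0.05 or abs(rho) < 0.5

    def test_all_points_in_top_bin(self):
        bmap = self._map()
        pts = pd.DataFrame({"x": [395.0] * 5, "y": [5.0] * 5})
        # rows 36..39 are bin 10 (row 0 = north edge)
        rho, p, detail = area_adjusted_validation(pts, bmap)
        assert detail.loc[detail["bin"] == 10, "count"].iloc[0] == 5
        assert detail.loc[detail["bin"] != 10, "count"].sum() == 0
        assert rho > 0

    def test_points_proportional_to_rank_give_high_rho(self, rng):
        bmap = self._map()
        ys = []
        for b in range(1, 11):
            n = 30 * b
            ys.append(rng.uniform(400 - 40 * b, 440 - 40 * b, n))
        y = np.concatenate(ys)
        pts = pd.DataFrame({"x": rng.uniform(0, 400, len(y)), "y": y})
        rho, p, _ = area_adjusted_validation(pts, bmap)
        assert rho >= 0.9


class TestMapRsf:
    def _fit(self, data):
        from ptarmigan_rsf.rsf import build_design, fit_mixed_logistic

        params = cov.fit_standardization(data)
        std = cov.apply_standardization(data, params)
        y, X, g = build_design(std, SPEC)
        levels = [cov.REFERENCE_CLASS] + [
            c[4:-1] for c in X.columns if c.startswith("veg[")
        ]
        return fit_mixed_logistic(y, X, g, std_params=params, spec=SPEC,
                                  veg_levels=levels)

    def test_map_consistent_with_pointwise_prediction(self, sim_data):
        from ptarmigan_rsf.rsf import predict_rsf, scale_rsf

        fit = self._fit(sim_data.drop(columns=[c for c in sim_data.columns
                                               if c.endswith("_std")]))
        landscape = syn.make_landscape(
            seed=9, rows=48, cols=48,
            class_mixing_params=syn.RECOVERY_WEIGHTS,
        )
        edges = quantile_bin(np.linspace(0.01, 1.0, 200))
        bmap = map_rsf(fit, landscape, edges)
        assert np.nanmax(bmap.rsf) == pytest.approx(1.0, abs=1e-12)
        # cell-level value equals prediction on that cell's extracted record
        grid = landscape.grid
        r, c = 10, 20
        xs, ys = grid.cell_centers()
        pt = pd.DataFrame({"x": [xs[r, c]], "y": [ys[r, c]]})
        rec = cov.extract_at_points(landscape, pt)
        if rec.loc[0, "vegetation_class"] != cov.NON_HABITAT:
            rec = cov.apply_standardization(rec, fit.std_params)
            w = predict_rsf(fit, rec)[0]
            ratio = bmap.rsf[r, c]
            scale = np.nanmax(
                np.where(bmap.bins > 0, bmap.rsf, np.nan)
            )  # = 1 by construction
            assert ratio * 1.0 == pytest.approx(
                w / _map_max(fit, landscape), rel=1e-9
            )

    def test_nonhabitat_cells_are_nodata(self, sim_data):
        fit = self._fit(sim_data.drop(columns=[c for c in sim_data.columns
                                               if c.endswith("_std")]))
        landscape = syn.make_landscape(
            seed=9, rows=48, cols=48,
            class_mixing_params={12: 0.4, 17: 0.4, 22: 0.2},
        )
        bmap = map_rsf(fit, landscape, quantile_bin(np.linspace(0.1, 1, 50)))
        nonhab = landscape.vegetation >= 21
        assert (bmap.bins[nonhab] == 0).all()
        assert np.isnan(bmap.rsf[nonhab]).all()


def _map_max(fit, landscape):
    from ptarmigan_rsf.rsf import predict_rsf

    grid = landscape.grid
    xs, ys = grid.cell_centers()
    rec = cov.extract_at_points(
        landscape, pd.DataFrame({"x": xs.ravel(), "y": ys.ravel()})
    )
    rec = rec[rec["vegetation_class"] != cov.NON_HABITAT]
    rec = cov.apply_standardization(rec.reset_index(drop=True), fit.std_params)
    return predict_rsf(fit, rec).max()


class TestSummarizeBinCoverage:
    def _uniform_map(self):
        grid = Grid(xll=0, yll=0, cell_size=10.0, nrows=40, ncols=40)
        bins = np.repeat(np.arange(1, 11), 160).reshape(40, 40)
        return BinnedMap(rsf=np.ones((40, 40)), bins=bins, grid=grid)

    def test_equal_areas_give_ten_percent_each(self):
        table = summarize_bin_coverage(self._uniform_map())
        np.testing.assert_allclose(table["domain_pct"], 10.0)

    def test_used_points_all_in_top_bin(self):
        pts = pd.DataFrame({"x": [5.0, 15.0], "y": [5.0, 15.0]})  # south rows
        table = summarize_bin_coverage(self._uniform_map(), used_points=pts)
        np.testing.assert_allclose(
            table["used_pct"], [0] * 9 + [100.0], atol=1e-12
        )

    def test_columns_sum_to_100(self, rng):
        mask = rng.uniform(size=(40, 40)) < 0.5
        pts = pd.DataFrame(
            {"x": rng.uniform(0, 400, 100), "y": rng.uniform(0, 400, 100)}
        )
        table = summarize_bin_coverage(self._uniform_map(), mask, pts)
        for col in ("domain_pct", "buffer_pct", "used_pct"):
            assert table[col].sum() == pytest.approx(100.0, abs=1e-9)
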