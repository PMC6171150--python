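"""Cross-validation, independent validation and RSF mapping.

Predictive skill is measured Boyce-style: predictions of a held-out test
set are cut into 10 quantile bins ranked 1 (low) to 10 (high relative
probability of selection); a well-calibrated model places increasingly
many used locations in higher bins, quantified by the Spearman rank
correlation between bin rank and per-bin used count.  Folds are either
random (k-fold) or geographical regions (spatial blocking).  The fitted
model can also be pushed through a whole raster stack to produce a binned
suitability map with per-bin coverage summaries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from . import covariates as cov
from .rasters import LandscapeStack
from .rsf import (
    BinAssignment,
    ModelSpec,
    RSFFit,
    build_design,
    fit_mixed_logistic,
    predict_rsf,
    quantile_bin,
    scale_rsf,
)


@dataclass
class FoldPlan:
    """Assignment of modelling units to folds 1..k."""

    unit_ids: np.ndarray
    fold: np.ndarray
    k: int
    seed: int | None = None

    def indices(self, label: int) -> np.ndarray:
        return self.unit_ids[self.fold == label]


def kfold_split(unit_ids, k: int = 5, seed: int = 0, strata=None) -> FoldPlan:
    """Random partition into k approximately equal folds (sizes within 1).

    With ``strata`` (e.g. the used/available response) the partition is
    stratified so each fold's composition matches the global one.
    """
    ids = np.asarray(unit_ids)
    if k > len(ids):
        raise ValueError(f"k={k} exceeds number of units {len(ids)}")
    rng = np.random.default_rng(seed)
    fold = np.empty(len(ids), dtype=int)
    if strata is None:
        strata = np.zeros(len(ids))
    strata = np.asarray(strata)
    offset = 0  # rotate fold sizes across strata so totals stay within 1
    for s in pd.unique(strata):
        idx = np.flatnonzero(strata == s)
        perm = rng.permutation(idx)
        fold[perm] = (np.arange(len(perm)) + offset) % k + 1
        offset += len(perm)
    return FoldPlan(unit_ids=ids, fold=fold, k=k, seed=seed)


@dataclass
class ValidationResult:
    """Per-fold (or per-region) Boyce-style rank correlations."""

    per_fold: pd.DataFrame  # columns: fold, rho, p_value, n_used
    bin_counts: pd.DataFrame  # fold x bin used-location counts

    @property
    def mean_rho(self) -> float:
        return float(self.per_fold["rho"].mean())


def _bin_rank_correlation(bin_idx_used: np.ndarray, n_bins: int = 10):
    """Spearman correlation of bin rank (1..n) against used counts."""
    counts = np.bincount(bin_idx_used, minlength=n_bins + 1)[1:]
    rho, p = spearmanr(np.arange(1, n_bins + 1), counts)
    return float(rho), float(p), counts


def _fit_fold(train: pd.DataFrame, spec: ModelSpec) -> RSFFit:
    params = cov.fit_standardization(train)
    train_std = cov.apply_standardization(train, params)
    y, X, groups = build_design(train_std, spec)
    veg_levels = [c[4:-1] for c in X.columns if c.startswith("veg[")]
    fit = fit_mixed_logistic(
        y, X, groups, std_params=params, spec=spec,
        veg_levels=[cov.REFERENCE_CLASS] + veg_levels,
    )
    return fit


def _score_fold(fit: RSFFit, test: pd.DataFrame, n_bins: int = 10):
    known = set(fit.veg_levels)
    unseen = ~test["vegetation_class"].isin(known)
    if unseen.any():
        warnings.warn(
            f"dropping {int(unseen.sum())} test point(s) in vegetation "
            "class(es) unseen during training"
        )
        test = test[~unseen].reset_index(drop=True)
    test_std = cov.apply_standardization(test, fit.std_params)
    w = scale_rsf(predict_rsf(fit, test_std))
    bins = quantile_bin(w, n_bins=n_bins)
    idx = bins.assign(w)
    used = test["response"].to_numpy() == 1
    return _bin_rank_correlation(idx[used], n_bins)


def cv_boyce(
    data: pd.DataFrame,
    spec: ModelSpec,
    k: int = 5,
    seed: int = 0,
    fold_plan: FoldPlan | None = None,
    n_bins: int = 10,
) -> ValidationResult:
    """K-fold cross-validation of the selection model.

    Folds partition used and available points jointly, stratified on the
    response.  Per fold: fit on the training folds (standardization
    refitted on the training data), predict the test fold, 10-quantile bin
    the test predictions and rank-correlate bin rank with used counts.
    """
    if fold_plan is None:
        fold_plan = kfold_split(
            np.arange(len(data)), k=k, seed=seed, strata=data["response"]
        )
    rows, count_rows = [], []
    for f in range(1, fold_plan.k + 1):
        test_mask = fold_plan.fold == f
        train = data[~test_mask].reset_index(drop=True)
        test = data[test_mask].reset_index(drop=True)
        if (test["response"] == 1).sum() == 0:
            warnings.warn(f"fold {f} has no used locations; rho undefined")
            rows.append({"fold": f, "rho": np.nan, "p_value": np.nan, "n_used": 0})
            continue
        fit = _fit_fold(train, spec)
        rho, p, counts = _score_fold(fit, test, n_bins)
        rows.append(
            {"fold": f, "rho": rho, "p_value": p, "n_used": int(counts.sum())}
        )
        count_rows.append(pd.Series(counts, name=f, index=np.arange(1, n_bins + 1)))
    return ValidationResult(
        per_fold=pd.DataFrame(rows),
        bin_counts=pd.DataFrame(count_rows),
    )


def spatial_block_cv(
    data: pd.DataFrame, region_labels, spec: ModelSpec, n_bins: int = 10
) -> ValidationResult:
    """Leave-one-region-out validation (geographical blocking)."""
    regions = np.asarray(region_labels)
    names = pd.unique(regions)
    if len(names) < 2:
        raise ValueError("need >=2 regions for spatial blocking")
    rows, count_rows = [], []
    for name in names:
        test_mask = regions == name
        train = data[~test_mask].reset_index(drop=True)
        test = data[test_mask].reset_index(drop=True)
        if (test["response"] == 1).sum() == 0:
            warnings.warn(f"region {name!r} has no used locations; rho undefined")
            rows.append(
                {"fold": name, "rho": np.nan, "p_value": np.nan, "n_used": 0}
            )
            continue
        fit = _fit_fold(train, spec)
        rho, p, counts = _score_fold(fit, test, n_bins)
        rows.append(
            {"fold": name, "rho": rho, "p_value": p, "n_used": int(counts.sum())}
        )
        count_rows.append(
            pd.Series(counts, name=name, index=np.arange(1, n_bins + 1))
        )
    return ValidationResult(
        per_fold=pd.DataFrame(rows), bin_counts=pd.DataFrame(count_rows)
    )


@dataclass
class BinnedMap:
    """Scaled RSF raster and its 10-bin classification."""

    rsf: np.ndarray  # scaled (0,1], NaN outside habitat
    bins: np.ndarray  # int 1..n_bins, 0 = nodata/non-habitat
    grid: object
    n_bins: int = 10
    bin_edges: BinAssignment | None = None

    def coverage_fractions(self, mask=None) -> np.ndarray:
        """Per-bin percentage of valid (optionally masked) cells."""
        b = self.bins
        valid = b > 0
        if mask is not None:
            valid &= np.asarray(mask, dtype=bool)
        n = valid.sum()
        if n == 0:
            warnings.warn("empty mask: coverage undefined, returning zeros")
            return np.zeros(self.n_bins)
        counts = np.bincount(b[valid], minlength=self.n_bins + 1)[1:]
        return 100.0 * counts / n


def map_rsf(fit: RSFFit, landscape: LandscapeStack, bin_edges: BinAssignment) -> BinnedMap:
    """Predict w(x) for every habitat cell, max-scale, and bin with the
    supplied (cross-validation) quantile edges.  Non-habitat and nodata
    cells become nodata in the bin raster."""
    if fit.std_params is None:
        raise ValueError("fit carries no standardization parameters")
    grid = landscape.grid
    xs, ys = grid.cell_centers()
    pts = pd.DataFrame({"x": xs.ravel(), "y": ys.ravel()})
    rec = cov.extract_at_points(landscape, pts)
    habitat = (~rec["missing"]) & (rec["vegetation_class"] != cov.NON_HABITAT)
    rec_h = cov.apply_standardization(rec[habitat].reset_index(drop=True), fit.std_params)
    w = predict_rsf(fit, rec_h)
    w_scaled = np.full(len(pts), np.nan)
    w_scaled[np.flatnonzero(habitat.to_numpy())] = scale_rsf(w)
    bins = np.zeros(len(pts), dtype=int)
    bins[np.flatnonzero(habitat.to_numpy())] = bin_edges.assign(
        w_scaled[np.flatnonzero(habitat.to_numpy())]
    )
    return BinnedMap(
        rsf=w_scaled.reshape(grid.nrows, grid.ncols),
        bins=bins.reshape(grid.nrows, grid.ncols),
        grid=grid,
        n_bins=bin_edges.n_bins,
        bin_edges=bin_edges,
    )


def summarize_bin_coverage(
    binned_map: BinnedMap,
    buffer_mask: np.ndarray | None = None,
    used_points: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Percentage of each RSF bin across the whole domain, within the
    surveyed (buffer) area, and among used locations.  Columns each sum
    to 100 up to rounding."""
    table = pd.DataFrame({"bin": np.arange(1, binned_map.n_bins + 1)})
    table["domain_pct"] = binned_map.coverage_fractions()
    if buffer_mask is not None:
        table["buffer_pct"] = binned_map.coverage_fractions(buffer_mask)
    if used_points is not None:
        row, col = binned_map.grid.point_to_rowcol(
            used_points["x"].to_numpy(), used_points["y"].to_numpy()
        )
        b = binned_map.bins[row, col]
        b = b[b > 0]
        if len(b) == 0:
            warnings.warn("no used points fall in valid map cells")
            table["used_pct"] = 0.0
        else:
            counts = np.bincount(b, minlength=binned_map.n_bins + 1)[1:]
            table["used_pct"] = 100.0 * counts / counts.sum()
    return table


def area_adjusted_validation(
    points: pd.DataFrame, binned_map: BinnedMap
) -> tuple[float, float, pd.DataFrame]:
    """Independent validation: per-bin point counts divided by the bin's
    areal availability, rank-correlated against bin rank.

    Points in nodata cells are counted and excluded.  Bins with zero
    availability are excluded with a warning.
    """
    row, col = binned_map.grid.point_to_rowcol(
        points["x"].to_numpy(), points["y"].to_numpy()
    )
    b = binned_map.bins[row, col]
    n_excluded = int((b == 0).sum())
    b = b[b > 0]
    counts = np.bincount(b, minlength=binned_map.n_bins + 1)[1:].astype(float)
    avail = binned_map.coverage_fractions() / 100.0
    ok = avail > 0
    if not ok.all():
        warnings.warn(f"{(~ok).sum()} bin(s) with zero availability excluded")
    adjusted = np.full(binned_map.n_bins, np.nan)
    adjusted[ok] = counts[ok] / avail[ok]
    ranks = np.arange(1, binned_map.n_bins + 1)
    rho, p = spearmanr(ranks[ok], adjusted[ok])
    detail = pd.DataFrame(
        {
            "bin": ranks,
            "count": counts,
            "availability": avail,
            "adjusted_count": adjusted,
        }
    )
    detail.attrs["n_excluded"] = n_excluded
    return float(rho), float(p), detail
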