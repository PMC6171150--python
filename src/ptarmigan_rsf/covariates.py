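"""Predictor variables at point locations.

The model's covariates are derived from three aligned rasters: a 25-code
satellite vegetation map, a digital elevation model, and the regional
empirical timberline (RET).  From these we compute

* the vegetation modelling class (25 raw codes pooled to 16 classes plus a
  non-habitat category),
* timberline deviation (elevation − RET, metres; 0 = at the timberline),
* slope (degrees) and aspect, both as trigonometric components
  (N = cos r, E = sin r with r the aspect in radians) and as a 5-level
  category (north/east/south/west/flat),
* standardized copies of the continuous terms (zero mean, unit SD).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .rasters import LandscapeStack, slope_aspect

NON_HABITAT = "non-habitat"
LOWLAND_FOREST = "Lowland forest"

#: raw vegetation codes kept as their own modelling class
_CLASS_NAMES = {
    6: "Bilberry-low fern birch forest",
    7: "Crowberry birch forest",
    8: "Lichen-rich birch forest",
    9: "Ombrotrophic bog and low-grown lawn vegetation",
    10: "Tall-grown lawn vegetation",
    11: "Wet mires, sedge swamps and reed beds",
    12: "Exposed alpine ridges",
    13: "Graminoid alpine ridge",
    14: "Heather-rich alpine ridge",
    15: "Lichen-rich heathland",
    16: "Heather- and grass-rich early snow patch communities",
    17: "Fresh heather and dwarf-shrub communities",
    18: "Herb-rich meadows",
    19: "Grass and dwarf willow snow-patch vegetation",
    20: "Bryophyte late snow patch vegetation",
}

#: the 16 modelling classes; exposed alpine ridges first (reference level)
MODELLING_CLASSES = tuple(
    ["Exposed alpine ridges"]
    + sorted(set(_CLASS_NAMES.values()) - {"Exposed alpine ridges"})
    + [LOWLAND_FOREST]
)
REFERENCE_CLASS = "Exposed alpine ridges"

#: continuous model terms, standardized before fitting
CONTINUOUS_TERMS = ("timberline_dev_m", "slope_deg", "n_aspect", "e_aspect")

ASPECT_CATEGORIES = ("flat", "north", "east", "south", "west")


def reclassify_vegetation(code: int) -> str:
    """Map a raw vegetation code 1..25 to its modelling class.

    Codes 1–5 (lowland/coniferous forests) pool to one lowland-forest
    class; 6–20 keep their own class; the water/agriculture/built-up/
    unclassified codes 21–25 are non-habitat.
    """
    code = int(code)
    if not 1 <= code <= 25:
        raise ValueError(f"unknown vegetation code {code}; expected 1..25")
    if code <= 5:
        return LOWLAND_FOREST
    if code <= 20:
        return _CLASS_NAMES[code]
    return NON_HABITAT


def aspect_components(aspect_deg):
    """North and east exposure: (cos r, sin r) with r = aspect in radians."""
    a = np.asarray(aspect_deg, dtype=float)
    if np.any((a < 0) | (a > 360)):
        raise ValueError("aspect_deg must lie in [0, 360]")
    r = np.deg2rad(a)
    return np.cos(r), np.sin(r)


def aspect_category(aspect_deg, slope_deg, flat_slope_threshold: float = 0.0):
    """5-level aspect category.

    Cells with slope ≤ ``flat_slope_threshold`` (default exactly 0) are
    'flat' — aspect is undefined on level ground.  Otherwise half-open
    compass sectors: north [315, 360) ∪ [0, 45), east [45, 135),
    south [135, 225), west [225, 315).
    """
    a = np.asarray(aspect_deg, dtype=float) % 360.0
    s = np.asarray(slope_deg, dtype=float)
    out = np.full(a.shape, "north", dtype=object)
    out[(a >= 45) & (a < 135)] = "east"
    out[(a >= 135) & (a < 225)] = "south"
    out[(a >= 225) & (a < 315)] = "west"
    out[s <= flat_slope_threshold] = "flat"
    if out.ndim == 0:
        return out.item()
    return out


def timberline_deviation(elevation_m, ret_m):
    """Elevation minus the regional empirical timberline; positive above."""
    return np.asarray(elevation_m, dtype=float) - np.asarray(ret_m, dtype=float)


@dataclass
class StandardizationParams:
    """Per-variable centring/scaling parameters (sample SD, n−1)."""

    mean: dict[str, float] = field(default_factory=dict)
    sd: dict[str, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {"mean": dict(self.mean), "sd": dict(self.sd)}

    @classmethod
    def from_dict(cls, d: dict) -> "StandardizationParams":
        return cls(mean=dict(d["mean"]), sd=dict(d["sd"]))


def fit_standardization(
    records: pd.DataFrame, columns=CONTINUOUS_TERMS
) -> StandardizationParams:
    """Mean/SD of each continuous term on the combined used+available set."""
    params = StandardizationParams()
    for col in columns:
        values = records[col].to_numpy(dtype=float)
        sd = float(np.std(values, ddof=1))
        if not np.isfinite(sd) or sd <= 0:
            raise ValueError(f"cannot standardize '{col}': zero or undefined SD")
        params.mean[col] = float(np.mean(values))
        params.sd[col] = sd
    return params


def apply_standardization(
    records: pd.DataFrame, params: StandardizationParams
) -> pd.DataFrame:
    """Append ``<col>_std`` columns; quadratic model terms are squares of
    the standardized value (computed later in the design matrix)."""
    out = records.copy()
    for col, m in params.mean.items():
        out[f"{col}_std"] = (out[col] - m) / params.sd[col]
    return out


def invert_standardization(value_std, column: str, params: StandardizationParams):
    """Back-transform a standardized value to its raw scale."""
    return np.asarray(value_std, dtype=float) * params.sd[column] + params.mean[column]


def extract_at_points(
    landscape: LandscapeStack, points: pd.DataFrame, flat_slope_threshold: float = 0.0
) -> pd.DataFrame:
    """Extract every model covariate at point locations.

    Lookup is cell-containing (no interpolation).  Slope and aspect come
    from the elevation raster via Horn's method.  Rows where any layer is
    nodata get ``missing=True`` and NaN covariates.
    """
    grid = landscape.grid
    row, col = grid.point_to_rowcol(points["x"].to_numpy(), points["y"].to_numpy())
    slope, aspect = slope_aspect(landscape.elevation, grid)

    veg_code = landscape.vegetation[row, col]
    elev = landscape.elevation[row, col].astype(float)
    ret = landscape.timberline[row, col].astype(float)
    missing = (
        (veg_code == grid.nodata) | (elev == grid.nodata) | (ret == grid.nodata)
    )

    out = points.copy().reset_index(drop=True)
    out["vegetation_code"] = veg_code
    out["vegetation_class"] = [
        reclassify_vegetation(c) if not m else NON_HABITAT
        for c, m in zip(veg_code, missing)
    ]
    out["elevation_m"] = np.where(missing, np.nan, elev)
    out["ret_m"] = np.where(missing, np.nan, ret)
    out["timberline_dev_m"] = timberline_deviation(out["elevation_m"], out["ret_m"])
    out["slope_deg"] = np.where(missing, np.nan, slope[row, col])
    out["aspect_deg"] = np.where(missing, np.nan, aspect[row, col])
    n_asp, e_asp = aspect_components(np.nan_to_num(out["aspect_deg"].to_numpy()))
    out["n_aspect"] = np.where(missing, np.nan, n_asp)
    out["e_aspect"] = np.where(missing, np.nan, e_asp)
    cat = aspect_category(
        np.nan_to_num(out["aspect_deg"].to_numpy()),
        np.nan_to_num(out["slope_deg"].to_numpy()),
        flat_slope_threshold,
    )
    out["aspect_category"] = np.where(missing, "missing", cat)
    out["missing"] = missing
    return out


def drop_nonhabitat(points: pd.DataFrame, ledger=None) -> pd.DataFrame:
    """Remove rows classified as non-habitat (or with missing covariates)."""
    bad = (points["vegetation_class"] == NON_HABITAT) | points.get(
        "missing", pd.Series(False, index=points.index)
    )
    kept = points[~bad].reset_index(drop=True)
    if ledger is not None:
        used = kept.get("response")
        if used is not None:
            n_used = int((used == 1).sum())
            n_avail = int((used == 0).sum())
        else:
            n_used, n_avail = len(kept), None
        ledger.append(
            "removed non-habitat (final dataset)", used=n_used, available=n_avail
        )
    return kept
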