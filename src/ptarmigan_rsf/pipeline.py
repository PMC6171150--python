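"""End-to-end pipeline orchestration and the packaged survey-summary fixture.

``run`` executes the stages simulate → qc → availability → covariates →
fit → validate → map → report on a synthetic landscape, writing each stage's
artifacts (CSV tables, plain-text rasters, a JSON fit) into a run
directory together with the resolved configuration, so a rerun with the
same config bit-reproduces every stochastic output.
"""

from __future__ import annotations

import dataclasses
import importlib.resources
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import availability as av
from . import covariates as cov
from . import survey as sq
from . import synthetic
from .rasters import write_ascii_grid
from .rsf import (
    ModelSpec,
    build_design,
    candidate_set,
    fit_mixed_logistic,
    model_comparison_table,
    predict_rsf,
    quantile_bin,
    scale_rsf,
    select_model,
)
from .validation import cv_boyce, map_rsf, summarize_bin_coverage

log = logging.getLogger("ptarmigan_rsf")

STAGES = ("simulate", "qc", "availability", "covariates", "fit",
          "validate", "map", "report")


@dataclass
class PipelineConfig:
    """Run settings; the numeric defaults are the survey protocol's:
    200-m buffers, 30-m deviation cutoff, 3 available points per km of
    effort, 5 cross-validation folds."""

    seed: int = 1
    output_dir: str = "runs/default"
    buffer_m: float = 200.0
    max_deviation_m: float = 30.0
    availability_multiplier: float = 3.0
    detection_truncation_m: float | None = None
    k_folds: int = 5
    rows: int = 256
    cols: int = 256
    cell_size: float = 30.0
    transect_spacing_m: float = 500.0
    n_areas: int = 6
    n_surveys_per_transect: int = 4
    expected_candidates_per_km: float = 2.5
    class_weights: dict | None = None
    candidate_grid: str = "parsimonious"  # or "full"
    n_bins: int = 10

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)


def _model_specs(config: PipelineConfig) -> list[ModelSpec]:
    if config.candidate_grid == "full":
        return candidate_set()
    return [ModelSpec(timberline="quadratic", slope="quadratic")]


def run(config: PipelineConfig, stages=STAGES) -> Path:
    """Execute the requested stages in canonical order.

    Stages are always computed from the front of the pipeline (they are
    deterministic in the seed); naming a stage means its artifacts are
    written.  Returns the run directory.
    """
    stages = set(stages)
    unknown = stages - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "resolved_config.yaml")

    rcfg = synthetic.RecoveryConfig(
        rows=config.rows,
        cols=config.cols,
        cell_size=config.cell_size,
        class_weights=dict(config.class_weights or synthetic.RECOVERY_WEIGHTS),
        transect_spacing_m=config.transect_spacing_m,
        n_areas=config.n_areas,
        n_surveys_per_transect=config.n_surveys_per_transect,
        expected_candidates_per_km=config.expected_candidates_per_km,
        buffer_m=config.buffer_m,
        max_deviation_m=config.max_deviation_m,
        availability_multiplier=config.availability_multiplier,
        seed=config.seed,
    )
    data, params, truth, extras = synthetic.simulate_modelling_data(
        rcfg, seed=config.seed
    )
    landscape = extras["landscape"]
    transects = extras["transects"]
    ledger = extras["ledger"]
    log.info("ledger after filtering:\n%s", ledger.to_frame().to_string())

    if "simulate" in stages:
        write_ascii_grid(out / "vegetation.asc", landscape.vegetation, landscape.grid)
        write_ascii_grid(out / "elevation.asc", landscape.elevation, landscape.grid)
        write_ascii_grid(out / "timberline.asc", landscape.timberline, landscape.grid)
        with open(out / "transects.geojson", "w") as fh:
            json.dump(sq.transects_to_geojson(transects), fh, indent=1)
    if "qc" in stages:
        ledger.to_csv(out / "qc_ledger.csv")
    if "availability" in stages:
        det = extras["detection"]
        (out / "detection.txt").write_text(
            f"sigma_m {det.sigma_m!r}\nn {det.n_distances}\nloglik {det.loglik!r}\n"
        )
    if "covariates" in stages:
        data.to_csv(out / "modelling_data.csv", index=False)

    if not stages & {"fit", "validate", "map", "report"}:
        return out

    specs = _model_specs(config)
    fits = []
    for spec in specs:
        y, X, groups = build_design(data, spec)
        veg_levels = [cov.REFERENCE_CLASS] + [
            c[4:-1] for c in X.columns if c.startswith("veg[")
        ]
        fits.append(
            fit_mixed_logistic(
                y, X, groups, std_params=params, spec=spec, veg_levels=veg_levels
            )
        )
    chosen = select_model(fits)
    if "fit" in stages:
        (out / "fit.json").write_text(chosen.to_json())
        model_comparison_table(fits).to_csv(out / "model_comparison.csv", index=False)

    w_model = scale_rsf(predict_rsf(chosen, data))
    bins = quantile_bin(w_model, n_bins=config.n_bins)

    if "validate" in stages:
        cv = cv_boyce(data, chosen.spec, k=config.k_folds, seed=config.seed)
        cv.per_fold.to_csv(out / "cv_results.csv", index=False)
        cv.bin_counts.to_csv(out / "cv_bin_counts.csv")
        log.info("mean CV rho = %.3f", cv.mean_rho)

    if "map" in stages or "report" in stages:
        bmap = map_rsf(chosen, landscape, bins)
        if "map" in stages:
            write_ascii_grid(out / "rsf_bins.asc", bmap.bins, landscape.grid)
            rsf_out = np.where(np.isfinite(bmap.rsf), bmap.rsf, landscape.grid.nodata)
            write_ascii_grid(out / "rsf_scaled.asc", rsf_out, landscape.grid)
        if "report" in stages:
            mask = _buffer_mask(landscape, transects, config.buffer_m)
            used = data[data["response"] == 1]
            coverage = summarize_bin_coverage(bmap, mask, used)
            coverage.to_csv(out / "bin_coverage.csv", index=False)
    return out


def _buffer_mask(landscape, transects, buffer_m: float) -> np.ndarray:
    import shapely
    from shapely.ops import unary_union

    poly = unary_union(
        [t.geometry.buffer(buffer_m, cap_style="flat") for t in transects]
    )
    xs, ys = landscape.grid.cell_centers()
    return shapely.intersects(
        poly, shapely.points(xs.ravel(), ys.ravel())
    ).reshape(xs.shape)


# ---------------------------------------------------------------------------
# packaged survey-summary fixture
# ---------------------------------------------------------------------------

USED_TOTAL = 12146
AVAILABLE_TOTAL = 38149


@dataclass
class Table2Fixture:
    """Published per-class used/available counts of the national survey
    dataset (12,146 used and 38,149 available locations)."""

    vegetation: pd.DataFrame
    aspect: pd.DataFrame

    def validate(self) -> None:
        for name, frame in (("vegetation", self.vegetation),
                            ("aspect", self.aspect)):
            for col, total in (("used", USED_TOTAL), ("available", AVAILABLE_TOTAL)):
                got = int(frame[col].sum())
                if got != total:
                    raise ValueError(
                        f"{name} {col} counts sum to {got}, expected {total}"
                    )


def load_table2_fixture() -> Table2Fixture:
    pkg = importlib.resources.files("ptarmigan_rsf") / "data"
    fx = Table2Fixture(
        vegetation=pd.read_csv(pkg / "table2_vegetation.csv"),
        aspect=pd.read_csv(pkg / "table2_aspect.csv"),
    )
    fx.validate()
    return fx


def fixture_summary(fixture: Table2Fixture | None = None) -> dict:
    """Totals and naive per-class selection ratios
    (used share / available share) — exploratory only, not the model."""
    fx = fixture if fixture is not None else load_table2_fixture()
    fx.validate()
    veg = fx.vegetation.copy()
    u, a = veg["used"].sum(), veg["available"].sum()
    veg["naive_ratio"] = (veg["used"] / u) / (veg["available"] / a)
    return {
        "used_total": int(u),
        "available_total": int(a),
        "vegetation": veg,
        "aspect": fx.aspect.copy(),
    }
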