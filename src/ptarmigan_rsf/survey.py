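"""Transects, surveys, observations and the quality-control filters.

Line-transect surveys record willow ptarmigan locations together with the
perpendicular distance from the transect line reported in the field.  Two
filters clean the raw locations before modelling:

1. the *buffer rule* — locations farther than 200 m (the buffer half-width)
   from their transect line are discarded;
2. the *deviation rule* — locations whose reported perpendicular distance
   disagrees with the geometry-derived distance by more than 30 m are
   discarded (30 m is the resolution of the vegetation raster).

Every removal is appended to a :class:`QcLedger`, an ordered accounting of
dataset sizes through the workflow.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import LineString, Point

QC_RETAINED = "retained"
QC_REMOVED_BUFFER = "removed_buffer"
QC_REMOVED_DEVIATION = "removed_deviation"
QC_REMOVED_NONHABITAT = "removed_nonhabitat"

#: columns of the observation table used throughout the pipeline
OBS_COLUMNS = [
    "survey_id",
    "transect_id",
    "area_id",
    "year",
    "x",
    "y",
    "reported_perp_distance_m",
]


@dataclass(frozen=True)
class TransectLine:
    """A surveyed polyline with its survey-area label."""

    id: str
    area_id: str
    vertices: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        if len(self.vertices) < 2:
            raise ValueError(f"transect {self.id}: needs >=2 vertices")
        if self.length_km <= 0:
            raise ValueError(f"transect {self.id}: zero-length polyline")

    @property
    def geometry(self) -> LineString:
        return LineString(self.vertices)

    @property
    def length_km(self) -> float:
        v = np.asarray(self.vertices, dtype=float)
        return float(np.hypot(*(v[1:] - v[:-1]).T).sum()) / 1000.0


@dataclass(frozen=True)
class SurveyEvent:
    """One pass along a transect; ``survey_id`` is unique per pass."""

    survey_id: str
    transect_id: str
    year: int
    effort_km: float


@dataclass
class Observation:
    """A single used location with its QC outcome."""

    survey_id: str
    x: float
    y: float
    reported_perp_distance_m: float
    computed_perp_distance_m: float | None = None
    qc_status: str | None = None


@dataclass
class QcLedger:
    """Ordered ledger of dataset sizes after each processing action."""

    rows: list[dict] = field(default_factory=list)

    def append(self, action, used=None, surveys=None, available=None,
               transects=None, areas=None):
        self.rows.append(
            {
                "action": action,
                "used_locations": used,
                "surveys": surveys,
                "available_locations": available,
                "transects": transects,
                "survey_areas": areas,
            }
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def perpendicular_distance(point, polyline) -> float:
    """Minimum Euclidean distance (m) from a point to a polyline.

    The minimum is taken over all segments with endpoint capping, so bends
    and line ends are handled exactly.
    """
    if isinstance(polyline, TransectLine):
        geom = polyline.geometry
    else:
        verts = list(polyline)
        if len(verts) < 2:
            raise ValueError("polyline needs >=2 vertices")
        geom = LineString(verts)
    if geom.length == 0:
        raise ValueError("degenerate zero-length polyline")
    return float(Point(point).distance(geom))


def in_buffer(transect, point, half_width_m: float = 200.0) -> bool:
    """True iff the point lies within ``half_width_m`` of the transect line
    (boundary inclusive)."""
    if half_width_m <= 0:
        raise ValueError("half_width_m must be > 0")
    return perpendicular_distance(point, transect) <= half_width_m


def _transect_lookup(transects) -> dict[str, TransectLine]:
    if isinstance(transects, dict):
        return transects
    return {t.id: t for t in transects}


def compute_perp_distances(observations: pd.DataFrame, transects) -> pd.Series:
    """Geometry-based perpendicular distance for every observation row."""
    lut = _transect_lookup(transects)
    missing = sorted(set(observations["transect_id"]) - set(lut))
    if missing:
        raise ValueError(f"observations reference unknown transects: {missing}")
    out = np.empty(len(observations), dtype=float)
    tids = observations["transect_id"].to_numpy()
    xs = observations["x"].to_numpy(dtype=float)
    ys = observations["y"].to_numpy(dtype=float)
    for tid in pd.unique(tids):
        sel = tids == tid
        geom = lut[tid].geometry
        if geom.length == 0:
            raise ValueError(f"degenerate zero-length transect {tid}")
        out[sel] = shapely.distance(shapely.points(xs[sel], ys[sel]), geom)
    return pd.Series(out, index=observations.index, name="computed_perp_distance_m")


def apply_qc(
    observations: pd.DataFrame,
    transects,
    buffer_m: float = 200.0,
    max_deviation_m: float = 30.0,
    ledger: QcLedger | None = None,
) -> tuple[pd.DataFrame, QcLedger]:
    """Apply the buffer rule then the deviation rule.

    Returns the observation table with ``computed_perp_distance_m`` and
    ``qc_status`` columns plus the ledger.  The buffer test uses the
    geometry-derived (computed) distance, boundary inclusive; the deviation
    rule is strict (``> max_deviation_m`` removed, equality kept).
    Observations are only ever kept or removed, never moved.
    """
    obs = observations.copy()
    obs["computed_perp_distance_m"] = compute_perp_distances(obs, transects)
    ledger = ledger if ledger is not None else QcLedger()

    def _counts(frame):
        return dict(
            used=len(frame),
            surveys=frame["survey_id"].nunique(),
            transects=frame["transect_id"].nunique(),
            areas=frame["area_id"].nunique(),
        )

    if not ledger.rows:
        ledger.append("imported", **_counts(obs))

    status = np.full(len(obs), QC_RETAINED, dtype=object)
    outside = obs["computed_perp_distance_m"].to_numpy() > buffer_m
    status[outside] = QC_REMOVED_BUFFER
    kept = obs[~outside]
    ledger.append(f"removed used locations > {buffer_m:g} m", **_counts(kept))

    deviation = np.abs(
        obs["reported_perp_distance_m"].to_numpy()
        - obs["computed_perp_distance_m"].to_numpy()
    )
    deviating = ~outside & (deviation > max_deviation_m)
    status[deviating] = QC_REMOVED_DEVIATION
    obs["qc_status"] = status
    kept = obs[obs["qc_status"] == QC_RETAINED]
    ledger.append(
        f"removed used locations > {max_deviation_m:g} m deviation", **_counts(kept)
    )
    return obs, ledger


def drop_empty_surveys(
    observations: pd.DataFrame, surveys: pd.DataFrame, ledger: QcLedger | None = None
) -> tuple[pd.DataFrame, QcLedger]:
    """Drop surveys with no retained observation from the *used* side.

    The returned survey table only drives the used-location dataset;
    availability generation deliberately keeps covering every survey,
    including those without observations.
    """
    retained = observations[observations.get("qc_status", QC_RETAINED) == QC_RETAINED]
    with_obs = surveys["survey_id"].isin(retained["survey_id"])
    kept = surveys[with_obs].copy()
    if kept.empty:
        warnings.warn("all surveys are empty after QC", stacklevel=2)
    ledger = ledger if ledger is not None else QcLedger()
    ledger.append(
        "removed surveys without used locations",
        used=len(retained),
        surveys=len(kept),
        transects=kept["transect_id"].nunique() if not kept.empty else 0,
        areas=retained["area_id"].nunique(),
    )
    return kept, ledger


def surveys_from_observations(observations: pd.DataFrame) -> pd.DataFrame:
    """Derive a unique-survey table from an observation table."""
    cols = ["survey_id", "transect_id", "area_id", "year"]
    return observations[cols].drop_duplicates("survey_id").reset_index(drop=True)


def transects_to_geojson(transects) -> dict:
    lut = _transect_lookup(transects)
    return {
        "type": "FeatureCollection",
        "features": [
            {
                "type": "Feature",
                "geometry": {
                    "type": "LineString",
                    "coordinates": [list(v) for v in t.vertices],
                },
                "properties": {"id": t.id, "area_id": t.area_id,
                               "length_km": t.length_km},
            }
            for t in lut.values()
        ],
    }


def transects_from_geojson(obj: dict) -> list[TransectLine]:
    out = []
    for feat in obj["features"]:
        props = feat["properties"]
        out.append(
            TransectLine(
                id=str(props["id"]),
                area_id=str(props["area_id"]),
                vertices=tuple(tuple(c) for c in feat["geometry"]["coordinates"]),
            )
        )
    return out
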