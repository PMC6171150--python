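"""Detection-adjusted available locations for the used–available design.

Observations from line transects thin with distance from the line, so
uniform random points would overstate availability far from the line.  The
four-step remedy:

1. draw candidate points uniformly in the 200-m transect buffers, three per
   kilometre of effort (transect length × number of surveys);
2. fit a half-normal detection function g(d) = exp(−d²/(2σ²)) to the used
   perpendicular distances;
3. score each candidate's detection probability O_i = g(d_i);
4. keep the candidate when an independent uniform draw P_i < O_i.

The surviving points share the distance distribution of the observations,
so the logistic contrast of used vs available is detection-free.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd
import shapely
from scipy import optimize, special

from .survey import TransectLine


@dataclass(frozen=True)
class HalfNormalDetection:
    """Fitted half-normal detection function, g(0) = 1 by construction."""

    sigma_m: float
    n_distances: int
    loglik: float
    truncation_m: float | None = None

    def __post_init__(self) -> None:
        if self.sigma_m <= 0:
            raise ValueError("sigma_m must be > 0")


def n_available(effort_km_total: float, multiplier: float = 3.0) -> int:
    """Number of candidate points for a line-buffer: effort × multiplier,
    rounded to the nearest integer with ties away from zero
    (e.g. 16 km × 3 = 48; 2.5 km × 3 = 7.5 → 8)."""
    if effort_km_total < 0:
        raise ValueError("effort must be >= 0")
    return int(math.floor(effort_km_total * multiplier + 0.5))


def sample_in_buffer(
    n: int,
    transect: TransectLine,
    half_width_m: float = 200.0,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """``n`` points uniform over the transect's flat-capped buffer polygon.

    Rejection sampling from the buffer's bounding box; perpendicular
    distances to the line are recorded for each point.
    """
    rng = rng if rng is not None else np.random.default_rng()
    if n == 0:
        return pd.DataFrame(columns=["x", "y", "perp_distance_m"])
    line = transect.geometry
    poly = line.buffer(half_width_m, cap_style="flat")
    minx, miny, maxx, maxy = poly.bounds
    xs = np.empty(0)
    ys = np.empty(0)
    while len(xs) < n:
        m = max(2 * (n - len(xs)), 64)
        cx = rng.uniform(minx, maxx, m)
        cy = rng.uniform(miny, maxy, m)
        inside = shapely.intersects(poly, shapely.points(cx, cy))
        xs = np.concatenate([xs, cx[inside]])
        ys = np.concatenate([ys, cy[inside]])
    xs, ys = xs[:n], ys[:n]
    d = shapely.distance(shapely.points(xs, ys), line)
    return pd.DataFrame({"x": xs, "y": ys, "perp_distance_m": d})


def halfnormal_negloglik(
    sigma: float, distances: np.ndarray, truncation: float | None = None
) -> float:
    """Negative log-likelihood of perpendicular distances under the
    half-normal detection model, optionally truncated at ``truncation``."""
    d = np.asarray(distances, dtype=float)
    ll = -np.sum(d**2) / (2 * sigma**2) - len(d) * math.log(sigma)
    ll -= len(d) * 0.5 * math.log(math.pi / 2)
    if truncation is not None:
        # normalize on [0, W]: integral of exp(-d^2/2s^2) over [0, W]
        frac = special.erf(truncation / (sigma * math.sqrt(2)))
        ll -= len(d) * math.log(frac)
    return -ll


def fit_halfnormal(
    perp_distances, truncation_m: float | None = None
) -> HalfNormalDetection:
    """Maximum-likelihood σ̂ of the half-normal detection function.

    Untruncated (default) the MLE has the closed form σ̂ = sqrt(Σd²/n).
    With ``truncation_m`` the likelihood is normalized on [0, W] and
    maximized numerically.
    """
    d = np.asarray(perp_distances, dtype=float)
    d = d[np.isfinite(d)]
    if len(d) < 2 or np.count_nonzero(d > 0) < 2:
        raise ValueError("need >=2 strictly positive distances to fit detection")
    if np.any(d < 0):
        raise ValueError("perpendicular distances must be >= 0")
    if truncation_m is None:
        sigma = float(np.sqrt(np.mean(d**2)))
    else:
        res = optimize.minimize_scalar(
            halfnormal_negloglik,
            bounds=(1e-6, max(float(d.max()), truncation_m) * 10),
            args=(d, truncation_m),
            method="bounded",
            options={"xatol": 1e-10},
        )
        sigma = float(res.x)
    ll = -halfnormal_negloglik(sigma, d, truncation_m)
    return HalfNormalDetection(
        sigma_m=sigma, n_distances=len(d), loglik=ll, truncation_m=truncation_m
    )


def detection_probability(d_m, detection: HalfNormalDetection):
    """O_i = exp(−d²/(2σ²)) ∈ (0, 1], strictly decreasing in distance."""
    d = np.asarray(d_m, dtype=float)
    if np.any(d < 0):
        raise ValueError("distance must be >= 0")
    out = np.exp(-(d**2) / (2 * detection.sigma_m**2))
    if out.ndim == 0:
        return float(out)
    return out


def thin_by_detection(
    points: pd.DataFrame,
    detection: HalfNormalDetection,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Rejection step: keep point i iff its uniform draw P_i < O_i.

    Adds ``detection_prob``, ``uniform_draw`` and ``kept`` columns; the
    draws are stored so the thinning is exactly reproducible.
    """
    rng = rng if rng is not None else np.random.default_rng()
    out = points.copy()
    out["detection_prob"] = detection_probability(
        out["perp_distance_m"].to_numpy(), detection
    )
    out["uniform_draw"] = rng.uniform(0.0, 1.0, len(out))
    out["kept"] = out["uniform_draw"] < out["detection_prob"]
    return out


def expected_retained_fraction(
    detection: HalfNormalDetection, half_width_m: float
) -> float:
    """(1/W)·∫₀^W exp(−x²/(2σ²)) dx — the thinning acceptance rate for
    points whose distances are uniform on [0, W]."""
    s = detection.sigma_m
    return float(
        s * math.sqrt(math.pi / 2) * special.erf(half_width_m / (s * math.sqrt(2)))
        / half_width_m
    )


def truncated_halfnormal_cdf(d, sigma: float, half_width_m: float):
    """CDF on [0, W] of the post-thinning distance distribution."""
    d = np.asarray(d, dtype=float)
    z = special.erf(np.clip(d, 0, half_width_m) / (sigma * math.sqrt(2)))
    return z / special.erf(half_width_m / (sigma * math.sqrt(2)))


def generate_available(
    transects,
    surveys: pd.DataFrame,
    detection: HalfNormalDetection,
    half_width_m: float = 200.0,
    multiplier: float = 3.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Steps 1, 3 and 4 for every survey.

    Candidates are drawn per survey (effort = that survey's transect
    length) from an RNG substream keyed by survey id, so adding a survey
    never perturbs the points of another.
    """
    lut = transects if isinstance(transects, dict) else {t.id: t for t in transects}
    frames = []
    for rec in surveys.itertuples(index=False):
        transect = lut[rec.transect_id]
        n = n_available(transect.length_km, multiplier)
        key = zlib.crc32(str(rec.survey_id).encode())  # stable across processes
        sub = np.random.default_rng(
            np.random.SeedSequence([seed & 0x7FFFFFFF, key])
        )
        pts = sample_in_buffer(n, transect, half_width_m, sub)
        pts = thin_by_detection(pts, detection, sub)
        pts.insert(0, "survey_id", rec.survey_id)
        pts.insert(1, "transect_id", rec.transect_id)
        pts.insert(2, "area_id", transect.area_id)
        frames.append(pts)
    if not frames:
        return pd.DataFrame()
    out = pd.concat(frames, ignore_index=True)
    return out
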