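"""Per-species environmental-variation and geography metrics.

Converts a gridded vegetation-greenness/snow time series plus species range
masks into the covariates of the comparative analysis: mean greenness,
within-year (seasonal) and among-year coefficients of variation, weeks of
snow cover, range centroid latitude, and migratory distance.

Aggregation order is spatial-mean-first by default: the series is averaged
over the range cells for each (year, period) and temporal statistics are
taken on that range-mean series.  A per-cell alternative (CV per cell, then
averaged over the range) is available for sensitivity checks.  Coefficients
of variation use the population standard deviation — they describe a fixed
climatological profile, not a sample estimate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synthetic import RasterSeries, RangeMask

__all__ = [
    "range_mean_series",
    "seasonal_cv",
    "among_year_cv",
    "snow_duration",
    "range_centroid",
    "migratory_distance",
    "seasonal_extremes",
    "diet_breadth",
    "compute_env_metrics",
    "haversine_km",
    "EARTH_RADIUS_KM",
]

EARTH_RADIUS_KM = 6371.0088
DAYS_PER_PERIOD = 365.25 / 23.0  # 16-day composite convention


def range_mean_series(raster: RasterSeries, mask: RangeMask) -> np.ndarray:
    """Unweighted mean greenness over the range cells, per (year, period)."""
    if mask.cells.size == 0:
        raise ValueError("empty range mask")
    return raster.evi[mask.cells].mean(axis=0)  # (n_years, n_periods)


def _cv(values: np.ndarray) -> float:
    m = values.mean()
    if m <= 0:
        raise ValueError("coefficient of variation undefined for non-positive mean")
    return float(values.std(ddof=0) / m)


def seasonal_cv(series: np.ndarray) -> float:
    """Within-year CV: average the (year, period) series across years into a
    climatological profile and return population SD / mean of the profile."""
    series = np.atleast_2d(np.asarray(series, dtype=float))
    profile = series.mean(axis=0)
    return _cv(profile)


def among_year_cv(series: np.ndarray) -> float:
    """Among-year CV: population SD / mean of the annual mean greenness."""
    series = np.atleast_2d(np.asarray(series, dtype=float))
    if series.shape[0] < 2:
        raise ValueError("among-year CV needs at least two years")
    return _cv(series.mean(axis=1))


def snow_duration(
    raster: RasterSeries, mask: RangeMask, cell_fraction: float = 0.5
) -> tuple[float, float]:
    """Weeks of snow per year and log(weeks + 1).

    A period counts as snow-covered when at least ``cell_fraction`` of the
    range cells are flagged (>= rule at the boundary); period counts are
    converted to weeks via the 16-day composite calendar and averaged over
    years.  The log uses the natural logarithm.
    """
    frac = raster.snow[mask.cells].mean(axis=0)           # (years, periods)
    periods_per_year = (frac >= cell_fraction).sum(axis=1)
    weeks = float(periods_per_year.mean() * DAYS_PER_PERIOD / 7.0)
    return weeks, float(np.log(weeks + 1.0))


def range_centroid(raster: RasterSeries, mask: RangeMask) -> tuple[float, float]:
    """Spherical centroid (lat, lon) of the range cells via the mean of unit
    vectors — robust across the antimeridian."""
    lat = np.radians(raster.lat[mask.cells])
    lon = np.radians(raster.lon[mask.cells])
    x = np.cos(lat) * np.cos(lon)
    y = np.cos(lat) * np.sin(lon)
    z = np.sin(lat)
    v = np.array([x.mean(), y.mean(), z.mean()])
    norm = np.linalg.norm(v)
    if norm < 1e-9:
        raise ValueError("degenerate centroid: range cells cancel antipodally")
    v /= norm
    return float(np.degrees(np.arcsin(np.clip(v[2], -1, 1)))), float(np.degrees(np.arctan2(v[1], v[0])))


def haversine_km(lat1: float, lon1: float, lat2: float, lon2: float) -> float:
    """Great-circle distance in km (haversine, Earth radius 6371.0088 km)."""
    p1, p2 = np.radians(lat1), np.radians(lat2)
    dphi = p2 - p1
    dlam = np.radians(lon2) - np.radians(lon1)
    a = np.sin(dphi / 2.0) ** 2 + np.cos(p1) * np.cos(p2) * np.sin(dlam / 2.0) ** 2
    return float(2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0, 1))))


def migratory_distance(
    breeding: tuple[float, float], wintering: tuple[float, float]
) -> tuple[float, float]:
    """Great-circle km between breeding and wintering centroids, and its
    log(km + 1)."""
    d = haversine_km(breeding[0], breeding[1], wintering[0], wintering[1])
    return d, float(np.log(d + 1.0))


def seasonal_extremes(
    raster: RasterSeries, mask: RangeMask, n_periods: int = 4
) -> tuple[float, float]:
    """Summer and winter mean greenness of the breeding range: the means of
    the ``n_periods`` highest and lowest climatological periods."""
    profile = range_mean_series(raster, mask).mean(axis=0)
    srt = np.sort(profile)
    return float(srt[-n_periods:].mean()), float(srt[:n_periods].mean())


def diet_breadth(frequencies, similarity=None) -> float:
    """Similarity-weighted inverse-Simpson dietary breadth.

    ``1 / sum_ij p_i p_j s_ij`` where p are diet-category use frequencies and
    ``s`` is a symmetric category-similarity matrix with unit diagonal.  With
    the identity similarity this is the ordinary inverse Simpson index; fully
    similar categories collapse to breadth 1.
    """
    p = np.asarray(frequencies, dtype=float)
    if np.any(p < 0) or not np.isclose(p.sum(), 1.0, atol=1e-8):
        raise ValueError("frequencies must be a probability vector")
    if similarity is None:
        S = np.eye(len(p))
    else:
        S = np.asarray(similarity, dtype=float)
        if S.shape != (len(p), len(p)) or not np.allclose(S, S.T, atol=1e-10):
            raise ValueError("similarity must be a symmetric k x k matrix")
        if not np.allclose(np.diag(S), 1.0, atol=1e-10) or S.min() < 0 or S.max() > 1 + 1e-10:
            raise ValueError("similarity entries must lie in [0, 1] with unit diagonal")
    return float(1.0 / (p @ S @ p))


#: Documented default similarity among broad diet groups (animal / plant /
#: mixed): items within a trophic group are more substitutable than items
#: across groups.  Synthetic stand-in for a supplementary-data matrix.
DEFAULT_DIET_CATEGORIES = ["invertebrates", "vertebrates", "fruit", "seeds", "nectar", "omnivore"]
DEFAULT_DIET_SIMILARITY = np.array(
    [
        [1.0, 0.6, 0.1, 0.1, 0.1, 0.4],
        [0.6, 1.0, 0.1, 0.1, 0.1, 0.4],
        [0.1, 0.1, 1.0, 0.5, 0.5, 0.4],
        [0.1, 0.1, 0.5, 1.0, 0.5, 0.4],
        [0.1, 0.1, 0.5, 0.5, 1.0, 0.4],
        [0.4, 0.4, 0.4, 0.4, 0.4, 1.0],
    ]
)


def _per_cell_cvs(raster: RasterSeries, mask: RangeMask) -> tuple[float, float]:
    """Sensitivity-check variant: CV per cell, then averaged over the range."""
    s_cv, a_cv = [], []
    for c in mask.cells:
        series = raster.evi[c]
        s_cv.append(seasonal_cv(series))
        a_cv.append(among_year_cv(series))
    return float(np.mean(s_cv)), float(np.mean(a_cv))


def compute_env_metrics(
    raster: RasterSeries,
    masks: list[RangeMask],
    per_cell: bool = False,
) -> pd.DataFrame:
    """One row of environmental metrics per species.

    Migrants (separate breeding/wintering masks) get a breeding-range row
    with migratory distance filled in; residents get distance 0.  Columns:
    mean_evi, cv_within_year, cv_among_years, snow_weeks, log_snow,
    breeding_latitude, breeding_longitude, migratory_status,
    migratory_distance_km, log_migratory_distance, evi_summer, evi_winter.
    """
    by_species: dict[str, dict[str, RangeMask]] = {}
    for m in masks:
        by_species.setdefault(m.species, {})[m.season] = m
    rows = []
    for sp, seasons in by_species.items():
        main = seasons.get("resident") or seasons.get("breeding")
        if main is None:
            raise ValueError(f"{sp}: need a resident or breeding mask")
        series = range_mean_series(raster, main)
        if per_cell:
            cv_w, cv_a = _per_cell_cvs(raster, main)
        else:
            cv_w, cv_a = seasonal_cv(series), among_year_cv(series)
        weeks, logw = snow_duration(raster, main)
        clat, clon = range_centroid(raster, main)
        summer, winter = seasonal_extremes(raster, main)
        migratory = "wintering" in seasons
        if migratory:
            wlat, wlon = range_centroid(raster, seasons["wintering"])
            dist, logd = migratory_distance((clat, clon), (wlat, wlon))
        else:
            dist, logd = 0.0, 0.0
        rows.append(
            {
                "species": sp,
                "mean_evi": float(series.mean()),
                "cv_within_year": cv_w,
                "cv_among_years": cv_a,
                "snow_weeks": weeks,
                "log_snow": logw,
                "breeding_latitude": clat,
                "breeding_longitude": clon,
                "migratory_status": "migrant" if migratory else "resident",
                "migratory_distance_km": dist,
                "log_migratory_distance": logd,
                "evi_summer": summer,
                "evi_winter": winter,
            }
        )
    return pd.DataFrame(rows).set_index("species")
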