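"""Station-to-grid interpolation of meteorological point records.

Monthly station measurements (mean temperature, total radiation, ...) are
spread onto the working grid either by ordinary kriging with an exponential
variogram (the default for sparse climate networks) or by inverse-distance
weighting (power 2), the documented fallback when the variogram system is
singular or the network is too small.

Both interpolators are exact: a grid cell co-located with a station
reproduces that station's value, and a constant field interpolates to that
constant everywhere.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.spatial.distance import cdist

from .grids import MonthIndex, RasterGrid

logger = logging.getLogger(__name__)

MIN_STATIONS_IDW = 3
MIN_STATIONS_KRIGING = 5


class InterpolationError(ValueError):
    """Raised for unusable station sets or unsolvable interpolation systems."""


@dataclasses.dataclass(frozen=True)
class StationRecord:
    """One station's measurement for one month, in projected coordinates (m)."""

    station_id: str
    x: float
    y: float
    value: float
    month: MonthIndex


def read_stations_csv(path) -> pd.DataFrame:
    """Load a station table with columns station_id,x,y,year,month,variable,value."""
    df = pd.read_csv(Path(path))
    required = {"station_id", "x", "y", "year", "month", "variable", "value"}
    missing = required - set(df.columns)
    if missing:
        raise InterpolationError(f"station CSV missing columns: {sorted(missing)}")
    return df


def station_records(df: pd.DataFrame, variable: str, month: MonthIndex) -> list[StationRecord]:
    sel = df[(df["variable"] == variable)
             & (df["year"] == month.year) & (df["month"] == month.month)]
    return [StationRecord(str(r.station_id), float(r.x), float(r.y), float(r.value), month)
            for r in sel.itertuples()]


def _station_arrays(stations):
    pts = np.array([[s.x, s.y] for s in stations], dtype=float)
    vals = np.array([s.value for s in stations], dtype=float)
    if not np.isfinite(vals).all():
        raise InterpolationError("non-finite station values")
    return pts, vals


def _grid_cell_centers(template: RasterGrid) -> np.ndarray:
    rows, cols = np.indices(template.shape)
    x, y = template.transform.xy(rows, cols)
    return np.column_stack([x.ravel(), y.ravel()])


def idw(stations, template: RasterGrid, power: float = 2.0) -> RasterGrid:
    """Inverse-distance-weighted interpolation onto the template grid."""
    if len(stations) < MIN_STATIONS_IDW:
        raise InterpolationError(
            f"idw needs at least {MIN_STATIONS_IDW} stations, got {len(stations)}")
    pts, vals = _station_arrays(stations)
    targets = _grid_cell_centers(template)
    d = cdist(targets, pts)
    # exact at stations: a zero-distance target takes the station value outright
    with np.errstate(divide="ignore"):
        w = d ** (-power)
    hit = d == 0.0
    out = np.empty(len(targets))
    any_hit = hit.any(axis=1)
    out[any_hit] = vals[np.argmax(hit[any_hit], axis=1)]
    wn = w[~any_hit]
    out[~any_hit] = (wn @ vals) / wn.sum(axis=1)
    return template.like(out.reshape(template.shape))


def _exponential_variogram(h, nugget, psill, rng):
    return nugget + psill * (1.0 - np.exp(-h / np.maximum(rng, 1e-12)))


def fit_exponential_variogram(pts: np.ndarray, vals: np.ndarray, n_bins: int = 12):
    """Weighted least-squares fit of an exponential semivariogram to binned pairs.

    Returns (nugget, partial_sill, range). Deterministic given inputs.
    """
    d = cdist(pts, pts)
    iu = np.triu_indices(len(pts), k=1)
    h = d[iu]
    gamma = 0.5 * (vals[iu[0]] - vals[iu[1]]) ** 2
    if np.allclose(gamma, 0.0):
        # constant field: pure-nugget-free flat variogram
        return 0.0, 0.0, max(h.max(), 1.0)
    edges = np.linspace(0.0, h.max() * (1 + 1e-9), n_bins + 1)
    which = np.clip(np.digitize(h, edges) - 1, 0, n_bins - 1)
    bh, bg, bw = [], [], []
    for i in range(n_bins):
        m = which == i
        if m.any():
            bh.append(h[m].mean())
            bg.append(gamma[m].mean())
            bw.append(m.sum())
    bh, bg, bw = map(np.asarray, (bh, bg, bw))

    sill0 = vals.var() if vals.var() > 0 else bg.mean()
    x0 = np.array([0.0, max(sill0, 1e-9), max(bh.mean(), 1e-6)])

    def resid(p):
        return np.sqrt(bw) * (_exponential_variogram(bh, *p) - bg)

    fit = least_squares(resid, x0, bounds=([0, 1e-12, 1e-9], [np.inf] * 3))
    return tuple(float(v) for v in fit.x)


def ordinary_kriging(stations, template: RasterGrid,
                     variogram: tuple[float, float, float] | None = None) -> RasterGrid:
    """Ordinary kriging onto the template grid with an exponential variogram.

    The variogram (nugget, partial sill, range) is fitted automatically when
    not supplied.  A singular kriging system raises with advice to fall back
    to IDW.
    """
    if len(stations) < MIN_STATIONS_KRIGING:
        raise InterpolationError(
            f"ordinary kriging needs at least {MIN_STATIONS_KRIGING} stations, "
            f"got {len(stations)}")
    pts, vals = _station_arrays(stations)
    if variogram is None:
        variogram = fit_exponential_variogram(pts, vals)
    nugget, psill, rng = variogram
    if psill <= 0:  # flat variogram: constant field
        return template.like(np.full(template.shape, vals.mean()))

    n = len(pts)
    gamma_ss = _exponential_variogram(cdist(pts, pts), nugget, psill, rng)
    np.fill_diagonal(gamma_ss, 0.0)
    A = np.ones((n + 1, n + 1))
    A[:n, :n] = gamma_ss
    A[n, n] = 0.0

    targets = _grid_cell_centers(template)
    gamma_st = _exponential_variogram(cdist(pts, targets), nugget, psill, rng)
    # exact interpolation at station cells
    gamma_st[cdist(pts, targets) == 0.0] = 0.0
    b = np.vstack([gamma_st, np.ones(len(targets))])
    try:
        weights = np.linalg.solve(A, b)
    except np.linalg.LinAlgError as exc:
        raise InterpolationError(
            "singular kriging system (co-located or degenerate stations); "
            "fall back to method='idw'") from exc
    out = vals @ weights[:n]
    lo, hi = vals.min(), vals.max()
    span = hi - lo
    if span > 0 and (out.min() < lo - 0.1 * span or out.max() > hi + 0.1 * span):
        logger.warning("kriging extrapolates >10%% beyond station range "
                       "[%.4g, %.4g]", lo, hi)
    return template.like(out.reshape(template.shape))


def interpolate_stations(stations, template: RasterGrid,
                         method: str = "ordinary_kriging", **params) -> RasterGrid:
    """Interpolate station records onto the template grid.

    method : {'ordinary_kriging', 'idw'}
    """
    if method == "ordinary_kriging":
        return ordinary_kriging(stations, template, params.get("variogram"))
    if method == "idw":
        return idw(stations, template, params.get("power", 2.0))
    raise ValueError(f"unknown interpolation method {method!r}")
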