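"""The CASA light-use-efficiency NPP core.

Monthly net primary productivity (gC/m^2) is estimated per pixel as

    NPP = APAR * E

where APAR = 0.5 * SOL * FPAR is the absorbed photosynthetically active
radiation (half the monthly total solar radiation SOL, MJ/m^2, times the
canopy absorption fraction FPAR), and the realized light-use efficiency

    E = TE1 * TE2 * WE * Emax

scales the vegetation class's maximum efficiency Emax (gC/MJ) by two
temperature stress factors and a water stress factor:

    SR   = (1 + NDVI) / (1 - NDVI)                      (simple ratio)
    FPAR = min((SR - SRmin) / (SRmax - SRmin), 0.95)    (floored at 0)
    TE1  = 0.8 + 0.02 Topt - 0.0005 Topt^2
    TE2  = 1.1841 / (1 + exp(0.2 (Topt - 10 - T)))
                 / (1 + exp(0.3 (-Topt - 10 + T)))
    WE   = 0.5 + 0.5 ET / ETp

Topt is the mean air temperature of the month in which the pixel's NDVI
peaks within the year.  SRmax and Emax are per-land-cover constants for
high-cold-altitude southwest China (shipped as the default parameter table);
SRmin = 1.08 is the simple ratio of unvegetated land.
"""

from __future__ import annotations

import dataclasses
import importlib.resources
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .grids import MonthIndex, RasterGrid

logger = logging.getLogger(__name__)

SR_MIN_DEFAULT = 1.08
FPAR_CAP_DEFAULT = 0.95


class CasaError(ValueError):
    pass


class ParameterLookupError(CasaError):
    """A land-cover code has no entry in the parameter table."""


@dataclasses.dataclass
class CasaParams:
    """Per-land-cover SRmax / Emax lookup plus the global SRmin and FPAR cap."""

    per_class: dict[int, tuple[float, float]]  # code -> (sr_max, e_max)
    sr_min: float = SR_MIN_DEFAULT
    fpar_cap: float = FPAR_CAP_DEFAULT
    names: dict[int, str] = dataclasses.field(default_factory=dict)

    def __post_init__(self):
        if not 0 < self.fpar_cap <= 1:
            raise CasaError(f"fpar_cap must be in (0, 1], got {self.fpar_cap}")
        for code, (sr_max, e_max) in self.per_class.items():
            if sr_max <= self.sr_min:
                raise CasaError(f"class {code}: sr_max {sr_max} <= sr_min {self.sr_min}")
            if e_max <= 0:
                raise CasaError(f"class {code}: e_max must be positive, got {e_max}")

    @classmethod
    def from_table(cls, df: pd.DataFrame, sr_min: float = SR_MIN_DEFAULT,
                   fpar_cap: float = FPAR_CAP_DEFAULT) -> "CasaParams":
        per_class = {int(r.class_code): (float(r.sr_max), float(r.e_max))
                     for r in df.itertuples()}
        names = ({int(r.class_code): str(r.class_name) for r in df.itertuples()}
                 if "class_name" in df.columns else {})
        return cls(per_class, sr_min, fpar_cap, names)

    @classmethod
    def from_csv(cls, path, **kw) -> "CasaParams":
        return cls.from_table(pd.read_csv(Path(path)), **kw)

    @classmethod
    def default(cls) -> "CasaParams":
        """The shipped high-cold-altitude vegetation parameter set."""
        ref = importlib.resources.files("casanpp.data") / "vegetation_params.csv"
        with importlib.resources.as_file(ref) as p:
            return cls.from_csv(p)

    def _lookup(self, land_cover: RasterGrid, which: int) -> np.ndarray:
        codes = land_cover.values
        valid = land_cover.mask()
        present = np.unique(codes[valid]).astype(int)
        unknown = [c for c in present if c not in self.per_class]
        if unknown:
            raise ParameterLookupError(
                f"land-cover code(s) {unknown} missing from the parameter table")
        out = np.full(codes.shape, np.nan)
        for code in present:
            out[valid & (codes == code)] = self.per_class[int(code)][which]
        return out

    def sr_max_grid(self, land_cover: RasterGrid) -> np.ndarray:
        return self._lookup(land_cover, 0)

    def e_max_grid(self, land_cover: RasterGrid) -> np.ndarray:
        return self._lookup(land_cover, 1)


@dataclasses.dataclass
class MonthlyScene:
    """Co-registered monthly inputs for one CASA evaluation.

    ET > ETp violates the water-stress range and is clamped to equality with
    a logged count at construction.
    """

    ndvi: RasterGrid
    temperature: RasterGrid
    solar: RasterGrid
    et: RasterGrid
    etp: RasterGrid
    land_cover: RasterGrid
    month: MonthIndex

    def __post_init__(self):
        for name in ("temperature", "solar", "et", "etp", "land_cover"):
            self.ndvi.require_aligned(getattr(self, name), f"ndvi and {name}")
        both = self.et.mask() & self.etp.mask()
        excess = both & (self.et.values > self.etp.values)
        if excess.any():
            logger.warning("clamping ET > ETp in %d cells", int(excess.sum()))
            v = self.et.values.copy()
            v[excess] = self.etp.values[excess]
            self.et = self.et.like(v)


def _binary_op(out, *grids):
    """Nodata propagation: output nodata wherever any input is nodata."""
    template = grids[0]
    ok = np.ones(template.shape, dtype=bool)
    for g in grids:
        ok &= g.mask()
    return template.like(np.where(ok, out, template.nodata))


def simple_ratio(ndvi: RasterGrid, clamp: float = 0.999) -> RasterGrid:
    """SR = (1 + NDVI) / (1 - NDVI); NDVI clamped to ±clamp to stay finite."""
    v = np.clip(ndvi.values, -clamp, clamp)
    sr = (1.0 + v) / (1.0 - v)
    return _binary_op(sr, ndvi)


def fpar(sr: RasterGrid, land_cover: RasterGrid, params: CasaParams) -> RasterGrid:
    """Canopy absorption fraction: capped linear ramp of SR between SRmin and SRmax."""
    sr.require_aligned(land_cover, "SR and land cover")
    sr_max = params.sr_max_grid(land_cover)
    frac = (sr.values - params.sr_min) / (sr_max - params.sr_min)
    out = np.clip(np.minimum(frac, params.fpar_cap), 0.0, None)
    return _binary_op(out, sr, land_cover)


def apar(solar: RasterGrid, fpar_grid: RasterGrid) -> RasterGrid:
    """APAR = 0.5 * SOL * FPAR (MJ/m^2). Negative solar radiation is rejected."""
    solar.require_aligned(fpar_grid, "solar and FPAR")
    if (solar.values[solar.mask()] < 0).any():
        raise CasaError("negative solar radiation")
    return _binary_op(0.5 * solar.values * fpar_grid.values, solar, fpar_grid)


def optimum_temperature(ndvi_series: list[RasterGrid],
                        temp_series: list[RasterGrid]) -> RasterGrid:
    """Per-cell mean temperature of the month with maximal NDVI (ties: earliest)."""
    if not ndvi_series:
        raise CasaError("empty NDVI series")
    if len(ndvi_series) != len(temp_series):
        raise CasaError("NDVI and temperature series lengths differ")
    ref = ndvi_series[0]
    for g in ndvi_series[1:] + list(temp_series):
        ref.require_aligned(g, "series grids")
    ndvi = np.stack([g.masked() for g in ndvi_series])
    temp = np.stack([g.masked() for g in temp_series])
    with np.errstate(invalid="ignore"):
        filled = np.where(np.isnan(ndvi), -np.inf, ndvi)
        best = filled.argmax(axis=0)  # argmax takes the first (earliest) maximum
    any_valid = np.isfinite(filled).any(axis=0)
    rows, cols = np.indices(ref.shape)
    topt = temp[best, rows, cols]
    topt = np.where(any_valid & ~np.isnan(topt), topt, ref.nodata)
    return ref.like(topt)


def te1(topt: RasterGrid) -> RasterGrid:
    """Low/high-temperature biochemical stress, floored at 0 (non-physical below)."""
    t = topt.values
    out = np.clip(0.8 + 0.02 * t - 0.0005 * t * t, 0.0, None)
    return _binary_op(out, topt)


def te2(topt: RasterGrid, temperature: RasterGrid) -> RasterGrid:
    """Efficiency falloff as the month's temperature departs from the optimum."""
    topt.require_aligned(temperature, "Topt and temperature")
    to, t = topt.values, temperature.values
    with np.errstate(over="ignore"):
        out = (1.1841 / (1.0 + np.exp(0.2 * (to - 10.0 - t)))
               / (1.0 + np.exp(0.3 * (-to - 10.0 + t))))
    return _binary_op(out, topt, temperature)


def water_stress(et: RasterGrid, etp: RasterGrid) -> RasterGrid:
    """WE = 0.5 + 0.5 ET/ETp, clamped to [0.5, 1]; ETp = 0 cells take the dry floor."""
    et.require_aligned(etp, "ET and ETp")
    if (et.values[et.mask()] < 0).any():
        raise CasaError("negative ET")
    if (etp.values[etp.mask()] < 0).any():
        raise CasaError("negative ETp")
    zero = etp.mask() & (etp.values == 0)
    if zero.any():
        logger.info("%d cells with ETp = 0 assigned WE = 0.5", int(zero.sum()))
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(etp.values != 0, et.values / etp.values, 0.0)
    out = np.clip(0.5 + 0.5 * ratio, 0.5, 1.0)
    return _binary_op(out, et, etp)


def light_use_efficiency(te1_grid: RasterGrid, te2_grid: RasterGrid,
                         we: RasterGrid, land_cover: RasterGrid,
                         params: CasaParams) -> RasterGrid:
    """E = TE1 * TE2 * WE * Emax (gC/MJ), Emax looked up per cell class."""
    for g in (te2_grid, we, land_cover):
        te1_grid.require_aligned(g, "efficiency factors")
    e_max = params.e_max_grid(land_cover)
    out = te1_grid.values * te2_grid.values * we.values * e_max
    return _binary_op(out, te1_grid, te2_grid, we, land_cover)


def npp(apar_grid: RasterGrid, efficiency: RasterGrid) -> RasterGrid:
    """NPP = APAR * E (gC/m^2 per month), floored at 0."""
    apar_grid.require_aligned(efficiency, "APAR and efficiency")
    out = np.clip(apar_grid.values * efficiency.values, 0.0, None)
    return _binary_op(out, apar_grid, efficiency)


def run_casa(scene: MonthlyScene, topt: RasterGrid, params: CasaParams | None = None,
             return_intermediates: bool = False):
    """Evaluate the full CASA chain for one monthly scene.

    Returns the monthly NPP grid, or ``(npp, intermediates)`` where
    intermediates maps stage names (sr, fpar, apar, te1, te2, we, efficiency)
    to their grids.
    """
    params = params or CasaParams.default()
    stages = {}
    try:
        stages["sr"] = simple_ratio(scene.ndvi)
        stages["fpar"] = fpar(stages["sr"], scene.land_cover, params)
        stages["apar"] = apar(scene.solar, stages["fpar"])
        stages["te1"] = te1(topt)
        stages["te2"] = te2(topt, scene.temperature)
        stages["we"] = water_stress(scene.et, scene.etp)
        stages["efficiency"] = light_use_efficiency(
            stages["te1"], stages["te2"], stages["we"], scene.land_cover, params)
        result = npp(stages["apar"], stages["efficiency"])
    except Exception as exc:
        done = list(stages)
        raise CasaError(f"CASA failed after stages {done}: {exc}") from exc
    if return_intermediates:
        return result, stages
    return result


def casa_scalar(ndvi: float, temperature: float, solar: float, et: float, etp: float,
                topt: float, sr_max: float, e_max: float,
                sr_min: float = SR_MIN_DEFAULT, fpar_cap: float = FPAR_CAP_DEFAULT) -> float:
    """Scalar single-pixel evaluation of the full chain (independent of the grid path).

    Useful as a cross-check of the raster pipeline at sampled cells.
    """
    import math

    ndvi = min(max(ndvi, -0.999), 0.999)
    sr = (1.0 + ndvi) / (1.0 - ndvi)
    f = max(0.0, min((sr - sr_min) / (sr_max - sr_min), fpar_cap))
    a = 0.5 * solar * f
    t1 = max(0.0, 0.8 + 0.02 * topt - 0.0005 * topt ** 2)
    t2 = (1.1841 / (1.0 + math.exp(0.2 * (topt - 10.0 - temperature)))
          / (1.0 + math.exp(0.3 * (-topt - 10.0 + temperature))))
    ratio = et / etp if etp != 0 else 0.0
    we = min(1.0, max(0.5, 0.5 + 0.5 * min(ratio, 1.0)))
    return max(0.0, a * t1 * t2 * we * e_max)
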