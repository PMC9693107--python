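"""Earthquake impact on vegetation productivity: vulnerability, resilience, impact.

The assessment compares monthly NPP across the earthquake month:

* dur-quake change:  dNPP = NPP(quake month) - NPP(month before)
* post-quake change: dNPP = NPP(month after) - NPP(quake month)

Changes are min-max normalized to [0, 1] with anchors taken over the whole
region, binned into five equal classes (0-0.2, ..., 0.8-1), and summarized
per zone by the expected value of the class mid-values (0.1, 0.3, 0.5, 0.7,
0.9) weighted by the per-class area proportions B:

    S (vulnerability) = sum_i A_i B_i   over the dur-quake damage field
    R (resilience)    = sum_i A_i B_i   over the post-quake recovery field
    I (impact)        = S * (1 - R)     the residual impact after self-recovery

Two normalization conventions are provided.  The default "oriented" modes
select the dominant sign of each period — declines for damage, gains for
recovery — and scale magnitudes so the region's largest decline (or gain)
maps to 1.  The ``raw`` mode is the literal signed min-max over all cells.
Because the dur-quake field is almost entirely negative and the post-quake
field almost entirely positive in a shocked scene, the two conventions rank
zones identically; the oriented one makes the indices direct damage and
recovery magnitudes.
"""

from __future__ import annotations

import dataclasses
import importlib.resources
import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .grids import MonthIndex, RasterGrid
from .zonal import ZoneSet

logger = logging.getLogger(__name__)

BIN_EDGES = (0.0, 0.2, 0.4, 0.6, 0.8, 1.0)
MID_VALUES = (0.1, 0.3, 0.5, 0.7, 0.9)
REGION_CODE = 0  # pseudo-zone covering every valid cell


class ImpactError(ValueError):
    pass


@dataclasses.dataclass
class ChangeGrid:
    """Per-pixel NPP difference across one month boundary."""

    delta: RasterGrid
    period_label: str  # {dur_quake, post_quake}
    month_before: MonthIndex | None = None
    month_after: MonthIndex | None = None

    def __post_init__(self):
        if self.period_label not in ("dur_quake", "post_quake"):
            raise ImpactError(f"unknown period label {self.period_label!r}")
        if (self.month_before is not None and self.month_after is not None
                and not self.month_after > self.month_before):
            raise ImpactError("month_after must follow month_before")


@dataclasses.dataclass
class NormalizedChange:
    """Min-max normalized change field with its region-wide anchors."""

    values: RasterGrid  # in [0, 1] on selected cells, nodata elsewhere
    n_min: float
    n_max: float
    orientation: str  # {damage, recovery, raw}


@dataclasses.dataclass(frozen=True)
class BinSpec:
    edges: tuple = BIN_EDGES
    mid_values: tuple = MID_VALUES

    def __post_init__(self):
        if len(self.edges) != len(self.mid_values) + 1:
            raise ImpactError("edges must be one longer than mid_values")
        mids = [(a + b) / 2 for a, b in zip(self.edges, self.edges[1:])]
        if not np.allclose(mids, self.mid_values):
            raise ImpactError("mid_values must be the bin midpoints")


@dataclasses.dataclass
class ImpactResult:
    """One zone's assessment row: bin proportions, S, R, I and sign fractions."""

    zone: int
    name: str
    dur_proportions: np.ndarray  # 5-vector B for S
    post_proportions: np.ndarray  # 5-vector B for R
    vulnerability_s: float
    resilience_r: float
    impact_i: float
    dur_sign_fractions: tuple[float, float]  # (fraction dNPP<0, fraction dNPP>0)
    post_sign_fractions: tuple[float, float]
    defined: bool = True


def npp_change(npp_after: RasterGrid, npp_before: RasterGrid, label: str,
               month_before: MonthIndex | None = None,
               month_after: MonthIndex | None = None) -> ChangeGrid:
    """delta = after - before, valid where both inputs are valid."""
    npp_after.require_aligned(npp_before, "NPP grids")
    ok = npp_after.mask() & npp_before.mask()
    delta = np.where(ok, npp_after.values - npp_before.values, npp_after.nodata)
    return ChangeGrid(npp_after.like(delta), label, month_before, month_after)


def sign_partition(change: ChangeGrid, zones: ZoneSet,
                   include_region: bool = True) -> pd.DataFrame:
    """Per-zone fractions of cells with dNPP < 0 and dNPP > 0.

    Exact zeros are reported in their own column and excluded from both
    signed fractions; the three columns sum to 1 per zone.
    """
    g = change.delta
    g.require_aligned(zones.labels, "change and zones")
    valid = g.mask()
    rows = []
    items = ([(REGION_CODE, "region")] if include_region else []) + \
        [(c, zones.names[c]) for c in zones.codes]
    for code, name in items:
        m = valid if code == REGION_CODE else (zones.mask_of(code) & valid)
        n = int(m.sum())
        if n == 0:
            rows.append({"zone": code, "name": name, "frac_negative": np.nan,
                         "frac_positive": np.nan, "frac_zero": np.nan,
                         "n_cells": 0, "defined": False})
            continue
        d = g.values[m]
        rows.append({"zone": code, "name": name,
                     "frac_negative": float((d < 0).mean()),
                     "frac_positive": float((d > 0).mean()),
                     "frac_zero": float((d == 0).mean()),
                     "n_cells": n, "defined": True})
    return pd.DataFrame(rows)


def normalize_change(change: ChangeGrid, orientation: str = "damage") -> NormalizedChange:
    """Min-max normalize the change field over the whole region.

    damage   : select dNPP < 0, normalize |dNPP| so the largest decline -> 1
    recovery : select dNPP > 0, normalize the gain so the largest gain -> 1
    raw      : signed min-max over every valid cell (region min -> 0, max -> 1)
    """
    g = change.delta
    valid = g.mask()
    d = g.values
    if orientation == "raw":
        sel = valid
        vals = d
    elif orientation == "damage":
        sel = valid & (d < 0)
        vals = -d
    elif orientation == "recovery":
        sel = valid & (d > 0)
        vals = d
    else:
        raise ImpactError(f"unknown orientation {orientation!r}")
    if not sel.any():
        raise ImpactError(f"no cells selected for orientation {orientation!r}")
    if orientation == "raw":
        n_min, n_max = float(d[sel].min()), float(d[sel].max())
    else:
        n_min, n_max = 0.0, float(vals[sel].max())
    if n_max == n_min:
        raise ImpactError("degenerate change field: n_max == n_min")
    norm = np.where(sel, (vals - n_min) / (n_max - n_min), g.nodata)
    return NormalizedChange(g.like(norm), n_min, n_max, orientation)


def bin_proportions(norm: NormalizedChange, zones: ZoneSet,
                    bins: BinSpec = BinSpec(),
                    include_region: bool = True) -> dict[int, np.ndarray]:
    """Per-zone area proportions of selected cells in the five normalized bins.

    Bins are half-open [lo, hi), last bin closed; a zone with no selected
    cells maps to None (undefined).
    """
    g = norm.values
    g.require_aligned(zones.labels, "normalized change and zones")
    sel = g.mask()
    edges = np.asarray(bins.edges)
    n_bins = len(bins.mid_values)
    out: dict[int, np.ndarray | None] = {}
    codes = ([REGION_CODE] if include_region else []) + zones.codes
    for code in codes:
        m = sel if code == REGION_CODE else (sel & zones.mask_of(code))
        if not m.any():
            out[code] = None
            continue
        idx = np.clip(np.digitize(g.values[m], edges[1:], right=False), 0, n_bins - 1)
        counts = np.bincount(idx, minlength=n_bins).astype(float)
        out[code] = counts / counts.sum()
    return out


def expected_index(proportions, bins: BinSpec = BinSpec()) -> float:
    """Expected value of the bin mid-values under the area proportions B.

    B must sum to 1; sums in [0.999, 1.001] (printed-table rounding) are
    renormalized with a warning.
    """
    b = np.asarray(proportions, dtype=float)
    if b.shape != (len(bins.mid_values),):
        raise ImpactError(f"expected {len(bins.mid_values)} proportions, got {b.shape}")
    if (b < 0).any():
        raise ImpactError("negative proportion")
    s = b.sum()
    if abs(s - 1.0) > 1e-6:
        if 0.999 <= s <= 1.001:
            warnings.warn(f"proportions sum to {s:.4f}; renormalizing", stacklevel=2)
            b = b / s
        else:
            raise ImpactError(f"proportions sum to {s}, not 1")
    return float(b @ np.asarray(bins.mid_values))


def impact_coefficient(s: float, r: float) -> float:
    """I = S * (1 - R): the damage that self-recovery does not undo."""
    if not (0 <= s <= 1 and 0 <= r <= 1):
        raise ImpactError(f"indices must lie in [0, 1], got S={s}, R={r}")
    return s * (1.0 - r)


def assess(npp_before: RasterGrid, npp_quake: RasterGrid, npp_after: RasterGrid,
           zones: ZoneSet, orientation: str = "oriented",
           bins: BinSpec = BinSpec()) -> list[ImpactResult]:
    """Full per-zone assessment from the three monthly NPP grids.

    orientation 'oriented' uses damage-magnitude normalization for S and
    recovery-magnitude for R; 'raw' uses the literal signed min-max for both.
    A region-wide row (zone code 0) is always included.
    """
    dur = npp_change(npp_quake, npp_before, "dur_quake")
    post = npp_change(npp_after, npp_quake, "post_quake")
    dur_orient = "damage" if orientation == "oriented" else "raw"
    post_orient = "recovery" if orientation == "oriented" else "raw"
    dur_norm = normalize_change(dur, dur_orient)
    post_norm = normalize_change(post, post_orient)
    dur_b = bin_proportions(dur_norm, zones, bins)
    post_b = bin_proportions(post_norm, zones, bins)
    dur_signs = sign_partition(dur, zones).set_index("zone")
    post_signs = sign_partition(post, zones).set_index("zone")

    results = []
    for code in [REGION_CODE] + zones.codes:
        name = "region" if code == REGION_CODE else zones.names[code]
        bd, bp = dur_b[code], post_b[code]
        if bd is None or bp is None:
            results.append(ImpactResult(code, name, bd, bp, np.nan, np.nan, np.nan,
                                        (np.nan, np.nan), (np.nan, np.nan),
                                        defined=False))
            continue
        s = expected_index(bd, bins)
        r = expected_index(bp, bins)
        results.append(ImpactResult(
            code, name, bd, bp, s, r, impact_coefficient(s, r),
            (float(dur_signs.loc[code, "frac_negative"]),
             float(dur_signs.loc[code, "frac_positive"])),
            (float(post_signs.loc[code, "frac_negative"]),
             float(post_signs.loc[code, "frac_positive"]))))
    return results


def assess_frame(results: list[ImpactResult]) -> pd.DataFrame:
    """Flatten assessment rows into a report table (zone, b1..b5 per period, S, R, I)."""
    rows = []
    for r in results:
        row = {"zone": r.zone, "name": r.name}
        for i in range(5):
            row[f"dur_b{i + 1}"] = (r.dur_proportions[i]
                                    if r.dur_proportions is not None else np.nan)
        for i in range(5):
            row[f"post_b{i + 1}"] = (r.post_proportions[i]
                                     if r.post_proportions is not None else np.nan)
        row.update(S=r.vulnerability_s, R=r.resilience_r, I=r.impact_i,
                   dur_frac_neg=r.dur_sign_fractions[0],
                   dur_frac_pos=r.dur_sign_fractions[1],
                   post_frac_neg=r.post_sign_fractions[0],
                   post_frac_pos=r.post_sign_fractions[1],
                   defined=r.defined)
        rows.append(row)
    return pd.DataFrame(rows)


def load_reference_proportions() -> pd.DataFrame:
    """The published per-intensity 5-bin area proportions for the 2017
    Jiuzhaigou Ms7.0 earthquake (dur- and post-quake periods, percent)."""
    ref = importlib.resources.files("casanpp.data") / "jiuzhaigou_intensity_proportions.csv"
    with importlib.resources.as_file(ref) as p:
        return pd.read_csv(p)


def indices_from_proportions(table: pd.DataFrame, bins: BinSpec = BinSpec(),
                             decimals: int = 3) -> pd.DataFrame:
    """Compute S, R and I per zone from a printed-proportions table.

    The table has columns ``period`` (dur_quake / post_quake), ``zone`` and
    ``b1..b5`` in percent.  Indices are reported rounded to ``decimals``; I is
    computed from the rounded S and R so that every reported (S, R, I) triple
    is internally consistent at the reporting precision.
    """
    bcols = [f"b{i}" for i in range(1, 6)]
    out = {}
    for _, row in table.iterrows():
        b = row[bcols].to_numpy(dtype=float) / 100.0
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            idx = expected_index(b, bins)
        zone = row["zone"]
        out.setdefault(zone, {})[row["period"]] = round(idx, decimals)
    rows = []
    for zone, d in out.items():
        s, r = d.get("dur_quake", np.nan), d.get("post_quake", np.nan)
        i = round(impact_coefficient(s, r), decimals) if np.isfinite(s) and np.isfinite(r) else np.nan
        rows.append({"zone": zone, "S": s, "R": r, "I": i})
    return pd.DataFrame(rows)
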