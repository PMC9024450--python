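"""Step-wise potential-yield model and county aggregation.

Potential grain yield is estimated per cultivated cell by successively
correcting the photosynthetic production potential for temperature, water and
soil:

    YQ = (1e5 / C) * F * Q * E          photosynthetic potential, kg ha^-1
    YT = (T / 30) * YQ                  light-temperature potential
    YW = f(w) * YT                      climatic potential
    YS = f(s) * YW                      soil potential

with C the calorific value of dry matter (kcal g^-1), F the light-energy
utilization rate, Q the growing-season total solar radiation (kcal cm^-2),
E the crop economic coefficient, and f(w), f(s) in [0, 1].  Unit check for
YQ: (kcal cm^-2) / (kcal g^-1) = g cm^-2, and 1 g cm^-2 = 1e5 kg ha^-1.

The T/30 ratio is clamped to [0, 1] by default so each step can only reduce
yield, preserving the monotone chain YQ >= YT >= YW >= YS; the unclamped mode
is kept for sensitivity runs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from shapely.strtree import STRtree
from shapely.geometry import Point

from .io_core import (
    ClimateFieldSet,
    CULTIVATED_CLASSES,
    RasterGrid,
    logger,
)

T_REF = 30.0  # temperature scaling denominator, degC (fixed by the model)


@dataclass
class StepModelParams:
    """Parameters of the step-wise revision model.

    C: calorific value of dry matter, kcal g^-1 (4.25 for rice/corn).
    F: light-energy utilization rate, dimensionless (0.03).
    E: crop economic coefficient — harvestable fraction of dry matter (0.4).
    clamp_temperature_ratio: clamp T/30 into [0, 1] (default on).
    """

    C: float = 4.25
    F: float = 0.03
    E: float = 0.4
    clamp_temperature_ratio: bool = True

    def __post_init__(self) -> None:
        if self.C <= 0:
            raise ValueError("C must be positive")
        if not 0 < self.F < 1:
            raise ValueError("F must be in (0, 1)")
        if not 0 < self.E <= 0.5:
            raise ValueError("E must be in (0, 0.5]")


@dataclass
class PotentialYieldGrid:
    """Co-registered YQ/YT/YW/YS surfaces, kg ha^-1."""

    epoch: str
    YQ: RasterGrid
    YT: RasterGrid
    YW: RasterGrid
    YS: RasterGrid


def photosynthetic_potential(Q, params: StepModelParams = StepModelParams()):
    """YQ = (1e5 / C) * F * Q * E, kg ha^-1 from Q in kcal cm^-2.

    NaN (nodata) propagates; negative radiation is a physical impossibility
    and raises.
    """
    Q = np.asarray(Q, dtype=float)
    if np.any(Q[~np.isnan(Q)] < 0):
        raise ValueError("negative solar radiation is physically impossible")
    return (1e5 / params.C) * params.F * Q * params.E


def light_temperature_potential(T, YQ, params: StepModelParams = StepModelParams()):
    """YT = (T/30) * YQ with the ratio clamped to [0, 1] in clamped mode."""
    T = np.asarray(T, dtype=float)
    ratio = T / T_REF
    if params.clamp_temperature_ratio:
        ratio = np.clip(ratio, 0.0, 1.0)
    else:
        logger.info("temperature ratio unclamped (sensitivity mode)")
    return ratio * np.asarray(YQ, dtype=float)


def climatic_potential(fw, YT):
    """YW = f(w) * YT; f(w) must lie in [0, 1]."""
    fw = np.asarray(fw, dtype=float)
    valid = fw[~np.isnan(fw)]
    if np.any((valid < 0) | (valid > 1)):
        raise ValueError("water correction coefficient f(w) must be within [0, 1]")
    return fw * np.asarray(YT, dtype=float)


def soil_potential(fs, YW):
    """YS = f(s) * YW; f(s) must lie in (0, 1]."""
    fs = np.asarray(fs, dtype=float)
    valid = fs[~np.isnan(fs)]
    if np.any((valid <= 0) | (valid > 1)):
        raise ValueError("soil correction coefficient f(s) must be within (0, 1]")
    return fs * np.asarray(YW, dtype=float)


def potential_yield_chain(
    fields: ClimateFieldSet, params: StepModelParams = StepModelParams()
) -> PotentialYieldGrid:
    """Evaluate the four-step chain on co-registered climate layers.

    Nodata in any input layer propagates to all outputs at that cell.
    """
    Q = fields.Q.masked()
    T = fields.T.masked()
    fw = fields.fw.masked()
    fs = fields.fs.masked()
    yq = photosynthetic_potential(Q, params)
    yt = light_temperature_potential(T, yq, params)
    yw = climatic_potential(fw, yt)
    ys = soil_potential(fs, yw)
    nodata = fields.Q.nodata_value

    def _wrap(arr: np.ndarray) -> RasterGrid:
        out = arr.copy()
        out[np.isnan(out)] = nodata
        return RasterGrid(
            values=out,
            transform=fields.Q.transform,
            nodata_value=nodata,
            crs_id=fields.Q.crs_id,
            units="kg ha-1",
        )

    return PotentialYieldGrid(
        epoch=fields.epoch, YQ=_wrap(yq), YT=_wrap(yt), YW=_wrap(yw), YS=_wrap(ys)
    )


def assign_cells_to_counties(grid: RasterGrid, counties: pd.DataFrame) -> np.ndarray:
    """Map each cell to a county index by its center point, -1 if outside.

    Center-point assignment is the deterministic zonal rule used throughout;
    a cell belongs to the county polygon containing its center.
    """
    nrows, ncols = grid.shape
    xs, ys = grid.transform.cell_centers(nrows, ncols)
    points = [Point(x, y) for x, y in zip(xs.ravel(), ys.ravel())]
    tree = STRtree(counties["geometry"].tolist())
    assignment = np.full(nrows * ncols, -1, dtype=int)
    hit_pt, hit_poly = tree.query(points, predicate="intersects")
    # a center on a shared edge intersects both polygons; keep the first
    # (lowest county index) for determinism
    order = np.lexsort((hit_poly, hit_pt))
    hit_pt, hit_poly = hit_pt[order], hit_poly[order]
    first = np.unique(hit_pt, return_index=True)[1]
    assignment[hit_pt[first]] = hit_poly[first]
    return assignment.reshape(nrows, ncols)


def county_mean_potential(
    grid: PotentialYieldGrid,
    landuse: RasterGrid,
    counties: pd.DataFrame,
    cultivated_classes: tuple[int, ...] = CULTIVATED_CLASSES,
) -> pd.DataFrame:
    """Mean YS over cultivated cells per county, reported in t ha^-1.

    Cells count toward a county when their center falls inside it and their
    land-use class is cultivated (paddy or dryland).  Counties with no
    cultivated cell — including counties entirely outside the raster — are
    returned with a missing mean, never zero.
    """
    ys = grid.YS.masked()
    lu = landuse.values
    assignment = assign_cells_to_counties(grid.YS, counties)
    cultivated = np.isin(lu, cultivated_classes) & ~landuse.mask() & ~np.isnan(ys)
    rows = []
    for idx, county_id in enumerate(counties["county_id"]):
        sel = (assignment == idx) & cultivated
        n = int(sel.sum())
        mean_t_ha = float(ys[sel].mean() / 1000.0) if n else np.nan
        rows.append(
            {
                "county_id": county_id,
                "epoch": grid.epoch,
                "ys_mean": mean_t_ha,
                "n_cultivated_cells": n,
            }
        )
    out = pd.DataFrame(rows)
    n_missing = int(out["ys_mean"].isna().sum())
    if n_missing:
        logger.warning("%d counties have no cultivated cells; means flagged missing", n_missing)
    return out
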