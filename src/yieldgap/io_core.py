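"""Raster, vector and tabular I/O plus shared conventions.

Rasters are single-band grids in the Esri ASCII grid format (``.asc``):
row-major, origin at the top-left corner, square cells, half-open pixel
extents.  A cell belongs to the polygon containing its *center* (center-point
zonal assignment).  The format has no CRS slot, so an optional sidecar file
``<name>.crs`` carries a free-text CRS identifier; all layers of one run must
agree on it.  County polygons travel as GeoJSON; per-county/per-epoch panels
as CSV.

Internal units: solar radiation Q in kcal cm^-2 (growing-season total),
temperature T in degC (growing-season mean), yields in kg ha^-1 internally and
t ha^-1 (/1000) in reports.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from shapely.geometry import mapping, shape
from shapely.validation import explain_validity

logger = logging.getLogger("yieldgap")

#: Table-1 determinant abbreviations, grouped by category.
CLIMATIC_VARS = ["SH", "SMI", "Temp", "Prec"]
SOCIOECONOMIC_VARS = ["RSP", "LDD", "UR", "FL", "GDPPC", "RAGDP", "PCAI"]
LANDUSE_VARS = ["DEM", "Slope", "RPF", "NP", "PD", "LPI", "CLPL"]
HUMAN_INVESTMENT_VARS = ["PSAGC", "MCI", "APPA", "REC", "FPA", "TPA", "IA", "PAMPA", "ASFF"]
DETERMINANT_VARS = CLIMATIC_VARS + SOCIOECONOMIC_VARS + LANDUSE_VARS + HUMAN_INVESTMENT_VARS

#: variable -> category name
CATEGORY_MAP = {
    **{v: "climatic" for v in CLIMATIC_VARS},
    **{v: "socioeconomic" for v in SOCIOECONOMIC_VARS},
    **{v: "land_use" for v in LANDUSE_VARS},
    **{v: "human_investment" for v in HUMAN_INVESTMENT_VARS},
}

#: land-use class codes used throughout
LANDUSE_PADDY = 1
LANDUSE_DRYLAND = 2
LANDUSE_OTHER = 0
CULTIVATED_CLASSES = (LANDUSE_PADDY, LANDUSE_DRYLAND)

MANDATORY_PANEL_COLUMNS = ["county_id", "epoch", "actual_farm_yield", "sown_area_grain"]


class YieldGapIOError(Exception):
    """Raised for malformed or inconsistent input files."""


@dataclass
class GridTransform:
    """Affine georeference of an axis-aligned, square-celled grid.

    ``x0, y0`` is the *top-left* corner of the top-left cell; ``cell_size`` is
    the positive edge length.  Rows increase southward.
    """

    x0: float
    y0: float
    cell_size: float

    def __post_init__(self) -> None:
        if self.cell_size <= 0:
            raise ValueError("cell size must be strictly positive")

    def cell_centers(self, nrows: int, ncols: int) -> tuple[np.ndarray, np.ndarray]:
        """Return (xs, ys) center coordinates, each shaped (nrows, ncols)."""
        cols = np.arange(ncols)
        rows = np.arange(nrows)
        xs = self.x0 + (cols + 0.5) * self.cell_size
        ys = self.y0 - (rows + 0.5) * self.cell_size
        return np.meshgrid(xs, ys)


@dataclass
class RasterGrid:
    """A single-band raster layer with nodata handling.

    ``values`` is a float array; nodata cells hold ``nodata_value`` and are
    excluded from every aggregation via :meth:`mask` / :meth:`masked`.
    """

    values: np.ndarray
    transform: GridTransform
    nodata_value: float = -9999.0
    crs_id: str = "local"
    units: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("raster values must be 2-D")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def mask(self) -> np.ndarray:
        """Boolean array, True where the cell is nodata."""
        return self.values == self.nodata_value

    def masked(self) -> np.ndarray:
        """Values with nodata replaced by NaN (safe for nan-aggregations)."""
        out = self.values.copy()
        out[self.mask()] = np.nan
        return out

    def same_grid(self, other: "RasterGrid") -> bool:
        return (
            self.shape == other.shape
            and self.transform == other.transform
            and self.crs_id == other.crs_id
        )


@dataclass
class ClimateFieldSet:
    """Co-registered layers driving the potential-yield chain for one epoch.

    Q: growing-season total solar radiation, kcal cm^-2.
    T: growing-season mean temperature, degC.
    fw, fs: water and soil correction coefficients in [0, 1].
    landuse: integer-coded class grid (paddy / dryland / other).
    """

    epoch: str
    Q: RasterGrid
    T: RasterGrid
    fw: RasterGrid
    fs: RasterGrid
    landuse: RasterGrid

    def __post_init__(self) -> None:
        ref = self.Q
        for name in ("T", "fw", "fs", "landuse"):
            layer = getattr(self, name)
            if not ref.same_grid(layer):
                raise ValueError(
                    f"layer {name!r} is not co-registered with Q "
                    f"(shape/transform/crs must match)"
                )


# ---------------------------------------------------------------------------
# raster I/O (Esri ASCII grid)
# ---------------------------------------------------------------------------

def read_raster(path: str | Path) -> RasterGrid:
    """Read a single-band georeferenced ASCII grid (.asc).

    The six-line header (ncols/nrows/xllcorner/yllcorner/cellsize/
    nodata_value) supplies the georeference; a ``<stem>.crs`` sidecar, if
    present, supplies the CRS id.  Units are configuration, never guessed.
    """
    path = Path(path)
    if not path.exists():
        raise YieldGapIOError(f"raster file not found: {path}")
    header: dict[str, float] = {}
    with open(path) as fh:
        pos = fh.tell()
        for _ in range(6):
            line = fh.readline()
            parts = line.split()
            if len(parts) != 2 or not _is_number(parts[1]):
                raise YieldGapIOError(
                    f"{path}: malformed ASCII-grid header line {line!r}; "
                    "expected single-band grid with 6-line header "
                    "(multi-band rasters are not supported — supply one band per file)"
                )
            header[parts[0].lower()] = float(parts[1])
            pos = fh.tell()
        fh.seek(pos)
        values = np.loadtxt(fh, ndmin=2)
    required = {"ncols", "nrows", "xllcorner", "yllcorner", "cellsize"}
    missing = required - header.keys()
    if missing:
        raise YieldGapIOError(f"{path}: header missing georeference keys {sorted(missing)}")
    nrows, ncols = int(header["nrows"]), int(header["ncols"])
    if values.shape != (nrows, ncols):
        raise YieldGapIOError(
            f"{path}: data block shape {values.shape} does not match header "
            f"({nrows}, {ncols})"
        )
    cell = header["cellsize"]
    transform = GridTransform(
        x0=header["xllcorner"], y0=header["yllcorner"] + nrows * cell, cell_size=cell
    )
    crs_path = path.with_suffix(path.suffix + ".crs")
    crs_id = crs_path.read_text().strip() if crs_path.exists() else "local"
    return RasterGrid(
        values=values,
        transform=transform,
        nodata_value=header.get("nodata_value", -9999.0),
        crs_id=crs_id,
    )


def write_raster(grid: RasterGrid, path: str | Path) -> None:
    """Write a RasterGrid as an ASCII grid plus a ``.crs`` sidecar."""
    path = Path(path)
    nrows, ncols = grid.shape
    t = grid.transform
    header = (
        f"ncols {ncols}\n"
        f"nrows {nrows}\n"
        f"xllcorner {t.x0!r}\n"
        f"yllcorner {t.y0 - nrows * t.cell_size!r}\n"
        f"cellsize {t.cell_size!r}\n"
        f"nodata_value {grid.nodata_value!r}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, grid.values, fmt="%.17g")
    path.with_suffix(path.suffix + ".crs").write_text(grid.crs_id + "\n")


def _is_number(token: str) -> bool:
    try:
        float(token)
        return True
    except ValueError:
        return False


# ---------------------------------------------------------------------------
# county polygons (GeoJSON)
# ---------------------------------------------------------------------------

def read_counties(path: str | Path, repair: bool = True) -> pd.DataFrame:
    """Read county polygons from GeoJSON into a CountyFrame.

    Returns a DataFrame with columns ``county_id`` (unique), ``name``,
    ``is_municipal_district``, ``area_ha`` and a shapely ``geometry`` column.
    Invalid geometries are repaired with buffer(0) when ``repair`` is true,
    otherwise rejected.
    """
    path = Path(path)
    if not path.exists():
        raise YieldGapIOError(f"county file not found: {path}")
    with open(path) as fh:
        gj = json.load(fh)
    if gj.get("type") != "FeatureCollection":
        raise YieldGapIOError(f"{path}: expected a GeoJSON FeatureCollection")
    rows = []
    for feat in gj["features"]:
        props = feat.get("properties", {})
        if "county_id" not in props:
            raise YieldGapIOError(f"{path}: feature missing 'county_id' attribute")
        geom = shape(feat["geometry"])
        if not geom.is_valid:
            if repair:
                geom = geom.buffer(0)
            if not geom.is_valid:
                raise YieldGapIOError(
                    f"{path}: invalid geometry for county "
                    f"{props['county_id']!r}: {explain_validity(geom)}"
                )
        rows.append(
            {
                "county_id": str(props["county_id"]),
                "name": props.get("name", str(props["county_id"])),
                "is_municipal_district": bool(props.get("is_municipal_district", False)),
                "area_ha": float(props.get("area_ha", geom.area / 1e4)),
                "geometry": geom,
            }
        )
    frame = pd.DataFrame(rows)
    dupes = frame["county_id"][frame["county_id"].duplicated()]
    if len(dupes):
        raise YieldGapIOError(f"duplicate county_id(s): {sorted(dupes.unique())}")
    return frame.reset_index(drop=True)


def write_counties(counties: pd.DataFrame, path: str | Path) -> None:
    """Write a CountyFrame to GeoJSON."""
    feats = []
    for _, row in counties.iterrows():
        feats.append(
            {
                "type": "Feature",
                "properties": {
                    "county_id": row["county_id"],
                    "name": row.get("name", row["county_id"]),
                    "is_municipal_district": bool(row.get("is_municipal_district", False)),
                    "area_ha": float(row.get("area_ha", row["geometry"].area / 1e4)),
                },
                "geometry": mapping(row["geometry"]),
            }
        )
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": feats}, fh)


# ---------------------------------------------------------------------------
# epoch tables (CSV)
# ---------------------------------------------------------------------------

def read_epoch_table(path: str | Path, schema: dict[str, str] | None = None) -> pd.DataFrame:
    """Read a per-county per-epoch panel from CSV.

    ``schema`` optionally maps file column names onto canonical ones.  All 27
    determinant abbreviations must be resolvable after renaming; unknown extra
    columns are retained but logged.  Blank cells stay missing (NaN) — they
    are never silently zero.
    """
    path = Path(path)
    if not path.exists():
        raise YieldGapIOError(f"panel file not found: {path}")
    table = pd.read_csv(path, dtype={"county_id": str, "epoch": str})
    if schema:
        table = table.rename(columns=schema)
    missing = [c for c in MANDATORY_PANEL_COLUMNS if c not in table.columns]
    if missing:
        raise YieldGapIOError(f"{path}: missing mandatory column(s) {missing}")
    missing_det = [v for v in DETERMINANT_VARS if v not in table.columns]
    if missing_det:
        raise YieldGapIOError(f"{path}: missing determinant column(s) {missing_det}")
    for col in ["actual_farm_yield", "sown_area_grain"] + DETERMINANT_VARS:
        table[col] = pd.to_numeric(table[col], errors="raise")
    if table.duplicated(["county_id", "epoch"]).any():
        raise YieldGapIOError(f"{path}: duplicated (county_id, epoch) keys")
    neg = table[(table["actual_farm_yield"] < 0) | (table["sown_area_grain"] < 0)]
    if len(neg):
        raise YieldGapIOError(f"{path}: negative yield or area for {neg['county_id'].tolist()}")
    known = set(MANDATORY_PANEL_COLUMNS) | set(DETERMINANT_VARS)
    extra = [c for c in table.columns if c not in known]
    if extra:
        logger.info("panel %s: retaining unknown columns %s", path.name, extra)
    return table


def configure_logging(verbose: bool = False) -> None:
    logging.basicConfig(
        level=logging.DEBUG if verbose else logging.INFO,
        format="%(levelname)s %(name)s: %(message)s",
    )
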