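"""Synthetic study region: counties, climate rasters, yields, determinants.

Generates a fully self-contained landscape with known ground truth that
mimics the statistical structure the analysis assumes: a contiguous grid of
~121 county polygons over four epochs; spatially autocorrelated radiation and
temperature fields (Gaussian smoothing of seeded white noise); a soil
correction coefficient field centred near 0.42; a cultivated-land mosaic
split into paddy and dryland; farm yields generated as a covariate-driven
fraction of the modeled potential yield; and a 27-variable socioeconomic
panel in which a configurable subset of factors carries a planted effect, so
that the true importance ranking is known.

Everything is deterministic under the configured seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.ndimage import gaussian_filter
from shapely.geometry import box

from .io_core import (
    ClimateFieldSet,
    DETERMINANT_VARS,
    GridTransform,
    LANDUSE_DRYLAND,
    LANDUSE_OTHER,
    LANDUSE_PADDY,
    RasterGrid,
    write_counties,
    write_raster,
)

#: default exploitation schedule: fraction of potential yield realized per
#: epoch, producing strong gap narrowing in epoch 1->2 and partial widening
#: later (relative gaps ~63% -> 45% -> 43% -> 49%)
DEFAULT_EXPLOITATION = (0.37, 0.55, 0.57, 0.51)

#: default planted effects on the exploitation fraction, per standardized
#: covariate — mirrors the kind of macro-economic and sunshine signals the
#: determinant analysis is meant to recover
DEFAULT_EFFECTS = {"GDPPC": 0.06, "SH": 0.04, "PCAI": 0.03, "REC": 0.02}

DEFAULT_EPOCHS = ("E1990", "E2000", "E2010", "E2018")


@dataclass
class SimulationConfig:
    """All knobs of the synthetic study region.

    Climate ranges are growing-season values: Q the May–October total solar
    radiation in kcal cm^-2, T the mean temperature in degC.  The defaults
    put the region-mean soil potential in the 10–14 t ha^-1 band typical of
    a humid subtropical double-cropping province.
    """

    seed: int = 0
    n_county_x: int = 11
    n_county_y: int = 11
    cells_per_county_side: int = 8
    cell_size_m: float = 1000.0
    epochs: tuple[str, ...] = DEFAULT_EPOCHS
    Q_range: tuple[float, float] = (115.0, 145.0)  # kcal cm^-2
    T_range: tuple[float, float] = (20.0, 26.0)  # degC
    soil_coeff_mean: float = 0.42
    soil_coeff_spread: float = 0.08
    cultivated_fraction: tuple[float, float] = (0.45, 0.65)
    paddy_share: tuple[float, float] = (0.6, 0.85)
    smoothing_sigma: float = 8.0  # cells; controls spatial autocorrelation range
    exploitation_base: tuple[float, ...] = DEFAULT_EXPLOITATION
    effect_vector: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_EFFECTS))
    noise_sd: float = 0.02
    n_municipal_districts: int = 25

    def __post_init__(self) -> None:
        if self.n_county_x < 2 or self.n_county_y < 2:
            raise ValueError("county grid must be at least 2x2")
        for lo, hi in (self.Q_range, self.T_range, self.cultivated_fraction, self.paddy_share):
            if lo > hi:
                raise ValueError("range bounds must be well-ordered")
        if self.T_range[0] <= 0:
            raise ValueError("temperature range must be positive (growing-season mean)")
        if len(self.exploitation_base) != len(self.epochs):
            raise ValueError("need one exploitation_base entry per epoch")
        if not all(0 < e <= 1 for e in self.exploitation_base):
            raise ValueError("exploitation_base entries must be in (0, 1]")
        unknown = set(self.effect_vector) - set(DETERMINANT_VARS)
        if unknown:
            raise ValueError(f"effect_vector names unknown determinants: {sorted(unknown)}")

    @property
    def n_counties(self) -> int:
        return self.n_county_x * self.n_county_y

    @property
    def grid_shape(self) -> tuple[int, int]:
        return (
            self.n_county_y * self.cells_per_county_side,
            self.n_county_x * self.cells_per_county_side,
        )


@dataclass
class GroundTruth:
    """What the generator planted, for parameter-recovery checks."""

    effect_vector: dict[str, float]
    exploitation_base: dict[str, float]
    true_mean_ys: dict[str, float]  # per epoch, t ha^-1
    true_mean_ygap: dict[str, float]  # per epoch, t ha^-1
    importance_order: list[str]  # factors with planted effects, |beta| desc

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"key": f"effect:{k}", "value": v} for k, v in self.effect_vector.items()
        ]
        rows += [{"key": f"exploitation:{k}", "value": v} for k, v in self.exploitation_base.items()]
        rows += [{"key": f"mean_ys:{k}", "value": v} for k, v in self.true_mean_ys.items()]
        rows += [{"key": f"mean_ygap:{k}", "value": v} for k, v in self.true_mean_ygap.items()]
        rows += [
            {"key": f"importance_order:{i}", "value": f}
            for i, f in enumerate(self.importance_order)
        ]
        return pd.DataFrame(rows)


def _county_seed(config: SimulationConfig, salt: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([config.seed, salt]))


def generate_counties(config: SimulationConfig) -> pd.DataFrame:
    """Rectangular tessellation of n_county_x x n_county_y square counties.

    Ids run row-major from the top-left ('C001', ...).  A central block of
    ``n_municipal_districts`` counties is flagged as municipal districts to
    exercise the screening exclusion.
    """
    side = config.cells_per_county_side * config.cell_size_m
    nrows, ncols = config.n_county_y, config.n_county_x
    total_h = nrows * side
    district_ids = _central_block_ids(config)
    rows = []
    k = 0
    for r in range(nrows):
        for c in range(ncols):
            k += 1
            cid = f"C{k:03d}"
            geom = box(c * side, total_h - (r + 1) * side, (c + 1) * side, total_h - r * side)
            rows.append(
                {
                    "county_id": cid,
                    "name": f"County {k}",
                    "is_municipal_district": cid in district_ids,
                    "area_ha": geom.area / 1e4,
                    "geometry": geom,
                }
            )
    return pd.DataFrame(rows)


def _central_block_ids(config: SimulationConfig) -> set[str]:
    """Ids of a centered, roughly square block of municipal districts."""
    m = config.n_municipal_districts
    if m <= 0:
        return set()
    side = int(np.ceil(np.sqrt(m)))
    r0 = (config.n_county_y - side) // 2
    c0 = (config.n_county_x - side) // 2
    ids = []
    for r in range(r0, min(r0 + side, config.n_county_y)):
        for c in range(c0, min(c0 + side, config.n_county_x)):
            ids.append(f"C{r * config.n_county_x + c + 1:03d}")
    return set(ids[:m])


def _smooth_field(
    rng: np.random.Generator, shape: tuple[int, int], sigma: float
) -> np.ndarray:
    """Spatially autocorrelated field in [0, 1]: smoothed white noise."""
    raw = gaussian_filter(rng.standard_normal(shape), sigma=sigma, mode="reflect")
    lo, hi = raw.min(), raw.max()
    if hi == lo:
        return np.full(shape, 0.5)
    return (raw - lo) / (hi - lo)


def _scale(u: np.ndarray, lo: float, hi: float) -> np.ndarray:
    return lo + u * (hi - lo)


def generate_climate_fields(
    config: SimulationConfig, counties: pd.DataFrame | None = None
) -> dict[str, ClimateFieldSet]:
    """Per-epoch co-registered Q/T/f(w)/f(s)/land-use rasters.

    Q and T are smoothed-noise fields rescaled into the configured ranges
    with a small epoch-specific shift; f(w) is 1 everywhere (humid region
    default); f(s) is a smoothed field clipped to (0, 1] centred on
    ``soil_coeff_mean``; the land-use mosaic is carved from two further
    smoothed fields into paddy / dryland / other.
    """
    shape = config.grid_shape
    nrows, ncols = shape
    transform = GridTransform(x0=0.0, y0=nrows * config.cell_size_m, cell_size=config.cell_size_m)

    def _grid(values: np.ndarray, units: str = "") -> RasterGrid:
        return RasterGrid(values=values, transform=transform, crs_id="synthetic-aea", units=units)

    out: dict[str, ClimateFieldSet] = {}
    # static soil field, shared across epochs (soil changes slowly)
    rng_soil = _county_seed(config, 10)
    fs = config.soil_coeff_mean + (_smooth_field(rng_soil, shape, config.smoothing_sigma) - 0.5) * (
        2 * config.soil_coeff_spread
    )
    fs = np.clip(fs, 1e-6, 1.0)
    for e_idx, epoch in enumerate(config.epochs):
        rng = _county_seed(config, 100 + e_idx)
        q_lo, q_hi = config.Q_range
        t_lo, t_hi = config.T_range
        # epoch shift: up to ~10% of the range, deterministic per epoch
        q_shift = (rng.uniform(-0.1, 0.1)) * (q_hi - q_lo)
        t_shift = (rng.uniform(-0.1, 0.1)) * (t_hi - t_lo)
        Q = _scale(_smooth_field(rng, shape, config.smoothing_sigma), q_lo, q_hi) + q_shift
        Q = np.clip(Q, q_lo, q_hi)
        T = _scale(_smooth_field(rng, shape, config.smoothing_sigma), t_lo, t_hi) + t_shift
        T = np.clip(T, t_lo, t_hi)
        fw = np.ones(shape)
        cf = rng.uniform(*config.cultivated_fraction)
        ps = rng.uniform(*config.paddy_share)
        # fine-grained mosaic (sigma ~2 cells) so every county keeps some
        # cultivated land, as real county units do
        suit = _smooth_field(rng, shape, 2.0)
        wet = _smooth_field(rng, shape, 2.0)
        landuse = np.full(shape, LANDUSE_OTHER, dtype=float)
        cultivated = suit <= np.quantile(suit, cf)
        # every county unit keeps at least one cultivated cell, as real
        # county units do: force the most suitable cell where none made it
        cps = config.cells_per_county_side
        rows_idx, cols_idx = np.indices(shape)
        county_of_cell = (rows_idx // cps) * config.n_county_x + (cols_idx // cps)
        for k in range(config.n_counties):
            in_county = county_of_cell == k
            if not cultivated[in_county].any():
                flat = np.flatnonzero(in_county.ravel())
                best = flat[np.argmin(suit.ravel()[flat])]
                cultivated.ravel()[best] = True
        paddy = cultivated & (wet <= np.quantile(wet[cultivated], ps))
        landuse[cultivated] = LANDUSE_DRYLAND
        landuse[paddy] = LANDUSE_PADDY
        out[epoch] = ClimateFieldSet(
            epoch=epoch,
            Q=_grid(Q, "kcal cm-2"),
            T=_grid(T, "degC"),
            fw=_grid(fw),
            fs=_grid(fs.copy()),
            landuse=_grid(landuse),
        )
    return out


def generate_determinant_panel(
    config: SimulationConfig, counties: pd.DataFrame
) -> pd.DataFrame:
    """27-variable panel per county per epoch with trends and correlations.

    Terrain variables (DEM, Slope) are fixed across epochs.  Socioeconomic
    and investment variables combine a persistent county effect, a shared
    latent 'development' factor that trends upward over epochs (inducing
    cross-correlation), and idiosyncratic noise.  Marginal scales are
    pragmatic round numbers; the analysis standardizes covariates anyway.
    """
    rng = _county_seed(config, 20)
    n = len(counties)
    epochs = list(config.epochs)
    dem = np.abs(rng.normal(300, 150, n))  # m
    slope = np.abs(rng.normal(6, 3, n))  # degrees
    county_effect = rng.standard_normal(n)
    development = rng.standard_normal(n)  # persistent development propensity
    rows = []
    for e_idx, epoch in enumerate(epochs):
        trend = e_idx / max(len(epochs) - 1, 1)
        dev = development + 2.0 * trend + rng.normal(0, 0.3, n)
        base = {
            # climatic: county means with epoch-to-epoch variation
            "SH": 1300 + 80 * county_effect + rng.normal(0, 40, n),
            "SMI": 150 + 12 * county_effect + rng.normal(0, 8, n),
            "Temp": 17 + 1.2 * county_effect + 0.4 * trend + rng.normal(0, 0.5, n),
            "Prec": 1400 + 120 * county_effect + rng.normal(0, 90, n),
            # socioeconomic: driven by the development latent
            "RSP": np.abs(50 - 8 * dev + rng.normal(0, 5, n)),
            "LDD": np.clip(10 + 6 * dev + rng.normal(0, 2, n), 0, 100),
            "UR": np.clip(20 + 12 * dev + rng.normal(0, 4, n), 0, 100),
            "FL": np.abs(25 - 4 * dev + rng.normal(0, 3, n)),
            "GDPPC": np.abs(8000 + 6000 * dev + rng.normal(0, 1500, n)),
            "RAGDP": np.clip(30 - 7 * dev + rng.normal(0, 3, n), 1, 80),
            "PCAI": np.abs(4000 + 2500 * dev + rng.normal(0, 700, n)),
            # land use conditions
            "DEM": dem,
            "Slope": slope,
            "RPF": np.clip(60 + 10 * county_effect + rng.normal(0, 6, n), 0, 100),
            "NP": np.abs(rng.normal(800, 200, n)),
            "PD": np.abs(rng.normal(0.5, 0.15, n)),
            "LPI": np.abs(rng.normal(12, 4, n)),
            "CLPL": np.clip(np.round(6 + county_effect + rng.normal(0, 1, n)), 1, 10),
            # human investment: also development-linked, trending up
            "PSAGC": np.clip(55 - 6 * dev + rng.normal(0, 5, n), 5, 100),
            "MCI": np.clip(120 + 20 * trend + 10 * county_effect + rng.normal(0, 10, n), 50, 250),
            "APPA": np.abs(rng.normal(1.5, 0.4, n)),
            "REC": np.abs(5000 + 4000 * dev + rng.normal(0, 1200, n)),
            "FPA": np.abs(0.4 + 0.1 * trend + rng.normal(0, 0.08, n)),
            "TPA": np.abs(30000 + 12000 * dev + rng.normal(0, 5000, n)),
            "IA": np.abs(rng.normal(40000, 9000, n)),
            "PAMPA": np.abs(4 + 3 * trend + 0.8 * dev + rng.normal(0, 0.8, n)),
            "ASFF": np.abs(20000 * trend + 5000 * dev + rng.normal(0, 4000, n)),
        }
        frame = pd.DataFrame(base)
        frame.insert(0, "epoch", epoch)
        frame.insert(0, "county_id", counties["county_id"].to_numpy())
        rows.append(frame)
    panel = pd.concat(rows, ignore_index=True)
    return panel[["county_id", "epoch"] + DETERMINANT_VARS]


def generate_farm_yields(
    config: SimulationConfig, ys_means: pd.DataFrame, panel: pd.DataFrame
) -> tuple[pd.DataFrame, GroundTruth]:
    """Farm yields as a covariate-driven fraction of potential yield.

    farm_yield = ys_mean * clip(base_e(epoch) + sum_v beta_v z_v + noise,
    0.05, 0.95), with z the population-standardized determinant values within
    the epoch.  Sown grain area is proportional to county cultivated area.
    Returns the completed panel (actual_farm_yield, sown_area_grain columns
    added) and the recorded ground truth.
    """
    rng = _county_seed(config, 30)
    merged = panel.merge(ys_means[["county_id", "epoch", "ys_mean"]], on=["county_id", "epoch"])
    out = []
    mean_ys: dict[str, float] = {}
    mean_ygap: dict[str, float] = {}
    for e_idx, epoch in enumerate(config.epochs):
        sub = merged[merged["epoch"] == epoch].copy()
        effect = np.zeros(len(sub))
        for var, beta in config.effect_vector.items():
            v = sub[var].to_numpy(dtype=float)
            sd = v.std()
            if sd > 0:
                effect += beta * (v - v.mean()) / sd
        exploitation = np.clip(
            config.exploitation_base[e_idx] + effect + rng.normal(0, config.noise_sd, len(sub)),
            0.05,
            0.95,
        )
        sub["actual_farm_yield"] = sub["ys_mean"].to_numpy() * exploitation
        # sown area ~ 40% of county land, in ha, jittered per county
        sub["sown_area_grain"] = np.abs(rng.normal(25000, 6000, len(sub)))
        ys = sub["ys_mean"].to_numpy(dtype=float)
        mean_ys[epoch] = float(np.nanmean(ys))
        mean_ygap[epoch] = float(np.nanmean(ys - sub["actual_farm_yield"].to_numpy()))
        out.append(sub)
    full = pd.concat(out, ignore_index=True).drop(columns=["ys_mean"])
    order = sorted(config.effect_vector, key=lambda v: -abs(config.effect_vector[v]))
    truth = GroundTruth(
        effect_vector=dict(config.effect_vector),
        exploitation_base={e: b for e, b in zip(config.epochs, config.exploitation_base)},
        true_mean_ys=mean_ys,
        true_mean_ygap=mean_ygap,
        importance_order=order,
    )
    cols = ["county_id", "epoch", "actual_farm_yield", "sown_area_grain"] + DETERMINANT_VARS
    return full[cols], truth


def write_fixture_set(
    directory: str | Path,
    config: SimulationConfig,
    counties: pd.DataFrame,
    fields: dict[str, ClimateFieldSet],
    panel: pd.DataFrame,
    truth: GroundTruth,
) -> None:
    """Emit the full synthetic input set as text files (asc/GeoJSON/CSV/YAML)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_counties(counties, directory / "counties.geojson")
    for epoch, fs in fields.items():
        for layer in ("Q", "T", "fw", "fs", "landuse"):
            write_raster(getattr(fs, layer), directory / f"{layer}_{epoch}.asc")
    panel.to_csv(directory / "panel.csv", index=False)
    truth.to_frame().to_csv(directory / "ground_truth.csv", index=False)
    with open(directory / "config.yaml", "w") as fh:
        yaml.safe_dump(asdict(config), fh, sort_keys=True)
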