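"""Synthetic multi-zone raster scenes with known ground truth.

The generator emulates the statistical structure of a plateau-scale drought
study built on 1 km vegetation-index / surface-temperature products:

* a triangular NDVI-LST feature space inside each geomorphic zone, with the
  per-NDVI-bin maximum LST (dry edge) decreasing and the minimum LST (wet
  edge) increasing as NDVI grows;
* a latent per-pixel surface wetness in [0, 1] (1 = saturated) that places
  each pixel's LST between its zone's wet and dry edge — so the true TVDI is
  exactly ``1 - wetness`` and negative TVDI-soil-moisture coupling follows
  by construction;
* annual precipitation / mean-temperature fields with a linear spatial
  gradient (the southeast-to-northwest climate gradient of the study design)
  plus weak linear interannual trends;
* static factor rasters (elevation, slope, aspect, distances to water and
  built-up land, land use) for driver-importance analysis;
* sparse point samples of near-surface volumetric soil moisture.

Every random draw flows from one root seed through a fixed
``SeedSequence.spawn`` order, so identical configs give bit-identical scenes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .rasters import Raster, ZoneMap, read_ascii_grid, write_ascii_grid

__all__ = [
    "SceneConfig",
    "SyntheticScene",
    "generate_scene",
    "write_scene",
    "read_scene",
    "LANDUSE_CATEGORIES",
]

LANDUSE_CATEGORIES = ("forest", "grassland", "cultivated", "water", "built-up", "other")
VEGETATED = (0, 1, 2)  # forest, grassland, cultivated

SEASONS = ("spring", "summer", "autumn", "winter")


class ConfigError(ValueError):
    """Raised for inconsistent scene configurations."""


@dataclass
class SceneConfig:
    """Ground-truth parameters of a synthetic scene.

    Edge tuples are ``(a1, b1, a2, b2)``: wet edge ``LSTmin = a1 + b1*NDVI``
    (b1 > 0), dry edge ``LSTmax = a2 + b2*NDVI`` (b2 < 0), dry strictly above
    wet over NDVI in [0, 1].

    ``wetness_tail`` widens the latent wetness distribution before clipping
    to [0, 1], planting genuine fully-dry (0) and saturated (1) pixels — the
    physical anchors that make the dry/wet edges observable.

    ``ndvi_quantum`` snaps NDVI to the centres of a fixed grid (default
    0.01), emulating the discretised values of scaled satellite products and
    aligning pixels with the conventional 0.01 feature-space bins.

    ``wetness_precip_coupling`` / ``wetness_temp_coupling`` mix standardised
    interannual climate anomalies into wetness (wetter after wet years,
    drier after warm years), giving scenes with a known climate driver.
    """

    grid_rows: int = 120
    grid_cols: int = 120
    n_zones: int = 8
    years: tuple[int, ...] = tuple(range(2000, 2020))
    seasons: tuple[str, ...] = SEASONS
    true_edges_per_zone: tuple[tuple[float, float, float, float], ...] | None = None
    ndvi_beta_params: tuple[tuple[float, float], ...] | None = None
    moisture_trend_per_zone: tuple[float, ...] | None = None  # wetness units / yr
    precip_base: float = 650.0          # mm at column 0
    precip_gradient: float = -2.0       # mm per cell along columns
    precip_trend: float = -0.39         # mm / yr
    precip_noise_sd: float = 15.0       # mm, interannual pixel noise
    temp_base: float = 6.0              # deg C at column 0
    temp_gradient: float = -0.03        # deg C per cell along columns
    temp_trend: float = 0.02            # deg C / yr
    temp_noise_sd: float = 0.3          # deg C
    noise_sd_lst: float = 1.0           # deg C
    wetness_tail: float = 0.25
    wetness_noise_sd: float = 0.15
    wetness_precip_coupling: float = 0.0
    wetness_temp_coupling: float = 0.0
    ndvi_quantum: float | None = 0.01
    ndvi_smooth_window: int = 1
    n_moisture_points_per_year: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if self.grid_rows < 1 or self.grid_cols < 1 or self.n_zones < 1:
            raise ConfigError("grid_rows, grid_cols and n_zones must be positive")
        if self.grid_cols < self.n_zones:
            raise ConfigError("need at least one column per zone")
        if self.true_edges_per_zone is None:
            self.true_edges_per_zone = tuple(
                (5.0 + 0.7 * z, 7.0 + 0.4 * z, 44.0 + 0.9 * z, -16.0 - 0.5 * z)
                for z in range(self.n_zones)
            )
        if self.ndvi_beta_params is None:
            self.ndvi_beta_params = tuple((2.0, 2.0) for _ in range(self.n_zones))
        if self.moisture_trend_per_zone is None:
            # most zones dry slowly; the last two trend wetter, mirroring the
            # humid southern divisions of the study design
            self.moisture_trend_per_zone = tuple(
                0.004 if z >= self.n_zones - 2 else -0.004 for z in range(self.n_zones)
            )
        for name, seq in (
            ("true_edges_per_zone", self.true_edges_per_zone),
            ("ndvi_beta_params", self.ndvi_beta_params),
            ("moisture_trend_per_zone", self.moisture_trend_per_zone),
        ):
            if len(seq) != self.n_zones:
                raise ConfigError(f"{name} must have one entry per zone")
        for a1, b1, a2, b2 in self.true_edges_per_zone:
            if not (b1 > 0 and b2 < 0 and a2 > a1):
                raise ConfigError(f"edge ({a1},{b1},{a2},{b2}) violates b1>0, b2<0, a2>a1")
            # linear edges: checking the NDVI range endpoints suffices
            for n in (0.0, 1.0):
                if (a2 + b2 * n) <= (a1 + b1 * n):
                    raise ConfigError(
                        f"dry edge not above wet edge at NDVI={n} for ({a1},{b1},{a2},{b2})"
                    )
        for alpha, beta in self.ndvi_beta_params:
            if alpha <= 0 or beta <= 0:
                raise ConfigError("Beta parameters must be positive")
        if not (0 <= self.wetness_tail < 2):
            raise ConfigError("wetness_tail must be in [0, 2)")


@dataclass
class SyntheticScene:
    """A generated scene plus the truth that produced it.

    Time-varying stacks are indexed ``[year_index, season_index, row, col]``
    (climate fields ``[year_index, row, col]``).
    """

    config: SceneConfig
    zone_map: ZoneMap
    ndvi: np.ndarray
    lst: np.ndarray
    wetness_truth: np.ndarray
    precip: np.ndarray
    temp: np.ndarray
    elevation: Raster
    slope: Raster
    aspect: Raster
    dist_water: Raster
    dist_built: Raster
    landuse: Raster
    soil_moisture_points: pd.DataFrame  # columns: row, col, year, moisture

    def raster(self, data: np.ndarray, units: str = "") -> Raster:
        return self.zone_map.like(np.asarray(data, dtype=float), nodata=-9999.0, units=units)

    def ndvi_raster(self, yi: int, si: int) -> Raster:
        return self.raster(self.ndvi[yi, si], "ndvi")

    def lst_raster(self, yi: int, si: int) -> Raster:
        return self.raster(self.lst[yi, si], "degC")

    def true_tvdi(self, yi: int, si: int) -> np.ndarray:
        return 1.0 - self.wetness_truth[yi, si]


def _zone_strips(rows: int, cols: int, n_zones: int) -> np.ndarray:
    """Contiguous vertical strips: zone ids 1..n_zones left to right."""
    edges = np.linspace(0, cols, n_zones + 1).astype(int)
    zone = np.zeros((rows, cols), dtype=np.int64)
    for z in range(n_zones):
        zone[:, edges[z]:edges[z + 1]] = z + 1
    return zone


def _quantize(ndvi: np.ndarray, quantum: float | None) -> np.ndarray:
    if quantum is None:
        return ndvi
    return (np.floor(ndvi / quantum) + 0.5) * quantum


def _smooth_field(rng: np.random.Generator, shape: tuple[int, int], sigma: float) -> np.ndarray:
    field = ndimage.gaussian_filter(rng.standard_normal(shape), sigma, mode="nearest")
    field /= max(field.std(), 1e-12)
    return field


def generate_scene(config: SceneConfig) -> SyntheticScene:
    """Generate a scene deterministically from ``config`` (root seed inside).

    LST construction: ``wet_edge(NDVI) + (1 - wetness) * (dry_edge(NDVI) -
    wet_edge(NDVI)) + noise`` with noise truncated at three standard
    deviations, so every pixel stays within +-3*noise_sd_lst of its edges.
    """
    cfg = config
    rows, cols = cfg.grid_rows, cfg.grid_cols
    ny, ns = len(cfg.years), len(cfg.seasons)
    # fixed spawning order: changing one consumer never reshuffles the others
    seeds = np.random.SeedSequence(cfg.seed).spawn(6)
    rng_ndvi, rng_wet, rng_lst, rng_clim, rng_static, rng_pts = (
        np.random.default_rng(s) for s in seeds
    )

    zone_data = _zone_strips(rows, cols, cfg.n_zones)
    zone_map = ZoneMap(zone_data, cellsize=1000.0)

    # --- NDVI: per-pixel i.i.d. Beta within zone, drawn once per year and
    # held constant across the year's seasons (so a maximum-value composite
    # pairs each pixel's LST extreme with that same pixel NDVI, preserving
    # the triangle); optional mean filter, then quantised
    ndvi_annual = np.empty((ny, rows, cols))
    for z in range(cfg.n_zones):
        alpha, beta = cfg.ndvi_beta_params[z]
        m = zone_data == z + 1
        ndvi_annual[:, m] = rng_ndvi.beta(alpha, beta, size=(ny, int(m.sum())))
    if cfg.ndvi_smooth_window > 1:
        w = cfg.ndvi_smooth_window
        for yi in range(ny):
            ndvi_annual[yi] = ndimage.uniform_filter(ndvi_annual[yi], w, mode="nearest")
    ndvi_annual = np.clip(_quantize(ndvi_annual, cfg.ndvi_quantum), 0.0, 1.0)
    ndvi = np.repeat(ndvi_annual[:, None], ns, axis=1)

    # --- climate: base + column gradient + annual trend + interannual noise
    col_idx = np.arange(cols)[None, :] * np.ones((rows, 1))
    t_idx = np.arange(ny)
    precip_mean = cfg.precip_base + cfg.precip_gradient * col_idx
    temp_mean = cfg.temp_base + cfg.temp_gradient * col_idx
    precip_noise = rng_clim.normal(0.0, cfg.precip_noise_sd, size=(ny, rows, cols))
    temp_noise = rng_clim.normal(0.0, cfg.temp_noise_sd, size=(ny, rows, cols))
    precip = precip_mean[None] + cfg.precip_trend * t_idx[:, None, None] + precip_noise
    temp = temp_mean[None] + cfg.temp_trend * t_idx[:, None, None] + temp_noise
    precip = np.maximum(precip, 0.0)

    # --- latent wetness: static base + zone drift + climate coupling + noise
    tail = cfg.wetness_tail
    base = rng_wet.uniform(-tail, 1.0 + tail, size=(rows, cols))
    drift = np.zeros((rows, cols))
    for z in range(cfg.n_zones):
        drift[zone_data == z + 1] = cfg.moisture_trend_per_zone[z]
    wet_noise = rng_wet.normal(0.0, cfg.wetness_noise_sd, size=(ny, ns, rows, cols))
    if cfg.wetness_noise_sd == 0:
        wet_noise[:] = 0.0
    # standardised interannual anomalies (noise part only), shared across seasons
    z_p = precip_noise / cfg.precip_noise_sd if cfg.precip_noise_sd > 0 else 0.0 * precip
    z_t = temp_noise / cfg.temp_noise_sd if cfg.temp_noise_sd > 0 else 0.0 * temp
    coupling = (
        cfg.wetness_precip_coupling * z_p - cfg.wetness_temp_coupling * z_t
    )[:, None, :, :]
    wetness = np.clip(
        base[None, None]
        + drift[None, None] * t_idx[:, None, None, None]
        + coupling
        + wet_noise,
        0.0,
        1.0,
    )

    # --- LST from the configured edges
    lst = np.empty_like(ndvi)
    for z in range(cfg.n_zones):
        a1, b1, a2, b2 = cfg.true_edges_per_zone[z]
        m = zone_data == z + 1
        wet_edge = a1 + b1 * ndvi[:, :, m]
        dry_edge = a2 + b2 * ndvi[:, :, m]
        lst[:, :, m] = wet_edge + (1.0 - wetness[:, :, m]) * (dry_edge - wet_edge)
    if cfg.noise_sd_lst > 0:
        noise = rng_lst.normal(0.0, cfg.noise_sd_lst, size=lst.shape)
        np.clip(noise, -3 * cfg.noise_sd_lst, 3 * cfg.noise_sd_lst, out=noise)
        lst = lst + noise

    # --- static factors
    elev_data = 4500.0 + 600.0 * _smooth_field(rng_static, (rows, cols), sigma=8.0) \
        + 2.0 * col_idx
    gy, gx = np.gradient(elev_data, 1000.0)  # cellsize in m
    slope_data = np.degrees(np.arctan(np.hypot(gx, gy)))
    aspect_data = (np.degrees(np.arctan2(-gx, gy)) + 360.0) % 360.0
    landuse_data = _draw_landuse(rng_static, zone_data, cfg.n_zones)
    dist_water_data = _distance_to(rng_static, landuse_data == 3, (rows, cols))
    dist_built_data = _distance_to(rng_static, landuse_data == 4, (rows, cols))

    mk = lambda d, u: Raster(np.asarray(d, dtype=float), cellsize=1000.0, units=u)
    elevation = mk(elev_data, "m")
    slope = mk(slope_data, "deg")
    aspect = mk(aspect_data, "deg")
    dist_water = mk(dist_water_data, "m")
    dist_built = mk(dist_built_data, "m")
    landuse = Raster(landuse_data.astype(np.int64), cellsize=1000.0, nodata=-1,
                     units="category")

    # --- soil-moisture points: summer wetness rescaled to volumetric fraction
    si_summer = min(1, ns - 1)
    veg = np.isin(landuse_data, VEGETATED)
    veg_rc = np.argwhere(veg)
    records = []
    for yi, year in enumerate(cfg.years):
        take = rng_pts.choice(len(veg_rc), size=min(cfg.n_moisture_points_per_year,
                                                    len(veg_rc)), replace=False)
        for r, c in veg_rc[take]:
            w = wetness[yi, si_summer, r, c]
            moist = 0.05 + 0.40 * w + rng_pts.normal(0.0, 0.02)
            records.append((int(r), int(c), int(year), float(np.clip(moist, 0.005, 0.5))))
    points = pd.DataFrame(records, columns=["row", "col", "year", "moisture"])

    return SyntheticScene(
        config=cfg, zone_map=zone_map, ndvi=ndvi, lst=lst, wetness_truth=wetness,
        precip=precip, temp=temp, elevation=elevation, slope=slope, aspect=aspect,
        dist_water=dist_water, dist_built=dist_built, landuse=landuse,
        soil_moisture_points=points,
    )


def _draw_landuse(rng: np.random.Generator, zone_data: np.ndarray, n_zones: int) -> np.ndarray:
    """Grassland-dominated categorical field with sparse water/built cells."""
    rows, cols = zone_data.shape
    probs = np.array([0.12, 0.60, 0.08, 0.02, 0.02, 0.16])
    lu = rng.choice(len(LANDUSE_CATEGORIES), size=(rows, cols), p=probs)
    return lu


def _distance_to(rng: np.random.Generator, targets: np.ndarray, shape) -> np.ndarray:
    """Euclidean distance (m) to the nearest target cell; 1 km cells."""
    if not targets.any():
        # guarantee at least one target so distances stay finite
        targets = np.zeros(shape, dtype=bool)
        targets[shape[0] // 2, shape[1] // 2] = True
    return ndimage.distance_transform_edt(~targets) * 1000.0


def write_scene(scene: SyntheticScene, out_dir: str | Path) -> Path:
    """Write a scene as ASCII grids + CSV points + a truth key=value file.

    Naming convention: ``var_YYYY_season.asc`` for seasonal stacks,
    ``var_YYYY.asc`` for annual climate, bare ``var.asc`` for statics.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = scene.config
    write_ascii_grid(scene.zone_map, out / "zones.asc")
    for name, rast in [
        ("elevation", scene.elevation), ("slope", scene.slope),
        ("aspect", scene.aspect), ("dist_water", scene.dist_water),
        ("dist_built", scene.dist_built), ("landuse", scene.landuse),
    ]:
        write_ascii_grid(rast, out / f"{name}.asc")
    for yi, year in enumerate(cfg.years):
        write_ascii_grid(scene.raster(scene.precip[yi], "mm"), out / f"precip_{year}.asc")
        write_ascii_grid(scene.raster(scene.temp[yi], "degC"), out / f"temp_{year}.asc")
        for si, season in enumerate(cfg.seasons):
            write_ascii_grid(scene.ndvi_raster(yi, si), out / f"ndvi_{year}_{season}.asc")
            write_ascii_grid(scene.lst_raster(yi, si), out / f"lst_{year}_{season}.asc")
            write_ascii_grid(scene.raster(scene.wetness_truth[yi, si], "wetness"),
                             out / f"wetness_{year}_{season}.asc")
    scene.soil_moisture_points.to_csv(out / "soil_moisture_points.csv", index=False)
    with open(out / "truth_config.txt", "w") as fh:
        for key, val in vars(cfg).items():
            fh.write(f"{key} = {val!r}\n")
    return out


def read_scene(scene_dir: str | Path) -> SyntheticScene:
    """Load a scene previously written by :func:`write_scene`."""
    import ast

    d = Path(scene_dir)
    kwargs = {}
    for line in (d / "truth_config.txt").read_text().splitlines():
        key, _, val = line.partition(" = ")
        kwargs[key.strip()] = ast.literal_eval(val.strip())
    cfg = SceneConfig(**kwargs)
    ny, ns = len(cfg.years), len(cfg.seasons)
    rows, cols = cfg.grid_rows, cfg.grid_cols
    zone_map = read_ascii_grid(d / "zones.asc", categorical="zones")
    ndvi = np.empty((ny, ns, rows, cols))
    lst = np.empty_like(ndvi)
    wetness = np.full_like(ndvi, np.nan)
    precip = np.empty((ny, rows, cols))
    temp = np.empty_like(precip)
    for yi, year in enumerate(cfg.years):
        precip[yi] = read_ascii_grid(d / f"precip_{year}.asc").data
        temp[yi] = read_ascii_grid(d / f"temp_{year}.asc").data
        for si, season in enumerate(cfg.seasons):
            ndvi[yi, si] = read_ascii_grid(d / f"ndvi_{year}_{season}.asc").data
            lst[yi, si] = read_ascii_grid(d / f"lst_{year}_{season}.asc").data
            wpath = d / f"wetness_{year}_{season}.asc"
            if wpath.exists():
                wetness[yi, si] = read_ascii_grid(wpath).data
    statics = {name: read_ascii_grid(d / f"{name}.asc")
               for name in ("elevation", "slope", "aspect", "dist_water", "dist_built")}
    landuse = read_ascii_grid(d / "landuse.asc", categorical=True)
    points = pd.read_csv(d / "soil_moisture_points.csv")
    return SyntheticScene(
        config=cfg, zone_map=zone_map, ndvi=ndvi, lst=lst, wetness_truth=wetness,
        precip=precip, temp=temp, elevation=statics["elevation"],
        slope=statics["slope"], aspect=statics["aspect"],
        dist_water=statics["dist_water"], dist_built=statics["dist_built"],
        landuse=landuse, soil_moisture_points=points,
    )
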