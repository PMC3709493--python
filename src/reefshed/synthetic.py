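"""Synthetic watershed, climate, GCM-ensemble and gauge generators.

Everything downstream of this module is exercised on generated inputs with
the statistical structure the analysis assumes: a drained DEM (smoothed random
field plus a ramp toward the grid edges, then depression-filled), soils within
realistic ranges, forest preferentially on steep road-remote cells (emulating
accessibility-driven deforestation history), a quadrant region mask with a
strongly seasonal wet/dry climate that is wettest in the NE analogue and
driest in the SW, and GCM ensembles drawn as per-member warming offsets plus
seasonal precipitation scalings.  Every generator is a pure function of its
arguments including the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from . import terrain
from .climate import DRY_MONTHS, WET_MONTHS
from .datatypes import (
    BARE,
    CROPLAND,
    FOREST,
    GRASSLAND,
    HSG_A,
    HSG_B,
    HSG_C,
    HSG_D,
    REGION_NE,
    REGION_NW,
    REGION_SW,
    REGION_W,
    WATER,
    DischargeSeries,
    MonthlyClimateCube,
    WatershedStack,
)

#: Regional mean monthly precipitation (mm/month): NE wettest, SW driest.
DEFAULT_PRECIP_WET = {REGION_NE: 300.0, REGION_NW: 230.0, REGION_W: 170.0, REGION_SW: 110.0}
DEFAULT_PRECIP_DRY = {REGION_NE: 100.0, REGION_NW: 40.0, REGION_W: 25.0, REGION_SW: 15.0}
DEFAULT_TEMP_MEAN = {REGION_NE: 25.0, REGION_NW: 26.5, REGION_W: 25.5, REGION_SW: 24.0}


@dataclass
class SyntheticClimateParams:
    n_years: int = 31
    start_year: int = 1975
    wet_months: frozenset = WET_MONTHS
    dry_months: frozenset = DRY_MONTHS
    precip_mean_wet: dict[int, float] = field(default_factory=lambda: dict(DEFAULT_PRECIP_WET))
    precip_mean_dry: dict[int, float] = field(default_factory=lambda: dict(DEFAULT_PRECIP_DRY))
    precip_shape: float = 4.0       # gamma shape; inf → deterministic months
    year_cv: float = 0.25           # CV of the regional interannual wetness factor
    temp_mean: dict[int, float] = field(default_factory=lambda: dict(DEFAULT_TEMP_MEAN))
    temp_amplitude: float = 3.0     # °C seasonal half-range
    temp_noise_sd: float = 0.5      # °C
    seed: int = 0

    def __post_init__(self) -> None:
        if set(self.wet_months) | set(self.dry_months) != set(range(1, 13)):
            raise ValueError("wet and dry months must partition the year")
        if set(self.wet_months) & set(self.dry_months):
            raise ValueError("wet and dry months overlap")
        if self.n_years < 2:
            raise ValueError("climatology needs at least 2 years")


@dataclass
class GcmEnsembleParams:
    n_gcms: int = 6
    warming_range: tuple[float, float] = (1.0, 4.0)          # °C, uniform
    precip_change_wet: tuple[float, float] = (-0.05, 0.10)   # fractional
    precip_change_dry: tuple[float, float] = (-0.20, -0.05)
    wet_months: frozenset = WET_MONTHS
    future_start_year: int = 2065
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_gcms < 1:
            raise ValueError("n_gcms must be ≥ 1")
        for lo, hi in (self.warming_range, self.precip_change_wet, self.precip_change_dry):
            if hi < lo:
                raise ValueError("empty parameter range")
        if not -10.0 <= self.warming_range[0] <= self.warming_range[1] <= 15.0:
            raise ValueError("warming range outside the physical band [-10, 15] °C")


def _smooth_field(rng: np.random.Generator, shape: tuple[int, int], sigma: float) -> np.ndarray:
    """Zero-mean, unit-ish-scale smoothed Gaussian random field."""
    f = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=sigma, mode="nearest")
    sd = f.std()
    return f / sd if sd > 0 else f


def _unit01(f: np.ndarray) -> np.ndarray:
    lo, hi = f.min(), f.max()
    return (f - lo) / (hi - lo) if hi > lo else np.full_like(f, 0.5)


def _roads(rng: np.random.Generator, shape: tuple[int, int], n_roads: int = 3) -> np.ndarray:
    """Rasterize a few random cross-grid polylines; only distance matters."""
    nr, nc = shape
    mask = np.zeros(shape, dtype=bool)
    for _ in range(n_roads):
        if rng.random() < 0.5:  # west→east
            r0, r1 = rng.integers(0, nr, size=2)
            cs = np.arange(nc)
            rs = np.round(np.linspace(r0, r1, nc)).astype(int)
        else:                    # north→south
            c0, c1 = rng.integers(0, nc, size=2)
            rs = np.arange(nr)
            cs = np.round(np.linspace(c0, c1, nr)).astype(int)
        mask[rs, cs] = True
    return mask


def region_quadrants(shape: tuple[int, int]) -> np.ndarray:
    """Quadrant region mask: NE top-right, NW top-left, SW bottom-left,
    W bottom-right (row 0 is north)."""
    nr, nc = shape
    region = np.empty(shape, dtype=np.int64)
    top = np.arange(nr)[:, None] < nr // 2
    left = np.arange(nc)[None, :] < nc // 2
    region[top & ~left] = REGION_NE
    region[top & left] = REGION_NW
    region[~top & left] = REGION_SW
    region[~top & ~left] = REGION_W
    return region


def generate_watershed(
    nrows: int,
    ncols: int,
    cell_size: float,
    seed: int,
    forest_fraction: float = 0.4,
    relief: float = 60.0,
    water_fraction: float = 0.02,
) -> WatershedStack:
    """Generate a complete aligned raster stack for one synthetic domain.

    The DEM is a smoothed random field plus a ramp rising away from the grid
    edges, depression-filled so that every cell drains; each quadrant drains
    to its own max-accumulation edge cell, which becomes that region's outlet.
    Forest is placed preferentially on steep, road-remote land.
    """
    if nrows < 4 or ncols < 4:
        raise ValueError("grid must be at least 4×4")
    if cell_size <= 0:
        raise ValueError("cell_size must be positive")
    if not 0.0 <= forest_fraction <= 1.0:
        raise ValueError("forest_fraction must lie in [0,1]")
    rng = np.random.default_rng(seed)
    shape = (nrows, ncols)

    # terrain: edge-distance ramp + smooth noise, then filled
    rr = np.arange(nrows)[:, None]
    cc = np.arange(ncols)[None, :]
    edge_dist = np.minimum(np.minimum(rr, nrows - 1 - rr), np.minimum(cc, ncols - 1 - cc))
    ramp = relief * edge_dist / max(edge_dist.max(), 1)
    noise = _smooth_field(rng, shape, sigma=max(min(nrows, ncols) / 10.0, 1.0))
    dem = terrain.fill_depressions(ramp + 0.35 * relief * noise)

    fdir = terrain.d8_flow_direction(dem, cell_size)
    acc = terrain.flow_accumulation(fdir)
    slope = terrain.slope_grid(dem, cell_size)
    region = region_quadrants(shape)

    # one outlet per quadrant: its max-accumulation edge cell
    on_edge = np.zeros(shape, dtype=bool)
    on_edge[0, :] = on_edge[-1, :] = True
    on_edge[:, 0] = on_edge[:, -1] = True
    outlets: dict[int, tuple[int, int]] = {}
    for code in (REGION_NE, REGION_NW, REGION_SW, REGION_W):
        sel = on_edge & (region == code)
        masked = np.where(sel, acc, -1.0)
        idx = int(np.argmax(masked))
        outlets[code] = (idx // ncols, idx % ncols)

    # soils: smooth correlated fields in realistic ranges
    whc = 50.0 + 150.0 * _unit01(_smooth_field(rng, shape, 2.0))
    tex = np.stack([np.exp(0.8 * _smooth_field(rng, shape, 2.0)) for _ in range(3)])
    tex = 100.0 * tex / tex.sum(axis=0)
    sand, silt, clay = tex
    org_carbon = 0.5 + 3.5 * _unit01(_smooth_field(rng, shape, 2.0))
    hsg = np.full(shape, HSG_D, dtype=np.int64)
    hsg[clay < 40.0] = HSG_C
    hsg[sand >= 40.0] = HSG_B
    hsg[sand >= 55.0] = HSG_A

    # roads and land cover
    road_mask = _roads(rng, shape)
    road_dist = ndimage.distance_transform_edt(~road_mask) * cell_size

    landcover = np.zeros(shape, dtype=np.int64)
    n_cells = nrows * ncols
    n_water = int(round(water_fraction * n_cells))
    if n_water > 0:
        # water on the highest-accumulation cells (the river network)
        order = np.argsort(-acc.ravel(), kind="stable")
        landcover.ravel()[order[:n_water]] = WATER
    land = landcover == 0
    n_land = int(land.sum())
    n_forest = int(round(forest_fraction * n_land))
    if n_forest > 0:
        from scipy.stats import rankdata

        sr = rankdata(slope[land], method="average")
        dr = rankdata(road_dist[land], method="average")
        score = (sr + dr) / (2.0 * n_land) + 0.10 * rng.random(n_land)
        land_idx = np.flatnonzero(land.ravel())
        top = land_idx[np.argsort(-score, kind="stable")[:n_forest]]
        landcover.ravel()[top] = FOREST
    open_land = landcover == 0
    landcover[open_land] = rng.choice(
        [GRASSLAND, CROPLAND, BARE], p=[0.45, 0.35, 0.20], size=int(open_land.sum())
    )

    stack = WatershedStack(
        dem=dem, whc=whc, sand=sand, silt=silt, clay=clay, org_carbon=org_carbon,
        hsg=hsg, landcover=landcover, road_dist=road_dist, region=region,
        cell_size=float(cell_size), outlets=outlets,
    )
    stack.validate()
    return stack


def generate_climate(stack: WatershedStack, params: SyntheticClimateParams) -> MonthlyClimateCube:
    """Monthly gamma precipitation and sinusoid-plus-noise temperature.

    Monthly cell precipitation is gamma-distributed around the region- and
    season-specific mean, scaled by a shared per-(year, region) lognormal
    wetness factor with unit mean and CV ``year_cv``: wet years are wet
    across a whole region, the spatially coherent interannual variability
    that makes annual flow and annual erosivity covary.  ``precip_shape =
    inf`` collapses every month to its exact seasonal mean (no noise of
    either kind).  Temperature peaks in January (Southern-Hemisphere summer).
    """
    rng = np.random.default_rng(params.seed)
    shape = stack.shape
    ny = params.n_years

    mean_by_month = np.empty((12, *shape))
    for m in range(1, 13):
        table = params.precip_mean_wet if m in params.wet_months else params.precip_mean_dry
        mm = np.zeros(shape)
        for code, value in table.items():
            mm[stack.region == code] = value
        mean_by_month[m - 1] = mm

    if np.isinf(params.precip_shape):
        precip = np.broadcast_to(mean_by_month, (ny, 12, *shape)).copy()
    else:
        scale = np.broadcast_to(mean_by_month, (ny, 12, *shape)).copy()
        if params.year_cv > 0:
            sigma2 = np.log1p(params.year_cv**2)
            codes = sorted(params.precip_mean_wet)
            wet_factor = rng.lognormal(-sigma2 / 2.0, np.sqrt(sigma2),
                                       size=(ny, len(codes)))
            year_field = np.ones((ny, *shape))
            for j, code in enumerate(codes):
                year_field[:, stack.region == code] = wet_factor[:, j][:, None]
            scale = scale * year_field[:, None]
        k = params.precip_shape
        precip = rng.gamma(k, scale / k, size=(ny, 12, *shape))

    tmean = np.zeros(shape)
    for code, value in params.temp_mean.items():
        tmean[stack.region == code] = value
    months = np.arange(12)
    season = params.temp_amplitude * np.cos(2.0 * np.pi * months / 12.0)
    temp = (tmean[None, None] + season[None, :, None, None]
            + rng.normal(0.0, params.temp_noise_sd, size=(ny, 12, *shape)))
    return MonthlyClimateCube(precip=precip, temp=temp, start_year=params.start_year)


def generate_gcm_ensemble(
    base: MonthlyClimateCube, params: GcmEnsembleParams
) -> list[MonthlyClimateCube]:
    """Synthesize future cubes: per-GCM uniform warming offset plus seasonal
    precipitation scaling, applied to the base series and relabelled to the
    future window."""
    rng = np.random.default_rng(params.seed)
    members = []
    wet_idx = np.array([m - 1 for m in sorted(params.wet_months)])
    for _ in range(params.n_gcms):
        dt = rng.uniform(*params.warming_range)
        f_wet = rng.uniform(*params.precip_change_wet)
        f_dry = rng.uniform(*params.precip_change_dry)
        factor = np.full(12, 1.0 + f_dry)
        factor[wet_idx] = 1.0 + f_wet
        precip = base.precip * factor[None, :, None, None]
        temp = base.temp + dt
        members.append(MonthlyClimateCube(precip=precip, temp=temp,
                                          start_year=params.future_start_year))
    return members


def generate_observed_discharge(
    true_series: DischargeSeries, noise_cv: float, seed: int
) -> DischargeSeries:
    """Pseudo-gauge record: multiplicative lognormal noise with unit mean and
    coefficient of variation ``noise_cv``; zero flows stay zero."""
    if noise_cv < 0:
        raise ValueError("noise_cv must be nonnegative")
    q = np.asarray(true_series.q, dtype=float)
    if noise_cv == 0:
        noisy = q.copy()
    else:
        sigma2 = np.log1p(noise_cv**2)
        rng = np.random.default_rng(seed)
        factors = rng.lognormal(mean=-sigma2 / 2.0, sigma=np.sqrt(sigma2), size=q.shape)
        noisy = q * factors
    return DischargeSeries(outlet_id=true_series.outlet_id, q=noisy,
                           start_year=true_series.start_year,
                           start_month=true_series.start_month)
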