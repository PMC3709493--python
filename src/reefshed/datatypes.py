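"""Shared containers for grids, climate cubes and time series.

All rasters are 2-D ``float64``/``int64`` numpy arrays on a common rectangular
grid; ``nan`` (float) or negative codes (int) mark nodata.  A climate cube is a
dense ``(n_years, 12, nrows, ncols)`` array pair — precipitation in mm/month
and air temperature in °C — labelled by its first calendar year.
"""

from __future__ import annotations

import calendar
from dataclasses import dataclass, field

import numpy as np

# Land-cover class codes.
FOREST = 1
GRASSLAND = 2
CROPLAND = 3
BARE = 4
WATER = 5
DEFORESTED = 6  # former forest, carries the weighted non-forest factors
NODATA_INT = -1

LANDCOVER_NAMES = {
    FOREST: "forest",
    GRASSLAND: "grassland",
    CROPLAND: "cropland",
    BARE: "bare",
    WATER: "water",
    DEFORESTED: "deforested",
}

# Hydrologic soil groups A–D, coded 1–4 (A = highest infiltration).
HSG_A, HSG_B, HSG_C, HSG_D = 1, 2, 3, 4
HSG_NAMES = {HSG_A: "A", HSG_B: "B", HSG_C: "C", HSG_D: "D"}

# Region codes (quadrant analogues of the four coastal catchments).
REGION_NE, REGION_NW, REGION_W, REGION_SW = 1, 2, 3, 4
REGION_NAMES = {REGION_NE: "NE", REGION_NW: "NW", REGION_W: "W", REGION_SW: "SW"}


@dataclass
class WatershedStack:
    """Aligned raster stack describing one synthetic watershed domain.

    Every grid shares shape, cell size and nodata mask.  ``outlets`` maps a
    region code to the (row, col) of that region's gauged outlet cell.
    """

    dem: np.ndarray          # elevation, m
    whc: np.ndarray          # soil water-holding capacity, mm
    sand: np.ndarray         # %
    silt: np.ndarray         # %
    clay: np.ndarray         # %
    org_carbon: np.ndarray   # %
    hsg: np.ndarray          # int codes 1–4 (A–D)
    landcover: np.ndarray    # int class codes
    road_dist: np.ndarray    # distance to nearest road, m
    region: np.ndarray       # int region codes
    cell_size: float         # m
    outlets: dict[int, tuple[int, int]] = field(default_factory=dict)

    @property
    def shape(self) -> tuple[int, int]:
        return self.dem.shape

    @property
    def valid(self) -> np.ndarray:
        return ~np.isnan(self.dem)

    @property
    def cell_area(self) -> float:
        """Cell area in m²."""
        return float(self.cell_size) ** 2

    def validate(self) -> None:
        shp = self.dem.shape
        for name in ("whc", "sand", "silt", "clay", "org_carbon", "hsg",
                     "landcover", "road_dist", "region"):
            if getattr(self, name).shape != shp:
                raise ValueError(f"grid {name!r} shape {getattr(self, name).shape} != {shp}")
        v = self.valid
        if np.any(self.whc[v] < 0):
            raise ValueError("negative water-holding capacity")
        tex = self.sand + self.silt + self.clay
        if np.any(np.abs(tex[v] - 100.0) > 0.5):
            raise ValueError("soil fractions do not sum to 100 ± 0.5")


@dataclass
class MonthlyClimateCube:
    """Monthly precipitation (mm) and temperature (°C) per cell and year."""

    precip: np.ndarray  # (n_years, 12, nrows, ncols)
    temp: np.ndarray    # same shape
    start_year: int

    def __post_init__(self) -> None:
        if self.precip.shape != self.temp.shape:
            raise ValueError("precip and temp shapes differ")
        if self.precip.ndim != 4 or self.precip.shape[1] != 12:
            raise ValueError("cube must have shape (n_years, 12, nrows, ncols)")

    @property
    def n_years(self) -> int:
        return self.precip.shape[0]

    @property
    def grid_shape(self) -> tuple[int, int]:
        return self.precip.shape[2:]

    @property
    def years(self) -> np.ndarray:
        return np.arange(self.start_year, self.start_year + self.n_years)

    def copy(self) -> "MonthlyClimateCube":
        return MonthlyClimateCube(self.precip.copy(), self.temp.copy(), self.start_year)


@dataclass
class DischargeSeries:
    """Monthly outlet discharge in m³ s⁻¹, starting at January of start_year
    unless ``start_month`` says otherwise (1-based)."""

    outlet_id: int | str
    q: np.ndarray            # m³ s⁻¹ per month
    start_year: int
    start_month: int = 1

    def __len__(self) -> int:
        return len(self.q)


@dataclass
class SedimentRecord:
    """Annual watershed sediment yield."""

    watershed_id: int | str
    year: int
    yield_t: float           # tonnes yr⁻¹
    yield_t_per_ha: float    # tonnes ha⁻¹ yr⁻¹


def month_days(year: int, month: int) -> int:
    """Actual calendar length of a month (1-based month)."""
    return calendar.monthrange(year, month)[1]


def month_seconds(year: int, month: int) -> float:
    return month_days(year, month) * 86400.0
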