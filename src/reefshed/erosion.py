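"""Annual hillslope erosion and watershed sediment yield.

Cell soil loss follows RUSLE, A = R·K·LS·C·P: rainfall erosivity R from the
Modified Fournier Index through a power law, soil erodibility K from texture
and organic carbon (Williams/EPIC form), the topographic LS factor from the
terrain module, and land-cover C from the scenario tables.  Gross hillslope
loss is reduced to outlet yield by a lumped sediment-delivery ratio.  A
curve-number runoff channel (SCS) is computed as a diagnostic alongside.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datatypes import (
    BARE,
    CROPLAND,
    DEFORESTED,
    FOREST,
    GRASSLAND,
    HSG_A,
    HSG_B,
    HSG_C,
    HSG_D,
    WATER,
    SedimentRecord,
)


@dataclass
class ErosivityModel:
    """Power-law map from annual MFI to rainfall erosivity, R = a·MFI^b."""

    a: float = 0.264
    b: float = 1.50

    def __post_init__(self) -> None:
        if self.a <= 0 or self.b <= 0:
            raise ValueError("erosivity coefficients must be positive")


@dataclass
class RusleFactors:
    r: np.ndarray | float
    k: np.ndarray | float
    ls: np.ndarray | float
    c: np.ndarray | float
    p_factor: np.ndarray | float = 1.0


def mfi(monthly_precip: np.ndarray) -> np.ndarray | float:
    """Modified Fournier Index, Σ pᵢ² / Σ pᵢ over the 12 months (axis 0).

    Equals the monthly amount for uniform rain and the annual total when all
    rain falls in one month; an all-zero year maps to 0 by convention.
    """
    p = np.asarray(monthly_precip, dtype=float)
    if p.shape[0] != 12:
        raise ValueError("mfi needs 12 monthly values along the first axis")
    if np.nanmin(p) < 0:
        raise ValueError("negative precipitation")
    total = p.sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(total > 0, (p**2).sum(axis=0) / np.where(total > 0, total, 1.0), 0.0)
    if np.isscalar(monthly_precip[0]) or np.ndim(monthly_precip) == 1:
        return float(out)
    return out


def erosivity_from_mfi(mfi_values: np.ndarray | float, model: ErosivityModel) -> np.ndarray | float:
    """R = a·MFI^b, elementwise and monotone in MFI."""
    m = np.asarray(mfi_values, dtype=float)
    if np.nanmin(m) < 0:
        raise ValueError("negative MFI")
    return model.a * m**model.b


def k_factor(
    sand: np.ndarray | float,
    silt: np.ndarray | float,
    clay: np.ndarray | float,
    org_carbon: np.ndarray | float,
) -> np.ndarray | float:
    """Soil erodibility from texture fractions (%) and organic carbon (%).

    Williams/EPIC formulation: coarse, organic-rich soils resist erosion
    (K ≈ 0.05–0.2) while silty, carbon-poor soils erode easily (K ≳ 0.4).
    """
    sa = np.asarray(sand, dtype=float)
    si = np.asarray(silt, dtype=float)
    cl = np.asarray(clay, dtype=float)
    oc = np.asarray(org_carbon, dtype=float)
    tot = sa + si + cl
    bad = np.abs(tot - 100.0) > 0.5
    if np.any(bad[~np.isnan(tot)] if np.ndim(tot) else (bad and not np.isnan(tot))):
        raise ValueError("sand+silt+clay must sum to 100 ± 0.5")
    f_coarse = 0.2 + 0.3 * np.exp(-0.0256 * sa * (1.0 - si / 100.0))
    f_clsi = (si / np.maximum(cl + si, 1e-12)) ** 0.3
    f_org = 1.0 - 0.25 * oc / (oc + np.exp(3.72 - 2.95 * oc))
    sn1 = 1.0 - sa / 100.0
    f_sand = 1.0 - 0.7 * sn1 / (sn1 + np.exp(-5.51 + 22.9 * sn1))
    k = f_coarse * f_clsi * f_org * f_sand
    return float(k) if np.ndim(k) == 0 else k


#: Default curve numbers per land-cover class for hydrologic soil groups A–D.
DEFAULT_CN_TABLE: dict[int, tuple[int, int, int, int]] = {
    FOREST: (30, 55, 70, 77),
    GRASSLAND: (39, 61, 74, 80),
    CROPLAND: (67, 78, 85, 89),
    BARE: (77, 86, 91, 94),
    DEFORESTED: (60, 75, 83, 87),
    WATER: (98, 98, 98, 98),
}


def curve_number(
    hsg: np.ndarray | int,
    landcover: np.ndarray | int,
    table: dict[int, tuple[int, int, int, int]] | None = None,
) -> np.ndarray | float:
    """Look up the SCS curve number for (land cover, soil group).

    The default table is monotone: wetter-response groups (A→D) and barer
    covers carry higher numbers.
    """
    if table is None:
        table = DEFAULT_CN_TABLE
    h = np.asarray(hsg)
    lc = np.asarray(landcover)
    if h.ndim == 0:
        cls, grp = int(lc), int(h)
        if cls not in table:
            raise KeyError(f"no curve-number row for land-cover class {cls}")
        if grp not in (HSG_A, HSG_B, HSG_C, HSG_D):
            raise KeyError(f"unknown hydrologic soil group code {grp}")
        return float(table[cls][grp - 1])
    out = np.full(h.shape, np.nan)
    for cls in np.unique(lc[lc > 0]):
        if int(cls) not in table:
            raise KeyError(f"no curve-number row for land-cover class {int(cls)}")
        row = table[int(cls)]
        for grp in (HSG_A, HSG_B, HSG_C, HSG_D):
            out[(lc == cls) & (h == grp)] = row[grp - 1]
    return out


def scs_runoff(precip: np.ndarray | float, cn: np.ndarray | float) -> np.ndarray | float:
    """SCS curve-number direct runoff (mm) for an event/period depth.

    S = 25400/CN − 254; Q = 0 below the initial abstraction 0.2 S, else
    (P − 0.2S)² / (P + 0.8S).  Always 0 ≤ Q ≤ P.
    """
    p = np.asarray(precip, dtype=float)
    c = np.asarray(cn, dtype=float)
    if np.nanmin(p) < 0:
        raise ValueError("negative precipitation")
    if np.nanmin(c) < 30 or np.nanmax(c) > 100:
        raise ValueError("curve number outside [30, 100]")
    s = 25400.0 / c - 254.0
    ia = 0.2 * s
    with np.errstate(invalid="ignore"):
        q = np.where(p > ia, (p - ia) ** 2 / (p + 0.8 * s), 0.0)
    return float(q) if q.ndim == 0 else q


def rusle_cell(factors: RusleFactors) -> np.ndarray | float:
    """Annual soil loss A = R·K·LS·C·P, t ha⁻¹ yr⁻¹; linear in each factor."""
    a = factors.r * factors.k * factors.ls * factors.c * factors.p_factor
    return a


def annual_sediment_yield(
    a_grid: np.ndarray,
    watershed_mask: np.ndarray,
    cell_area: float,
    sdr: float = 0.1,
    watershed_id: int | str = 0,
    year: int = 0,
) -> SedimentRecord:
    """Reduce gross cell loss (t ha⁻¹ yr⁻¹) to outlet yield via the SDR.

    yield_t = sdr · Σ_mask A · cell_area/10⁴;  per-hectare yield divides by
    the masked area in ha.
    """
    if not 0.0 < sdr <= 1.0:
        raise ValueError("sdr must lie in (0, 1]")
    if not watershed_mask.any():
        raise ValueError("empty watershed mask")
    ha = cell_area / 1e4
    gross = np.nansum(a_grid[watershed_mask]) * ha
    total = sdr * gross
    area_ha = watershed_mask.sum() * ha
    return SedimentRecord(
        watershed_id=watershed_id, year=year,
        yield_t=float(total), yield_t_per_ha=float(total / area_ha),
    )


@dataclass
class ErosionConfig:
    erosivity: ErosivityModel = field(default_factory=ErosivityModel)
    sdr: float = 0.1
    p_factor: float = 1.0
    cn_table: dict[int, tuple[int, int, int, int]] = field(
        default_factory=lambda: dict(DEFAULT_CN_TABLE))


def run_annual(
    precip_year: np.ndarray,
    c_grid: np.ndarray,
    k_grid: np.ndarray,
    ls_grid: np.ndarray,
    masks: dict[int | str, np.ndarray],
    cell_area: float,
    config: ErosionConfig,
    year: int = 0,
) -> dict[int | str, SedimentRecord]:
    """One year of the erosion chain: per-cell MFI → R → RUSLE → yields.

    ``precip_year`` is the (12, nrows, ncols) monthly stack of that year;
    ``masks`` maps watershed ids to boolean masks.  Deterministic composition
    of the component operators.
    """
    if precip_year.shape[0] != 12:
        raise ValueError("precip_year must hold 12 monthly grids")
    mfi_grid = mfi(precip_year)
    r_grid = erosivity_from_mfi(mfi_grid, config.erosivity)
    a_grid = rusle_cell(RusleFactors(r=r_grid, k=k_grid, ls=ls_grid,
                                     c=c_grid, p_factor=config.p_factor))
    return {
        wid: annual_sediment_yield(a_grid, mask, cell_area, config.sdr,
                                   watershed_id=wid, year=year)
        for wid, mask in masks.items()
    }
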