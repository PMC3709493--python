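"""Delta-method climate downscaling building blocks.

A GCM's coarse signal enters as the change between two monthly climatologies —
additive for temperature, multiplicative for precipitation — and is applied to
the higher-resolution present-day monthly series.  Seasons default to the
Southern-Hemisphere convention (wet Nov–Apr, dry May–Oct).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datatypes import MonthlyClimateCube

WET_MONTHS = frozenset({11, 12, 1, 2, 3, 4})
DRY_MONTHS = frozenset({5, 6, 7, 8, 9, 10})


@dataclass
class MonthlyClimatology:
    """Per-cell 12-vector of monthly means over a stated year window."""

    precip: np.ndarray  # (12, nrows, ncols), mm/month
    temp: np.ndarray    # (12, nrows, ncols), °C
    window: tuple[int, int]  # inclusive (start_year, end_year)


@dataclass
class DeltaFields:
    """Monthly change fields of one GCM × scenario: additive temperature
    anomaly (°C) and multiplicative precipitation ratio (dimensionless)."""

    temp_delta: np.ndarray    # (12, nrows, ncols)
    precip_ratio: np.ndarray  # (12, nrows, ncols), ≥ 0 and finite
    source: str = ""


@dataclass
class ScenarioSpec:
    climate_id: str            # "present", "B1", "A1b", "A2"
    lulcc_id: str
    gcm_ids: list[str] = field(default_factory=list)
    baseline_window: tuple[int, int] = (1975, 2005)
    future_window: tuple[int, int] = (2065, 2095)

    def __post_init__(self) -> None:
        if self.climate_id == "present" and self.gcm_ids:
            raise ValueError("present-day climate takes no GCMs")


def monthly_climatology(cube: MonthlyClimateCube, window: tuple[int, int] | None = None) -> MonthlyClimatology:
    """Arithmetic mean of each calendar month over the window years."""
    if window is None:
        window = (cube.start_year, cube.start_year + cube.n_years - 1)
    y0, y1 = window
    i0 = y0 - cube.start_year
    i1 = y1 - cube.start_year + 1
    if i0 < 0 or i1 > cube.n_years or i1 - i0 < 2:
        raise ValueError(f"window {window} outside cube coverage or shorter than 2 years")
    return MonthlyClimatology(
        precip=cube.precip[i0:i1].mean(axis=0),
        temp=cube.temp[i0:i1].mean(axis=0),
        window=(y0, y1),
    )


def running_monthly_climatology(cube: MonthlyClimateCube, window_length: int = 31) -> list[MonthlyClimatology]:
    """All consecutive ``window_length``-year climatologies, earliest first.

    Window i covers years [start_year + i, start_year + i + window_length - 1];
    the window label is that inclusive year pair.
    """
    if cube.n_years < window_length:
        raise ValueError("cube coverage shorter than the running window")
    out = []
    for i in range(cube.n_years - window_length + 1):
        y0 = cube.start_year + i
        out.append(monthly_climatology(cube, (y0, y0 + window_length - 1)))
    return out


def temperature_delta(future_clim: MonthlyClimatology, baseline_clim: MonthlyClimatology) -> np.ndarray:
    """Signed monthly anomaly, future − baseline (°C)."""
    if future_clim.temp.shape != baseline_clim.temp.shape:
        raise ValueError("climatology grids not aligned")
    return future_clim.temp - baseline_clim.temp


def precipitation_ratio(
    future_clim: MonthlyClimatology,
    baseline_clim: MonthlyClimatology,
    zero_floor: float = 1.0,
    ceiling: float = 10.0,
) -> np.ndarray:
    """Monthly multiplier future / max(baseline, floor), clamped to ``ceiling``.

    The floor (default 1 mm/month) keeps the ratio finite where the baseline
    is dry; the ceiling bounds physically meaningless blow-ups.
    """
    if zero_floor <= 0:
        raise ValueError("zero_floor must be positive")
    if future_clim.precip.shape != baseline_clim.precip.shape:
        raise ValueError("climatology grids not aligned")
    fut, base = future_clim.precip, baseline_clim.precip
    if np.nanmin(fut) < 0 or np.nanmin(base) < 0:
        raise ValueError("negative precipitation in climatology")
    ratio = fut / np.maximum(base, zero_floor)
    return np.minimum(ratio, ceiling)


def apply_delta(present: MonthlyClimateCube, deltas: DeltaFields) -> MonthlyClimateCube:
    """Perturb a present-day series: T' = T + ΔT(m), P' = P × ratio(m)."""
    if deltas.temp_delta.shape != (12,) + tuple(present.grid_shape):
        raise ValueError("delta fields not aligned with cube grid")
    temp = present.temp + deltas.temp_delta[None, :, :, :]
    precip = present.precip * deltas.precip_ratio[None, :, :, :]
    return MonthlyClimateCube(precip=precip, temp=temp, start_year=present.start_year)


def delta_fields(
    future_clim: MonthlyClimatology,
    baseline_clim: MonthlyClimatology,
    zero_floor: float = 1.0,
    ceiling: float = 10.0,
    source: str = "",
) -> DeltaFields:
    """Bundle the temperature anomaly and precipitation ratio of one member."""
    return DeltaFields(
        temp_delta=temperature_delta(future_clim, baseline_clim),
        precip_ratio=precipitation_ratio(future_clim, baseline_clim, zero_floor, ceiling),
        source=source,
    )


def identity_deltas(grid_shape: tuple[int, int], source: str = "identity") -> DeltaFields:
    return DeltaFields(
        temp_delta=np.zeros((12,) + tuple(grid_shape)),
        precip_ratio=np.ones((12,) + tuple(grid_shape)),
        source=source,
    )


def ensemble_summary(members: list[np.ndarray] | list[float], stat: str = "mean") -> np.ndarray | float:
    """Elementwise mean or median across ensemble members."""
    if len(members) == 0:
        raise ValueError("empty ensemble")
    arr = np.asarray(members, dtype=float)
    if stat == "mean":
        return arr.mean(axis=0)
    if stat == "median":
        return np.median(arr, axis=0)
    raise ValueError(f"unknown stat {stat!r}")


def seasonal_change(
    present: MonthlyClimateCube,
    future: MonthlyClimateCube,
    season: frozenset[int] | set[int],
    variable: str,
    mode: str,
    region_mask: np.ndarray | None = None,
) -> float:
    """Season-mean change between two cubes over the (optionally masked) grid.

    ``additive`` returns mean(future) − mean(present); ``proportional``
    returns the ratio of season means minus 1.
    """
    if not season:
        raise ValueError("empty season set")
    idx = sorted(m - 1 for m in season)
    p = getattr(present, variable)[:, idx]
    f = getattr(future, variable)[:, idx]
    if region_mask is not None:
        p = p[..., region_mask]
        f = f[..., region_mask]
    pm, fm = float(np.nanmean(p)), float(np.nanmean(f))
    if mode == "additive":
        return fm - pm
    if mode == "proportional":
        return fm / pm - 1.0
    raise ValueError(f"unknown mode {mode!r}")
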