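"""Distributed monthly water-balance hydrology.

Each cell keeps a soil-moisture store bounded by its water-holding capacity
and a linear groundwater reservoir.  Per month: potential evapotranspiration
(Thornthwaite, temperature-only) is scaled by the land-cover crop factor to a
demand; actual ET draws on rain plus soil moisture; surplus above capacity
splits into quickflow (``direct_fraction``) and groundwater recharge, and the
groundwater store releases a fixed ``gw_recession`` fraction per month.  The
balance P = AET + runoff + Δstores closes to machine precision by
construction.  Cell runoff is converted to outlet discharge (m³ s⁻¹) by
summing volumes over the outlet's watershed mask and dividing by the actual
calendar month length.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from . import terrain
from .datatypes import DischargeSeries, MonthlyClimateCube, WatershedStack, month_seconds


@dataclass
class HydroParams:
    direct_fraction: float = 0.4   # share of surplus that becomes quickflow
    gw_recession: float = 0.3      # monthly groundwater outflow fraction
    spinup_months: int = 24        # discarded from all outputs
    daylength_hours: float = 12.0  # Thornthwaite day-length factor

    def __post_init__(self) -> None:
        if not 0.0 <= self.direct_fraction <= 1.0:
            raise ValueError("direct_fraction must lie in [0,1]")
        if not 0.0 < self.gw_recession <= 1.0:
            raise ValueError("gw_recession must lie in (0,1]")


@dataclass
class CellWaterState:
    soil_store: np.ndarray | float  # mm, in [0, whc]
    gw_store: np.ndarray | float    # mm, ≥ 0


def potential_et(
    monthly_temp: np.ndarray,
    daylength_hours: float = 12.0,
    days_in_month: np.ndarray | None = None,
) -> np.ndarray:
    """Thornthwaite potential evapotranspiration, mm/month.

    ``monthly_temp`` holds the 12 monthly mean temperatures along its first
    axis (any trailing grid axes).  The annual heat index I = Σ (T/5)^1.514
    over months with T > 0; PET = 16 (L/12)(N/30)(10 T / I)^a with the usual
    cubic a(I).  Months at or below 0 °C evaporate nothing.
    """
    t = np.asarray(monthly_temp, dtype=float)
    if t.shape[0] != 12:
        raise ValueError("potential_et needs 12 monthly mean temperatures")
    if days_in_month is None:
        days = np.full(12, 30.0)
    else:
        days = np.asarray(days_in_month, dtype=float)
    tp = np.maximum(t, 0.0)
    heat = np.sum((tp / 5.0) ** 1.514, axis=0)
    a = 6.75e-7 * heat**3 - 7.71e-5 * heat**2 + 1.7912e-2 * heat + 0.49239
    shape = [12] + [1] * (t.ndim - 1)
    day_fac = (days / 30.0).reshape(shape)
    with np.errstate(divide="ignore", invalid="ignore"):
        pet = 16.0 * (daylength_hours / 12.0) * day_fac * (10.0 * tp / heat) ** a
    pet = np.where((tp <= 0.0) | (heat <= 0.0), 0.0, pet)
    return pet


def step_cell(
    precip: np.ndarray | float,
    pet: np.ndarray | float,
    kc: np.ndarray | float,
    whc: np.ndarray | float,
    state: CellWaterState,
    params: HydroParams,
) -> tuple[np.ndarray | float, CellWaterState]:
    """Advance one month; returns (runoff mm, new state).

    Works elementwise on grids or scalars.  The water balance
    P = AET + runoff + Δsoil + Δgw closes exactly.
    """
    if np.any(np.asarray(whc) < 0):
        raise ValueError("negative water-holding capacity")
    demand = kc * pet
    available = precip + state.soil_store
    aet = np.minimum(demand, available)
    soil = available - aet
    surplus = np.maximum(soil - whc, 0.0)
    soil = np.minimum(soil, whc)
    quick = params.direct_fraction * surplus
    gw_in = state.gw_store + (1.0 - params.direct_fraction) * surplus
    baseflow = params.gw_recession * gw_in
    runoff = quick + baseflow
    new_state = CellWaterState(soil_store=soil, gw_store=gw_in - baseflow)
    return runoff, new_state


@dataclass
class SimulationResult:
    """Runoff stack plus mass-balance diagnostics for one simulation."""

    runoff: np.ndarray            # (n_out_months, nrows, ncols), mm/month
    start_year: int
    start_month: int              # 1-based, first month after spin-up
    month_lengths: np.ndarray     # seconds per output month
    balance_error: np.ndarray     # per-cell |P − AET − R − Δstores|, mm
    total_precip: float           # basin total over the whole run, mm·cells
    final_state: CellWaterState = field(repr=False, default=None)

    @property
    def max_rel_balance_error(self) -> float:
        return float(np.nanmax(self.balance_error) / max(self.total_precip, 1e-300))


def simulate(
    stack: WatershedStack,
    climate: MonthlyClimateCube,
    kc_grid: np.ndarray,
    params: HydroParams,
) -> SimulationResult:
    """Run the monthly water balance over the whole cube.

    Stores start empty; the first ``spinup_months`` are simulated but dropped
    from the returned runoff stack so initialization does not contaminate
    statistics.
    """
    if tuple(climate.grid_shape) != stack.shape or kc_grid.shape != stack.shape:
        raise ValueError("climate cube / kc grid not aligned with stack")
    n_months = climate.n_years * 12
    if params.spinup_months >= n_months:
        raise ValueError("spin-up consumes the whole simulation")
    valid = stack.valid
    whc = np.where(valid, stack.whc, 0.0)
    kc = np.where(valid, kc_grid, 0.0)
    state = CellWaterState(
        soil_store=np.zeros(stack.shape), gw_store=np.zeros(stack.shape)
    )
    out_months = n_months - params.spinup_months
    runoff_out = np.empty((out_months, *stack.shape))
    seconds = np.empty(out_months)
    sum_p = np.zeros(stack.shape)
    sum_aet_r = np.zeros(stack.shape)  # AET + runoff accumulated
    t_out = 0
    for y in range(climate.n_years):
        year = climate.start_year + y
        pet_year = potential_et(climate.temp[y], params.daylength_hours,
                                days_in_month=np.array(
                                    [month_seconds(year, m + 1) / 86400.0 for m in range(12)]))
        for m in range(12):
            p = np.where(valid, climate.precip[y, m], 0.0)
            demand = kc * pet_year[m]
            available = p + state.soil_store
            aet = np.minimum(demand, available)
            soil = available - aet
            surplus = np.maximum(soil - whc, 0.0)
            soil = soil - surplus  # == min(soil, whc) but exact for balance
            quick = params.direct_fraction * surplus
            gw_in = state.gw_store + (1.0 - params.direct_fraction) * surplus
            baseflow = params.gw_recession * gw_in
            runoff = quick + baseflow
            state = CellWaterState(soil_store=soil, gw_store=gw_in - baseflow)
            sum_p += p
            sum_aet_r += aet + runoff
            t = y * 12 + m
            if t >= params.spinup_months:
                runoff_out[t_out] = np.where(valid, runoff, np.nan)
                seconds[t_out] = month_seconds(year, m + 1)
                t_out += 1
    d_store = state.soil_store + state.gw_store  # initial stores were zero
    balance = np.where(valid, np.abs(sum_p - sum_aet_r - d_store), np.nan)
    start_total = params.spinup_months
    return SimulationResult(
        runoff=runoff_out,
        start_year=climate.start_year + start_total // 12,
        start_month=start_total % 12 + 1,
        month_lengths=seconds,
        balance_error=balance,
        total_precip=float(np.nansum(np.where(valid, sum_p, 0.0))),
        final_state=state,
    )


def route_discharge(
    runoff_grid: np.ndarray,
    fdir: terrain.FlowDirectionGrid,
    outlet: tuple[int, int],
    cell_area: float,
    month_secs: float,
) -> float:
    """Discharge at an outlet for one month, m³ s⁻¹.

    Q = Σ over the outlet's watershed of runoff·10⁻³·cell_area, divided by the
    month length in seconds.  Equivalent to the terrain accumulation of runoff
    volumes evaluated at the outlet.
    """
    r0, c0 = outlet
    if not (0 <= r0 < fdir.shape[0] and 0 <= c0 < fdir.shape[1]):
        raise ValueError("outlet outside grid")
    if np.nanmin(runoff_grid) < 0:
        raise ValueError("negative runoff")
    mask = terrain.delineate_watershed(fdir, outlet)
    volume = np.nansum(runoff_grid[mask]) * 1e-3 * cell_area
    return float(volume / month_secs)


def discharge_series(
    sim: SimulationResult,
    mask: np.ndarray,
    cell_area: float,
    outlet_id: int | str = 0,
) -> DischargeSeries:
    """Monthly discharge at an outlet from a simulation's runoff stack."""
    flat = sim.runoff.reshape(sim.runoff.shape[0], -1)
    vols = np.nansum(flat[:, mask.ravel()], axis=1) * 1e-3 * cell_area
    q = vols / sim.month_lengths
    return DischargeSeries(outlet_id=outlet_id, q=q,
                           start_year=sim.start_year, start_month=sim.start_month)


def nse(observed: np.ndarray, modeled: np.ndarray) -> float:
    """Nash–Sutcliffe efficiency: 1 − Σ(O−M)²/Σ(O−Ō)²; 1 is perfect."""
    o = np.asarray(observed, dtype=float)
    m = np.asarray(modeled, dtype=float)
    if o.shape != m.shape or o.size < 2:
        raise ValueError("series must share length ≥ 2")
    denom = np.sum((o - o.mean()) ** 2)
    if denom == 0:
        raise ValueError("NSE undefined for constant observations")
    return float(1.0 - np.sum((o - m) ** 2) / denom)


def modeled_observed_ratio(observed: np.ndarray, modeled: np.ndarray) -> float:
    """Ratio of modeled to observed means — a bias check on total volume."""
    o = np.asarray(observed, dtype=float)
    if o.mean() <= 0:
        raise ValueError("observed mean must be positive")
    return float(np.asarray(modeled, dtype=float).mean() / o.mean())


@dataclass
class CalibrationResult:
    params: HydroParams
    nse: float
    ratio: float
    trials: list[tuple[float, float, float]] = field(default_factory=list)
    # trials rows: (direct_fraction, gw_recession, nse)


def calibrate(
    stack: WatershedStack,
    climate: MonthlyClimateCube,
    kc_grid: np.ndarray,
    observed: DischargeSeries,
    mask: np.ndarray,
    direct_fractions: list[float] | None = None,
    gw_recessions: list[float] | None = None,
    spinup_months: int = 24,
) -> CalibrationResult:
    """Exhaustive grid search maximizing NSE at the calibration outlet.

    Ties go to the first candidate in (direct_fraction, gw_recession) grid
    order.  ``mask`` is the watershed mask of the gauged outlet.
    """
    if direct_fractions is None:
        direct_fractions = [round(0.1 * i, 2) for i in range(1, 10)]
    if gw_recessions is None:
        gw_recessions = [round(0.1 * i, 2) for i in range(1, 10)]
    if not direct_fractions or not gw_recessions:
        raise ValueError("empty calibration grid")
    best = None
    trials = []
    for df, gr in itertools.product(direct_fractions, gw_recessions):
        params = HydroParams(direct_fraction=df, gw_recession=gr,
                             spinup_months=spinup_months)
        sim = simulate(stack, climate, kc_grid, params)
        series = discharge_series(sim, mask, stack.cell_area)
        if len(series.q) != len(observed.q):
            raise ValueError("observed series length does not match simulation")
        score = nse(observed.q, series.q)
        trials.append((df, gr, score))
        if best is None or score > best[0]:
            best = (score, params, modeled_observed_ratio(observed.q, series.q))
    if best is None:
        raise RuntimeError("no valid candidate")
    return CalibrationResult(params=best[1], nse=best[0], ratio=best[2], trials=trials)
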