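"""Flow→sediment regression and the climate × land-use scenario grid.

Future sediment is not re-run through the erosion model: following the study
design, present-day annual yields are regressed on annual flow statistics
(mean, maximum, minimum discharge) and the best-fitting relationship — in
practice annual maximum flow — projects yields under the perturbed climates.
One regression is fitted per watershed and per land-use configuration, so the
land-use signal carries into the future columns.  The grid reports each
(LULCC × climate) cell as a fractional change relative to the
(2000 land use × present climate) reference, alongside a companion ratio
relative to the natural (biome) configuration.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sstats

from . import climate as clim
from . import erosion as ero
from . import hydrology as hyd
from . import lulcc
from . import terrain
from .datatypes import REGION_NAMES, DischargeSeries, MonthlyClimateCube, WatershedStack

logger = logging.getLogger(__name__)

FLOW_STATS = ("annual_mean", "annual_max", "annual_min")


@dataclass
class FlowSedimentRegression:
    flow_stat: str
    intercept: float          # tonnes yr⁻¹
    slope: float              # tonnes yr⁻¹ per m³ s⁻¹
    r_squared: float
    n: int
    intercept_stderr: float = float("nan")
    slope_stderr: float = float("nan")
    all_r_squared: dict[str, float] = field(default_factory=dict)


def annual_flow_stats(discharge: DischargeSeries) -> pd.DataFrame:
    """Per-calendar-year mean, max and min of monthly discharge.

    A partial leading year (series starting mid-year) and a partial trailing
    year are dropped; at least one complete year must remain.
    """
    q = np.asarray(discharge.q, dtype=float)
    if len(q) < 12:
        raise ValueError("need at least 12 months of discharge")
    start = 0
    year = discharge.start_year
    if discharge.start_month != 1:
        start = 13 - discharge.start_month
        year += 1
    n_full = (len(q) - start) // 12
    if n_full < 1:
        raise ValueError("no complete calendar year in the series")
    rows = []
    for i in range(n_full):
        block = q[start + 12 * i: start + 12 * (i + 1)]
        rows.append({"year": year + i, "annual_mean": block.mean(),
                     "annual_max": block.max(), "annual_min": block.min()})
    return pd.DataFrame(rows).set_index("year")


def fit_flow_sediment(
    flow_stats: pd.DataFrame,
    sediment: pd.Series | np.ndarray,
    stat: str | None = None,
) -> FlowSedimentRegression:
    """OLS of annual yield on each candidate flow statistic; keep the best r².

    Ties (and an all-degenerate response) resolve to ``annual_max``.
    Zero-variance predictors are skipped; if every predictor is degenerate the
    fit fails.  ``stat`` forces the returned relationship to one named
    statistic (all three r² are still reported) — the scenario grid uses this
    to keep a single statistic per watershed across land-use configurations.
    """
    y = np.asarray(sediment, dtype=float)
    if len(y) != len(flow_stats):
        raise ValueError("sediment and flow stats years misaligned")
    if len(y) < 3:
        raise ValueError("need at least 3 years to fit")
    fits: dict[str, FlowSedimentRegression] = {}
    r2 = {}
    for name in FLOW_STATS:
        x = flow_stats[name].to_numpy(dtype=float)
        if np.ptp(x) == 0.0:
            continue
        if np.ptp(y) == 0.0:
            fits[name] = FlowSedimentRegression(
                flow_stat=name, intercept=float(y.mean()), slope=0.0,
                r_squared=0.0, n=len(y))
            r2[name] = 0.0
            continue
        res = sstats.linregress(x, y)
        fits[name] = FlowSedimentRegression(
            flow_stat=name, intercept=float(res.intercept), slope=float(res.slope),
            r_squared=float(res.rvalue**2), n=len(y),
            intercept_stderr=float(res.intercept_stderr),
            slope_stderr=float(res.stderr))
        r2[name] = fits[name].r_squared
    if not fits:
        raise ValueError("all flow statistics are degenerate (zero variance)")
    if stat is not None:
        if stat not in fits:
            raise ValueError(f"requested statistic {stat!r} is degenerate or unknown")
        best_name = stat
    else:
        # highest r² wins; ties go to annual_max
        best = max(r2.values())
        if r2.get("annual_max", -1.0) == best:
            best_name = "annual_max"
        else:
            best_name = max(r2, key=r2.get)
    fit = fits[best_name]
    fit.all_r_squared = r2
    return fit


def project_sediment(
    regression: FlowSedimentRegression, future_stats: pd.DataFrame
) -> np.ndarray:
    """Apply yield = max(0, a + b·stat) per future year (clamp logged)."""
    if regression.flow_stat not in future_stats.columns:
        raise ValueError(f"future stats lack column {regression.flow_stat!r}")
    x = future_stats[regression.flow_stat].to_numpy(dtype=float)
    y = regression.intercept + regression.slope * x
    if np.any(y < 0):
        logger.warning("clamping %d negative projected yields to 0", int((y < 0).sum()))
        y = np.maximum(y, 0.0)
    return y


def fractional_change(scenario_mean: float, reference_mean: float) -> float:
    """Scenario mean divided by reference mean."""
    if reference_mean <= 0:
        raise ValueError("reference mean must be positive")
    return float(scenario_mean / reference_mean)


@dataclass
class ScenarioGridResult:
    """Table-shaped summary plus the per-GCM long table."""

    table: pd.DataFrame      # lulcc_id, climate_id, region, fractional_change_mean/sd, ...
    per_gcm: pd.DataFrame    # lulcc_id, climate_id, gcm_id, region, yields & flows
    regressions: dict = field(default_factory=dict)


def _region_masks(stack: WatershedStack, fdir: terrain.FlowDirectionGrid) -> dict[int, np.ndarray]:
    return {code: terrain.delineate_watershed(fdir, outlet)
            for code, outlet in stack.outlets.items()}


def scenario_grid(
    stack: WatershedStack,
    base_climate: MonthlyClimateCube,
    gcm_ensembles: dict[str, list[MonthlyClimateCube]],
    hydro_params: hyd.HydroParams,
    erosion_config: ero.ErosionConfig | None = None,
    cover_table: lulcc.CoverFactorTable | None = None,
    scenarios: tuple[lulcc.LulccScenario, ...] = lulcc.LULCC_LADDER,
    suitability_weights: tuple[float, float] = (0.5, 0.5),
    zero_floor: float = 1.0,
    ratio_ceiling: float = 10.0,
) -> ScenarioGridResult:
    """Run every (LULCC × climate) combination and tabulate fractional changes.

    Present-climate cells run the full hydrology + erosion chain; future cells
    re-run hydrology under each GCM's delta-perturbed forcing and project
    sediment through the per-(watershed, LULCC) regression.  Fractional
    changes are relative to (baseline_2000 × present) — that cell itself reads
    1.0 — with the ratio to the natural (biome) configuration in a companion
    column.
    """
    if erosion_config is None:
        erosion_config = ero.ErosionConfig()
    if cover_table is None:
        cover_table = lulcc.CoverFactorTable()
    labels = [s.label for s in scenarios]
    if "baseline_2000" not in labels:
        raise ValueError("scenario set must include baseline_2000 (the reference)")

    # shared terrain substrate
    fdir = terrain.d8_flow_direction(stack.dem, stack.cell_size)
    acc = terrain.flow_accumulation(fdir)
    lsf = terrain.slope_and_ls(stack.dem, acc, stack.cell_size)
    masks = _region_masks(stack, fdir)
    k_grid = ero.k_factor(stack.sand, stack.silt, stack.clay, stack.org_carbon)

    # future forcings are LULCC-independent: build once per (climate, gcm)
    base_clim = clim.monthly_climatology(base_climate)
    future_cubes: dict[str, list[tuple[str, MonthlyClimateCube]]] = {}
    for climate_id, members in gcm_ensembles.items():
        futs = []
        for g, member in enumerate(members):
            deltas = clim.delta_fields(
                clim.monthly_climatology(member), base_clim,
                zero_floor=zero_floor, ceiling=ratio_ceiling,
                source=f"{climate_id}/gcm{g}")
            futs.append((f"gcm{g}", clim.apply_delta(base_climate, deltas)))
        future_cubes[climate_id] = futs

    spin_years = hydro_params.spinup_months // 12
    mean_yield: dict[tuple[str, str, str], dict[int, float]] = {}
    per_gcm_rows = []
    regressions: dict[tuple[str, int], FlowSedimentRegression] = {}

    # the baseline configuration is processed first: its best-fitting flow
    # statistic is then used for every land-use configuration of the same
    # watershed, as one relationship family per gauge
    chosen_stat: dict[int, str] = {}
    ordered = sorted(scenarios, key=lambda s: s.label != "baseline_2000")
    for scen in ordered:
        lc = lulcc.apply_scenario(stack.landcover, lsf.slope_rad, stack.road_dist,
                                  scen, suitability_weights)
        kc_grid = lulcc.to_crop_factor(lc, cover_table)
        c_grid = lulcc.to_c_factor(lc, cover_table)

        sim = hyd.simulate(stack, base_climate, kc_grid, hydro_params)
        yields_by_region: dict[int, list[float]] = {code: [] for code in masks}
        for i, y in enumerate(range(spin_years, base_climate.n_years)):
            records = ero.run_annual(
                base_climate.precip[y], c_grid, k_grid, lsf.ls, masks,
                stack.cell_area, erosion_config, year=base_climate.start_year + y)
            for code, rec in records.items():
                yields_by_region[code].append(rec.yield_t)

        for code, mask in masks.items():
            series = hyd.discharge_series(sim, mask, stack.cell_area, outlet_id=code)
            stats = annual_flow_stats(series)
            yields = np.asarray(yields_by_region[code])
            mean_yield.setdefault((scen.label, "present", "-"), {})[code] = float(yields.mean())
            fit = fit_flow_sediment(stats, yields, stat=chosen_stat.get(code))
            if scen.label == "baseline_2000":
                chosen_stat[code] = fit.flow_stat
            regressions[(scen.label, code)] = fit
            per_gcm_rows.append({
                "lulcc_id": scen.label, "climate_id": "present", "gcm_id": "-",
                "region": REGION_NAMES[code],
                "mean_annual_q_m3s": float(stats["annual_mean"].mean()),
                "mean_annual_yield_t": float(yields.mean()),
            })

        for climate_id, futs in future_cubes.items():
            for gcm_id, fut_cube in futs:
                fsim = hyd.simulate(stack, fut_cube, kc_grid, hydro_params)
                for code, mask in masks.items():
                    fseries = hyd.discharge_series(fsim, mask, stack.cell_area, outlet_id=code)
                    fstats = annual_flow_stats(fseries)
                    proj = project_sediment(regressions[(scen.label, code)], fstats)
                    mean_yield.setdefault((scen.label, climate_id, gcm_id), {})[code] = float(proj.mean())
                    per_gcm_rows.append({
                        "lulcc_id": scen.label, "climate_id": climate_id, "gcm_id": gcm_id,
                        "region": REGION_NAMES[code],
                        "mean_annual_q_m3s": float(fstats["annual_mean"].mean()),
                        "mean_annual_yield_t": float(proj.mean()),
                    })

    # fractional changes: the primary column is relative to the
    # (2000 land use × present climate) cell, which therefore reads 1.0;
    # a companion column references the natural (biome) configuration so the
    # current-vs-natural ratio is also in the table.
    reference = mean_yield[("baseline_2000", "present", "-")]
    biome_ref = mean_yield.get(("biome", "present", "-"))
    climate_ids = ["present"] + list(gcm_ensembles.keys())
    rows = []
    for scen in scenarios:
        for climate_id in climate_ids:
            if climate_id == "present":
                gcm_ids = ["-"]
            else:
                gcm_ids = [gcm_id for gcm_id, _ in future_cubes[climate_id]]
            for code in masks:
                yields = [mean_yield[(scen.label, climate_id, g)][code] for g in gcm_ids]
                fracs = [fractional_change(v, reference[code]) for v in yields]
                vs_nat = (float(np.mean([fractional_change(v, biome_ref[code]) for v in yields]))
                          if biome_ref is not None else float("nan"))
                rows.append({
                    "lulcc_id": scen.label, "climate_id": climate_id,
                    "region": REGION_NAMES[code],
                    "mean_annual_yield_t": float(np.mean(yields)),
                    "fractional_change_mean": float(np.mean(fracs)),
                    "fractional_change_sd": float(np.std(fracs, ddof=0)),
                    "reference": "baseline_2000_present",
                    "fractional_change_vs_natural": vs_nat,
                    "n_gcms": len(gcm_ids) if climate_id != "present" else 0,
                })
    table = pd.DataFrame(rows)
    return ScenarioGridResult(table=table, per_gcm=pd.DataFrame(per_gcm_rows),
                              regressions=regressions)
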