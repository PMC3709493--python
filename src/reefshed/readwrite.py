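"""ESRI ASCII grid and CSV series I/O.

ASCII grids are written with 6 significant digits (the documented round-trip
precision); nodata cells use the header's NODATA_value and survive the round
trip.  Both LF and CRLF line endings parse.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import DischargeSeries, MonthlyClimateCube

DEFAULT_NODATA = -9999.0


class AsciiGridError(ValueError):
    pass


def write_raster(path, grid: np.ndarray, cell_size: float,
                 xllcorner: float = 0.0, yllcorner: float = 0.0,
                 nodata: float = DEFAULT_NODATA) -> None:
    """Write a 2-D array as an ESRI ASCII grid (.asc)."""
    grid = np.asarray(grid, dtype=float)
    nr, nc = grid.shape
    out = np.where(np.isnan(grid), nodata, grid)
    with open(path, "w", newline="\n") as fh:
        fh.write(f"ncols {nc}\n")
        fh.write(f"nrows {nr}\n")
        fh.write(f"xllcorner {xllcorner:.6g}\n")
        fh.write(f"yllcorner {yllcorner:.6g}\n")
        fh.write(f"cellsize {cell_size:.6g}\n")
        fh.write(f"NODATA_value {nodata:.6g}\n")
        for row in out:
            fh.write(" ".join(f"{v:.6g}" for v in row) + "\n")


def read_raster(path) -> tuple[np.ndarray, float]:
    """Read an ESRI ASCII grid; returns (array with nan nodata, cell size)."""
    header: dict[str, float] = {}
    rows: list[list[float]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            parts = line.split()
            if len(header) < 6 and parts[0].lower() in (
                    "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value"):
                try:
                    header[parts[0].lower()] = float(parts[1])
                except (IndexError, ValueError) as exc:
                    raise AsciiGridError(f"malformed header at line {lineno}") from exc
            else:
                try:
                    rows.append([float(v) for v in parts])
                except ValueError as exc:
                    raise AsciiGridError(f"malformed data at line {lineno}") from exc
    for key in ("ncols", "nrows", "cellsize"):
        if key not in header:
            raise AsciiGridError(f"missing header field {key!r}")
    grid = np.array(rows, dtype=float)
    if grid.shape != (int(header["nrows"]), int(header["ncols"])):
        raise AsciiGridError(
            f"data shape {grid.shape} does not match header "
            f"({int(header['nrows'])}, {int(header['ncols'])})")
    nodata = header.get("nodata_value", DEFAULT_NODATA)
    grid[grid == nodata] = np.nan
    return grid, header["cellsize"]


def write_series(path, series: DischargeSeries) -> None:
    """Discharge series as CSV (outlet_id, year, month, q_m3s)."""
    months = np.arange(len(series.q))
    year = series.start_year + (series.start_month - 1 + months) // 12
    month = (series.start_month - 1 + months) % 12 + 1
    pd.DataFrame({
        "outlet_id": series.outlet_id, "year": year, "month": month,
        "q_m3s": series.q,
    }).to_csv(path, index=False)


def read_series(path) -> DischargeSeries:
    df = pd.read_csv(path)
    return DischargeSeries(
        outlet_id=df["outlet_id"].iloc[0],
        q=df["q_m3s"].to_numpy(dtype=float),
        start_year=int(df["year"].iloc[0]),
        start_month=int(df["month"].iloc[0]),
    )


def write_climate_cube(path, cube: MonthlyClimateCube) -> None:
    """Long-format CSV (cell_id, year, month, precip_mm, temp_c)."""
    ny = cube.n_years
    nr, nc = cube.grid_shape
    years, months, cells = np.meshgrid(
        cube.years, np.arange(1, 13), np.arange(nr * nc), indexing="ij")
    pd.DataFrame({
        "cell_id": cells.ravel(),
        "year": years.ravel(),
        "month": months.ravel(),
        "precip_mm": cube.precip.reshape(ny, 12, -1).ravel(),
        "temp_c": cube.temp.reshape(ny, 12, -1).ravel(),
    }).to_csv(path, index=False)


def read_climate_cube(path, grid_shape: tuple[int, int]) -> MonthlyClimateCube:
    df = pd.read_csv(path)
    years = np.sort(df["year"].unique())
    ny = len(years)
    nr, nc = grid_shape
    precip = np.empty((ny, 12, nr, nc))
    temp = np.empty((ny, 12, nr, nc))
    df = df.sort_values(["year", "month", "cell_id"])
    precip.ravel()[:] = df["precip_mm"].to_numpy()
    temp.ravel()[:] = df["temp_c"].to_numpy()
    return MonthlyClimateCube(precip=precip, temp=temp, start_year=int(years[0]))


def write_stack(outdir, stack) -> None:
    """Dump every raster of a watershed stack as .asc files."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name in ("dem", "whc", "sand", "silt", "clay", "org_carbon",
                 "hsg", "landcover", "road_dist", "region"):
        write_raster(outdir / f"{name}.asc",
                     np.asarray(getattr(stack, name), dtype=float),
                     stack.cell_size)
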