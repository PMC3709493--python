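"""Terrain operators: depression filling, D8 routing, accumulation, LS factors.

All operators work on 2-D float DEMs with ``nan`` nodata.  Flow directions use
single-direction D8 routing with the ESRI power-of-two codes (1=E, 2=SE, 4=S,
8=SW, 16=W, 32=NW, 64=N, 128=NE); 0 marks a cell that exits the grid (edge or
nodata-adjacent sink) and -1 marks nodata.  Ties in steepest descent are broken
in the fixed order E, SE, S, SW, W, NW, N, NE so that repeated runs agree.
"""

from __future__ import annotations

import heapq
import math
from dataclasses import dataclass

import numpy as np

# (dr, dc, esri code, distance in cell units), in tie-break order.
D8_NEIGHBORS = (
    (0, 1, 1, 1.0),
    (1, 1, 2, math.sqrt(2.0)),
    (1, 0, 4, 1.0),
    (1, -1, 8, math.sqrt(2.0)),
    (0, -1, 16, 1.0),
    (-1, -1, 32, math.sqrt(2.0)),
    (-1, 0, 64, 1.0),
    (-1, 1, 128, math.sqrt(2.0)),
)
CODE_TO_OFFSET = {code: (dr, dc) for dr, dc, code, _ in D8_NEIGHBORS}

OUTLET_CODE = 0
NODATA_CODE = -1


@dataclass
class FlowDirectionGrid:
    dirs: np.ndarray  # int, ESRI codes / 0 outlet / -1 nodata
    cell_size: float

    @property
    def shape(self) -> tuple[int, int]:
        return self.dirs.shape


@dataclass
class LsFactors:
    slope_rad: np.ndarray
    ls: np.ndarray


def fill_depressions(dem: np.ndarray) -> np.ndarray:
    """Raise interior depressions to their pour level (priority flood).

    The result is ≥ the input everywhere, every valid cell has a non-ascending
    path to the grid edge (or to a nodata hole, treated as an exit), and the
    operation is idempotent.
    """
    dem = np.asarray(dem, dtype=float)
    nr, nc = dem.shape
    valid = ~np.isnan(dem)
    if not valid.any():
        raise ValueError("all-nodata grid cannot be filled")
    filled = dem.copy()
    closed = np.zeros_like(valid)
    heap: list[tuple[float, int, int, int]] = []
    counter = 0
    # seed: valid cells on the grid boundary or adjacent to nodata
    for r in range(nr):
        for c in range(nc):
            if not valid[r, c]:
                continue
            edge = r == 0 or c == 0 or r == nr - 1 or c == nc - 1
            if not edge:
                for dr, dc, _, _ in D8_NEIGHBORS:
                    if not valid[r + dr, c + dc]:
                        edge = True
                        break
            if edge:
                heapq.heappush(heap, (filled[r, c], counter, r, c))
                counter += 1
                closed[r, c] = True
    while heap:
        z, _, r, c = heapq.heappop(heap)
        for dr, dc, _, _ in D8_NEIGHBORS:
            rr, cc = r + dr, c + dc
            if 0 <= rr < nr and 0 <= cc < nc and valid[rr, cc] and not closed[rr, cc]:
                closed[rr, cc] = True
                filled[rr, cc] = max(filled[rr, cc], z)
                heapq.heappush(heap, (filled[rr, cc], counter, rr, cc))
                counter += 1
    return filled


def d8_flow_direction(dem: np.ndarray, cell_size: float = 1.0) -> FlowDirectionGrid:
    """Steepest-descent D8 directions on a depression-free DEM.

    Each cell points to the neighbor with the largest distance-weighted drop.
    Cells with no lower in-grid neighbor exit the grid (code 0) if they touch
    the boundary or a nodata hole; flat interior cells are resolved by a
    breadth-first sweep from already-draining cells of equal elevation, so that
    every flat drains without cycles.
    """
    dem = np.asarray(dem, dtype=float)
    nr, nc = dem.shape
    valid = ~np.isnan(dem)
    dirs = np.full((nr, nc), NODATA_CODE, dtype=np.int32)
    unresolved: list[tuple[int, int]] = []
    from collections import deque

    queue: deque[tuple[int, int]] = deque()
    for r in range(nr):
        for c in range(nc):
            if not valid[r, c]:
                continue
            z = dem[r, c]
            best_drop = 0.0
            best_code = None
            touches_exit = r == 0 or c == 0 or r == nr - 1 or c == nc - 1
            for dr, dc, code, dist in D8_NEIGHBORS:
                rr, cc = r + dr, c + dc
                if not (0 <= rr < nr and 0 <= cc < nc) or not valid[rr, cc]:
                    touches_exit = True
                    continue
                drop = (z - dem[rr, cc]) / dist
                if drop > best_drop:
                    best_drop = drop
                    best_code = code
            if best_code is not None:
                dirs[r, c] = best_code
                queue.append((r, c))
            elif touches_exit:
                dirs[r, c] = OUTLET_CODE
                queue.append((r, c))
            else:
                unresolved.append((r, c))
    # Flat resolution: FIFO sweep; an unresolved cell drains to the first
    # resolved equal-or-lower neighbor reached, scanning in the fixed order.
    pending = set(unresolved)
    while queue and pending:
        r, c = queue.popleft()
        z = dem[r, c]
        for dr, dc, code, _ in D8_NEIGHBORS:
            rr, cc = r - dr, c - dc  # neighbor that would point AT (r, c)
            if (rr, cc) in pending and dem[rr, cc] >= z:
                # direction from (rr,cc) toward (r,c) is `code`
                dirs[rr, cc] = code
                pending.discard((rr, cc))
                queue.append((rr, cc))
    if pending:
        raise ValueError("unresolvable flat region; DEM is not depression-free")
    return FlowDirectionGrid(dirs=dirs, cell_size=float(cell_size))


def downstream_index(fdir: FlowDirectionGrid) -> np.ndarray:
    """Flat index of each cell's downstream cell; -1 for exits/nodata."""
    nr, nc = fdir.shape
    down = np.full(nr * nc, -1, dtype=np.int64)
    dirs = fdir.dirs
    for r in range(nr):
        for c in range(nc):
            code = dirs[r, c]
            if code > 0:
                dr, dc = CODE_TO_OFFSET[int(code)]
                down[r * nc + c] = (r + dr) * nc + (c + dc)
    return down


def flow_accumulation(fdir: FlowDirectionGrid, weights: np.ndarray | None = None) -> np.ndarray:
    """Accumulate ``weights`` (default 1 per valid cell) down the D8 network.

    acc(c) = weights(c) + Σ acc(upstream cells draining to c), evaluated in
    topological order.  Raises if the direction grid contains a cycle.
    """
    nr, nc = fdir.shape
    valid = fdir.dirs >= 0
    if weights is None:
        weights = valid.astype(float)
    else:
        weights = np.asarray(weights, dtype=float)
        if np.any(weights[valid] < 0):
            raise ValueError("weights must be nonnegative")
    down = downstream_index(fdir)
    acc = np.where(valid, weights, np.nan).ravel().copy()
    indeg = np.zeros(nr * nc, dtype=np.int64)
    for i in range(nr * nc):
        if down[i] >= 0:
            indeg[down[i]] += 1
    from collections import deque

    queue = deque(i for i in range(nr * nc) if valid.ravel()[i] and indeg[i] == 0)
    seen = 0
    while queue:
        i = queue.popleft()
        seen += 1
        j = down[i]
        if j >= 0:
            acc[j] += acc[i]
            indeg[j] -= 1
            if indeg[j] == 0:
                queue.append(j)
    if seen != int(valid.sum()):
        raise RuntimeError("cycle detected in flow directions")
    return acc.reshape(nr, nc)


def slope_grid(dem: np.ndarray, cell_size: float) -> np.ndarray:
    """Slope angle (radians) by maximum downhill gradient over 8 neighbors."""
    if cell_size <= 0:
        raise ValueError("cell_size must be positive")
    dem = np.asarray(dem, dtype=float)
    nr, nc = dem.shape
    valid = ~np.isnan(dem)
    slope = np.full((nr, nc), np.nan)
    for r in range(nr):
        for c in range(nc):
            if not valid[r, c]:
                continue
            best = 0.0
            for dr, dc, _, dist in D8_NEIGHBORS:
                rr, cc = r + dr, c + dc
                if 0 <= rr < nr and 0 <= cc < nc and valid[rr, cc]:
                    g = (dem[r, c] - dem[rr, cc]) / (dist * cell_size)
                    if g > best:
                        best = g
            slope[r, c] = math.atan(best)
    return slope


def slope_and_ls(
    dem: np.ndarray,
    acc: np.ndarray,
    cell_size: float,
    *,
    slope_length_ref: float = 22.13,
    sin_ref: float = 0.0896,
    m_exp: float = 0.4,
    n_exp: float = 1.3,
) -> LsFactors:
    """RUSLE LS by the unit-contributing-area form.

    LS = (A_s / 22.13)^0.4 · (sin θ / 0.0896)^1.3 with specific contributing
    area A_s = acc · cell_size (acc counts upstream cells including self).
    Flat cells (θ = 0) get LS = 0; LS is monotone in both slope and
    accumulation.  Reference constants are overridable.
    """
    if cell_size <= 0:
        raise ValueError("cell_size must be positive")
    slope = slope_grid(dem, cell_size)
    a_s = np.asarray(acc, dtype=float) * cell_size
    with np.errstate(invalid="ignore"):
        ls = (a_s / slope_length_ref) ** m_exp * (np.sin(slope) / sin_ref) ** n_exp
    ls = np.where(np.isnan(slope), np.nan, ls)
    return LsFactors(slope_rad=slope, ls=ls)


def delineate_watershed(fdir: FlowDirectionGrid, outlet: tuple[int, int]) -> np.ndarray:
    """Boolean mask of every cell whose flow path reaches ``outlet``."""
    nr, nc = fdir.shape
    r0, c0 = outlet
    if not (0 <= r0 < nr and 0 <= c0 < nc) or fdir.dirs[r0, c0] < 0:
        raise ValueError("outlet outside grid or on nodata")
    down = downstream_index(fdir)
    upstream: dict[int, list[int]] = {}
    for i, j in enumerate(down):
        if j >= 0:
            upstream.setdefault(int(j), []).append(i)
    mask = np.zeros(nr * nc, dtype=bool)
    from collections import deque

    start = r0 * nc + c0
    mask[start] = True
    queue = deque([start])
    while queue:
        j = queue.popleft()
        for i in upstream.get(j, ()):
            if not mask[i]:
                mask[i] = True
                queue.append(i)
    return mask.reshape(nr, nc)
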