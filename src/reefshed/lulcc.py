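"""Land-use/land-cover change scenarios.

Nine configurations span fully forested ("biome") to fully deforested, with
incremental 10/25/50 % island-wide targets on either side of the year-2000
baseline.  Conversion is suitability-ranked: deforestation prefers flat,
road-accessible forest; afforestation prefers steep, road-remote open land.
Both factors are rank-normalized to [0, 1] so the score is scale-free.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .datatypes import (
    BARE,
    CROPLAND,
    DEFORESTED,
    FOREST,
    GRASSLAND,
    LANDCOVER_NAMES,
    WATER,
)

#: Non-forest classes eligible for afforestation (water never converts).
NON_FOREST_LAND = (GRASSLAND, CROPLAND, BARE, DEFORESTED)

#: Mixture used for the "weighted average non-forest" factors of converted
#: cells: grassland/cropland/bare shares of a typical open landscape.
NON_FOREST_WEIGHTS = {GRASSLAND: 0.5, CROPLAND: 0.3, BARE: 0.2}


class ConfigurationError(KeyError):
    pass


@dataclass
class SuitabilitySurface:
    score: np.ndarray            # in [0,1] on eligible cells, nan elsewhere
    direction: str               # "deforestation" | "afforestation"
    weights: tuple[float, float] # (w_slope, w_road)


@dataclass(frozen=True)
class LulccScenario:
    label: str
    target_fraction: float
    direction: str  # "deforestation", "afforestation" or "none"


#: The nine configurations, ordered from most to least forested.
LULCC_LADDER: tuple[LulccScenario, ...] = (
    LulccScenario("biome", 1.0, "afforestation"),
    LulccScenario("afforest_50", 0.50, "afforestation"),
    LulccScenario("afforest_25", 0.25, "afforestation"),
    LulccScenario("afforest_10", 0.10, "afforestation"),
    LulccScenario("baseline_2000", 0.0, "none"),
    LulccScenario("deforest_10", 0.10, "deforestation"),
    LulccScenario("deforest_25", 0.25, "deforestation"),
    LulccScenario("deforest_50", 0.50, "deforestation"),
    LulccScenario("deforest_100", 1.0, "deforestation"),
)
LULCC_LABELS = tuple(s.label for s in LULCC_LADDER)
SCENARIOS_BY_LABEL = {s.label: s for s in LULCC_LADDER}


@dataclass
class CoverFactorTable:
    """Per-class crop factor kc (evapotranspiration coefficient) and RUSLE
    cover factor C.  Converted (deforested) cells carry the weighted average
    of the non-forest classes."""

    kc: dict[int, float] = field(default_factory=lambda: {
        FOREST: 1.00, GRASSLAND: 0.85, CROPLAND: 0.90, BARE: 0.40, WATER: 1.05,
    })
    c_factor: dict[int, float] = field(default_factory=lambda: {
        FOREST: 0.02, GRASSLAND: 0.05, CROPLAND: 0.25, BARE: 0.45, WATER: 0.0,
    })

    def __post_init__(self) -> None:
        if DEFORESTED not in self.kc:
            self.kc = dict(self.kc)
            self.kc[DEFORESTED] = self.non_forest_weighted_kc
        if DEFORESTED not in self.c_factor:
            self.c_factor = dict(self.c_factor)
            self.c_factor[DEFORESTED] = self.non_forest_weighted_c
        for cls, c in self.c_factor.items():
            if not 0.0 <= c <= 1.0:
                raise ValueError(f"C factor out of [0,1] for class {cls}")
        for cls, k in self.kc.items():
            if k <= 0:
                raise ValueError(f"kc must be positive for class {cls}")

    def _weighted(self, table: dict[int, float]) -> float:
        return sum(w * table[cls] for cls, w in NON_FOREST_WEIGHTS.items())

    @property
    def non_forest_weighted_kc(self) -> float:
        return self._weighted(self.kc)

    @property
    def non_forest_weighted_c(self) -> float:
        return self._weighted(self.c_factor)

    @classmethod
    def from_csv(cls, path) -> "CoverFactorTable":
        df = pd.read_csv(path)
        name_to_code = {v: k for k, v in LANDCOVER_NAMES.items()}
        kc, cf = {}, {}
        for _, row in df.iterrows():
            code = name_to_code[row["class"]]
            kc[code] = float(row["kc"])
            cf[code] = float(row["c_factor"])
        return cls(kc=kc, c_factor=cf)

    def to_csv(self, path) -> None:
        rows = [
            {"class": LANDCOVER_NAMES[c], "kc": self.kc[c], "c_factor": self.c_factor[c]}
            for c in sorted(self.kc)
        ]
        pd.DataFrame(rows).to_csv(path, index=False)


def _rank01(values: np.ndarray) -> np.ndarray:
    """Average-tie ranks mapped to [0,1]; a single value maps to 0.5."""
    n = len(values)
    if n == 1:
        return np.array([0.5])
    r = rankdata(values, method="average")
    return (r - 1.0) / (n - 1.0)


def eligible_mask(landcover: np.ndarray, direction: str) -> np.ndarray:
    if direction == "deforestation":
        return landcover == FOREST
    if direction == "afforestation":
        return np.isin(landcover, NON_FOREST_LAND)
    raise ValueError(f"unknown direction {direction!r}")


def suitability(
    slope: np.ndarray,
    road_dist: np.ndarray,
    landcover: np.ndarray,
    direction: str,
    weights: tuple[float, float] = (0.5, 0.5),
) -> SuitabilitySurface:
    """Weighted rank score on eligible cells.

    Deforestation: low slope and short road distance score high.
    Afforestation: the complements.  Weights must sum to 1.
    """
    w_slope, w_road = weights
    if abs(w_slope + w_road - 1.0) > 1e-9:
        raise ValueError("weights must sum to 1")
    elig = eligible_mask(landcover, direction)
    score = np.full(landcover.shape, np.nan)
    if elig.any():
        sr = _rank01(slope[elig])
        dr = _rank01(road_dist[elig])
        if direction == "deforestation":
            score[elig] = w_slope * (1.0 - sr) + w_road * (1.0 - dr)
        else:
            score[elig] = w_slope * sr + w_road * dr
    return SuitabilitySurface(score=score, direction=direction, weights=(w_slope, w_road))


def apply_target(
    landcover: np.ndarray,
    surface: SuitabilitySurface,
    target_fraction: float,
) -> np.ndarray:
    """Convert the highest-scoring ``round(f·n_eligible)`` cells grid-wide.

    Deforested cells become the DEFORESTED class (they keep the weighted
    non-forest factors); afforested cells become FOREST.  Ties at the cut are
    broken by row-major cell index.  Ineligible and nodata cells never change.
    """
    if not 0.0 <= target_fraction <= 1.0:
        raise ValueError("target_fraction must lie in [0,1]")
    out = landcover.copy()
    elig = ~np.isnan(surface.score)
    n_elig = int(elig.sum())
    k = int(round(target_fraction * n_elig))
    if k == 0:
        return out
    flat_idx = np.flatnonzero(elig.ravel())
    scores = surface.score.ravel()[flat_idx]
    # sort by descending score, then ascending row-major index
    order = np.lexsort((flat_idx, -scores))
    chosen = flat_idx[order[:k]]
    new_class = DEFORESTED if surface.direction == "deforestation" else FOREST
    out.ravel()[chosen] = new_class
    return out


def apply_scenario(
    landcover: np.ndarray,
    slope: np.ndarray,
    road_dist: np.ndarray,
    scenario: LulccScenario,
    weights: tuple[float, float] = (0.5, 0.5),
) -> np.ndarray:
    """Build the land-cover map of one ladder configuration.

    ``biome`` converts all eligible open land to forest (the natural-cover
    stand-in); ``baseline_2000`` returns the input unchanged.
    """
    if scenario.direction == "none":
        return landcover.copy()
    surf = suitability(slope, road_dist, landcover, scenario.direction, weights)
    return apply_target(landcover, surf, scenario.target_fraction)


def regional_forest_fraction(landcover: np.ndarray, region: np.ndarray) -> dict[int, float]:
    """Forest share of valid cells per region; regions with no valid cells
    are reported as nan."""
    out: dict[int, float] = {}
    valid = landcover > 0
    for code in np.unique(region[region > 0]):
        sel = (region == code) & valid
        out[int(code)] = float((landcover[sel] == FOREST).mean()) if sel.any() else float("nan")
    return out


def _lookup(landcover: np.ndarray, table: dict[int, float], what: str) -> np.ndarray:
    out = np.full(landcover.shape, np.nan)
    present = np.unique(landcover[landcover > 0])
    for cls in present:
        if int(cls) not in table:
            raise ConfigurationError(
                f"no {what} entry for land-cover class "
                f"{LANDCOVER_NAMES.get(int(cls), int(cls))!r}"
            )
        out[landcover == cls] = table[int(cls)]
    return out


def to_crop_factor(landcover: np.ndarray, table: CoverFactorTable) -> np.ndarray:
    """Per-cell evapotranspiration crop factor kc."""
    return _lookup(landcover, table.kc, "kc")


def to_c_factor(landcover: np.ndarray, table: CoverFactorTable) -> np.ndarray:
    """Per-cell RUSLE cover factor C."""
    return _lookup(landcover, table.c_factor, "C")
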