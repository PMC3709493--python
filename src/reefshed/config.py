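"""Run configuration: one YAML file determines a full reproducible run.

Unknown keys are rejected by name; a single global seed is fanned out to
independent per-stage streams via ``numpy.random.SeedSequence([seed, k])``
with a fixed stage index k (0 = watershed, 1 = climate, 2–4 = GCM ensembles
B1/A1b/A2, 5 = gauge noise).
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import numpy as np
import yaml

STAGE_SEEDS = {"watershed": 0, "climate": 1, "gcm_B1": 2, "gcm_A1b": 3,
               "gcm_A2": 4, "gauge": 5}


def child_seed(seed: int, stage: str) -> int:
    """Derive a stage seed below 2^31 from the global seed."""
    ss = np.random.SeedSequence([int(seed), STAGE_SEEDS[stage]])
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))


class ConfigError(ValueError):
    pass


def _from_mapping(cls, data: dict):
    names = {f.name for f in fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ConfigError(f"unknown config key(s) in {cls.__name__}: {sorted(unknown)}")
    return cls(**data)


@dataclass
class GridConfig:
    nrows: int = 16
    ncols: int = 16
    cell_size: float = 500.0
    forest_fraction: float = 0.4


@dataclass
class ClimateConfig:
    n_years: int = 20
    start_year: int = 1986
    precip_shape: float = 4.0


@dataclass
class GcmConfig:
    n_gcms: int = 3
    # (lo, hi) warming °C per scenario; B1 < A1b < A2 magnitudes
    warming: dict = field(default_factory=lambda: {
        "B1": [1.0, 2.0], "A1b": [1.5, 3.0], "A2": [2.0, 4.0]})
    precip_change_wet: list = field(default_factory=lambda: [-0.05, 0.10])
    precip_change_dry: list = field(default_factory=lambda: [-0.20, -0.05])


@dataclass
class HydroConfig:
    direct_fractions: list = field(default_factory=lambda: [0.2, 0.4, 0.6, 0.8])
    gw_recessions: list = field(default_factory=lambda: [0.2, 0.4, 0.6, 0.8])
    spinup_months: int = 24
    gauge_noise_cv: float = 0.1
    calibration_region: int = 4   # SW analogue of the gauged catchment


@dataclass
class ErosionConfigBlock:
    erosivity_a: float = 0.264
    erosivity_b: float = 1.50
    sdr: float = 0.1


@dataclass
class RunConfig:
    seed: int = 1
    outdir: str = "out"
    scenarios: list = field(default_factory=lambda: [
        "biome", "afforest_50", "afforest_25", "afforest_10", "baseline_2000",
        "deforest_10", "deforest_25", "deforest_50", "deforest_100"])
    grid: GridConfig = field(default_factory=GridConfig)
    climate: ClimateConfig = field(default_factory=ClimateConfig)
    gcm: GcmConfig = field(default_factory=GcmConfig)
    hydro: HydroConfig = field(default_factory=HydroConfig)
    erosion: ErosionConfigBlock = field(default_factory=ErosionConfigBlock)

    def __post_init__(self) -> None:
        if not self.scenarios:
            raise ConfigError("scenario list must not be empty")

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        data = dict(data)
        sub = {"grid": GridConfig, "climate": ClimateConfig, "gcm": GcmConfig,
               "hydro": HydroConfig, "erosion": ErosionConfigBlock}
        for key, subcls in sub.items():
            if key in data and isinstance(data[key], dict):
                data[key] = _from_mapping(subcls, data[key])
        return _from_mapping(cls, data)

    def to_dict(self) -> dict:
        return asdict(self)


def load_config(path) -> RunConfig:
    """Read and validate a YAML run configuration; defaults fill gaps."""
    path = Path(path)
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ConfigError("config root must be a mapping")
    return RunConfig.from_dict(data)


def save_config(config: RunConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)
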