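"""Configuration objects for the simulator and the estimation pipeline.

Both configs are plain dataclasses serializable to YAML so that a run is
fully described by (config file, seed).
"""

from __future__ import annotations

import dataclasses
import hashlib
import math
from dataclasses import dataclass, field
from pathlib import Path

import yaml

#: Multiplicative correction for fish not recovered after rotenone poisoning,
#: the mean of published species-level recovery rates for cove surveys.
RECOVERY_CONSTANT = 1.773056

#: Common prediction year used to standardize densities estimated from
#: reservoirs sampled in different calendar years.
STANDARDIZATION_YEAR = 1993

#: The 22 states contributing nearly all legacy rotenone surveys; used as the
#: default "southern" reporting region.
SOUTHERN_STATES = (
    "AL", "AR", "FL", "GA", "IA", "IL", "IN", "KS", "KY", "LA", "MA",
    "MD", "MO", "MS", "NC", "NM", "OK", "SC", "TN", "TX", "VA", "WV",
)

#: Named natural lakes that carry small regulating dams and enter dam
#: inventories despite not being reservoirs.
NATURAL_LAKE_NAMES = (
    "Lake Superior",
    "Lake Michigan",
    "Lake Huron",
    "Lake Erie",
    "Lake Ontario",
    "Lake Okeechobee",
    "Lake Champlain",
)


class ConfigError(ValueError):
    """Raised for invalid configuration values."""


@dataclass
class SimulationConfig:
    """Parameters of the synthetic dam-inventory / survey generator.

    The generator emulates the statistical structure the estimation pipeline
    assumes: jointly log-normal storage volume (m^3) and maximum discharge
    (m^3 s^-1) with ecoregion structure, a power-law area-volume relation,
    and survey densities built from a class-specific baseline, a transient
    age response (trophic-upsurge shaped), a sampling-year trend, a
    per-reservoir random intercept, and multiplicative Gamma noise.
    Recorded raw densities are true densities divided by the recovery
    constant, so the pipeline's correction step round-trips exactly.
    """

    seed: int = 0
    n_reservoirs: int = 10_000
    n_ecoregions: int = 6

    # ln-volume (m^3) and ln-discharge (m^3 s^-1), jointly normal
    ln_volume_mean: float = 11.0
    ln_volume_sd: float = 2.5
    ln_discharge_mean: float = 1.5
    ln_discharge_sd: float = 1.8
    volume_discharge_corr: float = 0.7
    #: sd of a per-ecoregion shift added to ln-volume (ecoregion structure)
    ecoregion_volume_shift_sd: float = 0.3
    #: blob separation (in sd units) of the four latent size-flow classes
    class_separation: float = 0.75

    # area_ha = area_coeff * volume^area_exponent * exp(N(0, area_noise_sd))
    area_coeff: float = 0.01
    area_exponent: float = 0.8
    area_noise_sd: float = 0.3

    # density model, log scale: beta0[class] + alpha*age*exp(-age/tau)
    #   + slope*(year - year_range[0]) + u_i,  u_i ~ N(0, random_intercept_sd)
    density_intercept_per_class: tuple[float, ...] = (5.0, 5.4, 5.8, 6.2)
    age_curve_alpha: float = 0.1
    age_curve_tau: float = 10.0
    year_trend_slope: float = -0.005
    random_intercept_sd: float = 0.4
    #: shape of the multiplicative Gamma(shape, scale=1/shape) noise;
    #: math.inf disables the noise (expectation mode)
    gamma_shape: float = 2.0
    recovery_constant: float = RECOVERY_CONSTANT

    survey_fraction: float = 0.035
    surveys_per_reservoir: int = 5
    year_range: tuple[int, int] = (1948, 1978)
    completion_year_range: tuple[int, int] = (1900, 1975)

    # MCAR missingness fractions exercising the cleaning / approximation paths
    missing_area_fraction: float = 0.10
    missing_coord_fraction: float = 0.02
    missing_discharge_fraction: float = 0.05
    #: fraction of reservoirs listed a second time under another dam
    duplicate_fraction: float = 0.01
    #: number of flagged natural-lake rows injected
    n_natural_lakes: int = 3

    n_validation: int = 42
    validation_noise_sd: float = 0.2

    # synthetic geography (lon/lat bounding box tiled into ecoregions)
    bbox: tuple[float, float, float, float] = (-100.0, 30.0, -80.0, 40.0)

    def __post_init__(self) -> None:
        if self.n_reservoirs < 0:
            raise ConfigError("n_reservoirs must be >= 0")
        if self.n_ecoregions < 1:
            raise ConfigError("n_ecoregions must be >= 1")
        for name in (
            "ln_volume_sd", "ln_discharge_sd", "area_noise_sd",
            "random_intercept_sd", "ecoregion_volume_shift_sd",
            "validation_noise_sd", "missing_area_fraction",
            "missing_coord_fraction", "missing_discharge_fraction",
            "duplicate_fraction", "survey_fraction",
        ):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if not self.gamma_shape > 0:
            raise ConfigError("gamma_shape must be > 0")
        if self.recovery_constant < 1:
            raise ConfigError("recovery_constant must be >= 1")
        if not -1.0 <= self.volume_discharge_corr <= 1.0:
            raise ConfigError("volume_discharge_corr must be in [-1, 1]")
        if self.year_range[0] > self.year_range[1]:
            raise ConfigError("year_range must be (lo, hi) with lo <= hi")

    @property
    def expectation_mode(self) -> bool:
        """True when the multiplicative Gamma noise is disabled."""
        return math.isinf(self.gamma_shape)


@dataclass
class PipelineConfig:
    """End-to-end run configuration: paths, constants, schemas, regions."""

    inventory_path: str | None = None
    surveys_path: str | None = None
    ecoregions_path: str | None = None
    validation_path: str | None = None
    output_dir: str = "results"

    recovery_constant: float = RECOVERY_CONSTANT
    standardization_year: int = STANDARDIZATION_YEAR
    k_clusters: int = 4
    min_class_n: int = 5
    basis_dim: int = 10
    pb_mean: float = 1.30
    pb_q25: float = 0.583
    pb_q75: float = 1.823

    schemas: tuple[int, ...] = (1, 2, 3, 4, 5)
    seed: int = 0
    southern_states: tuple[str, ...] = SOUTHERN_STATES
    natural_lake_names: tuple[str, ...] = NATURAL_LAKE_NAMES
    plausible_year_range: tuple[int, int] = (1900, 2026)

    #: used when the pipeline simulates its own inputs
    simulation: SimulationConfig | None = None

    def __post_init__(self) -> None:
        for name in ("recovery_constant", "k_clusters", "min_class_n",
                     "basis_dim", "pb_mean", "pb_q25", "pb_q75"):
            if not getattr(self, name) > 0:
                raise ConfigError(f"{name} must be > 0")
        if not self.schemas:
            raise ConfigError("schema list must be non-empty")
        if not set(self.schemas) <= {1, 2, 3, 4, 5}:
            raise ConfigError("schemas must be a subset of {1..5}")


def _to_plain(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _to_plain(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, (list, tuple)):
        return [_to_plain(v) for v in obj]
    if isinstance(obj, Path):
        return str(obj)
    return obj


def save_config(config, path: str | Path) -> None:
    """Write a config dataclass as a YAML mapping."""
    Path(path).write_text(yaml.safe_dump(_to_plain(config), sort_keys=True))


def _tuplify(cls, data: dict) -> dict:
    out = dict(data)
    for f in dataclasses.fields(cls):
        if f.name in out and isinstance(out[f.name], list):
            out[f.name] = tuple(out[f.name])
    return out


def load_simulation_config(path: str | Path) -> SimulationConfig:
    data = yaml.safe_load(Path(path).read_text()) or {}
    return SimulationConfig(**_tuplify(SimulationConfig, data))


def load_pipeline_config(path: str | Path) -> PipelineConfig:
    data = yaml.safe_load(Path(path).read_text()) or {}
    sim = data.pop("simulation", None)
    cfg = PipelineConfig(**_tuplify(PipelineConfig, data))
    if sim is not None:
        cfg.simulation = SimulationConfig(**_tuplify(SimulationConfig, sim))
    return cfg


def config_hash(config) -> str:
    """Stable sha256 of the canonical YAML serialization."""
    text = yaml.safe_dump(_to_plain(config), sort_keys=True)
    return hashlib.sha256(text.encode()).hexdigest()[:16]
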