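"""Configuration objects shared across the pipeline.

All randomness in the package flows from the single ``seed`` carried by
:class:`SimulationConfig`; sub-generators derive independent streams from it
by fixed integer labels, so adding a new generator never perturbs the output
of existing ones.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml


class ConfigurationError(ValueError):
    """A configuration field failed validation. The message names the field."""


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic small-area population and activity model.

    Defaults emulate England in 2011/12: ~32 482 lower-layer super output
    areas (LSOAs) of ~1 500 residents; a deprivation gradient in admission
    rates that is steeper for emergency (Q1/Q5 = 1.71) than elective (1.20)
    activity; a mortality gradient between the most and least deprived fifth
    of areas; a female cost spike in the reproductive years; and an 8.8%
    rate of episodes with a missing age, sex or area field.

    Parameters
    ----------
    n_areas:
        Number of small areas. Must be at least 5 (one per quintile).
    mean_area_pop:
        Mean residents per area.
    rate_gradient_elective, rate_gradient_emergency:
        Q1/Q5 admission-rate ratios (most deprived over least deprived),
        applied multiplicatively per cell with a log-linear ramp across
        quintiles. Both must be >= 1.
    female_repro_multiplier:
        Factor applied to female admission rates at ages 20-40.
    gompertz_intercept, gompertz_slope:
        Baseline mortality hazard h(a) = intercept * exp(slope * a) per year
        (male, least-deprived quintile).
    mortality_gradient:
        Q1/Q5 hazard ratio, again ramped log-linearly across quintiles.
    missing_rate:
        Proportion of episodes with one of age/sex/area blanked, in [0, 1).
    tariff_mean, tariff_shape:
        Mean (GBP) and gamma shape of the synthetic tariff unit costs.
    seed:
        Master seed for all random streams.
    """

    n_areas: int = 32482
    mean_area_pop: float = 1500.0
    rate_gradient_elective: float = 1.20
    rate_gradient_emergency: float = 1.71
    female_repro_multiplier: float = 2.0
    gompertz_intercept: float = 3.3e-5
    gompertz_slope: float = 0.095
    mortality_gradient: float = 1.5
    missing_rate: float = 0.088
    tariff_mean: float = 1400.0
    tariff_shape: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_areas < 5:
            raise ConfigurationError(
                f"n_areas must be >= 5 (one area per quintile); got {self.n_areas}"
            )
        if self.mean_area_pop <= 0:
            raise ConfigurationError(f"mean_area_pop must be > 0; got {self.mean_area_pop}")
        for name in ("rate_gradient_elective", "rate_gradient_emergency", "mortality_gradient"):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must be >= 1; got {getattr(self, name)}")
        if self.female_repro_multiplier < 1:
            raise ConfigurationError(
                f"female_repro_multiplier must be >= 1; got {self.female_repro_multiplier}"
            )
        if not 0 <= self.missing_rate < 1:
            raise ConfigurationError(f"missing_rate must be in [0, 1); got {self.missing_rate}")
        if self.gompertz_intercept <= 0 or self.gompertz_slope < 0:
            raise ConfigurationError(
                "gompertz_intercept must be > 0 and gompertz_slope >= 0; got "
                f"{self.gompertz_intercept}, {self.gompertz_slope}"
            )
        if self.tariff_mean <= 0 or self.tariff_shape <= 0:
            raise ConfigurationError("tariff_mean and tariff_shape must be > 0")

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "SimulationConfig":
        return cls(**d)


@dataclass(frozen=True)
class LifeTableOptions:
    """Conventions for turning banded death rates into survival curves.

    ``q_convention`` chooses how the central death rate m is converted to an
    annual death probability q: ``"central"`` uses q = m directly (default),
    ``"actuarial"`` uses q = m / (1 + m/2). ``max_age`` closes the open 85+
    interval. ``survival_weighting`` picks the survival weight for expected
    annual costs: probability of being alive at the start of the year
    (``"start"``, default) or mid-year (``"midyear"``).
    """

    q_convention: str = "central"
    max_age: int = 110
    survival_weighting: str = "start"

    def __post_init__(self) -> None:
        if self.q_convention not in ("central", "actuarial"):
            raise ConfigurationError(f"q_convention must be 'central' or 'actuarial'; got {self.q_convention!r}")
        if self.max_age < 86:
            raise ConfigurationError(f"max_age must be >= 86 to close the 85+ interval; got {self.max_age}")
        if self.survival_weighting not in ("start", "midyear"):
            raise ConfigurationError(
                f"survival_weighting must be 'start' or 'midyear'; got {self.survival_weighting!r}"
            )

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "LifeTableOptions":
        return cls(**d)


@dataclass(frozen=True)
class PipelineConfig:
    """End-to-end run configuration.

    Either ``simulate`` holds a :class:`SimulationConfig` (inputs are
    generated), or ``inputs`` maps the five input roles (episodes, tariffs,
    population, deaths, areas) to file paths. The config is echoed into every
    output directory so a run is reproducible from the echo alone.
    """

    out_dir: str = "results"
    simulate: SimulationConfig | None = field(default_factory=SimulationConfig)
    inputs: dict[str, str] | None = None
    life_table: LifeTableOptions = field(default_factory=LifeTableOptions)

    _ROLES = ("episodes", "tariffs", "population", "deaths", "areas")

    def __post_init__(self) -> None:
        if (self.simulate is None) == (self.inputs is None):
            raise ConfigurationError("exactly one of 'simulate' and 'inputs' must be given")
        if self.inputs is not None:
            missing = [r for r in self._ROLES if r not in self.inputs]
            if missing:
                raise ConfigurationError(f"inputs is missing roles: {missing}")

    def to_dict(self) -> dict[str, Any]:
        return {
            "out_dir": self.out_dir,
            "simulate": None if self.simulate is None else self.simulate.to_dict(),
            "inputs": self.inputs,
            "life_table": self.life_table.to_dict(),
        }

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "PipelineConfig":
        sim = d.get("simulate")
        return cls(
            out_dir=d.get("out_dir", "results"),
            simulate=None if sim is None else SimulationConfig.from_dict(sim),
            inputs=d.get("inputs"),
            life_table=LifeTableOptions.from_dict(d.get("life_table", {})),
        )


def save_config(cfg: SimulationConfig | PipelineConfig, path: str | Path) -> None:
    """Write a config to YAML; the file round-trips exactly via load_*."""
    Path(path).write_text(yaml.safe_dump(cfg.to_dict(), sort_keys=True))


def load_simulation_config(path: str | Path) -> SimulationConfig:
    return SimulationConfig.from_dict(yaml.safe_load(Path(path).read_text()))


def load_pipeline_config(path: str | Path) -> PipelineConfig:
    return PipelineConfig.from_dict(yaml.safe_load(Path(path).read_text()))
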