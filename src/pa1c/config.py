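"""Simulation and run configuration with validation and YAML loading."""
from __future__ import annotations

from dataclasses import dataclass, fields, replace

import yaml

__all__ = ["SimulationConfig", "load_simulation_config", "dump_simulation_config"]


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic cohort.

    Defaults reproduce the reported cohort structure: 64 subjects, mean
    glucose ~ truncated Normal(257, 57) mg/dL, glucose CV ~ truncated
    Normal(44, 10)% on [23, 62], sensor range 40–500 mg/dL at 15-minute
    cadence, three wears of 10–14 days with ≤48 h gaps, and per-subject AGR
    centered at the 65.1 mL/mg reference constant (population SD 6 mL/mg, a
    modelling choice — no between-subject AGR spread is reported).  Assay
    noise is multiplicative lognormal: laboratory CV 2%, point-of-care CV 4%
    (assay imprecision was not quantifiable from the source, so these are
    explicit knobs; set to 0 for noise-free runs).
    """

    n_subjects: int = 64
    seed: int = 0
    wear_days_min: int = 10
    wear_days_max: int = 14
    gap_hours_max: float = 48.0
    cadence_minutes: int = 15
    sensor_min: float = 40.0
    sensor_max: float = 500.0
    mg_mean: float = 257.0
    mg_sd: float = 57.0
    mg_min: float = 80.0
    mg_max: float = 450.0
    cv_mean: float = 44.0
    cv_sd: float = 10.0
    cv_min: float = 23.0
    cv_max: float = 62.0
    agr_mean: float = 65.1
    agr_sd: float = 6.0
    a1c_assay_cv_lab: float = 2.0
    a1c_assay_cv_poc: float = 4.0
    #: OU mean-reversion rate of the glucose process, 1/hours (~4 h memory)
    ou_mean_reversion: float = 0.25
    #: peak-to-mean amplitude of the diurnal sinusoid, as a fraction of MG
    diurnal_amplitude_frac: float = 0.10

    def __post_init__(self) -> None:
        if self.n_subjects < 0:
            raise ValueError("n_subjects must be non-negative")
        if self.sensor_min >= self.sensor_max:
            raise ValueError("sensor_min must be below sensor_max")
        if self.wear_days_min > self.wear_days_max:
            raise ValueError("wear_days_min must not exceed wear_days_max")
        if self.mg_min >= self.mg_max or self.cv_min >= self.cv_max:
            raise ValueError("truncation bounds inverted")
        if self.gap_hours_max <= 0 or self.cadence_minutes <= 0:
            raise ValueError("gap_hours_max and cadence_minutes must be positive")
        for name in ("mg_mean", "mg_sd", "cv_mean", "cv_sd", "agr_mean"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("agr_sd", "a1c_assay_cv_lab", "a1c_assay_cv_poc"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    def with_overrides(self, **kwargs) -> "SimulationConfig":
        return replace(self, **kwargs)


def load_simulation_config(path) -> SimulationConfig:
    """Load a flat key:value YAML file; unknown keys are an error."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError(f"{path}: expected a flat mapping of config keys")
    known = {f.name for f in fields(SimulationConfig)}
    unknown = sorted(set(data) - known)
    if unknown:
        raise ValueError(f"{path}: unknown config key(s): {', '.join(unknown)}")
    return SimulationConfig(**data)


def dump_simulation_config(config: SimulationConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(
            {f.name: getattr(config, f.name) for f in fields(config)},
            fh,
            sort_keys=False,
        )
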