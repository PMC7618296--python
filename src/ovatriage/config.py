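"""Run configuration: base-case defaults, scenario switches, YAML round-trip."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

__all__ = ["RunConfig", "ConfigError", "load_config", "save_config"]


class ConfigError(ValueError):
    """Invalid or unknown configuration content."""


@dataclass
class RunConfig:
    """All run settings; every field defaults to the base case.

    Scenario switches mirror the one-way sensitivity analyses: alternative
    discount rate, extended survival-model horizon, alternative late-stage
    utility decrements, scaled ultrasound accuracy, ultrasound cost variants,
    scaled benign-surgery rate, a surgery-complication cost add-on, effects
    on other cancers, and a stage-stratified accuracy table.
    """

    population: str = "synthetic"          # "synthetic" or a parameter directory
    parameter_dir: str | None = None
    age_group: str | None = None           # UNDER50 / GE50 / None (both)
    discount_rate_qaly: float = 0.035      # scenario: 0.015
    discount_rate_cost: float = 0.035
    survival_horizon: int = 8              # scenario: 15
    late_stage_decrement: float = 0.046    # scenarios: 0.06, 0.0
    uss_sensitivity_scale: float = 1.0     # scenario: 0.95 / 1.05
    uss_specificity_scale: float = 1.0
    uss_cost: float | None = None          # scenario: service-specific USS cost
    surgery_rate_scale: float = 1.0        # scenario: 0.85 / 1.15
    surgery_complication_cost: float = 0.0
    surgery_complication_rate: float = 0.0
    other_cancer_effects: bool = False
    stage_accuracy_table: str | None = None
    rr_late: float = 0.836
    psa_n: int = 1000
    seed: int = 0
    moderate_grid: list[float] = field(default_factory=list)
    high_grid: list[float] = field(default_factory=list)
    output_dir: str = "results"


def load_config(path: str | Path | None) -> RunConfig:
    """Load a YAML config; unknown keys are rejected by name.

    A missing or empty file yields the full base-case defaults.
    """
    if path is None:
        return RunConfig()
    path = Path(path)
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ConfigError(f"cannot parse {path}: {exc}") from exc
    if raw is None:
        return RunConfig()
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    known = {f.name for f in fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"unknown configuration key(s): {', '.join(sorted(unknown))}")
    return RunConfig(**raw)


def save_config(config: RunConfig, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(yaml.safe_dump(asdict(config), sort_keys=True))
    return path


def build_profile(config: RunConfig):
    """Materialize the parametrization a config describes.

    Starts from the synthetic base case (or a parameter directory) and layers
    the scenario switches on top.
    """
    from dataclasses import replace

    from .accuracy import AccuracyTable, TestAccuracy, TestId
    from .decision_tree import StageShiftParams, UnitCosts
    from .markov import MarkovSpec
    from .synthetic_data import default_profile, read_profile, synth_qol_params

    if config.population == "synthetic" and config.parameter_dir is None:
        profile = default_profile(seed=config.seed)
    else:
        if config.parameter_dir is None:
            raise ConfigError("parameter_dir is required for non-synthetic populations")
        profile = read_profile(config.parameter_dir, seed=config.seed)

    spec = MarkovSpec(
        survival_model_horizon=config.survival_horizon,
        discount_qaly=config.discount_rate_qaly,
        discount_cost=config.discount_rate_cost,
    )
    utility = replace(
        synth_qol_params(late_stage_extra=config.late_stage_decrement),
        decrements=profile.utility_model.decrements,
    )
    unit_costs = profile.unit_costs
    if config.uss_cost is not None:
        unit_costs = replace(unit_costs, uss=float(config.uss_cost))
    surgery_rate = min(1.0, unit_costs.benign_surgery_rate * config.surgery_rate_scale)
    unit_costs = replace(unit_costs, benign_surgery_rate=surgery_rate)
    if config.surgery_complication_cost and config.surgery_complication_rate:
        extra = config.surgery_complication_cost * config.surgery_complication_rate
        unit_costs = replace(unit_costs, benign_surgery=unit_costs.benign_surgery + extra)
    accuracy = profile.accuracy
    if config.uss_sensitivity_scale != 1.0 or config.uss_specificity_scale != 1.0:
        rows = []
        for row in accuracy.rows():
            if row.test_id is TestId.USS:
                rows.append(
                    TestAccuracy(
                        test_id=row.test_id,
                        age_group=row.age_group,
                        threshold_label=row.threshold_label,
                        sensitivity=min(1.0, row.sensitivity * config.uss_sensitivity_scale),
                        specificity=min(1.0, row.specificity * config.uss_specificity_scale),
                    )
                )
            else:
                rows.append(row)
        accuracy = AccuracyTable(rows)
    if config.stage_accuracy_table is not None:
        accuracy = AccuracyTable.from_csv(config.stage_accuracy_table)
    return replace(
        profile,
        spec=spec,
        utility_model=utility,
        unit_costs=unit_costs,
        accuracy=accuracy,
        stage_shift=StageShiftParams(rr_late=config.rr_late),
        seed=config.seed,
    )
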