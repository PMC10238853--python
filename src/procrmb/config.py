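"""Design configuration files and scenario fixtures.

A design configuration bundles everything needed to run or simulate the
two-endpoint adaptive trial: dose labels, per-endpoint targets, skeletons
(given directly or via calibration parameters), prior variances, and trial
conduct settings.  Configurations load from YAML or JSON, are validated
against all type invariants, reject unknown keys, and round-trip through
``to_dict``.
"""

from __future__ import annotations

import importlib.resources
import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Mapping

import yaml

from .model import (
    CLINICIAN,
    PATIENT,
    CalibrationParams,
    DoseGrid,
    EndpointSpec,
    calibrate_skeleton,
)
from .simulate import Scenario, TrialConfig

__all__ = [
    "DesignConfig",
    "ConfigError",
    "default_config",
    "load_config",
    "load_scenarios",
    "builtin_scenarios",
]

SCHEMA_VERSION = 1


class ConfigError(ValueError):
    """Invalid or malformed design configuration."""


@dataclass(frozen=True)
class DesignConfig:
    """Validated design configuration for one trial."""

    grid: DoseGrid
    clinician: EndpointSpec
    patient: EndpointSpec
    trial: TrialConfig

    @property
    def specs(self) -> tuple[EndpointSpec, EndpointSpec]:
        return (self.clinician, self.patient)

    def to_dict(self) -> dict[str, Any]:
        return {
            "schema_version": SCHEMA_VERSION,
            "dose_labels": list(self.grid.labels),
            "clinician": {
                "target": self.clinician.target,
                "skeleton": list(self.clinician.skeleton),
                "prior_var": self.clinician.prior_var,
            },
            "patient": {
                "target": self.patient.target,
                "skeleton": list(self.patient.skeleton),
                "prior_var": self.patient.prior_var,
            },
            "trial": {
                "cohort_size": self.trial.cohort_size,
                "max_n": self.trial.max_n,
                "start_dose": self.trial.start_dose,
                "stop_confidence": self.trial.stop_confidence,
                "dose_cap": self.trial.dose_cap,
                "estimator": self.trial.estimator,
            },
        }


def _check_keys(section: Mapping[str, Any], allowed: set[str], where: str) -> None:
    unknown = set(section) - allowed
    if unknown:
        raise ConfigError(f"unknown key(s) in {where}: {sorted(unknown)}")


def _endpoint_from_dict(
    endpoint_id: str, section: Mapping[str, Any], num_levels: int
) -> EndpointSpec:
    _check_keys(
        section, {"target", "skeleton", "calibration", "prior_var", "prior_sd"}, endpoint_id
    )
    try:
        target = float(section["target"])
    except KeyError as exc:
        raise ConfigError(f"{endpoint_id}: missing target") from exc
    if "prior_sd" in section and "prior_var" in section:
        raise ConfigError(f"{endpoint_id}: give prior_sd or prior_var, not both")
    if "prior_sd" in section:
        prior_sd = float(section["prior_sd"])
    elif "prior_var" in section:
        prior_sd = math.sqrt(float(section["prior_var"]))
    else:
        raise ConfigError(f"{endpoint_id}: missing prior_var (or prior_sd)")
    if "skeleton" in section and "calibration" in section:
        raise ConfigError(f"{endpoint_id}: give skeleton or calibration, not both")
    if "skeleton" in section:
        skeleton = tuple(float(p) for p in section["skeleton"])
        if len(skeleton) != num_levels:
            raise ConfigError(f"{endpoint_id}: skeleton length != number of doses")
    elif "calibration" in section:
        cal = section["calibration"]
        _check_keys(cal, {"halfwidth", "prior_mtd_index"}, f"{endpoint_id}.calibration")
        params = CalibrationParams(
            halfwidth=float(cal["halfwidth"]),
            prior_mtd_index=int(cal.get("prior_mtd_index", 1)),
        )
        try:
            skeleton = calibrate_skeleton(target, params, num_levels)
        except ValueError as exc:
            raise ConfigError(f"{endpoint_id}: {exc}") from exc
    else:
        raise ConfigError(f"{endpoint_id}: missing skeleton or calibration")
    try:
        return EndpointSpec(
            endpoint_id=endpoint_id, target=target, skeleton=skeleton, prior_sd=prior_sd
        )
    except ValueError as exc:
        raise ConfigError(f"{endpoint_id}: {exc}") from exc


def config_from_dict(data: Mapping[str, Any]) -> DesignConfig:
    _check_keys(
        data, {"schema_version", "dose_labels", "clinician", "patient", "trial"}, "config"
    )
    version = data.get("schema_version", SCHEMA_VERSION)
    if version != SCHEMA_VERSION:
        raise ConfigError(f"unsupported schema_version {version!r}")
    try:
        grid = DoseGrid(labels=tuple(str(x) for x in data["dose_labels"]))
    except (KeyError, ValueError) as exc:
        raise ConfigError(f"dose_labels: {exc}") from exc
    for key in (CLINICIAN, PATIENT):
        if key not in data:
            raise ConfigError(f"missing section: {key}")
    clinician = _endpoint_from_dict(CLINICIAN, data[CLINICIAN], grid.num_levels)
    patient = _endpoint_from_dict(PATIENT, data[PATIENT], grid.num_levels)
    trial_section = dict(data.get("trial", {}))
    _check_keys(
        trial_section,
        {"cohort_size", "max_n", "start_dose", "stop_confidence", "dose_cap", "estimator"},
        "trial",
    )
    try:
        trial = TrialConfig(**trial_section)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"trial: {exc}") from exc
    if trial.start_dose > grid.num_levels:
        raise ConfigError("trial: start_dose exceeds the number of dose levels")
    return DesignConfig(grid=grid, clinician=clinician, patient=patient, trial=trial)


def load_config(path: str | Path) -> DesignConfig:
    """Load and validate a YAML or JSON design configuration file."""
    text = Path(path).read_text()
    data = yaml.safe_load(text)  # YAML is a JSON superset
    if not isinstance(data, Mapping):
        raise ConfigError(f"{path}: expected a mapping at top level")
    return config_from_dict(data)


def default_config() -> DesignConfig:
    """The hypofractionated whole-pelvis radiotherapy trial design.

    Two biologically equivalent courses (level 1: 41.25 Gy in 15 fractions,
    level 2: 38 Gy in 10 fractions, ordered by expected toxicity), clinician
    target 20% and patient target 55%, indifference-interval skeletons with
    halfwidth 0.05 anchored at level 1, least-informative prior variances
    1.60 / 1.58, cohorts of 3 to a maximum of 15, 70% stopping confidence.
    """
    return config_from_dict(
        {
            "schema_version": SCHEMA_VERSION,
            "dose_labels": ["41.25 Gy / 15 fractions", "38 Gy / 10 fractions"],
            "clinician": {
                "target": 0.20,
                "calibration": {"halfwidth": 0.05, "prior_mtd_index": 1},
                "prior_var": 1.60,
            },
            "patient": {
                "target": 0.55,
                "calibration": {"halfwidth": 0.05, "prior_mtd_index": 1},
                "prior_var": 1.58,
            },
            "trial": {
                "cohort_size": 3,
                "max_n": 15,
                "start_dose": 1,
                "stop_confidence": 0.70,
                "dose_cap": 16,
                "estimator": "plugin",
            },
        }
    )


def _scenarios_from_data(data: Any, where: str) -> list[Scenario]:
    if isinstance(data, Mapping):
        data = data.get("scenarios", data)
    if not isinstance(data, list):
        raise ConfigError(f"{where}: expected a list of scenarios")
    out = []
    for item in data:
        _check_keys(item, {"name", "true_c_dlt", "true_p_dlt"}, f"{where} scenario")
        try:
            out.append(
                Scenario(
                    name=str(item["name"]),
                    true_c_dlt=tuple(float(v) for v in item["true_c_dlt"]),
                    true_p_dlt=tuple(float(v) for v in item["true_p_dlt"]),
                )
            )
        except (KeyError, ValueError) as exc:
            raise ConfigError(f"{where}: {exc}") from exc
    return out


def load_scenarios(path: str | Path) -> list[Scenario]:
    """Load simulation scenarios from a YAML or JSON file."""
    data = yaml.safe_load(Path(path).read_text())
    return _scenarios_from_data(data, str(path))


def builtin_scenarios() -> dict[str, Scenario]:
    """The six bundled benchmark scenarios, keyed by name."""
    text = (
        importlib.resources.files("procrmb").joinpath("data/scenarios.yaml").read_text()
    )
    return {s.name: s for s in _scenarios_from_data(yaml.safe_load(text), "builtin")}
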