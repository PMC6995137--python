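"""YAML configuration: parameter distributions, model structure, population
settings, bias scenarios, and the synthetic-study block.

A configuration file has blocks ``parameters``, ``model``, ``population``,
``scenarios`` and ``study``; any omitted block (or an empty file) falls back
to the packaged base-case defaults.  Validation errors report the offending
field path.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import yaml

from .parameters import ParameterSpec, ParameterSpecSet, lognormal_from_median_ci
from .scenarios import BiasScenario
from .study import StudyConfig
from .tree import ModelConfig
from .voi import PopulationConfig

__all__ = ["Config", "load_config", "default_config_path", "parse_parameter"]


@dataclass
class Config:
    """Fully validated analysis configuration."""

    parameters: ParameterSpecSet
    model: ModelConfig
    population: PopulationConfig
    scenarios: tuple[BiasScenario, ...]
    study: StudyConfig


class ConfigError(ValueError):
    """A schema violation in a configuration file, with its field path."""


def _packaged(name: str) -> dict:
    text = resources.files("graftce.data").joinpath(name).read_text()
    return yaml.safe_load(text)


def default_config_path() -> Path:
    """Path of the packaged base-case configuration (for inspection/copying)."""
    return Path(str(resources.files("graftce.data").joinpath("base_case.yaml")))


def parse_parameter(name: str, block: dict) -> ParameterSpec:
    """Parse one parameter block into a spec.

    Lognormals accept either raw ``meanlog``/``sdlog`` or a ``median`` with a
    95% ``ci`` pair (inverted on the log scale); betas take ``shape_a``/
    ``shape_b``; points take ``value``.
    """
    if not isinstance(block, dict):
        raise ConfigError(f"parameters.{name}: expected a mapping, got {type(block).__name__}")
    family = block.get("family")
    units = block.get("units", "")
    try:
        if family == "lognormal":
            if "median" in block:
                lo, hi = block["ci"]
                return lognormal_from_median_ci(block["median"], lo, hi, name=name, units=units)
            return ParameterSpec(
                name=name, family="lognormal",
                shape_a=float(block["meanlog"]), shape_b=float(block["sdlog"]), units=units,
            )
        if family == "beta":
            return ParameterSpec(
                name=name, family="beta",
                shape_a=float(block["shape_a"]), shape_b=float(block["shape_b"]), units=units,
            )
        if family == "point":
            return ParameterSpec(name=name, family="point", value=float(block["value"]), units=units)
    except ConfigError:
        raise
    except KeyError as exc:
        raise ConfigError(f"parameters.{name}: missing field {exc.args[0]!r} for family {family!r}") from exc
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"parameters.{name}: {exc}") from exc
    raise ConfigError(
        f"parameters.{name}.family: expected beta, lognormal or point, got {family!r}"
    )


def _parse_parameters(block: dict) -> ParameterSpecSet:
    specs = [parse_parameter(name, sub) for name, sub in block.items()]
    try:
        return ParameterSpecSet(specs)
    except ValueError as exc:
        raise ConfigError(f"parameters: {exc}") from exc


def _parse_dataclass(cls, block: dict, path: str, list_fields: tuple[str, ...] = ()):
    if not isinstance(block, dict):
        raise ConfigError(f"{path}: expected a mapping, got {type(block).__name__}")
    known = set(cls.__dataclass_fields__)
    unknown = set(block) - known
    if unknown:
        raise ConfigError(f"{path}: unknown fields {sorted(unknown)}; expected {sorted(known)}")
    kwargs = {k: (tuple(v) if k in list_fields and isinstance(v, list) else v) for k, v in block.items()}
    try:
        return cls(**kwargs)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"{path}: {exc}") from exc


def _parse_scenarios(block) -> tuple[BiasScenario, ...]:
    if not isinstance(block, list):
        raise ConfigError(f"scenarios: expected a list, got {type(block).__name__}")
    out = []
    for i, sc in enumerate(block):
        if not isinstance(sc, dict):
            raise ConfigError(f"scenarios[{i}]: expected a mapping")
        try:
            out.append(
                BiasScenario(
                    label=str(sc["label"]),
                    bias_median=float(sc["median"]),
                    bias_ci=(float(sc["ci"][0]), float(sc["ci"][1])),
                    note=str(sc.get("note", "")),
                )
            )
        except KeyError as exc:
            raise ConfigError(f"scenarios[{i}]: missing field {exc.args[0]!r}") from exc
        except (TypeError, ValueError) as exc:
            raise ConfigError(f"scenarios[{i}]: {exc}") from exc
    return tuple(out)


def load_config(path: str | Path | None = None) -> Config:
    """Load and validate a configuration file.

    ``path=None`` (or an empty file) loads the packaged base-case defaults;
    otherwise user blocks override the defaults block-by-block.
    """
    data = dict(_packaged("base_case.yaml"))
    data["scenarios"] = _packaged("bias_scenarios.yaml")["scenarios"]
    if path is not None:
        user = yaml.safe_load(Path(path).read_text())
        if user is None:
            user = {}
        if not isinstance(user, dict):
            raise ConfigError(f"{path}: top level must be a mapping of blocks")
        unknown = set(user) - {"parameters", "model", "population", "scenarios", "study"}
        if unknown:
            raise ConfigError(f"{path}: unknown top-level blocks {sorted(unknown)}")
        data.update(user)

    return Config(
        parameters=_parse_parameters(data["parameters"]),
        model=_parse_dataclass(ModelConfig, data["model"], "model", list_fields=("arms",)),
        population=_parse_dataclass(PopulationConfig, data["population"], "population"),
        scenarios=_parse_scenarios(data["scenarios"]),
        study=_parse_dataclass(
            StudyConfig, data["study"], "study",
            list_fields=("utility_baseline_ab", "utility_no_ab", "utility_re_ab"),
        ),
    )
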