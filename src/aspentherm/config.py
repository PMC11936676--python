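"""Run configuration: schema-validated YAML for site, scenarios, leaf and
analysis options, plus the shipped calibrated study-site configuration."""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Any, Mapping

import yaml

from .leaf_energy import LeafParameters
from .microclimate import MicroclimateError, MonthlyNormals, ScenarioSpec, SiteSpec

__all__ = ["RunConfig", "ConfigError", "load_config", "default_config", "config_hash"]


class ConfigError(ValueError):
    """The configuration file is malformed or violates the schema."""


@dataclass(frozen=True)
class AnalysisOptions:
    levene_center: str = "median"
    link: str = "logit"
    lt50_host: float | None = None  # pinned host LT50 if no host trials supplied
    tpref_mark_temperatures: bool = True

    def __post_init__(self) -> None:
        if self.levene_center not in ("median", "mean"):
            raise ConfigError("levene_center must be 'median' or 'mean'")
        if self.link not in ("logit", "probit"):
            raise ConfigError("link must be 'logit' or 'probit'")


@dataclass(frozen=True)
class RunConfig:
    site: SiteSpec
    scenarios: tuple[ScenarioSpec, ...]
    leaf: LeafParameters
    analysis: AnalysisOptions = field(default_factory=AnalysisOptions)
    seed: int = 0
    output_dir: Path = Path("aspentherm-run")

    def __post_init__(self) -> None:
        if not self.scenarios:
            raise ConfigError("at least one scenario is required")


_TOP_KEYS = {"site", "scenarios", "leaf", "analysis", "seed", "output_dir"}
_SITE_KEYS = {"latitude", "longitude", "elevation", "reference_height", "normals"}
_NORMAL_KEYS = {"t_min", "t_max", "wind_mean", "rh_mean", "cloud_fraction"}
_SCENARIO_KEYS = {"name", "delta", "monthly_deltas"}
_LEAF_KEYS = {
    "shortwave_absorptance",
    "emissivity",
    "characteristic_dimension",
    "stomatal_conductance",
    "exposure",
    "free_convection_floor",
}
_ANALYSIS_KEYS = {"levene_center", "link", "lt50_host", "tpref_mark_temperatures"}


def _check_keys(mapping: Mapping[str, Any], allowed: set[str], where: str) -> None:
    unknown = set(mapping) - allowed
    if unknown:
        raise ConfigError(f"unknown key(s) {sorted(unknown)} in {where}")


def _build(raw: Mapping[str, Any]) -> RunConfig:
    if not isinstance(raw, Mapping):
        raise ConfigError("configuration root must be a mapping")
    _check_keys(raw, _TOP_KEYS, "top level")
    for key in ("site", "scenarios", "leaf"):
        if key not in raw:
            raise ConfigError(f"missing required section {key!r}")

    site_raw = raw["site"]
    _check_keys(site_raw, _SITE_KEYS, "site")
    normals = {}
    for month, nv in site_raw.get("normals", {}).items():
        _check_keys(nv, _NORMAL_KEYS, f"site.normals[{month}]")
        try:
            normals[int(month)] = MonthlyNormals(**nv)
        except (TypeError, MicroclimateError) as exc:
            raise ConfigError(f"site.normals[{month}]: {exc}") from exc
    try:
        site = SiteSpec(
            latitude=float(site_raw["latitude"]),
            longitude=float(site_raw["longitude"]),
            elevation=float(site_raw["elevation"]),
            reference_height=float(site_raw.get("reference_height", 1.2)),
            normals=normals,
        )
    except (KeyError, MicroclimateError) as exc:
        raise ConfigError(f"site: {exc}") from exc

    scenarios = []
    for s in raw["scenarios"]:
        _check_keys(s, _SCENARIO_KEYS, f"scenario {s.get('name', '?')!r}")
        scenarios.append(
            ScenarioSpec(
                name=str(s.get("name", "unnamed")),
                delta=float(s.get("delta", 0.0)),
                monthly_deltas={int(k): float(v) for k, v in s.get("monthly_deltas", {}).items()},
            )
        )

    leaf_raw = raw["leaf"]
    _check_keys(leaf_raw, _LEAF_KEYS, "leaf")
    leaf = LeafParameters(**leaf_raw)

    analysis_raw = raw.get("analysis", {})
    _check_keys(analysis_raw, _ANALYSIS_KEYS, "analysis")
    analysis = AnalysisOptions(**analysis_raw)

    return RunConfig(
        site=site,
        scenarios=tuple(scenarios),
        leaf=leaf,
        analysis=analysis,
        seed=int(raw.get("seed", 0)),
        output_dir=Path(raw.get("output_dir", "aspentherm-run")),
    )


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML run configuration."""
    with Path(path).open(encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    return _build(raw)


def default_config() -> RunConfig:
    """The shipped, calibrated study-site configuration (synthetic monthly
    normals tuned so current-scenario maxima match the published site)."""
    text = resources.files("aspentherm.data").joinpath("mpg_north.yaml").read_text()
    return _build(yaml.safe_load(text))


def config_hash(path_or_config: str | Path | RunConfig) -> str:
    """Stable SHA-256 of a configuration's canonical representation.

    For a RunConfig the hash covers the scientific inputs (site, scenarios,
    leaf, analysis, seed) but not the output directory, so reruns into
    different directories hash identically.
    """
    if isinstance(path_or_config, RunConfig):
        c = path_or_config
        text = repr((c.site, c.scenarios, c.leaf, c.analysis, c.seed))
    else:
        text = Path(path_or_config).read_text(encoding="utf-8")
    return hashlib.sha256(text.encode("utf-8")).hexdigest()
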