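"""Scenario configuration: one YAML document per scenario, strictly validated.

A scenario file assembles a particle, a species (preset name or explicit
mapping), an exposure regimen, clearance parameters and optional threshold
overrides::

    particle:
      name: generic-psp
      rho_apparent: 1.0
    species: rat
    regimen:
      volume_concentration: 2.2
      duration_weeks: 4
      postexposure_days: 90
    clearance:
      mode: loglinear
      k_dissolution: 0.0

Unknown keys are rejected at every level so typos fail loudly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields as dc_fields
from typing import Optional

import yaml

from .clearance import ClearanceParams, RetardationModel
from .errors import InvalidParameterError
from .params import ExposureRegimen, ParticleSpec, SPECIES_PRESETS, SpeciesDosimetry
from .thresholds import DEFAULT_THRESHOLDS, ThresholdSet

__all__ = ["ScenarioConfig", "load_scenario", "dump_scenario"]


def _build(cls, mapping, context):
    if not isinstance(mapping, dict):
        raise InvalidParameterError(f"{context}: expected a mapping")
    allowed = {f.name for f in dc_fields(cls)}
    unknown = set(mapping) - allowed
    if unknown:
        raise InvalidParameterError(f"{context}: unknown keys {sorted(unknown)}")
    return cls(**mapping)


def _build_clearance(mapping) -> ClearanceParams:
    if not isinstance(mapping, dict):
        raise InvalidParameterError("clearance: expected a mapping")
    mapping = dict(mapping)
    k_dissolution = mapping.pop("k_dissolution", 0.0)
    retardation = _build(RetardationModel, mapping, "clearance")
    return ClearanceParams(retardation=retardation, k_dissolution=k_dissolution)


@dataclass
class ScenarioConfig:
    """A fully validated simulation scenario."""

    particle: ParticleSpec
    species: SpeciesDosimetry
    regimen: ExposureRegimen
    clearance: ClearanceParams = field(default_factory=ClearanceParams)
    thresholds: ThresholdSet = DEFAULT_THRESHOLDS
    name: str = "scenario"

    @classmethod
    def from_mapping(cls, doc: dict) -> "ScenarioConfig":
        if not isinstance(doc, dict):
            raise InvalidParameterError("scenario document must be a mapping")
        allowed = {"particle", "species", "regimen", "clearance", "thresholds", "name"}
        unknown = set(doc) - allowed
        if unknown:
            raise InvalidParameterError(f"scenario: unknown keys {sorted(unknown)}")
        for key in ("particle", "species", "regimen"):
            if key not in doc:
                raise InvalidParameterError(f"scenario: missing required key {key!r}")

        species_doc = doc["species"]
        if isinstance(species_doc, str):
            try:
                species = SPECIES_PRESETS[species_doc]
            except KeyError:
                raise InvalidParameterError(
                    f"unknown species preset {species_doc!r}; "
                    f"available: {sorted(SPECIES_PRESETS)}"
                ) from None
        else:
            species = _build(SpeciesDosimetry, species_doc, "species")

        clearance = (
            _build_clearance(doc["clearance"]) if "clearance" in doc else ClearanceParams()
        )
        thresholds = (
            _build(ThresholdSet, doc["thresholds"], "thresholds")
            if "thresholds" in doc
            else DEFAULT_THRESHOLDS
        )
        return cls(
            particle=_build(ParticleSpec, doc["particle"], "particle"),
            species=species,
            regimen=_build(ExposureRegimen, doc["regimen"], "regimen"),
            clearance=clearance,
            thresholds=thresholds,
            name=doc.get("name", "scenario"),
        )


def load_scenario(path) -> ScenarioConfig:
    """Load and validate a scenario YAML file."""
    with open(path, "r", encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    return ScenarioConfig.from_mapping(doc)


def dump_scenario(config: ScenarioConfig, path) -> None:
    """Serialise a scenario back to YAML (species written as explicit mapping)."""
    def _asdict(obj):
        return {
            f.name: getattr(obj, f.name)
            for f in dc_fields(obj)
            if getattr(obj, f.name) is not None
        }

    doc = {
        "name": config.name,
        "particle": _asdict(config.particle),
        "species": _asdict(config.species),
        "regimen": _asdict(config.regimen),
        "clearance": {
            **_asdict(config.clearance.retardation),
            "k_dissolution": config.clearance.k_dissolution,
        },
    }
    doc["clearance"].pop("custom_anchors", None)
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)
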