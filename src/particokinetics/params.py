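"""Shared domain types, unit conventions and dosimetry conversions.

Unit conventions used package-wide
----------------------------------
* volumes in microlitres (1 ul = 1e9 um^3 = 1 mm^3)
* densities in g/cm^3, numerically identical to mg/ul
* airborne concentrations in ul/m^3 (volume basis) or mg/m^3 (mass basis)
* time in days unless stated otherwise

The conversion between the volume and mass concentration bases is a pure
multiplication by the apparent agglomerate density rho: the displacement
volume of the particle structure as it is retained inside phagocytes is the
dose metric, and rho maps it onto the gravimetric scale used for airborne
exposure limits.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .errors import InvalidParameterError

__all__ = [
    "ParticleSpec",
    "SpeciesDosimetry",
    "ExposureRegimen",
    "RAT",
    "HUMAN",
    "SPECIES_PRESETS",
    "volume_to_mass_concentration",
    "mass_to_volume_concentration",
    "cumulative_exposure",
    "daily_deposited_volume_per_kg",
    "lining_fluid_density",
]


@dataclass(frozen=True)
class ParticleSpec:
    """Physical descriptors of a poorly soluble low-toxicity particle (PSP).

    Parameters
    ----------
    name
        Free-text label.
    rho_apparent
        Apparent agglomerate density of the particle structure as retained in
        phagocytes, g/cm^3 (= mg/ul).
    respirable_fraction
        Fraction of aerosol mass in the respirable range, in (0, 1].
    mmad, gsd
        Mass median aerodynamic diameter (um) and geometric standard
        deviation of the aerosol size distribution; descriptive only, no
        deposition modelling is performed from them.
    solubility_cs
        Saturation solubility, mg/L.
    diffusion_d
        Diffusion coefficient of the dissolved species, m^2/s.
    """

    name: str
    rho_apparent: float
    respirable_fraction: float = 1.0
    mmad: Optional[float] = None
    gsd: Optional[float] = None
    solubility_cs: Optional[float] = None
    diffusion_d: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.rho_apparent > 0:
            raise InvalidParameterError("rho_apparent must be positive")
        if not 0 < self.respirable_fraction <= 1:
            raise InvalidParameterError("respirable_fraction must be in (0, 1]")
        if self.gsd is not None and self.gsd < 1:
            raise InvalidParameterError("gsd must be >= 1")
        if self.mmad is not None and self.mmad <= 0:
            raise InvalidParameterError("mmad must be positive")
        if self.solubility_cs is not None and self.solubility_cs < 0:
            raise InvalidParameterError("solubility_cs must be >= 0")
        if self.diffusion_d is not None and self.diffusion_d <= 0:
            raise InvalidParameterError("diffusion_d must be positive")


@dataclass(frozen=True)
class SpeciesDosimetry:
    """Species-level respiratory dosimetry constants.

    Fields that only enter species comparisons (lining fluid, surface area,
    macrophage patrol area) are optional; operations raise
    :class:`InvalidParameterError` when a required field is missing.
    """

    species: str  # "rat", "human" or "custom"
    inhaled_volume_per_kg_day: Optional[float] = None  # m^3/kg per exposure day
    reference_hours_per_day: float = 6.0
    lung_rel_weight: Optional[float] = None  # g lung per kg body weight
    lining_fluid_volume: Optional[float] = None  # ul
    alveolar_surface_area: Optional[float] = None  # m^2
    patrol_area_per_am: Optional[float] = None  # um^2 per alveolar macrophage

    def __post_init__(self) -> None:
        if not 0 < self.reference_hours_per_day <= 24:
            raise InvalidParameterError("reference_hours_per_day must be in (0, 24]")
        for name in (
            "inhaled_volume_per_kg_day",
            "lung_rel_weight",
            "lining_fluid_volume",
            "alveolar_surface_area",
            "patrol_area_per_am",
        ):
            value = getattr(self, name)
            if value is not None and not value > 0:
                raise InvalidParameterError(f"{name} must be positive")

    def require(self, *names: str) -> None:
        missing = [n for n in names if getattr(self, n) is None]
        if missing:
            raise InvalidParameterError(
                f"species '{self.species}' lacks required dosimetry fields: {missing}"
            )


#: Rat dosimetry: 0.29 m^3 inhaled per kg body weight per 6-h exposure day,
#: ~4.5 g lung/kg, 26.4 ul lining fluid over 0.34 m^2 alveolar surface,
#: 140,000 um^2 patrolled per alveolar macrophage.
RAT = SpeciesDosimetry(
    species="rat",
    inhaled_volume_per_kg_day=0.29,
    reference_hours_per_day=6.0,
    lung_rel_weight=4.5,
    lining_fluid_volume=26.4,
    alveolar_surface_area=0.34,
    patrol_area_per_am=140_000.0,
)

#: Human dosimetry constants used in species-capacity comparisons.
HUMAN = SpeciesDosimetry(
    species="human",
    lining_fluid_volume=8900.0,
    alveolar_surface_area=54.0,
    patrol_area_per_am=22_000.0,
)

SPECIES_PRESETS = {"rat": RAT, "human": HUMAN}


@dataclass(frozen=True)
class ExposureRegimen:
    """An intermittent inhalation exposure schedule.

    ``volume_concentration`` is the respirable volume concentration in
    ul PSP/m^3; the schedule defaults to the standard repeated-dose
    regimen of 6 h/day on 5 consecutive exposure days per week.
    """

    volume_concentration: float  # ul/m^3 (respirable basis)
    duration_weeks: float
    hours_per_day: float = 6.0
    days_per_week: int = 5
    postexposure_days: int = 0

    def __post_init__(self) -> None:
        if self.volume_concentration < 0:
            raise InvalidParameterError("volume_concentration must be >= 0")
        if not 0 < self.hours_per_day <= 24:
            raise InvalidParameterError("hours_per_day must be in (0, 24]")
        if not 1 <= int(self.days_per_week) <= 7 or self.days_per_week != int(self.days_per_week):
            raise InvalidParameterError("days_per_week must be an integer in 1..7")
        if not self.duration_weeks > 0:
            raise InvalidParameterError("duration_weeks must be positive")
        if self.postexposure_days < 0:
            raise InvalidParameterError("postexposure_days must be >= 0")


def volume_to_mass_concentration(vol_conc: float, rho: float) -> float:
    """Convert a volume concentration (ul/m^3) to mass (mg/m^3) via rho.

    With rho in g/cm^3 = mg/ul, the mass concentration is simply
    ``vol_conc * rho``.
    """
    if not rho > 0:
        raise InvalidParameterError("rho must be positive")
    if vol_conc < 0:
        raise InvalidParameterError("vol_conc must be >= 0")
    return vol_conc * rho


def mass_to_volume_concentration(mass_conc: float, rho: float) -> float:
    """Inverse of :func:`volume_to_mass_concentration`."""
    if not rho > 0:
        raise InvalidParameterError("rho must be positive")
    if mass_conc < 0:
        raise InvalidParameterError("mass_conc must be >= 0")
    return mass_conc / rho


def cumulative_exposure(regimen: ExposureRegimen, reference_hours: float = 6.0) -> float:
    """Cumulative external dose C x Sigma-t in ul*day/m^3.

    Exposure days are counted over the full schedule and scaled linearly by
    ``hours_per_day`` relative to the reference daily duration.
    """
    n_days = regimen.duration_weeks * regimen.days_per_week
    return regimen.volume_concentration * n_days * (regimen.hours_per_day / reference_hours)


def daily_deposited_volume_per_kg(regimen: ExposureRegimen, species: SpeciesDosimetry) -> float:
    """Nominal inhaled respirable volume per kg body weight per exposure day (ul/kg).

    This is the dose-rate term the accumulation-factor formalism multiplies;
    deposition efficiency and intermittency are lumped into the accumulation
    factor itself, so no deposition fraction is applied here.
    """
    species.require("inhaled_volume_per_kg_day")
    return (
        regimen.volume_concentration
        * species.inhaled_volume_per_kg_day
        * (regimen.hours_per_day / species.reference_hours_per_day)
    )


def lining_fluid_density(species: SpeciesDosimetry) -> float:
    """Alveolar lining-fluid volume per unit alveolar surface, ul/m^2.

    Full precision is returned; rat and human presets round to the
    conventional 78 and 165 ul/m^2 for display.
    """
    species.require("lining_fluid_volume", "alveolar_surface_area")
    return species.lining_fluid_volume / species.alveolar_surface_area
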