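"""Particle dissolution kinetics (Nernst-Brunner / Noyes-Whitney).

The dissolution rate of a solid in a liquid is modelled as diffusion through
a boundary layer, driven by the undersaturation of the medium:

    dM/dt = -(D / (V_m * h)) * S_A * (C_s - C)

with M the solid mass (mg), S_A the area available for mass transfer (m^2),
D the diffusion coefficient (m^2/s), V_m the dissolution medium volume (L),
h the diffusion boundary layer thickness (m), C the dissolved concentration
and C_s the saturation solubility (mg/L).  The equation is evaluated
literally in these units with time converted to days; the 1/V_m factor makes
the prefactor a lumped first-order coefficient rather than a strict
dimensional flux, which is how the relationship is conventionally applied to
lung-burden half-time reasoning.

Two surface-evolution laws are provided:

``constant_area``
    The *specific* transfer area (area per unit solid mass) is held
    constant, S_A(m) = S_A0 * m/m0.  Under sink conditions this yields
    first-order kinetics m(t) = m0 * exp(-k_d t), the form used throughout
    the package to express dissolution as an elimination half-time.
``shrinking_sphere``
    A monodisperse population of shrinking spheres, S_A(m) =
    S_A0 * (m/m0)^(2/3).  Under sink conditions the cube root of the mass
    decreases linearly in time until exhaustion.

Closed (non-sink) systems conserve total mass exactly: the dissolved
concentration is computed from the solid mass balance,
C(t) = C(0) + (m0 - m(t))/V_m.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .errors import (
    InvalidParameterError,
    SupersaturationWarning,
    UndefinedHalfTimeError,
)

__all__ = [
    "DissolutionSystem",
    "dissolution_rate",
    "simulate_dissolution",
    "dissolution_half_time",
    "half_time_from_fraction_cleared",
]

SECONDS_PER_DAY = 86_400.0

#: exponent of the (m/m0) surface-scaling law per geometry
_AREA_EXPONENT = {"constant_area": 1.0, "shrinking_sphere": 2.0 / 3.0}


@dataclass(frozen=True)
class DissolutionSystem:
    """State and parameters of a dissolving solid in a liquid medium.

    Parameters
    ----------
    m0, m
        Initial and current solid mass, mg.  ``m`` defaults to ``m0``.
    s_a
        Surface area available for mass transfer at ``m = m0``, m^2.
    diffusion_d
        Diffusion coefficient of the dissolved species, m^2/s.
    medium_volume_vm
        Dissolution medium volume, L.
    boundary_thickness_h
        Diffusion boundary layer thickness, m.
    concentration_c
        Current dissolved concentration, mg/L.
    saturation_cs
        Saturation solubility, mg/L.
    geometry
        ``"constant_area"`` (constant specific area; first order under sink)
        or ``"shrinking_sphere"`` (cube-root law under sink).
    sink
        If True the dissolved concentration is pinned at 0.
    pinned_concentration
        If set (and ``sink`` is False), the dissolved concentration is held
        at this value instead of evolving — a generalised sink condition for
        media continuously exchanged at a fixed degree of saturation.
    """

    m0: float
    s_a: float
    diffusion_d: float
    medium_volume_vm: float
    boundary_thickness_h: float
    saturation_cs: float
    m: Optional[float] = None
    concentration_c: float = 0.0
    geometry: str = "constant_area"
    sink: bool = True
    pinned_concentration: Optional[float] = None

    def __post_init__(self) -> None:
        if self.m is None:
            object.__setattr__(self, "m", self.m0)
        if not self.m0 > 0:
            raise InvalidParameterError("m0 must be positive")
        if not 0 <= self.m <= self.m0:
            raise InvalidParameterError("current mass m must satisfy 0 <= m <= m0")
        if self.s_a < 0:
            raise InvalidParameterError("s_a must be >= 0")
        if not self.diffusion_d > 0:
            raise InvalidParameterError("diffusion_d must be positive")
        if not self.medium_volume_vm > 0:
            raise InvalidParameterError("medium_volume_vm must be positive")
        if not self.boundary_thickness_h > 0:
            raise InvalidParameterError("boundary_thickness_h must be positive")
        if self.saturation_cs < 0:
            raise InvalidParameterError("saturation_cs must be >= 0")
        if self.concentration_c < 0:
            raise InvalidParameterError("concentration_c must be >= 0")
        if self.geometry not in _AREA_EXPONENT:
            raise InvalidParameterError(
                f"geometry must be one of {sorted(_AREA_EXPONENT)}"
            )
        if self.pinned_concentration is not None and self.pinned_concentration < 0:
            raise InvalidParameterError("pinned_concentration must be >= 0")

    @property
    def transfer_coefficient_per_day(self) -> float:
        """Lumped prefactor D*S_A0/(V_m*h) in (mg/day)/(mg/L)."""
        d_day = self.diffusion_d * SECONDS_PER_DAY
        return d_day * self.s_a / (self.medium_volume_vm * self.boundary_thickness_h)

    def _effective_concentration(self, m: float) -> float:
        if self.sink:
            return 0.0
        if self.pinned_concentration is not None:
            return self.pinned_concentration
        return self.concentration_c + (self.m0 - m) / self.medium_volume_vm


def dissolution_rate(system: DissolutionSystem) -> float:
    """Instantaneous dissolution rate dM/dt in mg/day (negative while dissolving).

    Evaluated at the system's current mass and concentration with the
    current transfer area; exactly 0 at saturation.  A dissolved
    concentration above saturation is reported via
    :class:`SupersaturationWarning` — the returned (positive) value is the
    formal driving-force reversal, not a precipitation model.
    """
    c = 0.0 if system.sink else (
        system.pinned_concentration
        if system.pinned_concentration is not None
        else system.concentration_c
    )
    if c > system.saturation_cs:
        warnings.warn(
            "dissolved concentration exceeds saturation solubility; "
            "precipitation kinetics are not modelled",
            SupersaturationWarning,
            stacklevel=2,
        )
    exponent = _AREA_EXPONENT[system.geometry]
    area_scale = (system.m / system.m0) ** exponent if system.m > 0 else 0.0
    return -system.transfer_coefficient_per_day * area_scale * (system.saturation_cs - c)


def _mass_rhs(system: DissolutionSystem):
    exponent = _AREA_EXPONENT[system.geometry]
    k = system.transfer_coefficient_per_day

    def rhs(t, y):
        m = max(y[0], 0.0)
        c = system._effective_concentration(m)
        driving = max(system.saturation_cs - c, 0.0)
        return [-k * (m / system.m0) ** exponent * driving]

    return rhs


def _integrate(system: DissolutionSystem, t_span, t_eval=None, events=None):
    rhs = _mass_rhs(system)
    for method in ("LSODA", "RK45"):
        sol = solve_ivp(
            rhs,
            t_span,
            [system.m],
            method=method,
            t_eval=t_eval,
            events=events,
            rtol=1e-10,
            atol=1e-14 * system.m0,
            dense_output=t_eval is None,
        )
        if sol.success:
            return sol
    raise RuntimeError(f"dissolution integrator failed: {sol.message}")


def simulate_dissolution(system: DissolutionSystem, t_grid) -> pd.DataFrame:
    """Integrate the dissolution ODE over a monotone time grid (days).

    Returns a DataFrame with columns ``t_days``, ``mass_mg`` and
    ``concentration_mg_per_l``.  Mass is non-increasing; closed systems
    conserve ``mass + C*V_m`` exactly because the concentration is computed
    from the solid-mass balance.
    """
    t = np.asarray(t_grid, dtype=float)
    if t.ndim != 1 or t.size < 2 or t[0] != 0 or np.any(np.diff(t) <= 0):
        raise InvalidParameterError("t_grid must be monotone increasing and start at 0")
    sol = _integrate(system, (0.0, float(t[-1])), t_eval=t)
    mass = np.clip(sol.y[0], 0.0, system.m0)
    conc = np.array([system._effective_concentration(m) for m in mass])
    return pd.DataFrame({"t_days": t, "mass_mg": mass, "concentration_mg_per_l": conc})


def dissolution_half_time(system: DissolutionSystem, t_max: Optional[float] = None):
    """Time (days) for the solid mass to fall to half its initial value.

    Returns ``(t_half, dissolution_relevant)`` where the flag marks
    half-times shorter than 60 days — dissolution fast enough to interfere
    with the interpretation of macrophage-mediated clearance and therefore
    potentially incompatible with the PSP paradigm.

    Raises
    ------
    UndefinedHalfTimeError
        If the system cannot dissolve (saturated medium) or equilibrates
        before reaching half mass.
    """
    c0 = system._effective_concentration(system.m)
    if c0 >= system.saturation_cs or system.transfer_coefficient_per_day == 0:
        raise UndefinedHalfTimeError("system does not dissolve: no driving force")
    # a closed system that saturates before half the mass is dissolved
    if not system.sink and system.pinned_concentration is None:
        dissolvable = (system.saturation_cs - system.concentration_c) * system.medium_volume_vm
        if dissolvable < system.m0 / 2:
            raise UndefinedHalfTimeError(
                "medium saturates before half of the solid dissolves"
            )
    rate0 = abs(dissolution_rate(system))
    if t_max is None:
        t_max = 1e4 * system.m0 / rate0  # generous multiple of the initial timescale

    half = system.m0 / 2.0

    def crossing(t, y):
        return y[0] - half

    crossing.terminal = True
    crossing.direction = -1
    sol = _integrate(system, (0.0, t_max), events=crossing)
    if len(sol.t_events[0]) == 0:
        raise UndefinedHalfTimeError(f"half mass not reached within {t_max:g} days")
    t_half = float(sol.t_events[0][0])
    return t_half, t_half < 60.0


def half_time_from_fraction_cleared(fraction_cleared: float, elapsed_days: float) -> float:
    """First-order half-time implied by a fraction cleared over a period.

    ``t_half = elapsed * ln2 / ln(1/(1 - fraction))``; e.g. 70% cleared in
    21 days implies a half-time of about 12.1 days.
    """
    if not 0 < fraction_cleared < 1:
        raise InvalidParameterError("fraction_cleared must be in (0, 1)")
    if not elapsed_days > 0:
        raise InvalidParameterError("elapsed_days must be positive")
    return elapsed_days * math.log(2) / math.log(1.0 / (1.0 - fraction_cleared))
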