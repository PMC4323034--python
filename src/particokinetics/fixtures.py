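"""Synthetic lung-burden observation tables and named scenario presets.

Real repeated-dose inhalation studies report retained lung burdens measured
in small groups of animals at a handful of post-exposure days.  The
generator here emulates that sampling scheme: a first-order decay trajectory
observed with multiplicative lognormal measurement noise (burdens are
positive and assay coefficients of variation are roughly proportional),

    observed = B0 * 2^(-t / t_half) * exp(eps),   eps ~ Normal(0, sigma_log^2).

All stochastic output is seeded; unseeded generation is refused so fixture
data are reproducible by construction.  The presets mirror the classic
classification examples: fast-dissolving zinc compounds (half-times of 3 and
0.8 days), nano barium sulfate (70% cleared in 3 weeks, i.e. a ~12.1-day
half-time), a generic poorly soluble particle in the normal clearance band
(80 days) and one at beginning overload (120 days).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd

from .clearance import ClearanceRegime, classify_clearance_regime
from .dissolution import half_time_from_fraction_cleared
from .errors import InvalidParameterError

__all__ = [
    "generate_burden_observations",
    "ScenarioPreset",
    "preset_scenarios",
    "DEFAULT_SIGMA_LOG",
]

DEFAULT_SIGMA_LOG = 0.15
DEFAULT_INITIAL_BURDEN_UL = 4.0


def generate_burden_observations(
    true_t_half: float,
    schedule: Sequence[float],
    n_per_timepoint: int,
    sigma_log: float,
    seed: Optional[int],
    initial_burden: float = DEFAULT_INITIAL_BURDEN_UL,
) -> pd.DataFrame:
    """Generate a synthetic post-exposure burden observation table.

    Returns a DataFrame with columns ``animal_id``, ``day``, ``burden_ul``
    and ``phase`` (= "postexposure"), deterministic for a given seed.
    ``schedule`` lists the post-exposure sampling days; ``n_per_timepoint``
    animals are sampled at each.
    """
    if not true_t_half > 0:
        raise InvalidParameterError("true_t_half must be positive")
    if sigma_log < 0:
        raise InvalidParameterError("sigma_log must be >= 0")
    if n_per_timepoint < 1:
        raise InvalidParameterError("n_per_timepoint must be >= 1")
    if len(schedule) == 0:
        raise InvalidParameterError("schedule must contain at least one day")
    if not initial_burden > 0:
        raise InvalidParameterError("initial_burden must be positive")
    if seed is None and sigma_log > 0:
        raise InvalidParameterError(
            "stochastic generation requires an explicit seed"
        )

    rng = np.random.default_rng(seed)
    rows = []
    for day in sorted(schedule):
        true = initial_burden * 2.0 ** (-day / true_t_half)
        noise = rng.normal(0.0, sigma_log, size=n_per_timepoint) if sigma_log else np.zeros(n_per_timepoint)
        for i, eps in enumerate(noise):
            rows.append(
                {
                    "animal_id": f"d{day:g}_a{i + 1}",
                    "day": day,
                    "burden_ul": true * math.exp(eps),
                    "phase": "postexposure",
                }
            )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class ScenarioPreset:
    """A named kinetic scenario with its expected classification outcome."""

    name: str
    t_half: float  # days
    sampling_days: tuple
    expected_regime: ClearanceRegime
    description: str

    @property
    def classified_regime(self) -> ClearanceRegime:
        return classify_clearance_regime(self.t_half)


def preset_scenarios() -> Dict[str, ScenarioPreset]:
    """Named kinetic presets spanning the clearance-regime bands."""
    baso4_t_half = half_time_from_fraction_cleared(0.70, 21.0)  # ~12.1 d
    presets = [
        ScenarioPreset(
            "zn_chelate",
            3.0,
            (1, 3, 15),
            ClearanceRegime.DISSOLUTION_DOMINATED,
            "zinc chelate: slow enough to be endocytosed, dissolves in days",
        ),
        ScenarioPreset(
            "zno",
            0.8,
            (1, 3, 15),
            ClearanceRegime.DISSOLUTION_DOMINATED,
            "pigment-grade zinc oxide: near-instant dissolution in lining fluid",
        ),
        ScenarioPreset(
            "baso4_nano",
            baso4_t_half,
            (1, 7, 21),
            ClearanceRegime.DISSOLUTION_DOMINATED,
            "nano barium sulfate: 70% of the burden cleared within 3 weeks",
        ),
        ScenarioPreset(
            "generic_psp",
            80.0,
            (3, 28, 56, 90),
            ClearanceRegime.NORMAL_AM_CLEARANCE,
            "typical poorly soluble particle in the normal 60-90 d band",
        ),
        ScenarioPreset(
            "overload_psp",
            120.0,
            (3, 28, 56, 90),
            ClearanceRegime.OVERLOAD_ONSET,
            "beginning overload-related clearance retardation",
        ),
    ]
    return {p.name: p for p in presets}
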