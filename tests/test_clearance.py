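"""Burden kinetics, retardation, half-time estimation and classification."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from particokinetics import (
    ClearanceParams,
    ClearanceRegime,
    ExposureRegimen,
    RetardationModel,
    classify_clearance_regime,
    estimate_elimination_half_time,
    retarded_half_time,
    simulate_burden,
    simulate_decay,
    steady_state_burden,
)
from particokinetics.errors import (
    InsufficientDataError,
    InvalidParameterError,
    ShortFitWindowWarning,
)
from particokinetics.fixtures import generate_burden_observations

LN2 = math.log(2)


def fixed_clearance(t_half):
    return ClearanceParams(retardation=RetardationModel(mode="none", t_half_base=t_half))


class TestRetardedHalfTime:
    def test_anchor_values_exact(self):
        model = RetardationModel()
        assert retarded_half_time(1.0, model) == pytest.approx(80.0)
        assert retarded_half_time(10.0, model) == pytest.approx(365.0)

    def test_baseline_below_adaptive_threshold(self):
        assert retarded_half_time(0.5, RetardationModel()) == 80.0
        assert retarded_half_time(0.0, RetardationModel()) == 80.0

    def test_loglinear_interpolation_closed_form(self):
        # t(v) = 80 * (365/80)^log10(v) between the (1, 80) and (10, 365) anchors
        assert retarded_half_time(5.5, RetardationModel(mode="loglinear")) == (
            pytest.approx(80 * (365 / 80) ** math.log10(5.5), rel=1e-12)
        )

    def test_linear_interpolation_midpoint(self):
        model = RetardationModel(mode="linear")
        assert retarded_half_time(5.5, model) == pytest.approx(80 + 285 / 2)

    @given(v=st.floats(0, 50, allow_nan=False))
    def test_monotone_nondecreasing(self, v):
        model = RetardationModel()
        assert retarded_half_time(v + 0.5, model) >= retarded_half_time(v, model)

    def test_custom_anchors_and_validation(self):
        model = RetardationModel(
            mode="custom", custom_anchors=[(1.0, 80.0), (5.0, 200.0), (10.0, 365.0)]
        )
        assert retarded_half_time(5.0, model) == pytest.approx(200.0)
        assert retarded_half_time(3.0, model) == pytest.approx(np.interp(3, [1, 5], [80, 200]))
        with pytest.raises(InvalidParameterError):
            RetardationModel(mode="custom", custom_anchors=[(5.0, 200.0), (1.0, 80.0)])


class TestBurdenSimulation:
    def test_pure_decay_halves_in_one_half_time(self):
        regimen = ExposureRegimen(
            volume_concentration=0.0, duration_weeks=1, postexposure_days=80
        )
        series = simulate_burden(
            regimen, None, None, fixed_clearance(80.0), 0.0, initial_burden=4.0
        )
        assert series.burden_at(80) == pytest.approx(2.0, rel=1e-9)

    def test_postexposure_matches_analytic_exponential(self):
        trajectory = simulate_decay(5.0, 200, fixed_clearance(70.0))
        days = np.arange(201)
        np.testing.assert_allclose(
            trajectory, 5.0 * np.exp(-LN2 * days / 70.0), rtol=1e-6
        )

    def test_steady_state_matches_geometric_series(self):
        t_half, dose = 80.0, 0.05
        regimen = ExposureRegimen(
            volume_concentration=1.0, duration_weeks=600, days_per_week=7
        )
        series = simulate_burden(regimen, None, None, fixed_clearance(t_half), dose)
        assert series.final_burden == pytest.approx(
            steady_state_burden(dose, t_half), rel=1e-6
        )

    def test_zero_clearance_conserves_deposition(self):
        clearance = fixed_clearance(math.inf)
        regimen = ExposureRegimen(volume_concentration=1.0, duration_weeks=4)
        series = simulate_burden(regimen, None, None, clearance, 0.3)
        assert series.final_burden == pytest.approx(0.3 * 20, rel=1e-12)

    def test_burden_never_negative_and_days_increasing(self):
        regimen = ExposureRegimen(
            volume_concentration=1.0, duration_weeks=4, postexposure_days=120
        )
        series = simulate_burden(regimen, None, None, ClearanceParams(), 0.2)
        assert (series.frame["burden_ul"] >= 0).all()
        assert series.frame["day"].is_monotonic_increasing

    def test_dissolution_adds_to_elimination_rate(self):
        k_diss = 0.01
        with_diss = ClearanceParams(
            retardation=RetardationModel(mode="none", t_half_base=80.0),
            k_dissolution=k_diss,
        )
        trajectory = simulate_decay(4.0, 100, with_diss)
        expected = 4.0 * np.exp(-(LN2 / 80.0 + k_diss) * np.arange(101))
        np.testing.assert_allclose(trajectory, expected, rtol=1e-9)

    def test_superlinear_accumulation_under_retardation(self):
        """Once burdens cross the adaptive threshold, retardation makes the
        end-of-study burden ratio exceed the concentration ratio."""
        clearance = ClearanceParams()
        regimen = ExposureRegimen(volume_concentration=1.0, duration_weeks=52)
        ratio = 4.3
        low_dose = 0.012  # ends just below the 1 ul adaptive anchor
        low = simulate_burden(regimen, None, None, clearance, low_dose)
        high = simulate_burden(regimen, None, None, clearance, low_dose * ratio)
        assert low.final_burden < 1.5  # close to the threshold
        assert high.final_burden / low.final_burden > ratio


class TestHalfTimeEstimation:
    @pytest.mark.parametrize("t_half", [80.0, 12.089])
    def test_exact_recovery_on_noise_free_data(self, t_half):
        table = generate_burden_observations(
            t_half, [1, 10, 20, 40], n_per_timepoint=1, sigma_log=0.0, seed=None
        )
        estimate = estimate_elimination_half_time(table)
        assert estimate.t_half == pytest.approx(t_half, rel=1e-9)

    @pytest.mark.parametrize("sigma", [0.1, 0.01, 0.0])
    def test_consistency_as_noise_vanishes(self, sigma):
        table = generate_burden_observations(
            80.0, [7, 28, 56, 90], n_per_timepoint=5, sigma_log=sigma, seed=42
        )
        estimate = estimate_elimination_half_time(table)
        # tolerance shrinks with the noise level
        assert estimate.t_half == pytest.approx(80.0, rel=max(3 * sigma, 1e-9))

    @pytest.mark.filterwarnings(
        "ignore::particokinetics.errors.ShortFitWindowWarning"
    )
    def test_monte_carlo_recovery_median_bias_below_two_percent(self):
        estimates = []
        for i in range(500):
            table = generate_burden_observations(
                80.0, [7, 28, 56, 90], n_per_timepoint=5, sigma_log=0.15, seed=1000 + i
            )
            estimates.append(estimate_elimination_half_time(table).t_half)
        median_bias = abs(np.median(estimates) - 80.0) / 80.0
        assert median_bias < 0.02

    def test_short_window_warns(self):
        table = generate_burden_observations(
            200.0, [1, 5, 10], n_per_timepoint=1, sigma_log=0.0, seed=None
        )
        with pytest.warns(ShortFitWindowWarning):
            estimate_elimination_half_time(table)

    def test_insufficient_data_rejected(self):
        with pytest.raises(InsufficientDataError):
            estimate_elimination_half_time(
                pd.DataFrame({"day": [1, 2], "burden_ul": [1.0, 0.9]})
            )
        with pytest.raises(InsufficientDataError):
            estimate_elimination_half_time(
                pd.DataFrame({"day": [1, 2, 3], "burden_ul": [1.0, 0.0, 0.5]})
            )


class TestRegimeClassification:
    @pytest.mark.parametrize(
        "t_half, regime",
        [
            (0.8, ClearanceRegime.DISSOLUTION_DOMINATED),  # fast-dissolving oxide
            (3.0, ClearanceRegime.DISSOLUTION_DOMINATED),  # slower chelate
            (59.9, ClearanceRegime.DISSOLUTION_DOMINATED),
            (60.0, ClearanceRegime.NORMAL_AM_CLEARANCE),
            (80.0, ClearanceRegime.NORMAL_AM_CLEARANCE),
            (90.0, ClearanceRegime.NORMAL_AM_CLEARANCE),
            (120.0, ClearanceRegime.OVERLOAD_ONSET),
            (364.0, ClearanceRegime.OVERLOAD_ONSET),
            (365.0, ClearanceRegime.MTD_EXCEEDED),
            (400.0, ClearanceRegime.MTD_EXCEEDED),
        ],
    )
    def test_band_assignment(self, t_half, regime):
        assert classify_clearance_regime(t_half) is regime

    def test_nonpositive_rejected(self):
        with pytest.raises(InvalidParameterError):
            classify_clearance_regime(0.0)
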