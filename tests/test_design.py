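"""Kinetically targeted study design and PSP-status verification."""

import math

import pytest

from particokinetics import (
    BurdenTimeSeries,
    ClearanceParams,
    ParticleSpec,
    PspStatus,
    RAT,
    RetardationModel,
    ThresholdSet,
    design_study,
    reversibility_window,
    verify_psp_status,
)
from particokinetics.design import reversibility_window_from_burdens
from particokinetics.fixtures import generate_burden_observations


@pytest.fixture
def particle():
    return ParticleSpec(name="generic", rho_apparent=1.0)


@pytest.fixture
def four_week_design(particle):
    return design_study(4.0, RAT, particle, ClearanceParams())


class TestDesignStudy:
    def test_four_week_concentrations(self, four_week_design):
        c = four_week_design.concentrations
        assert c["low"] == pytest.approx(0.20, abs=5e-3)
        assert c["mid"] == pytest.approx(0.64, abs=5e-3)
        assert c["high"] == pytest.approx(2.02, abs=5e-3)

    def test_within_band_of_conventional_picks(self, four_week_design):
        # conventional rounded study concentrations for the 4-week design
        for computed, printed in zip(
            (four_week_design.concentrations[g] for g in ("low", "mid", "high")),
            (0.25, 0.75, 2.2),
        ):
            assert abs(computed - printed) / printed < 0.25

    def test_high_low_ratio_is_pool_fraction_ratio(self, four_week_design):
        c = four_week_design.concentrations
        assert c["high"] / c["low"] == pytest.approx(10.0, rel=1e-12)

    def test_end_burdens_hit_thresholds(self, four_week_design):
        b = four_week_design.predicted_end_burdens
        assert b["low"] == pytest.approx(1.0, rel=1e-12)
        assert b["high"] == pytest.approx(10.0, rel=1e-12)
        assert b["mid"] == pytest.approx(math.sqrt(10.0), rel=1e-12)

    def test_predicted_half_times_follow_retardation(self, four_week_design):
        t = four_week_design.predicted_post_t_half
        assert t["low"] == pytest.approx(80.0)
        assert t["high"] == pytest.approx(365.0)
        assert 80.0 < t["mid"] < 365.0

    def test_scale_consistency_in_per_lung_thresholds(self, particle):
        base = design_study(4.0, RAT, particle, ClearanceParams())
        scaled_thresholds = ThresholdSet(
            noael_per_kg=8.4, mtd_per_kg=84.0, noael_per_lung=2.0, mtd_per_lung=20.0,
            adaptive_per_cell=120.0, exhausted_per_cell=1200.0,
        )
        scaled = design_study(4.0, RAT, particle, ClearanceParams(), scaled_thresholds)
        for g in ("low", "mid", "high"):
            assert scaled.concentrations[g] == pytest.approx(
                2 * base.concentrations[g], rel=1e-12
            )

    def test_mass_concentrations_track_density(self):
        dense = ParticleSpec(name="dense", rho_apparent=4.0)
        design = design_study(4.0, RAT, dense, ClearanceParams())
        for g in ("low", "mid", "high"):
            assert design.mass_concentrations[g] == pytest.approx(
                4.0 * design.concentrations[g]
            )

    def test_reference_half_times_attached_for_four_weeks(self, four_week_design):
        assert four_week_design.reference_half_times == (92.0, 148.0, 292.0)


class TestReversibilityWindow:
    def test_floor_when_mid_burden_already_recovered(self):
        result = reversibility_window_from_burdens(0.8, 10.0, ClearanceParams())
        assert result.days == 90
        assert result.mid_reversible

    def test_analytic_decay_time_at_fixed_half_time(self):
        clearance = ClearanceParams(
            retardation=RetardationModel(mode="none", t_half_base=110.0)
        )
        result = reversibility_window_from_burdens(2.0, 10.0, clearance)
        assert abs(result.days - 110) <= 1

    def test_high_dose_remains_overloaded_in_default_design(self, four_week_design):
        result = reversibility_window(four_week_design, ClearanceParams())
        assert result.mid_reversible
        assert result.high_still_overloaded

    def test_window_nondecreasing_in_mid_burden(self):
        clearance = ClearanceParams()
        windows = [
            reversibility_window_from_burdens(v, 10.0, clearance).days
            for v in (1.5, 2.5, 4.0)
        ]
        assert windows == sorted(windows)


class TestVerifyPspStatus:
    def observed_series(self, t_half, days=(7, 30, 60, 90, 120)):
        table = generate_burden_observations(
            t_half, list(days), n_per_timepoint=1, sigma_log=0.0, seed=None
        )
        frame = table.rename(columns={"burden_ul": "burden_ul"}).assign(
            burden_mg=lambda df: df["burden_ul"]
        )
        return BurdenTimeSeries(frame=frame[["day", "phase", "burden_ul", "burden_mg"]])

    def test_fast_clearance_flags_dissolution(self, four_week_design):
        observed = self.observed_series(3.0, days=(1, 3, 15))
        verdict = verify_psp_status(observed, four_week_design)
        assert verdict.status is PspStatus.DISSOLUTION_INFLUENCED

    def test_normal_band_agreement_is_typical_psp(self, four_week_design):
        observed = self.observed_series(80.0)
        verdict = verify_psp_status(observed, four_week_design, dose_group="low")
        assert verdict.status is PspStatus.TYPICAL_PSP
        assert verdict.observed_t_half == pytest.approx(80.0, rel=1e-9)

    def test_retarded_clearance_within_tolerance_confirms_overload(self, four_week_design):
        # observed 150 d against the mid-group prediction (~171 d): within 30%
        observed = self.observed_series(150.0)
        verdict = verify_psp_status(observed, four_week_design, dose_group="mid")
        assert verdict.status is PspStatus.OVERLOAD_CONFIRMED

    def test_disagreement_is_inconsistent(self, four_week_design):
        observed = self.observed_series(100.0)
        verdict = verify_psp_status(observed, four_week_design, dose_group="high")
        assert verdict.status is PspStatus.INCONSISTENT_WITH_PREDICTION

    def test_unit_invariance_of_verdict(self, four_week_design):
        observed = self.observed_series(150.0)
        scaled = BurdenTimeSeries(
            frame=observed.frame.assign(
                burden_ul=observed.frame["burden_ul"] * 3.7,
                burden_mg=observed.frame["burden_mg"] * 3.7,
            )
        )
        v1 = verify_psp_status(observed, four_week_design, dose_group="mid")
        v2 = verify_psp_status(scaled, four_week_design, dose_group="mid")
        assert v1.status is v2.status
        assert v1.observed_t_half == pytest.approx(v2.observed_t_half)
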