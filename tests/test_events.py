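"""Two-cycle event projection and bed-day intensity calibration."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from stentbim import (
    calibrate_day_intensities,
    default_imperial_config,
    project_events,
    split_tlr_by_procedure,
)
from stentbim.events import mean_stay_per_patient, trial_stay_reduction
from stentbim.population import CohortSchedule
from stentbim.reporting import round_half_up

COHORTS = CohortSchedule(N=[5674.0, 6060.0, 6474.0, 6915.0, 7386.0, 7890.0])


@pytest.fixture(scope="module")
def config():
    return default_imperial_config()


class TestProjection:
    # Published per-year CD-TLR counts, both arms, and the unrounded-sum totals.
    @pytest.mark.parametrize(
        "arm_key, cells, total",
        [
            ("arm_a", [509, 1684, 1798, 1921, 2052, 2192], 10_156),
            ("arm_b", [257, 995, 1063, 1135, 1213, 1295], 5_959),
        ],
    )
    def test_reproduces_published_tlr_rows(self, config, arm_key, cells, total):
        proj = project_events(COHORTS, getattr(config, arm_key))
        assert round_half_up(proj.tlr_total).tolist() == cells
        assert round_half_up(proj.tlr_total.sum()) == total

    def test_first_year_has_no_second_cycle(self, config):
        proj = project_events(COHORTS, config.arm_a)
        assert proj.tlr_second_cycle[0] == 0.0
        assert proj.tlr_first_cycle[0] == pytest.approx(5674 * 13 / 145)

    def test_second_year_mixes_both_cycles(self, config):
        """Year 1 = new cohort at 12-month rate + prior cohort at 24-month rate."""
        proj = project_events(COHORTS, config.arm_a)
        assert proj.tlr_total[1] == pytest.approx(5674 * 0.201 + 6060 * 13 / 145)

    def test_zero_rates_give_zero_projection(self, config):
        arm = config.arm_a.model_copy(
            update={"r12": 0.0, "r24": 0.0, "a12": 0.0, "a24": 0.0, "h12": 0.0, "h24": 0.0}
        )
        proj = project_events(COHORTS, arm)
        assert np.all(proj.tlr_total == 0)
        assert np.all(proj.amputations_total == 0)
        assert np.all(proj.hospital_days == 0)

    def test_incremental_mode_never_exceeds_cumulative(self, config):
        """The second-cycle terms differ by N_{t-1}*r12, so incremental totals
        are below cumulative-recount totals exactly when r12 > 0."""
        cum = project_events(COHORTS, config.arm_a, "cumulative_recount")
        inc = project_events(COHORTS, config.arm_a, "incremental")
        assert np.all(inc.tlr_total <= cum.tlr_total + 1e-12)
        assert inc.tlr_total.sum() < cum.tlr_total.sum()
        no_first_cycle = config.arm_a.model_copy(update={"r12": 0.0})
        assert np.allclose(
            project_events(COHORTS, no_first_cycle, "incremental").tlr_total,
            project_events(COHORTS, no_first_cycle, "cumulative_recount").tlr_total,
        )

    @given(st.floats(0.0, 10.0))
    def test_homogeneous_of_degree_one_in_cohorts(self, factor):
        config = default_imperial_config()
        base = project_events(COHORTS, config.arm_a)
        scaled = project_events(
            CohortSchedule(N=COHORTS.N * factor), config.arm_a
        )
        assert np.allclose(scaled.tlr_total, base.tlr_total * factor, rtol=1e-12)
        assert np.allclose(scaled.hospital_days, base.hospital_days * factor, rtol=1e-12)

    def test_unknown_mode_rejected(self, config):
        with pytest.raises(ValueError, match="mode"):
            project_events(COHORTS, config.arm_a, "annual")


class TestProcedureSplit:
    def test_first_year_split_uses_twelve_month_mix(self, config):
        proj = project_events(COHORTS, config.arm_a)
        perc, open_ = split_tlr_by_procedure(
            proj.tlr_first_cycle, proj.tlr_second_cycle, config.arm_a
        )
        year0_tlr = 5674 * 13 / 145
        assert perc[0] == pytest.approx(year0_tlr * 0.96, abs=1e-9)
        assert open_[0] == pytest.approx(year0_tlr * 0.04, abs=1e-9)

    def test_pure_percutaneous_mix(self, config):
        arm = config.arm_a.model_copy(
            update={"m12_perc": 1.0, "m12_open": 0.0, "m24_perc": 1.0, "m24_open": 0.0}
        )
        perc, open_ = split_tlr_by_procedure(np.array([10.0]), np.array([5.0]), arm)
        assert perc[0] == 15.0 and open_[0] == 0.0

    @given(
        st.lists(st.floats(0, 1e4), min_size=1, max_size=8),
        st.lists(st.floats(0, 1e4), min_size=1, max_size=8),
    )
    def test_split_conserves_total(self, first, second):
        n = min(len(first), len(second))
        arm = default_imperial_config().arm_b
        f, s = np.array(first[:n]), np.array(second[:n])
        perc, open_ = split_tlr_by_procedure(f, s, arm)
        assert np.allclose(perc + open_, f + s, rtol=1e-12)


class TestCalibration:
    # Day totals implied by the published first-two-year hospital costs / 2003.
    @pytest.mark.parametrize(
        "costs, expected",
        [
            ((14_184_422, 46_724_823), (1.248077, 2.778300)),
            ((6_134_905, 31_964_449), (0.539806, 2.236000)),
        ],
    )
    def test_back_solved_intensities(self, costs, expected):
        d0, d1 = costs[0] / 2003, costs[1] / 2003
        h12, h24 = calibrate_day_intensities(5674, 6060, d0, d1)
        assert h12 == pytest.approx(expected[0], abs=5e-6)
        assert h24 == pytest.approx(expected[1], abs=5e-6)
        # exact inversion of the projection's day formula
        assert 5674 * h12 == pytest.approx(d0, abs=1e-9)
        assert 6060 * h12 + 5674 * h24 == pytest.approx(d1, abs=1e-9)

    # Published later-year day cells predicted by the calibrated intensities.
    @pytest.mark.parametrize(
        "arm_key, cells",
        [
            ("arm_a", [7082, 23_327, 24_917, 26_617, 28_430, 30_368]),
            ("arm_b", [3063, 15_958, 17_045, 18_209, 19_449, 20_774]),
        ],
    )
    def test_predicts_remaining_day_cells_to_nearest_day(self, config, arm_key, cells):
        proj = project_events(COHORTS, getattr(config, arm_key))
        assert round_half_up(proj.hospital_days).tolist() == cells

    def test_consistent_inputs_give_zero_h24(self):
        h12, h24 = calibrate_day_intensities(100, 120, 50.0, 120 * 0.5)
        assert h24 == 0.0

    def test_zero_cohort_rejected(self):
        with pytest.raises(ValueError):
            calibrate_day_intensities(0, 100, 10, 10)

    def test_inconsistent_inputs_warn(self):
        with pytest.warns(UserWarning, match="h24"):
            calibrate_day_intensities(100, 1000, 50.0, 10.0)


class TestStaySummary:
    def test_mean_stay_per_patient(self):
        assert mean_stay_per_patient(17.7, 60, 156) == pytest.approx(6.8, abs=0.01)
        assert mean_stay_per_patient(13.9, 123, 309) == pytest.approx(5.5, abs=0.04)

    def test_twelve_month_stay_reduction_is_about_nineteen_percent(self):
        assert trial_stay_reduction("12m") == pytest.approx(0.19, abs=0.01)
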