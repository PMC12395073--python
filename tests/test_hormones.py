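"""Closed-form hormone equations: point values, far fields, brute force."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cyclesim import EUM, PCOS
from cyclesim.cohort import CycleParams, SubjectProfile, sample_cycle_params, sample_subject
from cyclesim.hormones import (
    PulseTrainParams,
    amh,
    e2_eum,
    fsh_eum,
    gnrh_eum,
    gnrh_pulse_train_daily_area,
    lh_eum,
    pcos_levels,
    rescale_time,
    sample_pulse_train,
    true_panel,
)
from cyclesim.hormones import testosterone as t_sinusoid


def make_eum(**kw):
    base = dict(
        subject_id="S0001", phenotype=EUM, age=30.0, bmi=24.0, amh_trait=2.9,
        t_baseline=0.4, t_amplitude=0.04, t_phase=0.0,
        e2_baseline=20.0, e2_peak1=260.0, e2_peak2=125.0,
        lh_baseline=7.0, lh_peak=53.0, fsh_baseline=7.8, gnrh_baseline=1.0,
        sigma1=1.1, sigma2=2.0, sigma_lh=0.75, sigma_early=1.5,
        sigma_periov=0.8, sigma_gnrh=1.0, alpha_early=1.5, alpha_periov=1.2,
        a_periov_gnrh=0.22, beta_e2=0.01, theta_e2=100.0, t_early=2.0,
    )
    base.update(kw)
    return SubjectProfile(**base)


def make_pcos(**kw):
    base = dict(
        subject_id="S0002", phenotype=PCOS, age=30.0, bmi=28.0, amh_trait=5.7,
        t_baseline=1.25, t_amplitude=0.04, t_phase=0.5,
        e1_level=115.0, e2_level=33.0, lh_level=18.0, fsh_level=5.2,
        gnrh_level=1.37,
    )
    base.update(kw)
    return SubjectProfile(**base)


CYCLE = CycleParams(cycle_index=1, length=28.0, lh_surge_day=14.0,
                    delta=1.5, mu1=12.5, delta_luteal=6.5, mu2=19.0)


class TestRescaleTime:
    def test_endpoints(self):
        assert rescale_time(1, 35.0) == 1.0
        assert rescale_time(28, 35.0) == 35.0

    def test_midgrid_day(self):
        # 1 + 13/27 * 27 = 14 for the reference 28-day cycle
        assert rescale_time(14, 28.0) == pytest.approx(14.0)

    def test_out_of_grid_rejected(self):
        with pytest.raises(ValueError):
            rescale_time(0, 28.0)
        with pytest.raises(ValueError):
            rescale_time(29, 28.0)

    @settings(derandomize=True, max_examples=50)
    @given(L=st.floats(24, 60), g=st.integers(2, 100))
    def test_monotone_and_spans_cycle(self, L, g):
        t = rescale_time(np.arange(1, g + 1), L, g)
        assert t[0] == 1.0
        assert t[-1] == pytest.approx(L)
        assert np.all(np.diff(t) > 0) or L == 1.0


class TestEumClosedForms:
    def test_e2_at_first_center_is_peak1(self):
        # second bump is >3 sigma away: contributes < 1 pg/mL
        assert e2_eum(CYCLE.mu1, make_eum(), CYCLE) == pytest.approx(260.0, abs=1.0)

    def test_e2_far_field_is_baseline(self):
        assert e2_eum(CYCLE.mu2 + 5 * 2.0, make_eum(), CYCLE) == pytest.approx(20.0, abs=0.1)

    def test_e2_luteal_point_value(self):
        # 125 + 240*exp(-6.5^2/(2*1.21)) = 125.0 to within 1e-4
        assert e2_eum(19.0, make_eum(), CYCLE) == pytest.approx(125.0, abs=1e-4)

    def test_lh_peak_exact_at_surge(self):
        assert lh_eum(14.0, make_eum(), CYCLE) == pytest.approx(53.0)

    def test_lh_one_sigma_from_surge(self):
        # 7 + 46*e^{-1/2} = 34.90
        assert lh_eum(14.75, make_eum(), CYCLE) == pytest.approx(7 + 46 * math.exp(-0.5))

    def test_lh_far_field_is_baseline(self):
        assert lh_eum(14.0 + 5 * 0.75, make_eum(), CYCLE) == pytest.approx(7.0, abs=0.01)

    def test_fsh_no_suppression_at_or_below_threshold(self):
        s = make_eum()
        far = 26.0  # away from both bumps
        assert fsh_eum(far, s, CYCLE, 100.0) == fsh_eum(far, s, CYCLE, 50.0)

    def test_fsh_early_bump_peak(self):
        s = make_eum(alpha_periov=0.0)
        assert fsh_eum(2.0, s, CYCLE, 50.0) == pytest.approx(7.8 + 1.5)

    def test_fsh_periovulatory_with_suppression(self):
        # 7.8 + 1.2 - 0.01*(260-100) = 7.4 at t = surge - 1
        s = make_eum(alpha_early=0.0)
        assert fsh_eum(13.0, s, CYCLE, 260.0) == pytest.approx(7.4)

    def test_fsh_suppression_only_lowers(self):
        s = make_eum()
        t = np.linspace(1, 28, 200)
        e2 = e2_eum(t, s, CYCLE)
        with_fb = fsh_eum(t, s, CYCLE, e2)
        without = fsh_eum(t, make_eum(beta_e2=0.0), CYCLE, e2)
        assert np.all(with_fb <= without + 1e-12)

    def test_fsh_floored_at_zero(self):
        s = make_eum(beta_e2=10.0)
        assert fsh_eum(13.0, s, CYCLE, 500.0) == 0.0

    def test_gnrh_bump_and_far_field(self):
        s = make_eum()
        assert gnrh_eum(13.0, s, CYCLE) == pytest.approx(1.22)
        assert gnrh_eum(27.0, s, CYCLE) == pytest.approx(1.0, abs=1e-4)
        # peri-ovulatory relative rise is 22% of baseline
        rise = (gnrh_eum(13.0, s, CYCLE) - s.gnrh_baseline) / s.gnrh_baseline
        assert rise == pytest.approx(0.22)

    def test_testosterone_quarter_cycle(self):
        assert t_sinusoid(28.0 / 4, make_eum(), CYCLE) == pytest.approx(0.44)

    def test_testosterone_zero_amplitude_constant(self):
        s = make_eum(t_amplitude=0.0)
        t = np.linspace(1, 28, 50)
        assert np.allclose(t_sinusoid(t, s, CYCLE), 0.4)

    def test_testosterone_cycle_mean_is_baseline(self):
        t = np.linspace(0, 28, 100_001)[:-1]  # one full period
        assert t_sinusoid(t, make_eum(), CYCLE).mean() == pytest.approx(0.4, abs=1e-6)


class TestAmhAndPcos:
    def test_amh_constant_across_cycles(self, rng):
        s = sample_subject(EUM, "S1", rng)
        assert amh(s) == s.amh_trait
        c1 = sample_cycle_params(s, 1, rng)
        c2 = sample_cycle_params(s, 2, rng)
        assert true_panel(5.0, s, c1)["AMH"] == true_panel(20.0, s, c2)["AMH"]

    def test_pcos_panel_flat_in_time(self):
        s = make_pcos()
        c = CycleParams(cycle_index=1, length=40.0)
        p1, p2 = pcos_levels(3.0, s, c), pcos_levels(33.0, s, c)
        assert p1 == p2
        assert p1["LH"] < 30.0
        assert p1["GnRH"] > 1.3

    def test_pcos_levels_reject_eum_subject(self):
        with pytest.raises(ValueError, match="PCOS"):
            pcos_levels(3.0, make_eum(), CYCLE)

    def test_pcos_truth_constant_except_testosterone(self):
        s = make_pcos()
        c = CycleParams(cycle_index=1, length=40.0)
        t = np.linspace(1, 40, 40)
        panel = true_panel(t, s, c)
        for h in ("E1", "E2", "LH", "FSH", "GnRH", "AMH"):
            assert np.ptp(panel[h]) == 0.0, h
        assert np.ptp(panel["T"]) > 0.0


def test_closed_forms_match_straight_line_reimplementation():
    """1,000 random parameter draws: vectorized equations agree with a
    scalar math.exp re-evaluation to float tolerance."""
    rng = np.random.default_rng(2024)
    for _ in range(1000):
        s = sample_subject(EUM, "S1", rng)
        c = sample_cycle_params(s, 1, rng)
        t = float(rng.uniform(1, c.length))
        e2_ref = (s.e2_baseline
                  + (s.e2_peak1 - s.e2_baseline) * math.exp(-(t - c.mu1) ** 2 / (2 * s.sigma1 ** 2))
                  + (s.e2_peak2 - s.e2_baseline) * math.exp(-(t - c.mu2) ** 2 / (2 * s.sigma2 ** 2)))
        lh_ref = (s.lh_baseline + (s.lh_peak - s.lh_baseline)
                  * math.exp(-(t - c.lh_surge_day) ** 2 / (2 * s.sigma_lh ** 2)))
        fsh_ref = max(
            s.fsh_baseline
            + s.alpha_early * math.exp(-(t - s.t_early) ** 2 / (2 * s.sigma_early ** 2))
            + s.alpha_periov * math.exp(-(t - (c.lh_surge_day - 1)) ** 2 / (2 * s.sigma_periov ** 2))
            - s.beta_e2 * max(e2_ref - s.theta_e2, 0.0), 0.0)
        gnrh_ref = (s.gnrh_baseline + s.a_periov_gnrh
                    * math.exp(-(t - (c.lh_surge_day - 1)) ** 2 / (2 * s.sigma_gnrh ** 2)))
        t_ref = s.t_baseline + s.t_amplitude * math.sin(2 * math.pi * t / c.length + s.t_phase)
        assert e2_eum(t, s, c) == pytest.approx(e2_ref, rel=1e-12)
        assert lh_eum(t, s, c) == pytest.approx(lh_ref, rel=1e-12)
        assert fsh_eum(t, s, c, e2_ref) == pytest.approx(fsh_ref, rel=1e-12)
        assert gnrh_eum(t, s, c) == pytest.approx(gnrh_ref, rel=1e-12)
        assert t_sinusoid(t, s, c) == pytest.approx(t_ref, rel=1e-12)


def test_grid_maximum_attenuated_when_surge_off_grid():
    """The on-grid LH max equals the peak only when the surge center falls
    exactly on a grid point; otherwise it is strictly smaller."""
    s = make_eum()
    on = CycleParams(cycle_index=1, length=28.0, lh_surge_day=14.0,
                     delta=1.5, mu1=12.5, delta_luteal=6.5, mu2=19.0)
    off = CycleParams(cycle_index=1, length=28.0, lh_surge_day=14.4,
                      delta=1.5, mu1=12.9, delta_luteal=6.5, mu2=19.4)
    t = rescale_time(np.arange(1, 29), 28.0)
    assert lh_eum(t, s, on).max() == pytest.approx(53.0)
    assert lh_eum(t, s, off).max() < 53.0


class TestPulseTrain:
    def test_empty_train_has_zero_area(self):
        assert gnrh_pulse_train_daily_area(PulseTrainParams()) == 0.0

    def test_fixed_60min_interpulse_gives_24_pulses(self):
        rng = np.random.default_rng(0)
        params = sample_pulse_train(rng, interpulse_low=60.0, interpulse_high=60.0)
        assert len(params.pulse_times) == 24
        gaps = np.diff(params.pulse_times)
        assert np.allclose(gaps, 60.0)

    def test_interpulse_intervals_within_range(self, rng):
        params = sample_pulse_train(rng)
        gaps = np.diff(params.pulse_times)
        assert np.all((gaps >= 60.0) & (gaps <= 90.0))

    def test_single_pulse_area_matches_gaussian_integral(self):
        params = PulseTrainParams(pulse_amplitudes=[6.0], pulse_times=[720.0],
                                  pulse_width=5.0)
        expected = 6.0 * 5.0 * math.sqrt(2 * math.pi) / 1440.0
        assert gnrh_pulse_train_daily_area(params) == pytest.approx(expected, rel=1e-4)

    def test_default_train_area_near_one_au(self):
        rng = np.random.default_rng(3)
        areas = [gnrh_pulse_train_daily_area(sample_pulse_train(rng))
                 for _ in range(20)]
        assert np.mean(areas) == pytest.approx(1.0, abs=0.1)
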