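"""Tests for the compartmental model, optical forward model, adaptive
acquisition and scenario presets."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fluorogut.errors import NoPeakError, ScenarioError
from fluorogut.spectra import FLUORESCEIN, normalized_intensity
from fluorogut.synthetic import (
    ARM,
    FINGERTIP,
    WRIST,
    OpticalParams,
    PKParams,
    PKState,
    Route,
    SitePreset,
    adaptive_acquire,
    make_scenario,
    render_spectrum,
    simulate_pk,
    skin_signal,
)
from fluorogut.timecourse import (
    assemble_timecourse,
    auc_to_peak,
    baseline_subtract,
    detect_peak,
)


def bateman_blood(t, dose, f_perm, k_abs, k_el):
    """Two-exponential closed form: dose starts in the gut, no skin leak."""
    return (
        dose * f_perm * k_abs / (k_el - k_abs)
        * (np.exp(-k_abs * t) - np.exp(-k_el * t))
    )


def chain_blood(t, dose, f_perm, k_ge, k_abs, k_el):
    """Three-exponential closed form for stomach -> gut -> blood, no leak."""
    out = np.zeros_like(t, dtype=float)
    rates = (k_ge, k_abs, k_el)
    for i, ki in enumerate(rates):
        denom = np.prod([kj - ki for j, kj in enumerate(rates) if j != i])
        out += np.exp(-ki * t) / denom
    return dose * f_perm * k_ge * k_abs * out


class TestSimulatePK:
    def test_zero_dose_all_zero(self):
        states = simulate_pk(PKParams(dose=0.0), np.arange(0.0, 1000.0, 100.0))
        assert all(s.total == 0.0 for s in states)

    def test_mass_conservation(self):
        p = PKParams(dose=500.0)
        states = simulate_pk(p, np.arange(0.0, 14401.0, 60.0))
        for s in states:
            assert s.total == pytest.approx(p.dose, rel=1e-8)
            for field in ("stomach", "gut", "blood", "dermis", "epidermis",
                          "eliminated"):
                assert getattr(s, field) >= -1e-9 * p.dose

    def test_bateman_limit_instant_emptying(self):
        """With the dose placed directly in the gut and no skin leak, blood
        follows the two-exponential absorption/elimination closed form."""
        p = PKParams(dose=1.0, f_perm=0.6, k_abs=1 / 400.0, k_el=1 / 3600.0,
                     k_leak=0.0)
        t = np.arange(60.0, 10801.0, 60.0)
        start = PKState(stomach=0.0, gut=1.0, blood=0.0, dermis=0.0,
                        epidermis=0.0, eliminated=0.0)
        states = simulate_pk(p, t, initial_state=start)
        blood = np.array([s.blood for s in states])
        expected = bateman_blood(t, 1.0, 0.6, p.k_abs, p.k_el)
        np.testing.assert_allclose(blood, expected, rtol=1e-6)

    def test_full_chain_closed_form(self):
        p = PKParams(dose=2.0, f_perm=0.4, k_leak=0.0)
        t = np.arange(60.0, 10801.0, 60.0)
        blood = np.array([s.blood for s in simulate_pk(p, t)])
        expected = chain_blood(t, 2.0, 0.4, p.k_ge, p.k_abs, p.k_el)
        np.testing.assert_allclose(blood, expected, rtol=1e-9)

    def test_iv_route_starts_in_blood_and_decays(self):
        p = PKParams(dose=500.0, route=Route.IV)
        t = np.array([0.0, 60.0, 600.0, 3600.0])
        states = simulate_pk(p, t)
        assert states[0].blood == pytest.approx(500.0)
        assert states[0].stomach == 0.0
        blood = [s.blood for s in states]
        assert all(b2 < b1 for b1, b2 in zip(blood, blood[1:]))

    def test_icg_clearance_rate_20_percent_per_minute(self):
        # k_el = 0.0033/s: blood falls by ~18-25% over each minute IV
        p = PKParams(dose=1.0, k_el=0.0033, k_leak=0.0, route=Route.IV)
        states = simulate_pk(p, np.array([60.0, 120.0]))
        drop = 1.0 - states[0].blood
        assert 0.15 < drop < 0.25

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError, match="k_el"):
            PKParams(k_el=-1e-3)

    def test_f_perm_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="f_perm"):
            PKParams(f_perm=1.5)


class TestMonotoneResponses:
    """Parameter-recovery orderings mirrored from the clinical contrasts."""

    def test_time_to_peak_decreases_with_gastric_emptying_rate(self):
        t = np.arange(0.0, 14401.0, 30.0)
        peaks = []
        for k_ge in (1 / 2400.0, 1 / 1200.0, 1 / 600.0, 1 / 300.0):
            blood = np.array(
                [s.blood for s in simulate_pk(PKParams(k_ge=k_ge), t)])
            peaks.append(t[np.argmax(blood)])
        assert all(b > a for a, b in zip(peaks[1:], peaks[:-1]))

    def test_auc_to_peak_increases_with_permeability(self):
        t = np.arange(0.0, 14401.0, 60.0)
        aucs = []
        from fluorogut.timecourse import TimeCourse

        for f in (0.2, 0.4, 0.6, 0.8):
            sig = skin_signal(simulate_pk(PKParams(f_perm=f), t), FINGERTIP)
            course = TimeCourse(t, sig, 0.0)
            pk = detect_peak(course, smooth_window_s=300.0)
            aucs.append(auc_to_peak(course, pk).auc)
        assert all(b > a for a, b in zip(aucs, aucs[1:]))


class TestSkinSignal:
    def test_blood_only_site_proportional_to_blood(self):
        t = np.arange(0.0, 7200.0, 60.0)
        states = simulate_pk(PKParams(), t)
        site = SitePreset("bloodonly", w_blood=2.0, w_epidermis=0.0)
        sig = skin_signal(states, site)
        blood = np.array([s.blood for s in states])
        np.testing.assert_allclose(sig, 2.0 * blood)

    def test_arm_peaks_later_than_blood(self):
        t = np.arange(0.0, 14401.0, 60.0)
        states = simulate_pk(PKParams(), t)
        sig = skin_signal(states, ARM)
        blood = np.array([s.blood for s in states])
        assert t[np.argmax(sig)] > t[np.argmax(blood)]

    def test_zero_states_zero_signal(self):
        states = [PKState(0, 0, 0, 0, 0, 0)] * 5
        assert np.all(skin_signal(states, ARM) == 0.0)

    def test_fingertip_more_blood_weighted_than_arm_and_wrist(self):
        f = FINGERTIP.w_blood / FINGERTIP.w_epidermis
        assert f > ARM.w_blood / ARM.w_epidermis
        assert f > WRIST.w_blood / WRIST.w_epidermis

    def test_both_zero_weights_rejected(self):
        with pytest.raises(ValueError):
            SitePreset("bad", 0.0, 0.0)


class TestRenderSpectrum:
    def test_zero_signal_flat_background_gives_zero_intensity(self):
        optics = OpticalParams(autofluor_amplitude=0.0, shot_noise=False,
                               read_noise_sd=0.0)
        rec = render_spectrum(0.0, FLUORESCEIN, optics, 1.0)
        assert normalized_intensity(rec, FLUORESCEIN) == pytest.approx(0.0, abs=1e-12)

    def test_laser_power_factor_cancels(self):
        optics = OpticalParams(shot_noise=False, read_noise_sd=0.0)
        r1 = render_spectrum(5.0, FLUORESCEIN, optics, 1.0, laser_power_factor=1.0)
        r2 = render_spectrum(5.0, FLUORESCEIN, optics, 1.0, laser_power_factor=2.0)
        assert normalized_intensity(r1, FLUORESCEIN) == pytest.approx(
            normalized_intensity(r2, FLUORESCEIN), rel=1e-12)

    def test_integration_time_cancels(self):
        optics = OpticalParams(shot_noise=False, read_noise_sd=0.0)
        r1 = render_spectrum(5.0, FLUORESCEIN, optics, 1.0)
        r2 = render_spectrum(5.0, FLUORESCEIN, optics, 2.0)
        np.testing.assert_allclose(2.0 * r1.fluorescence.intensities,
                                   r2.fluorescence.intensities)
        assert normalized_intensity(r1, FLUORESCEIN) == pytest.approx(
            normalized_intensity(r2, FLUORESCEIN), rel=1e-12)

    def test_intensity_linear_in_signal(self):
        # flat background: the autofluorescence residual adds a constant
        # offset, so strict linearity holds for the dye term alone
        optics = OpticalParams(shot_noise=False, read_noise_sd=0.0,
                               autofluor_amplitude=0.0)
        i1 = normalized_intensity(
            render_spectrum(1.0, FLUORESCEIN, optics, 1.0), FLUORESCEIN)
        i3 = normalized_intensity(
            render_spectrum(3.0, FLUORESCEIN, optics, 1.0), FLUORESCEIN)
        assert i3 == pytest.approx(3.0 * i1, rel=1e-9)

    def test_fixed_seed_bit_identical(self):
        optics = OpticalParams()
        a = render_spectrum(5.0, FLUORESCEIN, optics, 1.0,
                            rng=np.random.default_rng(42))
        b = render_spectrum(5.0, FLUORESCEIN, optics, 1.0,
                            rng=np.random.default_rng(42))
        assert np.array_equal(a.fluorescence.intensities,
                              b.fluorescence.intensities)
        assert np.array_equal(a.laser.intensities, b.laser.intensities)

    def test_negative_signal_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            render_spectrum(-1.0, FLUORESCEIN, OpticalParams(), 1.0)


class TestAdaptiveAcquire:
    def test_flux_at_threshold_single_frame(self):
        out = adaptive_acquire(1000.0, 1000.0)
        assert out.integration_time_s == 0.5
        assert out.reached_threshold

    def test_quarter_flux_four_frames(self):
        out = adaptive_acquire(250.0, 1000.0)
        assert out.integration_time_s == pytest.approx(2.0)
        assert out.counts == pytest.approx(1000.0)
        assert out.reached_threshold

    def test_zero_flux_hits_cap_with_flag(self):
        out = adaptive_acquire(0.0, 1000.0, max_frames=10)
        assert out.integration_time_s == pytest.approx(5.0)
        assert not out.reached_threshold

    def test_nonpositive_threshold_rejected(self):
        with pytest.raises(ValueError, match="threshold"):
            adaptive_acquire(100.0, 0.0)

    @given(frac=st.integers(min_value=1, max_value=15))
    @settings(derandomize=True, max_examples=15, deadline=None)
    def test_frame_count_matches_counting_oracle(self, frac):
        threshold = 1200.0
        flux = threshold / frac
        # oracle: smallest n with n*flux >= threshold under float arithmetic
        expected_n = next(n for n in range(1, 21)
                          if sum([flux] * n) >= threshold)
        out = adaptive_acquire(flux, threshold, max_frames=20)
        assert out.integration_time_s == pytest.approx(0.5 * expected_n)


class TestScenarios:
    def test_unknown_scenario_rejected(self):
        with pytest.raises(ScenarioError, match="unknown scenario"):
            make_scenario("nope", seed=0)

    def test_same_seed_identical_sessions(self):
        a = make_scenario("fluorescein_water", seed=5, duration_s=1800.0)
        b = make_scenario("fluorescein_water", seed=5, duration_s=1800.0)
        for ra, rb in zip(a.records, b.records):
            assert np.array_equal(ra.fluorescence.intensities,
                                  rb.fluorescence.intensities)

    def test_water_peak_within_factor_two_of_reported(self):
        s = make_scenario("fluorescein_water", seed=1)
        tc = baseline_subtract(
            assemble_timecourse(s.records, s.dye, s.t_ingest_s))
        pk = detect_peak(tc)
        assert 1100.0 <= pk.time_to_peak_s <= 4400.0

    def test_milkshake_peak_later_than_water(self):
        peaks = {}
        for name in ("fluorescein_water", "fluorescein_milkshake"):
            s = make_scenario(name, seed=2, noise=False)
            tc = baseline_subtract(
                assemble_timecourse(s.records, s.dye, s.t_ingest_s))
            peaks[name] = detect_peak(tc).time_to_peak_s
        assert peaks["fluorescein_milkshake"] > peaks["fluorescein_water"]

    def test_icg_session_has_no_detectable_peak(self):
        s = make_scenario("icg_oral", seed=3)
        tc = baseline_subtract(
            assemble_timecourse(s.records, s.dye, s.t_ingest_s))
        with pytest.raises(NoPeakError):
            detect_peak(tc)

    def test_icg_blood_peak_below_one_percent_of_fluorescein(self):
        icg = make_scenario("icg_oral", seed=0, noise=False)
        water = make_scenario("fluorescein_water", seed=0, noise=False)
        icg_peak = max(s.blood for s in icg.states)
        water_peak = max(s.blood for s in water.states)
        assert icg_peak < 0.01 * water_peak

    def test_fitc_dextran_low_dose_subnoise_but_eliminated(self):
        s = make_scenario("fitc_dextran_lowdose", seed=4, noise=False)
        peak_emission_rate = (
            s.optics.counts_per_unit_concentration * float(np.max(s.signal)))
        assert peak_emission_rate < s.optics.read_noise_sd
        assert s.states[-1].eliminated > 0.0

    def test_end_to_end_noiseless_curve_matches_generator_signal(self):
        """Pipeline output correlates > 0.999 with the ground-truth signal."""
        s = make_scenario("fluorescein_water", seed=1, noise=False)
        tc = assemble_timecourse(s.records, s.dye, s.t_ingest_s)
        r = np.corrcoef(tc.intensities, s.signal)[0, 1]
        assert r > 0.999

    def test_adaptive_integration_times_vary_with_signal(self):
        s = make_scenario("fluorescein_water", seed=1, noise=False)
        t_ints = np.array(
            [r.fluorescence.integration_time_s for r in s.records])
        assert t_ints.min() < t_ints.max()  # brighter records acquire faster
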