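"""Indentation analysis: contact, segmentation, fits, moduli, permeability."""

import dataclasses
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import curve_fit

from cartiq import (
    ForceCurve,
    IndenterGeometry,
    SimulationConfig,
    analyze_curve,
    apparent_modulus,
    contact_area,
    detect_contact,
    fit_loading,
    fit_relaxation,
    permeability,
    simulate_indentation_curve,
    split_phases,
)
from cartiq.mechanics import ContactError, SegmentationError

from test_synthetic import make_site


def ramp_hold_curve(n_ramp=50, n_hold=100, peak=1.0):
    t = np.arange(n_ramp + n_hold) * 0.1
    f = np.concatenate([np.linspace(0, peak, n_ramp), np.full(n_hold, peak * 0.5)])
    f[n_ramp - 1] = peak
    return ForceCurve(t, np.zeros_like(t), f)


class TestDetectContact:
    def test_threshold_crossing_index(self):
        f = np.linspace(0, 0.2, 41)  # crosses 0.1 N at sample 20
        curve = ForceCurve(np.arange(41) * 0.1, np.zeros(41), f)
        assert detect_contact(curve, 0.1) == 20

    def test_already_in_contact(self):
        curve = ForceCurve([0, 1, 2, 3, 4], np.zeros(5), [0.2, 0.3, 0.4, 0.5, 0.6])
        assert detect_contact(curve, 0.1) == 0

    def test_denuded_site_raises(self):
        curve = ForceCurve(np.arange(10.0) + 1, np.zeros(10), np.zeros(10))
        with pytest.raises(ContactError):
            detect_contact(curve, 0.1)


class TestSplitPhases:
    def test_noiseless_curve_splits_at_ramp_end(self, geometry, noiseless_config):
        site = make_site()
        curve = simulate_indentation_curve(site, geometry, noiseless_config)
        loading, relaxation = split_phases(curve, geometry)
        assert relaxation.time_s[0] == 0.0
        assert relaxation.force_N[0] == pytest.approx(site.peak_force_N, abs=1e-12)
        assert loading.force_N[-1] == relaxation.force_N[0]

    def test_noisy_peak_within_two_samples_of_ramp_end(self, geometry):
        cfg = SimulationConfig(seed=11)  # default 1%-scale force noise
        site = make_site()
        for site_id in range(1, 21):
            s = dataclasses.replace(site, site_id=site_id)
            curve = simulate_indentation_curve(s, geometry, cfg)
            _, relaxation = split_phases(curve, geometry)
            n_hold_expected = int(geometry.hold_s * cfg.sampling_rate_hz) + 1
            assert abs(len(relaxation) - n_hold_expected) <= 2

    def test_monotonically_rising_curve_has_no_relaxation(self, geometry):
        t = np.arange(50) * 0.1
        curve = ForceCurve(t, np.zeros_like(t), np.linspace(0, 1, 50))
        with pytest.raises(SegmentationError):
            split_phases(curve, geometry)


class TestFitLoading:
    def test_exact_line(self):
        t = np.arange(20) * 0.1
        seg = ForceCurve(t, np.zeros_like(t), 2 * t)
        fit = fit_loading(seg)
        assert fit.slope_N_s == pytest.approx(2.0, abs=1e-12)
        np.testing.assert_allclose(fit.residuals_N, 0, atol=1e-12)

    def test_constant_force_has_zero_slope(self):
        t = np.arange(10) * 0.1
        fit = fit_loading(ForceCurve(t, np.zeros_like(t), np.full(10, 0.5)))
        assert fit.slope_N_s == pytest.approx(0.0, abs=1e-12)

    def test_noisy_slope_within_three_standard_errors(self):
        rng = np.random.default_rng(42)
        t = np.arange(100) * 0.01
        f = 2.0 * t + rng.normal(0, 0.01, t.size)
        fit = fit_loading(ForceCurve(t, np.zeros_like(t), f))
        # closed-form OLS standard error of the slope
        resid_var = np.sum(fit.residuals_N**2) / (t.size - 2)
        se = math.sqrt(resid_var / np.sum((t - t.mean()) ** 2))
        assert abs(fit.slope_N_s - 2.0) < 3 * se

    def test_too_few_samples_rejected(self):
        seg = ForceCurve([0, 1, 2], np.zeros(3), [0, 1, 2])
        with pytest.raises(ValueError):
            fit_loading(seg)


class TestFitRelaxation:
    def test_noiseless_parameter_recovery(self):
        t = np.arange(0, 240, 0.1)
        amps, taus, feq = (0.5, 0.3, 0.2), (2.0, 20.0, 120.0), 0.4
        f = feq + sum(a * np.exp(-t / tau) for a, tau in zip(amps, taus))
        fit = fit_relaxation(ForceCurve(t, np.zeros_like(t), f))
        assert fit.converged
        assert fit.eq_force_N == pytest.approx(feq, rel=0.01)
        np.testing.assert_allclose(fit.amplitudes_N, sorted(amps, reverse=True), rtol=0.01)
        np.testing.assert_allclose(fit.taus_s, taus, rtol=0.01)
        assert fit.taus_s[0] < fit.taus_s[1] < fit.taus_s[2]

    def test_constant_force_zero_decay_limit(self):
        t = np.arange(0, 100, 0.5)
        fit = fit_relaxation(ForceCurve(t, np.zeros_like(t), np.full(t.size, 0.7)))
        assert fit.eq_force_N == pytest.approx(0.7, abs=1e-9)
        np.testing.assert_allclose(fit.amplitudes_N, 0, atol=1e-9)

    def test_single_exponential_data_not_overfit(self):
        rng = np.random.default_rng(0)
        t = np.arange(0, 240, 0.1)
        f = 0.3 + 0.5 * np.exp(-t / 30.0) + rng.normal(0, 0.002, t.size)
        fit = fit_relaxation(ForceCurve(t, np.zeros_like(t), f))

        def monoexp(t, feq, a, tau):
            return feq + a * np.exp(-t / tau)

        popt, _ = curve_fit(monoexp, t, f, p0=[0.3, 0.5, 20.0])
        rss_mono = np.sum((f - monoexp(t, *popt)) ** 2)
        rss_tri = np.sum(fit.residuals_N**2)
        assert rss_tri <= rss_mono * 1.001
        # triexp residuals stay at the noise floor
        assert np.std(fit.residuals_N) == pytest.approx(0.002, rel=0.1)


class TestContactArea:
    def test_protocol_nominal_area(self):
        # R = 1 mm, depth = 0.3 mm -> pi * 0.51 = 1.60 mm^2
        assert contact_area(1.0, 0.3) == pytest.approx(1.6, abs=0.005)

    def test_edge_values(self):
        assert contact_area(1.0, 0.0) == 0.0
        assert contact_area(1.0, 1.0) == pytest.approx(math.pi, rel=1e-12)

    def test_depth_beyond_radius_rejected(self):
        with pytest.raises(ValueError):
            contact_area(1.0, 1.1)

    @given(st.floats(0.0, 1.0), st.floats(0.0, 1.0))
    @settings(max_examples=50, deadline=None)
    def test_monotonic_in_depth(self, d1, d2):
        lo, hi = sorted((d1, d2))
        assert contact_area(1.0, lo) <= contact_area(1.0, hi)


class TestApparentModulus:
    @pytest.mark.parametrize(
        "force, area, depth, thickness, expected",
        [
            (0.32, 1.6, 0.3, 3.0, 2.0),
            (1.075, 1.602, 0.3, 1.5, 3.3552),
        ],
    )
    def test_arithmetic(self, force, area, depth, thickness, expected):
        assert apparent_modulus(force, area, depth, thickness) == pytest.approx(
            expected, rel=1e-3
        )

    def test_half_thickness_strain(self):
        # thickness = 2 * depth -> strain 0.5 -> modulus = 2 * stress
        stress = 0.5 / 1.6
        assert apparent_modulus(0.5, 1.6, 0.3, 0.6) == pytest.approx(2 * stress)

    @given(st.floats(0.1, 10.0))
    @settings(max_examples=30, deadline=None)
    def test_invariant_under_joint_force_area_scaling(self, scale):
        base = apparent_modulus(0.5, 1.6, 0.3, 2.0)
        scaled = apparent_modulus(0.5 * scale, 1.6 * scale, 0.3, 2.0)
        assert scaled == pytest.approx(base, rel=1e-9)

    def test_strain_at_or_above_one_rejected(self):
        with pytest.raises(ValueError):
            apparent_modulus(0.5, 1.6, 0.3, 0.3)


class TestPermeability:
    @pytest.mark.parametrize(
        "z, h, tau, expected",
        [(2.0, 1.0, 400.0, 0.01), (1.5, 0.81, 365.0, 0.00761)],
    )
    def test_arithmetic(self, z, h, tau, expected):
        assert permeability(z, h, tau) == pytest.approx(expected, rel=1e-2)

    def test_quadratic_in_thickness(self):
        assert permeability(2.0, 1.0, 100.0) == pytest.approx(
            4 * permeability(1.0, 1.0, 100.0)
        )

    @given(st.floats(0.5, 5.0), st.floats(0.1, 5.0), st.floats(1.0, 500.0))
    @settings(max_examples=50, deadline=None)
    def test_inverse_identity(self, z, h, tau):
        assert permeability(z, h, tau) * h * tau / z**2 == pytest.approx(1.0, rel=1e-12)

    def test_rejects_nonpositive_inputs(self):
        with pytest.raises(ValueError):
            permeability(1.0, 0.0, 10.0)


class TestAnalyzeCurve:
    def test_noiseless_end_to_end_recovers_generator_truth(
        self, geometry, noiseless_config
    ):
        site = make_site()
        curve = simulate_indentation_curve(site, geometry, noiseless_config)
        res = analyze_curve(curve, site.thickness_mm, geometry)
        assert res.qc_flag == "ok"
        expected_peak_mod = apparent_modulus(
            site.peak_force_N, res.contact_area_mm2, 0.3, site.thickness_mm
        )
        assert res.apparent_peak_modulus_MPa == pytest.approx(
            expected_peak_mod, rel=0.005
        )
        assert res.eq_force_N == pytest.approx(site.eq_force_N, abs=1e-6)
        np.testing.assert_allclose(res.taus_s, site.taus_s, rtol=0.01)

    def test_denuded_site_returns_flagged_result(self, geometry):
        t = np.arange(100) * 0.1
        res = analyze_curve(
            ForceCurve(t, np.zeros_like(t), np.zeros_like(t)), 2.0, geometry
        )
        assert res.qc_flag == "no_contact"
        assert res.apparent_peak_modulus_MPa is None

    def test_batch_of_64_sites_none_dropped(self, sites64, geometry, default_config):
        results = [
            analyze_curve(
                simulate_indentation_curve(s, geometry, default_config),
                s.thickness_mm,
                geometry,
            )
            for s in sites64
        ]
        assert len(results) == 64
        assert all(r.qc_flag == "ok" for r in results)
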