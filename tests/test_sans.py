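"""Unit and property tests for the composite scattering model."""

import numpy as np
import pytest
from dataclasses import replace
from hypothesis import given, settings, strategies as st
from scipy.optimize import brentq
from scipy.signal import argrelmax

from lipidphase.sans import (
    BCCParams,
    CompositeParams,
    LamellarParams,
    ScatteringCurve,
    VesicleParams,
    bcc_intensity,
    bcc_lattice_factor,
    bilayer_form,
    bragg_peaks,
    composite_intensity,
    fit_composite,
    lamellar_intensity,
    params_to_flat,
    sphere_form_factor,
    stack_interference,
    table_start_params,
    vesicle_intensity,
    PARAM_NAMES,
)


class TestSphereFormFactor:
    def test_forward_limit_is_unity(self):
        assert sphere_form_factor(0.0, 250.0)[0] == pytest.approx(1.0, abs=1e-12)

    def test_first_zero_matches_bisection_oracle(self):
        # amplitude vanishes where tan(x) = x; bracket the first positive root
        root = brentq(lambda x: np.sin(x) - x * np.cos(x), np.pi, 1.5 * np.pi)
        assert root == pytest.approx(4.4934, abs=1e-3)
        R = 250.0
        q = np.linspace(0.9 * root / R, 1.1 * root / R, 2001)
        p = sphere_form_factor(q, R)
        assert q[np.argmin(p)] == pytest.approx(root / R, rel=1e-3)

    def test_monotone_decreasing_before_first_zero(self):
        R = 250.0
        q = np.linspace(1e-4, 4.49 / R, 500)
        p = sphere_form_factor(q, R)
        assert np.all(np.diff(p) < 0)

    def test_rejects_nonpositive_radius(self):
        with pytest.raises(ValueError):
            sphere_form_factor(0.01, -1.0)


class TestBCCLatticeFactor:
    def test_large_distortion_flattens_to_unity(self):
        q = np.geomspace(0.002, 0.221, 30)
        z = bcc_lattice_factor(q, 460.0, 10.0, n_orient=16)
        np.testing.assert_allclose(z, 1.0, atol=1e-12)

    def test_powder_peak_at_110_reflection(self):
        # ordered lattice: the strongest powder peak is the (110) reflection
        a = 460.0
        q = np.geomspace(0.002, 0.221, 100)
        z = bcc_lattice_factor(q, a, 0.05, n_orient=150)
        q_peak = q[np.argmax(z)]
        q110 = 2.0 * np.pi * np.sqrt(2.0) / a
        k = np.searchsorted(q, q110)
        assert abs(np.argmax(z) - k) <= 1

    def test_quadrature_doubling_invariance(self):
        q = np.geomspace(0.002, 0.221, 25)
        z1 = bcc_lattice_factor(q, 519.6, 0.1, n_orient=150)
        z2 = bcc_lattice_factor(q, 519.6, 0.1, n_orient=300)
        assert np.max(np.abs(z2 - z1) / z1) < 1e-3

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            bcc_lattice_factor(0.01, 460.0, -0.1)
        with pytest.raises(ValueError):
            bcc_lattice_factor(0.01, 460.0, 0.1, n_orient=4)


class TestBCCIntensity:
    def test_zero_scale_gives_zero(self, q_window):
        p = BCCParams(scale_bcc=0.0)
        np.testing.assert_array_equal(bcc_intensity(q_window, p), 0.0)

    def test_reduces_to_sphere_scattering_at_large_distortion(self):
        q = np.geomspace(0.005, 0.2, 40)
        p = BCCParams(scale_bcc=2.0, distortion_g=10.0)
        i = bcc_intensity(q, p, n_orient=16)
        v_p = 4.0 / 3.0 * np.pi * p.sphere_radius**3
        expected = (
            p.scale_bcc
            * (p.sld_particle - p.sld_solvent) ** 2
            * v_p
            * sphere_form_factor(q, p.sphere_radius)
        )
        np.testing.assert_allclose(i, expected, rtol=1e-10)

    def test_intensity_ratio_independent_of_scale(self):
        q = np.array([0.01, 0.05])
        r = []
        for s in (0.5, 3.0):
            i = bcc_intensity(q, BCCParams(scale_bcc=s), n_orient=16)
            r.append(i[0] / i[1])
        assert r[0] == pytest.approx(r[1], rel=1e-12)


class TestVesicleIntensity:
    def test_forward_limit_matches_algebraic_value(self):
        p = VesicleParams()
        v_core = 4 / 3 * np.pi * p.r_core**3
        v_tot = 4 / 3 * np.pi * p.r_total**3
        v_shell = v_tot - v_core
        drho = p.sld_shell - p.sld_solvent
        expected = p.scale_ves * p.volume_fraction_phi * v_shell * drho**2
        assert vesicle_intensity(1e-8, p)[0] == pytest.approx(expected, rel=1e-8)

    def test_zero_contrast_gives_zero(self, q_window):
        p = VesicleParams(sld_shell=6.36e-6, sld_solvent=6.36e-6)
        np.testing.assert_allclose(vesicle_intensity(q_window, p), 0.0, atol=1e-30)

    def test_first_minimum_matches_shell_integral_oracle(self):
        p = VesicleParams(r_core=4960.0, shell_thickness=40.0)
        q = np.linspace(2e-4, 1.2e-3, 500)
        i_impl = vesicle_intensity(q, p)

        def amplitude(qv):
            # brute-force radial integration of the shell contrast profile
            r = np.linspace(p.r_core, p.r_total, 4000)
            drho = p.sld_shell - p.sld_solvent
            return np.trapezoid(drho * 4 * np.pi * r**2 * np.sinc(qv * r / np.pi), r)

        i_oracle = np.array([amplitude(x) ** 2 for x in q])
        k_impl = int(np.argmin(i_impl[: q.size * 4 // 5]))
        k_oracle = int(np.argmin(i_oracle[: q.size * 4 // 5]))
        assert abs(k_impl - k_oracle) <= 1

    def test_rejects_invalid_geometry(self):
        with pytest.raises(ValueError):
            VesicleParams(r_core=-1.0)
        with pytest.raises(ValueError):
            VesicleParams(shell_thickness=0.0)


class TestBilayerForm:
    @pytest.mark.parametrize(
        "qt, expected",
        [(0.0, 1.0), (np.pi, 0.0), (np.pi / 2, (2 / np.pi) ** 2)],
    )
    def test_reference_values(self, qt, expected):
        t = 30.0
        assert bilayer_form(qt / t, t)[0] == pytest.approx(expected, abs=1e-12)


def _stack_double_sum(q, n, d, sigma_d):
    """O(N²) pairwise-sum oracle for the paracrystal stack factor."""
    w = np.exp(-0.5 * sigma_d**2 * q**2)
    z = np.zeros_like(q)
    for j in range(n):
        for k in range(n):
            z += w ** abs(j - k) * np.cos((j - k) * q * d)
    return z / n


class TestStackInterference:
    def test_uncorrelated_layers_limit(self):
        q = np.linspace(0.005, 0.2, 50)
        z = stack_interference(q, 6, 250.0, 1e5)
        np.testing.assert_allclose(z, 1.0, atol=1e-10)

    def test_single_layer_is_unity(self):
        q = np.linspace(0.005, 0.2, 50)
        np.testing.assert_allclose(
            stack_interference(q, 1, 250.0, 10.0), _stack_double_sum(q, 1, 250.0, 10.0)
        )

    def test_closed_form_matches_double_sum_oracle(self):
        q = np.linspace(0.002, 0.25, 200)
        z = stack_interference(q, 4, 250.0, 10.0)
        oracle = _stack_double_sum(q, 4, 250.0, 10.0)
        assert np.max(np.abs(z - oracle) / np.abs(oracle)) < 1e-10

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(
        n=st.integers(min_value=1, max_value=10),
        d=st.floats(min_value=100.0, max_value=500.0),
        sigma=st.floats(min_value=0.5, max_value=50.0),
    )
    def test_closed_form_property(self, n, d, sigma):
        # near-Bragg q points with w -> 1 amplify float cancellation in the
        # closed form, so the random sweep uses a looser bound than the
        # fixed-parameter oracle check above
        q = np.linspace(0.003, 0.22, 60)
        z = stack_interference(q, n, d, sigma)
        oracle = _stack_double_sum(q, n, d, sigma)
        np.testing.assert_allclose(z, oracle, rtol=1e-7, atol=1e-9)

    def test_noninteger_stack_mixes_neighbours(self):
        q = np.linspace(0.005, 0.2, 60)
        z = stack_interference(q, 4.3, 250.0, 15.0)
        expected = 0.7 * stack_interference(q, 4, 250.0, 15.0) + 0.3 * stack_interference(
            q, 5, 250.0, 15.0
        )
        np.testing.assert_allclose(z, expected, rtol=1e-12)

    def test_perfectly_correlated_layers_finite(self):
        # sigma_D = 0 hits the Bragg singularity of the closed form; the
        # direct lattice sum keeps the value finite
        d = 250.0
        q = np.array([2 * np.pi / d])
        z = stack_interference(q, 4, d, 0.0)
        assert np.isfinite(z[0])
        assert z[0] == pytest.approx(4.0, rel=1e-9)  # N-fold coherent peak

    def test_rejects_substack(self):
        with pytest.raises(ValueError):
            stack_interference(0.01, 0.5, 250.0, 10.0)


class TestLamellarIntensity:
    def test_interference_maximum_near_bragg_position(self):
        q = np.linspace(0.004, 0.05, 4601)
        z = stack_interference(q, 4, 250.0, 25.0)
        assert q[np.argmax(z)] == pytest.approx(2 * np.pi / 250.0, abs=2e-4)

    def test_peak_converges_to_bragg_for_large_ordered_stack(self):
        q = np.linspace(0.02, 0.03, 2001)
        z = stack_interference(q, 20, 250.0, 1.0)
        step = q[1] - q[0]
        assert abs(q[np.argmax(z)] - 2 * np.pi / 250.0) <= step

    def test_linearity_in_scale(self, q_window):
        p1 = LamellarParams(scale_lam=1.0)
        p2 = LamellarParams(scale_lam=2.0)
        np.testing.assert_allclose(
            lamellar_intensity(q_window, p2), 2 * lamellar_intensity(q_window, p1)
        )

    def test_reduces_to_bilayer_form_without_interference(self, q_window):
        p = LamellarParams(scale_lam=1.0, sigma_D=1e5)
        iq2 = lamellar_intensity(q_window, p) * q_window**2
        np.testing.assert_allclose(
            iq2, bilayer_form(q_window, p.bilayer_thickness_t), rtol=1e-9
        )

    def test_rejects_q_zero(self):
        with pytest.raises(ValueError):
            lamellar_intensity(np.array([0.0, 0.01]), LamellarParams())


class TestCompositeIntensity:
    def test_zero_scales_leave_background(self, q_window):
        p = CompositeParams(
            bcc=BCCParams(scale_bcc=0.0),
            vesicle=VesicleParams(scale_ves=0.0),
            lamellar=LamellarParams(scale_lam=0.0),
            background_IB=0.42,
        )
        np.testing.assert_allclose(composite_intensity(q_window, p), 0.42)

    def test_additivity_of_components(self, truth_params, q_window):
        total = composite_intensity(q_window, truth_params, n_orient=24)
        parts = (
            bcc_intensity(q_window, truth_params.bcc, n_orient=24)
            + vesicle_intensity(q_window, truth_params.vesicle)
            + lamellar_intensity(q_window, truth_params.lamellar)
            + truth_params.background_IB
        )
        np.testing.assert_array_equal(total, parts)

    def test_forward_model_deterministic(self, truth_params, q_window):
        i1 = composite_intensity(q_window, truth_params, n_orient=24)
        i2 = composite_intensity(q_window, truth_params, n_orient=24)
        np.testing.assert_array_equal(i1, i2)

    def test_nonnegative_over_window(self, truth_params, q_window):
        assert np.all(composite_intensity(q_window, truth_params, n_orient=24) >= 0)


@settings(max_examples=25, derandomize=True, deadline=None)
@given(
    radius=st.floats(min_value=50.0, max_value=400.0),
    a=st.floats(min_value=250.0, max_value=800.0),
    g=st.floats(min_value=0.03, max_value=0.5),
    t=st.floats(min_value=20.0, max_value=60.0),
    n_layers=st.floats(min_value=1.0, max_value=12.0),
)
def test_all_intensities_nonnegative_for_valid_params(radius, a, g, t, n_layers):
    q = np.geomspace(0.003, 0.25, 25)
    bcc = BCCParams(sphere_radius=radius, lattice_constant_a=a, distortion_g=g)
    lam = LamellarParams(bilayer_thickness_t=t, n_layers_N=n_layers, spacing_D=4 * t)
    assert np.all(bcc_intensity(q, bcc, n_orient=12) >= 0)
    assert np.all(lamellar_intensity(q, lam) >= 0)
    assert np.all(vesicle_intensity(q, VesicleParams()) >= 0)


class TestFitComposite:
    def test_all_frozen_returns_start_chi2(self, truth_params):
        from lipidphase.synthetic import SansCurveSpec, gen_sans_curve

        curve, _ = gen_sans_curve(SansCurveSpec(relative_noise=0.05, seed=11))
        res = fit_composite(curve, start=truth_params, frozen=set(PARAM_NAMES))
        expected = float(
            np.sum(
                (
                    (composite_intensity(curve.q, truth_params, n_orient=48) - curve.intensity)
                    / curve.sigma
                )
                ** 2
            )
        ) / (len(curve) - 1)
        assert res.chi2_reduced == pytest.approx(expected, rel=1e-9)
        assert res.params == truth_params

    def test_noise_free_self_consistency(self, truth_params):
        from lipidphase.synthetic import SansCurveSpec, gen_sans_curve

        curve, _ = gen_sans_curve(SansCurveSpec(relative_noise=0.0))
        start = replace(
            truth_params,
            bcc=replace(truth_params.bcc, scale_bcc=0.7),
            vesicle=replace(truth_params.vesicle, scale_ves=30.0),
            lamellar=replace(
                truth_params.lamellar,
                scale_lam=8e-9,
                spacing_D=270.0,
                bilayer_thickness_t=27.0,
            ),
            background_IB=2e-6,
        )
        free = {"bcc_scale", "ves_scale", "lam_scale", "background", "lam_spacing", "lam_thickness"}
        res = fit_composite(curve, start=start, frozen=set(PARAM_NAMES) - free)
        assert res.converged
        truth_flat = params_to_flat(truth_params)
        best_flat = params_to_flat(res.params)
        for name in free:
            assert best_flat[name] == pytest.approx(truth_flat[name], rel=0.01), name

    def test_rejects_short_and_degenerate_curves(self):
        q = np.linspace(0.01, 0.02, 5)
        with pytest.raises(ValueError):
            fit_composite(ScatteringCurve(q, np.ones(5)))
        q = np.linspace(0.01, 0.2, 20)
        with pytest.raises(ValueError):
            fit_composite(ScatteringCurve(q, np.zeros(20)))


class TestBraggPeaks:
    def test_first_two_reflections_match_printed_positions(self):
        peaks = bragg_peaks(460.0)
        (hkl1, q1), (hkl2, q2) = peaks[0], peaks[1]
        assert hkl1 == (1, 1, 0)
        assert hkl2 == (2, 0, 0)
        assert q1 == pytest.approx(0.01932, abs=5e-5)
        assert q2 == pytest.approx(0.02732, abs=5e-5)

    def test_doubling_lattice_constant_halves_positions(self):
        q1 = np.array([q for _, q in bragg_peaks(460.0, q_max=0.1)])
        q2 = np.array([q for _, q in bragg_peaks(920.0, q_max=0.05)])
        np.testing.assert_allclose(q2, q1[: q2.size] / 2.0, rtol=1e-12)

    def test_selection_rule_excludes_odd_sums(self):
        for hkl, _ in bragg_peaks(460.0, q_max=0.3):
            assert sum(hkl) % 2 == 0
        assert all(hkl != (1, 0, 0) for hkl, _ in bragg_peaks(460.0, q_max=0.3))
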