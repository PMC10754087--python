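"""Neutron scattering models: geometry, NSE initial decay, rigid-body
first cumulant, mode amplitude functions and backscattering fits."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from molspan import neutron as nt
from molspan.synthetic import NSEConfig, QENSConfig, simulate_nse, simulate_qens
from molspan.synthetic.trajectories import default_bead_dimer_config


class TestGeometry:
    def test_backscattering_limit(self):
        g = nt.ScatteringGeometry(180 - 1e-9, 4 * np.pi)
        assert nt.q_from_geometry(g) == pytest.approx(1.0, rel=1e-6)

    def test_small_angle_spin_echo_configuration(self):
        g = nt.ScatteringGeometry(9.5, 10.0)
        assert nt.q_from_geometry(g) == pytest.approx(0.1041, abs=2e-4)

    def test_q_vanishes_at_zero_angle(self):
        q1 = nt.q_from_geometry(nt.ScatteringGeometry(1e-6, 10.0))
        assert q1 < 1e-7

    def test_invalid_geometry_rejected(self):
        with pytest.raises(ValueError):
            nt.ScatteringGeometry(0.0, 10.0)
        with pytest.raises(ValueError):
            nt.ScatteringGeometry(10.0, -1.0)

    def test_peak_length(self):
        assert nt.peak_length(2 * np.pi) == pytest.approx(1.0)
        assert nt.peak_length(0.13) == pytest.approx(48.33, abs=0.01)
        with pytest.raises(ValueError):
            nt.peak_length(0.0)


class TestRotationalTime:
    def test_scalar(self):
        assert nt.tau_r_from_Dr(1.0 / 6.0) == pytest.approx(1.0)

    def test_reference_rigid_body_value(self):
        # 1.64e6 1/s = 1.64e-3 1/ns
        assert nt.tau_r_from_Dr(1.64e-3) == pytest.approx(101.6, abs=0.1)

    def test_per_axis_harmonic_combination(self):
        # axis times (72, 125, 125) ns correspond to D_i = 1/(6 tau_i)
        taus = np.array([72.0, 125.0, 125.0])
        d = 1.0 / (6.0 * taus)
        per_axis, overall = nt.tau_r_from_Dr(d)
        assert np.allclose(per_axis, taus)
        assert overall == pytest.approx(1.0 / (6.0 * d.mean()))
        assert overall == pytest.approx(100.4, abs=0.5)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            nt.tau_r_from_Dr(0.0)


class TestOligomerRescale:
    def test_monomer_identity(self):
        assert nt.oligomer_rescale(4.0, 2.0, 1) == (4.0, 2.0)

    def test_hexamer_of_dimers(self):
        d_t, d_r = nt.oligomer_rescale(4.71, 1.64e-3, 3)
        assert d_t == pytest.approx(4.71 / 3 ** (1 / 3), rel=1e-12)
        assert d_t == pytest.approx(3.266, abs=0.001)
        assert d_r == pytest.approx(1.64e-3 / 3, rel=1e-12)


class TestInitialDecay:
    def test_exact_exponential_recovered(self):
        q = np.array([0.05, 0.1])
        tau = np.linspace(0, 25, 20)
        d_eff = 4.0
        vals = np.exp(-d_eff * q[:, None] ** 2 * tau[None, :])
        isf = nt.IntermediateScattering(q, tau, vals)
        out = nt.fit_initial_decay(isf)
        assert np.allclose(out.d_eff, 4.0, rtol=1e-8)

    def test_cut_rule_on_toy_grid(self):
        # tau < 30 and I > 0.3 keeps exactly the first three points
        tau = np.array([5.0, 10, 20, 40, 60])
        vals = np.array([[0.9, 0.8, 0.5, 0.25, 0.1]])
        mask = (tau < 30.0) & (vals[0] > 0.3)
        assert mask.sum() == 3
        isf = nt.IntermediateScattering([0.1], tau, vals)
        out = nt.fit_initial_decay(isf)
        assert out.q.size == 1 and np.isfinite(out.d_eff[0])

    def test_two_exponential_initial_slope_bound(self):
        q = np.array([0.1])
        tau = np.linspace(0, 25, 40)
        r1, r2 = 2.0 * 0.01, 8.0 * 0.01      # rates for q^2 = 0.01
        vals = 0.5 * np.exp(-r1 * tau) + 0.5 * np.exp(-r2 * tau)
        isf = nt.IntermediateScattering(q, tau, vals[None])
        out = nt.fit_initial_decay(isf)
        assert 2.0 < out.d_eff[0] < 8.0

    def test_insufficient_points_omitted(self):
        tau = np.array([40.0, 50.0, 60.0])
        isf = nt.IntermediateScattering([0.1], tau, np.array([[0.2, 0.1, 0.05]]))
        with pytest.warns(UserWarning, match="omitted"):
            out = nt.fit_initial_decay(isf)
        assert out.q.size == 0


class TestRigidBodyDeff:
    def test_point_scatterer_is_translational(self):
        body = nt.RigidBody(np.zeros((1, 3)), np.ones(1), 3.2, 1e-3)
        out = nt.rigid_body_deff(body, [0.02, 0.1, 0.5])
        assert np.allclose(out.d_eff, 3.2, rtol=1e-10)

    def test_low_q_limit_and_monotonicity(self, rng):
        coords = rng.normal(0, 25, (40, 3))
        body = nt.RigidBody(coords, np.ones(40), 3.0, 1.6e-3)
        q = np.linspace(1e-4, 0.2, 30)
        out = nt.rigid_body_deff(body, q)
        assert out.d_eff[0] == pytest.approx(3.0, rel=1e-3)
        # rotational contribution only adds to translation
        assert np.all(out.d_eff >= 3.0 - 1e-9)
        # monotone rise below the structure-factor peak
        rise = q < 0.08
        assert np.all(np.diff(out.d_eff[rise]) > -1e-6)

    def test_quadrature_convergence(self, rng):
        coords = rng.normal(0, 20, (5, 3))
        b = rng.uniform(0.5, 1.5, 5)
        body = nt.RigidBody(coords, b, 3.0, 1.6e-3)
        c1 = nt.rigid_body_deff(body, [0.08], n_directions=256)
        c2 = nt.rigid_body_deff(body, [0.08], n_directions=2048)
        assert abs(c1.d_eff[0] - c2.d_eff[0]) / c2.d_eff[0] < 0.005

    def test_anisotropic_tensor_validated(self):
        with pytest.raises(ValueError):
            nt.RigidBody(np.zeros((2, 3)), np.ones(2), 3.0, np.array([-1e-3, 1e-3, 1e-3]))


class TestAmplitudeFunction:
    def test_single_atom_isotropic_average(self):
        amp = nt.amplitude_function(np.array([[[0.0, 0, 1]]]), np.zeros((1, 3)),
                                    np.ones(1), [0.05, 0.1, 0.5])
        assert np.allclose(amp.per_mode, 1 / 3, atol=2e-3)

    def test_matches_double_sum_oracle(self, rng):
        """|sum_a b_a e^{iq r_a} (q_hat.v_a)|^2 equals the explicit pair sum
        sum_ab b_a b_b cos(q.(r_a - r_b)) (q_hat.v_a)(q_hat.v_b)."""
        coords = rng.normal(0, 10, (5, 3))
        b = rng.uniform(0.5, 2.0, 5)
        v = rng.normal(0, 1, (5, 3))
        q = 0.11
        dirs = nt.fibonacci_sphere(8)
        amp = nt.amplitude_function(v[None], coords, b, [q], n_directions=8)
        expect = 0.0
        for qh in dirs:
            acc = 0.0
            for a in range(5):
                for c in range(5):
                    phase = np.cos(q * qh @ (coords[a] - coords[c]))
                    acc += b[a] * b[c] * phase * (qh @ v[a]) * (qh @ v[c])
            expect += acc / len(dirs)
        assert amp.per_mode[0, 0] == pytest.approx(expect, rel=1e-12)

    @settings(deadline=None, max_examples=20)
    @given(seed=st.integers(0, 1000))
    def test_nonnegative_for_random_inputs(self, seed):
        r = np.random.default_rng(seed)
        coords = r.normal(0, 15, (6, 3))
        v = r.normal(0, 1, (6, 3))
        amp = nt.amplitude_function(v[None], coords, r.uniform(0.1, 2, 6),
                                    [0.05, 0.15], n_directions=16)
        assert np.all(amp.per_mode >= -1e-12)

    def test_two_blob_hinge_peaks_near_2pi_over_d(self, rng):
        d = 48.0
        blob1 = rng.normal(0, 3, (15, 3)) + [-d / 2, 0, 0]
        blob2 = rng.normal(0, 3, (15, 3)) + [d / 2, 0, 0]
        coords = np.vstack([blob1, blob2])
        v = np.zeros((30, 3))
        v[:15, 0] = -1
        v[15:, 0] = 1
        q = np.linspace(0.02, 0.3, 60)
        amp = nt.amplitude_function(v[None], coords, np.ones(30), q)
        peak_q = q[np.argmax(amp.per_mode[0])]
        # anti-phase blob pair: |F|^2 ~ sin^2(q_x d/2); the orientation
        # average puts the first maximum slightly above pi/d
        assert np.pi / d * 0.8 < peak_q < 2 * np.pi / d
        # the corresponding real-space scale is the blob separation within a
        # geometric factor
        assert nt.peak_length(peak_q) == pytest.approx(d, rel=0.8)


class TestBackscattering:
    def test_eisf_small_q_expansion(self):
        q = np.linspace(1e-4, 0.2, 50)
        a = 1.95
        a0 = nt.eisf_sphere(q, a)
        expansion = 1 - (q * a) ** 2 / 5
        assert np.allclose(a0, expansion, atol=(q * a).max() ** 4)

    def test_spectra_nonnegative_and_normalized(self):
        sp = simulate_qens(QENSConfig(noise_level=0.0, background=0.0, seed=0))
        assert np.all(sp.clean >= 0)
        # integral closure needs the omega window to cover the Lorentzian
        # tails: use narrow linewidths on a wide grid
        cfg = QENSConfig(q=np.linspace(0.2, 0.6, 5),
                         omega=np.arange(-200.0, 200.0, 0.25),
                         d_app=1.0, gamma_int=1.0, background=0.0,
                         noise_level=0.0, seed=0)
        sp2 = simulate_qens(cfg)
        integrals = np.trapezoid(sp2.clean, sp2.omega, axis=1)
        assert np.allclose(integrals, 1.0, rtol=0.01)

    def test_zero_radius_gives_single_lorentzian(self):
        cfg = QENSConfig(a=1e-9, noise_level=0.0, background=0.0, seed=0)
        sp = simulate_qens(cfg)
        from scipy.special import voigt_profile

        from molspan.neutron import HBAR_UEV_NS

        for i, q in enumerate(sp.q[::5]):
            g = HBAR_UEV_NS * cfg.d_app * q**2
            ref = voigt_profile(sp.omega, cfg.res_width, g)
            assert np.allclose(sp.clean[::5][i], ref, atol=1e-10)

    def test_roundtrip_recovery_noiseless(self):
        sp = simulate_qens(QENSConfig(noise_level=1e-6, seed=2))
        res = nt.nbs_fit(sp.q, sp.omega, sp.values, sp.errors, sp.res_width)
        assert res.d_app == pytest.approx(3.27, rel=0.02)
        assert res.a == pytest.approx(1.95, rel=0.02)

    def test_widths_scale_with_q_squared(self):
        sp = simulate_qens(QENSConfig(noise_level=1e-6, seed=3))
        res = nt.nbs_fit(sp.q, sp.omega, sp.values, sp.errors, sp.res_width)
        slope = np.polyfit(sp.q**2, res.per_q_widths, 1)[0]
        assert slope == pytest.approx(nt.HBAR_UEV_NS * res.d_app, rel=1e-6)

    def test_too_few_q_rejected(self):
        sp = simulate_qens(QENSConfig(seed=0))
        with pytest.raises(ValueError):
            nt.nbs_fit(sp.q[:3], sp.omega, sp.values[:3], sp.errors[:3], sp.res_width)


class TestSimulateNSE:
    @pytest.fixture(scope="class")
    def geometry(self):
        cfg = default_bead_dimer_config()
        return cfg.coords, np.ones(len(cfg.coords))

    def test_normalized_at_zero_lag(self, geometry):
        coords, b = geometry
        isf = simulate_nse(NSEConfig(coords=coords, b=b))
        assert np.allclose(isf.values[:, 0], 1.0, atol=1e-12)

    def test_rigid_only_matches_first_cumulant_model(self, geometry):
        coords, b = geometry
        cfg = NSEConfig(coords=coords, b=b, d_t=3.27, d_r=5.5e-4)
        isf = simulate_nse(cfg)
        fit = nt.fit_initial_decay(isf)
        model = nt.rigid_body_deff(nt.RigidBody(coords, b, 3.27, 5.5e-4), isf.q)
        assert np.allclose(fit.d_eff, model.d_eff, rtol=1e-6)

    def test_internal_mode_creates_deff_peak_at_amplitude_peak(self, geometry):
        coords, b = geometry
        v = np.zeros_like(coords)
        v[:12, 0] = -1
        v[12:, 0] = 1
        q = np.linspace(0.04, 0.25, 40)
        cfg = NSEConfig(coords=coords, b=b, q=q, mode_vectors=v,
                        mode_weight=0.5, mode_tau=100.0)
        isf = simulate_nse(cfg)
        fit = nt.fit_initial_decay(isf)
        rigid = nt.rigid_body_deff(nt.RigidBody(coords, b, cfg.d_t, cfg.d_r), q)
        excess = fit.d_eff - rigid.d_eff
        amp = nt.amplitude_function(v[None], coords, b, q)
        # compare the q of maximal D_eff excess with the amplitude peak
        # (skip the lowest q where both are translation-dominated)
        sel = q > 0.06
        q_excess = q[sel][np.argmax(excess[sel])]
        q_amp = q[sel][np.argmax((amp.per_mode[0] / np.trapezoid(amp.per_mode[0], q))[sel])]
        assert abs(q_excess - q_amp) <= 0.05

    def test_mismatched_mode_length_rejected(self, geometry):
        coords, b = geometry
        with pytest.raises(ValueError):
            NSEConfig(coords=coords, b=b, mode_vectors=np.zeros((3, 3)))
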