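"""Trajectory mode analysis: superposition, inertia axis, PCA, AV, ANM."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from molspan import mdmodes as md
from molspan.synthetic import (
    default_bead_dimer_config,
    simulate_bead_dimer,
)


@pytest.fixture(scope="module")
def dimer():
    cfg = default_bead_dimer_config(seed=3)
    traj = simulate_bead_dimer(cfg)
    sup = md.superpose(traj, cfg.coords)
    return cfg, traj, sup


class TestTrajectoryIO:
    @pytest.mark.filterwarnings("ignore::UserWarning")
    @pytest.mark.filterwarnings("ignore::DeprecationWarning")
    def test_pdb_dcd_roundtrip(self, tmp_path):
        mda = pytest.importorskip("MDAnalysis")
        n = 6
        u = mda.Universe.empty(n, n_residues=n, atom_resindex=np.arange(n),
                               trajectory=True)
        u.add_TopologyAttr("names", ["CA"] * n)
        u.add_TopologyAttr("masses", [12.0] * n)
        u.add_TopologyAttr("resids", list(range(1, n + 1)))
        base = np.arange(n * 3, dtype=float).reshape(n, 3)
        u.atoms.positions = base
        pdb, dcd = tmp_path / "toy.pdb", tmp_path / "toy.dcd"
        u.atoms.write(str(pdb))
        with mda.Writer(str(dcd), n) as w:
            for k in range(3):
                u.atoms.positions = base + (k + 1)
                w.write(u.atoms)
        traj = md.load_trajectory(pdb, dcd, frame_interval=0.1)
        assert traj.coords.shape == (3, n, 3)
        assert np.allclose(traj.coords[1], base + 2, atol=1e-3)
        assert traj.backbone.all()


class TestSuperpose:
    def test_identity_when_already_aligned(self, rng):
        ref = rng.normal(0, 10, (8, 3))
        traj = md.Trajectory(ref[None], np.ones(8), 0.1)
        sup = md.superpose(traj, ref)
        assert np.allclose(sup.coords[0], ref, atol=1e-10)

    def test_recovers_random_rigid_transform(self, rng):
        ref = rng.normal(0, 10, (20, 3))
        rot = Rotation.random(rng=np.random.default_rng(3)).as_matrix()
        mob = ref @ rot.T + np.array([5.0, -7.0, 2.0])
        traj = md.Trajectory(mob[None], np.ones(20), 0.1)
        sup = md.superpose(traj, ref)
        assert np.sqrt(np.mean((sup.coords[0] - ref) ** 2)) < 1e-8

    def test_matches_rotation_grid_minimum(self, rng):
        """4-atom toy vs an exhaustive Euler-angle grid minimizer."""
        ref = rng.normal(0, 5, (4, 3))
        mob = ref + rng.normal(0, 0.8, (4, 3))
        traj = md.Trajectory(mob[None], np.ones(4), 0.1)
        sup = md.superpose(traj, ref, mass_weighted=False)
        rmsd_kabsch = np.sqrt(np.mean((sup.coords[0] - ref) ** 2))

        grid = np.linspace(-np.pi, np.pi, 25)
        best = np.inf
        mc = mob - mob.mean(axis=0)
        rc = ref - ref.mean(axis=0)
        for a in grid:
            for b in np.linspace(-np.pi / 2, np.pi / 2, 13):
                for c in grid:
                    r = Rotation.from_euler("zyx", [a, b, c]).as_matrix()
                    best = min(best, np.sqrt(np.mean((mc @ r.T - rc) ** 2)))
        assert rmsd_kabsch <= best + 0.02

    def test_too_few_particles_rejected(self, rng):
        ref = rng.normal(0, 5, (4, 3))
        traj = md.Trajectory(ref[None], np.ones(4), 0.1)
        with pytest.raises(ValueError):
            md.superpose(traj, ref, selection=np.array([0, 1]))


class TestPrincipalAxis:
    def test_static_prolate_cloud(self):
        # 6-point ellipsoid: +-3 on x, +-1 on y, +-0.5 on z -> long axis = x
        pts = np.array([[3, 0, 0], [-3, 0, 0], [0, 1, 0], [0, -1, 0],
                        [0, 0, 0.5], [0, 0, -0.5]], dtype=float)
        traj = md.Trajectory(np.repeat(pts[None], 4, axis=0), np.ones(6), 0.1)
        series = md.principal_axis_series(traj)
        assert np.allclose(np.abs(series.axes @ [1, 0, 0]), 1.0, atol=1e-12)

    def test_sign_flip_correction(self):
        pts = np.array([[3, 0, 0], [-3, 0, 0], [0, 1, 0], [0, -1, 0],
                        [0, 0, 0.5], [0, 0, -0.5]], dtype=float)
        frames = np.repeat(pts[None], 6, axis=0)
        # invert the cloud in one frame: inertia axis sign is arbitrary anyway,
        # so eigenvector sign can flip; the rule must keep the series continuous
        traj = md.Trajectory(frames, np.ones(6), 0.1)
        series = md.principal_axis_series(traj)
        assert np.max(np.abs(np.diff(series.axes, axis=0))) < 0.5

    def test_axes_are_unit(self, dimer):
        _, traj, _ = dimer
        sub = md.Trajectory(traj.coords[:200], traj.masses, traj.frame_interval)
        series = md.principal_axis_series(sub)
        assert np.allclose(np.linalg.norm(series.axes, axis=1), 1.0, atol=1e-12)


class TestRotationACF:
    def test_white_noise_is_uncorrelated(self, rng):
        axes = rng.normal(0, 1, (4000, 3))
        axes /= np.linalg.norm(axes, axis=1, keepdims=True)
        series = md.PrincipalAxisSeries(axes, 0.1, np.empty(0, int))
        lags, acf = md.rotation_acf(series, max_lag=100)
        assert acf[0] == pytest.approx(1.0, abs=1e-10)
        assert np.all(np.abs(acf[1:]) < 4 / np.sqrt(4000))

    def test_matches_direct_sum_oracle(self, rng):
        axes = rng.normal(0, 1, (150, 3))
        axes /= np.linalg.norm(axes, axis=1, keepdims=True)
        series = md.PrincipalAxisSeries(axes, 0.1, np.empty(0, int))
        max_lag = 60
        lags, acf = md.rotation_acf(series, max_lag=max_lag)
        n = axes.shape[0]
        expect = np.zeros(max_lag + 1)
        for i in range(3):
            x = axes[:, i]
            xm, xv = x.mean(), x.var()
            for k in range(max_lag + 1):
                expect[k] += np.mean([(x[j + k] - xm) * (x[j] - xm)
                                      for j in range(n - k)]) / xv / 3
        assert np.allclose(acf, expect, atol=1e-12)

    def test_constant_series_rejected(self):
        axes = np.tile([1.0, 0, 0], (50, 1))
        series = md.PrincipalAxisSeries(axes, 0.1, np.empty(0, int))
        with pytest.raises(ValueError):
            md.rotation_acf(series)


class TestFitRotation:
    def test_noiseless_single_exponential(self):
        lags = np.arange(2000) * 0.1
        acf = 1.0 * np.exp(-lags / 81.0)
        fit = md.fit_rotation(lags, acf)
        assert fit.tau1 == pytest.approx(81.0, rel=1e-4)
        assert abs(fit.b) < 1e-4

    def test_cosine_component_detected(self):
        lags = np.arange(3000) * 0.1
        acf = 1.0 * np.exp(-lags / 81.0) + 0.18 * np.cos(2 * np.pi * 0.004 * lags + 0.5)
        fit = md.fit_rotation(lags, acf)
        assert fit.b > 0.1
        assert fit.tau1 == pytest.approx(81.0, rel=0.05)
        assert fit.omega == pytest.approx(0.004, rel=0.05)


class TestPCA:
    def test_orthonormal_eigenvectors(self, dimer):
        _, _, sup = dimer
        model = md.cartesian_pca(sup, exclude_residues=None)
        flat = model.eigenvectors.reshape(model.eigenvalues.size, -1)
        gram = flat @ flat.T
        assert np.allclose(gram, np.eye(gram.shape[0]), atol=1e-8)

    def test_eigenvalue_sum_equals_total_variance(self, dimer):
        _, _, sup = dimer
        model = md.cartesian_pca(sup, exclude_residues=None)
        x = (sup.coords - sup.coords.mean(axis=0)) * np.sqrt(sup.masses)[None, :, None]
        total = np.sum(x**2) / sup.n_frames
        assert model.eigenvalues.sum() == pytest.approx(total, rel=1e-8)

    def test_recovers_injected_mode(self, dimer):
        cfg, traj, sup = dimer
        model = md.cartesian_pca(sup, exclude_residues=None)
        v = cfg.modes[0].displacement
        vm = (v * np.sqrt(traj.masses)[:, None]).ravel()
        vm /= np.linalg.norm(vm)
        assert abs(model.eigenvectors[0].ravel() @ vm) > 0.95

    def test_residue_exclusion(self, dimer):
        cfg, traj, sup = dimer
        sup2 = md.Trajectory(sup.coords, sup.masses, sup.frame_interval,
                             residue_numbers=np.arange(1, 25))
        model = md.cartesian_pca(sup2, exclude_residues=(5, 8))
        assert model.selection_index.size == 24 - 4
        assert not np.any(np.isin(model.selection_index, [4, 5, 6, 7]))

    def test_rigid_body_only_trajectory_has_no_variance(self):
        cfg = default_bead_dimer_config(seed=9, n_frames=400)
        cfg.modes = []
        traj = simulate_bead_dimer(cfg)
        pre_var = np.var(traj.coords)
        sup = md.superpose(traj, cfg.coords)
        model = md.cartesian_pca(sup, exclude_residues=None)
        assert model.eigenvalues.sum() < 1e-6 * pre_var


class TestModeObservables:
    def test_uniform_translation_mode_rmsf_constant(self):
        n = 10
        ev = np.zeros((1, n, 3))
        ev[0, :, 0] = 1 / np.sqrt(n)
        model = md.PCAModel(np.zeros((n, 3)), ev, np.array([4.0]),
                            np.zeros((5, 1)), np.full(n, 2.0), 0.1)
        rmsf = md.mode_rmsf(model, 0)
        assert np.allclose(rmsf, rmsf[0])
        assert np.all(rmsf >= 0)

    def test_projection_acf_recovers_ou_time(self):
        # average over independent runs, as done for real trajectory ensembles
        taus = []
        for seed in (1, 2, 3):
            cfg = default_bead_dimer_config(seed=seed, n_frames=100_000)
            traj = simulate_bead_dimer(cfg)
            sup = md.superpose(traj, cfg.coords)
            model = md.cartesian_pca(sup, exclude_residues=None)
            _, _, tau = md.projection_acf(model, 0, max_lag=3000)
            taus.append(tau)
        assert np.mean(taus) == pytest.approx(100.0, rel=0.20)

    def test_mode_index_bounds(self, dimer):
        _, _, sup = dimer
        model = md.cartesian_pca(sup, exclude_residues=None)
        with pytest.raises(IndexError):
            md.mode_rmsf(model, model.eigenvalues.size + 1)


class TestAccessibleVolume:
    def test_isolated_attachment_is_sphere(self):
        av = md.accessible_volume(
            np.zeros((1, 3)),
            md.AVParams(attachment=0, linker_length=10.0, dye_radius=1.0,
                        grid_spacing=0.5))
        assert av == pytest.approx(4 / 3 * np.pi * 1000, rel=0.05)

    def test_enclosed_attachment_has_zero_volume(self):
        # attachment caged by a dense shell of obstacles at 3 A
        from molspan.neutron import fibonacci_sphere

        shell = 3.0 * fibonacci_sphere(400)
        coords = np.vstack([[0.0, 0, 0], shell])
        av = md.accessible_volume(
            coords, md.AVParams(attachment=0, linker_length=10.0, dye_radius=2.0,
                                grid_spacing=0.8, contact_radius=2.0))
        assert av == 0.0

    def test_monotone_in_linker_length(self, rng):
        coords = np.vstack([[0.0, 0, 0], rng.normal(0, 8, (30, 3))])
        avs = [
            md.accessible_volume(coords, md.AVParams(attachment=0, linker_length=L,
                                                     dye_radius=2.0, grid_spacing=1.0))
            for L in (6.0, 9.0, 12.0)
        ]
        assert avs[0] <= avs[1] <= avs[2]


class TestAVCorrelation:
    def test_acf_starts_at_one_and_recovers_ou_time(self, rng):
        # OU series with tau = 100 ns sampled at 0.1 ns
        tau, dt, n = 100.0, 0.1, 400_000
        rho = np.exp(-dt / tau)
        from scipy.signal import lfilter

        shocks = rng.normal(0, np.sqrt(1 - rho**2), n)
        x = lfilter([1.0], [1.0, -rho], shocks)
        lags, corr, fit = md.av_correlation(x, frame_interval=dt, max_lag=4000)
        assert corr[0] == pytest.approx(1.0, abs=1e-10)
        assert fit["tau_slow"] == pytest.approx(100.0, rel=0.15)

    def test_cross_correlation_of_independent_series(self, rng):
        a = rng.normal(0, 1, 20_000)
        b = rng.normal(0, 1, 20_000)
        lags, corr, fit = md.av_correlation(a, b, frame_interval=0.1, max_lag=100)
        assert np.all(np.abs(corr) < 4 / np.sqrt(20_000))

    def test_constant_series_rejected(self):
        with pytest.raises(ValueError):
            md.av_correlation(np.ones(100), frame_interval=0.1)


class TestANM:
    def test_two_nodes_single_spring(self):
        coords = np.array([[0.0, 0, 0], [2.0, 0, 0]])
        model = md.anm_modes(coords, cutoff=5.0, gamma=1.5)
        nonzero = model.eigenvalues[np.abs(model.eigenvalues) > 1e-10]
        assert nonzero.size == 1
        assert nonzero[0] == pytest.approx(2 * 1.5)

    def test_six_rigid_body_zero_modes(self, rng):
        coords = rng.normal(0, 5, (15, 3))
        model = md.anm_modes(coords, cutoff=30.0)
        near_zero = np.sum(np.abs(model.eigenvalues) < 1e-8 * model.eigenvalues.max())
        assert near_zero == 6

    def test_translation_in_null_space(self, rng):
        coords = rng.normal(0, 5, (12, 3))
        model = md.anm_modes(coords, cutoff=30.0)
        n = coords.shape[0]
        hessian = (model.eigenvectors * model.eigenvalues) @ model.eigenvectors.T
        t = np.tile([1.0, 0, 0], n) / np.sqrt(n)
        assert np.linalg.norm(hessian @ t) < 1e-8

    def test_disconnected_network_warns(self):
        coords = np.array([[0.0, 0, 0], [1, 0, 0], [100, 0, 0], [101, 0, 0]])
        with pytest.warns(UserWarning, match="disconnected"):
            md.anm_modes(coords, cutoff=5.0)
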