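"""Correlator estimator and FCS fit models."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from molspan.correlation import (
    CorrelationCurve,
    branch_difference,
    correlate,
    eq_log_model,
    eq_ns_model,
    fit_log,
    fit_ns,
    linear_lag_grid,
    log_lag_grid,
)

from conftest import make_stream


def brute_force_pairs(ta, tb, edges):
    """Direct O(N^2) pair histogram over arbitrary lag bins."""
    counts = np.zeros(edges.size - 1, dtype=int)
    for a in ta:
        for b in tb:
            d = b - a
            if edges[0] <= d < edges[-1]:
                counts[np.searchsorted(edges, d, side="right") - 1] += 1
    return counts


class TestCorrelator:
    @settings(deadline=None, max_examples=40)
    @given(
        n_a=st.integers(2, 60), n_b=st.integers(2, 60),
        seed=st.integers(0, 10_000),
        log_bins=st.booleans(),
    )
    def test_matches_brute_force_oracle(self, n_a, n_b, seed, log_bins):
        rng = np.random.default_rng(seed)
        t = np.sort(rng.uniform(0, 1e-3, n_a + n_b))
        ch = np.zeros(n_a + n_b, np.uint8)
        ch[rng.choice(n_a + n_b, n_b, replace=False)] = 1
        s = make_stream(t, ch, duration=1.1e-3)
        edges = log_lag_grid(1e-7, 1e-3, 4) if log_bins else linear_lag_grid(1e-4, 1e-6)
        curve = correlate(s, "DxD", edges)
        edges_ps = np.round(edges / 1e-12).astype(np.int64)
        expect = brute_force_pairs(s.macrotime[ch == 0], s.macrotime[ch == 1], edges_ps)
        assert np.array_equal(curve.n_pairs, expect)
        # normalization: counts / (rate_a rate_b width (T - tau))
        T = s.duration
        ta, tb = s.macrotime[ch == 0], s.macrotime[ch == 1]
        centers = 0.5 * (edges[:-1] + edges[1:])
        denom = ta.size * tb.size * np.diff(edges) * (T - centers) / T**2
        assert np.allclose(curve.g, expect / denom, rtol=1e-10)

    def test_poisson_stream_is_flat(self, poisson_stream):
        curve = correlate(poisson_stream, "DxD", linear_lag_grid(1e-5, 1e-7))
        resid = (curve.g - 1.0) / curve.err
        assert np.mean(np.abs(resid) < 3) > 0.98
        assert abs(np.mean(curve.g) - 1.0) < 0.02

    def test_telegraph_contrast(self, rng):
        """Photons from a symmetric two-state telegraph of brightness
        (1 +/- sigma) show zero-lag contrast 1 + sigma^2."""
        sigma, tau_flip, rate0, T = 0.6, 1e-3, 40_000.0, 40.0
        # simulate telegraph state trace on a fine grid, draw photons by thinning
        dt = 5e-5
        n = int(T / dt)
        flips = rng.random(n) < dt / (2 * tau_flip)
        state = 1.0 + sigma * np.cumprod(np.where(flips, -1.0, 1.0)) * rng.choice([-1, 1])
        lam = rate0 * state * dt
        counts = rng.poisson(lam)
        t = np.repeat(np.arange(n) * dt, counts) + rng.uniform(0, dt, counts.sum())
        t = np.sort(t)
        ch = rng.integers(0, 2, t.size)
        s = make_stream(t, ch, duration=T)
        width = 5e-5                       # lag bin well below the telegraph time
        curve = correlate(s, "DxD", np.array([0.0, width]))
        # telegraph correlation decays within the bin: average the decay factor
        decay_avg = (1 - np.exp(-width / tau_flip)) * tau_flip / width
        assert curve.g[0] == pytest.approx(1 + sigma**2 * decay_avg, abs=0.03)

    def test_empty_channel_errors(self):
        s = make_stream(np.linspace(0, 1, 50), np.zeros(50), duration=1.0)
        with pytest.raises(ValueError):
            correlate(s, "DxD", linear_lag_grid(1e-4, 1e-6))


class TestNsModel:
    def test_value_at_tau0(self):
        g = eq_ns_model(np.array([5e-9]), a=2.0, c_ab=0.4, tau_ab=3e-9,
                        c_b=0.25, tau_b=150e-9, tau_0=5e-9)
        assert g[0] == pytest.approx(2.0 * (1 - 0.4) * (1 + 0.25))

    def test_large_lag_limit(self):
        g = eq_ns_model(np.array([1.0]), a=1.7, c_ab=0.4, tau_ab=3e-9,
                        c_b=0.25, tau_b=150e-9)
        assert g[0] == pytest.approx(1.7, rel=1e-9)

    def test_global_roundtrip_noiseless(self):
        lag = linear_lag_grid(1e-6, 1e-9)
        centers = 0.5 * (lag[:-1] + lag[1:])
        truth = dict(c_b=0.2, tau_b=150e-9)
        curves = {}
        for i, pair in enumerate(("DxD", "AxA", "AxD")):
            g = eq_ns_model(centers, a=1.0 + 0.2 * i, c_ab=0.5 + 0.1 * i,
                            tau_ab=3e-9, c_b=truth["c_b"], tau_b=truth["tau_b"],
                            tau_0=2e-9)
            curves[pair] = CorrelationCurve(centers, g, np.full_like(g, 1e-3), pair)
        fit = fit_ns(curves)
        assert fit.tau_b == pytest.approx(150e-9, rel=0.01)
        for i, pair in enumerate(("DxD", "AxA", "AxD")):
            assert fit.per_curve[pair]["c_b"] == pytest.approx(0.2, rel=0.01)
            assert fit.per_curve[pair]["a"] == pytest.approx(1.0 + 0.2 * i, rel=0.01)


class TestLogModel:
    def test_short_lag_limit(self):
        g = eq_log_model(np.array([1e-15]), n=2.0, c_ab=0.3, tau_ab=3e-9,
                         c_b=0.2, tau_b=150e-9, c_t=0.1, tau_t=2e-6,
                         tau_d=1e-3, kappa=5.0)
        assert g[0] == pytest.approx(2.0 * 0.7 * 1.2 * 1.1, rel=1e-6)

    def test_diffusion_factor_half_at_tau_d(self):
        # with kappa -> infinity the axial factor is 1; at tau = tau_d the
        # lateral factor halves the amplitude
        g0 = eq_log_model(np.array([1e-15]), 1, 0, 1e-9, 0, 1e-9, 0, 1e-9, 1e-3, 1e9)
        g1 = eq_log_model(np.array([1e-3]), 1, 0, 1e-9, 0, 1e-9, 0, 1e-9, 1e-3, 1e9)
        assert g1[0] / g0[0] == pytest.approx(0.5, rel=1e-4)

    def test_reduces_to_ns_model_at_short_lags(self):
        tau = np.linspace(1e-9, 1e-6, 500)
        full = eq_log_model(tau, n=1.5, c_ab=0.4, tau_ab=3e-9, c_b=0.2,
                            tau_b=150e-9, c_t=0.0, tau_t=1e-5, tau_d=1e-2, kappa=5)
        ns = eq_ns_model(tau, a=1.5, c_ab=0.4, tau_ab=3e-9, c_b=0.2, tau_b=150e-9)
        assert np.allclose(full, ns, rtol=2e-4)

    def test_diffusion_roundtrip(self):
        edges = log_lag_grid(1e-8, 1.0, 10)
        centers = np.sqrt(edges[:-1] * edges[1:])
        g = eq_log_model(centers, n=1.0, c_ab=0.0, tau_ab=3e-9, c_b=0.0,
                         tau_b=150e-9, c_t=0.0, tau_t=2e-6, tau_d=8e-4, kappa=5.0)
        curve = CorrelationCurve(centers, g, np.full_like(g, 1e-4))
        fit = fit_log(curve, fix={"c_ab": 0.0, "c_b": 0.0, "c_t": 0.0})
        assert fit.tau_d == pytest.approx(8e-4, rel=0.02)
        assert fit.kappa == pytest.approx(5.0, rel=0.05)


class TestBranchDifference:
    def _curve(self, lag, g):
        return CorrelationCurve(lag, g, np.ones_like(g), normalization="counts")

    def test_identical_branches_give_zero(self):
        lag = np.arange(1, 1000) * 1e-9
        g = eq_ns_model(lag, 1.0, 0.5, 3e-9, 0.2, 150e-9)
        bd = branch_difference(self._curve(lag, g), self._curve(lag, g.copy()))
        assert np.all(bd.delta == 0)
        assert abs(bd.amp_slow) < 1e-6 and abs(bd.amp_fast) < 1e-6

    def test_grid_mismatch_rejected(self):
        lag = np.arange(1, 100) * 1e-9
        with pytest.raises(ValueError):
            branch_difference(self._curve(lag, np.ones(99)),
                              self._curve(lag * 2, np.ones(99)))

    def test_recovers_rotational_time_from_branch_asymmetry(self):
        """Branches carrying opposite-sign rotational contributions (a fast
        lifetime-scale term and a slow global-tumbling term) leave a
        two-exponential difference whose times are recovered."""
        lag = np.arange(1, 1001) * 1e-9
        base = (1 - 0.8 * np.exp(-lag / 3e-9)) * (1 + 0.2 * np.exp(-lag / 149e-9)) * 1e4
        rot = 1e4 * (0.05 * np.exp(-lag / 3e-9) + 0.02 * np.exp(-lag / 60e-9))
        rng = np.random.default_rng(4)
        noise = rng.normal(0, 10.0, lag.size)
        bd = branch_difference(
            CorrelationCurve(lag, base + rot + noise, np.full(lag.size, 10.0),
                             normalization="counts"),
            CorrelationCurve(lag, base - rot, np.full(lag.size, 10.0),
                             normalization="counts"),
        )
        assert bd.tau_slow == pytest.approx(60e-9, rel=0.25)
        assert bd.tau_fast == pytest.approx(3e-9, rel=0.5)
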