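"""Photon correlation functions and FCS model fits.

The correlator computes unbiased normalized intensity correlations over
arbitrary lag bins directly from photon arrival times (pair-histogram
estimator with symmetric per-bin normalization and edge correction), on
the full stream or restricted to selected bursts (pair counts aggregated
over bursts against the summed per-burst uncorrelated expectation).
Donor and acceptor autocorrelations
pair the parallel with the perpendicular detection channel to avoid
afterpulsing-like artefacts.

Fit models:

* linear-window nsFCS model
  ``G(tau) = a (1 - c_ab e^{-|tau - tau0|/tau_ab}) (1 + c_b e^{-|tau - tau0|/tau_b})``
  fitted globally over the D x D, A x A and A x D curves with a shared
  bunching time tau_b,
* the full logarithmic FCS model with triplet and 3D diffusion factors,
* branch subtraction (pq minus qp) with an unconstrained two-exponential
  fit, isolating polarization/rotation contributions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import lmfit
from numba import njit

from scipy.ndimage import uniform_filter1d

from .photons import PhotonStream, SRC_GREEN

__all__ = [
    "CorrelationCurve",
    "NsFitResult",
    "LogFitResult",
    "BranchDifference",
    "linear_lag_grid",
    "log_lag_grid",
    "correlate",
    "nsfcs_curves",
    "eq_ns_model",
    "eq_log_model",
    "fit_ns",
    "fit_log",
    "branch_difference",
]

PS = 1e-12

_PAIRS = {
    "DxD": ((0,), (1,)),          # donor parallel x donor perpendicular
    "AxA": ((2,), (3,)),          # acceptor parallel x acceptor perpendicular
    "AxD": ((2, 3), (0, 1)),      # acceptor emission x donor emission
    "DxA": ((0, 1), (2, 3)),
}


@dataclass
class CorrelationCurve:
    lag: np.ndarray                   # s, bin centers, strictly increasing
    g: np.ndarray
    err: np.ndarray
    pair: str = ""
    branch: str = "pq"
    normalization: str = "symmetric"  # estimator variant
    n_pairs: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.lag = np.asarray(self.lag, dtype=float)
        self.g = np.asarray(self.g, dtype=float)
        if np.any(np.diff(self.lag) <= 0):
            raise ValueError("lag grid must be strictly increasing")


@dataclass
class NsFitResult:
    tau_b: float                      # s, shared bunching time
    tau_b_err: float
    tau_0: float                      # s, shared channel delay
    per_curve: dict                   # label -> {a, c_ab, tau_ab, c_b}
    redchi: float
    fit_report: str = ""


@dataclass
class LogFitResult:
    n: float
    c_ab: float
    tau_ab: float
    c_b: float
    tau_b: float
    c_t: float
    tau_t: float
    tau_d: float
    kappa: float
    fixed: tuple = ()
    triplet_excluded: bool = False
    redchi: float = np.nan
    stderr: dict = field(default_factory=dict)


@dataclass
class BranchDifference:
    lag: np.ndarray
    delta: np.ndarray
    amp_slow: float
    tau_slow: float                   # s
    amp_fast: float
    tau_fast: float                   # s


# --------------------------------------------------------------------------
# pair counting
# --------------------------------------------------------------------------

@njit(cache=True)
def _pair_counts_uniform(ta, tb, e0, binw, nbins, counts):
    j_lo = 0
    hi_span = e0 + nbins * binw
    for i in range(ta.size):
        lo = ta[i] + e0
        hi = ta[i] + hi_span
        while j_lo < tb.size and tb[j_lo] < lo:
            j_lo += 1
        j = j_lo
        while j < tb.size and tb[j] < hi:
            k = (tb[j] - ta[i] - e0) // binw
            counts[k] += 1
            j += 1


@njit(cache=True)
def _pair_counts_edges(ta, tb, edges, counts):
    j_lo = 0
    lo_edge = edges[0]
    hi_edge = edges[-1]
    for i in range(ta.size):
        lo = ta[i] + lo_edge
        hi = ta[i] + hi_edge
        while j_lo < tb.size and tb[j_lo] < lo:
            j_lo += 1
        j = j_lo
        while j < tb.size and tb[j] < hi:
            d = tb[j] - ta[i]
            # binary search for the bin
            a, b = 0, edges.size - 1
            while b - a > 1:
                m = (a + b) // 2
                if d < edges[m]:
                    b = m
                else:
                    a = m
            counts[a] += 1
            j += 1


def linear_lag_grid(window: float = 1e-6, bin_width: float = 1e-9) -> np.ndarray:
    """Edges (s) of a uniform nanosecond grid covering [0, window]."""
    n = int(round(window / bin_width))
    return np.arange(n + 1) * bin_width


def log_lag_grid(lag_min: float = 1e-9, lag_max: float = 1.0, per_decade: int = 8) -> np.ndarray:
    """Logarithmically spaced lag-bin edges (s) from picoseconds to seconds."""
    n = int(np.ceil(np.log10(lag_max / lag_min) * per_decade))
    return lag_min * 10 ** (np.arange(n + 1) / per_decade)


def _poisson_errors(counts: np.ndarray, denom: np.ndarray, smooth: int = 51) -> np.ndarray:
    """Per-bin errors from locally smoothed expected pair counts.

    Using sqrt(observed counts) correlates the weight with the fluctuation
    and biases least squares low in sparse bins; smoothing the counts over
    neighboring lags estimates the expectation instead.
    """
    expected = uniform_filter1d(counts.astype(float), size=smooth, mode="nearest")
    err = np.full(counts.shape, np.nan)
    ok = denom > 0
    err[ok] = np.sqrt(np.clip(expected[ok], 0.25, None)) / denom[ok]
    return err


def _counts(ta_ps: np.ndarray, tb_ps: np.ndarray, edges_ps: np.ndarray) -> np.ndarray:
    nbins = edges_ps.size - 1
    counts = np.zeros(nbins, dtype=np.int64)
    widths = np.diff(edges_ps)
    if np.allclose(widths, widths[0]):
        _pair_counts_uniform(ta_ps, tb_ps, edges_ps[0], widths[0], nbins, counts)
    else:
        _pair_counts_edges(ta_ps, tb_ps, edges_ps.astype(np.float64), counts)
    return counts


def correlate(
    stream: PhotonStream,
    pair: str,
    lag_edges: np.ndarray | None = None,
    bursts: list | None = None,
    branch: str = "pq",
    normalization: str = "symmetric",
    green_only: bool = True,
) -> CorrelationCurve:
    """Normalized intensity correlation for a channel pair.

    ``pair`` is one of D x D, A x A, A x D (and D x A); ``branch='qp'``
    swaps the roles of the two channel groups.  With ``bursts`` given,
    photon pairs are counted only within each selected burst; the counts
    are aggregated over bursts and normalized by the summed per-burst
    uncorrelated expectation, so each pair enters with unit weight.
    ``normalization='counts'`` returns raw pair counts per bin (for
    branch subtraction).
    """
    if pair not in _PAIRS:
        raise ValueError(f"unknown pair {pair!r}")
    ch_a, ch_b = _PAIRS[pair]
    if branch == "qp":
        ch_a, ch_b = ch_b, ch_a
    elif branch != "pq":
        raise ValueError("branch must be 'pq' or 'qp'")
    if lag_edges is None:
        lag_edges = linear_lag_grid()
    edges_ps = np.round(np.asarray(lag_edges, dtype=float) / PS).astype(np.int64)
    widths_s = np.diff(lag_edges)
    centers = 0.5 * (np.asarray(lag_edges)[:-1] + np.asarray(lag_edges)[1:])

    mask_src = (stream.source == SRC_GREEN) if green_only else np.ones(len(stream), bool)
    mask_a = np.isin(stream.channel, ch_a) & mask_src
    mask_b = np.isin(stream.channel, ch_b) & mask_src

    nbins = centers.size
    if bursts is None:
        ta = stream.macrotime[mask_a]
        tb = stream.macrotime[mask_b]
        if ta.size < 2 or tb.size < 2:
            raise ValueError("fewer than 2 photons in a correlation channel")
        counts = _counts(ta, tb, edges_ps)
        if normalization == "counts":
            g = counts.astype(float)
            err = np.sqrt(np.clip(counts, 1, None)).astype(float)
        else:
            T = stream.duration
            tbar = np.clip(centers, 0.0, None)
            denom = ta.size * tb.size * widths_s * np.clip(T - tbar, 1e-12, None) / T**2
            g = counts / denom
            err = _poisson_errors(counts, denom)
        return CorrelationCurve(centers, g, err, pair, branch, normalization, counts)

    # burst-restricted: aggregate pair counts over bursts, normalized by the
    # summed per-burst uncorrelated expectation (every photon pair enters
    # with unit weight, so Poisson errors on the counts are exact)
    counts_tot = np.zeros(nbins, dtype=np.int64)
    denom_tot = np.zeros(nbins)
    n_used = 0
    tbar = np.clip(centers, 0.0, None)
    for b in bursts:
        idx = b.indices
        mt = stream.macrotime[idx]
        sel_a = mt[mask_a[idx]]
        sel_b = mt[mask_b[idx]]
        if sel_a.size < 1 or sel_b.size < 1:
            continue
        tb_dur = b.duration
        if tb_dur <= 0:
            continue
        counts_tot += _counts(sel_a, sel_b, edges_ps)
        edge = np.clip(tb_dur - tbar, 0.0, None)
        denom_tot += sel_a.size * sel_b.size * widths_s * edge / tb_dur**2
        n_used += 1
    if n_used == 0:
        raise ValueError("no usable bursts in selection")
    if normalization == "counts":
        g = counts_tot.astype(float)
        err = np.sqrt(np.clip(counts_tot, 1, None)).astype(float)
    else:
        ok = denom_tot > 0
        g = np.full(nbins, np.nan)
        g[ok] = counts_tot[ok] / denom_tot[ok]
        err = _poisson_errors(counts_tot, denom_tot)
    return CorrelationCurve(centers, g, err, pair, branch, normalization, counts_tot)


def nsfcs_curves(stream: PhotonStream, bursts: list | None = None,
                 window: float = 1e-6, bin_width: float = 1e-9) -> dict:
    """The three linear nsFCS curves (D x D, A x A, A x D) on a 1 ns grid."""
    edges = linear_lag_grid(window, bin_width)
    return {
        pair: correlate(stream, pair, edges, bursts=bursts)
        for pair in ("DxD", "AxA", "AxD")
    }


# --------------------------------------------------------------------------
# fit models
# --------------------------------------------------------------------------

def eq_ns_model(tau, a, c_ab, tau_ab, c_b, tau_b, tau_0=0.0):
    """Linear nsFCS model: antibunching dip times bunching rise around tau_0."""
    x = np.abs(tau - tau_0)
    return a * (1.0 - c_ab * np.exp(-x / tau_ab)) * (1.0 + c_b * np.exp(-x / tau_b))


def eq_log_model(tau, n, c_ab, tau_ab, c_b, tau_b, c_t, tau_t, tau_d, kappa):
    """Full FCS model: antibunching, bunching, triplet and 3D diffusion."""
    diff = (1.0 + tau / tau_d) * np.sqrt(1.0 + tau / (kappa**2 * tau_d))
    return (n * (1.0 - c_ab * np.exp(-tau / tau_ab))
            * (1.0 + c_b * np.exp(-tau / tau_b))
            * (1.0 + c_t * np.exp(-tau / tau_t)) / diff)


def fit_tail_contrast(curves: dict, tau_t: float):
    """Shared slow-bunching (triplet) contrast from tail-window correlations.

    Fits a (1 + beta tau)(1 + c_T exp(-tau/tau_T)) model per curve with the
    contrast c_T shared and the relaxation time fixed to the known dye
    constant; the linear term absorbs the slowly decaying burst-profile
    baseline.  Intended for lag windows well beyond the fast bunching
    (e.g. 0.5-25 us), where the estimate is insensitive to the
    conformational dynamics.  Returns (c_T, stderr, per-curve slopes 1/s).
    """
    p = lmfit.Parameters()
    p.add("c_t", value=0.03, min=0.0, max=2.0)
    data = {}
    for lab, c in curves.items():
        m = np.isfinite(c.g) & np.isfinite(c.err) & (c.err > 0)
        data[lab] = (c.lag[m], c.g[m], c.err[m])
        p.add(f"a_{lab}", value=float(np.median(c.g[m][-50:])), min=0.0)
        p.add(f"b_{lab}", value=0.0)

    def residual(pp):
        out = []
        for lab, (lag, g, err) in data.items():
            model = (pp[f"a_{lab}"].value * (1.0 + pp[f"b_{lab}"].value * lag)
                     * (1.0 + pp["c_t"].value * np.exp(-lag / tau_t)))
            out.append((model - g) / err)
        return np.concatenate(out)

    res = lmfit.minimize(residual, p, method="leastsq")
    if not res.success:
        raise RuntimeError(f"tail-contrast fit failed: {res.message}")
    slopes = {lab: res.params[f"b_{lab}"].value for lab in curves}
    return res.params["c_t"].value, res.params["c_t"].stderr or np.nan, slopes


def fit_ns(curves: dict, tau_b_starts: np.ndarray | None = None,
           fit_min_lag: float = 0.0,
           triplet: tuple[float, float] | None = None,
           baseline_slopes: dict | None = None) -> NsFitResult:
    """Global weighted fit of the nsFCS model to the three channel-pair
    curves with a shared bunching time (and shared channel delay tau_0).

    Multi-starts over decades of tau_b (10 ns to 1 us by default) guard
    against local minima.  ``triplet=(c_T, tau_T)`` multiplies the model
    by a triplet factor (1 + c_T exp(-|tau - tau0|/tau_T)) whose time
    constant is a beforehand-determined dye-photophysics constant, so the
    slow triplet tail inside the linear window cannot masquerade as
    bunching; pass ``c_T=None`` to fit a single shared triplet contrast
    (burst selection attenuates the equilibrium contrast by an amount
    that is not known a priori).  ``baseline_slopes`` (per curve, 1/s,
    e.g. from :func:`fit_tail_contrast`) multiplies the model by a fixed
    (1 + b tau) factor for the slowly decaying burst-profile baseline.
    """
    labels = list(curves)
    if tau_b_starts is None:
        tau_b_starts = np.array([10e-9, 50e-9, 150e-9, 400e-9, 1e-6])

    data, errs, lags = {}, {}, {}
    for lab in labels:
        c = curves[lab]
        m = np.isfinite(c.g) & np.isfinite(c.err) & (c.err > 0) & (c.lag >= fit_min_lag)
        lags[lab], data[lab], errs[lab] = c.lag[m], c.g[m], c.err[m]
        if m.sum() < 10:
            raise ValueError(f"too few usable points in curve {lab}")

    def make_params(tau_b0):
        p = lmfit.Parameters()
        p.add("tau_b", value=tau_b0, min=1e-9, max=5e-6)
        p.add("tau_0", value=0.0, min=-20e-9, max=20e-9)
        if triplet is not None and triplet[0] is None:
            p.add("c_t", value=0.05, min=0.0, max=2.0)
        for lab in labels:
            tail = np.median(data[lab][-100:]) if data[lab].size > 100 else np.median(data[lab])
            p.add(f"a_{lab}", value=max(tail, 1e-6), min=0.0)
            p.add(f"cab_{lab}", value=0.5, min=0.0, max=1.0)
            p.add(f"tab_{lab}", value=3e-9, min=0.2e-9, max=30e-9)
            p.add(f"cb_{lab}", value=0.2, min=0.0, max=5.0)
        return p

    def residual(p):
        res = []
        for lab in labels:
            model = eq_ns_model(
                lags[lab], p[f"a_{lab}"].value, p[f"cab_{lab}"].value,
                p[f"tab_{lab}"].value, p[f"cb_{lab}"].value,
                p["tau_b"].value, p["tau_0"].value,
            )
            if triplet is not None:
                c_t, tau_t = triplet
                if c_t is None:
                    c_t = p["c_t"].value
                model = model * (1.0 + c_t * np.exp(
                    -np.abs(lags[lab] - p["tau_0"].value) / tau_t))
            if baseline_slopes is not None:
                model = model * (1.0 + baseline_slopes[lab] * lags[lab])
            res.append((model - data[lab]) / errs[lab])
        return np.concatenate(res)

    best = None
    for t0 in tau_b_starts:
        try:
            out = lmfit.minimize(residual, make_params(t0), method="leastsq")
        except Exception:
            continue
        if out.success and (best is None or out.chisqr < best.chisqr):
            best = out
    if best is None:
        raise RuntimeError("global nsFCS fit failed from all starts")
    p = best.params
    per_curve = {
        lab: {
            "a": p[f"a_{lab}"].value,
            "c_ab": p[f"cab_{lab}"].value,
            "tau_ab": p[f"tab_{lab}"].value,
            "c_b": p[f"cb_{lab}"].value,
        }
        for lab in labels
    }
    return NsFitResult(
        tau_b=p["tau_b"].value,
        tau_b_err=p["tau_b"].stderr or np.nan,
        tau_0=p["tau_0"].value,
        per_curve=per_curve,
        redchi=best.redchi,
        fit_report=lmfit.fit_report(best),
    )


def fit_log(curve: CorrelationCurve, fix: dict | None = None,
            include_triplet: bool = True) -> LogFitResult:
    """Weighted fit of the full FCS model to one logarithmic curve.

    ``fix`` maps parameter names (e.g. ``tau_b``, ``tau_t``) to
    pre-determined values held constant; the triplet factor is excluded
    for cross-correlations via ``include_triplet=False``.
    """
    fix = fix or {}
    m = np.isfinite(curve.g) & np.isfinite(curve.err) & (curve.err > 0)
    lag, g, err = curve.lag[m], curve.g[m], curve.err[m]

    p = lmfit.Parameters()
    p.add("n", value=max(np.median(g[: max(g.size // 10, 1)]), 1e-6), min=0.0)
    p.add("c_ab", value=0.3, min=0.0, max=1.0)
    p.add("tau_ab", value=3e-9, min=0.1e-9, max=50e-9)
    p.add("c_b", value=0.2, min=0.0, max=5.0)
    p.add("tau_b", value=150e-9, min=5e-9, max=10e-6)
    p.add("c_t", value=0.1 if include_triplet else 0.0, min=0.0, max=5.0,
          vary=include_triplet)
    p.add("tau_t", value=3e-6, min=0.1e-6, max=100e-6, vary=include_triplet)
    p.add("tau_d", value=1e-3, min=1e-6, max=1.0)
    p.add("kappa", value=5.0, min=1.0, max=20.0)
    for name, val in fix.items():
        p[name].set(value=val, vary=False)

    def residual(pp):
        model = eq_log_model(lag, pp["n"].value, pp["c_ab"].value, pp["tau_ab"].value,
                             pp["c_b"].value, pp["tau_b"].value, pp["c_t"].value,
                             pp["tau_t"].value, pp["tau_d"].value, pp["kappa"].value)
        return (model - g) / err

    out = lmfit.minimize(residual, p, method="leastsq")
    if not out.success:
        raise RuntimeError(f"log-FCS fit failed: {out.message}")
    q = out.params
    return LogFitResult(
        n=q["n"].value, c_ab=q["c_ab"].value, tau_ab=q["tau_ab"].value,
        c_b=q["c_b"].value, tau_b=q["tau_b"].value, c_t=q["c_t"].value,
        tau_t=q["tau_t"].value, tau_d=q["tau_d"].value, kappa=q["kappa"].value,
        fixed=tuple(fix), triplet_excluded=not include_triplet, redchi=out.redchi,
        stderr={k: (q[k].stderr or np.nan) for k in q},
    )


def branch_difference(curve_pq: CorrelationCurve, curve_qp: CorrelationCurve,
                      fit_min_lag: float = 0.0) -> BranchDifference:
    """Pointwise difference of the two (unnormalized) correlation branches
    plus an unconstrained double-exponential fit of the difference.

    ``fit_min_lag`` excludes the shortest lags from the fit (the region
    around the antibunching dip is distorted by channel-delay kinks).
    """
    if curve_pq.lag.size != curve_qp.lag.size or not np.allclose(curve_pq.lag, curve_qp.lag):
        raise ValueError("branch curves must share the lag grid")
    delta_full = curve_pq.g - curve_qp.g
    sel = curve_pq.lag >= fit_min_lag
    delta = delta_full[sel]
    lag = curve_pq.lag[sel]
    err = np.sqrt(curve_pq.err**2 + curve_qp.err**2)[sel]
    weights = None
    if np.all(np.isfinite(err)) and np.all(err > 0):
        weights = 1.0 / err
    span = lag[-1]

    def model(t, a1, t1, a2, t2):
        return a1 * np.exp(-t / t1) + a2 * np.exp(-t / t2)

    m = lmfit.Model(model)
    best = None
    scale = np.max(np.abs(delta)) or 1.0
    for f_slow in (0.02, 0.05, 0.2):
        for s1 in (0.05, -0.05, 1.0, -1.0):
            for s2 in (1.0, -1.0):
                p = m.make_params(a1=s1 * scale, t1=span * f_slow,
                                  a2=s2 * scale, t2=span * 0.003)
                p["t1"].set(min=1e-12)
                p["t2"].set(min=1e-12)
                # amplitudes bounded near the data scale: excludes the
                # degenerate equal-time, opposite-sign solution family
                p["a1"].set(min=-3 * scale, max=3 * scale)
                p["a2"].set(min=-3 * scale, max=3 * scale)
                try:
                    r = m.fit(delta, p, t=lag, weights=weights)
                except Exception:
                    continue
                if best is None or r.chisqr < best.chisqr:
                    best = r
    if best is None:
        raise RuntimeError("branch-difference fit failed")
    a1, t1 = best.params["a1"].value, best.params["t1"].value
    a2, t2 = best.params["a2"].value, best.params["t2"].value
    if t1 < t2:
        a1, t1, a2, t2 = a2, t2, a1, t1
    return BranchDifference(curve_pq.lag, delta_full, a1, t1, a2, t2)
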