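"""Quasi-elastic neutron scattering models and fits.

Covers the neutron side of the integrative analysis:

* effective short-time diffusion ``D_eff(q)`` from the initial decay of
  NSE intermediate scattering functions ``I(q, tau)``,
* the rigid-body (first-cumulant) prediction of ``D_eff(q)`` for a body
  with translational and rotational diffusion coefficients,
* oligomer rescaling of diffusion coefficients,
* scattering amplitude functions ``A_k(q)`` of collective displacement
  modes (e.g. PCA eigenvectors),
* neutron backscattering (NBS) global fits yielding an apparent global
  diffusion coefficient and the confinement radius of local motions
  through the diffusion-in-a-sphere EISF.

Unit conventions: q in 1/Angstrom, lengths in Angstrom, times in ns,
diffusion coefficients in Angstrom^2/ns, energy transfer in ueV
(hbar = 0.6582 ueV ns).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import lmfit
from scipy.special import spherical_jn

__all__ = [
    "HBAR_UEV_NS",
    "IntermediateScattering",
    "DeffCurve",
    "RigidBody",
    "AmplitudeCurve",
    "NBSResult",
    "ScatteringGeometry",
    "q_from_geometry",
    "peak_length",
    "fit_initial_decay",
    "fibonacci_sphere",
    "rigid_body_deff",
    "oligomer_rescale",
    "tau_r_from_Dr",
    "amplitude_function",
    "eisf_sphere",
    "nbs_fit",
    "cm2_per_s_to_A2_per_ns",
    "A2_per_ns_to_cm2_per_s",
]

#: hbar in ueV * ns, converts relaxation rates (1/ns) to Lorentzian HWHM (ueV)
HBAR_UEV_NS = 0.6582119569


def cm2_per_s_to_A2_per_ns(d: float) -> float:
    """Convert a diffusion coefficient from cm^2/s to Angstrom^2/ns."""
    return d * 1e7


def A2_per_ns_to_cm2_per_s(d: float) -> float:
    return d * 1e-7


# --------------------------------------------------------------------------
# containers
# --------------------------------------------------------------------------

@dataclass
class IntermediateScattering:
    """Normalized intermediate scattering function I(q, tau).

    ``values`` has shape (len(q), len(tau)); ``errors`` matches or is None.
    """

    q: np.ndarray          # 1/A
    tau: np.ndarray        # ns
    values: np.ndarray     # dimensionless, I(q, 0) ~ 1
    errors: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float)
        self.tau = np.asarray(self.tau, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.q.size, self.tau.size):
            raise ValueError("values must have shape (n_q, n_tau)")
        if np.any(self.tau < 0):
            raise ValueError("tau grid must be >= 0")


@dataclass
class DeffCurve:
    """q-resolved effective diffusion coefficients."""

    q: np.ndarray
    d_eff: np.ndarray      # A^2/ns
    error: np.ndarray | None = None
    provenance: str = "experimental fit"


@dataclass
class RigidBody:
    """Coordinates + scattering lengths with rigid-body diffusion tensor.

    ``d_r`` may be a scalar (isotropic) or three principal values (1/ns);
    the rotational term is evaluated about the scattering-length-weighted
    centroid.
    """

    coords: np.ndarray          # (n, 3) Angstrom
    b: np.ndarray               # (n,) scattering lengths (arbitrary units)
    d_t: float                  # A^2/ns
    d_r: float | np.ndarray     # 1/ns

    def __post_init__(self) -> None:
        self.coords = np.atleast_2d(np.asarray(self.coords, dtype=float))
        self.b = np.asarray(self.b, dtype=float)
        if not np.all(np.isfinite(self.b)):
            raise ValueError("scattering lengths must be finite")
        dr = np.atleast_1d(np.asarray(self.d_r, dtype=float))
        if np.any(dr < 0):
            raise ValueError("D_r must be positive semidefinite")
        if self.d_t <= 0:
            raise ValueError("D_t must be > 0")

    @property
    def d_r_principal(self) -> np.ndarray:
        dr = np.atleast_1d(np.asarray(self.d_r, dtype=float))
        if dr.size == 1:
            return np.full(3, dr[0])
        if dr.size != 3:
            raise ValueError("d_r must be scalar or 3 principal values")
        return dr

    @property
    def tau_r(self) -> float:
        return tau_r_from_Dr(float(np.mean(self.d_r_principal)))


@dataclass
class AmplitudeCurve:
    """Orientation-averaged mode amplitude functions A_k(q)."""

    q: np.ndarray
    per_mode: np.ndarray        # (n_modes, n_q)
    weights: np.ndarray         # sqrt(eigenvalue) weights per mode
    combined: np.ndarray        # weighted sum over modes


@dataclass
class NBSResult:
    """Result of the conventional backscattering analysis."""

    d_app: float                # A^2/ns
    d_app_err: float
    a: float                    # confinement radius, Angstrom
    a_err: float
    gamma_int: float            # internal Lorentzian HWHM addition, ueV
    gamma_int_err: float
    eisf_model: str = "diffusion-in-a-sphere"
    per_q_widths: np.ndarray | None = None
    redchi: float = float("nan")
    fit_report: str = ""


@dataclass
class ScatteringGeometry:
    """Scattering angle / wavelength pair defining a momentum transfer."""

    two_theta_deg: float
    wavelength: float   # Angstrom

    def __post_init__(self) -> None:
        if not 0.0 < self.two_theta_deg < 180.0:
            raise ValueError("scattering angle must be in (0, 180) degrees")
        if self.wavelength <= 0:
            raise ValueError("wavelength must be > 0")


# --------------------------------------------------------------------------
# elementary relations
# --------------------------------------------------------------------------

def q_from_geometry(geom: ScatteringGeometry) -> float:
    """Momentum transfer magnitude q = 4 pi sin(2theta/2) / lambda."""
    return 4.0 * np.pi * np.sin(np.radians(geom.two_theta_deg) / 2.0) / geom.wavelength


def peak_length(q: float) -> float:
    """Real-space correlation length 2 pi / q for a feature at scattering vector q."""
    if q <= 0:
        raise ValueError("q must be > 0")
    return 2.0 * np.pi / q


def tau_r_from_Dr(d_r: float | np.ndarray) -> float | tuple[np.ndarray, float]:
    """Mean rotational correlation time tau_r = 1/(6 D_r).

    For a scalar rotational diffusion coefficient returns the scalar time.
    For per-axis coefficients returns (per-axis times, overall time), the
    overall time computed from the mean of the principal coefficients.
    """
    dr = np.atleast_1d(np.asarray(d_r, dtype=float))
    if np.any(dr <= 0):
        raise ValueError("D_r must be > 0")
    if dr.size == 1:
        return 1.0 / (6.0 * dr[0])
    per_axis = 1.0 / (6.0 * dr)
    return per_axis, 1.0 / (6.0 * dr.mean())


def oligomer_rescale(d_t: float, d_r: float, n_dimers: float) -> tuple[float, float]:
    """Rescale dimer diffusion coefficients to an n-dimer assembly.

    Stokes scaling with the effective radius R ~ n^{1/3}:
    D_t ~ 1/R => D_t/n^{1/3}; D_r ~ 1/R^3 => D_r/n.
    """
    if n_dimers < 1:
        raise ValueError("n_dimers must be >= 1")
    return d_t / n_dimers ** (1.0 / 3.0), d_r / n_dimers


# --------------------------------------------------------------------------
# NSE initial decay
# --------------------------------------------------------------------------

def fit_initial_decay(
    isf: IntermediateScattering,
    tau_max: float = 30.0,
    i_min: float = 0.3,
    min_points: int = 3,
) -> DeffCurve:
    """Fit C exp(-D_eff q^2 tau) to the initial decay of I(q, tau) per q.

    Only points with ``tau < tau_max`` (ns) and ``I > i_min`` enter the fit,
    isolating the first-cumulant regime. q values with fewer than
    ``min_points`` surviving points are omitted with a warning.
    """
    import warnings

    qs, deffs, errs = [], [], []
    for i, q in enumerate(isf.q):
        y = isf.values[i]
        mask = (isf.tau < tau_max) & (y > i_min) & (isf.tau >= 0)
        if mask.sum() < min_points:
            warnings.warn(f"q = {q:.4f} 1/A: fewer than {min_points} points survive cuts; omitted")
            continue
        t = isf.tau[mask]
        yy = y[mask]
        w = None
        if isf.errors is not None:
            e = np.clip(isf.errors[i][mask], 1e-12, None)
            w = 1.0 / e

        model = lmfit.Model(lambda tau, c, rate: c * np.exp(-rate * tau))
        # crude initial slope estimate
        pos = yy > 0
        slope = 0.1
        if pos.sum() >= 2:
            p = np.polyfit(t[pos], np.log(yy[pos]), 1)
            slope = max(-p[0], 1e-8)
        params = model.make_params(c=1.0, rate=slope)
        params["rate"].set(min=0)
        res = model.fit(yy, params, tau=t, weights=w)
        rate = res.params["rate"]
        deffs.append(rate.value / q**2)
        errs.append((rate.stderr or np.nan) / q**2)
        qs.append(q)
    return DeffCurve(np.array(qs), np.array(deffs), np.array(errs), provenance="experimental fit")


# --------------------------------------------------------------------------
# rigid-body first cumulant
# --------------------------------------------------------------------------

def fibonacci_sphere(n: int) -> np.ndarray:
    """n approximately uniformly distributed unit vectors (Fibonacci lattice)."""
    i = np.arange(n) + 0.5
    phi = np.pi * (1.0 + np.sqrt(5.0)) * i
    z = 1.0 - 2.0 * i / n
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, 1.0))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def rigid_body_deff(
    body: RigidBody,
    q_list: np.ndarray,
    n_directions: int = 256,
) -> DeffCurve:
    """First-cumulant effective diffusion D_eff(q) of a rigid diffusing body.

    For each orientation q_hat (Fibonacci-sphere average) the coherent
    first cumulant is

        Gamma(q) = D_t q^2 |F(q)|^2 + sum_i D_r,i |L_i(q)|^2

    with form factor F(q) = sum_a b_a exp(i q . r_a) and angular lever
    L(q) = sum_a b_a exp(i q . r_a) (q x r_a), coordinates relative to the
    scattering-length-weighted centroid.  D_eff = <Gamma> / (q^2 <|F|^2>).
    """
    dr = body.d_r_principal
    r = body.coords - np.average(body.coords, axis=0, weights=np.abs(body.b) + 1e-300)
    b = body.b
    dirs = fibonacci_sphere(n_directions)
    q_list = np.atleast_1d(np.asarray(q_list, dtype=float))

    deff = np.empty(q_list.size)
    for k, q in enumerate(q_list):
        qvecs = q * dirs                               # (m, 3)
        phase = np.exp(1j * qvecs @ r.T)               # (m, n)
        F = phase @ b                                  # (m,)
        s_q = np.mean(np.abs(F) ** 2)
        # q x r_a for all directions and atoms: (m, n, 3)
        cross = np.cross(qvecs[:, None, :], r[None, :, :])
        L = np.einsum("mn,n,mni->mi", phase, b, cross)  # (m, 3)
        rot = np.mean(np.sum(dr[None, :] * np.abs(L) ** 2, axis=1))
        num = body.d_t * q**2 * s_q + rot
        deff[k] = num / (q**2 * s_q)
    return DeffCurve(q_list, deff, provenance="rigid-body model")


# --------------------------------------------------------------------------
# mode amplitude functions
# --------------------------------------------------------------------------

def amplitude_function(
    eigenvectors: np.ndarray,
    coords: np.ndarray,
    b: np.ndarray,
    q_grid: np.ndarray,
    eigenvalues: np.ndarray | None = None,
    n_modes: int = 10,
    n_directions: int = 256,
    weight_mode: str = "amplitude",
) -> AmplitudeCurve:
    """Orientation-averaged scattering amplitude A_k(q) of displacement modes.

    For mode k with per-atom displacement vectors v_ka,

        A_k(q, q_hat) = | sum_a b_a exp(i q . r_a) (q_hat . v_ka) |^2

    which is averaged over a Fibonacci sphere of directions.  The combined
    curve sums the first ``n_modes`` modes weighted by sqrt(eigenvalue)
    (``weight_mode='amplitude'``) or applies the sqrt(eigenvalue) to the
    displacement vectors before squaring (``weight_mode='displacement'``).

    ``eigenvectors`` has shape (n_modes_total, n_atoms, 3) or
    (n_modes_total, 3*n_atoms).
    """
    coords = np.atleast_2d(np.asarray(coords, dtype=float))
    n_atoms = coords.shape[0]
    ev = np.asarray(eigenvectors, dtype=float)
    if ev.ndim == 2 and ev.shape[1] == 3 * n_atoms:
        ev = ev.reshape(ev.shape[0], n_atoms, 3)
    if ev.ndim == 2:  # single mode (n_atoms, 3)
        ev = ev[None, :, :]
    if ev.shape[1] != n_atoms:
        raise ValueError("mode and coordinate lengths do not match")
    n_use = min(n_modes, ev.shape[0])
    ev = ev[:n_use]
    b = np.asarray(b, dtype=float)
    q_grid = np.atleast_1d(np.asarray(q_grid, dtype=float))

    if eigenvalues is None:
        weights = np.ones(n_use)
    else:
        weights = np.sqrt(np.asarray(eigenvalues, dtype=float)[:n_use])

    dirs = fibonacci_sphere(n_directions)
    per_mode = np.empty((n_use, q_grid.size))
    for iq, q in enumerate(q_grid):
        qvecs = q * dirs
        phase = np.exp(1j * qvecs @ coords.T) * b[None, :]    # (m, n)
        for k in range(n_use):
            proj = dirs @ ev[k].T                             # (m, n) q_hat . v_ka
            if weight_mode == "displacement":
                proj = proj * weights[k]
            amp = np.sum(phase * proj, axis=1)                # (m,)
            per_mode[k, iq] = np.mean(np.abs(amp) ** 2)

    if weight_mode == "displacement":
        combined = per_mode.sum(axis=0)
    else:
        combined = (weights[:, None] * per_mode).sum(axis=0)
    return AmplitudeCurve(q_grid, per_mode, weights, combined)


# --------------------------------------------------------------------------
# backscattering (NBS)
# --------------------------------------------------------------------------

def eisf_sphere(q: np.ndarray, a: float) -> np.ndarray:
    """Diffusion-in-a-sphere EISF A0(q) = [3 j1(qa)/(qa)]^2."""
    qa = np.asarray(q, dtype=float) * a
    out = np.ones_like(qa)
    nz = np.abs(qa) > 1e-12
    out[nz] = (3.0 * spherical_jn(1, qa[nz]) / qa[nz]) ** 2
    return out


def _lorentzian(omega: np.ndarray, hwhm: float) -> np.ndarray:
    return hwhm / np.pi / (omega**2 + hwhm**2)


def _convolve_resolution(omega: np.ndarray, y: np.ndarray, res_width: float) -> np.ndarray:
    """Convolve a spectrum on a uniform omega grid with a Gaussian resolution
    of standard deviation ``res_width`` (same units as omega)."""
    domega = omega[1] - omega[0]
    half = int(np.ceil(5 * res_width / domega))
    x = np.arange(-half, half + 1) * domega
    kernel = np.exp(-0.5 * (x / res_width) ** 2)
    kernel /= kernel.sum()
    return np.convolve(y, kernel, mode="same")


def nbs_model_spectra(
    q: np.ndarray,
    omega: np.ndarray,
    d_app: float,
    a: float,
    gamma_int: float,
    amplitudes: np.ndarray,
    background: float,
    res_width: float,
) -> np.ndarray:
    """Resolution-convolved two-Lorentzian backscattering model.

    S(q, w) = R (x) beta_q [A0(q) L(G_glob) + (1 - A0(q)) L(G_glob + G_int)] + bg
    with G_glob = hbar D_app q^2 (ueV), the diffusion-in-a-sphere EISF and a
    Gaussian resolution of standard deviation ``res_width``.  The
    Lorentzian-Gaussian convolutions are evaluated analytically as Voigt
    profiles, which stays exact for linewidths far below the grid step.
    """
    from scipy.special import voigt_profile

    q = np.atleast_1d(np.asarray(q, dtype=float))
    omega = np.asarray(omega, dtype=float)
    a0 = eisf_sphere(q, a)
    out = np.empty((q.size, omega.size))
    for i in range(q.size):
        g_glob = HBAR_UEV_NS * d_app * q[i] ** 2
        y = (a0[i] * voigt_profile(omega, res_width, g_glob)
             + (1 - a0[i]) * voigt_profile(omega, res_width, g_glob + gamma_int))
        out[i] = amplitudes[i] * y + background
    return out


def nbs_fit(
    q: np.ndarray,
    omega: np.ndarray,
    spectra: np.ndarray,
    errors: np.ndarray | None,
    res_width: float,
    d_app_guess: float = 3.0,
    a_guess: float = 2.0,
    gamma_int_guess: float = 5.0,
) -> NBSResult:
    """Global 'conventional analysis' fit of backscattering spectra.

    Fits all q simultaneously with shared D_app, confinement radius a and
    internal linewidth Gamma_int, plus one amplitude per q and a flat
    background.  Requires >= 5 q values; warns when qa leaves the model's
    validity range.
    """
    import warnings

    q = np.atleast_1d(np.asarray(q, dtype=float))
    omega = np.asarray(omega, dtype=float)
    spectra = np.asarray(spectra, dtype=float)
    if q.size < 5:
        raise ValueError("nbs_fit requires at least 5 q values")
    if spectra.shape != (q.size, omega.size):
        raise ValueError("spectra must have shape (n_q, n_omega)")

    params = lmfit.Parameters()
    params.add("d_app", value=d_app_guess, min=1e-3)
    params.add("a", value=a_guess, min=0.0)
    params.add("gamma_int", value=gamma_int_guess, min=1e-6)
    params.add("background", value=float(np.median(spectra[:, [0, -1]])), min=0.0)
    for i in range(q.size):
        # integral of S over omega approximates the amplitude
        amp0 = max(np.trapezoid(spectra[i], omega), 1e-6)
        params.add(f"amp_{i}", value=amp0, min=0.0)

    weights = None
    if errors is not None:
        weights = 1.0 / np.clip(np.asarray(errors, dtype=float), 1e-12, None)

    def residual(p):
        amps = np.array([p[f"amp_{i}"].value for i in range(q.size)])
        model = nbs_model_spectra(
            q, omega, p["d_app"].value, p["a"].value, p["gamma_int"].value,
            amps, p["background"].value, res_width,
        )
        r = model - spectra
        if weights is not None:
            r = r * weights
        return r.ravel()

    res = lmfit.minimize(residual, params, method="leastsq")
    if not res.success:
        raise RuntimeError(f"NBS global fit failed: {res.message}")
    p = res.params
    if p["a"].value * q.max() > 4 * np.pi:
        warnings.warn("qa exceeds validity range of the diffusion-in-a-sphere model")
    widths = HBAR_UEV_NS * p["d_app"].value * q**2
    return NBSResult(
        d_app=p["d_app"].value,
        d_app_err=p["d_app"].stderr or float("nan"),
        a=p["a"].value,
        a_err=p["a"].stderr or float("nan"),
        gamma_int=p["gamma_int"].value,
        gamma_int_err=p["gamma_int"].stderr or float("nan"),
        per_q_widths=widths,
        redchi=res.redchi,
        fit_report=lmfit.fit_report(res),
    )
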