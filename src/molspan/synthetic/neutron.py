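"""Synthetic quasi-elastic neutron observables with known ground truth.

Generates backscattering spectra S(q, omega) and NSE intermediate
scattering functions I(q, tau) from the same models the analysis fits, so
that every fitted parameter can be checked by round-trip recovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..neutron import (
    HBAR_UEV_NS,
    IntermediateScattering,
    RigidBody,
    amplitude_function,
    nbs_model_spectra,
    rigid_body_deff,
)

__all__ = ["QENSConfig", "QENSSpectra", "NSEConfig", "simulate_qens", "simulate_nse"]


@dataclass
class QENSConfig:
    """Ground truth for a synthetic backscattering dataset.

    The default values are the fitted constants of the reference analysis:
    apparent diffusion 3.27 A^2/ns and confinement radius 1.95 A.
    """

    q: np.ndarray = field(default_factory=lambda: np.linspace(0.2, 1.8, 15))
    omega: np.ndarray = field(default_factory=lambda: np.arange(-30.0, 30.0 + 1e-9, 0.25))
    res_width: float = 0.4          # Gaussian sigma, ueV (IN16B-like)
    d_app: float = 3.27             # A^2/ns
    a: float = 1.95                 # Angstrom
    gamma_int: float = 8.0          # ueV, internal Lorentzian addition
    background: float = 1e-4
    noise_level: float = 0.01       # relative, on the peak amplitude per q
    seed: int = 0

    def __post_init__(self) -> None:
        self.q = np.atleast_1d(np.asarray(self.q, dtype=float))
        self.omega = np.asarray(self.omega, dtype=float)
        if self.q.size == 0 or self.omega.size == 0:
            raise ValueError("q and omega grids must be non-empty")
        if np.any(self.q <= 0):
            raise ValueError("q must be > 0")
        if self.res_width <= 0:
            raise ValueError("resolution width must be > 0")
        if self.a < 0:
            raise ValueError("confinement radius must be >= 0")


@dataclass
class QENSSpectra:
    q: np.ndarray
    omega: np.ndarray
    values: np.ndarray              # (n_q, n_omega)
    errors: np.ndarray
    res_width: float
    clean: np.ndarray | None = None  # pre-noise spectra


def simulate_qens(config: QENSConfig) -> QENSSpectra:
    """Resolution-convolved two-Lorentzian spectra with Gaussian noise.

    S(q, w) = R (x) [A0(q) L(D_app q^2) + (1 - A0(q)) L(D_app q^2 + G_int)] + bg,
    A0 the diffusion-in-a-sphere EISF. Per-q amplitudes are 1 (spectra
    integrate to ~1 over omega before background/noise).
    """
    rng = np.random.default_rng(config.seed)
    amps = np.ones(config.q.size)
    clean = nbs_model_spectra(
        config.q, config.omega, config.d_app, config.a, config.gamma_int,
        amps, config.background, config.res_width,
    )
    sigma = config.noise_level * clean.max(axis=1, keepdims=True)
    sigma = np.broadcast_to(np.clip(sigma, 1e-12, None), clean.shape).copy()
    values = clean + rng.normal(0.0, 1.0, clean.shape) * sigma
    return QENSSpectra(config.q, config.omega, values, sigma, config.res_width, clean=clean)


@dataclass
class NSEConfig:
    """Ground truth for a synthetic NSE dataset.

    A rigid scatterer (coordinates + scattering lengths) with isotropic or
    per-axis rotational diffusion, optionally carrying one internal
    relaxation mode whose q-signature follows its amplitude function.
    """

    coords: np.ndarray
    b: np.ndarray
    d_t: float = 3.0                # A^2/ns
    d_r: float | np.ndarray = 1.6e-3  # 1/ns
    q: np.ndarray = field(default_factory=lambda: np.linspace(0.03, 0.16, 12))
    tau: np.ndarray = field(default_factory=lambda: np.linspace(0.0, 100.0, 40))
    mode_vectors: np.ndarray | None = None   # (n_atoms, 3) displacement mode
    mode_weight: float = 0.0                 # fractional amplitude scale
    mode_tau: float = 100.0                  # ns
    noise_level: float = 0.0                 # relative on I
    seed: int = 0

    def __post_init__(self) -> None:
        self.coords = np.atleast_2d(np.asarray(self.coords, dtype=float))
        self.b = np.asarray(self.b, dtype=float)
        self.q = np.atleast_1d(np.asarray(self.q, dtype=float))
        self.tau = np.asarray(self.tau, dtype=float)
        if not np.all(np.isfinite(self.b)):
            raise ValueError("scattering lengths must be finite")
        if self.tau.size and self.tau[0] < 0:
            raise ValueError("tau grid must start >= 0")
        if self.mode_vectors is not None:
            self.mode_vectors = np.asarray(self.mode_vectors, dtype=float)
            if self.mode_vectors.shape[0] != self.coords.shape[0]:
                raise ValueError("mode vector length must match coordinates")


def simulate_nse(config: NSEConfig) -> IntermediateScattering:
    """I(q, tau) for rigid-body diffusion plus an optional internal mode.

    Rigid-only: I(q, tau) = exp(-D_eff(q) q^2 tau) with D_eff from the
    first-cumulant rigid-body model.  An internal mode relaxing with time
    mode_tau adds a faster component whose q-dependent weight is
    proportional to its amplitude function A_k(q) relative to the static
    structure factor:

        I = [(1 - w(q)) + w(q) exp(-tau/mode_tau)] exp(-D_rigid q^2 tau)
    """
    body = RigidBody(config.coords, config.b, config.d_t, config.d_r)
    rigid = rigid_body_deff(body, config.q)
    rate = rigid.d_eff * config.q**2                      # 1/ns per q

    values = np.exp(-rate[:, None] * config.tau[None, :])
    if config.mode_vectors is not None and config.mode_weight > 0:
        amp = amplitude_function(
            config.mode_vectors[None, :, :], config.coords, config.b, config.q,
            n_modes=1,
        )
        # static coherent structure factor per q for normalization
        from ..neutron import fibonacci_sphere

        dirs = fibonacci_sphere(256)
        s_q = np.empty(config.q.size)
        r = config.coords - config.coords.mean(axis=0)
        for i, q in enumerate(config.q):
            phase = np.exp(1j * (q * dirs) @ r.T) @ config.b
            s_q[i] = np.mean(np.abs(phase) ** 2)
        w = config.mode_weight * amp.per_mode[0] / s_q
        w = np.clip(w, 0.0, 0.95)
        internal = (1.0 - w)[:, None] + w[:, None] * np.exp(-config.tau[None, :] / config.mode_tau)
        values = values * internal

    errors = None
    if config.noise_level > 0:
        rng = np.random.default_rng(config.seed)
        errors = config.noise_level * np.ones_like(values)
        values = values + rng.normal(0.0, config.noise_level, values.shape)
    return IntermediateScattering(config.q, config.tau, values, errors)
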