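"""Synthetic orientation and bead-dimer trajectories with known dynamics.

Desk-scale stand-ins for microsecond MD trajectories: a rotational
Brownian axis (optionally with superimposed constant rotation) for the
inertia-axis ACF analysis, and a bead dimer carrying Ornstein-Uhlenbeck
internal modes on top of rigid-body diffusion for the PCA / AV pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from ..mdmodes import Trajectory

__all__ = [
    "OrientationConfig",
    "OrientationTrajectory",
    "BeadDimerConfig",
    "OUMode",
    "simulate_orientation",
    "simulate_bead_dimer",
    "default_rotor_config",
    "default_bead_dimer_config",
]


@dataclass
class OrientationConfig:
    """Rotational Brownian motion of a unit axis.

    ``d_r`` (1/ns) may be one value (isotropic) or three per-axis values.
    A constant angular velocity ``omega`` (rad/ns) about the lab z axis can
    be superimposed to emulate residual net rotation.  For isotropic
    diffusion the axis-component ACF decays with time constant 1/(2 D_r).
    """

    d_r: float | np.ndarray = 1.0 / (2.0 * 81.0)   # 1/ns -> 81 ns axis ACF decay
    omega: float = 0.0                              # rad/ns about lab z
    start: np.ndarray = field(default_factory=lambda: np.array([1.0, 0.0, 0.0]))
    frame_interval: float = 0.1                     # ns
    n_frames: int = 100_000
    replicas: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        dr = np.atleast_1d(np.asarray(self.d_r, dtype=float))
        if np.any(dr < 0):
            raise ValueError("D_r must be >= 0")
        if self.frame_interval <= 0:
            raise ValueError("frame interval must be > 0")
        if self.n_frames < 1:
            raise ValueError("need at least one frame")


@dataclass
class OrientationTrajectory:
    axes: np.ndarray            # (replicas, n_frames, 3) unit vectors
    frame_interval: float       # ns


def simulate_orientation(config: OrientationConfig) -> OrientationTrajectory:
    """Unit-axis trajectories under rotational diffusion (+ constant spin).

    Per step every replica's axis is rotated by an independent Gaussian
    rotation vector with per-component variance 2 D_i dt (Rodrigues
    formula, vectorized over replicas), then by omega dt about lab z.
    """
    rng = np.random.default_rng(config.seed)
    dr = np.atleast_1d(np.asarray(config.d_r, dtype=float))
    if dr.size == 1:
        dr = np.full(3, dr[0])
    dt = config.frame_interval
    sigma = np.sqrt(2.0 * dr * dt)

    n_r, n_f = config.replicas, config.n_frames
    out = np.empty((n_r, n_f, 3))
    u = np.tile(np.asarray(config.start, dtype=float) / np.linalg.norm(config.start),
                (n_r, 1))
    spin = Rotation.from_rotvec([0.0, 0.0, config.omega * dt]).as_matrix()
    diffusing = np.any(sigma > 0)
    for i in range(n_f):
        out[:, i] = u
        if diffusing:
            rv = rng.normal(0.0, 1.0, (n_r, 3)) * sigma[None, :]
            theta = np.linalg.norm(rv, axis=1, keepdims=True)
            theta = np.where(theta < 1e-15, 1e-15, theta)
            k = rv / theta
            c = np.cos(theta)
            s = np.sin(theta)
            kxu = np.cross(k, u)
            kdu = np.sum(k * u, axis=1, keepdims=True)
            u = u * c + kxu * s + k * kdu * (1.0 - c)
        if config.omega != 0.0:
            u = u @ spin.T
        u = u / np.linalg.norm(u, axis=1, keepdims=True)
    return OrientationTrajectory(out, dt)


def default_rotor_config(seed: int = 0) -> OrientationConfig:
    """Isotropic rotor whose axis ACF decays with 81 ns (D_r = 1/(2*81) per ns)."""
    return OrientationConfig(seed=seed)


@dataclass
class OUMode:
    """One internal Ornstein-Uhlenbeck mode of a bead model."""

    displacement: np.ndarray     # (n_beads, 3), unit-normalized internally
    tau: float                   # ns relaxation time
    amplitude: float             # RMS projection amplitude, Angstrom


@dataclass
class BeadDimerConfig:
    """Bead-dimer trajectory: OU internal modes on rigid-body diffusion."""

    coords: np.ndarray                       # (n_beads, 3) reference, Angstrom
    masses: np.ndarray                       # amu
    chain_ids: np.ndarray | None = None
    modes: list[OUMode] = field(default_factory=list)
    d_t: float = 3.0                         # A^2/ns
    d_r: float = 1.6e-3                      # 1/ns
    frame_interval: float = 0.1              # ns
    n_frames: int = 5_000
    seed: int = 0

    def __post_init__(self) -> None:
        self.coords = np.atleast_2d(np.asarray(self.coords, dtype=float))
        if self.coords.shape[0] < 4:
            raise ValueError("need at least 4 beads")
        self.masses = np.asarray(self.masses, dtype=float)
        for m in self.modes:
            v = np.asarray(m.displacement, dtype=float)
            if not np.all(np.isfinite(v)):
                raise ValueError("mode displacement vectors must be finite")
            if m.amplitude < 0:
                raise ValueError("mode amplitudes must be >= 0")


def simulate_bead_dimer(config: BeadDimerConfig) -> Trajectory:
    """Trajectory with exact-discretization OU mode dynamics.

    Each mode's scalar projection follows an OU process with the
    configured relaxation time and stationary RMS amplitude; frames are
    then translated/rotated by rigid-body Brownian motion so that the
    analysis chain (superposition -> PCA) has global motion to remove.
    """
    from scipy.signal import lfilter

    rng = np.random.default_rng(config.seed)
    n_frames, n_beads = config.n_frames, config.coords.shape[0]
    dt = config.frame_interval

    disp = np.zeros((n_frames, n_beads, 3))
    for mode in config.modes:
        v = np.asarray(mode.displacement, dtype=float)
        v = v / np.linalg.norm(v)
        if mode.amplitude == 0:
            continue
        rho = np.exp(-dt / mode.tau)
        noise_sd = mode.amplitude * np.sqrt(1.0 - rho**2)
        shocks = rng.normal(0.0, noise_sd, n_frames)
        shocks[0] = rng.normal(0.0, mode.amplitude)   # stationary start
        x = lfilter([1.0], [1.0, -rho], shocks)
        disp += x[:, None, None] * v[None, :, :]

    coords = config.coords[None, :, :] + disp

    # rigid-body diffusion: cumulative translation + composed random rotations
    trans_sd = np.sqrt(2.0 * config.d_t * dt)
    shifts = np.cumsum(rng.normal(0.0, trans_sd, (n_frames, 3)), axis=0)
    rot_sd = np.sqrt(2.0 * config.d_r * dt)
    if rot_sd > 0:
        rotvecs = rng.normal(0.0, rot_sd, (n_frames, 3))
        quats = _quat_walk(rotvecs)                       # (n, 4) scalar-last
        mats = Rotation.from_quat(quats).as_matrix()      # (n, 3, 3)
    else:
        mats = np.broadcast_to(np.eye(3), (n_frames, 3, 3))
    center = config.coords.mean(axis=0)
    coords = np.einsum("nij,naj->nai", mats, coords - center) + center + shifts[:, None, :]

    return Trajectory(coords, config.masses, dt, chain_ids=config.chain_ids)


def _quat_walk(rotvecs: np.ndarray) -> np.ndarray:
    """Cumulative composition of small rotations (scalar-last quaternions).

    quat[i] corresponds to rotvec[i] applied after the accumulated
    rotation of frames 0..i-1; rotvec[0] is ignored (identity start).
    """
    return _quat_walk_jit(np.ascontiguousarray(rotvecs))


try:
    from numba import njit as _njit

    @_njit(cache=True)
    def _quat_walk_jit(rotvecs):
        n = rotvecs.shape[0]
        out = np.empty((n, 4))
        qx, qy, qz, qw = 0.0, 0.0, 0.0, 1.0
        out[0, 0], out[0, 1], out[0, 2], out[0, 3] = qx, qy, qz, qw
        for i in range(1, n):
            rx, ry, rz = rotvecs[i]
            theta = np.sqrt(rx * rx + ry * ry + rz * rz)
            if theta < 1e-300:
                dx = dy = dz = 0.0
                dw = 1.0
            else:
                s = np.sin(0.5 * theta) / theta
                dx, dy, dz = rx * s, ry * s, rz * s
                dw = np.cos(0.5 * theta)
            # q_new = dq * q
            nx = dw * qx + dx * qw + dy * qz - dz * qy
            ny = dw * qy - dx * qz + dy * qw + dz * qx
            nz = dw * qz + dx * qy - dy * qx + dz * qw
            nw = dw * qw - dx * qx - dy * qy - dz * qz
            norm = np.sqrt(nx * nx + ny * ny + nz * nz + nw * nw)
            qx, qy, qz, qw = nx / norm, ny / norm, nz / norm, nw / norm
            out[i, 0], out[i, 1], out[i, 2], out[i, 3] = qx, qy, qz, qw
        return out
except Exception:  # pragma: no cover - numba is a hard dependency anyway
    def _quat_walk_jit(rotvecs):
        raise RuntimeError("numba unavailable")


def default_bead_dimer_config(seed: int = 0, n_frames: int = 20_000) -> BeadDimerConfig:
    """Two 12-bead chains with one slow breathing OU mode (tau = 100 ns).

    The mode displaces the chains toward/away from each other along the
    dimer axis (a contraction), which is orthogonal to rigid-body
    translations and rotations and therefore survives superposition.
    """
    rng = np.random.default_rng(12345)  # fixed geometry, independent of dynamics seed
    chain_a = np.column_stack([np.linspace(-30, -5, 12), rng.normal(0, 3, 12), rng.normal(0, 3, 12)])
    chain_b = np.column_stack([np.linspace(5, 30, 12), rng.normal(0, 3, 12), rng.normal(0, 3, 12)])
    coords = np.vstack([chain_a, chain_b])
    masses = np.full(24, 110.0)
    chains = np.array([0] * 12 + [1] * 12)
    v = np.zeros((24, 3))
    v[:12, 0] = -1.0
    v[12:, 0] = 1.0
    mode = OUMode(displacement=v, tau=100.0, amplitude=2.5)
    return BeadDimerConfig(coords=coords, masses=masses, chain_ids=chains,
                           modes=[mode], frame_interval=0.1, n_frames=n_frames, seed=seed)
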