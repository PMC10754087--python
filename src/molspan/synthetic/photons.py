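"""Confocal photon-stream Monte Carlo with known ground truth.

Emulates the statistical structure of single-molecule FRET photon
records: molecules diffuse through a 3D-Gaussian confocal volume
(reproducing the FCS diffusion term with diffusion time tau_D and
eccentricity kappa), carry a brightness-fluctuation (bunching) process
and a triplet on/off telegraph, are suppressed after each emission by
antibunching renewal, and are detected in four channels
(donor/acceptor x parallel/perpendicular) after FRET partitioning,
crosstalk routing and polarization-sensitive detection driven by a
hierarchical rotational-diffusion dipole (dye wobble in a local cone, a
local cone on the protein, and global tumbling).

The default configurations carry the reference ground truths: a closed
conformation with a 149 ns bunching time and an open conformation with
187 ns.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..photons import PhotonStream, SRC_GREEN
from . import _photon_kernel

__all__ = [
    "FretState",
    "PhotonStreamConfig",
    "ResourceCapError",
    "simulate_photon_stream",
    "default_closed_a_config",
    "default_open_config",
    "default_tra_config",
]


class ResourceCapError(RuntimeError):
    """Raised when a configuration would exceed the photon memory cap."""


@dataclass
class FretState:
    """One conformational species: transfer efficiency, occupancy and
    (optionally) a state-specific bunching time in seconds."""

    efficiency: float
    occupancy: float
    tau_b: float | None = None


@dataclass
class PhotonStreamConfig:
    # observation
    duration: float = 10.0               # s
    brightness: float = 5.0e6            # photons/s, molecular peak before photoselection
    brightness_red: float = 0.0          # direct acceptor excitation (PIE), photons/s
    background: float = 400.0            # photons/s per detection channel
    # diffusion
    diffusion: bool = True
    tau_d: float = 1.0e-3                # s
    kappa: float = 5.0
    mean_occupancy: float = 0.3          # mean molecules in the confocal volume
    # photophysics
    c_t: float = 0.05                    # triplet contrast
    tau_t: float = 5.0e-6                # s
    c_b: float = 0.2                     # bunching contrast
    tau_b: float = 149e-9                # s, global default bunching time
    bunching_process: str = "telegraph"  # or "ou"
    tau_ab: float = 3.0e-9               # s, antibunching renewal time
    lifetime_donor: float = 3.6e-9       # s (unquenched)
    lifetime_acceptor: float = 3.5e-9    # s
    # species
    fret_states: list[FretState] = field(default_factory=lambda: [FretState(0.63, 1.0)])
    # correction-factor counterparts realized by the detection model
    alpha: float = 0.05                  # crosstalk
    delta: float = 0.0                   # direct excitation (needs brightness_red > 0)
    gamma: float = 1.0
    beta: float = 1.0
    g_factor: float = 1.0
    channel_delays: tuple[float, float, float, float] = (0.0, 0.0, 0.0, 0.0)
    tau_0: float = 0.0                   # s, convenience: extra delay on acceptor channels
    # rotational hierarchy (polarization)
    polarization: bool = True
    rho_dye: float = 0.35e-9             # s
    rho_local: float = 3.0e-9            # s
    rho_global: float = 52e-9            # s
    a_dye: float = 0.5                   # cone plateaus of the anisotropy decay
    a_local: float = 0.5
    r_0: float = 0.4
    photoselection_weight: float = 1.0   # 1 = ideal cos^2 photoselection, 0 = saturated
    polarization_fidelity: float = 1.0   # 1 = ideal polarized detection, 0 = scrambled
    # pulsing
    excitation: str = "cw"               # or "pie"
    rep_period: float = 50e-9            # s
    # bookkeeping
    seed: int = 0
    max_photons: float = 5e7

    def __post_init__(self) -> None:
        if self.duration <= 0 or self.brightness < 0 or self.background < 0:
            raise ValueError("duration must be > 0 and rates >= 0")
        for name in ("tau_d", "tau_t", "tau_b", "tau_ab", "lifetime_donor",
                     "lifetime_acceptor", "rho_dye", "rho_local", "rho_global"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for name in ("c_t", "c_b", "alpha", "delta", "kappa"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not self.fret_states:
            raise ValueError("at least one FRET state required")
        occ = sum(s.occupancy for s in self.fret_states)
        if abs(occ - 1.0) > 1e-9:
            raise ValueError("state occupancies must sum to 1")
        for s in self.fret_states:
            if not 0.0 <= s.efficiency <= 1.0:
                raise ValueError("transfer efficiencies must lie in [0, 1]")
        if not 0.0 < self.r_0 <= 0.4:
            raise ValueError("r_0 must lie in (0, 0.4]")
        if not 0.0 <= self.a_dye <= 1.0 or not 0.0 <= self.a_local <= 1.0:
            raise ValueError("cone plateaus must lie in [0, 1]")
        if self.bunching_process not in ("telegraph", "ou"):
            raise ValueError("bunching_process must be 'telegraph' or 'ou'")
        if self.excitation not in ("cw", "pie"):
            raise ValueError("excitation must be 'cw' or 'pie'")

    # -- the analysis factors that exactly invert this generator ----------
    def correction_factors(self):
        """CorrectionFactors consistent with the generator's detection model."""
        from ..bursts import CorrectionFactors

        return CorrectionFactors(
            alpha=self.alpha, delta=self.delta, gamma=self.gamma,
            beta=self.beta, g_factor=self.g_factor, l1=0.0, l2=0.0,
        )


def _cone_sigma(a_plateau: float) -> float:
    """Per-component tangent tilt sd giving a rank-2 plateau ~ a_plateau.

    Small-tilt mapping: <P2(cos theta)> ~ 1 - 3 sigma^2 and plateau = S^2.
    """
    s_order = np.sqrt(max(a_plateau, 1e-12))
    return float(np.sqrt(max(1.0 - s_order, 0.0) / 3.0))


def _estimate_photons(config: PhotonStreamConfig) -> float:
    mean_det = config.brightness * (1 / 3) * (2 / 3) + config.brightness_red * (1 / 3) * (2 / 3)
    occ = config.mean_occupancy if config.diffusion else 1.0
    return (mean_det * occ + 4 * config.background) * config.duration


def _diffusion_profiles(config: PhotonStreamConfig, rng: np.random.Generator):
    """Brownian paths through the Gaussian focus, returned as per-molecule
    piecewise-constant brightness profiles (pruned to molecules that ever
    come near the focus)."""
    kappa = config.kappa
    box_xy, box_z = 2.5, 2.5 * kappa
    # V_box / V_eff with V_eff = (pi/2)^{3/2} w^2 w_z for exp(-2 r^2/w^2)
    v_ratio = (2 * box_xy) ** 2 * (2 * box_z) / ((np.pi / 2) ** 1.5 * kappa)
    t_mol = 10.0 * config.tau_d
    n_windows = int(np.ceil(config.duration / t_mol))
    step_s = config.tau_d / 25.0
    n_steps = int(round(t_mol / step_s))
    d_coeff = 1.0 / (4.0 * config.tau_d)     # beam-waist units^2 / s
    sd = np.sqrt(2.0 * d_coeff * step_s)

    profiles, starts = [], []
    for w in range(n_windows):
        k = rng.poisson(config.mean_occupancy * v_ratio)
        if k == 0:
            continue
        x0 = np.empty((k, 3))
        x0[:, 0] = rng.uniform(-box_xy, box_xy, k)
        x0[:, 1] = rng.uniform(-box_xy, box_xy, k)
        x0[:, 2] = rng.uniform(-box_z, box_z, k)
        steps = rng.normal(0.0, sd, (k, n_steps, 3))
        steps[:, 0, :] = 0.0
        pos = x0[:, None, :] + np.cumsum(steps, axis=1)
        b = np.exp(-2 * (pos[:, :, 0] ** 2 + pos[:, :, 1] ** 2)
                   - 2 * pos[:, :, 2] ** 2 / kappa**2)
        keep = b.max(axis=1) > 1e-3
        t0 = w * t_mol
        for bi in b[keep]:
            profiles.append(bi)
            starts.append(t0)
    return profiles, starts, step_s


def simulate_photon_stream(config: PhotonStreamConfig) -> PhotonStream:
    """Generate a sorted photon record stream from a ground-truth config."""
    est = _estimate_photons(config)
    if est > config.max_photons:
        raise ResourceCapError(
            f"expected ~{est:.2e} photons exceeds cap {config.max_photons:.2e}"
        )
    rng = np.random.default_rng(config.seed)

    if config.diffusion:
        profiles, starts_s, step_s = _diffusion_profiles(config, rng)
    else:
        # one molecule, unit brightness, present for the whole duration
        step_s = config.duration / 1000.0
        profiles = [np.ones(1000)]
        starts_s = [0.0]

    n_mol = len(profiles)
    if n_mol == 0:
        return PhotonStream(np.empty(0, np.int64), np.empty(0, np.uint8),
                            np.empty(0, np.uint16), np.empty(0, np.uint8), config.duration)

    b_len = np.array([len(p) for p in profiles], dtype=np.int64)
    b_off = np.concatenate([[0], np.cumsum(b_len[:-1])]).astype(np.int64)
    b_flat = np.concatenate(profiles)
    t_starts = np.asarray(starts_s, dtype=float) * 1e9           # ns
    seeds = rng.integers(0, 2**32 - 1, n_mol).astype(np.int64)

    # per-molecule species
    occ = np.array([s.occupancy for s in config.fret_states])
    state_idx = rng.choice(len(occ), size=n_mol, p=occ / occ.sum())
    e_fret = np.array([config.fret_states[i].efficiency for i in state_idx])
    tau_b_mol = np.array([
        (config.fret_states[i].tau_b if config.fret_states[i].tau_b is not None
         else config.tau_b) * 1e9
        for i in state_idx
    ])

    p_ct = config.alpha / (1.0 + config.alpha)
    det_d, det_a = 1.0, min(config.gamma * (1.0 - p_ct), 1.0)
    q_red = config.brightness_red * 1e-9
    q_dir = config.delta * q_red

    step_ns = step_s * 1e9
    expected_cand = (config.brightness + config.brightness_red) * 1e-9 * (1 + np.sqrt(config.c_b)) \
        * b_flat.sum() * step_ns
    cap = int(expected_cand + 6 * np.sqrt(expected_cand + 1.0) + 10_000)

    sig_loc = _cone_sigma(config.a_local) if config.polarization else 0.0
    sig_dye = _cone_sigma(config.a_dye) if config.polarization else 0.0
    args = dict(
        seeds=seeds, t_starts=t_starts, b_off=b_off, b_len=b_len, b_flat=b_flat,
        step_ns=step_ns,
        q_green=config.brightness * 1e-9, q_red=q_red, q_dir=q_dir,
        e_fret=e_fret, tau_b_mol=tau_b_mol,
        sigma_b=np.sqrt(config.c_b),
        bunching_is_ou=1 if config.bunching_process == "ou" else 0,
        p_off=config.c_t / (1.0 + config.c_t), tau_T=config.tau_t * 1e9,
        tau_ab=config.tau_ab * 1e9,
        lifetime_d=config.lifetime_donor * 1e9, lifetime_a=config.lifetime_acceptor * 1e9,
        p_ct=p_ct, det_d=det_d, det_a=det_a,
        g_par=min(1.0 / config.g_factor, 1.0),
        pol_enabled=1 if config.polarization else 0,
        d_rot_g=1.0 / (6.0 * config.rho_global * 1e9),
        sig_loc=sig_loc, tau_loc=config.rho_local * 1e9,
        sig_dye=sig_dye, tau_dye=config.rho_dye * 1e9,
        pie=1 if config.excitation == "pie" else 0,
        t_rep=config.rep_period * 1e9,
    )
    # photoselection / fidelity interpolation handled in the kernel wrapper
    while True:
        out_t = np.empty(cap, dtype=np.float64)
        out_ch = np.empty(cap, dtype=np.uint8)
        out_mt = np.empty(cap, dtype=np.float64)
        out_src = np.empty(cap, dtype=np.uint8)
        n = _photon_kernel.generate_photons(
            **args,
            w_sel=config.photoselection_weight if config.polarization else 0.0,
            v_pol=config.polarization_fidelity if config.polarization else 0.0,
            out_t=out_t, out_ch=out_ch, out_mt=out_mt, out_src=out_src,
        )
        if n >= 0:
            break
        cap *= 2

    t_ns = out_t[:n]
    ch = out_ch[:n]
    mt = out_mt[:n]
    src = out_src[:n]

    # background photons, uniform in time and channel
    n_bg = rng.poisson(config.background * config.duration, 4)
    bg_t = np.concatenate([
        rng.uniform(0.0, config.duration * 1e9, n_bg[c]) for c in range(4)
    ])
    bg_ch = np.repeat(np.arange(4, dtype=np.uint8), n_bg)
    if config.excitation == "pie":
        bg_mt = rng.uniform(0.0, config.rep_period * 1e9, bg_t.size)
    else:
        bg_mt = np.zeros(bg_t.size)
    t_ns = np.concatenate([t_ns, bg_t])
    ch = np.concatenate([ch, bg_ch])
    mt = np.concatenate([mt, bg_mt])
    src = np.concatenate([src, np.full(bg_t.size, SRC_GREEN, dtype=np.uint8)])

    # channel delays (instrumental), tau_0 adds to acceptor channels
    delays = np.asarray(config.channel_delays, dtype=float) * 1e9
    delays[2:] += config.tau_0 * 1e9
    t_ns = t_ns + delays[ch]

    order = np.argsort(t_ns, kind="stable")
    macro_ps = np.round(t_ns[order] * 1000.0).astype(np.int64)
    micro_ps = np.clip(np.round(mt[order] * 1000.0), 0, 65535).astype(np.uint16)
    return PhotonStream(macro_ps, ch[order].astype(np.uint8), micro_ps,
                        src[order].astype(np.uint8), config.duration)


# --------------------------------------------------------------------------
# reference configurations (ground truths = the reference fitted values)
# --------------------------------------------------------------------------

def default_closed_a_config(seed: int = 0, duration: float = 30.0) -> PhotonStreamConfig:
    """Closed conformation A under saturating nucleotide: single species at
    E = 0.63 with the 149 ns bunching time.

    Photoselection weight and polarization fidelity are reduced to emulate
    partially saturated excitation and high-NA depolarized collection, so
    rotational intensity modulation stays small next to the conformational
    bunching term, as observed.
    """
    return PhotonStreamConfig(
        duration=duration,
        seed=seed,
        fret_states=[FretState(0.63, 1.0)],
        tau_b=149e-9,
        c_b=0.2,
        photoselection_weight=0.1,
        polarization_fidelity=0.15,
    )


def default_open_config(seed: int = 0, duration: float = 30.0) -> PhotonStreamConfig:
    """Open-state sample (no nucleotide): mostly open molecules at E = 0.13
    with a 187 ns bunching time, plus a residual closed subpopulation.

    The excitation power is higher than for the closed-state sample: the
    donor-dominated signal at E = 0.13 otherwise carries about half the
    pair statistics of the closed state for equal measurement time.
    """
    return PhotonStreamConfig(
        duration=duration,
        seed=seed,
        brightness=7.1e6,
        fret_states=[
            FretState(0.13, 0.85, tau_b=187e-9),
            FretState(0.63, 0.15, tau_b=149e-9),
        ],
        tau_b=187e-9,
        c_b=0.2,
        photoselection_weight=0.1,
        polarization_fidelity=0.15,
    )


def default_tra_config(seed: int = 0, duration: float = 10.0) -> PhotonStreamConfig:
    """Pulsed-interleaved-excitation stream for time-resolved anisotropy:
    three conformational states, ideal photoselection and polarized
    detection, reference rotational hierarchy (0.35 / 3 / 52 ns)."""
    return PhotonStreamConfig(
        duration=duration,
        seed=seed,
        excitation="pie",
        brightness_red=1.1e6,
        fret_states=[
            FretState(0.13, 0.25),
            FretState(0.63, 0.5),
            FretState(0.93, 0.25),
        ],
        rho_dye=0.35e-9,
        rho_local=3.0e-9,
        rho_global=52e-9,
        a_dye=0.5,
        a_local=0.5,
        photoselection_weight=1.0,
        polarization_fidelity=1.0,
    )
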