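"""Numba event loop for the confocal photon-stream Monte Carlo.

All times are in ns inside the kernel.  Each molecule is processed
independently with its own RNG seed, so streams are reproducible
regardless of batching.  Candidate photons are drawn from a Poisson
process at the (thinning) ceiling rate; acceptance applies, in order, the
molecule's diffusion brightness profile, the brightness-fluctuation
(bunching) process, the triplet telegraph, antibunching renewal,
excitation photoselection and polarized detection.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# channel codes (must match molspan.photons)
_DP, _DS, _AP, _AS = 0, 1, 2, 3


@njit(cache=True, inline="always")
def _exprand(mean):
    return -mean * np.log(np.random.random())


@njit(cache=True, inline="always")
def _rand_unit_vector():
    while True:
        x = 2.0 * np.random.random() - 1.0
        y = 2.0 * np.random.random() - 1.0
        z = 2.0 * np.random.random() - 1.0
        r2 = x * x + y * y + z * z
        if 1e-12 < r2 <= 1.0:
            r = np.sqrt(r2)
            return x / r, y / r, z / r


@njit(cache=True, inline="always")
def _diffuse_axis(ax, ay, az, d_rot, dt):
    """Brownian step of a unit axis on the sphere (resample if decorrelated)."""
    if d_rot <= 0.0 or dt <= 0.0:
        return ax, ay, az
    if d_rot * dt > 5.0:          # many relaxation times: uniform resample
        return _rand_unit_vector()
    sd = np.sqrt(2.0 * d_rot * dt)
    nx = ax + sd * np.random.normal()
    ny = ay + sd * np.random.normal()
    nz = az + sd * np.random.normal()
    r = np.sqrt(nx * nx + ny * ny + nz * nz)
    if r < 1e-12:
        return _rand_unit_vector()
    return nx / r, ny / r, nz / r


@njit(cache=True, inline="always")
def _ou_step(x, tau, sigma, dt):
    if tau <= 0.0 or sigma <= 0.0:
        return 0.0
    if dt <= 0.0:
        return x
    if dt > 10.0 * tau:
        return sigma * np.random.normal()
    rho = np.exp(-dt / tau)
    return rho * x + sigma * np.sqrt(1.0 - rho * rho) * np.random.normal()


@njit(cache=True, inline="always")
def _dipole(ax, ay, az, t1, t2):
    """Dipole = global axis tilted by a 2D wobble (t1, t2) in its tangent plane."""
    # tangent frame from the axis (deterministic)
    if abs(az) < 0.9:
        # cross(a, z) = (ay, -ax, 0)
        e1x, e1y, e1z = ay, -ax, 0.0
    else:
        # cross(a, x) = (0, az, -ay)
        e1x, e1y, e1z = 0.0, az, -ay
    n1 = np.sqrt(e1x * e1x + e1y * e1y + e1z * e1z)
    e1x, e1y, e1z = e1x / n1, e1y / n1, e1z / n1
    e2x = ay * e1z - az * e1y
    e2y = az * e1x - ax * e1z
    e2z = ax * e1y - ay * e1x
    ux = ax + t1 * e1x + t2 * e2x
    uy = ay + t1 * e1y + t2 * e2y
    uz = az + t1 * e1z + t2 * e2z
    r = np.sqrt(ux * ux + uy * uy + uz * uz)
    return ux / r, uy / r, uz / r


@njit(cache=True)
def generate_photons(
    seeds,            # (n_mol,) uint32-compatible int64
    t_starts,         # (n_mol,) ns
    b_off, b_len,     # slices into b_flat
    b_flat,           # brightness profile values in [0, 1]
    step_ns,          # brightness step duration
    q_green, q_red, q_dir,    # candidate peak rates, photons/ns (pre-selection)
    e_fret,           # (n_mol,)
    tau_b_mol,        # (n_mol,) bunching time ns
    sigma_b,          # telegraph amplitude sqrt(c_b)
    bunching_is_ou,   # 0 telegraph / 1 lognormal-OU
    p_off, tau_T,     # triplet off-fraction and relaxation time
    tau_ab,           # antibunching renewal time ns
    lifetime_d,       # unquenched donor lifetime ns
    lifetime_a,       # acceptor lifetime ns
    p_ct,             # crosstalk routing probability donor->acceptor channel
    det_d, det_a,     # detection efficiency per emitting species
    g_par,            # parallel-channel relative detection efficiency (1/G)
    pol_enabled,
    d_rot_g,          # global rotational diffusion, rad^2/ns
    sig_loc, tau_loc, # local wobble OU (per tangent component)
    sig_dye, tau_dye, # dye wobble OU
    pie, t_rep,       # pulsed-interleaved mode, repetition period ns
    w_sel,            # photoselection weight: 1 ideal cos^2, 0 saturated
    v_pol,            # polarized-detection fidelity: 1 ideal, 0 scrambled
    out_t, out_ch, out_mt, out_src,
):
    qs = q_green + q_red + q_dir
    # thinning ceiling of the bunching multiplier
    if bunching_is_ou == 1:
        var = np.log(1.0 + sigma_b * sigma_b)   # interpret sigma_b^2 as contrast
        sd_ln = np.sqrt(var)
        bmax = np.exp(3.0 * sd_ln - 0.5 * var)
    else:
        bmax = 1.0 + sigma_b
    count = 0
    cap = out_t.size

    for m in range(seeds.size):
        np.random.seed(np.uint32(seeds[m]))
        t0 = t_starts[m]
        off = b_off[m]
        e = e_fret[m]
        tau_b = tau_b_mol[m]
        tau_dq = lifetime_d * (1.0 - e) if e < 1.0 else 0.05  # quenched donor lifetime

        # bunching state
        bs = 1.0 if np.random.random() < 0.5 else -1.0
        ou_x = sd_ln * np.random.normal() if bunching_is_ou == 1 else 0.0
        next_flip_b = t0 + _exprand(2.0 * tau_b)
        last_b_eval = t0
        # triplet state
        trip_on = np.random.random() >= p_off
        if tau_T > 0.0 and p_off > 0.0:
            mean_wait = tau_T / p_off if trip_on else tau_T / (1.0 - p_off)
            next_flip_t = t0 + _exprand(mean_wait)
        else:
            next_flip_t = t0 + 1e18
        # dipoles
        dax, day, daz = _rand_unit_vector()   # donor global axis
        aax, aay, aaz = _rand_unit_vector()   # acceptor global axis
        dl1 = sig_loc * np.random.normal()
        dl2 = sig_loc * np.random.normal()
        dd1 = sig_dye * np.random.normal()
        dd2 = sig_dye * np.random.normal()
        al1 = sig_loc * np.random.normal()
        al2 = sig_loc * np.random.normal()
        ad1 = sig_dye * np.random.normal()
        ad2 = sig_dye * np.random.normal()
        t_pol = t0

        last_exc = t0 - 1e9

        for j in range(b_len[m]):
            b = b_flat[off + j]
            lam = qs * b * bmax
            if lam <= 0.0:
                continue
            t = t0 + j * step_ns
            t_end = t + step_ns
            mean_wait_cand = 1.0 / lam
            while True:
                t += _exprand(mean_wait_cand)
                if t >= t_end:
                    break
                # advance bunching process
                if bunching_is_ou == 1:
                    ou_x = _ou_step(ou_x, tau_b, sd_ln, t - last_b_eval)
                    last_b_eval = t
                    bf = np.exp(ou_x - 0.5 * var)
                    if bf > bmax:
                        bf = bmax
                else:
                    if t - next_flip_b > 15.0 * tau_b:
                        bs = 1.0 if np.random.random() < 0.5 else -1.0
                        next_flip_b = t + _exprand(2.0 * tau_b)
                    else:
                        while next_flip_b <= t:
                            bs = -bs
                            next_flip_b += _exprand(2.0 * tau_b)
                    bf = 1.0 + sigma_b * bs
                # advance triplet
                if p_off > 0.0:
                    if t - next_flip_t > 15.0 * tau_T:
                        trip_on = np.random.random() >= p_off
                        mean_wait = tau_T / p_off if trip_on else tau_T / (1.0 - p_off)
                        next_flip_t = t + _exprand(mean_wait)
                    else:
                        while next_flip_t <= t:
                            trip_on = not trip_on
                            mean_wait = tau_T / p_off if trip_on else tau_T / (1.0 - p_off)
                            next_flip_t += _exprand(mean_wait)
                    if not trip_on:
                        continue
                p = bf / bmax
                # antibunching renewal
                if tau_ab > 0.0:
                    p *= 1.0 - np.exp(-(t - last_exc) / tau_ab)
                # source of excitation
                r = np.random.random() * qs
                src_red = r >= q_green + q_dir        # red laser
                acc_direct = (r >= q_green) and (not src_red)

                # evolve dipoles to excitation time
                if pol_enabled == 1:
                    dt_pol = t - t_pol
                    dax, day, daz = _diffuse_axis(dax, day, daz, d_rot_g, dt_pol)
                    aax, aay, aaz = _diffuse_axis(aax, aay, aaz, d_rot_g, dt_pol)
                    dl1 = _ou_step(dl1, tau_loc, sig_loc, dt_pol)
                    dl2 = _ou_step(dl2, tau_loc, sig_loc, dt_pol)
                    dd1 = _ou_step(dd1, tau_dye, sig_dye, dt_pol)
                    dd2 = _ou_step(dd2, tau_dye, sig_dye, dt_pol)
                    al1 = _ou_step(al1, tau_loc, sig_loc, dt_pol)
                    al2 = _ou_step(al2, tau_loc, sig_loc, dt_pol)
                    ad1 = _ou_step(ad1, tau_dye, sig_dye, dt_pol)
                    ad2 = _ou_step(ad2, tau_dye, sig_dye, dt_pol)
                    t_pol = t
                    if src_red or acc_direct:
                        ux, uy, uz = _dipole(aax, aay, aaz, al1 + ad1, al2 + ad2)
                    else:
                        ux, uy, uz = _dipole(dax, day, daz, dl1 + dd1, dl2 + dd2)
                    # photoselection along lab z (partially saturated)
                    p *= (1.0 - w_sel) / 3.0 + w_sel * uz * uz

                if np.random.random() >= p:
                    continue

                # -- an excitation happened --
                last_exc = t
                is_acceptor_emission = src_red or acc_direct
                micro = 0.0
                if not is_acceptor_emission:
                    if np.random.random() < e:
                        is_acceptor_emission = True
                        micro = _exprand(tau_dq) + _exprand(lifetime_a)
                    else:
                        micro = _exprand(tau_dq)
                else:
                    micro = _exprand(lifetime_a)

                det = det_a if is_acceptor_emission else det_d
                if det < 1.0 and np.random.random() >= det:
                    continue

                # polarization channel from the emitting dipole at emission time
                par = True
                if pol_enabled == 1:
                    if is_acceptor_emission:
                        aax, aay, aaz = _diffuse_axis(aax, aay, aaz, d_rot_g, micro)
                        al1 = _ou_step(al1, tau_loc, sig_loc, micro)
                        al2 = _ou_step(al2, tau_loc, sig_loc, micro)
                        ad1 = _ou_step(ad1, tau_dye, sig_dye, micro)
                        ad2 = _ou_step(ad2, tau_dye, sig_dye, micro)
                        ux, uy, uz = _dipole(aax, aay, aaz, al1 + ad1, al2 + ad2)
                    else:
                        dax, day, daz = _diffuse_axis(dax, day, daz, d_rot_g, micro)
                        dl1 = _ou_step(dl1, tau_loc, sig_loc, micro)
                        dl2 = _ou_step(dl2, tau_loc, sig_loc, micro)
                        dd1 = _ou_step(dd1, tau_dye, sig_dye, micro)
                        dd2 = _ou_step(dd2, tau_dye, sig_dye, micro)
                        ux, uy, uz = _dipole(dax, day, daz, dl1 + dd1, dl2 + dd2)
                    t_pol = t + micro
                    w_par = uz * uz
                    w_perp = ux * ux
                    tot = w_par + w_perp
                    # depolarized high-NA collection interpolates to isotropic
                    tot_eff = (1.0 - v_pol) * (2.0 / 3.0) + v_pol * tot
                    if np.random.random() >= tot_eff:   # polarized collection losses
                        continue
                    par = np.random.random() < (1.0 - v_pol) * 0.5 + v_pol * w_par / tot
                else:
                    par = np.random.random() < 0.5
                if par and g_par < 1.0 and np.random.random() >= g_par:
                    continue

                # crosstalk routing: donor emission spilling into acceptor channel
                channel_acceptor = is_acceptor_emission
                if (not is_acceptor_emission) and p_ct > 0.0 and np.random.random() < p_ct:
                    channel_acceptor = True

                if pie == 1:
                    pulse = np.floor(t / t_rep) * t_rep
                    exc_in_period = 0.0 if not src_red else 0.5 * t_rep
                    macro = pulse + exc_in_period + micro
                    mt = exc_in_period + micro
                else:
                    macro = t + micro
                    mt = micro

                if count < cap:
                    out_t[count] = macro
                    ch = (_AP if par else _AS) if channel_acceptor else (_DP if par else _DS)
                    out_ch[count] = ch
                    out_mt[count] = mt
                    out_src[count] = 1 if src_red else 0
                    count += 1
                else:
                    return -1   # buffer overflow: caller retries with larger buffer
    return count
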