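"""Numba kernels for force evaluation and Brownian propagation.

All kernels are deterministic: bead-model kernels consume pre-generated
Gaussian noise arrays (drawn from a NumPy Generator by the caller), and the
brute-force 1-D kernel seeds numba's internal RNG explicitly.
"""

from __future__ import annotations

import numpy as np
from numba import njit

STATUS_OK = 0
STATUS_NONFINITE = 1
STATUS_BLOWUP = 2


@njit(cache=False)
def forces_energy(x, bond_idx, bond_r0, bond_k,
                  angle_idx, angle_theta0, angle_k,
                  dih_idx, dih_phi0, dih_k1, dih_k3,
                  con_i, con_j, con_r0, con_eps,
                  ev_idx, ev_eps, ev_sigma, r_floor, f):
    """Fill ``f`` with forces and return the potential energy.

    Terms: harmonic bonds/angles, 1+3-fold periodic dihedrals, 12-10 native
    contact wells, r^-12 excluded volume.  Returns +inf if any interacting
    pair falls below ``r_floor``.
    """
    n = x.shape[0]
    for a in range(n):
        f[a, 0] = 0.0
        f[a, 1] = 0.0
        f[a, 2] = 0.0
    e = 0.0

    # bonds: U = k (r - r0)^2
    for m in range(bond_idx.shape[0]):
        i = bond_idx[m, 0]
        j = bond_idx[m, 1]
        dx = x[j, 0] - x[i, 0]
        dy = x[j, 1] - x[i, 1]
        dz = x[j, 2] - x[i, 2]
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        if r < 1e-10:
            return np.inf
        dr = r - bond_r0[m]
        e += bond_k[m] * dr * dr
        c = -2.0 * bond_k[m] * dr / r
        f[j, 0] += c * dx
        f[j, 1] += c * dy
        f[j, 2] += c * dz
        f[i, 0] -= c * dx
        f[i, 1] -= c * dy
        f[i, 2] -= c * dz

    # angles: U = k (cos(theta) - cos(theta0))^2 — the cosine-harmonic
    # form has a regular gradient at theta = pi, unlike acos-based angles
    for m in range(angle_idx.shape[0]):
        i = angle_idx[m, 0]
        j = angle_idx[m, 1]
        k = angle_idx[m, 2]
        ux = x[i, 0] - x[j, 0]
        uy = x[i, 1] - x[j, 1]
        uz = x[i, 2] - x[j, 2]
        vx = x[k, 0] - x[j, 0]
        vy = x[k, 1] - x[j, 1]
        vz = x[k, 2] - x[j, 2]
        ru = np.sqrt(ux * ux + uy * uy + uz * uz)
        rv = np.sqrt(vx * vx + vy * vy + vz * vz)
        if ru < 1e-10 or rv < 1e-10:
            return np.inf
        c = (ux * vx + uy * vy + uz * vz) / (ru * rv)
        if c > 1.0:
            c = 1.0
        if c < -1.0:
            c = -1.0
        dc = c - np.cos(angle_theta0[m])
        e += angle_k[m] * dc * dc
        dudc = 2.0 * angle_k[m] * dc
        # dc/dx_i = (v_hat - c u_hat) / |u| ; dc/dx_k = (u_hat - c v_hat) / |v|
        gi = -dudc / ru
        gk = -dudc / rv
        fix = gi * (vx / rv - c * ux / ru)
        fiy = gi * (vy / rv - c * uy / ru)
        fiz = gi * (vz / rv - c * uz / ru)
        fkx = gk * (ux / ru - c * vx / rv)
        fky = gk * (uy / ru - c * vy / rv)
        fkz = gk * (uz / ru - c * vz / rv)
        f[i, 0] += fix
        f[i, 1] += fiy
        f[i, 2] += fiz
        f[k, 0] += fkx
        f[k, 1] += fky
        f[k, 2] += fkz
        f[j, 0] -= fix + fkx
        f[j, 1] -= fiy + fky
        f[j, 2] -= fiz + fkz

    # dihedrals: U = k1 (1 - cos(phi - phi0)) + k3 (1 - cos 3(phi - phi0))
    for m in range(dih_idx.shape[0]):
        i = dih_idx[m, 0]
        j = dih_idx[m, 1]
        k = dih_idx[m, 2]
        l = dih_idx[m, 3]
        b1x = x[j, 0] - x[i, 0]
        b1y = x[j, 1] - x[i, 1]
        b1z = x[j, 2] - x[i, 2]
        b2x = x[k, 0] - x[j, 0]
        b2y = x[k, 1] - x[j, 1]
        b2z = x[k, 2] - x[j, 2]
        b3x = x[l, 0] - x[k, 0]
        b3y = x[l, 1] - x[k, 1]
        b3z = x[l, 2] - x[k, 2]
        n1x = b1y * b2z - b1z * b2y
        n1y = b1z * b2x - b1x * b2z
        n1z = b1x * b2y - b1y * b2x
        n2x = b2y * b3z - b2z * b3y
        n2y = b2z * b3x - b2x * b3z
        n2z = b2x * b3y - b2y * b3x
        n1sq = n1x * n1x + n1y * n1y + n1z * n1z
        n2sq = n2x * n2x + n2y * n2y + n2z * n2z
        b2n = np.sqrt(b2x * b2x + b2y * b2y + b2z * b2z)
        b1sq = b1x * b1x + b1y * b1y + b1z * b1z
        b3sq = b3x * b3x + b3y * b3y + b3z * b3z
        b2sq = b2n * b2n
        # near-collinear geometry: the torsion (and its gradient) becomes
        # singular; the term is smoothly negligible there and is skipped
        if n1sq < 1e-2 * b1sq * b2sq or n2sq < 1e-2 * b2sq * b3sq \
                or b2n < 1e-10:
            continue
        m1x = n1y * n2z - n1z * n2y
        m1y = n1z * n2x - n1x * n2z
        m1z = n1x * n2y - n1y * n2x
        sy = (m1x * b2x + m1y * b2y + m1z * b2z) / b2n
        sx = n1x * n2x + n1y * n2y + n1z * n2z
        phi = np.arctan2(sy, sx)
        dphi = phi - dih_phi0[m]
        e += dih_k1[m] * (1.0 - np.cos(dphi)) \
            + dih_k3[m] * (1.0 - np.cos(3.0 * dphi))
        dudphi = dih_k1[m] * np.sin(dphi) \
            + 3.0 * dih_k3[m] * np.sin(3.0 * dphi)
        # dphi/dr_i = -(|b2|/|n1|^2) n1 ; dphi/dr_l = (|b2|/|n2|^2) n2
        gi = dudphi * b2n / n1sq
        gl = -dudphi * b2n / n2sq
        fix = gi * n1x
        fiy = gi * n1y
        fiz = gi * n1z
        flx = gl * n2x
        fly = gl * n2y
        flz = gl * n2z
        t = (b1x * b2x + b1y * b2y + b1z * b2z) / (b2n * b2n)
        s2 = (b3x * b2x + b3y * b2y + b3z * b2z) / (b2n * b2n)
        # F_j = -(1+t) F_i + s F_l ; F_k = t F_i - (1+s) F_l
        fjx = -(1.0 + t) * fix + s2 * flx
        fjy = -(1.0 + t) * fiy + s2 * fly
        fjz = -(1.0 + t) * fiz + s2 * flz
        fkx = t * fix - (1.0 + s2) * flx
        fky = t * fiy - (1.0 + s2) * fly
        fkz = t * fiz - (1.0 + s2) * flz
        f[i, 0] += fix
        f[i, 1] += fiy
        f[i, 2] += fiz
        f[j, 0] += fjx
        f[j, 1] += fjy
        f[j, 2] += fjz
        f[k, 0] += fkx
        f[k, 1] += fky
        f[k, 2] += fkz
        f[l, 0] += flx
        f[l, 1] += fly
        f[l, 2] += flz

    # native contacts: U = eps (5 q^12 - 6 q^10), q = r0 / r
    for m in range(con_i.shape[0]):
        i = con_i[m]
        j = con_j[m]
        dx = x[j, 0] - x[i, 0]
        dy = x[j, 1] - x[i, 1]
        dz = x[j, 2] - x[i, 2]
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        if r < r_floor:
            return np.inf
        q = con_r0[m] / r
        q2 = q * q
        q10 = q2 * q2 * q2 * q2 * q2
        q12 = q10 * q2
        e += con_eps[m] * (5.0 * q12 - 6.0 * q10)
        dudr = con_eps[m] * 60.0 * (q10 - q12) / r
        c = -dudr / r
        f[j, 0] += c * dx
        f[j, 1] += c * dy
        f[j, 2] += c * dz
        f[i, 0] -= c * dx
        f[i, 1] -= c * dy
        f[i, 2] -= c * dz

    # excluded volume: U = eps_ev [(sigma/r)^12 - 2^-12], truncated and
    # shifted to zero at r = 2 sigma (the residual force there is ~1e-4
    # eps/Å, far below thermal forces)
    ev_cut2 = 4.0 * ev_sigma * ev_sigma
    ev_shift = ev_eps / 4096.0
    for m in range(ev_idx.shape[0]):
        i = ev_idx[m, 0]
        j = ev_idx[m, 1]
        dx = x[j, 0] - x[i, 0]
        dy = x[j, 1] - x[i, 1]
        dz = x[j, 2] - x[i, 2]
        r2 = dx * dx + dy * dy + dz * dz
        if r2 > ev_cut2:
            continue
        if r2 < r_floor * r_floor:
            return np.inf
        q2 = (ev_sigma * ev_sigma) / r2
        q12 = q2 * q2 * q2 * q2 * q2 * q2
        u = ev_eps * q12
        e += u - ev_shift
        c = 12.0 * u / r2
        f[j, 0] += c * dx
        f[j, 1] += c * dy
        f[j, 2] += c * dz
        f[i, 0] -= c * dx
        f[i, 1] -= c * dy
        f[i, 2] -= c * dz

    return e


@njit(cache=False)
def bd_segment(x, n_steps, coef, noise, sample_stride, max_step,
               bond_idx, bond_r0, bond_k,
               angle_idx, angle_theta0, angle_k,
               dih_idx, dih_phi0, dih_k1, dih_k3,
               con_i, con_j, con_r0, con_eps,
               ev_idx, ev_eps, ev_sigma, r_floor,
               f, samples):
    """Overdamped Brownian propagation of one fixed-length segment.

    x is modified in place; ``samples[s]`` receives the configuration after
    step (s+1) * sample_stride.  ``noise`` holds pre-scaled Gaussian
    displacements of shape (n_steps, n, 3).  Returns a status code.
    """
    n = x.shape[0]
    s_out = 0
    for step in range(n_steps):
        e = forces_energy(x, bond_idx, bond_r0, bond_k,
                          angle_idx, angle_theta0, angle_k,
                          dih_idx, dih_phi0, dih_k1, dih_k3,
                          con_i, con_j, con_r0, con_eps,
                          ev_idx, ev_eps, ev_sigma, r_floor, f)
        if not np.isfinite(e):
            return STATUS_NONFINITE
        for a in range(n):
            ddx = coef * f[a, 0] + noise[step, a, 0]
            ddy = coef * f[a, 1] + noise[step, a, 1]
            ddz = coef * f[a, 2] + noise[step, a, 2]
            if ddx * ddx + ddy * ddy + ddz * ddz > max_step * max_step:
                return STATUS_BLOWUP
            x[a, 0] += ddx
            x[a, 1] += ddy
            x[a, 2] += ddz
        if (step + 1) % sample_stride == 0:
            for a in range(n):
                samples[s_out, a, 0] = x[a, 0]
                samples[s_out, a, 1] = x[a, 1]
                samples[s_out, a, 2] = x[a, 2]
            s_out += 1
    return STATUS_OK


# ---------------------------------------------------------------------------
# 1-D double/triple-well kernels
# ---------------------------------------------------------------------------

@njit(cache=False, inline="always")
def well_force(xx, h, a, d, w):
    """Force of V(x) = h ((x/a)^2 - 1)^2 - d exp(-x^2 / 2 w^2)."""
    u = xx / a
    fq = -4.0 * h * u * (u * u - 1.0) / a
    if d != 0.0:
        fq += -d * xx / (w * w) * np.exp(-xx * xx / (2.0 * w * w))
    return fq


@njit(cache=False)
def dw_segment(x0, n_steps, coef, noise, sample_stride, h, a, d, w, samples):
    """1-D Brownian segment in the double/triple well; returns end position."""
    xx = x0
    s_out = 0
    for step in range(n_steps):
        xx += coef * well_force(xx, h, a, d, w) + noise[step]
        if (step + 1) % sample_stride == 0:
            samples[s_out] = xx
            s_out += 1
    return xx


@njit(cache=False)
def dw_first_passage(x0, dt, coef, sigma, h, a, d, w,
                     low_bound, high_bound, i_is_low,
                     n_events, max_steps, seed):
    """History-labeled waiting times in the 1-D well system.

    The walker carries the label of the state (low: x <= low_bound, high:
    x >= high_bound) it visited most recently; ``i_is_low`` selects which
    one is the initial state i.  Each completed i->j label switch yields
    one waiting time (time spent labeled i); this matches the steady-state
    rate definition k_ij = f_ij / p_i.  Returns (times, count, total_steps).
    """
    np.random.seed(seed)
    times = np.zeros(n_events)
    count = 0
    label = -1          # 0 = low state, 1 = high state
    i_label = 0 if i_is_low else 1
    entered = 0
    xx = x0
    step = 0
    while step < max_steps and count < n_events:
        xx += coef * well_force(xx, h, a, d, w) + sigma * np.random.normal()
        step += 1
        state = -1
        if xx <= low_bound:
            state = 0
        elif xx >= high_bound:
            state = 1
        if state < 0 or state == label:
            continue
        if state == i_label:
            entered = step
        elif label == i_label:
            times[count] = (step - entered) * dt
            count += 1
        label = state
    return times, count, step
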