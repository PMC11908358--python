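"""Numba kernels for the Metropolis Monte Carlo samplers.

All kernels work on raw arrays: chain coordinates ``x`` with shape
(2, N, 3) (or (N, 3) for a single chain), a per-bead boolean ``att`` mask
(True = attractive/hydrophobic), and per-bead diameters ``diam``.  Energies
are in kBT, lengths in sigma.  The pair potential is the WCA-decomposed HP
form of :mod:`twochain.model`; the Python layer is the reference
implementation and the two must agree (tested).
"""

from __future__ import annotations

import numpy as np
from numba import njit

RMIN2_FACTOR = 2.0 ** (1.0 / 3.0)  # (2^(1/6))^2


@njit(cache=True)
def _pair_u(r2, att_pair, eps, sij, cut, shift):
    s2 = sij * sij
    if r2 < RMIN2_FACTOR * s2:
        inv = s2 / r2
        x6 = inv * inv * inv
        u = 4.0 * (x6 * x6 - x6) + 1.0
        if att_pair:
            u += eps * (-1.0 - shift)
        return u
    if att_pair:
        if r2 < cut * cut * s2:
            inv = s2 / r2
            x6 = inv * inv * inv
            return eps * (4.0 * (x6 * x6 - x6) - shift)
    return 0.0


@njit(cache=True)
def _bond_u(r2, k, r0, sij):
    r02 = r0 * r0
    if r2 >= r02:
        return np.inf
    u = -0.5 * k * r02 * np.log(1.0 - r2 / r02)
    s2 = sij * sij
    if r2 < RMIN2_FACTOR * s2:
        inv = s2 / r2
        x6 = inv * inv * inv
        u += 4.0 * (x6 * x6 - x6) + 1.0
    return u


@njit(cache=True)
def _d2(p, q):
    dx = p[0] - q[0]
    dy = p[1] - q[1]
    dz = p[2] - q[2]
    return dx * dx + dy * dy + dz * dz


@njit(cache=True)
def _intra_energy(x, att, diam, eps, cut, shift, bk, br0):
    n = x.shape[0]
    e = 0.0
    for i in range(n - 1):
        e += _bond_u(_d2(x[i], x[i + 1]), bk, br0, 0.5 * (diam[i] + diam[i + 1]))
    for i in range(n):
        for j in range(i + 2, n):
            e += _pair_u(
                _d2(x[i], x[j]), att[i] and att[j], eps,
                0.5 * (diam[i] + diam[j]), cut, shift,
            )
    return e


@njit(cache=True)
def _inter_energy(xa, xb, att, diam, eps, cut, shift):
    n = xa.shape[0]
    m = xb.shape[0]
    e = 0.0
    for i in range(n):
        for j in range(m):
            e += _pair_u(
                _d2(xa[i], xb[j]), att[i] and att[j], eps,
                0.5 * (diam[i] + diam[j]), cut, shift,
            )
    return e


@njit(cache=True)
def two_chain_energy(x, att, diam, eps, cut, shift, bk, br0):
    return (
        _intra_energy(x[0], att, diam, eps, cut, shift, bk, br0)
        + _intra_energy(x[1], att, diam, eps, cut, shift, bk, br0)
        + _inter_energy(x[0], x[1], att, diam, eps, cut, shift)
    )


@njit(cache=True)
def _bead_env(x, c, i, pos, att, diam, eps, cut, shift, bk, br0):
    """Energy of a bead placed at ``pos`` in slot (c, i) against everything else."""
    n = x.shape[1]
    e = 0.0
    if i > 0:
        e += _bond_u(_d2(pos, x[c, i - 1]), bk, br0, 0.5 * (diam[i] + diam[i - 1]))
    if i < n - 1:
        e += _bond_u(_d2(pos, x[c, i + 1]), bk, br0, 0.5 * (diam[i] + diam[i + 1]))
    for j in range(n):
        dj = i - j
        if dj >= 2 or dj <= -2:
            e += _pair_u(
                _d2(pos, x[c, j]), att[i] and att[j], eps,
                0.5 * (diam[i] + diam[j]), cut, shift,
            )
    o = 1 - c
    for j in range(n):
        e += _pair_u(
            _d2(pos, x[o, j]), att[i] and att[j], eps,
            0.5 * (diam[i] + diam[j]), cut, shift,
        )
    return e


@njit(cache=True)
def _random_rotation(max_angle):
    """Rotation matrix: uniform random axis, angle uniform in [-max_angle, max_angle]."""
    # Marsaglia point picking for the axis
    while True:
        u1 = 2.0 * np.random.random() - 1.0
        u2 = 2.0 * np.random.random() - 1.0
        s = u1 * u1 + u2 * u2
        if s < 1.0 and s > 1e-12:
            break
    root = np.sqrt(1.0 - s)
    ax = 2.0 * u1 * root
    ay = 2.0 * u2 * root
    az = 1.0 - 2.0 * s
    theta = (2.0 * np.random.random() - 1.0) * max_angle
    ct = np.cos(theta)
    st = np.sin(theta)
    one_ct = 1.0 - ct
    R = np.empty((3, 3))
    R[0, 0] = ct + ax * ax * one_ct
    R[0, 1] = ax * ay * one_ct - az * st
    R[0, 2] = ax * az * one_ct + ay * st
    R[1, 0] = ay * ax * one_ct + az * st
    R[1, 1] = ct + ay * ay * one_ct
    R[1, 2] = ay * az * one_ct - ax * st
    R[2, 0] = az * ax * one_ct - ay * st
    R[2, 1] = az * ay * one_ct + ax * st
    R[2, 2] = ct + az * az * one_ct
    return R


@njit(cache=True)
def _segment_cross_energy(x, c, lo, hi, seg, att, diam, eps, cut, shift):
    """Nonbonded energy between chain-c beads [lo, hi) at positions ``seg``
    and (a) same-chain beads outside the segment at |i-j| >= 2,
    (b) all beads of the other chain.  Bonded terms are unchanged by a pivot
    about bead lo-1 (or hi) and are deliberately excluded."""
    n = x.shape[1]
    o = 1 - c
    e = 0.0
    for a in range(lo, hi):
        pa = seg[a - lo]
        for j in range(n):
            if j >= lo and j < hi:
                continue
            dj = a - j
            if dj >= 2 or dj <= -2:
                e += _pair_u(
                    _d2(pa, x[c, j]), att[a] and att[j], eps,
                    0.5 * (diam[a] + diam[j]), cut, shift,
                )
        for j in range(n):
            e += _pair_u(
                _d2(pa, x[o, j]), att[a] and att[j], eps,
                0.5 * (diam[a] + diam[j]), cut, shift,
            )
    return e


@njit(cache=True)
def _com(xc):
    n = xc.shape[0]
    out = np.zeros(3)
    for i in range(n):
        for d in range(3):
            out[d] += xc[i, d]
    for d in range(3):
        out[d] /= n
    return out


@njit(cache=True)
def run_two_chain_window(
    x0, att, diam, eps, cut, shift, bk, br0,
    r_lo, r_hi, kappa, r_center, n_sweeps, n_burn, stride,
    max_disp, max_angle, seed,
):
    """Metropolis MC of two chains restrained in centre-of-mass distance r.

    Hard mode: moves leaving [r_lo, r_hi) are rejected (kappa = 0).
    Harmonic mode: a restraint 0.5*kappa*(r - r_center)^2 is added to the
    acceptance rule (set r_lo = 0, r_hi = inf).

    Moves per sweep: 2N single-bead displacements, one pivot per chain
    (N >= 2), a rigid rotation of each chain about its own centre of mass,
    and a rigid translation of chain B.  Returns retained snapshots
    (coords, r, total energy) plus acceptance counters.
    """
    np.random.seed(seed)
    x = x0.copy()
    n = x.shape[1]
    n_keep = (n_sweeps - n_burn + stride - 1) // stride
    out_x = np.empty((n_keep, 2, n, 3))
    out_r = np.empty(n_keep)
    out_e = np.empty(n_keep)
    accepted = 0
    attempted = 0
    coms = np.empty((2, 3))
    coms[0] = _com(x[0])
    coms[1] = _com(x[1])
    r_cur = np.sqrt(_d2(coms[0], coms[1]))
    pos_new = np.empty(3)
    com_new = np.empty(3)
    k_out = 0
    for sweep in range(n_sweeps):
        # --- single-bead displacements -----------------------------------
        for _ in range(2 * n):
            attempted += 1
            c = 0 if np.random.random() < 0.5 else 1
            i = int(np.random.random() * n)
            if i >= n:
                i = n - 1
            for d in range(3):
                pos_new[d] = x[c, i, d] + (2.0 * np.random.random() - 1.0) * max_disp
            for d in range(3):
                com_new[d] = coms[c, d] + (pos_new[d] - x[c, i, d]) / n
            r_new = np.sqrt(_d2(com_new, coms[1 - c]))
            if r_new < r_lo or r_new >= r_hi:
                continue
            e_old = _bead_env(x, c, i, x[c, i], att, diam, eps, cut, shift, bk, br0)
            e_new = _bead_env(x, c, i, pos_new, att, diam, eps, cut, shift, bk, br0)
            de = e_new - e_old
            if kappa > 0.0:
                de += 0.5 * kappa * ((r_new - r_center) ** 2 - (r_cur - r_center) ** 2)
            if de <= 0.0 or np.random.random() < np.exp(-de):
                for d in range(3):
                    x[c, i, d] = pos_new[d]
                    coms[c, d] = com_new[d]
                r_cur = r_new
                accepted += 1
        # --- pivots ------------------------------------------------------
        if n >= 2:
            for c in range(2):
                attempted += 1
                p = int(np.random.random() * n)
                if p >= n:
                    p = n - 1
                if np.random.random() < 0.5:
                    lo, hi = p + 1, n
                else:
                    lo, hi = 0, p
                if hi <= lo:
                    continue
                R = _random_rotation(max_angle)
                seg = np.empty((hi - lo, 3))
                for a in range(lo, hi):
                    for d in range(3):
                        seg[a - lo, d] = (
                            R[d, 0] * (x[c, a, 0] - x[c, p, 0])
                            + R[d, 1] * (x[c, a, 1] - x[c, p, 1])
                            + R[d, 2] * (x[c, a, 2] - x[c, p, 2])
                            + x[c, p, d]
                        )
                for d in range(3):
                    com_new[d] = coms[c, d]
                    for a in range(lo, hi):
                        com_new[d] += (seg[a - lo, d] - x[c, a, d]) / n
                r_new = np.sqrt(_d2(com_new, coms[1 - c]))
                if r_new < r_lo or r_new >= r_hi:
                    continue
                e_old = _segment_cross_energy(x, c, lo, hi, x[c, lo:hi], att, diam, eps, cut, shift)
                e_new = _segment_cross_energy(x, c, lo, hi, seg, att, diam, eps, cut, shift)
                de = e_new - e_old
                if kappa > 0.0:
                    de += 0.5 * kappa * ((r_new - r_center) ** 2 - (r_cur - r_center) ** 2)
                if de <= 0.0 or np.random.random() < np.exp(-de):
                    for a in range(lo, hi):
                        for d in range(3):
                            x[c, a, d] = seg[a - lo, d]
                    for d in range(3):
                        coms[c, d] = com_new[d]
                    r_cur = r_new
                    accepted += 1
        # --- rigid rotations about each chain's own COM (r unchanged) ----
        for c in range(2):
            attempted += 1
            R = _random_rotation(max_angle)
            seg = np.empty((n, 3))
            for a in range(n):
                for d in range(3):
                    seg[a, d] = (
                        R[d, 0] * (x[c, a, 0] - coms[c, 0])
                        + R[d, 1] * (x[c, a, 1] - coms[c, 1])
                        + R[d, 2] * (x[c, a, 2] - coms[c, 2])
                        + coms[c, d]
                    )
            e_old = _inter_energy(x[0], x[1], att, diam, eps, cut, shift)
            if c == 0:
                e_new = _inter_energy(seg, x[1], att, diam, eps, cut, shift)
            else:
                e_new = _inter_energy(x[0], seg, att, diam, eps, cut, shift)
            de = e_new - e_old
            if de <= 0.0 or np.random.random() < np.exp(-de):
                for a in range(n):
                    for d in range(3):
                        x[c, a, d] = seg[a, d]
                accepted += 1
        # --- rigid translation of chain B --------------------------------
        attempted += 1
        for d in range(3):
            pos_new[d] = (2.0 * np.random.random() - 1.0) * max_disp
        for d in range(3):
            com_new[d] = coms[1, d] + pos_new[d]
        r_new = np.sqrt(_d2(coms[0], com_new))
        if r_lo <= r_new < r_hi:
            e_old = _inter_energy(x[0], x[1], att, diam, eps, cut, shift)
            seg = np.empty((n, 3))
            for a in range(n):
                for d in range(3):
                    seg[a, d] = x[1, a, d] + pos_new[d]
            e_new = _inter_energy(x[0], seg, att, diam, eps, cut, shift)
            de = e_new - e_old
            if kappa > 0.0:
                de += 0.5 * kappa * ((r_new - r_center) ** 2 - (r_cur - r_center) ** 2)
            if de <= 0.0 or np.random.random() < np.exp(-de):
                for a in range(n):
                    for d in range(3):
                        x[1, a, d] = seg[a, d]
                for d in range(3):
                    coms[1, d] = com_new[d]
                r_cur = r_new
                accepted += 1
        # --- snapshot -----------------------------------------------------
        if sweep >= n_burn and (sweep - n_burn) % stride == 0:
            out_x[k_out] = x
            out_r[k_out] = r_cur
            out_e[k_out] = two_chain_energy(x, att, diam, eps, cut, shift, bk, br0)
            k_out += 1
    return out_x[:k_out], out_r[:k_out], out_e[:k_out], accepted, attempted


@njit(cache=True)
def _single_bead_env(x, i, pos, att, diam, eps, cut, shift, bk, br0):
    n = x.shape[0]
    e = 0.0
    if i > 0:
        e += _bond_u(_d2(pos, x[i - 1]), bk, br0, 0.5 * (diam[i] + diam[i - 1]))
    if i < n - 1:
        e += _bond_u(_d2(pos, x[i + 1]), bk, br0, 0.5 * (diam[i] + diam[i + 1]))
    for j in range(n):
        dj = i - j
        if dj >= 2 or dj <= -2:
            e += _pair_u(
                _d2(pos, x[j]), att[i] and att[j], eps,
                0.5 * (diam[i] + diam[j]), cut, shift,
            )
    return e


@njit(cache=True)
def run_single_chain(
    x0, att, diam, eps, cut, shift, bk, br0,
    n_sweeps, n_burn, stride, max_disp, max_angle, seed,
):
    """Metropolis MC of one chain: bead displacements plus one pivot per sweep."""
    np.random.seed(seed)
    x = x0.copy()
    n = x.shape[0]
    n_keep = (n_sweeps - n_burn + stride - 1) // stride
    out_x = np.empty((n_keep, n, 3))
    accepted = 0
    attempted = 0
    pos_new = np.empty(3)
    k_out = 0
    for sweep in range(n_sweeps):
        for _ in range(n):
            attempted += 1
            i = int(np.random.random() * n)
            if i >= n:
                i = n - 1
            for d in range(3):
                pos_new[d] = x[i, d] + (2.0 * np.random.random() - 1.0) * max_disp
            e_old = _single_bead_env(x, i, x[i], att, diam, eps, cut, shift, bk, br0)
            e_new = _single_bead_env(x, i, pos_new, att, diam, eps, cut, shift, bk, br0)
            de = e_new - e_old
            if de <= 0.0 or np.random.random() < np.exp(-de):
                for d in range(3):
                    x[i, d] = pos_new[d]
                accepted += 1
        if n >= 2:
            attempted += 1
            p = int(np.random.random() * n)
            if p >= n:
                p = n - 1
            if np.random.random() < 0.5:
                lo, hi = p + 1, n
            else:
                lo, hi = 0, p
            if hi > lo:
                R = _random_rotation(max_angle)
                seg = np.empty((hi - lo, 3))
                for a in range(lo, hi):
                    for d in range(3):
                        seg[a - lo, d] = (
                            R[d, 0] * (x[a, 0] - x[p, 0])
                            + R[d, 1] * (x[a, 1] - x[p, 1])
                            + R[d, 2] * (x[a, 2] - x[p, 2])
                            + x[p, d]
                        )
                e_old = 0.0
                e_new = 0.0
                for a in range(lo, hi):
                    for j in range(n):
                        if lo <= j < hi:
                            continue
                        dj = a - j
                        if dj >= 2 or dj <= -2:
                            sij = 0.5 * (diam[a] + diam[j])
                            ap = att[a] and att[j]
                            e_old += _pair_u(_d2(x[a], x[j]), ap, eps, sij, cut, shift)
                            e_new += _pair_u(_d2(seg[a - lo], x[j]), ap, eps, sij, cut, shift)
                de = e_new - e_old
                if de <= 0.0 or np.random.random() < np.exp(-de):
                    for a in range(lo, hi):
                        for d in range(3):
                            x[a, d] = seg[a - lo, d]
                    accepted += 1
        if sweep >= n_burn and (sweep - n_burn) % stride == 0:
            out_x[k_out] = x
            k_out += 1
    return out_x[:k_out], accepted, attempted


@njit(cache=True)
def interchain_contact_counts(states, rc):
    """Number of interchain bead pairs within rc, per snapshot.

    ``states`` has shape (M, 2, N, 3)."""
    m = states.shape[0]
    n = states.shape[2]
    rc2 = rc * rc
    out = np.empty(m, dtype=np.int64)
    for s in range(m):
        cnt = 0
        for i in range(n):
            for j in range(n):
                if _d2(states[s, 0, i], states[s, 1, j]) < rc2:
                    cnt += 1
        out[s] = cnt
    return out
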