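"""Numba kernels for the DPD engine and trajectory analysis.

Everything here works on plain float64/int64 arrays in reduced units with a
cubic periodic box; the friendly API lives in :mod:`hgdpd.core` and
:mod:`hgdpd.observables`.  Pair lists are ordered (i < j) and duplicate-free.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = [
    "pairs_bruteforce",
    "pairs_cells",
    "count_missing_pairs",
    "pair_forces_kernel",
    "bond_forces_kernel",
    "angle_forces_kernel",
    "pair_energy_kernel",
    "bond_energy_kernel",
    "angle_energy_kernel",
    "self_distances",
    "cross_distances",
]


@njit(cache=True, inline="always")
def _mic(d: float, L: float) -> float:
    return d - L * np.rint(d / L)


@njit(cache=True)
def pairs_bruteforce(pos, box, rmax):
    """All minimum-image pairs with r < rmax, by an O(N^2) scan."""
    n = pos.shape[0]
    r2max = rmax * rmax
    count = 0
    for i in range(n - 1):
        for j in range(i + 1, n):
            dx = _mic(pos[i, 0] - pos[j, 0], box[0])
            dy = _mic(pos[i, 1] - pos[j, 1], box[1])
            dz = _mic(pos[i, 2] - pos[j, 2], box[2])
            if dx * dx + dy * dy + dz * dz < r2max:
                count += 1
    pi = np.empty(count, dtype=np.int64)
    pj = np.empty(count, dtype=np.int64)
    k = 0
    for i in range(n - 1):
        for j in range(i + 1, n):
            dx = _mic(pos[i, 0] - pos[j, 0], box[0])
            dy = _mic(pos[i, 1] - pos[j, 1], box[1])
            dz = _mic(pos[i, 2] - pos[j, 2], box[2])
            if dx * dx + dy * dy + dz * dz < r2max:
                pi[k] = i
                pj[k] = j
                k += 1
    return pi, pj


# half stencil: the 13 forward neighbour cells plus the cell itself
_STENCIL = np.array(
    [
        (0, 0, 1), (0, 1, -1), (0, 1, 0), (0, 1, 1),
        (1, -1, -1), (1, -1, 0), (1, -1, 1),
        (1, 0, -1), (1, 0, 0), (1, 0, 1),
        (1, 1, -1), (1, 1, 0), (1, 1, 1),
    ],
    dtype=np.int64,
)


@njit(cache=True)
def _cells_pass(pos, box, rmax, pi, pj, fill):
    """Count (fill=False) or emit (fill=True) cell-list pairs with r < rmax.

    Requires at least 3 cells per axis; the wrapper falls back to the
    brute-force scan otherwise.
    """
    n = pos.shape[0]
    ncx = int(box[0] / rmax)
    ncy = int(box[1] / rmax)
    ncz = int(box[2] / rmax)
    ncell = ncx * ncy * ncz
    r2max = rmax * rmax

    cell = np.empty(n, dtype=np.int64)
    count = np.zeros(ncell + 1, dtype=np.int64)
    for i in range(n):
        ix = int(pos[i, 0] / box[0] * ncx) % ncx
        iy = int(pos[i, 1] / box[1] * ncy) % ncy
        iz = int(pos[i, 2] / box[2] * ncz) % ncz
        c = (ix * ncy + iy) * ncz + iz
        cell[i] = c
        count[c + 1] += 1
    start = np.cumsum(count)
    fillp = start[:-1].copy()
    order = np.empty(n, dtype=np.int64)
    for i in range(n):
        order[fillp[cell[i]]] = i
        fillp[cell[i]] += 1

    total = 0
    for cx in range(ncx):
        for cy in range(ncy):
            for cz in range(ncz):
                c = (cx * ncy + cy) * ncz + cz
                a0, a1 = start[c], start[c + 1]
                # pairs within the cell
                for u in range(a0, a1):
                    i = order[u]
                    for v in range(u + 1, a1):
                        j = order[v]
                        dx = _mic(pos[i, 0] - pos[j, 0], box[0])
                        dy = _mic(pos[i, 1] - pos[j, 1], box[1])
                        dz = _mic(pos[i, 2] - pos[j, 2], box[2])
                        if dx * dx + dy * dy + dz * dz < r2max:
                            if fill:
                                if i < j:
                                    pi[total] = i
                                    pj[total] = j
                                else:
                                    pi[total] = j
                                    pj[total] = i
                            total += 1
                # pairs with forward neighbour cells
                for soff in range(_STENCIL.shape[0]):
                    nx = (cx + _STENCIL[soff, 0]) % ncx
                    ny = (cy + _STENCIL[soff, 1]) % ncy
                    nz = (cz + _STENCIL[soff, 2]) % ncz
                    d = (nx * ncy + ny) * ncz + nz
                    b0, b1 = start[d], start[d + 1]
                    for u in range(a0, a1):
                        i = order[u]
                        for v in range(b0, b1):
                            j = order[v]
                            dx = _mic(pos[i, 0] - pos[j, 0], box[0])
                            dy = _mic(pos[i, 1] - pos[j, 1], box[1])
                            dz = _mic(pos[i, 2] - pos[j, 2], box[2])
                            if dx * dx + dy * dy + dz * dz < r2max:
                                if fill:
                                    if i < j:
                                        pi[total] = i
                                        pj[total] = j
                                    else:
                                        pi[total] = j
                                        pj[total] = i
                                total += 1
    return total


def pairs_cells(pos, box, rmax):
    """Cell-list pair search; falls back to brute force for small boxes."""
    if min(int(box[0] / rmax), int(box[1] / rmax), int(box[2] / rmax)) < 3:
        return pairs_bruteforce(pos, box, rmax)
    empty = np.empty(0, dtype=np.int64)
    total = _cells_pass(pos, box, rmax, empty, empty, False)
    pi = np.empty(total, dtype=np.int64)
    pj = np.empty(total, dtype=np.int64)
    _cells_pass(pos, box, rmax, pi, pj, True)
    return pi, pj


@njit(cache=True)
def count_missing_pairs(pos, box, cutoff, pi, pj):
    """Number of in-cutoff pairs absent from the (sorted-key) pair list."""
    n = pos.shape[0]
    keys = np.empty(pi.shape[0], dtype=np.int64)
    for k in range(pi.shape[0]):
        keys[k] = pi[k] * n + pj[k]
    keys = np.sort(keys)
    r2max = cutoff * cutoff
    missing = 0
    for i in range(n - 1):
        for j in range(i + 1, n):
            dx = _mic(pos[i, 0] - pos[j, 0], box[0])
            dy = _mic(pos[i, 1] - pos[j, 1], box[1])
            dz = _mic(pos[i, 2] - pos[j, 2], box[2])
            if dx * dx + dy * dy + dz * dz < r2max:
                key = i * n + j
                lo, hi = 0, keys.shape[0]
                while lo < hi:
                    mid = (lo + hi) // 2
                    if keys[mid] < key:
                        lo = mid + 1
                    else:
                        hi = mid
                if lo >= keys.shape[0] or keys[lo] != key:
                    missing += 1
    return missing


@njit(cache=True)
def pair_forces_kernel(pos, vel, box, pi, pj, types, amat, gamma, sigma, s,
                       inv_sqrt_dt, xi, cutoff, f):
    """Accumulate conservative + dissipative + random pair forces into ``f``.

    ``xi`` holds one noise draw per listed pair (symmetric by construction).
    Exactly overlapping beads contribute no force (direction undefined under
    the soft potential); the number of such events is returned.
    """
    n_overlap = 0
    half_s = 0.5 * s
    for k in range(pi.shape[0]):
        i = pi[k]
        j = pj[k]
        dx = _mic(pos[i, 0] - pos[j, 0], box[0])
        dy = _mic(pos[i, 1] - pos[j, 1], box[1])
        dz = _mic(pos[i, 2] - pos[j, 2], box[2])
        r2 = dx * dx + dy * dy + dz * dz
        if r2 >= cutoff * cutoff:
            continue
        r = np.sqrt(r2)
        if r < 1e-12:
            n_overlap += 1
            continue
        ex = dx / r
        ey = dy / r
        ez = dz / r
        wc = 1.0 - r / cutoff
        fmag = amat[types[i], types[j]] * wc
        if gamma != 0.0 or sigma != 0.0:
            wr = wc**half_s
            wd = wr * wr  # omega_D = (omega_R)^2 by construction
            vdotr = ((vel[i, 0] - vel[j, 0]) * ex
                     + (vel[i, 1] - vel[j, 1]) * ey
                     + (vel[i, 2] - vel[j, 2]) * ez)
            fmag += -gamma * wd * vdotr + sigma * wr * xi[k] * inv_sqrt_dt
        f[i, 0] += fmag * ex
        f[i, 1] += fmag * ey
        f[i, 2] += fmag * ez
        f[j, 0] -= fmag * ex
        f[j, 1] -= fmag * ey
        f[j, 2] -= fmag * ez
    return n_overlap


@njit(cache=True)
def bond_forces_kernel(pos, box, bi, bj, ks, l0, f):
    """Harmonic distance-bond forces, -k_S (r - l0) along the bond axis."""
    for b in range(bi.shape[0]):
        i = bi[b]
        j = bj[b]
        dx = _mic(pos[i, 0] - pos[j, 0], box[0])
        dy = _mic(pos[i, 1] - pos[j, 1], box[1])
        dz = _mic(pos[i, 2] - pos[j, 2], box[2])
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        if r < 1e-12:
            continue
        fmag = -ks[b] * (r - l0[b]) / r
        f[i, 0] += fmag * dx
        f[i, 1] += fmag * dy
        f[i, 2] += fmag * dz
        f[j, 0] -= fmag * dx
        f[j, 1] -= fmag * dy
        f[j, 2] -= fmag * dz


@njit(cache=True)
def angle_forces_kernel(pos, box, ai, aj, ak, ka, th0, f):
    """Harmonic angle forces from U = k_A (theta - theta0)^2 / 2.

    theta is the interior angle at the middle bead j.  The analytic gradient
    is distributed over the three beads with zero net force (and zero net
    torque).  Near-collinear geometries are handled by clamping cos(theta);
    the number of clamped events is returned.
    """
    eps = 1e-9
    n_clamped = 0
    for t in range(ai.shape[0]):
        i = ai[t]
        j = aj[t]
        k = ak[t]
        ux = _mic(pos[i, 0] - pos[j, 0], box[0])
        uy = _mic(pos[i, 1] - pos[j, 1], box[1])
        uz = _mic(pos[i, 2] - pos[j, 2], box[2])
        wx = _mic(pos[k, 0] - pos[j, 0], box[0])
        wy = _mic(pos[k, 1] - pos[j, 1], box[1])
        wz = _mic(pos[k, 2] - pos[j, 2], box[2])
        ru = np.sqrt(ux * ux + uy * uy + uz * uz)
        rw = np.sqrt(wx * wx + wy * wy + wz * wz)
        if ru < 1e-12 or rw < 1e-12:
            n_clamped += 1
            continue
        c = (ux * wx + uy * wy + uz * wz) / (ru * rw)
        if c > 1.0 - eps:
            c = 1.0 - eps
            n_clamped += 1
        elif c < -1.0 + eps:
            c = -1.0 + eps
            n_clamped += 1
        sin_th = np.sqrt(1.0 - c * c)
        theta = np.arccos(c)
        coef = ka[t] * (theta - th0[t]) / sin_th
        # F_i = coef * (w_hat - c*u_hat)/ru ; F_k symmetric; F_j balances
        fix = coef * (wx / (ru * rw) - c * ux / (ru * ru))
        fiy = coef * (wy / (ru * rw) - c * uy / (ru * ru))
        fiz = coef * (wz / (ru * rw) - c * uz / (ru * ru))
        fkx = coef * (ux / (ru * rw) - c * wx / (rw * rw))
        fky = coef * (uy / (ru * rw) - c * wy / (rw * rw))
        fkz = coef * (uz / (ru * rw) - c * wz / (rw * rw))
        f[i, 0] += fix
        f[i, 1] += fiy
        f[i, 2] += fiz
        f[k, 0] += fkx
        f[k, 1] += fky
        f[k, 2] += fkz
        f[j, 0] -= fix + fkx
        f[j, 1] -= fiy + fky
        f[j, 2] -= fiz + fkz
    return n_clamped


@njit(cache=True)
def pair_energy_kernel(pos, box, pi, pj, types, amat, cutoff):
    """Conservative pair energy, U = a_ij (1 - r/r_C)^2 r_C / 2 per pair."""
    e = 0.0
    for k in range(pi.shape[0]):
        i = pi[k]
        j = pj[k]
        dx = _mic(pos[i, 0] - pos[j, 0], box[0])
        dy = _mic(pos[i, 1] - pos[j, 1], box[1])
        dz = _mic(pos[i, 2] - pos[j, 2], box[2])
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        if r < cutoff:
            wc = 1.0 - r / cutoff
            e += 0.5 * amat[types[i], types[j]] * wc * wc * cutoff
    return e


@njit(cache=True)
def bond_energy_kernel(pos, box, bi, bj, ks, l0):
    e = 0.0
    for b in range(bi.shape[0]):
        dx = _mic(pos[bi[b], 0] - pos[bj[b], 0], box[0])
        dy = _mic(pos[bi[b], 1] - pos[bj[b], 1], box[1])
        dz = _mic(pos[bi[b], 2] - pos[bj[b], 2], box[2])
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        e += 0.5 * ks[b] * (r - l0[b]) ** 2
    return e


@njit(cache=True)
def angle_energy_kernel(pos, box, ai, aj, ak, ka, th0):
    e = 0.0
    for t in range(ai.shape[0]):
        ux = _mic(pos[ai[t], 0] - pos[aj[t], 0], box[0])
        uy = _mic(pos[ai[t], 1] - pos[aj[t], 1], box[1])
        uz = _mic(pos[ai[t], 2] - pos[aj[t], 2], box[2])
        wx = _mic(pos[ak[t], 0] - pos[aj[t], 0], box[0])
        wy = _mic(pos[ak[t], 1] - pos[aj[t], 1], box[1])
        wz = _mic(pos[ak[t], 2] - pos[aj[t], 2], box[2])
        ru = np.sqrt(ux * ux + uy * uy + uz * uz)
        rw = np.sqrt(wx * wx + wy * wy + wz * wz)
        c = (ux * wx + uy * wy + uz * wz) / (ru * rw)
        if c > 1.0:
            c = 1.0
        elif c < -1.0:
            c = -1.0
        theta = np.arccos(c)
        e += 0.5 * ka[t] * (theta - th0[t]) ** 2
    return e


@njit(cache=True)
def self_distances(pos, box, rmax):
    """Distances of all minimum-image pairs with r < rmax within one set."""
    n = pos.shape[0]
    r2max = rmax * rmax
    count = 0
    for i in range(n - 1):
        for j in range(i + 1, n):
            dx = _mic(pos[i, 0] - pos[j, 0], box[0])
            dy = _mic(pos[i, 1] - pos[j, 1], box[1])
            dz = _mic(pos[i, 2] - pos[j, 2], box[2])
            if dx * dx + dy * dy + dz * dz < r2max:
                count += 1
    out = np.empty(count, dtype=np.float64)
    k = 0
    for i in range(n - 1):
        for j in range(i + 1, n):
            dx = _mic(pos[i, 0] - pos[j, 0], box[0])
            dy = _mic(pos[i, 1] - pos[j, 1], box[1])
            dz = _mic(pos[i, 2] - pos[j, 2], box[2])
            r2 = dx * dx + dy * dy + dz * dz
            if r2 < r2max:
                out[k] = np.sqrt(r2)
                k += 1
    return out


@njit(cache=True)
def cross_distances(pos_a, pos_b, box, rmax):
    """Distances of minimum-image pairs (a, b) with r < rmax across two sets."""
    na = pos_a.shape[0]
    nb = pos_b.shape[0]
    r2max = rmax * rmax
    count = 0
    for i in range(na):
        for j in range(nb):
            dx = _mic(pos_a[i, 0] - pos_b[j, 0], box[0])
            dy = _mic(pos_a[i, 1] - pos_b[j, 1], box[1])
            dz = _mic(pos_a[i, 2] - pos_b[j, 2], box[2])
            if dx * dx + dy * dy + dz * dz < r2max:
                count += 1
    out = np.empty(count, dtype=np.float64)
    k = 0
    for i in range(na):
        for j in range(nb):
            dx = _mic(pos_a[i, 0] - pos_b[j, 0], box[0])
            dy = _mic(pos_a[i, 1] - pos_b[j, 1], box[1])
            dz = _mic(pos_a[i, 2] - pos_b[j, 2], box[2])
            r2 = dx * dx + dy * dy + dz * dz
            if r2 < r2max:
                out[k] = np.sqrt(r2)
                k += 1
    return out
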