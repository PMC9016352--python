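"""Numba kernels: minimum-image pair interactions and neighbor lists.

All kernels operate on plain float64 arrays in package units (Angstrom,
kJ/mol, Da).  Pair energies are truncated-and-shifted at the cutoffs;
directly bonded pairs are excluded from nonbonded sums via ``excl_next``
(True at ``i`` when beads ``i`` and ``i+1`` are bonded).
"""

from __future__ import annotations

import numpy as np
from numba import njit

TWO_POW_16 = 2.0 ** (1.0 / 6.0)


def bond_exclusion_mask(n: int, bonds: np.ndarray) -> np.ndarray:
    excl = np.zeros(n, dtype=np.bool_)
    for a, b in bonds:
        if b == a + 1:
            excl[a] = True
    return excl


@njit(cache=True)
def _min_image(d: float, box: float) -> float:
    return d - box * round(d / box)


@njit(cache=True, fastmath=True)
def _pair_terms(
    dx, dy, dz, r2,
    sigma_ij, lam_ij, qq,
    eps, coul_pref, debye, rc_vdw, rc_el,
    compute_forces,
):
    """Energy and (-dU/dr)/r for one pair; sqrt only when electrostatics
    contribute."""
    e_vdw = 0.0
    e_el = 0.0
    fscal_r = 0.0  # (-du/dr)/r, multiply by displacement for vector force
    if r2 < rc_vdw * rc_vdw:
        sr2 = sigma_ij * sigma_ij / r2
        sr6 = sr2 * sr2 * sr2
        sr12 = sr6 * sr6
        lj = 4.0 * eps * (sr12 - sr6)
        # tail shift: lambda-scaled LJ at the cutoff
        src2 = sigma_ij * sigma_ij / (rc_vdw * rc_vdw)
        src6 = src2 * src2 * src2
        shift = lam_ij * 4.0 * eps * (src6 * src6 - src6)
        # -dLJ/dr / r
        flj_r = 24.0 * eps * (2.0 * sr12 - sr6) / r2
        if sr2 >= 0.7937005259840998:  # r <= 2^(1/6) sigma  <=>  (s/r)^2 >= 2^(-1/3)
            e_vdw = lj + (1.0 - lam_ij) * eps - shift
            if compute_forces:
                fscal_r += flj_r
        else:
            e_vdw = lam_ij * lj - shift
            if compute_forces:
                fscal_r += lam_ij * flj_r
    if qq != 0.0 and r2 < rc_el * rc_el:
        r = np.sqrt(r2)
        a = coul_pref * qq
        e_el = a * np.exp(-r / debye) / r - a * np.exp(-rc_el / debye) / rc_el
        if compute_forces:
            fscal_r += a * np.exp(-r / debye) * (1.0 / r2 + 1.0 / (debye * r)) / r
    return e_vdw, e_el, fscal_r


@njit(cache=True, fastmath=True)
def nonbonded_pairs(
    pairs, pos, box, sigma, lam, charge,
    eps, coul_pref, debye, rc_vdw, rc_el, excl_next,
    compute_forces=True,
):
    n = pos.shape[0]
    f = np.zeros((n, 3))
    e_vdw = 0.0
    e_el = 0.0
    rc_max2 = max(rc_vdw, rc_el) ** 2
    for k in range(pairs.shape[0]):
        i = pairs[k, 0]
        j = pairs[k, 1]
        if j == i + 1 and excl_next[i]:
            continue
        dx = _min_image(pos[i, 0] - pos[j, 0], box[0])
        dy = _min_image(pos[i, 1] - pos[j, 1], box[1])
        dz = _min_image(pos[i, 2] - pos[j, 2], box[2])
        r2 = dx * dx + dy * dy + dz * dz
        if r2 >= rc_max2 or r2 == 0.0:
            continue
        ev, ee, fr = _pair_terms(
            dx, dy, dz, r2,
            0.5 * (sigma[i] + sigma[j]), 0.5 * (lam[i] + lam[j]),
            charge[i] * charge[j],
            eps, coul_pref, debye, rc_vdw, rc_el, compute_forces,
        )
        e_vdw += ev
        e_el += ee
        if compute_forces and fr != 0.0:
            f[i, 0] += fr * dx
            f[i, 1] += fr * dy
            f[i, 2] += fr * dz
            f[j, 0] -= fr * dx
            f[j, 1] -= fr * dy
            f[j, 2] -= fr * dz
    return e_vdw, e_el, f


@njit(cache=True, fastmath=True)
def nonbonded_all(
    pos, box, sigma, lam, charge,
    eps, coul_pref, debye, rc_vdw, rc_el, excl_next,
    compute_forces=True,
):
    """Brute-force O(N^2) nonbonded sum (reference path)."""
    n = pos.shape[0]
    f = np.zeros((n, 3))
    e_vdw = 0.0
    e_el = 0.0
    rc_max2 = max(rc_vdw, rc_el) ** 2
    for i in range(n):
        for j in range(i + 1, n):
            if j == i + 1 and excl_next[i]:
                continue
            dx = _min_image(pos[i, 0] - pos[j, 0], box[0])
            dy = _min_image(pos[i, 1] - pos[j, 1], box[1])
            dz = _min_image(pos[i, 2] - pos[j, 2], box[2])
            r2 = dx * dx + dy * dy + dz * dz
            if r2 >= rc_max2 or r2 == 0.0:
                continue
            ev, ee, fr = _pair_terms(
                dx, dy, dz, r2,
                0.5 * (sigma[i] + sigma[j]), 0.5 * (lam[i] + lam[j]),
                charge[i] * charge[j],
                eps, coul_pref, debye, rc_vdw, rc_el, compute_forces,
            )
            e_vdw += ev
            e_el += ee
            if compute_forces and fr != 0.0:
                f[i, 0] += fr * dx
                f[i, 1] += fr * dy
                f[i, 2] += fr * dz
                f[j, 0] -= fr * dx
                f[j, 1] -= fr * dy
                f[j, 2] -= fr * dz
    return e_vdw, e_el, f


@njit(cache=True, fastmath=True)
def bond_energy_forces(pos, box, bonds, k_bond, r0, compute_forces=True):
    n = pos.shape[0]
    f = np.zeros((n, 3))
    e = 0.0
    for b in range(bonds.shape[0]):
        i = bonds[b, 0]
        j = bonds[b, 1]
        dx = _min_image(pos[i, 0] - pos[j, 0], box[0])
        dy = _min_image(pos[i, 1] - pos[j, 1], box[1])
        dz = _min_image(pos[i, 2] - pos[j, 2], box[2])
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        e += 0.5 * k_bond * (r - r0) ** 2
        if compute_forces and r > 0.0:
            fr = -k_bond * (r - r0) / r
            f[i, 0] += fr * dx
            f[i, 1] += fr * dy
            f[i, 2] += fr * dz
            f[j, 0] -= fr * dx
            f[j, 1] -= fr * dy
            f[j, 2] -= fr * dz
    return e, f


# ---------------------------------------------------------------------------
# Neighbor list (cell list with brute-force fallback for small boxes)


@njit(cache=True)
def _brute_pairs(pos, box, rlist):
    n = pos.shape[0]
    r2max = rlist * rlist
    cap = 64
    out = np.empty((cap, 2), dtype=np.int64)
    cnt = 0
    for i in range(n):
        for j in range(i + 1, n):
            dx = _min_image(pos[i, 0] - pos[j, 0], box[0])
            dy = _min_image(pos[i, 1] - pos[j, 1], box[1])
            dz = _min_image(pos[i, 2] - pos[j, 2], box[2])
            if dx * dx + dy * dy + dz * dz < r2max:
                if cnt == cap:
                    cap *= 2
                    new = np.empty((cap, 2), dtype=np.int64)
                    new[:cnt] = out[:cnt]
                    out = new
                out[cnt, 0] = i
                out[cnt, 1] = j
                cnt += 1
    return out[:cnt].copy()


@njit(cache=True)
def _cell_pairs(pos, box, rlist, ncx, ncy, ncz):
    n = pos.shape[0]
    ncell = ncx * ncy * ncz
    r2max = rlist * rlist
    # assign beads to cells
    cell_of = np.empty(n, dtype=np.int64)
    counts = np.zeros(ncell, dtype=np.int64)
    for i in range(n):
        cx = int(((pos[i, 0] / box[0]) % 1.0) * ncx)
        cy = int(((pos[i, 1] / box[1]) % 1.0) * ncy)
        cz = int(((pos[i, 2] / box[2]) % 1.0) * ncz)
        if cx == ncx:
            cx = ncx - 1
        if cy == ncy:
            cy = ncy - 1
        if cz == ncz:
            cz = ncz - 1
        c = (cx * ncy + cy) * ncz + cz
        cell_of[i] = c
        counts[c] += 1
    starts = np.zeros(ncell + 1, dtype=np.int64)
    for c in range(ncell):
        starts[c + 1] = starts[c] + counts[c]
    order = np.empty(n, dtype=np.int64)
    fill = starts[:ncell].copy()
    for i in range(n):
        c = cell_of[i]
        order[fill[c]] = i
        fill[c] += 1
    # half-stencil of 13 neighbor offsets + self cell
    cap = max(64, n * 64)
    out = np.empty((cap, 2), dtype=np.int64)
    cnt = 0
    for cx in range(ncx):
        for cy in range(ncy):
            for cz in range(ncz):
                c = (cx * ncy + cy) * ncz + cz
                # pairs within the cell
                for a in range(starts[c], starts[c + 1]):
                    i = order[a]
                    for bidx in range(a + 1, starts[c + 1]):
                        j = order[bidx]
                        dx = _min_image(pos[i, 0] - pos[j, 0], box[0])
                        dy = _min_image(pos[i, 1] - pos[j, 1], box[1])
                        dz = _min_image(pos[i, 2] - pos[j, 2], box[2])
                        if dx * dx + dy * dy + dz * dz < r2max:
                            if cnt == cap:
                                cap *= 2
                                new = np.empty((cap, 2), dtype=np.int64)
                                new[:cnt] = out[:cnt]
                                out = new
                            if i < j:
                                out[cnt, 0] = i
                                out[cnt, 1] = j
                            else:
                                out[cnt, 0] = j
                                out[cnt, 1] = i
                            cnt += 1
                # pairs with half the neighboring cells
                for s in range(13):
                    ox = _HALF_STENCIL[s, 0]
                    oy = _HALF_STENCIL[s, 1]
                    oz = _HALF_STENCIL[s, 2]
                    nx = (cx + ox) % ncx
                    ny = (cy + oy) % ncy
                    nz = (cz + oz) % ncz
                    c2 = (nx * ncy + ny) * ncz + nz
                    if c2 == c:
                        continue
                    for a in range(starts[c], starts[c + 1]):
                        i = order[a]
                        for bidx in range(starts[c2], starts[c2 + 1]):
                            j = order[bidx]
                            dx = _min_image(pos[i, 0] - pos[j, 0], box[0])
                            dy = _min_image(pos[i, 1] - pos[j, 1], box[1])
                            dz = _min_image(pos[i, 2] - pos[j, 2], box[2])
                            if dx * dx + dy * dy + dz * dz < r2max:
                                if cnt == cap:
                                    cap *= 2
                                    new = np.empty((cap, 2), dtype=np.int64)
                                    new[:cnt] = out[:cnt]
                                    out = new
                                if i < j:
                                    out[cnt, 0] = i
                                    out[cnt, 1] = j
                                else:
                                    out[cnt, 0] = j
                                    out[cnt, 1] = i
                                cnt += 1
    return out[:cnt].copy()


_HALF_STENCIL = np.array(
    [
        (1, 0, 0), (0, 1, 0), (0, 0, 1),
        (1, 1, 0), (1, -1, 0), (1, 0, 1), (1, 0, -1),
        (0, 1, 1), (0, 1, -1),
        (1, 1, 1), (1, 1, -1), (1, -1, 1), (1, -1, -1),
    ],
    dtype=np.int64,
)


def neighbor_pairs(pos: np.ndarray, box: np.ndarray, cutoff: float,
                   skin: float = 0.0) -> np.ndarray:
    """Unique (i < j) bead pairs within ``cutoff + skin`` under minimum image.

    Uses a periodic cell list when the box accommodates at least three cells
    per dimension; otherwise falls back to an exact O(N^2) scan.  Either path
    yields the identical pair set (deduplicated, sorted).
    """
    rlist = cutoff + skin
    pos = np.ascontiguousarray(pos, dtype=np.float64)
    box = np.asarray(box, dtype=np.float64)
    nc = np.floor(box / rlist).astype(np.int64)
    if np.any(nc < 3):
        pairs = _brute_pairs(pos, box, rlist)
    else:
        pairs = _cell_pairs(pos, box, rlist, int(nc[0]), int(nc[1]), int(nc[2]))
        # wrap-around stencils can revisit a pair; deduplicate
        if len(pairs):
            key = pairs[:, 0] * pos.shape[0] + pairs[:, 1]
            _, idx = np.unique(key, return_index=True)
            pairs = pairs[idx]
    if len(pairs) == 0:
        return np.empty((0, 2), dtype=np.int64)
    order = np.lexsort((pairs[:, 1], pairs[:, 0]))
    return pairs[order]
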