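"""Numba-compiled engine: neighbor search, force evaluation, time integration.

Everything here operates on plain arrays packed from a
:class:`~gelperm.system.BeadSystem`.  The integrator is velocity-Verlet with a
per-step Langevin kick; shell-bead normals follow an overdamped rotational
Langevin update; rigid particles are propagated as rigid bodies (quaternion
orientation, body-frame angular velocity).

The thermostat noise is uniform with the fluctuation-dissipation variance
(the accumulated velocity distribution is Gaussian by the central limit
theorem); this is the usual cheap choice for Langevin dynamics and is why the
pure-Python step operations in :mod:`gelperm.dynamics`, which use Gaussian
noise, are statistically but not bitwise equivalent to the compiled loop.

Neighbor search is a linked-cell binning into a counting-sorted layout with a
precomputed 13-cell half stencil; pair lists carry a Verlet skin and are
rebuilt when the largest accumulated bead displacement exceeds half the skin.
"""

from __future__ import annotations

import math
from typing import NamedTuple

import numpy as np
from numba import njit

F8 = np.float64
I8 = np.int64

# status codes returned by the run loop
STATUS_OK = 0
STATUS_BLOWUP = 1
STATUS_NAN = 2
STATUS_OVERFLOW = 3

MAX_STEP_DISPLACEMENT = 0.5  # sigma; blow-up guard
DEFAULT_SKIN = 1.0


class PackedSystem(NamedTuple):
    pos: np.ndarray          # (N,3) wrapped
    img: np.ndarray          # (N,3) int64 periodic image counts
    vel: np.ndarray
    nrm: np.ndarray
    masses: np.ndarray
    btype: np.ndarray        # (N,) int8
    np_id: np.ndarray        # (N,) int32
    rigid_bead: np.ndarray   # (N,) uint8
    bead_eps: np.ndarray     # (N,) shell interaction strength
    bond_i: np.ndarray
    bond_j: np.ndarray
    bond_k: np.ndarray
    bond_r0: np.ndarray
    teth_i: np.ndarray
    teth_anchor: np.ndarray
    teth_k: np.ndarray
    excl: np.ndarray         # sorted int64 keys i*N+j (i<j) of bonded pairs
    np_start: np.ndarray
    np_count: np.ndarray
    np_rigid: np.ndarray     # (n_np,) uint8
    body_pos: np.ndarray     # (n_np, max_nb, 3) principal body frame (rigid only)
    body_nrm: np.ndarray
    quat: np.ndarray         # (n_np, 4) w,x,y,z
    com: np.ndarray          # (n_np, 3) unwrapped centers
    com_vel: np.ndarray
    omega: np.ndarray        # (n_np, 3) body frame
    inertia: np.ndarray      # (n_np, 3) principal moments
    box: float
    ff: np.ndarray           # packed force-field scalars, see pack_params


def pack_params(params) -> np.ndarray:
    """Flatten ForceFieldParams into a scalar array for the kernels."""
    sc6 = (params.sigma_pn / params.cutoff_pn) ** 6
    shift_pn = 4.0 * params.eps_pn * (sc6 * sc6 - sc6)
    sw6 = (params.sigma_pp / params.cutoff_pp) ** 6
    shift_pp = 4.0 * params.eps_pp * (sw6 * sw6 - sw6)
    return np.array([
        params.eps_pp, params.sigma_pp, params.cutoff_pp, shift_pp,
        params.eps_pn, params.sigma_pn, params.cutoff_pn, shift_pn,
        params.np_rmin, params.np_rcut, float(params.np_zeta), params.np_mu,
        math.sin(params.np_theta0),
    ])


def pack_system(system, params) -> PackedSystem:
    """Assemble kernel-ready arrays, including rigid-body frames."""
    n = system.n_beads
    n_np = system.n_nps
    max_nb = int(system.np_count.max()) if n_np else 1

    rigid_bead = np.zeros(n, dtype=np.uint8)
    body_pos = np.zeros((max(n_np, 1), max_nb, 3))
    body_nrm = np.zeros_like(body_pos)
    quat = np.zeros((max(n_np, 1), 4))
    quat[:, 0] = 1.0
    com = np.zeros((max(n_np, 1), 3))
    com_vel = np.zeros_like(com)
    omega = np.zeros_like(com)
    inertia = np.ones((max(n_np, 1), 3))

    box = system.box_length
    for k in range(n_np):
        sl = system.np_slice(k)
        pos = system.positions[sl]
        # coherent (minimum-image) coordinates relative to the first bead
        rel = pos - pos[0]
        rel -= box * np.round(rel / box)
        centroid = rel.mean(axis=0)
        rel -= centroid
        com[k] = pos[0] + centroid
        if not system.np_rigid[k]:
            continue
        rigid_bead[sl] = 1
        m = system.masses[sl]
        itens = np.zeros((3, 3))
        for b in range(len(rel)):
            r = rel[b]
            itens += m[b] * ((r @ r) * np.eye(3) - np.outer(r, r))
        w, v = np.linalg.eigh(itens)
        if np.linalg.det(v) < 0:
            v[:, 0] = -v[:, 0]
        nb = len(rel)
        body_pos[k, :nb] = rel @ v
        body_nrm[k, :nb] = system.normals[sl] @ v
        inertia[k] = np.maximum(w, 1e-12)
        quat[k] = _mat_to_quat(v)
        vels = system.velocities[sl]
        com_vel[k] = (m[:, None] * vels).sum(axis=0) / m.sum()
        ang = np.zeros(3)
        for b in range(nb):
            ang += m[b] * np.cross(rel[b], vels[b] - com_vel[k])
        omega[k] = (v.T @ ang) / inertia[k]

    excl = np.sort(
        np.minimum(system.bond_i, system.bond_j).astype(np.int64) * n
        + np.maximum(system.bond_i, system.bond_j).astype(np.int64)
    )
    return PackedSystem(
        pos=np.ascontiguousarray(system.positions, dtype=F8),
        img=np.zeros((n, 3), dtype=I8),
        vel=np.ascontiguousarray(system.velocities, dtype=F8),
        nrm=np.ascontiguousarray(system.normals, dtype=F8),
        masses=np.ascontiguousarray(system.masses, dtype=F8),
        btype=np.ascontiguousarray(system.bead_type, dtype=np.int8),
        np_id=np.ascontiguousarray(system.np_membership, dtype=np.int32),
        rigid_bead=rigid_bead,
        bead_eps=params.bead_np_eps(system),
        bond_i=np.ascontiguousarray(system.bond_i, dtype=np.int32),
        bond_j=np.ascontiguousarray(system.bond_j, dtype=np.int32),
        bond_k=np.ascontiguousarray(system.bond_k, dtype=F8),
        bond_r0=np.ascontiguousarray(system.bond_r0, dtype=F8),
        teth_i=np.ascontiguousarray(system.tether_idx, dtype=np.int32),
        teth_anchor=np.ascontiguousarray(system.tether_anchor, dtype=F8),
        teth_k=np.ascontiguousarray(system.tether_k, dtype=F8),
        excl=excl,
        np_start=np.ascontiguousarray(system.np_start, dtype=np.int32),
        np_count=np.ascontiguousarray(system.np_count, dtype=np.int32),
        np_rigid=system.np_rigid.astype(np.uint8),
        body_pos=body_pos,
        body_nrm=body_nrm,
        quat=quat,
        com=com,
        com_vel=com_vel,
        omega=omega,
        inertia=inertia,
        box=float(system.box_length),
        ff=pack_params(params),
    )


def _mat_to_quat(m: np.ndarray) -> np.ndarray:
    """Rotation matrix (columns = body axes in space frame) to quaternion."""
    t = np.trace(m)
    if t > 0:
        s = math.sqrt(t + 1.0) * 2
        return np.array([0.25 * s, (m[2, 1] - m[1, 2]) / s,
                         (m[0, 2] - m[2, 0]) / s, (m[1, 0] - m[0, 1]) / s])
    i = int(np.argmax(np.diag(m)))
    j, k = (i + 1) % 3, (i + 2) % 3
    s = math.sqrt(max(1e-12, 1.0 + m[i, i] - m[j, j] - m[k, k])) * 2
    q = np.zeros(4)
    q[0] = (m[k, j] - m[j, k]) / s
    q[1 + i] = 0.25 * s
    q[1 + j] = (m[j, i] + m[i, j]) / s
    q[1 + k] = (m[k, i] + m[i, k]) / s
    return q / np.linalg.norm(q)


# ---------------------------------------------------------------------------
# RNG: xorshift128+ seeded by splitmix64; uniform noise with matched variance
# ---------------------------------------------------------------------------

@njit(cache=True, inline="always")
def _splitmix64(x):
    x = (x + np.uint64(0x9E3779B97F4A7C15)) & np.uint64(0xFFFFFFFFFFFFFFFF)
    z = x
    z = ((z ^ (z >> np.uint64(30))) * np.uint64(0xBF58476D1CE4E5B9)) & np.uint64(0xFFFFFFFFFFFFFFFF)
    z = ((z ^ (z >> np.uint64(27))) * np.uint64(0x94D049BB133111EB)) & np.uint64(0xFFFFFFFFFFFFFFFF)
    return x, z ^ (z >> np.uint64(31))


@njit(cache=True, inline="always")
def _xs_next(s0, s1):
    x = s0
    y = s1
    s0 = y
    x ^= (x << np.uint64(23)) & np.uint64(0xFFFFFFFFFFFFFFFF)
    s1 = x ^ y ^ (x >> np.uint64(17)) ^ (y >> np.uint64(26))
    out = (s1 + y) & np.uint64(0xFFFFFFFFFFFFFFFF)
    return s0, s1, out


@njit(cache=True, inline="always")
def _uniform_centered(s0, s1):
    """Uniform in [-0.5, 0.5) with 53-bit resolution."""
    s0, s1, u = _xs_next(s0, s1)
    return s0, s1, (u >> np.uint64(11)) * (1.0 / 9007199254740992.0) - 0.5


@njit(cache=True)
def _seed_state(seed):
    st = np.uint64(seed)
    st, s0 = _splitmix64(st)
    st, s1 = _splitmix64(st)
    if s0 == np.uint64(0) and s1 == np.uint64(0):
        s1 = np.uint64(0x9E3779B97F4A7C15)
    return s0, s1


SQRT12 = math.sqrt(12.0)

@njit(cache=True, inline="always")
def _mi(d, box, half_box):
    """Minimum image for wrapped coordinates (|d| < box guaranteed)."""
    if d > half_box:
        return d - box
    if d < -half_box:
        return d + box
    return d



# ---------------------------------------------------------------------------
# neighbor lists
# ---------------------------------------------------------------------------

def make_cell_table(box: float, rmax: float):
    """Cell grid geometry and the 13-cell half-stencil neighbor table.

    Returns (ncell, cell_nbrs) where cell_nbrs[c] lists the 13 neighbor cell
    ids of cell c under periodic wrapping; ncell == 1 signals the all-pairs
    fallback for small boxes.
    """
    ncell = int(box / rmax)
    if ncell < 3:
        return 1, np.zeros((1, 13), dtype=I8)
    stencil = [(1, 0, 0), (0, 1, 0), (0, 0, 1),
               (1, 1, 0), (1, -1, 0), (1, 0, 1), (1, 0, -1),
               (0, 1, 1), (0, 1, -1),
               (1, 1, 1), (1, 1, -1), (1, -1, 1), (1, -1, -1)]
    nbrs = np.empty((ncell**3, 13), dtype=I8)
    for cx in range(ncell):
        for cy in range(ncell):
            for cz in range(ncell):
                c = (cx * ncell + cy) * ncell + cz
                for s, (ox, oy, oz) in enumerate(stencil):
                    nbrs[c, s] = (((cx + ox) % ncell) * ncell
                                  + (cy + oy) % ncell) * ncell + (cz + oz) % ncell
    return ncell, nbrs


@njit(cache=True, inline="always")
def _in_excl(excl, key):
    lo, hi = 0, excl.shape[0]
    while lo < hi:
        mid = (lo + hi) // 2
        if excl[mid] < key:
            lo = mid + 1
        else:
            hi = mid
    return lo < excl.shape[0] and excl[lo] == key


@njit(cache=True, fastmath=True)
def _build_pairs(pos, box, btype, np_id, rigid_bead, bead_eps, excl,
                 ncell, cell_nbrs, r_pp2, r_pn2, r_nn2,
                 pp, pn, nn, nn_eps):
    """Fill typed half pair lists via counting-sorted linked cells.

    Returns (n_pp, n_pn, n_nn); entries beyond an array's capacity are
    counted but not stored (the caller grows and retries).
    """
    n = pos.shape[0]
    half_box = 0.5 * box
    n_pp = 0
    n_pn = 0
    n_nn = 0

    if ncell == 1:
        count = np.zeros(2, dtype=I8)
        order = np.empty(n, dtype=I8)
        for i in range(n):
            order[i] = i
        count[1] = n
        ncells = 1
    else:
        ncells = ncell * ncell * ncell
        inv_cell = ncell / box
        count = np.zeros(ncells + 1, dtype=I8)
        cid = np.empty(n, dtype=I8)
        for i in range(n):
            cx = int(pos[i, 0] * inv_cell)
            cy = int(pos[i, 1] * inv_cell)
            cz = int(pos[i, 2] * inv_cell)
            if cx >= ncell:
                cx = ncell - 1
            if cy >= ncell:
                cy = ncell - 1
            if cz >= ncell:
                cz = ncell - 1
            c = (cx * ncell + cy) * ncell + cz
            cid[i] = c
            count[c + 1] += 1
        for c in range(ncells):
            count[c + 1] += count[c]
        order = np.empty(n, dtype=I8)
        fill = count[:-1].copy()
        for i in range(n):
            c = cid[i]
            order[fill[c]] = i
            fill[c] += 1

    n_stencil = 14 if ncells > 1 else 1
    for c in range(ncells):
        lo = count[c]
        hi = count[c + 1]
        for a in range(lo, hi):
            i = order[a]
            xi = pos[i, 0]
            yi = pos[i, 1]
            zi = pos[i, 2]
            ti = btype[i]
            for sidx in range(n_stencil):
                if sidx == 0:
                    b0 = a + 1
                    b1 = hi
                else:
                    c2 = cell_nbrs[c, sidx - 1]
                    b0 = count[c2]
                    b1 = count[c2 + 1]
                for b in range(b0, b1):
                    j = order[b]
                    dx = xi - pos[j, 0]
                    if dx > half_box:
                        dx -= box
                    elif dx < -half_box:
                        dx += box
                    dy = yi - pos[j, 1]
                    if dy > half_box:
                        dy -= box
                    elif dy < -half_box:
                        dy += box
                    dz = zi - pos[j, 2]
                    if dz > half_box:
                        dz -= box
                    elif dz < -half_box:
                        dz += box
                    d2 = dx * dx + dy * dy + dz * dz
                    tj = btype[j]
                    if ti + tj == 4:          # shell-shell
                        if d2 < r_nn2 and not (np_id[i] == np_id[j]
                                               and rigid_bead[i]):
                            if n_nn < nn.shape[0]:
                                ii = i if i < j else j
                                jj = j if i < j else i
                                nn[n_nn, 0] = ii
                                nn[n_nn, 1] = jj
                                nn_eps[n_nn] = math.sqrt(
                                    bead_eps[i] * bead_eps[j])
                            n_nn += 1
                    elif ti == 2 or tj == 2:  # polymer-shell
                        if d2 < r_pn2:
                            if n_pn < pn.shape[0]:
                                pn[n_pn, 0] = i
                                pn[n_pn, 1] = j
                            n_pn += 1
                    else:                     # network-network
                        if d2 < r_pp2:
                            ii = i if i < j else j
                            jj = j if i < j else i
                            if not _in_excl(excl, ii * n + jj):
                                if n_pp < pp.shape[0]:
                                    pp[n_pp, 0] = ii
                                    pp[n_pp, 1] = jj
                                n_pp += 1
    return n_pp, n_pn, n_nn


# ---------------------------------------------------------------------------
# force evaluation
# ---------------------------------------------------------------------------

@njit(cache=True, fastmath=True)
def _forces(pos, nrm, box, ff, nn_eps,
            bond_i, bond_j, bond_k, bond_r0,
            teth_i, teth_anchor, teth_k,
            pp, n_pp, pn, n_pn, nn, n_nn,
            f, tq, terms):
    eps_pp = ff[0]
    sig_pp = ff[1]
    cut_pp = ff[2]
    shift_pp = ff[3]
    eps_pn = ff[4]
    sig_pn = ff[5]
    cut_pn = ff[6]
    shift_pn = ff[7]
    rmin = ff[8]
    rcut = ff[9]
    zeta = int(ff[10])
    mu = ff[11]
    st0 = ff[12]

    half_box = 0.5 * box
    f[:] = 0.0
    tq[:] = 0.0
    e_bond = 0.0
    e_teth = 0.0
    e_wca = 0.0
    e_lj = 0.0
    e_np = 0.0

    cut_pp2 = cut_pp * cut_pp
    cut_pn2 = cut_pn * cut_pn
    rmin2 = rmin * rmin
    rcut2 = rcut * rcut
    half_pi_over_delta = 0.5 * math.pi / (rcut - rmin)
    sig_pp2 = sig_pp * sig_pp
    sig_pn2 = sig_pn * sig_pn

    # bonds
    for b in range(bond_i.shape[0]):
        i = bond_i[b]
        j = bond_j[b]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        dx = _mi(dx, box, half_box)
        dy = _mi(dy, box, half_box)
        dz = _mi(dz, box, half_box)
        r = math.sqrt(dx * dx + dy * dy + dz * dz)
        k = bond_k[b]
        dr = r - bond_r0[b]
        e_bond += k * dr * dr
        fr = -2.0 * k * dr / r
        f[i, 0] += fr * dx
        f[i, 1] += fr * dy
        f[i, 2] += fr * dz
        f[j, 0] -= fr * dx
        f[j, 1] -= fr * dy
        f[j, 2] -= fr * dz

    # tethers (anchors are fixed space points; compare under minimum image)
    for t in range(teth_i.shape[0]):
        i = teth_i[t]
        dx = pos[i, 0] - teth_anchor[t, 0]
        dy = pos[i, 1] - teth_anchor[t, 1]
        dz = pos[i, 2] - teth_anchor[t, 2]
        dx = _mi(dx, box, half_box)
        dy = _mi(dy, box, half_box)
        dz = _mi(dz, box, half_box)
        k = teth_k[t]
        e_teth += k * (dx * dx + dy * dy + dz * dz)
        f[i, 0] -= 2.0 * k * dx
        f[i, 1] -= 2.0 * k * dy
        f[i, 2] -= 2.0 * k * dz

    # polymer-polymer WCA
    for p in range(n_pp):
        i = pp[p, 0]
        j = pp[p, 1]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        dx = _mi(dx, box, half_box)
        dy = _mi(dy, box, half_box)
        dz = _mi(dz, box, half_box)
        d2 = dx * dx + dy * dy + dz * dz
        if d2 < cut_pp2:
            inv2 = sig_pp2 / d2
            sr6 = inv2 * inv2 * inv2
            e_wca += 4.0 * eps_pp * (sr6 * sr6 - sr6) - shift_pp
            fr = 24.0 * eps_pp * (2.0 * sr6 * sr6 - sr6) / d2
            f[i, 0] += fr * dx
            f[i, 1] += fr * dy
            f[i, 2] += fr * dz
            f[j, 0] -= fr * dx
            f[j, 1] -= fr * dy
            f[j, 2] -= fr * dz

    # polymer-NP LJ
    for p in range(n_pn):
        i = pn[p, 0]
        j = pn[p, 1]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        dx = _mi(dx, box, half_box)
        dy = _mi(dy, box, half_box)
        dz = _mi(dz, box, half_box)
        d2 = dx * dx + dy * dy + dz * dz
        if d2 < cut_pn2:
            inv2 = sig_pn2 / d2
            sr6 = inv2 * inv2 * inv2
            e_lj += 4.0 * eps_pn * (sr6 * sr6 - sr6) - shift_pn
            fr = 24.0 * eps_pn * (2.0 * sr6 * sr6 - sr6) / d2
            f[i, 0] += fr * dx
            f[i, 1] += fr * dy
            f[i, 2] += fr * dz
            f[j, 0] -= fr * dx
            f[j, 1] -= fr * dy
            f[j, 2] -= fr * dz

    # shell-bead pairs: orientation-weighted soft-core potential
    zeta4 = zeta == 4
    for p in range(n_nn):
        i = nn[p, 0]
        j = nn[p, 1]
        # r_vec points from i to j
        dx = pos[j, 0] - pos[i, 0]
        dx = _mi(dx, box, half_box)
        dy = pos[j, 1] - pos[i, 1]
        dy = _mi(dy, box, half_box)
        dz = pos[j, 2] - pos[i, 2]
        dz = _mi(dz, box, half_box)
        d2 = dx * dx + dy * dy + dz * dz
        if d2 >= rcut2:
            continue
        r = math.sqrt(d2)
        inv_r = 1.0 / r
        rx = dx * inv_r
        ry = dy * inv_r
        rz = dz * inv_r
        nix = nrm[i, 0]
        niy = nrm[i, 1]
        niz = nrm[i, 2]
        njx = nrm[j, 0]
        njy = nrm[j, 1]
        njz = nrm[j, 2]
        ni_r = nix * rx + niy * ry + niz * rz
        nj_r = njx * rx + njy * ry + njz * rz
        ninj = nix * njx + niy * njy + niz * njz
        e = nn_eps[p]

        a = ninj - ni_r * nj_r + st0 * (nj_r - ni_r) - st0 * st0
        phi = 1.0 + mu * (a - 1.0)
        if d2 < rmin2:
            x2 = rmin2 / d2
            u = e * (x2 * x2 - 2.0 * x2) + (1.0 - phi) * e
            du_dr = e * (-4.0 * x2 * x2 + 4.0 * x2) * inv_r
            du_da = -mu * e
        else:
            psi = half_pi_over_delta * (r - rmin)
            c = math.cos(psi)
            s = math.sqrt(max(0.0, 1.0 - c * c))  # psi in [0, pi/2]
            c2 = c * c
            if zeta4:
                c4 = c2 * c2
                cz2 = c4 * c4                     # cos^8
                czm = c4 * c2 * c                 # cos^7
            else:
                cz2 = c2
                for _ in range(zeta - 1):
                    cz2 *= c2                     # cos^(2 zeta)
                czm = cz2 / c
            ua = -e * cz2
            dua_dr = e * 2.0 * zeta * czm * s * half_pi_over_delta
            u = phi * ua
            du_dr = phi * dua_dr
            du_da = mu * ua
        e_np += u

        # da/drhat
        gx = -(nj_r * nix + ni_r * njx) + st0 * (njx - nix)
        gy = -(nj_r * niy + ni_r * njy) + st0 * (njy - niy)
        gz = -(nj_r * niz + ni_r * njz) + st0 * (njz - niz)
        g_dot_r = gx * rx + gy * ry + gz * rz
        # grad_{r_vec} U
        cx_ = du_dr * rx + du_da * (gx - g_dot_r * rx) * inv_r
        cy_ = du_dr * ry + du_da * (gy - g_dot_r * ry) * inv_r
        cz_ = du_dr * rz + du_da * (gz - g_dot_r * rz) * inv_r
        # F_j = -grad, F_i = +grad
        f[i, 0] += cx_
        f[i, 1] += cy_
        f[i, 2] += cz_
        f[j, 0] -= cx_
        f[j, 1] -= cy_
        f[j, 2] -= cz_
        # generalized forces on the normals
        tq[i, 0] -= du_da * (njx - nj_r * rx - st0 * rx)
        tq[i, 1] -= du_da * (njy - nj_r * ry - st0 * ry)
        tq[i, 2] -= du_da * (njz - nj_r * rz - st0 * rz)
        tq[j, 0] -= du_da * (nix - ni_r * rx + st0 * rx)
        tq[j, 1] -= du_da * (niy - ni_r * ry + st0 * ry)
        tq[j, 2] -= du_da * (niz - ni_r * rz + st0 * rz)

    terms[0] = e_bond
    terms[1] = e_teth
    terms[2] = e_wca
    terms[3] = e_lj
    terms[4] = e_np


def _list_radii(ff, skin):
    return ff[2] + skin, ff[6] + skin, ff[9] + skin


def build_pair_lists(packed: PackedSystem, skin: float = DEFAULT_SKIN):
    """Python-side wrapper that sizes, builds and (if needed) regrows lists."""
    n = packed.pos.shape[0]
    r_pp, r_pn, r_nn = _list_radii(packed.ff, skin)
    ncell, cell_nbrs = make_cell_table(packed.box, max(r_pp, r_pn, r_nn))
    cap_pp, cap_pn, cap_nn = 8 * n + 64, 8 * n + 64, 16 * n + 64
    while True:
        pp = np.empty((cap_pp, 2), dtype=I8)
        pn = np.empty((cap_pn, 2), dtype=I8)
        nn = np.empty((cap_nn, 2), dtype=I8)
        nn_eps = np.empty(cap_nn)
        n_pp, n_pn, n_nn = _build_pairs(
            packed.pos, packed.box, packed.btype, packed.np_id,
            packed.rigid_bead, packed.bead_eps, packed.excl,
            ncell, cell_nbrs, r_pp * r_pp, r_pn * r_pn, r_nn * r_nn,
            pp, pn, nn, nn_eps)
        if n_pp <= cap_pp and n_pn <= cap_pn and n_nn <= cap_nn:
            return pp, n_pp, pn, n_pn, nn, n_nn, nn_eps
        cap_pp = max(cap_pp, 2 * n_pp)
        cap_pn = max(cap_pn, 2 * n_pn)
        cap_nn = max(cap_nn, 2 * n_nn)


def evaluate_forces(packed: PackedSystem, skin: float = DEFAULT_SKIN):
    """One-shot force/torque/energy evaluation (used by compute_forces)."""
    pp, n_pp, pn, n_pn, nn, n_nn, nn_eps = build_pair_lists(packed, skin)
    n = packed.pos.shape[0]
    f = np.zeros((n, 3))
    tq = np.zeros((n, 3))
    terms = np.zeros(5)
    _forces(packed.pos, packed.nrm, packed.box, packed.ff, nn_eps,
            packed.bond_i, packed.bond_j, packed.bond_k, packed.bond_r0,
            packed.teth_i, packed.teth_anchor, packed.teth_k,
            pp, n_pp, pn, n_pn, nn, n_nn, f, tq, terms)
    return f, tq, terms


# ---------------------------------------------------------------------------
# quaternion helpers
# ---------------------------------------------------------------------------

@njit(cache=True, inline="always")
def _quat_to_mat(q, m):
    w, x, y, z = q[0], q[1], q[2], q[3]
    m[0, 0] = 1 - 2 * (y * y + z * z)
    m[0, 1] = 2 * (x * y - w * z)
    m[0, 2] = 2 * (x * z + w * y)
    m[1, 0] = 2 * (x * y + w * z)
    m[1, 1] = 1 - 2 * (x * x + z * z)
    m[1, 2] = 2 * (y * z - w * x)
    m[2, 0] = 2 * (x * z - w * y)
    m[2, 1] = 2 * (y * z + w * x)
    m[2, 2] = 1 - 2 * (x * x + y * y)


@njit(cache=True, inline="always")
def _quat_rotate_by_omega(q, wx, wy, wz, dt):
    """Rotate quaternion by space-frame angular velocity over dt (exact map)."""
    w = math.sqrt(wx * wx + wy * wy + wz * wz)
    ang = w * dt
    if ang < 1e-14:
        return
    h = 0.5 * ang
    s = math.sin(h) / w
    cw = math.cos(h)
    dx = wx * s
    dy = wy * s
    dz = wz * s
    w0, x0, y0, z0 = q[0], q[1], q[2], q[3]
    q[0] = cw * w0 - dx * x0 - dy * y0 - dz * z0
    q[1] = cw * x0 + dx * w0 + dy * z0 - dz * y0
    q[2] = cw * y0 - dx * z0 + dy * w0 + dz * x0
    q[3] = cw * z0 + dx * y0 - dy * x0 + dz * w0
    inv = 1.0 / math.sqrt(q[0] ** 2 + q[1] ** 2 + q[2] ** 2 + q[3] ** 2)
    for k in range(4):
        q[k] *= inv


# ---------------------------------------------------------------------------
# the run loop
# ---------------------------------------------------------------------------

@njit(cache=True, fastmath=True)
def run_loop(pos, img, vel, nrm, masses, btype, np_id, rigid_bead, bead_eps,
             bond_i, bond_j, bond_kk, bond_r0,
             teth_i, teth_anchor, teth_k, excl,
             np_start, np_count, np_rigid, body_pos, body_nrm,
             quat, com, com_vel, omega, inertia,
             box, ff,
             dt, gamma, gamma_n, kT, n_steps, seed, skin,
             ncell, cell_nbrs,
             pp, pn, nn, nn_eps, list_counts,
             frame_every, cent_every,
             frames_pos, frames_img, frames_nrm, frames_pe, frames_ke,
             cents, cent_times):
    """Integrate n_steps of Langevin/velocity-Verlet dynamics in place.

    Returns (status, steps_done).  Frames and NP centroids are written into
    the preallocated output arrays every frame_every / cent_every steps.
    """
    n = pos.shape[0]
    n_np = np_start.shape[0]

    s0, s1 = _seed_state(seed)

    r_pp, r_pn, r_nn = ff[2] + skin, ff[6] + skin, ff[9] + skin
    r_pp2 = r_pp * r_pp
    r_pn2 = r_pn * r_pn
    r_nn2 = r_nn * r_nn

    f = np.zeros((n, 3))
    tq = np.zeros((n, 3))
    terms = np.zeros(5)
    rot = np.empty((3, 3))
    half_dt = 0.5 * dt
    trigger2 = (0.5 * skin) ** 2
    blow2 = MAX_STEP_DISPLACEMENT * MAX_STEP_DISPLACEMENT

    # Langevin noise scales (uniform noise with matched variance);
    # per-bead because masses may differ
    lscale = np.empty(n)
    gdt = np.empty(n)
    for i in range(n):
        lscale[i] = SQRT12 * math.sqrt(2.0 * gamma * kT * dt) / masses[i]
        gdt[i] = gamma * dt / masses[i]
    nscale = SQRT12 * math.sqrt(2.0 * kT * dt / gamma_n) if gamma_n > 0 else 0.0
    inv_gn = dt / gamma_n if gamma_n > 0 else 0.0

    # accumulated displacement since the last list build (rebuild trigger)
    acc = np.zeros((n, 3))

    n_pp, n_pn, n_nn = _build_pairs(pos, box, btype, np_id, rigid_bead,
                                    bead_eps, excl, ncell, cell_nbrs,
                                    r_pp2, r_pn2, r_nn2, pp, pn, nn, nn_eps)
    if n_pp > pp.shape[0] or n_pn > pn.shape[0] or n_nn > nn.shape[0]:
        return STATUS_OVERFLOW, 0
    _forces(pos, nrm, box, ff, nn_eps, bond_i, bond_j, bond_kk, bond_r0,
            teth_i, teth_anchor, teth_k, pp, n_pp, pn, n_pn, nn, n_nn,
            f, tq, terms)

    Fb = np.zeros((n_np, 3))
    Tb = np.zeros((n_np, 3))
    any_rigid = False
    for k in range(n_np):
        if np_rigid[k]:
            any_rigid = True
    if any_rigid:
        _collect_rigid(f, pos, com, img, box, np_start, np_count, np_rigid,
                       Fb, Tb)

    frame_idx = 0
    cent_idx = 0
    rebuilds = 0

    for step in range(n_steps):
        # --- first half kick + drift
        max2 = 0.0
        step2 = 0.0
        for i in range(n):
            if rigid_bead[i]:
                continue
            inv_m = 1.0 / masses[i]
            dd2 = 0.0
            for d in range(3):
                vel[i, d] += half_dt * f[i, d] * inv_m
                dx = dt * vel[i, d]
                dd2 += dx * dx
                x = pos[i, d] + dx
                if x >= box:
                    x -= box
                    img[i, d] += 1
                elif x < 0.0:
                    x += box
                    img[i, d] -= 1
                pos[i, d] = x
                acc[i, d] += dx
            if dd2 > step2:
                step2 = dd2
            a2 = acc[i, 0] ** 2 + acc[i, 1] ** 2 + acc[i, 2] ** 2
            if a2 > max2:
                max2 = a2

        # rigid bodies: half kick com/omega, drift, rotate, rebuild beads
        if any_rigid:
            for k in range(n_np):
                if not np_rigid[k]:
                    continue
                nb = np_count[k]
                M = nb * 1.0  # unit masses
                for d in range(3):
                    com_vel[k, d] += half_dt * Fb[k, d] / M
                _quat_to_mat(quat[k], rot)
                tbx = rot[0, 0] * Tb[k, 0] + rot[1, 0] * Tb[k, 1] + rot[2, 0] * Tb[k, 2]
                tby = rot[0, 1] * Tb[k, 0] + rot[1, 1] * Tb[k, 1] + rot[2, 1] * Tb[k, 2]
                tbz = rot[0, 2] * Tb[k, 0] + rot[1, 2] * Tb[k, 1] + rot[2, 2] * Tb[k, 2]
                wx, wy, wz = omega[k, 0], omega[k, 1], omega[k, 2]
                Ix, Iy, Iz = inertia[k, 0], inertia[k, 1], inertia[k, 2]
                omega[k, 0] += half_dt * (tbx - (Iz - Iy) * wy * wz) / Ix
                omega[k, 1] += half_dt * (tby - (Ix - Iz) * wz * wx) / Iy
                omega[k, 2] += half_dt * (tbz - (Iy - Ix) * wx * wy) / Iz
                dd2 = 0.0
                for d in range(3):
                    dx = dt * com_vel[k, d]
                    com[k, d] += dx
                    dd2 += dx * dx
                if dd2 > step2:
                    step2 = dd2
                wsx = rot[0, 0] * omega[k, 0] + rot[0, 1] * omega[k, 1] + rot[0, 2] * omega[k, 2]
                wsy = rot[1, 0] * omega[k, 0] + rot[1, 1] * omega[k, 1] + rot[1, 2] * omega[k, 2]
                wsz = rot[2, 0] * omega[k, 0] + rot[2, 1] * omega[k, 1] + rot[2, 2] * omega[k, 2]
                _quat_rotate_by_omega(quat[k], wsx, wsy, wsz, dt)
                _quat_to_mat(quat[k], rot)
                st = np_start[k]
                for b in range(nb):
                    i = st + b
                    a2 = 0.0
                    for d in range(3):
                        raw = com[k, d] + rot[d, 0] * body_pos[k, b, 0] \
                            + rot[d, 1] * body_pos[k, b, 1] \
                            + rot[d, 2] * body_pos[k, b, 2]
                        im = math.floor(raw / box)
                        old_unwrapped = pos[i, d] + img[i, d] * box
                        pos[i, d] = raw - im * box
                        img[i, d] = int(im)
                        acc[i, d] += raw - old_unwrapped
                        a2 += acc[i, d] * acc[i, d]
                        nrm[i, d] = rot[d, 0] * body_nrm[k, b, 0] \
                            + rot[d, 1] * body_nrm[k, b, 1] \
                            + rot[d, 2] * body_nrm[k, b, 2]
                    if a2 > max2:
                        max2 = a2

        if step2 > blow2:
            return STATUS_BLOWUP, step
        if max2 > trigger2:
            rebuilds += 1
            n_pp, n_pn, n_nn = _build_pairs(
                pos, box, btype, np_id, rigid_bead, bead_eps, excl,
                ncell, cell_nbrs, r_pp2, r_pn2, r_nn2, pp, pn, nn, nn_eps)
            if n_pp > pp.shape[0] or n_pn > pn.shape[0] or n_nn > nn.shape[0]:
                return STATUS_OVERFLOW, step
            acc[:] = 0.0

        # --- new forces
        _forces(pos, nrm, box, ff, nn_eps, bond_i, bond_j, bond_kk, bond_r0,
                teth_i, teth_anchor, teth_k, pp, n_pp, pn, n_pn, nn, n_nn,
                f, tq, terms)
        if any_rigid:
            _collect_rigid(f, pos, com, img, box, np_start, np_count,
                           np_rigid, Fb, Tb)

        # --- second half kick + Langevin kick (translations)
        if gamma > 0.0:
            for i in range(n):
                if rigid_bead[i]:
                    continue
                inv_m = 1.0 / masses[i]
                for d in range(3):
                    v = vel[i, d] + half_dt * f[i, d] * inv_m
                    s0, s1, u = _uniform_centered(s0, s1)
                    vel[i, d] = v - gdt[i] * v + lscale[i] * u
        else:
            for i in range(n):
                if rigid_bead[i]:
                    continue
                inv_m = 1.0 / masses[i]
                for d in range(3):
                    vel[i, d] += half_dt * f[i, d] * inv_m

        if any_rigid:
            for k in range(n_np):
                if not np_rigid[k]:
                    continue
                nb = np_count[k]
                M = nb * 1.0
                _quat_to_mat(quat[k], rot)
                tbx = rot[0, 0] * Tb[k, 0] + rot[1, 0] * Tb[k, 1] + rot[2, 0] * Tb[k, 2]
                tby = rot[0, 1] * Tb[k, 0] + rot[1, 1] * Tb[k, 1] + rot[2, 1] * Tb[k, 2]
                tbz = rot[0, 2] * Tb[k, 0] + rot[1, 2] * Tb[k, 1] + rot[2, 2] * Tb[k, 2]
                wx, wy, wz = omega[k, 0], omega[k, 1], omega[k, 2]
                Ix, Iy, Iz = inertia[k, 0], inertia[k, 1], inertia[k, 2]
                omega[k, 0] += half_dt * (tbx - (Iz - Iy) * wy * wz) / Ix
                omega[k, 1] += half_dt * (tby - (Ix - Iz) * wz * wx) / Iy
                omega[k, 2] += half_dt * (tbz - (Iy - Ix) * wx * wy) / Iz
                for d in range(3):
                    com_vel[k, d] += half_dt * Fb[k, d] / M
                if gamma > 0.0:
                    # friction of nb beads acting on the center of mass ...
                    geff = nb * gamma
                    tscale = SQRT12 * math.sqrt(2.0 * geff * kT * dt) / M
                    for d in range(3):
                        s0, s1, u = _uniform_centered(s0, s1)
                        com_vel[k, d] += -geff * dt * com_vel[k, d] / M \
                            + tscale * u
                    # ... and on the body-frame angular velocity
                    for d in range(3):
                        s0, s1, u = _uniform_centered(s0, s1)
                        rscale = SQRT12 * math.sqrt(
                            2.0 * gamma * kT * dt / inertia[k, d])
                        omega[k, d] += -gamma * dt * omega[k, d] + rscale * u

        # --- overdamped rotational Langevin update of shell-bead normals
        if gamma_n > 0.0:
            for i in range(n):
                if btype[i] != 2 or rigid_bead[i]:
                    continue
                nx_, ny_, nz_ = nrm[i, 0], nrm[i, 1], nrm[i, 2]
                s0, s1, u0 = _uniform_centered(s0, s1)
                s0, s1, u1 = _uniform_centered(s0, s1)
                s0, s1, u2 = _uniform_centered(s0, s1)
                gx = tq[i, 0] * inv_gn + nscale * u0
                gy = tq[i, 1] * inv_gn + nscale * u1
                gz = tq[i, 2] * inv_gn + nscale * u2
                dot = gx * nx_ + gy * ny_ + gz * nz_
                nx_ += gx - dot * nx_
                ny_ += gy - dot * ny_
                nz_ += gz - dot * nz_
                inv = 1.0 / math.sqrt(nx_ * nx_ + ny_ * ny_ + nz_ * nz_)
                nrm[i, 0] = nx_ * inv
                nrm[i, 1] = ny_ * inv
                nrm[i, 2] = nz_ * inv

        # --- outputs
        if cent_every > 0 and (step + 1) % cent_every == 0:
            if cent_idx < cents.shape[0]:
                for k in range(n_np):
                    if np_rigid[k]:
                        for d in range(3):
                            cents[cent_idx, k, d] = com[k, d]
                    else:
                        st = np_start[k]
                        nb = np_count[k]
                        for d in range(3):
                            a = 0.0
                            for b in range(nb):
                                a += pos[st + b, d] + img[st + b, d] * box
                            cents[cent_idx, k, d] = a / nb
                cent_times[cent_idx] = (step + 1) * dt
                cent_idx += 1

        if frame_every > 0 and (step + 1) % frame_every == 0:
            if frame_idx < frames_pos.shape[0]:
                pe = terms[0] + terms[1] + terms[2] + terms[3] + terms[4]
                if not math.isfinite(pe):
                    return STATUS_NAN, step
                ke = 0.0
                for i in range(n):
                    if rigid_bead[i]:
                        continue
                    ke += 0.5 * masses[i] * (vel[i, 0] ** 2 + vel[i, 1] ** 2
                                             + vel[i, 2] ** 2)
                for k in range(n_np):
                    if np_rigid[k]:
                        M = np_count[k] * 1.0
                        ke += 0.5 * M * (com_vel[k, 0] ** 2
                                         + com_vel[k, 1] ** 2
                                         + com_vel[k, 2] ** 2)
                        for d in range(3):
                            ke += 0.5 * inertia[k, d] * omega[k, d] ** 2
                for i in range(n):
                    for d in range(3):
                        frames_pos[frame_idx, i, d] = pos[i, d]
                        frames_img[frame_idx, i, d] = img[i, d]
                        frames_nrm[frame_idx, i, d] = nrm[i, d]
                frames_pe[frame_idx] = pe
                frames_ke[frame_idx] = ke
                frame_idx += 1

    list_counts[0] = n_pp
    list_counts[1] = n_pn
    list_counts[2] = n_nn
    if list_counts.shape[0] > 3:
        list_counts[3] = rebuilds
    return STATUS_OK, n_steps


@njit(cache=True, fastmath=True)
def _collect_rigid(f, pos, com, img, box, np_start, np_count, np_rigid, Fb, Tb):
    for k in range(np_start.shape[0]):
        if not np_rigid[k]:
            continue
        st = np_start[k]
        nb = np_count[k]
        fx = 0.0
        fy = 0.0
        fz = 0.0
        tx = 0.0
        ty = 0.0
        tz = 0.0
        for b in range(nb):
            i = st + b
            rx = pos[i, 0] + img[i, 0] * box - com[k, 0]
            ry = pos[i, 1] + img[i, 1] * box - com[k, 1]
            rz = pos[i, 2] + img[i, 2] * box - com[k, 2]
            fx += f[i, 0]
            fy += f[i, 1]
            fz += f[i, 2]
            tx += ry * f[i, 2] - rz * f[i, 1]
            ty += rz * f[i, 0] - rx * f[i, 2]
            tz += rx * f[i, 1] - ry * f[i, 0]
        Fb[k, 0] = fx
        Fb[k, 1] = fy
        Fb[k, 2] = fz
        Tb[k, 0] = tx
        Tb[k, 1] = ty
        Tb[k, 2] = tz
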