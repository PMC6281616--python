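"""Numba-compiled simulation kernels: cell/Verlet lists, forces, MD loop.

All kernels are single-threaded so that trajectories are bit-reproducible
for a given seed.  Positions are wrapped into [0, box) in each dimension;
minimum-image convention applies in all three dimensions (implemented
with branches, which requires box >= 2 * list cutoff per dimension — the
wrappers enforce this).

The Verlet list is split by pair type so the dominant loop is branch- and
lookup-free:

  * type 1: hydrophobic (body/tail) lipid pairs — WCA core plus the
    attractive well, one shared parameter set;
  * type 0: head-involved lipid pairs — WCA only, per-pair packed
    (sigma^2, epsilon) including any per-species head scale;
  * type 2: protein--lipid-head Lennard-Jones (scalar parameters).

Pairs between two frozen (protein) sites, protein/non-head pairs, and
pairs within one lipid (covered by bonded terms) are never listed.

For cache locality the pair lists index a cell-sorted permutation of the
sites (``order``); each step the positions are gathered into that order,
forces are computed in sorted space, and the result is scattered back.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# status codes returned by md_chunk
OK = 0
DIVERGED = 1

_TWO13 = 2.0 ** (1.0 / 3.0)


@njit(cache=True, fastmath=True)
def build_pairs(
    pos, box, cls, lipid_id, eps_scale,
    rl2_lipid, rl2_pl, sig2_t, eps_t, depth_t, rcsq_t,
    order, p1_i, p1_j, p0_i, p0_j, p0_sig2, p0_eps, p0_depth, p0_rcsq, p2_i, p2_j,
):
    """Fill the typed Verlet pair lists (indices in cell-sorted space) and
    the ``order`` permutation (sorted index -> original site index).

    Returns (n1, n0, n2); any entry is negative (-needed) if the
    corresponding capacity was insufficient.
    """
    n = pos.shape[0]
    rl_max = 0.0
    for a in range(3):
        for b in range(3):
            if rl2_lipid[a, b] > rl_max:
                rl_max = rl2_lipid[a, b]
    if rl2_pl > rl_max:
        rl_max = rl2_pl
    rl = np.sqrt(rl_max)

    # sub-cell binning (cells ~ rl/reach) with a distance-pruned stencil:
    # finer cells cut the candidate volume toward the true interaction
    # sphere at the cost of more stencil offsets
    reach = 2
    while reach > 1:
        ncx = int(reach * box[0] / rl)
        ncy = int(reach * box[1] / rl)
        ncz = int(reach * box[2] / rl)
        if ncx >= 2 * reach + 1 and ncy >= 2 * reach + 1 and ncz >= 2 * reach + 1:
            break
        reach -= 1
    if reach == 1:
        ncx = max(3, int(box[0] / rl))
        ncy = max(3, int(box[1] / rl))
        ncz = max(3, int(box[2] / rl))
    csx = box[0] / ncx
    csy = box[1] / ncy
    csz = box[2] / ncz
    ncells = ncx * ncy * ncz

    # counting sort by cell
    cell_of = np.empty(n, dtype=np.int32)
    count = np.zeros(ncells + 1, dtype=np.int32)
    for i in range(n):
        ix = int(pos[i, 0] / csx)
        iy = int(pos[i, 1] / csy)
        iz = int(pos[i, 2] / csz)
        if ix >= ncx:
            ix = ncx - 1
        elif ix < 0:
            ix = 0
        if iy >= ncy:
            iy = ncy - 1
        elif iy < 0:
            iy = 0
        if iz >= ncz:
            iz = ncz - 1
        elif iz < 0:
            iz = 0
        c = ix + ncx * (iy + ncy * iz)
        cell_of[i] = c
        count[c + 1] += 1
    for c in range(ncells):
        count[c + 1] += count[c]
    start = count
    fill = start[:-1].copy()
    for i in range(n):
        c = cell_of[i]
        order[fill[c]] = i
        fill[c] += 1

    px = np.empty(n)
    py = np.empty(n)
    pz = np.empty(n)
    cl = np.empty(n, dtype=np.int8)
    lid = np.empty(n, dtype=np.int32)
    esc = np.empty(n)
    for k in range(n):
        i = order[k]
        px[k] = pos[i, 0]
        py[k] = pos[i, 1]
        pz[k] = pos[i, 2]
        cl[k] = cls[i]
        lid[k] = lipid_id[i]
        esc[k] = eps_scale[i]

    bx, by, bz = box[0], box[1], box[2]
    hx, hy, hz = 0.5 * bx, 0.5 * by, 0.5 * bz
    cap1 = p1_i.shape[0]
    cap0 = p0_i.shape[0]
    cap2 = p2_i.shape[0]
    n1 = 0
    n0 = 0
    n2 = 0

    n_off_max = ((2 * reach + 1) ** 3 - 1) // 2
    offs = np.empty((n_off_max, 3), dtype=np.int64)
    m = 0
    for oz in range(0, reach + 1):
        for oy in range(-reach, reach + 1):
            for ox in range(-reach, reach + 1):
                if oz == 0 and (oy < 0 or (oy == 0 and ox <= 0)):
                    continue
                # skip offsets whose closest cell-to-cell distance exceeds rl
                dmin2 = (
                    (max(abs(ox) - 1, 0) * csx) ** 2
                    + (max(abs(oy) - 1, 0) * csy) ** 2
                    + (max(abs(oz) - 1, 0) * csz) ** 2
                )
                if dmin2 > rl_max:
                    continue
                offs[m, 0] = oz
                offs[m, 1] = oy
                offs[m, 2] = ox
                m += 1
    n_off = m

    for cz in range(ncz):
        for cy in range(ncy):
            for cx in range(ncx):
                c = cx + ncx * (cy + ncy * cz)
                a0 = start[c]
                a1 = start[c + 1]
                if a0 == a1:
                    continue
                for k in range(n_off + 1):
                    if k == n_off:
                        b0 = a0
                        b1 = a1
                    else:
                        ox = cx + offs[k, 2]
                        oy = cy + offs[k, 1]
                        oz = cz + offs[k, 0]
                        if ox >= ncx:
                            ox -= ncx
                        elif ox < 0:
                            ox += ncx
                        if oy >= ncy:
                            oy -= ncy
                        elif oy < 0:
                            oy += ncy
                        if oz >= ncz:
                            oz -= ncz
                        elif oz < 0:
                            oz += ncz
                        c2 = ox + ncx * (oy + ncy * oz)
                        b0 = start[c2]
                        b1 = start[c2 + 1]
                        if b0 == b1:
                            continue
                    for ka in range(a0, a1):
                        xi = px[ka]
                        yi = py[ka]
                        zi = pz[ka]
                        jb0 = ka + 1 if k == n_off else b0
                        for kb in range(jb0, b1):
                            dx = xi - px[kb]
                            if dx > hx:
                                dx -= bx
                            elif dx < -hx:
                                dx += bx
                            dy = yi - py[kb]
                            if dy > hy:
                                dy -= by
                            elif dy < -hy:
                                dy += by
                            dz = zi - pz[kb]
                            if dz > hz:
                                dz -= bz
                            elif dz < -hz:
                                dz += bz
                            s = dx * dx + dy * dy + dz * dz
                            if s >= rl_max:
                                continue
                            ci = cl[ka]
                            cj = cl[kb]
                            if ci == 3:
                                if cj != 0:
                                    continue
                                if s < rl2_pl:
                                    if n2 < cap2:
                                        p2_i[n2] = ka
                                        p2_j[n2] = kb
                                    n2 += 1
                            elif cj == 3:
                                if ci != 0:
                                    continue
                                if s < rl2_pl:
                                    if n2 < cap2:
                                        p2_i[n2] = ka
                                        p2_j[n2] = kb
                                    n2 += 1
                            elif lid[ka] == lid[kb]:
                                continue
                            elif ci > 0 and cj > 0:
                                if s < rl2_lipid[1, 1]:
                                    if n1 < cap1:
                                        p1_i[n1] = ka
                                        p1_j[n1] = kb
                                    n1 += 1
                            else:
                                if s < rl2_lipid[ci, cj]:
                                    if n0 < cap0:
                                        p0_i[n0] = ka
                                        p0_j[n0] = kb
                                        p0_sig2[n0] = sig2_t[ci, cj]
                                        p0_eps[n0] = eps_t[ci, cj] * esc[ka] * esc[kb]
                                        p0_depth[n0] = depth_t[ci, cj]
                                        p0_rcsq[n0] = rcsq_t[ci, cj]
                                    n0 += 1

    r1 = n1 if n1 <= cap1 else -n1
    r0 = n0 if n0 <= cap0 else -n0
    r2 = n2 if n2 <= cap2 else -n2
    return r1, r0, r2


@njit(cache=True, fastmath=True)
def compute_forces(
    pos_s,
    box,
    p1_i, p1_j, n1,
    p0_i, p0_j, p0_sig2, p0_eps, p0_depth, p0_rcsq, n0,
    p2_i, p2_j, n2,
    hp_sig2, hp_eps, hp_r0sq, hp_depth, hp_rcsq,
    pl_sig2, pl_eps, pl_rcsq, pl_shift,
    bond_i_s, bond_j_s, bond_k, bond_r0,
    forces_s,
    want_energy,
):
    """Accumulate nonbonded + bonded forces in cell-sorted space; returns
    potential energy (0.0 unless ``want_energy``)."""
    bx, by, bz = box[0], box[1], box[2]
    hx, hy, hz = 0.5 * bx, 0.5 * by, 0.5 * bz
    epot = 0.0
    forces_s[:, :] = 0.0

    inv_denom = 1.0 / (hp_rcsq - hp_r0sq)
    inv_r0sq = 1.0 / hp_r0sq
    for p in range(n1):
        i = p1_i[p]
        j = p1_j[p]
        dx = pos_s[i, 0] - pos_s[j, 0]
        if dx > hx:
            dx -= bx
        elif dx < -hx:
            dx += bx
        dy = pos_s[i, 1] - pos_s[j, 1]
        if dy > hy:
            dy -= by
        elif dy < -hy:
            dy += by
        dz = pos_s[i, 2] - pos_s[j, 2]
        if dz > hz:
            dz -= bz
        elif dz < -hz:
            dz += bz
        s = dx * dx + dy * dy + dz * dz
        # branchless select between the soft core and the attractive well,
        # zeroed beyond the cutoff (the range branches are data-dependent
        # and would mispredict on a large fraction of listed pairs)
        gc = 1.0 - s * inv_r0sq
        # V_core = A gc^2 ; dV/ds = -2 A gc / r0sq ; coef = -2 dV/ds
        core = 4.0 * hp_eps * gc * inv_r0sq
        u = (s - hp_r0sq) * inv_denom
        g = 1.0 - u * u
        # dV/ds = 4 d u g / denom ; coef = -2 dV/ds
        att = -8.0 * hp_depth * u * g * inv_denom
        coef = core if s < hp_r0sq else att
        if s >= hp_rcsq:
            coef = 0.0
        if want_energy:
            if s < hp_r0sq:
                epot += hp_eps * gc * gc - hp_depth
            elif s < hp_rcsq:
                epot += -hp_depth * g * g
        fx = coef * dx
        fy = coef * dy
        fz = coef * dz
        forces_s[i, 0] += fx
        forces_s[i, 1] += fy
        forces_s[i, 2] += fz
        forces_s[j, 0] -= fx
        forces_s[j, 1] -= fy
        forces_s[j, 2] -= fz

    for p in range(n0):
        i = p0_i[p]
        j = p0_j[p]
        dx = pos_s[i, 0] - pos_s[j, 0]
        if dx > hx:
            dx -= bx
        elif dx < -hx:
            dx += bx
        dy = pos_s[i, 1] - pos_s[j, 1]
        if dy > hy:
            dy -= by
        elif dy < -hy:
            dy += by
        dz = pos_s[i, 2] - pos_s[j, 2]
        if dz > hz:
            dz -= bz
        elif dz < -hz:
            dz += bz
        s = dx * dx + dy * dy + dz * dz
        sg2 = p0_sig2[p]
        eps = p0_eps[p]
        dep = p0_depth[p]
        r0s = _TWO13 * sg2
        if s >= p0_rcsq[p] and s >= r0s:
            continue
        coef = 0.0
        if s < r0s:
            gc = 1.0 - s / r0s
            coef = 4.0 * eps * gc / r0s
            if want_energy:
                epot += eps * gc * gc - dep
        elif dep > 0.0:
            denom = p0_rcsq[p] - r0s
            u = (s - r0s) / denom
            g = 1.0 - u * u
            coef = -8.0 * dep * u * g / denom
            if want_energy:
                epot += -dep * g * g
        fx = coef * dx
        fy = coef * dy
        fz = coef * dz
        forces_s[i, 0] += fx
        forces_s[i, 1] += fy
        forces_s[i, 2] += fz
        forces_s[j, 0] -= fx
        forces_s[j, 1] -= fy
        forces_s[j, 2] -= fz

    for p in range(n2):
        i = p2_i[p]
        j = p2_j[p]
        dx = pos_s[i, 0] - pos_s[j, 0]
        if dx > hx:
            dx -= bx
        elif dx < -hx:
            dx += bx
        dy = pos_s[i, 1] - pos_s[j, 1]
        if dy > hy:
            dy -= by
        elif dy < -hy:
            dy += by
        dz = pos_s[i, 2] - pos_s[j, 2]
        if dz > hz:
            dz -= bz
        elif dz < -hz:
            dz += bz
        s = dx * dx + dy * dy + dz * dz
        if s >= pl_rcsq:
            continue
        s_inv = 1.0 / s
        sr2 = pl_sig2 * s_inv
        sr6 = sr2 * sr2 * sr2
        coef = 24.0 * pl_eps * (2.0 * sr6 * sr6 - sr6) * s_inv
        if want_energy:
            epot += 4.0 * pl_eps * (sr6 * sr6 - sr6) - pl_shift
        fx = coef * dx
        fy = coef * dy
        fz = coef * dz
        forces_s[i, 0] += fx
        forces_s[i, 1] += fy
        forces_s[i, 2] += fz
        forces_s[j, 0] -= fx
        forces_s[j, 1] -= fy
        forces_s[j, 2] -= fz

    for b in range(bond_i_s.shape[0]):
        i = bond_i_s[b]
        j = bond_j_s[b]
        dx = pos_s[i, 0] - pos_s[j, 0]
        if dx > hx:
            dx -= bx
        elif dx < -hx:
            dx += bx
        dy = pos_s[i, 1] - pos_s[j, 1]
        if dy > hy:
            dy -= by
        elif dy < -hy:
            dy += by
        dz = pos_s[i, 2] - pos_s[j, 2]
        if dz > hz:
            dz -= bz
        elif dz < -hz:
            dz += bz
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        dr = r - bond_r0[b]
        if want_energy:
            epot += bond_k[b] * dr * dr
        coef = -2.0 * bond_k[b] * dr / r
        forces_s[i, 0] += coef * dx
        forces_s[i, 1] += coef * dy
        forces_s[i, 2] += coef * dz
        forces_s[j, 0] -= coef * dx
        forces_s[j, 1] -= coef * dy
        forces_s[j, 2] -= coef * dz

    return epot


@njit(cache=True)
def _nhc_half(vxi, Q, ke2, nf_kt, kt, dt2):
    """Half-step update of a Nose-Hoover chain (length 3).

    Returns the velocity scale factor for the particle velocities.
    ke2 is twice the kinetic energy of the thermostatted sites.
    """
    dt4 = 0.5 * dt2
    dt8 = 0.5 * dt4
    g3 = (Q[1] * vxi[1] * vxi[1] - kt) / Q[2]
    vxi[2] += g3 * dt4
    g2 = (Q[0] * vxi[0] * vxi[0] - kt) / Q[1]
    vxi[1] *= np.exp(-vxi[2] * dt8)
    vxi[1] += g2 * dt4
    vxi[1] *= np.exp(-vxi[2] * dt8)
    g1 = (ke2 - nf_kt) / Q[0]
    vxi[0] *= np.exp(-vxi[1] * dt8)
    vxi[0] += g1 * dt4
    vxi[0] *= np.exp(-vxi[1] * dt8)
    scale = np.exp(-vxi[0] * dt2)
    ke2 = ke2 * scale * scale
    vxi[0] *= np.exp(-vxi[1] * dt8)
    g1 = (ke2 - nf_kt) / Q[0]
    vxi[0] += g1 * dt4
    vxi[0] *= np.exp(-vxi[1] * dt8)
    vxi[1] *= np.exp(-vxi[2] * dt8)
    g2 = (Q[0] * vxi[0] * vxi[0] - kt) / Q[1]
    vxi[1] += g2 * dt4
    vxi[1] *= np.exp(-vxi[2] * dt8)
    g3 = (Q[1] * vxi[1] * vxi[1] - kt) / Q[2]
    vxi[2] += g3 * dt4
    return scale


@njit(cache=True)
def _ke2_free(vel, n_free):
    ke2 = 0.0
    for i in range(n_free):
        ke2 += vel[i, 0] ** 2 + vel[i, 1] ** 2 + vel[i, 2] ** 2
    return ke2  # mass = 1 per site


@njit(cache=True, fastmath=True)
def md_chunk(
    pos,
    vel,
    forces,
    n_free,
    cls,
    lipid_id,
    eps_scale,
    box,
    nsteps,
    dt,
    temp_start,
    temp_end,
    kb,
    t_damp,
    use_thermostat,
    vxi,
    sig2_t,
    eps_t,
    depth_t,
    rcsq_t,
    hp_r0sq,
    hp_depth,
    hp_rcsq,
    pl_sig2,
    pl_eps,
    pl_rcsq,
    pl_shift,
    rl2_lipid,
    rl2_pl,
    skin,
    bond_i,
    bond_j,
    bond_k,
    bond_r0,
    guard_vmax,
    log_interval,
    log_temp,
    log_epot,
    max_move,
):
    """Run ``nsteps`` of velocity-Verlet NVT (Nose-Hoover chain) dynamics.

    Mutates pos/vel/forces/vxi in place.  The thermostat target ramps
    linearly from temp_start to temp_end over the chunk.  Returns a status
    code (OK or DIVERGED).  Every ``log_interval`` steps the instantaneous
    kinetic temperature and potential energy are recorded.  With
    ``max_move`` > 0 per-step site displacements are capped at that value
    (nm) — the gentle push-off used while relaxing freshly built lattices.
    """
    nf = 3.0 * n_free
    bx, by, bz = box[0], box[1], box[2]
    hp_sig2 = sig2_t[1, 1]
    hp_eps = eps_t[1, 1]

    n = pos.shape[0]
    cap1 = max(64, int(75.0 * n))
    cap0 = max(64, int(14.0 * n))
    cap2 = max(64, int(6.0 * n))
    order = np.empty(n, dtype=np.int32)
    inv = np.empty(n, dtype=np.int32)
    pos_s = np.empty((n, 3))
    forces_s = np.empty((n, 3))
    bis = np.empty(bond_i.shape[0], dtype=np.int32)
    bjs = np.empty(bond_i.shape[0], dtype=np.int32)
    p1_i = np.empty(cap1, dtype=np.int32)
    p1_j = np.empty(cap1, dtype=np.int32)
    p0_i = np.empty(cap0, dtype=np.int32)
    p0_j = np.empty(cap0, dtype=np.int32)
    p0_sig2 = np.empty(cap0)
    p0_eps = np.empty(cap0)
    p0_depth = np.empty(cap0)
    p0_rcsq = np.empty(cap0)
    p2_i = np.empty(cap2, dtype=np.int32)
    p2_j = np.empty(cap2, dtype=np.int32)

    n1, n0, n2 = build_pairs(
        pos, box, cls, lipid_id, eps_scale, rl2_lipid, rl2_pl,
        sig2_t, eps_t, depth_t, rcsq_t,
        order, p1_i, p1_j, p0_i, p0_j, p0_sig2, p0_eps, p0_depth, p0_rcsq, p2_i, p2_j,
    )
    while n1 < 0 or n0 < 0 or n2 < 0:
        if n1 < 0:
            cap1 = int(-n1 * 1.3) + 64
            p1_i = np.empty(cap1, dtype=np.int32)
            p1_j = np.empty(cap1, dtype=np.int32)
        if n0 < 0:
            cap0 = int(-n0 * 1.3) + 64
            p0_i = np.empty(cap0, dtype=np.int32)
            p0_j = np.empty(cap0, dtype=np.int32)
            p0_sig2 = np.empty(cap0)
            p0_eps = np.empty(cap0)
            p0_depth = np.empty(cap0)
            p0_rcsq = np.empty(cap0)
        if n2 < 0:
            cap2 = int(-n2 * 1.3) + 64
            p2_i = np.empty(cap2, dtype=np.int32)
            p2_j = np.empty(cap2, dtype=np.int32)
        n1, n0, n2 = build_pairs(
            pos, box, cls, lipid_id, eps_scale, rl2_lipid, rl2_pl,
            sig2_t, eps_t, depth_t, rcsq_t,
            order, p1_i, p1_j, p0_i, p0_j, p0_sig2, p0_eps, p0_depth, p0_rcsq, p2_i, p2_j,
        )
    for k in range(n):
        inv[order[k]] = k
    for b in range(bond_i.shape[0]):
        bis[b] = inv[bond_i[b]]
        bjs[b] = inv[bond_j[b]]

    disp = np.zeros((n_free, 3))

    for k in range(n):
        i = order[k]
        pos_s[k, 0] = pos[i, 0]
        pos_s[k, 1] = pos[i, 1]
        pos_s[k, 2] = pos[i, 2]
    epot = compute_forces(
        pos_s, box,
        p1_i, p1_j, n1, p0_i, p0_j, p0_sig2, p0_eps, p0_depth, p0_rcsq, n0, p2_i, p2_j, n2,
        hp_sig2, hp_eps, hp_r0sq, hp_depth, hp_rcsq,
        pl_sig2, pl_eps, pl_rcsq, pl_shift,
        bis, bjs, bond_k, bond_r0, forces_s, False,
    )
    for k in range(n):
        i = order[k]
        forces[i, 0] = forces_s[k, 0]
        forces[i, 1] = forces_s[k, 1]
        forces[i, 2] = forces_s[k, 2]

    nlog = 0
    Q = np.empty(3)
    for step in range(nsteps):
        frac = step / nsteps if nsteps > 1 else 0.0
        temp = temp_start + (temp_end - temp_start) * frac
        kt = kb * temp
        if use_thermostat:
            Q[0] = nf * kt * t_damp * t_damp
            Q[1] = kt * t_damp * t_damp
            Q[2] = Q[1]
            ke2 = _ke2_free(vel, n_free)
            scale = _nhc_half(vxi, Q, ke2, nf * kt, kt, 0.5 * dt)
            for i in range(n_free):
                vel[i, 0] *= scale
                vel[i, 1] *= scale
                vel[i, 2] *= scale

        half = 0.5 * dt
        max_d2 = 0.0
        max2_d2 = 0.0
        for i in range(n_free):
            vel[i, 0] += half * forces[i, 0]
            vel[i, 1] += half * forces[i, 1]
            vel[i, 2] += half * forces[i, 2]
            mx = dt * vel[i, 0]
            my = dt * vel[i, 1]
            mz = dt * vel[i, 2]
            if max_move > 0.0:
                m2 = mx * mx + my * my + mz * mz
                if m2 > max_move * max_move:
                    f = max_move / np.sqrt(m2)
                    mx *= f
                    my *= f
                    mz *= f
            x = pos[i, 0] + mx
            if x >= bx or x < 0.0:
                x -= bx * np.floor(x / bx)
            y = pos[i, 1] + my
            if y >= by or y < 0.0:
                y -= by * np.floor(y / by)
            z = pos[i, 2] + mz
            if z >= bz or z < 0.0:
                z -= bz * np.floor(z / bz)
            pos[i, 0] = x
            pos[i, 1] = y
            pos[i, 2] = z
            dxx = disp[i, 0] + mx
            dyy = disp[i, 1] + my
            dzz = disp[i, 2] + mz
            disp[i, 0] = dxx
            disp[i, 1] = dyy
            disp[i, 2] = dzz
            d2 = dxx * dxx + dyy * dyy + dzz * dzz
            if d2 > max_d2:
                max2_d2 = max_d2
                max_d2 = d2
            elif d2 > max2_d2:
                max2_d2 = d2

        # rebuild when the two fastest sites could have closed the skin gap
        if np.sqrt(max_d2) + np.sqrt(max2_d2) > skin:
            n1, n0, n2 = build_pairs(
                pos, box, cls, lipid_id, eps_scale, rl2_lipid, rl2_pl,
                sig2_t, eps_t, depth_t, rcsq_t,
                order, p1_i, p1_j, p0_i, p0_j, p0_sig2, p0_eps, p0_depth, p0_rcsq, p2_i, p2_j,
            )
            while n1 < 0 or n0 < 0 or n2 < 0:
                if n1 < 0:
                    cap1 = int(-n1 * 1.3) + 64
                    p1_i = np.empty(cap1, dtype=np.int32)
                    p1_j = np.empty(cap1, dtype=np.int32)
                if n0 < 0:
                    cap0 = int(-n0 * 1.3) + 64
                    p0_i = np.empty(cap0, dtype=np.int32)
                    p0_j = np.empty(cap0, dtype=np.int32)
                    p0_sig2 = np.empty(cap0)
                    p0_eps = np.empty(cap0)
                    p0_depth = np.empty(cap0)
                    p0_rcsq = np.empty(cap0)
                if n2 < 0:
                    cap2 = int(-n2 * 1.3) + 64
                    p2_i = np.empty(cap2, dtype=np.int32)
                    p2_j = np.empty(cap2, dtype=np.int32)
                n1, n0, n2 = build_pairs(
                    pos, box, cls, lipid_id, eps_scale, rl2_lipid, rl2_pl,
                    sig2_t, eps_t, depth_t, rcsq_t,
                    order, p1_i, p1_j, p0_i, p0_j, p0_sig2, p0_eps, p0_depth, p0_rcsq, p2_i, p2_j,
                )
            for k in range(n):
                inv[order[k]] = k
            for b in range(bond_i.shape[0]):
                bis[b] = inv[bond_i[b]]
                bjs[b] = inv[bond_j[b]]
            disp[:, :] = 0.0

        want_e = log_interval > 0 and (step + 1) % log_interval == 0
        for k in range(n):
            i = order[k]
            pos_s[k, 0] = pos[i, 0]
            pos_s[k, 1] = pos[i, 1]
            pos_s[k, 2] = pos[i, 2]
        epot = compute_forces(
            pos_s, box,
            p1_i, p1_j, n1, p0_i, p0_j, p0_sig2, p0_eps, p0_depth, p0_rcsq, n0, p2_i, p2_j, n2,
            hp_sig2, hp_eps, hp_r0sq, hp_depth, hp_rcsq,
            pl_sig2, pl_eps, pl_rcsq, pl_shift,
            bis, bjs, bond_k, bond_r0, forces_s, want_e,
        )
        for k in range(n):
            i = order[k]
            forces[i, 0] = forces_s[k, 0]
            forces[i, 1] = forces_s[k, 1]
            forces[i, 2] = forces_s[k, 2]

        for i in range(n_free):
            vel[i, 0] += half * forces[i, 0]
            vel[i, 1] += half * forces[i, 1]
            vel[i, 2] += half * forces[i, 2]

        if use_thermostat:
            ke2 = _ke2_free(vel, n_free)
            scale = _nhc_half(vxi, Q, ke2, nf * kt, kt, 0.5 * dt)
            for i in range(n_free):
                vel[i, 0] *= scale
                vel[i, 1] *= scale
                vel[i, 2] *= scale

        if want_e:
            if nlog < log_temp.shape[0]:
                log_temp[nlog] = _ke2_free(vel, n_free) / (nf * kb)
                log_epot[nlog] = epot
                nlog += 1

        if (step + 1) % 200 == 0:
            vmax2 = 0.0
            for i in range(n_free):
                v2 = vel[i, 0] ** 2 + vel[i, 1] ** 2 + vel[i, 2] ** 2
                if v2 > vmax2:
                    vmax2 = v2
            if vmax2 > guard_vmax * guard_vmax:
                return DIVERGED

    return OK
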