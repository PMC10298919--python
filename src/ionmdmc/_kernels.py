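"""Numba kernels for the overdamped-Langevin integrator.

All arrays are float64; positions in A, energies kJ/mol, time ps.  The pair
model is a truncated Lennard-Jones (9-6 or 12-6) plus screened Coulomb, the
membrane is an external slab/pore/well potential.  Species enter through
small per-pair lookup tables so the hot loops stay branch-light.
"""

import numpy as np
from numba import njit

# layout of the external-potential parameter vector
(EXT_ZLO, EXT_ZHI, EXT_WZ, EXT_WB, EXT_CX, EXT_CY, EXT_RPORE, EXT_WR,
 EXT_WALLH, EXT_WELL_Z1, EXT_WELL_Z2, EXT_WELL_S, EXT_RWELL, EXT_WRW,
 EXT_FA, EXT_FB, EXT_NWELL, EXT_BOFF, EXT_FUNNEL) = range(19)
EXT_SIZE = 19

LJ_9_6 = 0
LJ_12_6 = 1


@njit(cache=True, inline="always")
def _logistic(u, w):
    x = u / w
    if x > 35.0:
        return 1.0
    if x < -35.0:
        return 0.0
    return 1.0 / (1.0 + np.exp(-x))


@njit(cache=True, fastmath=True)
def ext_energy_force(x, y, z, s, ext, sp_barrier, sp_well, sp_qf):
    """External potential and force for one particle of species index s.

    Terms: repulsive slab outside the pore cylinder, in-pore confinement
    barrier, gaussian entrance wells localized at the pore mouths, and the
    constant field force inside the field region.  Returns (e, fx, fy, fz).
    """
    e = 0.0
    fx = 0.0
    fy = 0.0
    fz = 0.0

    zlo = ext[EXT_ZLO]
    zhi = ext[EXT_ZHI]
    zc = 0.5 * (zlo + zhi)
    span = 0.5 * (zhi - zlo) + 8.0 + ext[EXT_BOFF]

    if abs(z - zc) < span:
        dx = x - ext[EXT_CX]
        dy = y - ext[EXT_CY]
        rho = np.sqrt(dx * dx + dy * dy)

        wz = ext[EXT_WZ]
        g1 = _logistic(z - zlo, wz)
        g2 = _logistic(zhi - z, wz)
        gzw = g1 * g2
        dgzw = (g1 * (1.0 - g1) * g2 - g1 * g2 * (1.0 - g2)) / wz

        wb = ext[EXT_WB]
        boff = ext[EXT_BOFF]
        b1 = _logistic(z - (zlo - boff), wb)
        b2 = _logistic((zhi + boff) - z, wb)
        gzb = b1 * b2
        dgzb = (b1 * (1.0 - b1) * b2 - b1 * b2 * (1.0 - b2)) / wb

        # conical mouths: the radial gate widens toward the slab faces so
        # face-pressed particles are funnelled onto the pore axis
        wr = ext[EXT_WR]
        r_eff = ext[EXT_RPORE] + ext[EXT_FUNNEL] * (1.0 - gzw)
        h = _logistic(rho - r_eff, wr)
        dh = h * (1.0 - h) / wr                    # d h / d rho
        dh_dz = dh * ext[EXT_FUNNEL] * dgzw        # via d r_eff / dz

        wallh = ext[EXT_WALLH]
        bar = sp_barrier[s]
        # slab: wall off-pore + confinement barrier in-pore
        # the confinement ramp is radially uniform (the wall dominates
        # off-pore anyway); only the wall cone exerts radial guidance
        e += wallh * gzw * h + bar * gzb
        dez = wallh * (dgzw * h + gzw * dh_dz) + bar * dgzb
        derho = wallh * gzw * dh

        # entrance wells (gaussian in z, localized radially at the mouths)
        depth = sp_well[s]
        if depth != 0.0 and ext[EXT_NWELL] > 0.0:
            rw = _logistic(ext[EXT_RWELL] - rho, ext[EXT_WRW])
            drw = -rw * (1.0 - rw) / ext[EXT_WRW]
            sw = ext[EXT_WELL_S]
            gsum = 0.0
            dgsum = 0.0
            for k in range(int(ext[EXT_NWELL])):
                zk = ext[EXT_WELL_Z1 + k]
                u = (z - zk) / sw
                if abs(u) < 8.0:
                    g = np.exp(-0.5 * u * u)
                    gsum += g
                    dgsum += -u / sw * g
            e += -depth * rw * gsum
            dez += -depth * rw * dgsum
            derho += -depth * drw * gsum

        fz -= dez
        if rho > 1e-9:
            fx -= derho * dx / rho
            fy -= derho * dy / rho

    # field: constant force along +z inside [fa, fb]; the potential is the
    # matching continuous ramp (clamped outside the region)
    qf = sp_qf[s]
    if qf != 0.0:
        fa = ext[EXT_FA]
        fb = ext[EXT_FB]
        if z < fa:
            pass
        elif z <= fb:
            e += -qf * (z - fa)
            fz += qf
        else:
            e += -qf * (fb - fa)
    return e, fx, fy, fz


@njit(cache=True, fastmath=True)
def pair_ef(r2, eps, sig6, qq, lam, lj_form):
    """Energy and radial force (dE/dr with sign flipped) of one pair at r^2.

    ``sig6`` is sigma^6, ``qq`` the full Coulomb prefactor q_i q_j C / eps_r.
    Positive returned force means repulsion.  Cutoff handled by the caller.
    """
    r = np.sqrt(r2)
    e = 0.0
    f = 0.0
    if eps != 0.0:
        s6 = sig6 / (r2 * r2 * r2)
        if lj_form == LJ_9_6:
            s3 = np.sqrt(s6)
            s9 = s6 * s3
            e += eps * (2.0 * s9 - 3.0 * s6)
            f += 18.0 * eps * (s9 - s6) / r
        else:
            s12 = s6 * s6
            e += 4.0 * eps * (s12 - s6)
            f += 24.0 * eps * (2.0 * s12 - s6) / r
    if qq != 0.0:
        ex = np.exp(-r / lam)
        ec = qq * ex / r
        e += ec
        f += ec * (1.0 / r + 1.0 / lam)
    return e, f


@njit(cache=True, fastmath=True)
def build_pairs(pos, box, pbc, rlist2, pi, pj):
    """O(P^2) neighbour-list build; returns the number of pairs stored."""
    n = pos.shape[0]
    m = 0
    for i in range(n):
        for j in range(i + 1, n):
            r2 = 0.0
            for k in range(3):
                d = pos[i, k] - pos[j, k]
                if pbc[k]:
                    if d > 0.5 * box[k]:
                        d -= box[k]
                    elif d < -0.5 * box[k]:
                        d += box[k]
                r2 += d * d
            if r2 < rlist2:
                pi[m] = i
                pj[m] = j
                m += 1
    return m


@njit(cache=True, fastmath=True)
def build_pairs_params(pos, box, pbc, rlist2, sidx, eps_tab, sig6_tab, qq_tab,
                       pi, pj, peps, psig6, pqq):
    """Neighbour-list build that also gathers per-pair parameters."""
    m = build_pairs(pos, box, pbc, rlist2, pi, pj)
    for p in range(m):
        a = sidx[pi[p]]
        b = sidx[pj[p]]
        peps[p] = eps_tab[a, b]
        psig6[p] = sig6_tab[a, b]
        pqq[p] = qq_tab[a, b]
    return m


@njit(cache=True, fastmath=True)
def pair_forces_fast(pos, box, pbc, lam_inv, cutoff2, lj12, pi, pj, peps,
                     psig6, pqq, npairs, forces):
    """Force-only pair loop over a parameter-gathered neighbour list."""
    hx = 0.5 * box[0]
    hy = 0.5 * box[1]
    hz = 0.5 * box[2]
    for p in range(npairs):
        i = pi[p]
        j = pj[p]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        if pbc[0]:
            if dx > hx:
                dx -= box[0]
            elif dx < -hx:
                dx += box[0]
        if pbc[1]:
            if dy > hy:
                dy -= box[1]
            elif dy < -hy:
                dy += box[1]
        if pbc[2]:
            if dz > hz:
                dz -= box[2]
            elif dz < -hz:
                dz += box[2]
        r2 = dx * dx + dy * dy + dz * dz
        if r2 >= cutoff2:
            continue
        if r2 < 1e-12:
            return i
        eps = peps[p]
        inv_r2 = 1.0 / r2
        f = 0.0
        if eps != 0.0:
            s6 = psig6[p] * inv_r2 * inv_r2 * inv_r2
            if lj12 == 0:
                s9 = s6 * np.sqrt(s6)
                f += 18.0 * eps * (s9 - s6)
            else:
                s12 = s6 * s6
                f += 24.0 * eps * (2.0 * s12 - s6)
        qq = pqq[p]
        if qq != 0.0:
            r = np.sqrt(r2)
            ec = qq * np.exp(-r * lam_inv) / r
            f += ec * (1.0 + r * lam_inv)
        fr = f * inv_r2
        forces[i, 0] += fr * dx
        forces[i, 1] += fr * dy
        forces[i, 2] += fr * dz
        forces[j, 0] -= fr * dx
        forces[j, 1] -= fr * dy
        forces[j, 2] -= fr * dz
    return -1


@njit(cache=True, fastmath=True)
def pair_forces(pos, box, pbc, sidx, eps_tab, sig6_tab, qq_tab, lam, cutoff2,
                lj_form, pi, pj, npairs, forces):
    """Accumulate pair forces over the neighbour list.  Returns an error
    particle index if an (effectively overlapping) pair is found, else -1."""
    for p in range(npairs):
        i = pi[p]
        j = pj[p]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        # branch minimum image: wrapped coordinates keep |d| < box
        if pbc[0]:
            if dx > 0.5 * box[0]:
                dx -= box[0]
            elif dx < -0.5 * box[0]:
                dx += box[0]
        if pbc[1]:
            if dy > 0.5 * box[1]:
                dy -= box[1]
            elif dy < -0.5 * box[1]:
                dy += box[1]
        if pbc[2]:
            if dz > 0.5 * box[2]:
                dz -= box[2]
            elif dz < -0.5 * box[2]:
                dz += box[2]
        r2 = dx * dx + dy * dy + dz * dz
        if r2 >= cutoff2:
            continue
        if r2 < 1e-12:
            return i
        a = sidx[i]
        b = sidx[j]
        e, f = pair_ef(r2, eps_tab[a, b], sig6_tab[a, b], qq_tab[a, b], lam,
                       lj_form)
        r = np.sqrt(r2)
        fr = f / r
        forces[i, 0] += fr * dx
        forces[i, 1] += fr * dy
        forces[i, 2] += fr * dz
        forces[j, 0] -= fr * dx
        forces[j, 1] -= fr * dy
        forces[j, 2] -= fr * dz
    return -1


@njit(cache=True)
def total_forces_kernel(pos, box, pbc, sidx, eps_tab, sig6_tab, qq_tab, lam,
                        cutoff2, lj_form, ext, sp_barrier, sp_well, sp_qf,
                        include_external):
    n = pos.shape[0]
    forces = np.zeros((n, 3))
    pi = np.empty(n * (n - 1) // 2, dtype=np.int32)
    pj = np.empty(n * (n - 1) // 2, dtype=np.int32)
    m = build_pairs(pos, box, pbc, cutoff2, pi, pj)
    bad = pair_forces(pos, box, pbc, sidx, eps_tab, sig6_tab, qq_tab, lam,
                      cutoff2, lj_form, pi, pj, m, forces)
    if bad >= 0:
        return forces, bad
    if include_external:
        for i in range(n):
            _, fx, fy, fz = ext_energy_force(pos[i, 0], pos[i, 1], pos[i, 2],
                                             sidx[i], ext, sp_barrier,
                                             sp_well, sp_qf)
            forces[i, 0] += fx
            forces[i, 1] += fy
            forces[i, 2] += fz
    return forces, -1


@njit(cache=True, fastmath=True)
def run_chunk(pos, box, pbc, sidx, eps_tab, sig6_tab, qq_tab, lam, cutoff2,
              lj_form, ext, sp_barrier, sp_well, sp_qf, dt, gamma, noise,
              skin, pi, pj, peps, psig6, pqq, state, disp, frames,
              record_every, step0, max_move):
    """Advance ``noise.shape[0]`` Euler-Maruyama steps in place.

    ``noise`` is pre-scaled thermal displacement (sqrt(2 kB T dt / gamma) xi).
    ``state`` = [npairs, rebuild_flag]; ``disp`` accumulates displacement
    since the last neighbour-list build.  Frames are written whenever the
    global step index is a multiple of ``record_every``.  Returns
    (status, step, particle): status 0 ok, 1 overlap, 2 non-finite.
    """
    n = pos.shape[0]
    nsteps = noise.shape[0]
    rlist = np.sqrt(cutoff2) + skin if cutoff2 > 0.0 else 0.0
    rlist2 = rlist * rlist
    half_skin2 = (0.5 * skin) ** 2
    inv_g = dt / gamma
    forces = np.zeros((n, 3))

    lam_inv = 1.0 / lam
    for t in range(nsteps):
        if state[1] == 1:
            state[0] = build_pairs_params(pos, box, pbc, rlist2, sidx,
                                          eps_tab, sig6_tab, qq_tab, pi, pj,
                                          peps, psig6, pqq)
            state[1] = 0
            for i in range(n):
                disp[i, 0] = 0.0
                disp[i, 1] = 0.0
                disp[i, 2] = 0.0
        for i in range(n):
            forces[i, 0] = 0.0
            forces[i, 1] = 0.0
            forces[i, 2] = 0.0
        bad = pair_forces_fast(pos, box, pbc, lam_inv, cutoff2, lj_form, pi,
                               pj, peps, psig6, pqq, state[0], forces)
        if bad >= 0:
            return 1, step0 + t, bad
        for i in range(n):
            _, fx, fy, fz = ext_energy_force(pos[i, 0], pos[i, 1], pos[i, 2],
                                             sidx[i], ext, sp_barrier,
                                             sp_well, sp_qf)
            forces[i, 0] += fx
            forces[i, 1] += fy
            forces[i, 2] += fz

        maxd2 = 0.0
        for i in range(n):
            ddx = forces[i, 0] * inv_g
            ddy = forces[i, 1] * inv_g
            ddz = forces[i, 2] * inv_g
            dn = np.sqrt(ddx * ddx + ddy * ddy + ddz * ddz)
            if dn > max_move:  # guards against blow-up on steep wall contacts
                sc = max_move / dn
                ddx *= sc
                ddy *= sc
                ddz *= sc
            ddx += noise[t, i, 0]
            ddy += noise[t, i, 1]
            ddz += noise[t, i, 2]
            px = pos[i, 0] + ddx
            py = pos[i, 1] + ddy
            pz = pos[i, 2] + ddz
            if not (np.isfinite(px) and np.isfinite(py) and np.isfinite(pz)):
                return 2, step0 + t, i
            if pbc[0]:
                px -= box[0] * np.floor(px / box[0])
            if pbc[1]:
                py -= box[1] * np.floor(py / box[1])
            if pbc[2]:
                pz -= box[2] * np.floor(pz / box[2])
            pos[i, 0] = px
            pos[i, 1] = py
            pos[i, 2] = pz
            disp[i, 0] += ddx
            disp[i, 1] += ddy
            disp[i, 2] += ddz
            d2 = (disp[i, 0] ** 2 + disp[i, 1] ** 2 + disp[i, 2] ** 2)
            if d2 > maxd2:
                maxd2 = d2
        if maxd2 > half_skin2:
            state[1] = 1
        g = step0 + t + 1
        if g % record_every == 0:
            k = g // record_every
            for i in range(n):
                frames[k, i, 0] = pos[i, 0]
                frames[k, i, 1] = pos[i, 1]
                frames[k, i, 2] = pos[i, 2]
    return 0, step0 + nsteps, -1


@njit(cache=True, fastmath=True)
def harmonic_chunk(x0, k_spring, inv_g, noise, out, record_every, step0):
    """1D overdamped dynamics in a harmonic well (validation utility)."""
    x = x0
    for t in range(noise.shape[0]):
        x += -k_spring * x * inv_g + noise[t]
        g = step0 + t + 1
        if g % record_every == 0:
            out[g // record_every] = x
    return x


@njit(cache=True)
def sample_chain(indptr, indices, cumdata, start, rands, out):
    """Categorical sampling of a CSR row-stochastic matrix."""
    s = start
    out[0] = s
    for t in range(rands.shape[0]):
        lo = indptr[s]
        hi = indptr[s + 1]
        r = rands[t]
        # binary search in cumdata[lo:hi]
        a = lo
        b = hi - 1
        while a < b:
            m = (a + b) // 2
            if cumdata[m] < r:
                a = m + 1
            else:
                b = m
        s = indices[a]
        out[t + 1] = s
    return out
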