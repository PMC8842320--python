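"""Numba-compiled computational kernels.

Conventions shared by all kernels:

- positions are (N, 3) float64 in nm; the cell is rectangular, periodic in
  x and y only (minimum image applied to dx, dy; never to dz);
- pair interactions are evaluated from piecewise-cubic tables on an
  s = r^2 grid stored as per-interval polynomial coefficients (the Hermite
  construction makes the tabulated force the exact derivative of the
  tabulated energy);
- ``group`` codes: 0 = SUB rigid (frozen), 1 = SUP rigid (translating body),
  2 = molecule bead (thermostatted);
- the neighbour list is two-level: a long candidate list (cutoff + reservoir)
  rebuilt rarely by an O(N^2) scan, then split short lists (cutoff + skin)
  for Morse and real-space Coulomb pairs refiltered from it frequently.
  All rebuilds run on fixed step schedules so a restarted run rebuilds at
  exactly the same steps as an uninterrupted one.
"""

import numpy as np
from numba import njit

NJIT = dict(cache=True, fastmath=True)


# ---------------------------------------------------------------------------
# neighbour lists
# ---------------------------------------------------------------------------

@njit(**NJIT)
def build_long(pos, lx, ly, group, cid, charges, mol_id, tidmat,
               rc2_long_m, rc2_long_c, excl_ptr, excl_idx,
               lng_i, lng_j, lng_t, lng_qq):
    """O(N^2) candidate scan with a reservoir margin around both cutoffs.

    Skips rigid-rigid pairs, pairs with neither a Morse table nor charges,
    and excluded intramolecular pairs.  Returns count or -1 on overflow.
    """
    n = pos.shape[0]
    cap = lng_i.shape[0]
    cnt = 0
    rc_big = max(rc2_long_m, rc2_long_c)
    for i in range(n):
        gi = group[i]
        qi = charges[i]
        ci = cid[i]
        mi = mol_id[i]
        xi = pos[i, 0]
        yi = pos[i, 1]
        zi = pos[i, 2]
        e0 = excl_ptr[i]
        e1 = excl_ptr[i + 1]
        for j in range(i + 1, n):
            if gi < 2 and group[j] < 2:
                continue
            dz = zi - pos[j, 2]
            if dz * dz > rc_big:
                continue
            dx = xi - pos[j, 0]
            dy = yi - pos[j, 1]
            dx -= lx * np.rint(dx / lx)
            dy -= ly * np.rint(dy / ly)
            s = dx * dx + dy * dy + dz * dz
            t = tidmat[ci, cid[j]]
            qq = qi * charges[j]
            keep = (t > 0 and s < rc2_long_m) or (qq != 0.0 and
                                                  s < rc2_long_c)
            if not keep:
                continue
            if mi >= 0 and mi == mol_id[j]:
                excl = False
                for e in range(e0, e1):
                    if excl_idx[e] == j:
                        excl = True
                        break
                if excl:
                    continue
            if cnt >= cap:
                return -1
            lng_i[cnt] = i
            lng_j[cnt] = j
            lng_t[cnt] = t
            lng_qq[cnt] = qq
            cnt += 1
    return cnt


@njit(**NJIT)
def build_short(pos, lx, ly, n_long, lng_i, lng_j, lng_t, lng_qq,
                rc2_m, rc2_c,
                mp_i, mp_j, mp_t, cp_i, cp_j, cp_qq, counts):
    """Refilter the long list into separate Morse and Coulomb short lists.

    ``counts`` receives (n_morse, n_coul); both are set to -1 on overflow.
    """
    cap_m = mp_i.shape[0]
    cap_c = cp_i.shape[0]
    nm = 0
    nc = 0
    for p in range(n_long):
        i = lng_i[p]
        j = lng_j[p]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        dx -= lx * np.rint(dx / lx)
        dy -= ly * np.rint(dy / ly)
        s = dx * dx + dy * dy + dz * dz
        t = lng_t[p]
        qq = lng_qq[p]
        if t > 0 and s < rc2_m:
            if nm >= cap_m:
                counts[0] = -1
                counts[1] = -1
                return
            mp_i[nm] = i
            mp_j[nm] = j
            mp_t[nm] = t - 1
            nm += 1
        if qq != 0.0 and s < rc2_c:
            if nc >= cap_c:
                counts[0] = -1
                counts[1] = -1
                return
            cp_i[nc] = i
            cp_j[nc] = j
            cp_qq[nc] = qq
            nc += 1
    counts[0] = nm
    counts[1] = nc


# ---------------------------------------------------------------------------
# pair forces from per-interval cubic coefficient tables in s = r^2:
# V(u) = ((c3 u + c2) u + c1) u + c0,  dV/ds = ((3 c3 u + 2 c2) u + c1)/ds
# ---------------------------------------------------------------------------

@njit(**NJIT)
def morse_pair_forces(pos, lx, ly, n_pairs, mp_i, mp_j, mp_t,
                      coef, s0, inv_ds, nint, s_cut, frc):
    """Shifted-Morse pair sum; returns the Morse energy."""
    e = 0.0
    inv_lx = 1.0 / lx
    inv_ly = 1.0 / ly
    for p in range(n_pairs):
        i = mp_i[p]
        j = mp_j[p]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        dx -= lx * np.rint(dx * inv_lx)
        dy -= ly * np.rint(dy * inv_ly)
        s = dx * dx + dy * dy + dz * dz
        if s >= s_cut:
            continue
        x = (s - s0) * inv_ds
        if x < 0.0:
            x = 0.0
        k = int(x)
        if k > nint - 1:
            k = nint - 1
        u = x - k
        t = mp_t[p]
        c3 = coef[t, k, 0]
        c2 = coef[t, k, 1]
        c1 = coef[t, k, 2]
        c0 = coef[t, k, 3]
        e += ((c3 * u + c2) * u + c1) * u + c0
        g = ((3.0 * c3 * u + 2.0 * c2) * u + c1) * inv_ds
        fx = -2.0 * g * dx
        fy = -2.0 * g * dy
        fz = -2.0 * g * dz
        frc[i, 0] += fx
        frc[i, 1] += fy
        frc[i, 2] += fz
        frc[j, 0] -= fx
        frc[j, 1] -= fy
        frc[j, 2] -= fz
    return e


@njit(**NJIT)
def coul_pair_forces(pos, lx, ly, n_pairs, cp_i, cp_j, cp_qq,
                     coef, s0, inv_ds, nint, s_cut, frc):
    """erfc-damped real-space Coulomb pair sum; returns its energy."""
    e = 0.0
    inv_lx = 1.0 / lx
    inv_ly = 1.0 / ly
    for p in range(n_pairs):
        i = cp_i[p]
        j = cp_j[p]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        dx -= lx * np.rint(dx * inv_lx)
        dy -= ly * np.rint(dy * inv_ly)
        s = dx * dx + dy * dy + dz * dz
        if s >= s_cut:
            continue
        x = (s - s0) * inv_ds
        if x < 0.0:
            x = 0.0
        k = int(x)
        if k > nint - 1:
            k = nint - 1
        u = x - k
        qq = cp_qq[p]
        c3 = coef[k, 0]
        c2 = coef[k, 1]
        c1 = coef[k, 2]
        c0 = coef[k, 3]
        e += qq * (((c3 * u + c2) * u + c1) * u + c0)
        g = qq * ((3.0 * c3 * u + 2.0 * c2) * u + c1) * inv_ds
        fx = -2.0 * g * dx
        fy = -2.0 * g * dy
        fz = -2.0 * g * dz
        frc[i, 0] += fx
        frc[i, 1] += fy
        frc[i, 2] += fz
        frc[j, 0] -= fx
        frc[j, 1] -= fy
        frc[j, 2] -= fz
    return e


# ---------------------------------------------------------------------------
# bonded terms
# ---------------------------------------------------------------------------

@njit(**NJIT)
def bond_energy_forces(pos, lx, ly, bond_i, bond_j, bond_k, bond_r0, frc):
    """Harmonic bonds E = (k/2)(r - r_eq)^2; k is the literal 2nd derivative."""
    e = 0.0
    for b in range(bond_i.shape[0]):
        i = bond_i[b]
        j = bond_j[b]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        dx -= lx * np.rint(dx / lx)
        dy -= ly * np.rint(dy / ly)
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        if r < 1e-12:
            return np.nan
        dr = r - bond_r0[b]
        k = bond_k[b]
        e += 0.5 * k * dr * dr
        f = -k * dr / r
        frc[i, 0] += f * dx
        frc[i, 1] += f * dy
        frc[i, 2] += f * dz
        frc[j, 0] -= f * dx
        frc[j, 1] -= f * dy
        frc[j, 2] -= f * dz
    return e


@njit(**NJIT)
def angle_energy_forces(pos, lx, ly, ang_i, ang_j, ang_k, ang_kk, ang_t0,
                        frc):
    """Harmonic angles E = (k/2)(theta - theta_eq)^2 about the middle bead.

    The (theta - theta_eq)/sin(theta) ratio is finite at theta = 180 deg when
    theta_eq = 180 deg; sin(theta) is floored at 1e-8 to keep the limit
    numerically well behaved.
    """
    e = 0.0
    for a in range(ang_i.shape[0]):
        i = ang_i[a]
        j = ang_j[a]
        k = ang_k[a]
        ux = pos[i, 0] - pos[j, 0]
        uy = pos[i, 1] - pos[j, 1]
        uz = pos[i, 2] - pos[j, 2]
        wx = pos[k, 0] - pos[j, 0]
        wy = pos[k, 1] - pos[j, 1]
        wz = pos[k, 2] - pos[j, 2]
        ux -= lx * np.rint(ux / lx)
        uy -= ly * np.rint(uy / ly)
        wx -= lx * np.rint(wx / lx)
        wy -= ly * np.rint(wy / ly)
        ru = np.sqrt(ux * ux + uy * uy + uz * uz)
        rw = np.sqrt(wx * wx + wy * wy + wz * wz)
        if ru < 1e-12 or rw < 1e-12:
            return np.nan
        cth = (ux * wx + uy * wy + uz * wz) / (ru * rw)
        if cth > 1.0:
            cth = 1.0
        elif cth < -1.0:
            cth = -1.0
        th = np.arccos(cth)
        sth = np.sqrt(1.0 - cth * cth)
        if sth < 1e-8:
            sth = 1e-8
        dth = th - ang_t0[a]
        kk = ang_kk[a]
        e += 0.5 * kk * dth * dth
        # dE/dtheta * dtheta/dr: grad_i theta = -(w_hat - cth u_hat)/(ru sth)
        c = kk * dth / sth
        fix = c * (wx / (ru * rw) - cth * ux / (ru * ru))
        fiy = c * (wy / (ru * rw) - cth * uy / (ru * ru))
        fiz = c * (wz / (ru * rw) - cth * uz / (ru * ru))
        fkx = c * (ux / (ru * rw) - cth * wx / (rw * rw))
        fky = c * (uy / (ru * rw) - cth * wy / (rw * rw))
        fkz = c * (uz / (ru * rw) - cth * wz / (rw * rw))
        frc[i, 0] += fix
        frc[i, 1] += fiy
        frc[i, 2] += fiz
        frc[k, 0] += fkx
        frc[k, 1] += fky
        frc[k, 2] += fkz
        frc[j, 0] -= fix + fkx
        frc[j, 1] -= fiy + fky
        frc[j, 2] -= fiz + fkz
    return e


@njit(**NJIT)
def tilt_energy_forces(pos, np1_idx, np2_idx, sgn, k_tilt, frc):
    """Tail-verticality restraint E = (k/2) theta^2 per molecule.

    theta is the angle between the NP2->NP1 bond and the outward layer
    normal (sgn = +1 for SUB, -1 for SUP); equivalent to an angle term
    between the bond and a virtual node below NP2.  theta/sin(theta) is
    finite at the vertical equilibrium (floored sin).
    """
    e = 0.0
    for a in range(np1_idx.shape[0]):
        i = np1_idx[a]
        j = np2_idx[a]
        s = sgn[a]
        ux = pos[i, 0] - pos[j, 0]
        uy = pos[i, 1] - pos[j, 1]
        uz = pos[i, 2] - pos[j, 2]
        r = np.sqrt(ux * ux + uy * uy + uz * uz)
        if r < 1e-12:
            return np.nan
        c = s * uz / r
        if c > 1.0:
            c = 1.0
        elif c < -1.0:
            c = -1.0
        th = np.arccos(c)
        st = np.sqrt(1.0 - c * c)
        if st < 1e-8:
            st = 1e-8
        e += 0.5 * k_tilt * th * th
        # F = -dE/du = (k theta / sin theta) * dc/du
        f = k_tilt * th / st
        r3 = r * r * r
        fx = f * (-s * uz * ux / r3)
        fy = f * (-s * uz * uy / r3)
        fz = f * (s / r - s * uz * uz / r3)
        frc[i, 0] += fx
        frc[i, 1] += fy
        frc[i, 2] += fz
        frc[j, 0] -= fx
        frc[j, 1] -= fy
        frc[j, 2] -= fz
    return e


# ---------------------------------------------------------------------------
# Ewald reciprocal-space sum (3D-periodic with vacuum padding; the slab
# dipole correction is applied by the caller / chunk driver)
# ---------------------------------------------------------------------------

@njit(**NJIT)
def ewald_recip(pos, q_idx, charges, lx, ly, lz, alpha, kint, kc_e, frc):
    """k-space sum over the half-space vectors in ``kint`` (integer triples).

    kc_e holds the per-vector coefficient (4 pi kC / V) exp(-k^2/4a^2)/k^2;
    in this half-space convention E = sum_k kc_e |S|^2 and the force carries
    an extra factor 2.  Forces are accumulated into ``frc`` at the charged
    indices; returns the reciprocal energy (self-energy and slab terms are
    handled by the caller).
    """
    nq = q_idx.shape[0]
    nk = kint.shape[0]
    if nq == 0 or nk == 0:
        return 0.0
    tpx = 2.0 * np.pi / lx
    tpy = 2.0 * np.pi / ly
    tpz = 2.0 * np.pi / lz
    nxmax = 0
    nymax = 0
    nzmax = 0
    for m in range(nk):
        if abs(kint[m, 0]) > nxmax:
            nxmax = abs(kint[m, 0])
        if abs(kint[m, 1]) > nymax:
            nymax = abs(kint[m, 1])
        if abs(kint[m, 2]) > nzmax:
            nzmax = abs(kint[m, 2])
    exr = np.empty((nq, nxmax + 1))
    exi = np.empty((nq, nxmax + 1))
    eyr = np.empty((nq, nymax + 1))
    eyi = np.empty((nq, nymax + 1))
    ezr = np.empty((nq, nzmax + 1))
    ezi = np.empty((nq, nzmax + 1))
    for a in range(nq):
        j = q_idx[a]
        exr[a, 0] = 1.0
        exi[a, 0] = 0.0
        eyr[a, 0] = 1.0
        eyi[a, 0] = 0.0
        ezr[a, 0] = 1.0
        ezi[a, 0] = 0.0
        cx = np.cos(tpx * pos[j, 0])
        sx = np.sin(tpx * pos[j, 0])
        cy = np.cos(tpy * pos[j, 1])
        sy = np.sin(tpy * pos[j, 1])
        cz = np.cos(tpz * pos[j, 2])
        sz = np.sin(tpz * pos[j, 2])
        for m in range(1, nxmax + 1):
            exr[a, m] = exr[a, m - 1] * cx - exi[a, m - 1] * sx
            exi[a, m] = exr[a, m - 1] * sx + exi[a, m - 1] * cx
        for m in range(1, nymax + 1):
            eyr[a, m] = eyr[a, m - 1] * cy - eyi[a, m - 1] * sy
            eyi[a, m] = eyr[a, m - 1] * sy + eyi[a, m - 1] * cy
        for m in range(1, nzmax + 1):
            ezr[a, m] = ezr[a, m - 1] * cz - ezi[a, m - 1] * sz
            ezi[a, m] = ezr[a, m - 1] * sz + ezi[a, m - 1] * cz
    phr = np.empty(nq)
    phi = np.empty(nq)
    txyr = np.empty(nq)
    txyi = np.empty(nq)
    qv = np.empty(nq)
    for a in range(nq):
        qv[a] = charges[q_idx[a]]
    energy = 0.0
    last_xy = -2147483648
    for m in range(nk):
        kx = kint[m, 0]
        ky = kint[m, 1]
        kz = kint[m, 2]
        xy_key = kx * 100000 + ky
        if xy_key != last_xy:
            for a in range(nq):
                xr = exr[a, kx]
                xi = exi[a, kx]
                if ky >= 0:
                    yr = eyr[a, ky]
                    yi = eyi[a, ky]
                else:
                    yr = eyr[a, -ky]
                    yi = -eyi[a, -ky]
                txyr[a] = xr * yr - xi * yi
                txyi[a] = xr * yi + xi * yr
            last_xy = xy_key
        sr = 0.0
        si = 0.0
        if kz >= 0:
            for a in range(nq):
                zr = ezr[a, kz]
                zi = ezi[a, kz]
                pr = txyr[a] * zr - txyi[a] * zi
                pi = txyr[a] * zi + txyi[a] * zr
                phr[a] = pr
                phi[a] = pi
                sr += qv[a] * pr
                si += qv[a] * pi
        else:
            for a in range(nq):
                zr = ezr[a, -kz]
                zi = -ezi[a, -kz]
                pr = txyr[a] * zr - txyi[a] * zi
                pi = txyr[a] * zi + txyi[a] * zr
                phr[a] = pr
                phi[a] = pi
                sr += qv[a] * pr
                si += qv[a] * pi
        coef = kc_e[m]
        energy += coef * (sr * sr + si * si)
        gx = 2.0 * coef * kx * tpx
        gy = 2.0 * coef * ky * tpy
        gz = 2.0 * coef * kz * tpz
        for a in range(nq):
            j = q_idx[a]
            # Im[S* e^{ik r_j}] = sr*im_j - si*re_j
            w = qv[a] * (sr * phi[a] - si * phr[a])
            frc[j, 0] += gx * w
            frc[j, 1] += gy * w
            frc[j, 2] += gz * w
    return energy


# ---------------------------------------------------------------------------
# chunked Langevin / velocity-Verlet integrator
# ---------------------------------------------------------------------------

@njit(cache=True)
def integrate_chunk(pos, vel, frc, inv_m, group, mol_idx, sup_idx,
                    lx, ly, dt, n_steps, step0,
                    # two-level neighbour list state
                    lng_i, lng_j, lng_t, lng_qq, lng_n, long_every,
                    mp_i, mp_j, mp_t, cp_i, cp_j, cp_qq, counts,
                    rebuild_every,
                    cid, charges, mol_id, tidmat,
                    rc2_long_m, rc2_long_c, rc2_m, rc2_c,
                    excl_ptr, excl_idx,
                    # pair coefficient tables
                    mcoef, s0m, inv_dsm, nintm, s_cut_m,
                    ccoef, s0c, inv_dsc, nintc, s_cut_c,
                    # bonded
                    bond_i, bond_j, bond_k, bond_r0,
                    ang_i, ang_j, ang_k, ang_kk, ang_t0,
                    np1_idx, np2_idx, tilt_sgn, k_tilt,
                    # electrostatics (reciprocal + slab held for recip_every
                    # steps)
                    do_coulomb, recip_every, q_idx, kint, kc_e, lz, alpha,
                    kc_slab, rec_frc,
                    # Langevin thermostat (y, z of molecule beads only)
                    gamma, sig, noise,
                    # drive/load: mode 0 = free, 1 = constant-velocity
                    # running-in, 2 = spring-driven production
                    mode, v_stage, k_spring, load_fz, sup_mass,
                    state, sup_vel, f_sup):
    """Advance ``n_steps`` velocity-Verlet steps.  Mutates everything.

    ``state`` holds [stage_x, sup_com_x, sup_com_y, sup_com_z].  ``frc``,
    ``rec_frc`` and ``f_sup`` must hold the forces at the entry positions.
    Returns the potential-energy components (morse, coul_real, bonds,
    angles, recip+slab) of the LAST force evaluation; callers keep chunk
    boundaries aligned with recip_every so the last evaluation is fresh.
    """
    n_mol = mol_idx.shape[0]
    n_sup = sup_idx.shape[0]
    nq = q_idx.shape[0]
    inv_msup = 1.0 / sup_mass
    e_m = e_c = e_b = e_a = e_r = 0.0
    for s in range(n_steps):
        step = step0 + s
        # --- half kick -----------------------------------------------------
        for a in range(n_mol):
            i = mol_idx[a]
            hk = 0.5 * dt * inv_m[i]
            vel[i, 0] += hk * frc[i, 0]
            vel[i, 1] += hk * frc[i, 1]
            vel[i, 2] += hk * frc[i, 2]
        if mode == 1:
            sup_vel[0] = v_stage
        else:
            sup_vel[0] += 0.5 * dt * inv_msup * f_sup[0]
        sup_vel[1] += 0.5 * dt * inv_msup * f_sup[1]
        sup_vel[2] += 0.5 * dt * inv_msup * f_sup[2]
        # --- drift ---------------------------------------------------------
        for a in range(n_mol):
            i = mol_idx[a]
            pos[i, 0] += dt * vel[i, 0]
            pos[i, 1] += dt * vel[i, 1]
            pos[i, 2] += dt * vel[i, 2]
        for a in range(n_sup):
            i = sup_idx[a]
            pos[i, 0] += dt * sup_vel[0]
            pos[i, 1] += dt * sup_vel[1]
            pos[i, 2] += dt * sup_vel[2]
        state[1] += dt * sup_vel[0]
        state[2] += dt * sup_vel[1]
        state[3] += dt * sup_vel[2]
        if mode == 2:
            state[0] += dt * v_stage
        # --- neighbour lists (fixed deterministic schedules) ----------------
        if (step + 1) % long_every == 0 or lng_n[0] < 0:
            cnt = build_long(pos, lx, ly, group, cid, charges, mol_id,
                             tidmat, rc2_long_m, rc2_long_c,
                             excl_ptr, excl_idx,
                             lng_i, lng_j, lng_t, lng_qq)
            lng_n[0] = cnt
            if cnt < 0:
                return np.nan, np.nan, np.nan, np.nan, np.nan
            counts[0] = -1
        if (step + 1) % rebuild_every == 0 or counts[0] < 0:
            build_short(pos, lx, ly, lng_n[0], lng_i, lng_j, lng_t,
                        lng_qq, rc2_m, rc2_c,
                        mp_i, mp_j, mp_t, cp_i, cp_j, cp_qq, counts)
            if counts[0] < 0:
                return np.nan, np.nan, np.nan, np.nan, np.nan
        # --- forces ---------------------------------------------------------
        frc[:, :] = 0.0
        e_m = morse_pair_forces(pos, lx, ly, counts[0], mp_i, mp_j, mp_t,
                                mcoef, s0m, inv_dsm, nintm, s_cut_m, frc)
        e_c = coul_pair_forces(pos, lx, ly, counts[1], cp_i, cp_j, cp_qq,
                               ccoef, s0c, inv_dsc, nintc, s_cut_c, frc)
        e_b = bond_energy_forces(pos, lx, ly, bond_i, bond_j, bond_k,
                                 bond_r0, frc)
        e_a = angle_energy_forces(pos, lx, ly, ang_i, ang_j, ang_k,
                                  ang_kk, ang_t0, frc)
        if k_tilt > 0.0:
            e_a += tilt_energy_forces(pos, np1_idx, np2_idx, tilt_sgn,
                                      k_tilt, frc)
        if do_coulomb:
            # caller initializes rec_frc before the first chunk and keeps
            # chunk boundaries aligned with recip_every
            if (step + 1) % recip_every == 0:
                rec_frc[:, :] = 0.0
                e_r = ewald_recip(pos, q_idx, charges, lx, ly, lz, alpha,
                                  kint, kc_e, rec_frc)
                # slab (Yeh-Berkowitz) dipole term
                mz = 0.0
                for a in range(nq):
                    j = q_idx[a]
                    mz += charges[j] * pos[j, 2]
                e_r += kc_slab * 0.5 * mz * mz
                for a in range(nq):
                    j = q_idx[a]
                    rec_frc[j, 2] -= kc_slab * charges[j] * mz
            for a in range(nq):
                j = q_idx[a]
                frc[j, 0] += rec_frc[j, 0]
                frc[j, 1] += rec_frc[j, 1]
                frc[j, 2] += rec_frc[j, 2]
        # --- Langevin friction + noise on y, z of molecule beads -------------
        if gamma > 0.0:
            for a in range(n_mol):
                i = mol_idx[a]
                gm = gamma / inv_m[i]
                frc[i, 1] += -gm * vel[i, 1] + sig[a] * noise[s, a, 0]
                frc[i, 2] += -gm * vel[i, 2] + sig[a] * noise[s, a, 1]
        # --- SUP body force --------------------------------------------------
        f_sup[0] = 0.0
        f_sup[1] = 0.0
        f_sup[2] = 0.0
        for a in range(n_sup):
            i = sup_idx[a]
            f_sup[0] += frc[i, 0]
            f_sup[1] += frc[i, 1]
            f_sup[2] += frc[i, 2]
        if mode == 2:
            f_sup[0] += k_spring * (state[0] - state[1])
        f_sup[2] -= load_fz
        # --- half kick -------------------------------------------------------
        for a in range(n_mol):
            i = mol_idx[a]
            hk = 0.5 * dt * inv_m[i]
            vel[i, 0] += hk * frc[i, 0]
            vel[i, 1] += hk * frc[i, 1]
            vel[i, 2] += hk * frc[i, 2]
        if mode == 1:
            sup_vel[0] = v_stage
        else:
            sup_vel[0] += 0.5 * dt * inv_msup * f_sup[0]
        sup_vel[1] += 0.5 * dt * inv_msup * f_sup[1]
        sup_vel[2] += 0.5 * dt * inv_msup * f_sup[2]
    return e_m, e_c, e_b, e_a, e_r
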