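"""Compiled force, energy and integrator kernels.

These are the engine's fast paths (numba ``njit``). They are deliberately
plain O(N^2) loops over packed arrays — small enough to audit, fast enough for
the desk-scale systems the analyses run — and are cross-checked in the test
suite against the pure-numpy reference functions in :mod:`parfus.potentials`.

Energy-term order used throughout:
0 bond, 1 angle, 2 dihedral, 3 hps vdW, 4 electrostatic, 5 go_native,
6 go_repulsive, 7 restraint.
"""

from __future__ import annotations

import numpy as np
from numba import njit

N_TERMS = 8
SIXTH_ROOT_2 = 2.0 ** (1.0 / 6.0)


@njit(cache=True, inline="always")
def _key(i, j):
    if i < j:
        return i * 4294967296 + j
    return j * 4294967296 + i


@njit(cache=True, inline="always")
def _in_sorted(key, arr):
    lo, hi = 0, len(arr)
    while lo < hi:
        mid = (lo + hi) // 2
        if arr[mid] < key:
            lo = mid + 1
        else:
            hi = mid
    return lo < len(arr) and arr[lo] == key


@njit(cache=True, inline="always")
def _mi(d, box):
    # minimum image for one component; box <= 0 means non-periodic
    if box > 0.0:
        d -= box * np.round(d / box)
    return d


@njit(cache=True)
def compute_forces(pos, box, sdid, sigma, lam, charge, rep_radius, eps_res,
                   excl_keys, nat_keys, nat_pairs, nat_sigma, nat_eps,
                   bonds, bond_r0, bond_k,
                   angles, angle_theta0, angle_k,
                   dihedrals, dih_k, dih_delta, dih_n,
                   eps_lj, coul_pref, kappa, cut_vdw, cut_elec, rep_eps_factor,
                   grp_a, grp_b, mass, restraint_k, restraint_req):
    """Total force and per-term energy for one configuration.

    Returns (forces (N,3), energies (8,), restraint_distance).
    restraint_k <= 0 disables the COM-distance restraint (grp arrays ignored).
    """
    n = pos.shape[0]
    forces = np.zeros((n, 3))
    energies = np.zeros(N_TERMS)
    bx, by, bz = box[0], box[1], box[2]

    # ---- generic nonbonded double loop ----
    cut2 = max(cut_vdw, cut_elec) ** 2
    for i in range(n - 1):
        qi = charge[i]
        for j in range(i + 1, n):
            same_dom = sdid[i] >= 0 and sdid[i] == sdid[j]
            # bonded exclusions only ever span <= 3 positions; native-contact
            # pairs only exist inside one structured domain
            if j - i <= 3 and _in_sorted(_key(i, j), excl_keys):
                continue
            if same_dom and _in_sorted(_key(i, j), nat_keys):
                continue
            # z-first rejection: slab systems separate mostly along z
            dz = _mi(pos[i, 2] - pos[j, 2], bz)
            if not same_dom and dz * dz > cut2:
                continue
            dx = _mi(pos[i, 0] - pos[j, 0], bx)
            dy = _mi(pos[i, 1] - pos[j, 1], by)
            r2 = dx * dx + dy * dy + dz * dz
            if not same_dom and r2 > cut2:
                continue
            r = np.sqrt(r2)
            if r <= 0.0:
                continue
            if same_dom:
                # Gō repulsive r^-12
                sij = 0.5 * (rep_radius[i] + rep_radius[j])
                epsr = rep_eps_factor * eps_res[i]
                sr12 = (sij / r) ** 12
                e = epsr * sr12
                dedr = -12.0 * e / r
                energies[6] += e
            else:
                e = 0.0
                dedr = 0.0
                if r < cut_vdw:
                    sij = 0.5 * (sigma[i] + sigma[j])
                    lij = 0.5 * (lam[i] + lam[j])
                    sr6 = (sij / r) ** 6
                    phi = 4.0 * eps_lj * (sr6 * sr6 - sr6)
                    dphi = 4.0 * eps_lj * (-12.0 * sr6 * sr6 + 6.0 * sr6) / r
                    if r <= SIXTH_ROOT_2 * sij:
                        e += phi + (1.0 - lij) * eps_lj
                        dedr += dphi
                    else:
                        e += lij * phi
                        dedr += lij * dphi
                    energies[3] += (phi + (1.0 - lij) * eps_lj) if r <= SIXTH_ROOT_2 * sij else lij * phi
                qj = charge[j]
                if qi != 0.0 and qj != 0.0 and r < cut_elec:
                    ee = coul_pref * qi * qj / r * np.exp(-kappa * r)
                    e += ee
                    dedr += -ee * (1.0 / r + kappa)
                    energies[4] += ee
            fscale = -dedr / r
            fx, fy, fz = fscale * dx, fscale * dy, fscale * dz
            forces[i, 0] += fx; forces[i, 1] += fy; forces[i, 2] += fz
            forces[j, 0] -= fx; forces[j, 1] -= fy; forces[j, 2] -= fz

    # ---- native contacts (12-10-6) ----
    for c in range(nat_pairs.shape[0]):
        i, j = nat_pairs[c, 0], nat_pairs[c, 1]
        dx = _mi(pos[i, 0] - pos[j, 0], bx)
        dy = _mi(pos[i, 1] - pos[j, 1], by)
        dz = _mi(pos[i, 2] - pos[j, 2], bz)
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        sr = nat_sigma[c] / r
        sr6 = sr ** 6
        sr10 = sr6 * sr ** 4
        sr12 = sr6 * sr6
        e = nat_eps[c] * (13.0 * sr12 - 18.0 * sr10 + 4.0 * sr6)
        dedr = nat_eps[c] * (-156.0 * sr12 + 180.0 * sr10 - 24.0 * sr6) / r
        energies[5] += e
        fscale = -dedr / r
        forces[i, 0] += fscale * dx; forces[i, 1] += fscale * dy; forces[i, 2] += fscale * dz
        forces[j, 0] -= fscale * dx; forces[j, 1] -= fscale * dy; forces[j, 2] -= fscale * dz

    # ---- bonds ----
    for b in range(bonds.shape[0]):
        i, j = bonds[b, 0], bonds[b, 1]
        dx = _mi(pos[i, 0] - pos[j, 0], bx)
        dy = _mi(pos[i, 1] - pos[j, 1], by)
        dz = _mi(pos[i, 2] - pos[j, 2], bz)
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        dr = r - bond_r0[b]
        energies[0] += 0.5 * bond_k[b] * dr * dr
        fscale = -bond_k[b] * dr / r
        forces[i, 0] += fscale * dx; forces[i, 1] += fscale * dy; forces[i, 2] += fscale * dz
        forces[j, 0] -= fscale * dx; forces[j, 1] -= fscale * dy; forces[j, 2] -= fscale * dz

    # ---- angles ----
    for a in range(angles.shape[0]):
        i, j, k = angles[a, 0], angles[a, 1], angles[a, 2]
        ax = _mi(pos[i, 0] - pos[j, 0], bx); ay = _mi(pos[i, 1] - pos[j, 1], by)
        az = _mi(pos[i, 2] - pos[j, 2], bz)
        cx = _mi(pos[k, 0] - pos[j, 0], bx); cy = _mi(pos[k, 1] - pos[j, 1], by)
        cz = _mi(pos[k, 2] - pos[j, 2], bz)
        ra = np.sqrt(ax * ax + ay * ay + az * az)
        rc = np.sqrt(cx * cx + cy * cy + cz * cz)
        cost = (ax * cx + ay * cy + az * cz) / (ra * rc)
        if cost > 1.0:
            cost = 1.0
        elif cost < -1.0:
            cost = -1.0
        theta = np.arccos(cost)
        dth = theta - angle_theta0[a]
        energies[1] += 0.5 * angle_k[a] * dth * dth
        dvdt = angle_k[a] * dth
        sint = np.sqrt(1.0 - cost * cost)
        if sint < 1e-8:
            sint = 1e-8
        coef = -dvdt / sint
        fia = coef / ra * (cx / rc - cost * ax / ra)
        fib = coef / ra * (cy / rc - cost * ay / ra)
        fic = coef / ra * (cz / rc - cost * az / ra)
        fka = coef / rc * (ax / ra - cost * cx / rc)
        fkb = coef / rc * (ay / ra - cost * cy / rc)
        fkc = coef / rc * (az / ra - cost * cz / rc)
        forces[i, 0] += fia; forces[i, 1] += fib; forces[i, 2] += fic
        forces[k, 0] += fka; forces[k, 1] += fkb; forces[k, 2] += fkc
        forces[j, 0] -= fia + fka; forces[j, 1] -= fib + fkb; forces[j, 2] -= fic + fkc

    # ---- dihedrals: V = sum_t k_t (1 + cos(n_t phi - delta_t)) ----
    for d in range(dihedrals.shape[0]):
        i, j, k, l = dihedrals[d, 0], dihedrals[d, 1], dihedrals[d, 2], dihedrals[d, 3]
        b1x = _mi(pos[j, 0] - pos[i, 0], bx); b1y = _mi(pos[j, 1] - pos[i, 1], by)
        b1z = _mi(pos[j, 2] - pos[i, 2], bz)
        b2x = _mi(pos[k, 0] - pos[j, 0], bx); b2y = _mi(pos[k, 1] - pos[j, 1], by)
        b2z = _mi(pos[k, 2] - pos[j, 2], bz)
        b3x = _mi(pos[l, 0] - pos[k, 0], bx); b3y = _mi(pos[l, 1] - pos[k, 1], by)
        b3z = _mi(pos[l, 2] - pos[k, 2], bz)
        n1x = b1y * b2z - b1z * b2y
        n1y = b1z * b2x - b1x * b2z
        n1z = b1x * b2y - b1y * b2x
        n2x = b2y * b3z - b2z * b3y
        n2y = b2z * b3x - b2x * b3z
        n2z = b2x * b3y - b2y * b3x
        n1sq = n1x * n1x + n1y * n1y + n1z * n1z
        n2sq = n2x * n2x + n2y * n2y + n2z * n2z
        b2n = np.sqrt(b2x * b2x + b2y * b2y + b2z * b2z)
        if n1sq < 1e-12 or n2sq < 1e-12:
            continue
        cxx = n1y * n2z - n1z * n2y
        cxy = n1z * n2x - n1x * n2z
        cxz = n1x * n2y - n1y * n2x
        sinphi = (cxx * b2x + cxy * b2y + cxz * b2z) / b2n
        cosphi = n1x * n2x + n1y * n2y + n1z * n2z
        phi = np.arctan2(sinphi, cosphi)
        dv = 0.0
        for t in range(4):
            kt = dih_k[d, t]
            if kt != 0.0:
                nt = dih_n[d, t]
                energies[2] += kt * (1.0 + np.cos(nt * phi - dih_delta[d, t]))
                dv += -kt * nt * np.sin(nt * phi - dih_delta[d, t])
        fi_s = -dv * b2n / n1sq
        fl_s = dv * b2n / n2sq
        fix, fiy, fiz = fi_s * n1x, fi_s * n1y, fi_s * n1z
        flx, fly, flz = fl_s * n2x, fl_s * n2y, fl_s * n2z
        s12 = (b1x * b2x + b1y * b2y + b1z * b2z) / (b2n * b2n)
        s32 = (b3x * b2x + b3y * b2y + b3z * b2z) / (b2n * b2n)
        fjx = -fix + s12 * fix - s32 * flx
        fjy = -fiy + s12 * fiy - s32 * fly
        fjz = -fiz + s12 * fiz - s32 * flz
        fkx = -flx - s12 * fix + s32 * flx
        fky = -fly - s12 * fiy + s32 * fly
        fkz = -flz - s12 * fiz + s32 * flz
        forces[i, 0] += fix; forces[i, 1] += fiy; forces[i, 2] += fiz
        forces[j, 0] += fjx; forces[j, 1] += fjy; forces[j, 2] += fjz
        forces[k, 0] += fkx; forces[k, 1] += fky; forces[k, 2] += fkz
        forces[l, 0] += flx; forces[l, 1] += fly; forces[l, 2] += flz

    # ---- COM-distance restraint ----
    rdist = 0.0
    if restraint_k > 0.0:
        ma = 0.0
        comax = 0.0; comay = 0.0; comaz = 0.0
        for t in range(len(grp_a)):
            i = grp_a[t]
            comax += mass[i] * pos[i, 0]; comay += mass[i] * pos[i, 1]
            comaz += mass[i] * pos[i, 2]; ma += mass[i]
        mb = 0.0
        combx = 0.0; comby = 0.0; combz = 0.0
        for t in range(len(grp_b)):
            i = grp_b[t]
            combx += mass[i] * pos[i, 0]; comby += mass[i] * pos[i, 1]
            combz += mass[i] * pos[i, 2]; mb += mass[i]
        dx = comax / ma - combx / mb
        dy = comay / ma - comby / mb
        dz = comaz / ma - combz / mb
        rdist = np.sqrt(dx * dx + dy * dy + dz * dz)
        dr = rdist - restraint_req
        energies[7] += 0.5 * restraint_k * dr * dr
        if rdist > 1e-10:
            dedr = restraint_k * dr
            ux, uy, uz = dx / rdist, dy / rdist, dz / rdist
            for t in range(len(grp_a)):
                i = grp_a[t]
                w = mass[i] / ma
                forces[i, 0] -= dedr * ux * w
                forces[i, 1] -= dedr * uy * w
                forces[i, 2] -= dedr * uz * w
            for t in range(len(grp_b)):
                i = grp_b[t]
                w = mass[i] / mb
                forces[i, 0] += dedr * ux * w
                forces[i, 1] += dedr * uy * w
                forces[i, 2] += dedr * uz * w

    return forces, energies, rdist


@njit(cache=True)
def run_md(pos, vel, box, sdid, sigma, lam, charge, rep_radius, eps_res,
           excl_keys, nat_keys, nat_pairs, nat_sigma, nat_eps,
           bonds, bond_r0, bond_k, angles, angle_theta0, angle_k,
           dihedrals, dih_k, dih_delta, dih_n,
           eps_lj, coul_pref, kappa, cut_vdw, cut_elec, rep_eps_factor,
           grp_a, grp_b, mass, restraint_k, restraint_req,
           dt, n_steps, gamma, kT, save_every, sample_every, seed):
    """Langevin (BAOAB; gamma > 0) or velocity-Verlet NVE (gamma == 0) loop.

    Returns (saved positions, saved potential energies (n_save, 8), saved
    kinetic energies, restraint-distance samples). Deterministic for a seed.
    """
    np.random.seed(seed)
    n = pos.shape[0]
    n_save = n_steps // save_every
    n_samp = n_steps // sample_every if sample_every > 0 else 0
    traj = np.zeros((n_save, n, 3))
    epot = np.zeros((n_save, N_TERMS))
    ekin = np.zeros(n_save)
    rsamp = np.zeros(n_samp)

    c1 = np.exp(-gamma * dt) if gamma > 0.0 else 1.0
    c2 = np.sqrt(1.0 - c1 * c1)
    f, e, rd = compute_forces(pos, box, sdid, sigma, lam, charge, rep_radius, eps_res,
                              excl_keys, nat_keys, nat_pairs, nat_sigma, nat_eps,
                              bonds, bond_r0, bond_k, angles, angle_theta0, angle_k,
                              dihedrals, dih_k, dih_delta, dih_n,
                              eps_lj, coul_pref, kappa, cut_vdw, cut_elec,
                              rep_eps_factor, grp_a, grp_b, mass,
                              restraint_k, restraint_req)
    for step in range(n_steps):
        for i in range(n):
            inv_m = 1.0 / mass[i]
            for d in range(3):
                vel[i, d] += 0.5 * dt * f[i, d] * inv_m
                pos[i, d] += 0.5 * dt * vel[i, d]
        if gamma > 0.0:
            for i in range(n):
                sd = np.sqrt(kT / mass[i])
                for d in range(3):
                    vel[i, d] = c1 * vel[i, d] + c2 * sd * np.random.standard_normal()
        for i in range(n):
            for d in range(3):
                pos[i, d] += 0.5 * dt * vel[i, d]
        f, e, rd = compute_forces(pos, box, sdid, sigma, lam, charge, rep_radius, eps_res,
                                  excl_keys, nat_keys, nat_pairs, nat_sigma, nat_eps,
                                  bonds, bond_r0, bond_k, angles, angle_theta0, angle_k,
                                  dihedrals, dih_k, dih_delta, dih_n,
                                  eps_lj, coul_pref, kappa, cut_vdw, cut_elec,
                                  rep_eps_factor, grp_a, grp_b, mass,
                                  restraint_k, restraint_req)
        for i in range(n):
            inv_m = 1.0 / mass[i]
            for d in range(3):
                vel[i, d] += 0.5 * dt * f[i, d] * inv_m
        if sample_every > 0 and (step + 1) % sample_every == 0:
            rsamp[(step + 1) // sample_every - 1] = rd
        if (step + 1) % save_every == 0:
            idx = (step + 1) // save_every - 1
            traj[idx] = pos
            epot[idx] = e
            ke = 0.0
            for i in range(n):
                ke += 0.5 * mass[i] * (vel[i, 0] ** 2 + vel[i, 1] ** 2 + vel[i, 2] ** 2)
            ekin[idx] = ke
    return traj, epot, ekin, rsamp


@njit(cache=True)
def mbar_eval(x, req, kk, beta, f, logN, need_hess):
    """MBAR objective, gradient and (optionally) Hessian for harmonic biases.

    Exploits restraint locality: windows whose bias puts them more than ~46
    log-units below the per-sample maximum contribute nothing to the softmax
    and are skipped.
    """
    K = len(req)
    N = len(x)
    val = 0.0
    g = np.zeros(K)
    H = np.zeros((K, K))
    a = np.empty(K)
    w = np.empty(K)
    active = np.empty(K, dtype=np.int64)
    for n in range(N):
        xn = x[n]
        amax = -1e300
        for k in range(K):
            d = xn - req[k]
            a[k] = logN[k] + f[k] - beta * 0.5 * kk[k] * d * d
            if a[k] > amax:
                amax = a[k]
        s = 0.0
        na = 0
        for k in range(K):
            if a[k] > amax - 46.0:
                e = np.exp(a[k] - amax)
                w[na] = e
                active[na] = k
                na += 1
                s += e
        val += amax + np.log(s)
        inv = 1.0 / s
        for t in range(na):
            wt = w[t] * inv
            g[active[t]] += wt
            if need_hess:
                H[active[t], active[t]] += wt
                for u_ in range(na):
                    H[active[t], active[u_]] -= wt * (w[u_] * inv)
    return val, g, H


@njit(cache=True)
def mbar_log_weights(x, req, kk, beta, f, logN):
    """Log unbiased MBAR weights, -log sum_k N_k exp(f_k - u_k(x_n))."""
    K = len(req)
    N = len(x)
    out = np.empty(N)
    a = np.empty(K)
    for n in range(N):
        xn = x[n]
        amax = -1e300
        for k in range(K):
            d = xn - req[k]
            a[k] = logN[k] + f[k] - beta * 0.5 * kk[k] * d * d
            if a[k] > amax:
                amax = a[k]
        s = 0.0
        for k in range(K):
            if a[k] > amax - 46.0:
                s += np.exp(a[k] - amax)
        out[n] = -(amax + np.log(s))
    return out
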