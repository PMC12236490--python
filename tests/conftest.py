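"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately re-derive physics from first principles
(explicit formulas, double loops, union-find) rather than calling the
package's compiled paths, so every comparison is a genuine dual route.
"""

import math

import numpy as np
import pytest

from parfus.constants import COULOMB_KJ_NM, KB


# ---------------------------------------------------------------------------
# brute-force pair potentials (independent implementations)
# ---------------------------------------------------------------------------

def bf_lj(r, sigma, eps):
    return 4.0 * eps * ((sigma / r) ** 12 - (sigma / r) ** 6)


def bf_hps(r, sigma, lam, eps):
    if r <= 2.0 ** (1.0 / 6.0) * sigma:
        return bf_lj(r, sigma, eps) + (1.0 - lam) * eps
    return lam * bf_lj(r, sigma, eps)


def bf_elec(qi, qj, r, eps_r, ionic):
    kappa = math.sqrt(ionic) / 0.304
    return COULOMB_KJ_NM * qi * qj / (eps_r * r) * math.exp(-kappa * r)


def bf_go_native(r, sigma, eps, alpha):
    s = sigma / r
    return alpha * eps * (13.0 * s ** 12 - 18.0 * s ** 10 + 4.0 * s ** 6)


def bf_go_rep(r, sigma, eps_res, factor=1.5e-3):
    return factor * eps_res * (sigma / r) ** 12


def bf_min_image(d, L):
    if L is None or L <= 0:
        return d
    return d - L * round(d / L)


def bf_total_energy(system, pos, box=None):
    """O(N^2) reference evaluation of every term, built on pair_rule and the
    scalar formulas above (no compiled code)."""
    b = system.box if box is None else box
    b = [None, None, None] if b is None else list(b)

    def dist(i, j):
        return math.sqrt(sum(bf_min_image(pos[i, a] - pos[j, a], b[a]) ** 2
                             for a in range(3)))

    n = system.n_beads
    hps = system.hps
    kappa_cut = hps.cutoff_elec
    native = {(min(i, j), max(i, j)): (s, e) for (i, j), s, e in
              zip(map(tuple, system.native_pairs), system.native_sigma,
                  system.native_eps)}
    e = dict.fromkeys(("bond", "angle", "dihedral", "hps_vdw", "electrostatic",
                       "go_native", "go_repulsive"), 0.0)
    for i in range(n - 1):
        for j in range(i + 1, n):
            rule = system.pair_rule(i, j)
            if rule == "excluded":
                continue
            r = dist(i, j)
            if rule == "go_native":
                s, eps = native[(i, j)]
                e["go_native"] += bf_go_native(r, s, eps, 1.0)
            elif rule == "go_repulsive":
                sij = 0.5 * (system.rep_radius[i] + system.rep_radius[j])
                e["go_repulsive"] += bf_go_rep(r, sij, system.eps_res[i])
            else:
                if r < hps.cutoff_vdw:
                    sij = 0.5 * (system.sigma[i] + system.sigma[j])
                    lij = 0.5 * (system.lam[i] + system.lam[j])
                    e["hps_vdw"] += bf_hps(r, sij, lij, hps.eps_lj)
                if system.charge[i] and system.charge[j] and r < kappa_cut:
                    e["electrostatic"] += bf_elec(system.charge[i],
                                                  system.charge[j], r,
                                                  hps.eps_r, hps.ionic_strength)
    for (i, j), r0, k in zip(system.bonds, system.bond_r0, system.bond_k):
        e["bond"] += 0.5 * k * (dist(i, j) - r0) ** 2
    for (i, j, kk), t0, ka in zip(system.angles, system.angle_theta0,
                                  system.angle_k):
        va = np.array([bf_min_image(pos[i, a] - pos[j, a], b[a]) for a in range(3)])
        vc = np.array([bf_min_image(pos[kk, a] - pos[j, a], b[a]) for a in range(3)])
        ct = np.dot(va, vc) / (np.linalg.norm(va) * np.linalg.norm(vc))
        e["angle"] += 0.5 * ka * (math.acos(np.clip(ct, -1, 1)) - t0) ** 2
    for quad, ks, deltas, ns in zip(system.dihedrals, system.dihedral_k,
                                    system.dihedral_delta, system.dihedral_n):
        i, j, k, l = quad
        b1 = np.array([bf_min_image(pos[j, a] - pos[i, a], b[a]) for a in range(3)])
        b2 = np.array([bf_min_image(pos[k, a] - pos[j, a], b[a]) for a in range(3)])
        b3 = np.array([bf_min_image(pos[l, a] - pos[k, a], b[a]) for a in range(3)])
        n1, n2 = np.cross(b1, b2), np.cross(b2, b3)
        phi = math.atan2(np.dot(np.cross(n1, n2), b2 / np.linalg.norm(b2)),
                         np.dot(n1, n2))
        for kt, dt, nt in zip(ks, deltas, ns):
            if kt:
                e["dihedral"] += kt * (1.0 + math.cos(nt * phi - dt))
    e["total"] = sum(e.values())
    return e


# ---------------------------------------------------------------------------
# union-find clustering oracle
# ---------------------------------------------------------------------------

def union_find_clusters(points, box, cutoff):
    n = len(points)
    parent = list(range(n))

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for i in range(n):
        for j in range(i + 1, n):
            d2 = sum(bf_min_image(points[i][a] - points[j][a],
                                  box[a] if box is not None else None) ** 2
                     for a in range(3))
            if math.sqrt(d2) < cutoff:
                ra, rb = find(i), find(j)
                if ra != rb:
                    parent[ra] = rb
    roots = [find(i) for i in range(n)]
    relabel = {}
    return np.array([relabel.setdefault(r, len(relabel)) for r in roots])


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------

@pytest.fixture(scope="session")
def residue_table():
    from parfus.params import load_residue_table
    return load_residue_table()


@pytest.fixture(scope="session")
def toy_idr():
    from parfus.topology import build_idr_topology
    return build_idr_topology("GRGDSPYSGM")


@pytest.fixture(scope="session")
def par16():
    from parfus.topology import build_par_topology
    return build_par_topology(16)


def make_trajectory(xyz, box, chain_id, mass, dt=1.0):
    from parfus.engine import Trajectory
    xyz = np.asarray(xyz, dtype=float)
    return Trajectory(xyz=xyz, box=np.asarray(box, dtype=float),
                      time=dt * np.arange(1, len(xyz) + 1),
                      chain_id=np.asarray(chain_id),
                      domain_label=["X"] * xyz.shape[1],
                      mass=np.asarray(mass, dtype=float))
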