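"""Pairwise energy functions of the hybrid coarse-grained force field.

All functions are scalar/ufunc-style (numpy-broadcastable) reference
implementations; the simulation engine uses equivalent compiled kernels that
are cross-checked against these in the test suite.
"""

from __future__ import annotations

import numpy as np

from .constants import COULOMB_KJ_NM
from .params import HpsParams, debye_length

_SIXTH_ROOT_2 = 2.0 ** (1.0 / 6.0)


def _check_positive_r(r):
    if np.any(np.asarray(r) <= 0):
        raise ValueError("pair distance must be positive")


def lj(r, sigma, eps):
    """Plain 12-6 Lennard-Jones, kJ/mol."""
    sr6 = (sigma / r) ** 6
    return 4.0 * eps * (sr6 * sr6 - sr6)


def hps_pair_energy(r, sigma_ij, lam_ij, eps=0.8368):
    """Ashbaugh–Hatch hydropathy-scaled van der Waals energy, kJ/mol.

    Full LJ shifted up by (1-lambda)*eps inside the minimum (r <= 2^(1/6) sigma),
    lambda-scaled LJ outside; continuous at the branch point with value
    -lambda*eps there. sigma_ij and lam_ij are arithmetic means of the two
    beads' parameters.
    """
    _check_positive_r(r)
    r = np.asarray(r, dtype=float)
    phi = lj(r, sigma_ij, eps)
    inner = phi + (1.0 - lam_ij) * eps
    outer = lam_ij * phi
    return np.where(r <= _SIXTH_ROOT_2 * sigma_ij, inner, outer)


def electrostatic_energy(qi, qj, r, params: HpsParams | None = None, *,
                         eps_r: float | None = None,
                         ionic_strength: float | None = None):
    """Debye–Hückel screened Coulomb energy, kJ/mol.

    E = qi*qj / (4 pi eps0 eps_r r) * exp(-kappa r), charges in e, r in nm.
    """
    _check_positive_r(r)
    if params is None:
        params = HpsParams()
    if eps_r is None:
        eps_r = params.eps_r
    if ionic_strength is None:
        ionic_strength = params.ionic_strength
    kappa = 1.0 / debye_length(ionic_strength)
    return COULOMB_KJ_NM * qi * qj / (eps_r * np.asarray(r, dtype=float)) * np.exp(-kappa * np.asarray(r))


def go_native_pair_energy(r, sigma_ij, eps_ij, alpha=1.0):
    """Native-contact 12-10-6 potential, kJ/mol.

    V = alpha*eps_ij * [13 (s/r)^12 - 18 (s/r)^10 + 4 (s/r)^6]; the minimum is
    -alpha*eps_ij at r = sigma_ij (the native Ca–Ca distance).
    """
    _check_positive_r(r)
    sr = sigma_ij / np.asarray(r, dtype=float)
    sr6 = sr ** 6
    sr10 = sr6 * sr ** 4
    sr12 = sr6 * sr6
    return alpha * eps_ij * (13.0 * sr12 - 18.0 * sr10 + 4.0 * sr6)


def go_repulsive_energy(r, sigma_ij, eps_res, factor=1.5e-3):
    """Purely repulsive r^-12 term for non-native intra-domain pairs, kJ/mol.

    The energy scale is factor*eps_res (default 1.5e-3), sigma_ij the mean of
    the two residues' repulsive radii.
    """
    _check_positive_r(r)
    return factor * eps_res * (sigma_ij / np.asarray(r, dtype=float)) ** 12


def harmonic_bond_energy(r, r0, k):
    """Harmonic bond, kJ/mol: 0.5 k (r - r0)^2."""
    return 0.5 * k * (np.asarray(r, dtype=float) - r0) ** 2


def harmonic_angle_energy(theta, theta0, k):
    """Harmonic angle, kJ/mol: 0.5 k (theta - theta0)^2 (radians)."""
    return 0.5 * k * (np.asarray(theta, dtype=float) - theta0) ** 2


def dihedral_energy(phi, terms):
    """Cosine-series dihedral, kJ/mol: sum_n k_n (1 + cos(n phi - delta_n))."""
    phi = np.asarray(phi, dtype=float)
    out = np.zeros_like(phi)
    for n, k, delta in terms:
        out = out + k * (1.0 + np.cos(n * phi - delta))
    return out
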