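"""Slab-trajectory analytics: clustering, centering, density profiles,
coexistence densities, critical-temperature fits, contact maps and
domain-distance series.

The dense phase is located per frame by single-linkage clustering of chain
centers of mass (dendrogram cutoff 5 nm), the largest cluster is shifted to
z = 0, the box is cut into 60 z-bins, and the dilute/dense densities are the
bin averages outside/inside |z| = 50 nm. Coexistence points across a
temperature ladder are fitted to the 3-D Ising scaling law
rho_H - rho_L = A (Tc - T)^beta with beta fixed at 0.325.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.optimize import curve_fit
from scipy.spatial.distance import squareform


@dataclass
class AnalysisConfig:
    cluster_cutoff: float = 5.0      # nm, single-linkage dendrogram cutoff
    contact_cutoff: float = 1.2      # nm
    n_bins: int = 60
    slab_half_width: float = 50.0    # nm, |z| divide between dense and dilute
    analysis_window: tuple = (0.5, 1.0)  # fraction of trajectory analyzed

    def __post_init__(self):
        for name in ("cluster_cutoff", "contact_cutoff", "n_bins", "slab_half_width"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class CoexistenceFit:
    points: np.ndarray      # (n, 3): T, rho_L, rho_H
    beta: float
    A: float
    Tc: float
    covariance: np.ndarray  # 2x2 for (A, Tc)

    @property
    def tc_stderr(self) -> float:
        return float(np.sqrt(self.covariance[1, 1]))


@dataclass
class ContactMap:
    freq: np.ndarray
    axis_a: np.ndarray      # bead indices along rows
    axis_b: np.ndarray
    n_frames: int


# ---------------------------------------------------------------------------
# periodic helpers
# ---------------------------------------------------------------------------

def _mi_delta(d, L):
    if L is None or L <= 0:
        return d
    return d - L * np.round(d / L)


def periodic_com(x, L, weights=None):
    """Periodic-aware center of mass on one axis via the circular mean."""
    x = np.asarray(x, dtype=float)
    if weights is None:
        weights = np.ones_like(x)
    if L is None or L <= 0:
        return float(np.average(x, weights=weights))
    theta = 2.0 * np.pi * x / L
    s = np.average(np.sin(theta), weights=weights)
    c = np.average(np.cos(theta), weights=weights)
    return float((math.atan2(s, c) / (2.0 * np.pi)) * L % L)


def chain_coms(xyz, chain_id, mass, box):
    """Per-chain periodic-aware COM, (n_chains, 3)."""
    chains = np.unique(chain_id)
    out = np.zeros((len(chains), 3))
    for ci, c in enumerate(chains):
        idx = chain_id == c
        for ax in range(3):
            L = box[ax] if box is not None else None
            out[ci, ax] = periodic_com(xyz[idx, ax], L, weights=mass[idx])
    return out


def _periodic_pdist(points, box):
    n = len(points)
    d = np.zeros((n, n))
    for ax in range(3):
        L = box[ax] if box is not None else None
        diff = points[:, ax][:, None] - points[:, ax][None, :]
        d += _mi_delta(diff, L) ** 2
    return np.sqrt(d)


# ---------------------------------------------------------------------------
# clustering & centering
# ---------------------------------------------------------------------------

def single_linkage_clusters(coms, box, cutoff: float = 5.0) -> np.ndarray:
    """Cluster labels (0-based) from single-linkage clustering of COM
    distances with a dendrogram cutoff; equivalently the connected components
    of the graph with edges below the cutoff."""
    coms = np.asarray(coms, dtype=float)
    n = len(coms)
    if n == 0:
        raise ValueError("need at least one chain")
    if n == 1:
        return np.zeros(1, dtype=int)
    dm = _periodic_pdist(coms, box)
    Z = linkage(squareform(dm, checks=False), method="single")
    labels = fcluster(Z, t=cutoff, criterion="distance") - 1
    return labels


def largest_cluster(labels, chain_sizes=None) -> int:
    """Label of the most populous cluster; ties break to the cluster holding
    the lowest chain index."""
    labels = np.asarray(labels)
    counts = np.bincount(labels)
    best = counts.max()
    for chain, lab in enumerate(labels):
        if counts[lab] == best:
            return int(lab)
    raise AssertionError("unreachable")


def center_frame(xyz, box, labels, chain_id, mass):
    """Shift z so the periodic-aware COM of the largest cluster sits at z = 0
    (x, y untouched); coordinates are wrapped into [-Lz/2, Lz/2)."""
    xyz = np.asarray(xyz, dtype=float)
    lab = largest_cluster(labels)
    chains = np.unique(chain_id)
    members = chains[np.asarray(labels) == lab]
    sel = np.isin(chain_id, members)
    Lz = box[2] if box is not None else None
    zcom = periodic_com(xyz[sel, 2], Lz, weights=mass[sel])
    out = xyz.copy()
    out[:, 2] -= zcom
    if Lz is not None and Lz > 0:
        out[:, 2] = (out[:, 2] + 0.5 * Lz) % Lz - 0.5 * Lz
    return out


def center_trajectory(traj, config: AnalysisConfig | None = None):
    """Cluster + center every frame of a Trajectory; returns centered xyz."""
    config = config or AnalysisConfig()
    out = np.empty_like(traj.xyz)
    for f in range(traj.n_frames):
        coms = chain_coms(traj.xyz[f], traj.chain_id, traj.mass, traj.box)
        labels = single_linkage_clusters(coms, traj.box, config.cluster_cutoff)
        out[f] = center_frame(traj.xyz[f], traj.box, labels, traj.chain_id, traj.mass)
    return out


# ---------------------------------------------------------------------------
# density profiles & coexistence
# ---------------------------------------------------------------------------

def _analysis_frames(n_frames, config):
    lo = int(config.analysis_window[0] * n_frames)
    hi = int(config.analysis_window[1] * n_frames)
    if hi <= lo:
        raise ValueError("empty analysis window")
    return range(lo, hi)


def density_profile(traj, config: AnalysisConfig | None = None,
                    centered_xyz=None, number_density: bool = False):
    """Mass density (amu/nm^3) in 60 equal z-bins, frame-averaged over the
    analysis window. Returns (bin_centers, density). Frames are centered
    (largest cluster at z = 0) unless pre-centered coordinates are given."""
    config = config or AnalysisConfig()
    box = traj.box
    if box is None or box[2] <= 0:
        raise ValueError("density profile needs a periodic box")
    Lz = box[2]
    edges = np.linspace(-0.5 * Lz, 0.5 * Lz, config.n_bins + 1)
    bin_vol = (Lz / config.n_bins) * box[0] * box[1]
    weights = np.ones_like(traj.mass) if number_density else traj.mass
    xyz = centered_xyz
    if xyz is None:
        xyz = center_trajectory(traj, config)
    dens = np.zeros(config.n_bins)
    frames = _analysis_frames(traj.n_frames, config)
    for f in frames:
        z = (xyz[f][:, 2] + 0.5 * Lz) % Lz - 0.5 * Lz
        hist, _ = np.histogram(z, bins=edges, weights=weights)
        dens += hist / bin_vol
    dens /= len(frames)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return centers, dens


def coexistence_densities(bin_centers, density, config: AnalysisConfig | None = None):
    """(rho_L, rho_H): plain averages of bin densities with |z| above/below
    the slab half-width (default 50 nm)."""
    config = config or AnalysisConfig()
    bin_centers = np.asarray(bin_centers)
    density = np.asarray(density)
    outer = np.abs(bin_centers) > config.slab_half_width
    inner = ~outer
    if not outer.any() or not inner.any():
        raise ValueError("a coexistence region contains no bins; check box size")
    return float(density[outer].mean()), float(density[inner].mean())


def fit_critical_temperature(points, beta: float = 0.325, sigma=None,
                             fit_beta: bool = False) -> CoexistenceFit:
    """Fit rho_H - rho_L = A (Tc - T)^beta by (weighted) least squares.

    ``points``: iterable of (T, rho_L, rho_H); rows with rho_H <= rho_L are
    refused. Returns the fit with the (A, Tc) covariance; raises if fewer
    than 3 usable temperatures or if the fit is ill-conditioned.
    """
    pts = np.asarray([tuple(p) for p in points], dtype=float)
    if np.any(pts[:, 2] <= pts[:, 1]):
        bad = pts[pts[:, 2] <= pts[:, 1], 0]
        raise ValueError(f"rho_H <= rho_L at T={bad.tolist()}; no coexistence")
    if len(pts) < 3:
        raise ValueError("need at least 3 temperatures")
    T = pts[:, 0]
    diff = pts[:, 2] - pts[:, 1]
    Tmax = T.max()

    if fit_beta:
        def model(t, A, Tc, b):
            return A * np.clip(Tc - t, 1e-12, None) ** b
        p0 = [diff.max() / (Tmax - T.min() + 10) ** beta, Tmax + 10.0, beta]
        bounds = ([0.0, Tmax + 1e-6, 0.05], [np.inf, np.inf, 1.0])
    else:
        def model(t, A, Tc):
            return A * np.clip(Tc - t, 1e-12, None) ** beta
        p0 = [diff.max() / (Tmax - T.min() + 10) ** beta, Tmax + 10.0]
        bounds = ([0.0, Tmax + 1e-6], [np.inf, np.inf])

    popt, pcov = curve_fit(model, T, diff, p0=p0, sigma=sigma,
                           absolute_sigma=sigma is not None, bounds=bounds,
                           maxfev=20000)
    if not np.all(np.isfinite(pcov)):
        raise RuntimeError("ill-conditioned critical-temperature fit")
    return CoexistenceFit(points=pts, beta=(popt[2] if fit_beta else beta),
                          A=float(popt[0]), Tc=float(popt[1]),
                          covariance=np.asarray(pcov)[:2, :2])


# ---------------------------------------------------------------------------
# contacts
# ---------------------------------------------------------------------------

def _frame_contacts(xyz, box, idx_a, idx_b, cutoff):
    """Boolean contact matrix between two bead index sets (periodic)."""
    d2 = np.zeros((len(idx_a), len(idx_b)))
    for ax in range(3):
        L = box[ax] if box is not None else None
        diff = xyz[idx_a, ax][:, None] - xyz[idx_b, ax][None, :]
        d2 += _mi_delta(diff, L) ** 2
    return d2 < cutoff * cutoff


def contact_map(traj, idx_a, idx_b, config: AnalysisConfig | None = None) -> ContactMap:
    """Contact frequencies (fraction of analyzed frames within 1.2 nm) between
    two bead index sets."""
    config = config or AnalysisConfig()
    idx_a = np.asarray(idx_a, dtype=np.int64)
    idx_b = np.asarray(idx_b, dtype=np.int64)
    if idx_a.size == 0 or idx_b.size == 0:
        raise ValueError("empty contact group")
    frames = list(_analysis_frames(traj.n_frames, config))
    acc = np.zeros((len(idx_a), len(idx_b)))
    for f in frames:
        acc += _frame_contacts(traj.xyz[f], traj.box, idx_a, idx_b,
                               config.contact_cutoff)
    return ContactMap(acc / len(frames), idx_a, idx_b, len(frames))


def residue_contact_map(traj, chains_a, chains_b, config: AnalysisConfig | None = None):
    """Residue-resolved map averaged over molecule pairs of two chain sets
    (e.g. all FUS-FUS pairs): entry (p, q) is the frequency with which residue
    p of one molecule contacts residue q of another."""
    config = config or AnalysisConfig()
    frames = list(_analysis_frames(traj.n_frames, config))
    idx_by_chain = {c: np.where(traj.chain_id == c)[0] for c in
                    np.concatenate([chains_a, chains_b])}
    n_a = len(idx_by_chain[chains_a[0]])
    n_b = len(idx_by_chain[chains_b[0]])
    acc = np.zeros((n_a, n_b))
    count = 0
    for f in frames:
        for ca in chains_a:
            for cb in chains_b:
                if ca == cb:
                    continue
                acc += _frame_contacts(traj.xyz[f], traj.box, idx_by_chain[ca],
                                       idx_by_chain[cb], config.contact_cutoff)
                count += 1
    if count == 0:
        raise ValueError("no molecule pairs")
    return acc / count


class NoParContactError(RuntimeError):
    """Raised when no molecule ever contacts PAR (empty-result signal)."""


def par_contact_profile(traj, fus_chains, par_beads,
                        config: AnalysisConfig | None = None,
                        return_filtered_maps: bool = False):
    """Per-residue relative contact frequency of FUS with PAR.

    For each FUS molecule, frames where the molecule makes no PAR contact are
    excluded; per-residue frequencies are computed over the retained frames
    only, then averaged across molecules. A residue contacts PAR if it is
    within the cutoff of any PAR bead.
    """
    config = config or AnalysisConfig()
    par_beads = np.asarray(par_beads, dtype=np.int64)
    if par_beads.size == 0:
        raise NoParContactError("trajectory contains no PAR beads")
    frames = list(_analysis_frames(traj.n_frames, config))
    per_mol = []
    for c in fus_chains:
        idx = np.where(traj.chain_id == c)[0]
        acc = np.zeros(len(idx))
        retained = 0
        for f in frames:
            cm = _frame_contacts(traj.xyz[f], traj.box, idx, par_beads,
                                 config.contact_cutoff)
            res_contact = cm.any(axis=1)
            if res_contact.any():       # molecule contacts PAR this frame
                acc += res_contact
                retained += 1
        if retained:
            per_mol.append(acc / retained)
    if not per_mol:
        raise NoParContactError("no FUS molecule ever contacts PAR")
    return np.mean(per_mol, axis=0)


def contact_ratio_map(map_with: np.ndarray, map_without: np.ndarray,
                      pseudo: float | None = None, n_frames: int | None = None):
    """Elementwise (f_with + pseudo) / (f_without + pseudo). Ratios above 1
    mark contacts enhanced in the presence of PAR. The default pseudo-count is
    1/n_frames (a one-observation floor)."""
    a = np.asarray(map_with, dtype=float)
    b = np.asarray(map_without, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"axis mismatch: {a.shape} vs {b.shape}")
    if pseudo is None:
        if n_frames is None:
            raise ValueError("give pseudo or n_frames")
        pseudo = 1.0 / n_frames
    return (a + pseudo) / (b + pseudo)


def domain_distance_series(traj, idx_a, idx_b):
    """Periodic-aware COM distance between two bead groups per frame (nm);
    works for intra- and inter-molecule domain pairs."""
    idx_a = np.asarray(idx_a, dtype=np.int64)
    idx_b = np.asarray(idx_b, dtype=np.int64)
    out = np.zeros(traj.n_frames)
    for f in range(traj.n_frames):
        d2 = 0.0
        for ax in range(3):
            L = traj.box[ax] if traj.box is not None else None
            ca = periodic_com(traj.xyz[f][idx_a, ax], L, weights=traj.mass[idx_a])
            cb = periodic_com(traj.xyz[f][idx_b, ax], L, weights=traj.mass[idx_b])
            d2 += _mi_delta(ca - cb, L) ** 2
        out[f] = math.sqrt(d2)
    return out
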