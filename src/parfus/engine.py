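"""Reference simulation engine: Langevin dynamics, z-only Monte Carlo
barostat, the three-stage slab protocol, and umbrella-restrained runs.

The integrator is BAOAB Langevin (velocity Verlet when friction is zero),
with compiled kernels from :mod:`parfus._kernels`. Analyses depend only on
the :class:`Trajectory` schema, so a high-performance MD backend can
substitute this engine.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .constants import KB, COULOMB_KJ_NM, ATM_IN_KJ_PER_MOL_NM3
from .params import ParParams
from .topology import CGSystem, build_par_topology, combine_systems


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class Trajectory:
    """Frames of a run: coordinates (n_frames, n_beads, 3) nm, box (3,) nm
    (entries <= 0 mean non-periodic), times ps, and per-frame energy records."""

    xyz: np.ndarray
    box: np.ndarray
    time: np.ndarray
    chain_id: np.ndarray
    domain_label: list
    mass: np.ndarray
    potential: np.ndarray | None = None   # (n_frames, 8) term breakdown
    kinetic: np.ndarray | None = None

    @property
    def n_frames(self) -> int:
        return len(self.xyz)

    def __post_init__(self):
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("frame times must be strictly increasing")

    def save(self, path):
        """Write frames as compressed npz plus a JSON sidecar with the chain
        and domain index tables (``<path>.json``)."""
        np.savez_compressed(path, xyz=self.xyz, box=self.box, time=self.time,
                            potential=self.potential if self.potential is not None else np.zeros(0),
                            kinetic=self.kinetic if self.kinetic is not None else np.zeros(0))
        sidecar = {"chain_id": self.chain_id.tolist(),
                   "domain_label": list(self.domain_label),
                   "mass": self.mass.tolist()}
        with open(str(path) + ".json", "w") as f:
            json.dump(sidecar, f)

    def save_dcd(self, path):
        """Write frames as a DCD trajectory (one pseudo-atom per bead) plus
        the JSON sidecar with chain/domain index tables (``<path>.json``)."""
        import mdtraj as md
        top = md.Topology()
        chain_handles = {}
        carbon = md.element.carbon
        for i in range(self.xyz.shape[1]):
            c = int(self.chain_id[i])
            if c not in chain_handles:
                chain_handles[c] = top.add_chain()
            res = top.add_residue(str(self.domain_label[i])[:4], chain_handles[c])
            top.add_atom("CA", carbon, res)
        box = np.where(self.box > 0, self.box, 1000.0)
        traj = md.Trajectory(self.xyz, top, time=self.time,
                             unitcell_lengths=np.tile(box, (len(self.xyz), 1)),
                             unitcell_angles=np.full((len(self.xyz), 3), 90.0))
        traj.save_dcd(str(path))
        with open(str(path) + ".json", "w") as f:
            json.dump({"chain_id": self.chain_id.tolist(),
                       "domain_label": list(self.domain_label),
                       "mass": self.mass.tolist(),
                       "box": self.box.tolist()}, f)

    @classmethod
    def load(cls, path):
        d = np.load(str(path) if str(path).endswith(".npz") else str(path) + ".npz")
        with open(str(path).removesuffix(".npz") + ".json") as f:
            sc = json.load(f)
        return cls(xyz=d["xyz"], box=d["box"], time=d["time"],
                   chain_id=np.asarray(sc["chain_id"]), domain_label=sc["domain_label"],
                   mass=np.asarray(sc["mass"]),
                   potential=d["potential"] if d["potential"].size else None,
                   kinetic=d["kinetic"] if d["kinetic"].size else None)


@dataclass
class SlabProtocolConfig:
    """Parameters of the slab condensation recipe.

    Defaults are the full production protocol (25 x 25 x 3500 nm setup box,
    100 ns NVT equilibration and 300 ns z-compression at 250 K, 5 us
    production in a 25 x 25 x 200 nm box). Desk-scale runs pass reduced
    durations/compositions through the same code path.
    """

    setup_box: tuple = (25.0, 25.0, 3500.0)
    production_box: tuple = (25.0, 25.0, 200.0)
    equil_ns: float = 100.0
    compress_ns: float = 300.0
    production_ns: float = 5000.0
    equil_temperature: float = 250.0
    pressure_atm: float = 1.0
    temperatures: tuple = tuple(range(330, 430, 10))
    n_fus: int = 100
    n_par: int = 10
    dt: float = 0.01          # ps (10 fs)
    save_interval_ps: float = 100.0
    friction: float = 0.01    # ps^-1
    seed: int = 0

    def __post_init__(self):
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.production_box[:2] != self.setup_box[:2]:
            raise ValueError("production box x,y must equal setup box x,y")


@dataclass
class UmbrellaConfig:
    """Umbrella-sampling protocol: harmonic COM-distance restraints."""

    k: float = 50.0            # kJ/(mol nm^2)
    n_windows: int = 61
    r_min: float = 0.0
    r_max: float = 20.0
    temperature: float = 293.15
    equil_ns: float = 100.0
    production_ns: float = 30000.0
    dt: float = 0.01
    sample_interval_ps: float = 10.0
    friction: float = 0.01
    seed: int = 0

    def __post_init__(self):
        if self.n_windows < 2:
            raise ValueError("need at least 2 windows")
        if not self.r_max > self.r_min:
            raise ValueError("r_max must exceed r_min")


def window_centers(config: UmbrellaConfig) -> np.ndarray:
    """Restraint centers: arithmetic sequence from r_min to r_max inclusive."""
    return np.linspace(config.r_min, config.r_max, config.n_windows)


# ---------------------------------------------------------------------------
# packing
# ---------------------------------------------------------------------------

_EMPTY_I = np.zeros(0, dtype=np.int64)


def _pack(system: CGSystem, box=None):
    b = system.box if box is None else np.asarray(box, dtype=float)
    if b is None:
        b = np.array([-1.0, -1.0, -1.0])
    return dict(
        box=np.asarray(b, dtype=float),
        sdid=system.struct_domain_id.astype(np.int64),
        sigma=system.sigma, lam=system.lam, charge=system.charge,
        rep_radius=system.rep_radius, eps_res=system.eps_res,
        excl_keys=system._excluded_keys, nat_keys=system._native_keys,
        nat_pairs=np.ascontiguousarray(system.native_pairs.astype(np.int64).reshape(-1, 2)),
        nat_sigma=system.native_sigma, nat_eps=system.native_eps,
        bonds=np.ascontiguousarray(system.bonds.astype(np.int64).reshape(-1, 2)),
        bond_r0=system.bond_r0, bond_k=system.bond_k,
        angles=np.ascontiguousarray(system.angles.astype(np.int64).reshape(-1, 3)),
        angle_theta0=system.angle_theta0, angle_k=system.angle_k,
        dihedrals=np.ascontiguousarray(system.dihedrals.astype(np.int64).reshape(-1, 4)),
        dih_k=np.ascontiguousarray(system.dihedral_k.reshape(-1, 4)),
        dih_delta=np.ascontiguousarray(system.dihedral_delta.reshape(-1, 4)),
        dih_n=np.ascontiguousarray(system.dihedral_n.astype(np.int64).reshape(-1, 4)),
        eps_lj=system.hps.eps_lj,
        coul_pref=COULOMB_KJ_NM / system.hps.eps_r,
        kappa=system.hps.kappa,
        cut_vdw=system.hps.cutoff_vdw, cut_elec=system.hps.cutoff_elec,
        rep_eps_factor=(system.go.repulsive_eps_factor if system.go is not None else 1.5e-3),
        mass=system.mass,
    )


ENERGY_TERMS = ("bond", "angle", "dihedral", "hps_vdw", "electrostatic",
                "go_native", "go_repulsive", "restraint")


def total_energy(system: CGSystem, positions: np.ndarray, box=None) -> dict:
    """Per-term potential energy (kJ/mol) of one configuration, with
    minimum-image convention when the system is periodic."""
    positions = np.ascontiguousarray(positions, dtype=float)
    if positions.shape != (system.n_beads, 3):
        raise ValueError(f"positions shape {positions.shape} does not match "
                         f"system with {system.n_beads} beads")
    p = _pack(system, box=box)
    _, energies, _ = _kernels.compute_forces(
        positions, p["box"], p["sdid"], p["sigma"], p["lam"], p["charge"],
        p["rep_radius"], p["eps_res"], p["excl_keys"], p["nat_keys"],
        p["nat_pairs"], p["nat_sigma"], p["nat_eps"],
        p["bonds"], p["bond_r0"], p["bond_k"],
        p["angles"], p["angle_theta0"], p["angle_k"],
        p["dihedrals"], p["dih_k"], p["dih_delta"], p["dih_n"],
        p["eps_lj"], p["coul_pref"], p["kappa"], p["cut_vdw"], p["cut_elec"],
        p["rep_eps_factor"], _EMPTY_I, _EMPTY_I, p["mass"], -1.0, 0.0)
    out = {name: float(e) for name, e in zip(ENERGY_TERMS, energies)}
    out["total"] = float(np.sum(energies))
    return out


def compute_forces_energy(system: CGSystem, positions: np.ndarray, box=None):
    """Forces (kJ/mol/nm) and per-term energies for one configuration."""
    p = _pack(system, box=box)
    positions = np.ascontiguousarray(positions, dtype=float)
    f, e, _ = _kernels.compute_forces(
        positions, p["box"], p["sdid"], p["sigma"], p["lam"], p["charge"],
        p["rep_radius"], p["eps_res"], p["excl_keys"], p["nat_keys"],
        p["nat_pairs"], p["nat_sigma"], p["nat_eps"],
        p["bonds"], p["bond_r0"], p["bond_k"],
        p["angles"], p["angle_theta0"], p["angle_k"],
        p["dihedrals"], p["dih_k"], p["dih_delta"], p["dih_n"],
        p["eps_lj"], p["coul_pref"], p["kappa"], p["cut_vdw"], p["cut_elec"],
        p["rep_eps_factor"], _EMPTY_I, _EMPTY_I, p["mass"], -1.0, 0.0)
    return f, e


# ---------------------------------------------------------------------------
# dynamics
# ---------------------------------------------------------------------------

def _run(system, positions, velocities, temperature, dt, n_steps, seed,
         save_every, friction, box, restraint=None, sample_every=0):
    p = _pack(system, box=box)
    if restraint is None:
        grp_a, grp_b, rk, req = _EMPTY_I, _EMPTY_I, -1.0, 0.0
    else:
        grp_a, grp_b, rk, req = restraint
        grp_a = np.asarray(grp_a, dtype=np.int64)
        grp_b = np.asarray(grp_b, dtype=np.int64)
    traj, epot, ekin, rsamp = _kernels.run_md(
        positions, velocities, p["box"], p["sdid"], p["sigma"], p["lam"],
        p["charge"], p["rep_radius"], p["eps_res"], p["excl_keys"], p["nat_keys"],
        p["nat_pairs"], p["nat_sigma"], p["nat_eps"],
        p["bonds"], p["bond_r0"], p["bond_k"],
        p["angles"], p["angle_theta0"], p["angle_k"],
        p["dihedrals"], p["dih_k"], p["dih_delta"], p["dih_n"],
        p["eps_lj"], p["coul_pref"], p["kappa"], p["cut_vdw"], p["cut_elec"],
        p["rep_eps_factor"], grp_a, grp_b, p["mass"], rk, req,
        dt, n_steps, friction, KB * temperature, save_every, sample_every,
        seed % (2 ** 31))
    if not np.isfinite(traj).all():
        bad = np.argwhere(~np.isfinite(traj))
        raise FloatingPointError(
            f"force overflow / non-finite coordinates (first bad bead index "
            f"{int(bad[0][1])}); reduce dt or fix overlapping beads")
    return traj, epot, ekin, rsamp


def maxwell_velocities(system: CGSystem, temperature: float, rng) -> np.ndarray:
    """Maxwell–Boltzmann velocities (nm/ps) at the given temperature."""
    sd = np.sqrt(KB * temperature / system.mass)[:, None]
    return rng.standard_normal((system.n_beads, 3)) * sd


def run_langevin(system: CGSystem, positions: np.ndarray, temperature: float,
                 dt: float = 0.01, n_steps: int = 10000, seed: int = 0,
                 save_every: int = 100, friction: float = 0.01,
                 velocities: np.ndarray | None = None, box=None) -> Trajectory:
    """NVT Langevin run (BAOAB). Identical seeds give identical trajectories.

    ``friction`` is the Langevin collision rate in ps^-1; ``dt`` in ps.
    Pass ``friction=0`` for a deterministic constant-energy (NVE) run.
    """
    rng = np.random.default_rng(seed)
    pos = np.array(positions, dtype=float, copy=True)
    vel = (maxwell_velocities(system, temperature, rng) if velocities is None
           else np.array(velocities, dtype=float, copy=True))
    if temperature == 0:
        vel[:] = 0.0
    traj, epot, ekin, _ = _run(system, pos, vel, temperature, dt, n_steps,
                               seed, save_every, friction, box)
    b = system.box if box is None else np.asarray(box, dtype=float)
    return Trajectory(
        xyz=traj, box=(np.array([-1.0, -1.0, -1.0]) if b is None else b),
        time=dt * save_every * np.arange(1, len(traj) + 1),
        chain_id=system.chain_id, domain_label=system.domain_label,
        mass=system.mass, potential=epot, kinetic=ekin)


def minimize_energy(system: CGSystem, positions: np.ndarray, n_steps: int = 200,
                    max_disp: float = 0.02, box=None) -> np.ndarray:
    """Crude steepest-descent minimization with a per-step displacement cap."""
    pos = np.array(positions, dtype=float, copy=True)
    for _ in range(n_steps):
        f, e = compute_forces_energy(system, pos, box=box)
        fmax = np.abs(f).max()
        if fmax < 1.0:
            break
        step = min(max_disp / fmax, 1e-4)
        pos += step * f
    return pos


# ---------------------------------------------------------------------------
# z-only Monte Carlo barostat
# ---------------------------------------------------------------------------

def run_npt_z(system: CGSystem, positions: np.ndarray, temperature: float,
              pressure_atm: float = 1.0, n_steps: int = 100000, seed: int = 0,
              dt: float = 0.01, friction: float = 0.01, mc_every: int = 25,
              move_amplitude: float = 0.02, target_acceptance: float = 0.4,
              min_z: float | None = None, box=None):
    """NPT run with an anisotropic MC barostat acting on the z axis only.

    Volume moves are log-z proposals; chains are rescaled by their centers of
    mass so intramolecular geometry is untouched. The acceptance rule uses
    exp(-beta (dU + P dV - N kT ln(Vnew/Vold))) with N the number of chains.
    Move amplitude is auto-tuned toward ``target_acceptance``.

    Returns (positions, box, diagnostics dict).
    """
    rng = np.random.default_rng(seed)
    b = np.array(system.box if box is None else box, dtype=float)
    pos = np.array(positions, dtype=float, copy=True)
    vel = maxwell_velocities(system, temperature, rng)
    kT = KB * temperature
    P = pressure_atm * ATM_IN_KJ_PER_MOL_NM3
    n_chains = system.n_chains
    chains = [np.where(system.chain_id == c)[0] for c in np.unique(system.chain_id)]
    masses = system.mass
    if min_z is None:
        min_z = 2.0 * float(system.sigma.max())

    n_cycles = n_steps // mc_every
    accepted = attempted = 0
    z_history = np.zeros(n_cycles)
    e_old = total_energy(system, pos, box=b)["total"]
    for cyc in range(n_cycles):
        traj, epot, ekin, _ = _run(system, pos, vel, temperature, dt, mc_every,
                                   int(rng.integers(2 ** 31)), mc_every,
                                   friction, b)
        pos = traj[-1]
        e_old = float(epot[-1, :7].sum())
        # MC z-volume move
        lnz_new = math.log(b[2]) + rng.uniform(-move_amplitude, move_amplitude)
        z_new = math.exp(lnz_new)
        if move_amplitude > 0.0 and z_new > min_z:
            scale = z_new / b[2]
            pos_new = pos.copy()
            for idx in chains:
                mz = np.average(pos[idx, 2], weights=masses[idx])
                pos_new[idx, 2] = pos[idx, 2] + (scale - 1.0) * mz
            b_new = b.copy(); b_new[2] = z_new
            e_new = total_energy(system, pos_new, box=b_new)["total"]
            dV = b[0] * b[1] * (z_new - b[2])
            arg = -(e_new - e_old + P * dV - n_chains * kT * math.log(z_new / b[2])) / kT
            attempted += 1
            if math.log(rng.uniform()) < min(arg, 0.0):
                pos, b, e_old = pos_new, b_new, e_new
                accepted += 1
        # amplitude auto-tune every 50 attempts
        if attempted and attempted % 50 == 0 and move_amplitude > 0.0:
            rate = accepted / attempted
            move_amplitude *= 1.1 if rate > target_acceptance else 0.9
            move_amplitude = min(max(move_amplitude, 1e-4), 0.5)
        z_history[cyc] = b[2]
        if b[2] < min_z:
            raise RuntimeError(f"box collapsed below {min_z} nm")
    diag = {"acceptance": accepted / max(attempted, 1), "z_history": z_history,
            "move_amplitude": move_amplitude}
    return pos, b, diag


# ---------------------------------------------------------------------------
# slab protocol
# ---------------------------------------------------------------------------

def _chain_systems_for_composition(composition):
    """composition: list of (CGSystem, count)."""
    return combine_systems([s for s, _ in composition], [c for _, c in composition])


def serpentine_conformation(n: int, bond_length: float, sigma_max: float = 0.0,
                            per_row: int | None = None) -> np.ndarray:
    """Compact clash-free cubic-lattice serpentine used as the default chain
    conformation for slab setups: consecutive beads sit one lattice spacing
    apart, the walk folds back on itself so the chain occupies ~n^(1/3)
    spacings per side. The spacing is the bond length, widened if needed so
    non-bonded lattice neighbours do not overlap badly."""
    spacing = max(bond_length, 0.9 * sigma_max)
    m = per_row or max(int(round(n ** (1.0 / 3.0))), 1)
    pts = np.zeros((n, 3))
    for i in range(n):
        layer, rem = divmod(i, m * m)
        row, col = divmod(rem, m)
        if layer % 2:
            row, col = m - 1 - row, col
        if row % 2:
            col = m - 1 - col
        pts[i] = [col, row, layer]
    return pts * spacing


def helix_conformation(bond_lengths) -> np.ndarray:
    """Compact clash-free helix whose consecutive-bead distances equal the
    mean bond length (default initial conformation of a chain)."""
    b = float(np.mean(bond_lengths)) if len(bond_lengths) else 0.38
    n = len(bond_lengths) + 1
    dtheta = 1.0
    chord_frac = 0.7
    R = chord_frac * b / (2.0 * math.sin(dtheta / 2.0))
    rise = b * math.sqrt(1.0 - chord_frac ** 2)
    k = np.arange(n)
    return np.column_stack([R * np.cos(k * dtheta), R * np.sin(k * dtheta),
                            k * rise])


def prepare_slab(composition, box, spacing_margin: float = 2.0, seed: int = 0):
    """Place chains on a z-stacked lattice in an elongated box with adequate
    spacing (no inter-bead distance below half the smallest bead size).

    ``composition``: list of (single-chain CGSystem, count, conformation) where
    conformation is an (n,3) template for one chain (e.g. an extended or
    pre-relaxed coil), or None for a default extended conformation.

    Returns (combined CGSystem with the box set, initial positions).
    """
    box = np.asarray(box, dtype=float)
    systems, counts, confs = [], [], []
    for item in composition:
        s, c = item[0], item[1]
        conf = item[2] if len(item) > 2 else None
        if conf is None:
            b = float(np.mean(s.bond_r0)) if len(s.bond_r0) else 0.38
            conf = serpentine_conformation(s.n_beads, b, float(s.sigma.max()))
        conf = np.asarray(conf, dtype=float)
        conf = conf - conf.mean(axis=0)
        systems.append(s); counts.append(c); confs.append(conf)

    combined = combine_systems(systems, counts, box=box)
    all_confs = []
    for s, c, conf in zip(systems, counts, confs):
        all_confs.extend([conf] * c)

    n_chains = len(all_confs)
    extents = [conf[:, 2].ptp() if hasattr(conf[:, 2], "ptp") else np.ptp(conf[:, 2])
               for conf in all_confs]
    sizes = [max(np.ptp(conf, axis=0).max(), 1.0) for conf in all_confs]
    slot = max(sizes) + spacing_margin
    if n_chains * slot > box[2]:
        raise ValueError(f"box too small: need {n_chains * slot:.0f} nm in z, "
                         f"box has {box[2]:.0f} nm")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n_chains)
    positions = np.zeros((combined.n_beads, 3))
    offsets = np.split(np.arange(combined.n_beads),
                       np.cumsum([len(c) for c in all_confs])[:-1])
    z0 = -0.5 * n_chains * slot + 0.5 * slot
    if n_chains == 1:
        centers_z = [0.0]
    else:
        centers_z = [z0 + k * slot for k in range(n_chains)]
    for rank, ci in enumerate(order):
        idx = offsets[ci]
        conf = all_confs[ci]
        center = np.array([box[0] / 2.0 + rng.uniform(-0.1, 0.1) * box[0],
                           box[1] / 2.0 + rng.uniform(-0.1, 0.1) * box[1],
                           centers_z[rank]])
        # random in-plane jitter and z-rotation keep chains from stacking exactly
        theta = rng.uniform(0, 2 * np.pi)
        rot = np.array([[np.cos(theta), -np.sin(theta), 0.0],
                        [np.sin(theta), np.cos(theta), 0.0],
                        [0.0, 0.0, 1.0]])
        positions[idx] = conf @ rot.T + center
    _check_overlaps(combined, positions)
    return combined, positions


def _check_overlaps(system, positions, factor: float = 0.5):
    from scipy.spatial import cKDTree
    tree = cKDTree(positions)
    min_allowed = factor * float(system.sigma.min())
    pairs = tree.query_pairs(min_allowed)
    pairs = {(i, j) for i, j in pairs
             if abs(i - j) > 1 or system.chain_id[i] != system.chain_id[j]}
    if pairs:
        raise ValueError(f"{len(pairs)} bead pairs closer than {min_allowed:.2f} nm")


def run_slab_protocol(composition, config: SlabProtocolConfig,
                      checkpoint_dir=None, log=None):
    """Three-stage slab recipe: NVT equilibration in the elongated setup box,
    z-only NPT compression, then NVT production in the slab box at each ladder
    temperature. Returns {temperature: Trajectory}.
    """
    import time as _time

    def _log(msg):
        if log is not None:
            log(msg)

    rng = np.random.default_rng(config.seed)
    system, pos = composition if isinstance(composition, tuple) else (None, None)
    if system is None:
        raise ValueError("composition must be (CGSystem, positions) from prepare_slab")
    box = np.asarray(config.setup_box, dtype=float)

    t0 = _time.time()
    n_equil = int(round(config.equil_ns * 1000.0 / config.dt))
    traj = run_langevin(system, pos, config.equil_temperature, dt=config.dt,
                        n_steps=n_equil, seed=int(rng.integers(2 ** 31)),
                        save_every=max(n_equil, 1), friction=config.friction, box=box)
    pos = traj.xyz[-1]
    _log(f"equilibration done in {_time.time() - t0:.1f} s")

    t0 = _time.time()
    n_comp = int(round(config.compress_ns * 1000.0 / config.dt))
    pos, box, diag = run_npt_z(system, pos, config.equil_temperature,
                               pressure_atm=config.pressure_atm, n_steps=n_comp,
                               seed=int(rng.integers(2 ** 31)), dt=config.dt,
                               friction=config.friction, box=box)
    _log(f"compression done in {_time.time() - t0:.1f} s "
         f"(z: {config.setup_box[2]:.0f} -> {box[2]:.1f} nm, "
         f"acceptance {diag['acceptance']:.2f})")

    # map compressed configuration into the production box (wrap z)
    prod_box = np.asarray(config.production_box, dtype=float)
    pos_prod = pos.copy()
    # center the dense phase at z = 0 then wrap
    pos_prod[:, 2] -= np.average(pos_prod[:, 2], weights=system.mass)
    out = {}
    n_prod = int(round(config.production_ns * 1000.0 / config.dt))
    save_every = max(int(round(config.save_interval_ps / config.dt)), 1)
    if checkpoint_dir is not None:
        import os
        os.makedirs(checkpoint_dir, exist_ok=True)
    for T in config.temperatures:
        t0 = _time.time()
        traj = run_langevin(system, pos_prod, float(T), dt=config.dt,
                            n_steps=n_prod, seed=int(rng.integers(2 ** 31)),
                            save_every=save_every, friction=config.friction,
                            box=prod_box)
        out[float(T)] = traj
        if checkpoint_dir is not None:
            traj.save(f"{checkpoint_dir}/slab_T{T:.0f}.npz")
        _log(f"production at {T} K done in {_time.time() - t0:.1f} s")
    return out


# ---------------------------------------------------------------------------
# umbrella sampling
# ---------------------------------------------------------------------------

def run_umbrella(system: CGSystem, group_a, group_b, config: UmbrellaConfig,
                 positions: np.ndarray | None = None, minimize: bool = True):
    """Umbrella-restrained runs over all windows.

    Each window is energy-minimized, equilibrated, then sampled; the restraint
    is harmonic in the COM distance of the two (disjoint) bead groups. Returns
    an :class:`parfus.free_energy.UmbrellaDataset`.
    """
    from .free_energy import UmbrellaDataset, UmbrellaWindow

    group_a = np.asarray(group_a, dtype=np.int64)
    group_b = np.asarray(group_b, dtype=np.int64)
    if np.intersect1d(group_a, group_b).size:
        raise ValueError("restraint groups must be disjoint")
    rng = np.random.default_rng(config.seed)
    centers = window_centers(config)
    n_equil = int(round(config.equil_ns * 1000.0 / config.dt))
    n_prod = int(round(config.production_ns * 1000.0 / config.dt))
    sample_every = max(int(round(config.sample_interval_ps / config.dt)), 1)

    windows = []
    for req in centers:
        if positions is None:
            pos = _default_two_group_start(system, group_a, group_b, req)
        else:
            pos = np.array(positions, dtype=float, copy=True)
            pos = _shift_to_distance(system, pos, group_a, group_b, req)
        restraint = (group_a, group_b, config.k, float(req))
        if minimize:
            pos = minimize_energy(system, pos, n_steps=100)
            pos = _shift_to_distance(system, pos, group_a, group_b, req)
        vel = maxwell_velocities(system, config.temperature, rng)
        seed_w = int(rng.integers(2 ** 31))
        traj, _, _, _ = _run(system, pos, vel, config.temperature, config.dt,
                             n_equil, seed_w, max(n_equil, 1), config.friction,
                             None, restraint=restraint)
        pos = traj[-1] if len(traj) else pos
        traj, _, _, rsamp = _run(system, pos, vel, config.temperature, config.dt,
                                 n_prod, seed_w + 1, max(n_prod, 1),
                                 config.friction, None, restraint=restraint,
                                 sample_every=sample_every)
        windows.append(UmbrellaWindow(req=float(req), k=config.k,
                                      samples=rsamp,
                                      temperature=config.temperature))
    return UmbrellaDataset(windows=windows,
                           metadata={"k": config.k, "seed": config.seed,
                                     "groups": [group_a.tolist(), group_b.tolist()],
                                     "production_ns": config.production_ns})


def _group_com(system, pos, idx):
    return np.average(pos[idx], axis=0, weights=system.mass[idx])


def _shift_to_distance(system, pos, group_a, group_b, req):
    """Translate group_b rigidly so the COM distance equals req."""
    ca = _group_com(system, pos, group_a)
    cb = _group_com(system, pos, group_b)
    d = cb - ca
    r = np.linalg.norm(d)
    unit = d / r if r > 1e-9 else np.array([0.0, 0.0, 1.0])
    target = ca + unit * req
    out = pos.copy()
    out[group_b] += target - cb
    return out


def _default_two_group_start(system, group_a, group_b, req):
    """Starting coordinates: each chain a compact serpentine, chains strung
    along z, then group_b translated so the COM distance equals req."""
    pos = np.zeros((system.n_beads, 3))
    z_off = 0.0
    for c in np.unique(system.chain_id):
        idx = np.where(system.chain_id == c)[0]
        in_chain = np.isin(system.bonds[:, 0], idx)
        b = float(system.bond_r0[in_chain].mean()) if in_chain.any() else 1.0
        conf = serpentine_conformation(len(idx), b, float(system.sigma[idx].max()))
        conf[:, 2] += z_off
        pos[idx] = conf
        z_off = pos[idx, 2].max() + 2.0
    return _shift_to_distance(system, pos, group_a, group_b, req)
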