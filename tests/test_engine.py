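"""Integrator, thermostat, barostat, slab-preparation and umbrella tests."""

import numpy as np
import pytest
from scipy import integrate

from parfus.constants import ATM_IN_KJ_PER_MOL_NM3, KB
from parfus.engine import (SlabProtocolConfig, UmbrellaConfig, Trajectory,
                           helix_conformation, maxwell_velocities,
                           prepare_slab, run_langevin, run_npt_z, run_umbrella,
                           total_energy, window_centers)
from parfus.params import ParParams
from parfus.topology import build_idr_topology, build_par_topology


def _free_beads(n, sigma=0.05):
    """n non-interacting single-bead chains (ideal-gas stand-in)."""
    from parfus.topology import CGSystem
    return CGSystem(
        chain_id=np.arange(n), domain_label=["X"] * n,
        struct_domain_id=np.full(n, -1, dtype=np.int64), residue=["G"] * n,
        sigma=np.full(n, sigma), lam=np.zeros(n), charge=np.zeros(n),
        mass=np.full(n, 100.0), rep_radius=np.zeros(n), eps_res=np.zeros(n),
        bonds=np.zeros((0, 2), dtype=np.int64), bond_r0=np.zeros(0),
        bond_k=np.zeros(0))


class TestLangevin:
    def test_bond_length_variance_equipartition(self):
        """Harmonic bond at 300 K: Var(r) = kBT/k within 5%."""
        s = build_idr_topology("GG")
        pos = np.array([[0.0, 0.0, 0.0], [0.0, 0.0, 0.38]])
        traj = run_langevin(s, pos, 300.0, n_steps=400_000, save_every=40,
                            friction=1.0, seed=4)
        r = np.linalg.norm(traj.xyz[:, 1] - traj.xyz[:, 0], axis=1)
        r = r[len(r) // 10:]
        assert r.var() == pytest.approx(KB * 300.0 / 8033.0, rel=0.05)

    def test_zero_temperature_relaxes_to_minimum(self):
        s = build_idr_topology("GG")
        pos = np.array([[0.0, 0.0, 0.0], [0.0, 0.0, 0.55]])
        traj = run_langevin(s, pos, 0.0, n_steps=20000, save_every=20000,
                            friction=5.0, seed=0)
        r = np.linalg.norm(traj.xyz[-1, 1] - traj.xyz[-1, 0])
        assert r == pytest.approx(0.38, abs=1e-3)

    def test_seed_determinism(self, par16):
        z = np.cumsum(np.concatenate([[0.0], np.full(15, 1.16)]))
        pos = np.column_stack([np.zeros_like(z), np.zeros_like(z), z])
        t1 = run_langevin(par16, pos, 293.15, n_steps=2000, save_every=100, seed=9)
        t2 = run_langevin(par16, pos, 293.15, n_steps=2000, save_every=100, seed=9)
        np.testing.assert_array_equal(t1.xyz, t2.xyz)
        t3 = run_langevin(par16, pos, 293.15, n_steps=2000, save_every=100, seed=10)
        assert not np.array_equal(t1.xyz, t3.xyz)

    def test_kinetic_temperature_matches_setpoint(self):
        """NVT kinetic temperature within 2% of the thermostat over 1e5 steps."""
        s = build_idr_topology("GRGDSPYSGMKEQLGRGDSP")
        pos = helix_conformation(s.bond_r0)
        traj = run_langevin(s, pos, 320.0, n_steps=100_000, save_every=50,
                            friction=1.0, seed=2)
        t_kin = 2.0 * traj.kinetic / (3.0 * s.n_beads * KB)
        assert t_kin[len(t_kin) // 10:].mean() == pytest.approx(320.0, rel=0.02)

    def test_nve_energy_conservation(self):
        """Zero-friction integrator: drift < 0.1% of kinetic energy over 1e4
        steps at dt = 10 fs on a 5-bead toy chain."""
        s = build_idr_topology("GRGDS")
        pos = helix_conformation(s.bond_r0)
        rng = np.random.default_rng(8)
        vel = maxwell_velocities(s, 300.0, rng)
        traj = run_langevin(s, pos, 300.0, dt=0.01, n_steps=10_000,
                            save_every=10, friction=0.0, velocities=vel, seed=0)
        etot = traj.kinetic + traj.potential[:, :7].sum(axis=1)
        drift = abs(etot[-1] - etot[0])
        assert drift < 1e-3 * traj.kinetic.mean()

    def test_monotone_time_stamps(self, par16):
        z = np.cumsum(np.concatenate([[0.0], np.full(15, 1.16)]))
        pos = np.column_stack([np.zeros_like(z), np.zeros_like(z), z])
        traj = run_langevin(par16, pos, 293.15, n_steps=1000, save_every=100, seed=0)
        assert np.all(np.diff(traj.time) > 0)
        with pytest.raises(ValueError):
            Trajectory(xyz=traj.xyz, box=traj.box, time=traj.time[::-1],
                       chain_id=traj.chain_id, domain_label=traj.domain_label,
                       mass=traj.mass)


class TestNptZ:
    def test_ideal_gas_density(self):
        """Non-interacting beads: mean density converges to P/(kBT) within 5%."""
        n = 64
        s = _free_beads(n)
        T, P = 250.0, 1.0
        rho_target = P * ATM_IN_KJ_PER_MOL_NM3 / (KB * T)
        box = np.array([8.0, 8.0, n / (rho_target * 64.0)])  # start at target
        rng = np.random.default_rng(0)
        pos = rng.uniform(0, 1, (n, 3)) * box
        _, b, diag = run_npt_z(s, pos, T, pressure_atm=P, n_steps=120_000,
                               seed=3, box=box, friction=1.0)
        z = diag["z_history"]
        rho = n / (8.0 * 8.0 * z[len(z) // 2:])
        assert rho.mean() == pytest.approx(rho_target, rel=0.05)
        assert 0.2 < diag["acceptance"] < 0.7

    def test_zero_amplitude_leaves_box(self):
        s = _free_beads(10)
        box = np.array([5.0, 5.0, 50.0])
        rng = np.random.default_rng(1)
        pos = rng.uniform(0, 1, (10, 3)) * box
        _, b, _ = run_npt_z(s, pos, 300.0, n_steps=2000, seed=0, box=box,
                            move_amplitude=0.0)
        assert b[2] == pytest.approx(50.0)
        assert b[0] == 5.0 and b[1] == 5.0

    def test_attractive_fluid_compresses(self):
        """Sticky chains below their boiling point: z shrinks from a dilute
        start under 1 atm."""
        ch = build_idr_topology("FLFLFLFL")
        comp, pos = prepare_slab([(ch, 6)], box=(6.0, 6.0, 120.0), seed=0)
        _, b, diag = run_npt_z(comp, pos, 250.0, n_steps=30_000, seed=1,
                               box=np.array([6.0, 6.0, 120.0]))
        assert b[2] < 60.0
        z = diag["z_history"]
        assert z[-len(z) // 4:].mean() < z[: len(z) // 4].mean()


class TestPrepareSlab:
    def test_full_composition_bead_count(self):
        """100 FUS + 10 PAR 16-mers = 52,760 beads (constructibility)."""
        from parfus.topology import build_fus_topology, load_fus_assets
        from test_topology import _toy_domain_coords
        seq, cfg = load_fus_assets()
        natives = {lab: _toy_domain_coords(r["end"] - r["start"] + 1)
                   for lab, r in cfg["domains"].items()
                   if r["kind"] == "structured"}
        fus = build_fus_topology(seq, cfg["domains"], natives)
        par = build_par_topology(16)
        comp, pos = prepare_slab([(fus, 100), (par, 10)],
                                 box=(25.0, 25.0, 3500.0), seed=0)
        assert comp.n_beads == 100 * 526 + 10 * 16 == 52_760
        assert pos.shape == (52_760, 3)

    def test_single_chain_centered(self):
        ch = build_idr_topology("GSGSG")
        comp, pos = prepare_slab([(ch, 1)], box=(10.0, 10.0, 50.0), seed=0)
        assert abs(pos[:, 2].mean()) < 1.0

    def test_overlap_check_passes_and_box_too_small(self):
        ch = build_idr_topology("GSGSGSGSGS")
        prepare_slab([(ch, 5)], box=(8.0, 8.0, 100.0), seed=0)  # no raise
        with pytest.raises(ValueError, match="box too small"):
            prepare_slab([(ch, 50)], box=(8.0, 8.0, 20.0), seed=0)

    def test_production_box_xy_must_match(self):
        with pytest.raises(ValueError):
            SlabProtocolConfig(setup_box=(25, 25, 3500),
                               production_box=(20, 20, 200))


class TestUmbrella:
    def test_window_centers_default_61(self):
        c = window_centers(UmbrellaConfig())
        assert len(c) == 61
        assert c[0] == 0.0 and c[-1] == 20.0
        np.testing.assert_allclose(np.diff(c), 20.0 / 60.0)

    def test_two_windows_are_endpoints(self):
        c = window_centers(UmbrellaConfig(n_windows=2, r_min=1.0, r_max=9.0))
        np.testing.assert_allclose(c, [1.0, 9.0])

    def test_disjoint_groups_required(self, par16):
        with pytest.raises(ValueError, match="disjoint"):
            run_umbrella(par16, [0, 1], [1, 2], UmbrellaConfig())

    def test_free_dumbbell_matches_quadrature(self):
        """Two non-interacting beads under one restraint: mean sampled
        distance equals the r^2-weighted Boltzmann expectation."""
        s = _free_beads(2, sigma=0.01)
        k, req, T = 50.0, 5.0, 293.15
        cfg = UmbrellaConfig(k=k, n_windows=2, r_min=req, r_max=req + 1e-9,
                             temperature=T, equil_ns=0.2, production_ns=4.0,
                             sample_interval_ps=1.0, friction=1.0, seed=5)
        data = run_umbrella(s, [0], [1], cfg, minimize=False)
        samples = data.windows[0].samples
        beta = 1.0 / (KB * T)
        w = lambda r: r ** 2 * np.exp(-beta * 0.5 * k * (r - req) ** 2)
        num, _ = integrate.quad(lambda r: r * w(r), 0, 10)
        den, _ = integrate.quad(w, 0, 10)
        expect = num / den
        assert samples.mean() == pytest.approx(expect, abs=0.04)

    def test_stiff_restraint_pins_distance(self):
        s = _free_beads(2, sigma=0.01)
        cfg = UmbrellaConfig(k=5000.0, n_windows=2, r_min=6.0, r_max=6.0 + 1e-9,
                             equil_ns=0.1, production_ns=1.0,
                             sample_interval_ps=0.5, friction=1.0, seed=6)
        data = run_umbrella(s, [0], [1], cfg, minimize=False)
        samples = data.windows[0].samples
        assert abs(samples.mean() - 6.0) < 0.05
        assert samples.std() < 3 * np.sqrt(KB * 293.15 / 5000.0)


class TestTrajectoryIO:
    def test_dcd_export_round_trip(self, tmp_path, par16):
        """Frames exported to the standard DCD container (plus JSON sidecar)
        read back with matching coordinates."""
        import json
        from mdtraj.formats import DCDTrajectoryFile
        rng = np.random.default_rng(0)
        xyz = rng.uniform(0, 5, (3, 16, 3))
        tr = Trajectory(xyz=xyz, box=np.array([5.0, 5.0, 10.0]),
                        time=np.arange(1, 4.0), chain_id=par16.chain_id,
                        domain_label=par16.domain_label, mass=par16.mass)
        p = tmp_path / "t.dcd"
        tr.save_dcd(p)
        with DCDTrajectoryFile(str(p)) as f:
            x, _, _ = f.read()
        np.testing.assert_allclose(x / 10.0, xyz, atol=1e-5)  # DCD is in A
        sidecar = json.loads((tmp_path / "t.dcd.json").read_text())
        assert sidecar["domain_label"][0] == "PAR"
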