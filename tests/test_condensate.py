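"""Condensate analytics: clustering, centering, densities, Tc fits, contacts."""

import numpy as np
import pytest

from parfus.condensate import (AnalysisConfig, NoParContactError, center_frame,
                               chain_coms, coexistence_densities, contact_map,
                               contact_ratio_map, density_profile,
                               domain_distance_series, fit_critical_temperature,
                               largest_cluster, par_contact_profile,
                               periodic_com, single_linkage_clusters)
from parfus.synth import gen_coexistence_points, gen_two_phase_config

from conftest import make_trajectory, union_find_clusters

BOX = np.array([20.0, 20.0, 100.0])


class TestClustering:
    def test_chaining_joins_three(self):
        coms = np.array([[0, 0, 0], [0, 0, 4], [0, 0, 8.0]])
        labels = single_linkage_clusters(coms, BOX, cutoff=5.0)
        assert len(set(labels)) == 1

    def test_all_far_apart_are_singletons(self):
        coms = np.array([[0, 0, 0], [0, 0, 10], [0, 0, 20.0], [10, 10, 50]])
        labels = single_linkage_clusters(coms, BOX, cutoff=5.0)
        assert len(set(labels)) == 4

    def test_periodic_wraparound_joins(self):
        coms = np.array([[0, 0, 1.0], [0, 0, 99.0]])  # 2 nm apart through z wall
        labels = single_linkage_clusters(coms, BOX, cutoff=5.0)
        assert labels[0] == labels[1]

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_matches_union_find_oracle(self, seed):
        rng = np.random.default_rng(seed)
        coms = rng.uniform(0, 1, (50, 3)) * BOX
        got = single_linkage_clusters(coms, BOX, cutoff=6.0)
        want = union_find_clusters(coms, BOX, cutoff=6.0)
        # same partition up to label names
        for a in range(50):
            for b in range(a + 1, 50):
                assert (got[a] == got[b]) == (want[a] == want[b])

    def test_relabeling_invariance(self):
        rng = np.random.default_rng(7)
        coms = rng.uniform(0, 1, (20, 3)) * BOX
        perm = rng.permutation(20)
        l1 = single_linkage_clusters(coms, BOX, 6.0)
        l2 = single_linkage_clusters(coms[perm], BOX, 6.0)
        for a in range(20):
            for b in range(20):
                assert (l1[perm[a]] == l1[perm[b]]) == (l2[a] == l2[b])


class TestCentering:
    def test_single_chain_to_zero(self):
        xyz = np.array([[1.0, 2.0, 30.0]])
        out = center_frame(xyz, BOX, [0], np.array([0]), np.array([1.0]))
        assert out[0, 2] == pytest.approx(0.0)
        assert out[0, 0] == 1.0 and out[0, 1] == 2.0

    def test_equal_clusters_tie_breaks_to_lowest_chain(self):
        # two 2-chain clusters; tie must pick the one holding chain 0
        labels = np.array([1, 1, 0, 0])
        assert largest_cluster(labels) == 1

    def test_recentered_com_is_zero(self):
        rng = np.random.default_rng(2)
        xyz = rng.uniform(0, 1, (30, 3)) * BOX
        chain_id = np.repeat(np.arange(10), 3)
        mass = rng.uniform(50, 150, 30)
        coms = chain_coms(xyz, chain_id, mass, BOX)
        labels = single_linkage_clusters(coms, BOX, 8.0)
        out = center_frame(xyz, BOX, labels, chain_id, mass)
        lab = largest_cluster(labels)
        members = np.unique(chain_id)[labels == lab]
        sel = np.isin(chain_id, members)
        z = periodic_com(out[sel, 2], BOX[2], weights=mass[sel])
        assert min(abs(z), abs(z - BOX[2])) < 1e-9

    def test_translation_invariance_of_pipeline(self):
        rng = np.random.default_rng(3)
        xyz = rng.uniform(0, 1, (12, 3)) * BOX
        chain_id = np.repeat(np.arange(4), 3)
        mass = np.ones(12)
        coms1 = chain_coms(xyz, chain_id, mass, BOX)
        shift = np.array([3.1, -7.2, 41.0])
        coms2 = chain_coms((xyz + shift) % BOX, chain_id, mass, BOX)
        l1 = single_linkage_clusters(coms1, BOX, 6.0)
        l2 = single_linkage_clusters(coms2, BOX, 6.0)
        np.testing.assert_array_equal(l1, l2)


class TestDensityProfile:
    def _traj_from_frame(self, xyz, mass=None, box=BOX):
        n = len(xyz)
        mass = np.ones(n) if mass is None else mass
        return make_trajectory(xyz[None, :, :], box, np.arange(n), mass)

    def test_uniform_is_flat_within_poisson(self):
        rng = np.random.default_rng(0)
        n = 60_000
        xyz = rng.uniform(0, 1, (n, 3)) * BOX
        traj = make_trajectory(xyz[None], BOX, np.arange(n), np.ones(n))
        cfg = AnalysisConfig(analysis_window=(0.0, 1.0))
        centers, dens = density_profile(traj, cfg, centered_xyz=traj.xyz)
        per_bin = n / cfg.n_bins
        counts = dens * (BOX[0] * BOX[1] * BOX[2] / cfg.n_bins)
        assert np.all(np.abs(counts - per_bin) < 5 * np.sqrt(per_bin))

    def test_point_mass_single_spike(self):
        xyz = np.tile([[10.0, 10.0, 0.0]], (5, 1))
        traj = self._traj_from_frame(xyz, mass=np.full(5, 7.0))
        cfg = AnalysisConfig(analysis_window=(0.0, 1.0))
        centers, dens = density_profile(traj, cfg, centered_xyz=traj.xyz)
        binvol = BOX[0] * BOX[1] * BOX[2] / cfg.n_bins
        assert dens.max() == pytest.approx(35.0 / binvol)
        assert np.count_nonzero(dens) == 1

    def test_mass_conservation_every_frame(self):
        rng = np.random.default_rng(5)
        for f in range(4):
            xyz = rng.uniform(0, 1, (40, 3)) * BOX
            mass = rng.uniform(50, 200, 40)
            traj = self._traj_from_frame(xyz, mass=mass)
            cfg = AnalysisConfig(analysis_window=(0.0, 1.0))
            _, dens = density_profile(traj, cfg, centered_xyz=traj.xyz)
            binvol = BOX.prod() / cfg.n_bins
            assert (dens * binvol).sum() == pytest.approx(mass.sum(), rel=1e-12)


class TestCoexistence:
    CFG = AnalysisConfig(slab_half_width=25.0)

    def test_two_step_profile_exact(self):
        z = np.linspace(-49.5, 49.5, 60)
        dens = np.where(np.abs(z) < 25.0, 8.0, 0.5)
        rl, rh = coexistence_densities(z, dens, self.CFG)
        assert (rl, rh) == (0.5, 8.0)

    def test_flat_profile(self):
        z = np.linspace(-49.5, 49.5, 60)
        rl, rh = coexistence_densities(z, np.full(60, 3.3), self.CFG)
        assert rl == pytest.approx(3.3) and rh == pytest.approx(3.3)

    def test_tanh_interface_matches_quadrature(self):
        z = np.linspace(-49.5, 49.5, 60)
        prof = lambda zz: 0.5 + 3.5 * (1 - np.tanh((np.abs(zz) - 25.0) / 4.0))
        dens = prof(z)
        rl, rh = coexistence_densities(z, dens, self.CFG)
        assert rl == pytest.approx(dens[np.abs(z) > 25].mean())
        assert rh == pytest.approx(dens[np.abs(z) < 25].mean())

    def test_empty_region_rejected(self):
        z = np.linspace(-10, 10, 20)
        with pytest.raises(ValueError):
            coexistence_densities(z, np.ones(20), AnalysisConfig(slab_half_width=50.0))


class TestCriticalTemperature:
    def test_noiseless_recovery_to_four_digits(self):
        pts, _ = gen_coexistence_points(A=2.0, Tc=400.0, noise=0.0, seed=0)
        fit = fit_critical_temperature(pts)
        assert fit.Tc == pytest.approx(400.0, rel=1e-4)
        assert fit.A == pytest.approx(2.0, rel=1e-4)

    def test_noisy_ci_coverage(self):
        """1% multiplicative noise: the 95% CI covers the true Tc in >= 90 of
        100 seeds."""
        cover = 0
        for s in range(100):
            pts, _ = gen_coexistence_points(A=2.0, Tc=400.0, noise=0.01, seed=s)
            sig = 0.01 * np.sqrt(pts[:, 1] ** 2 + pts[:, 2] ** 2)
            fit = fit_critical_temperature(pts, sigma=sig)
            cover += abs(fit.Tc - 400.0) <= 1.96 * fit.tc_stderr
        assert cover >= 90

    def test_free_beta_agrees_on_clean_data(self):
        pts, _ = gen_coexistence_points(A=1.5, Tc=420.0, noise=0.0, seed=1)
        fixed = fit_critical_temperature(pts)
        free = fit_critical_temperature(pts, fit_beta=True)
        assert free.beta == pytest.approx(0.325, abs=1e-3)
        assert free.Tc == pytest.approx(fixed.Tc, rel=1e-3)

    def test_rejects_non_coexisting_points(self):
        with pytest.raises(ValueError, match="rho_H"):
            fit_critical_temperature([(300, 5.0, 4.0), (310, 1, 2), (320, 1, 2)])

    def test_needs_three_temperatures(self):
        with pytest.raises(ValueError):
            fit_critical_temperature([(300, 1, 5), (310, 1, 4)])


class TestContacts:
    def _two_bead_traj(self, d):
        xyz = np.array([[[0, 0, 0], [0, 0, d]]], dtype=float)
        return make_trajectory(xyz, BOX, [0, 1], [1.0, 1.0])

    def test_inside_cutoff(self):
        cm = contact_map(self._two_bead_traj(1.0), [0], [1],
                         AnalysisConfig(analysis_window=(0.0, 1.0)))
        assert cm.freq[0, 0] == 1.0

    def test_outside_cutoff(self):
        cm = contact_map(self._two_bead_traj(1.3), [0], [1],
                         AnalysisConfig(analysis_window=(0.0, 1.0)))
        assert cm.freq[0, 0] == 0.0

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(4)
        xyz = rng.uniform(0, 1, (6, 20, 3)) * np.array([5.0, 5.0, 5.0])
        box = np.array([5.0, 5.0, 5.0])
        traj = make_trajectory(xyz, box, np.arange(20), np.ones(20))
        cfg = AnalysisConfig(analysis_window=(0.0, 1.0))
        cm = contact_map(traj, np.arange(10), np.arange(10, 20), cfg)
        want = np.zeros((10, 10))
        for f in range(6):
            for a in range(10):
                for b in range(10):
                    d2 = 0.0
                    for ax in range(3):
                        dd = xyz[f, a, ax] - xyz[f, 10 + b, ax]
                        dd -= box[ax] * round(dd / box[ax])
                        d2 += dd * dd
                    want[a, b] += d2 < 1.2 ** 2
        np.testing.assert_allclose(cm.freq, want / 6)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            contact_map(self._two_bead_traj(1.0), [], [1])


class TestParContactProfile:
    def _fixture(self):
        """2 FUS chains x 10 residues + 1 PAR bead over 4 frames. Chain 0
        touches PAR through residue 7 in exactly half the frames; chain 1
        never touches."""
        n = 21
        xyz = np.full((4, n, 3), 50.0)
        for f in range(4):
            for c in range(2):
                base = c * 10
                for r in range(10):
                    xyz[f, base + r] = [5.0 + c * 30, 5.0, 2.0 + r * 1.5]
            xyz[f, 20] = [5.0, 5.0, 2.0 + 7 * 1.5 + (0.5 if f < 2 else 10.0)]
        chain_id = np.array([0] * 10 + [1] * 10 + [2])
        box = np.array([100.0, 100.0, 100.0])
        return make_trajectory(xyz, box, chain_id, np.ones(n))

    def test_retained_frame_filtering(self):
        traj = self._fixture()
        cfg = AnalysisConfig(analysis_window=(0.0, 1.0))
        prof = par_contact_profile(traj, fus_chains=[0, 1], par_beads=[20],
                                   config=cfg)
        # chain 0: residue 7 in contact in the 2 retained frames -> 1.0;
        # chain 1 contributes nothing (never in contact)
        assert prof[7] == pytest.approx(1.0)
        assert prof[[0, 1, 2, 3, 4, 5, 9]].max() == 0.0

    def test_par_absent_signals_empty(self):
        traj = self._fixture()
        with pytest.raises(NoParContactError):
            par_contact_profile(traj, [0, 1], [],
                                AnalysisConfig(analysis_window=(0.0, 1.0)))

    def test_always_in_contact_equals_unfiltered(self):
        traj = self._fixture()
        cfg = AnalysisConfig(analysis_window=(0.0, 1.0))
        prof = par_contact_profile(traj, fus_chains=[0], par_beads=[20],
                                   config=cfg)
        cm = contact_map(traj, np.arange(10), [20], cfg)
        # chain 0 is in contact in 2 of 4 frames; over retained frames the
        # profile equals the unfiltered frequencies rescaled by 4/2
        np.testing.assert_allclose(prof, cm.freq[:, 0] * 2.0)


class TestRatioMap:
    def test_identical_maps_unity(self):
        m = np.random.default_rng(0).uniform(0, 1, (5, 5))
        np.testing.assert_allclose(contact_ratio_map(m, m, pseudo=0.01), 1.0)

    def test_plain_ratio(self):
        r = contact_ratio_map(np.array([[0.2]]), np.array([[0.1]]), pseudo=0.0)
        assert r[0, 0] == pytest.approx(2.0)

    def test_zero_cells_finite_with_default_pseudo(self):
        r = contact_ratio_map(np.array([[0.3]]), np.array([[0.0]]), n_frames=100)
        assert np.isfinite(r).all()
        assert r[0, 0] == pytest.approx((0.3 + 0.01) / 0.01)

    def test_axis_mismatch(self):
        with pytest.raises(ValueError):
            contact_ratio_map(np.ones((2, 2)), np.ones((3, 2)), pseudo=0.1)


class TestDomainDistances:
    def test_single_bead_domains_equal_bead_distance(self):
        xyz = np.array([[[0, 0, 0], [3.0, 4.0, 0]]], dtype=float)
        traj = make_trajectory(xyz, BOX, [0, 1], [1.0, 1.0])
        d = domain_distance_series(traj, [0], [1])
        assert d[0] == pytest.approx(5.0)

    def test_rigid_translation_keeps_series_constant(self):
        rng = np.random.default_rng(1)
        base = rng.uniform(0, 5, (8, 3))
        frames = np.stack([(base + f * np.array([0.5, 0.2, 1.0])) % BOX
                           for f in range(5)])
        traj = make_trajectory(frames, BOX, np.zeros(8, int), np.ones(8))
        d = domain_distance_series(traj, [0, 1, 2], [5, 6, 7])
        np.testing.assert_allclose(d, d[0], rtol=1e-9)

    def test_scripted_approach_matches_hand_values(self):
        zs = [10.0, 6.0, 2.0]
        frames = np.array([[[0, 0, 0], [0, 0, z]] for z in zs])
        traj = make_trajectory(frames, BOX, [0, 1], [1.0, 1.0])
        np.testing.assert_allclose(domain_distance_series(traj, [0], [1]), zs)


class TestTwoPhaseGenerator:
    def test_plateaus_recovered_within_poisson_bands(self):
        xyz, chain_id, mass, box, labels, gt = gen_two_phase_config(
            n_chains=400, beads_per_chain=3, rho_dense=40.0, rho_dilute=2.0,
            interface_z=30.0, bead_mass=1.0, seed=8)
        traj = make_trajectory(xyz[None], box, chain_id, mass)
        cfg = AnalysisConfig(n_bins=40, slab_half_width=30.0,
                             analysis_window=(0.0, 1.0))
        centers, dens = density_profile(traj, cfg, centered_xyz=traj.xyz)
        rl, rh = coexistence_densities(centers, dens, cfg)
        n_dense = gt.params["n_dense"] * 3
        n_dil = 400 * 3 - n_dense
        v_dense = box[0] * box[1] * 60.0
        v_dil = box[0] * box[1] * (box[2] - 60.0)
        for got, cnt, vol in ((rh, n_dense, v_dense), (rl, n_dil, v_dil)):
            sd = np.sqrt(cnt) / vol
            assert abs(got - cnt / vol) < 3 * sd + 1e-9

    def test_equal_densities_flat(self):
        xyz, chain_id, mass, box, labels, gt = gen_two_phase_config(
            n_chains=300, rho_dense=5.0, rho_dilute=5.0, seed=0)
        traj = make_trajectory(xyz[None], box, chain_id, mass)
        cfg = AnalysisConfig(n_bins=20, slab_half_width=30.0,
                             analysis_window=(0.0, 1.0))
        centers, dens = density_profile(traj, cfg, centered_xyz=traj.xyz)
        rl, rh = coexistence_densities(centers, dens, cfg)
        assert rh / rl == pytest.approx(1.0, abs=0.35)

    def test_zero_dilute_single_cluster(self):
        xyz, chain_id, mass, box, labels, gt = gen_two_phase_config(
            n_chains=30, rho_dense=10.0, rho_dilute=0.0, interface_z=5.0, seed=3)
        assert all(l == "dense" for l in labels)
        coms = chain_coms(xyz, chain_id, mass, box)
        cl = single_linkage_clusters(coms, box, cutoff=8.0)
        assert len(set(cl)) == 1
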