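"""MBAR reweighting, PMF construction, binding free energy and block errors."""

import numpy as np
import pytest
from scipy.special import logsumexp

from parfus.constants import KB
from parfus.free_energy import (Pmf, UmbrellaDataset, UmbrellaWindow,
                                binding_free_energy, block_uncertainty,
                                check_window_overlap, mbar_pmf, mbar_solve)
from parfus.synth import gen_umbrella_samples

KT = KB * 293.15
CENTERS = np.linspace(0, 20, 61)


def wham_pmf(data, bins, n_iter=4000):
    """Independent WHAM oracle: histogram-based self-consistent reweighting."""
    beta = 1.0 / (KB * data.temperature)
    edges = np.asarray(bins)
    mids = 0.5 * (edges[:-1] + edges[1:])
    K = len(data.windows)
    H = np.zeros((K, len(mids)))
    N = np.zeros(K)
    for k, w in enumerate(data.windows):
        H[k], _ = np.histogram(w.samples, bins=edges)
        N[k] = len(w.samples)
    bias = np.array([[beta * 0.5 * w.k * (m - w.req) ** 2 for m in mids]
                     for w in data.windows])
    f = np.zeros(K)
    for _ in range(n_iter):
        denom = (N[:, None] * np.exp(f[:, None] - bias)).sum(axis=0)
        p = H.sum(axis=0) / np.maximum(denom, 1e-300)
        p /= p.sum()
        f_new = -np.log(np.maximum((np.exp(-bias) * p[None, :]).sum(axis=1),
                                   1e-300))
        f_new -= f_new[0]
        if np.abs(f_new - f).max() < 1e-12:
            f = f_new
            break
        f = f_new
    with np.errstate(divide="ignore"):
        F = -KB * data.temperature * np.log(p / np.maximum(mids, 1e-12) ** 2)
    F -= np.nanmin(F[p > 0])
    F[p == 0] = np.nan
    return mids, F


class TestMbarSolve:
    def test_state_weights_normalize(self):
        data, _ = gen_umbrella_samples(lambda r: 0.0, CENTERS, n_samples=200,
                                       seed=0)
        log_w, x, f, res = mbar_solve(data)
        assert res < 1e-8
        assert logsumexp(log_w) == pytest.approx(0.0, abs=1e-10)
        # per-state weights (biased reweighting) also normalize
        beta = 1.0 / KT
        for w in data.windows[::20]:
            u = beta * 0.5 * w.k * (x - w.req) ** 2
            lw_state = log_w - u
            p = np.exp(lw_state - logsumexp(lw_state))
            assert p.sum() == pytest.approx(1.0, rel=1e-9)

    def test_gauge_invariance(self):
        """Adding a constant to the surface changes nothing in the PMF."""
        d1, _ = gen_umbrella_samples(lambda r: 0.02 * (r - 10) ** 2, CENTERS,
                                     n_samples=400, seed=4)
        d2, _ = gen_umbrella_samples(lambda r: 0.02 * (r - 10) ** 2 + 37.0,
                                     CENTERS, n_samples=400, seed=4)
        p1 = mbar_pmf(d1, bins=np.arange(1, 19, 0.5))
        p2 = mbar_pmf(d2, bins=np.arange(1, 19, 0.5))
        np.testing.assert_allclose(p1.free_energy, p2.free_energy, atol=1e-9)


class TestPmf:
    def test_harmonic_surface_recovered(self):
        surf = lambda r: 0.05 * (r - 8.0) ** 2
        data, _ = gen_umbrella_samples(surf, CENTERS, k=50.0, n_samples=2000,
                                       seed=1, r_support=(0, 22))
        pmf = mbar_pmf(data, bins=np.arange(1.0, 19.01, 0.5))
        m = np.isfinite(pmf.free_energy)
        est = pmf.free_energy[m] - pmf.free_energy[m].min()
        ana = surf(pmf.bin_centers[m])
        ana -= ana.min()
        assert np.max(np.abs(est - ana)) < 0.5   # statistical floor at this n

    def test_single_unbiased_window_is_boltzmann_inversion(self):
        rng = np.random.default_rng(3)
        samples = rng.uniform(2.0, 6.0, 5000)
        data = UmbrellaDataset([UmbrellaWindow(4.0, 0.0, samples)])
        bins = np.arange(2.0, 6.01, 0.5)
        pmf = mbar_pmf(data, bins=bins, remove_jacobian=False,
                       check_overlap=False)
        hist, _ = np.histogram(samples, bins=bins)
        want = -KT * np.log(hist / np.diff(bins))
        want -= want.min()
        np.testing.assert_allclose(pmf.free_energy, want, atol=1e-9)

    def test_more_samples_shrink_error_bars(self):
        surf = lambda r: 0.05 * (r - 8.0) ** 2
        small, _ = gen_umbrella_samples(surf, CENTERS, n_samples=500, seed=5)
        big, _ = gen_umbrella_samples(surf, CENTERS, n_samples=2000, seed=5)
        bins = np.arange(2.0, 18.01, 0.5)
        ps = mbar_pmf(small, bins=bins)
        pb = mbar_pmf(big, bins=bins)
        assert np.nanmean(pb.uncertainty) < np.nanmean(ps.uncertainty)
        # profiles agree at the small-n statistical scale (the per-bin error
        # bars are local and do not include window-to-window accumulation)
        assert np.nanmean(np.abs(pb.free_energy - ps.free_energy)) < 0.8

    def test_agrees_with_wham_oracle(self):
        """MBAR vs an independent WHAM solve on the harmonic oracle. Few wide
        windows keep the WHAM fixed-point iteration well inside convergence."""
        surf = lambda r: 0.08 * (r - 10.0) ** 2
        centers = np.linspace(2, 18, 13)
        data, _ = gen_umbrella_samples(surf, centers, k=12.0, n_samples=4000,
                                       seed=6, r_support=(0, 22))
        bins = np.arange(0.25, 21.76, 0.5)
        pmf = mbar_pmf(data, bins=bins)
        mids, Fw = wham_pmf(data, bins, n_iter=30_000)
        m = (np.isfinite(pmf.free_energy) & np.isfinite(Fw)
             & (mids > 4) & (mids < 16))
        a = pmf.free_energy[m] - pmf.free_energy[m].mean()
        b = Fw[m] - Fw[m].mean()
        assert np.max(np.abs(a - b)) < 0.25

    def test_non_overlapping_windows_diagnosed(self):
        rng = np.random.default_rng(0)
        wins = [UmbrellaWindow(0.0, 5000.0, rng.normal(0.0, 0.02, 200)),
                UmbrellaWindow(10.0, 5000.0, rng.normal(10.0, 0.02, 200))]
        with pytest.raises(ValueError, match="overlap"):
            check_window_overlap(UmbrellaDataset(wins))


class TestBindingFreeEnergy:
    def test_flat_pmf_geometric_value(self):
        data, _ = gen_umbrella_samples(lambda r: 0.0, CENTERS, n_samples=2000,
                                       seed=2, r_support=(0, 20))
        dg = binding_free_energy(data, cutoff=10.0)
        want = -KT * np.log(1000.0 / (8000.0 - 1000.0))
        assert dg == pytest.approx(want, abs=0.35)

    def test_square_well_matches_quadrature(self):
        eps = 6.0
        surf = lambda r: -eps if r < 10.0 else 0.0
        data, _ = gen_umbrella_samples(surf, CENTERS, n_samples=3000, seed=7,
                                       r_support=(0, 20))
        dg = binding_free_energy(data, cutoff=10.0)
        beta = 1.0 / KT
        grid = np.linspace(1e-6, 20, 20001)
        w = grid ** 2 * np.exp(-beta * np.where(grid < 10, -eps, 0.0))
        pb = np.trapezoid(w[grid < 10], grid[grid < 10])
        pu = np.trapezoid(w[grid >= 10], grid[grid >= 10])
        want = -KT * np.log(pb / pu)
        assert dg == pytest.approx(want, abs=0.4)

    def test_sign_sanity(self):
        """Repulsive wall inside the cutoff: dG > 0; deep well: dG < 0."""
        rep, _ = gen_umbrella_samples(lambda r: 12.0 if r < 10 else 0.0,
                                      CENTERS, n_samples=800, seed=8,
                                      r_support=(0, 20))
        att, _ = gen_umbrella_samples(lambda r: -12.0 if r < 10 else 0.0,
                                      CENTERS, n_samples=800, seed=9,
                                      r_support=(0, 20))
        assert binding_free_energy(rep, cutoff=10.0) > 0
        assert binding_free_energy(att, cutoff=10.0) < 0

    def test_cutoff_outside_samples_rejected(self):
        data, _ = gen_umbrella_samples(lambda r: 0.0, CENTERS, n_samples=200,
                                       seed=0, r_support=(0, 20))
        with pytest.raises(ValueError, match="cutoff"):
            binding_free_energy(data, cutoff=30.0)


class TestBlocks:
    def test_duplicated_blocks_zero_sd(self):
        rng = np.random.default_rng(1)
        block = rng.uniform(0.5, 19.5, 300)
        wins = [UmbrellaWindow(req, 50.0, np.tile(block, 6))
                for req in CENTERS]
        data = UmbrellaDataset(wins)
        dgs, sd = block_uncertainty(data, n_blocks=5, discard_frac=1.0 / 6.0)
        assert sd == pytest.approx(0.0, abs=1e-9)

    def test_iid_blocks_comparable_to_bootstrap(self):
        data, _ = gen_umbrella_samples(lambda r: 0.0, CENTERS, n_samples=1200,
                                       seed=3, r_support=(0, 20))
        dgs, sd = block_uncertainty(data, n_blocks=5, discard_frac=1.0 / 6.0)
        # bootstrap over windows' samples at the same block size
        rng = np.random.default_rng(0)
        boots = []
        for _ in range(5):
            wins = [UmbrellaWindow(w.req, w.k,
                                   rng.choice(w.samples, size=200))
                    for w in data.windows]
            boots.append(binding_free_energy(UmbrellaDataset(wins), 10.0))
        bsd = np.std(boots, ddof=1)
        assert sd / bsd < 3.0 and bsd / sd < 3.0

    def test_single_block_rejected(self):
        data, _ = gen_umbrella_samples(lambda r: 0.0, CENTERS, n_samples=300,
                                       seed=0, r_support=(0, 20))
        with pytest.raises(ValueError):
            block_uncertainty(data, n_blocks=1)

    def test_short_series_flagged(self):
        data, _ = gen_umbrella_samples(lambda r: 0.0, CENTERS, n_samples=30,
                                       seed=0, r_support=(0, 20))
        with pytest.raises(ValueError, match="decorrelation"):
            block_uncertainty(data, n_blocks=5)


class TestDatasetContainer:
    def test_min_samples_enforced(self):
        with pytest.raises(ValueError, match="fewer"):
            UmbrellaDataset([UmbrellaWindow(0.0, 50.0, np.zeros(3))])

    def test_mixed_temperatures_rejected(self):
        w1 = UmbrellaWindow(0.0, 50.0, np.zeros(20), temperature=293.15)
        w2 = UmbrellaWindow(1.0, 50.0, np.zeros(20), temperature=300.0)
        with pytest.raises(ValueError, match="temperature"):
            UmbrellaDataset([w1, w2])

    def test_save_load_round_trip(self, tmp_path):
        data, _ = gen_umbrella_samples(lambda r: 0.0, CENTERS[:5],
                                       n_samples=50, seed=0, r_support=(0, 3))
        data.save(tmp_path / "umb")
        back = UmbrellaDataset.load(tmp_path / "umb")
        assert len(back.windows) == 5
        np.testing.assert_allclose(back.windows[2].samples,
                                   data.windows[2].samples)
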