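"""Umbrella-sampling thermodynamics: MBAR reweighting, PMF construction and
bound/unbound binding free energies with block-wise uncertainty.

The multistate Bennett acceptance ratio (MBAR) estimator is solved here via
its convex objective
``Phi(f) = sum_n logsumexp_k(log N_k + f_k - u_k(x_n)) - sum_k N_k f_k``,
whose stationary point is the MBAR self-consistency equation. Biased states
are the harmonic distance restraints u_k(r) = beta * k/2 (r - req_k)^2; the
unbiased state has zero potential along r.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from .constants import KB


@dataclass
class UmbrellaWindow:
    """One restraint window: center req (nm), force constant k, distance samples."""
    req: float
    k: float
    samples: np.ndarray
    temperature: float = 293.15

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)


@dataclass
class UmbrellaDataset:
    """Collection of umbrella windows at one temperature."""
    windows: list
    metadata: dict = field(default_factory=dict)
    min_samples: int = 10

    def __post_init__(self):
        temps = {w.temperature for w in self.windows}
        if len(temps) > 1:
            raise ValueError("all windows must share one temperature")
        small = [w.req for w in self.windows if len(w.samples) < self.min_samples]
        if small:
            raise ValueError(f"windows with fewer than {self.min_samples} samples: {small}")

    @property
    def temperature(self) -> float:
        return self.windows[0].temperature

    def sliced(self, lo_frac: float, hi_frac: float) -> "UmbrellaDataset":
        """Dataset restricted to a contiguous fraction of each window's series."""
        out = []
        for w in self.windows:
            n = len(w.samples)
            out.append(UmbrellaWindow(w.req, w.k,
                                      w.samples[int(lo_frac * n):int(hi_frac * n)],
                                      w.temperature))
        return UmbrellaDataset(out, dict(self.metadata), self.min_samples)

    def save(self, prefix):
        """Per-window CSV time series plus a JSON manifest."""
        import json, os
        os.makedirs(prefix, exist_ok=True)
        manifest = {"temperature": self.temperature, "windows": [],
                    "metadata": self.metadata}
        for i, w in enumerate(self.windows):
            fn = f"window_{i:03d}.csv"
            np.savetxt(os.path.join(prefix, fn), w.samples, header="distance_nm")
            manifest["windows"].append({"req": w.req, "k": w.k, "file": fn})
        with open(os.path.join(prefix, "manifest.json"), "w") as f:
            json.dump(manifest, f, indent=1)

    @classmethod
    def load(cls, prefix):
        import json, os
        with open(os.path.join(prefix, "manifest.json")) as f:
            manifest = json.load(f)
        windows = [UmbrellaWindow(w["req"], w["k"],
                                  np.loadtxt(os.path.join(prefix, w["file"])),
                                  manifest["temperature"])
                   for w in manifest["windows"]]
        return cls(windows, manifest.get("metadata", {}))


@dataclass
class Pmf:
    """Potential of mean force on distance bins, anchored so min(F) = 0."""
    bin_centers: np.ndarray
    free_energy: np.ndarray    # kJ/mol, NaN where unsampled
    uncertainty: np.ndarray
    temperature: float


def check_window_overlap(data: UmbrellaDataset, min_overlap: float = 0.01):
    """Histogram overlap coefficient between adjacent windows; raises naming
    the first gap if any adjacent pair shares (almost) no sampled range."""
    gaps = []
    order = np.argsort([w.req for w in data.windows])
    ws = [data.windows[i] for i in order]
    for a, b in zip(ws[:-1], ws[1:]):
        lo = min(a.samples.min(), b.samples.min())
        hi = max(a.samples.max(), b.samples.max())
        bins = np.linspace(lo, hi + 1e-12, 41)
        ha, _ = np.histogram(a.samples, bins=bins, density=True)
        hb, _ = np.histogram(b.samples, bins=bins, density=True)
        w = bins[1] - bins[0]
        ov = float(np.minimum(ha, hb).sum() * w)
        if ov < min_overlap:
            gaps.append((a.req, b.req, ov))
    if gaps:
        a, b, ov = gaps[0]
        raise ValueError(f"non-overlapping umbrella windows: req {a:.2f} and "
                         f"{b:.2f} nm overlap {ov:.3g} (need >= {min_overlap})")


def mbar_solve(data: UmbrellaDataset, tol: float = 1e-10,
               chunk: int = 500_000):
    """Solve MBAR: returns (log unbiased weights w_n (normalized), pooled
    samples x_n, per-state reduced free energies f_k, max self-consistency
    residual).

    Uses damped Newton iterations on the convex MBAR objective; the (K x N)
    bias matrix is evaluated in sample chunks so memory stays bounded for
    long window series.
    """
    beta = 1.0 / (KB * data.temperature)
    x = np.concatenate([w.samples for w in data.windows])
    N_k = np.array([len(w.samples) for w in data.windows], dtype=float)
    K = len(data.windows)
    req = np.array([w.req for w in data.windows])
    kk = np.array([w.k for w in data.windows])
    logN = np.log(N_k)
    N = len(x)

    def evaluate(f, xs, Nks, need_hess):
        from ._kernels import mbar_eval
        val0, g0, H = mbar_eval(xs, req, kk, beta, f, np.log(Nks),
                                bool(need_hess))
        val = val0 - np.dot(Nks, f)
        g = g0 - Nks
        return val, g, (H if need_hess else None)

    def newton(f, xs, Nks, gtol):
        val, g, H = evaluate(f, xs, Nks, True)
        residual = np.inf
        for _ in range(100):
            residual = float(np.abs(g).max() / max(Nks.max(), 1.0))
            if residual < gtol:
                break
            try:
                step = np.linalg.solve(H[1:, 1:] + 1e-12 * np.eye(K - 1), -g[1:])
            except np.linalg.LinAlgError:
                break
            scale, accepted = 1.0, False
            for _ in range(30):
                f_try = f.copy()
                f_try[1:] += scale * step
                val_t, g_t, _ = evaluate(f_try, xs, Nks, False)
                if val_t <= val + 1e-12 * abs(val):
                    f, val, g = f_try, val_t, g_t
                    accepted = True
                    break
                scale *= 0.5
            if not accepted:
                break
            _, _, H = evaluate(f, xs, Nks, True)
        return f, residual

    # warm start on a strided subsample, then polish on the full data
    # (damped Newton on the convex objective, gauge fixed by pinning f_0 = 0)
    f = np.zeros(K)
    stride = max(int(N_k.min()) // 2000, 1)
    if stride > 1:
        xs_sub = np.concatenate([w.samples[::stride] for w in data.windows])
        Nks_sub = np.array([len(w.samples[::stride]) for w in data.windows],
                           dtype=float)
        f, _ = newton(f, xs_sub, Nks_sub, tol)
    f, residual = newton(f, x, N_k, tol)
    f = f - f[0]
    from ._kernels import mbar_log_weights
    log_w = mbar_log_weights(x, req, kk, beta, f, logN)
    log_w -= logsumexp(log_w)
    return log_w, x, f, residual


def mbar_pmf(data: UmbrellaDataset, bins=None, remove_jacobian: bool = True,
             check_overlap: bool = True, residual_tol: float = 1e-8) -> Pmf:
    """PMF along the restrained distance from MBAR-reweighted histograms.

    With ``remove_jacobian`` (default) the radial r^2 phase-space factor is
    divided out, so the returned profile is the interaction free energy G(r)
    whose flat limit is a constant; without it the profile is
    -kT ln rho(r), the Boltzmann inversion of the sampled distance density.
    """
    if check_overlap:
        check_window_overlap(data)
    log_w, x, f, residual = mbar_solve(data)
    if residual > residual_tol:
        raise RuntimeError(f"MBAR did not converge: residual {residual:.2e}")
    if bins is None:
        bins = np.arange(x.min(), x.max() + 0.25, 0.25)
    bins = np.asarray(bins, dtype=float)
    kT = KB * data.temperature
    w = np.exp(log_w)
    hist, edges = np.histogram(x, bins=bins, weights=w)
    hist2, _ = np.histogram(x, bins=bins, weights=w * w)
    centers = 0.5 * (edges[:-1] + edges[1:])
    width = np.diff(edges)
    dens = hist / width
    if remove_jacobian:
        dens = dens / np.maximum(centers ** 2, 1e-12)
    F = np.full(len(centers), np.nan)
    mask = hist > 0
    F[mask] = -kT * np.log(dens[mask])
    F -= np.nanmin(F)
    # Kish effective sample size per bin -> multinomial-style error bar
    neff = np.zeros(len(centers))
    neff[mask] = hist[mask] ** 2 / np.maximum(hist2[mask], 1e-300)
    err = np.full(len(centers), np.nan)
    err[mask] = kT / np.sqrt(np.maximum(neff[mask], 1.0))
    return Pmf(centers, F, err, data.temperature)


def binding_free_energy(data: UmbrellaDataset, cutoff: float = 10.0) -> float:
    """Binding free energy from bound/unbound classification, kJ/mol.

    dG = -kT ln(P_bound / P_unbound) with probabilities from MBAR-reweighted
    configuration weights (bound: r < cutoff). More negative = tighter.
    No standard-state volume correction is applied.
    """
    log_w, x, _, _ = mbar_solve(data)
    if x.min() >= cutoff or x.max() <= cutoff:
        raise ValueError(f"cutoff {cutoff} nm not bracketed by samples "
                         f"[{x.min():.2f}, {x.max():.2f}]")
    kT = KB * data.temperature
    lb = logsumexp(log_w[x < cutoff])
    lu = logsumexp(log_w[x >= cutoff])
    return float(-kT * (lb - lu))


def block_uncertainty(data: UmbrellaDataset, n_blocks: int = 5,
                      cutoff: float = 10.0, discard_frac: float = 1.0 / 6.0,
                      min_block: int = 10):
    """SD of the binding free energy over contiguous trajectory blocks.

    The first ``discard_frac`` of every window's series is dropped (the
    production protocol discards the first 5 of 30 us), the remainder is cut
    into ``n_blocks`` contiguous segments, and dG is recomputed per segment.
    Returns (dG values per block, their standard deviation).
    """
    if n_blocks < 2:
        raise ValueError("block variance needs at least 2 blocks")
    shortest = min(len(w.samples) for w in data.windows)
    usable = int(shortest * (1.0 - discard_frac))
    if usable // n_blocks < min_block:
        raise ValueError(f"blocks of {usable // n_blocks} samples are below the "
                         f"decorrelation floor ({min_block})")
    dgs = []
    for b in range(n_blocks):
        lo = discard_frac + (1.0 - discard_frac) * b / n_blocks
        hi = discard_frac + (1.0 - discard_frac) * (b + 1) / n_blocks
        dgs.append(binding_free_energy(data.sliced(lo, hi), cutoff=cutoff))
    dgs = np.asarray(dgs)
    return dgs, float(dgs.std(ddof=1))
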