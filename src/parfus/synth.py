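"""Synthetic-data generators with recorded ground truth.

Every generator is deterministic under a fixed seed and returns (or writes) a
:class:`GroundTruth` record alongside its dataset, so downstream modules can
be exercised end-to-end (generate -> analyze -> recover) without external
data. Generators evaluate the forward models directly and never import the
analysis code paths they are used to test.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .constants import KB


@dataclass
class GroundTruth:
    """Provenance record serialized alongside every generated dataset."""
    generator: str
    params: dict
    seed: int
    schema_version: int = 1

    def save(self, path):
        with open(path, "w") as f:
            json.dump(asdict(self), f, indent=1, default=float)

    @classmethod
    def load(cls, path):
        with open(path) as f:
            return cls(**json.load(f))


# ---------------------------------------------------------------------------
# PAR FRET datasets
# ---------------------------------------------------------------------------

def gen_par_fret_dataset(sigma: float = 1.5, lam: float = 0.8,
                         lengths=(8, 16, 24, 32), noise: float = 0.0,
                         seed: int = 0, settings=None):
    """Synthetic per-length FRET efficiencies from the PAR model itself.

    Simulates single PAR chains at the stated (sigma, lambda), computes
    ensemble FRET per length, and adds Gaussian noise of the given absolute
    magnitude. Returns (FretDataset, GroundTruth).

    Note: this generator necessarily runs the forward simulation (the model
    IS the data-generating process); the calibration search it feeds is an
    independent optimization over the same forward model.
    """
    from .fret import (CalibrationSettings, FretDataset, ensemble_fret,
                       length_seed, simulate_par_end_to_end)
    if len(lengths) < 2:
        raise ValueError("need at least 2 PAR lengths")
    settings = settings or CalibrationSettings()
    rng = np.random.default_rng(seed)
    effs = []
    for n in lengths:
        r = simulate_par_end_to_end(int(n), sigma, lam, settings,
                                    length_seed(seed, int(n)))
        e = ensemble_fret(r)
        effs.append(np.clip(e + noise * rng.standard_normal(), 0.0, 1.0))
    data = FretDataset(np.asarray(lengths), np.asarray(effs),
                       np.full(len(lengths), max(noise, 0.01)))
    gt = GroundTruth("gen_par_fret_dataset",
                     {"sigma": sigma, "lam": lam, "lengths": list(lengths),
                      "noise": noise}, seed)
    return data, gt


# ---------------------------------------------------------------------------
# two-phase slab configurations
# ---------------------------------------------------------------------------

def gen_two_phase_config(n_chains: int = 40, beads_per_chain: int = 5,
                         box=(20.0, 20.0, 200.0), rho_dense: float = 0.5,
                         rho_dilute: float = 0.01, interface_z: float = 30.0,
                         bead_mass: float = 100.0, seed: int = 0):
    """Particle slab with two declared density plateaus (chains/nm^3 scaled
    by chain mass), known cluster structure, centered at z = 0.

    Chains are compact blobs; the fraction of chains inside |z| < interface_z
    follows from the requested densities. Returns (xyz, chain_id, mass, box,
    labels, GroundTruth) where labels[i] is 'dense' or 'dilute' per chain.
    """
    box = np.asarray(box, dtype=float)
    rng = np.random.default_rng(seed)
    v_dense = box[0] * box[1] * 2 * interface_z
    v_dilute = box[0] * box[1] * (box[2] - 2 * interface_z)
    w_dense = rho_dense * v_dense
    w_total = w_dense + rho_dilute * v_dilute
    if w_total <= 0:
        raise ValueError("densities must not both be zero")
    n_dense = int(round(n_chains * w_dense / w_total))
    chain_id = np.repeat(np.arange(n_chains), beads_per_chain)
    mass = np.full(n_chains * beads_per_chain, bead_mass)
    xyz = np.zeros((n_chains * beads_per_chain, 3))
    labels = []
    for c in range(n_chains):
        if c < n_dense:
            z = rng.uniform(-interface_z, interface_z)
            labels.append("dense")
        else:
            side = rng.choice([-1, 1])
            z = side * rng.uniform(interface_z, box[2] / 2)
            labels.append("dilute")
        center = np.array([rng.uniform(0, box[0]), rng.uniform(0, box[1]), z])
        blob = center + 0.3 * rng.standard_normal((beads_per_chain, 3))
        xyz[chain_id == c] = blob
    gt = GroundTruth("gen_two_phase_config",
                     {"n_chains": n_chains, "rho_dense": rho_dense,
                      "rho_dilute": rho_dilute, "interface_z": interface_z,
                      "n_dense": n_dense, "beads_per_chain": beads_per_chain,
                      "bead_mass": bead_mass, "box": box.tolist()}, seed)
    return xyz, chain_id, mass, box, labels, gt


# ---------------------------------------------------------------------------
# coexistence points
# ---------------------------------------------------------------------------

def gen_coexistence_points(A: float = 2.0, Tc: float = 400.0,
                           temps=(330, 340, 350, 360, 370, 380),
                           noise: float = 0.0, seed: int = 0,
                           rho_l_base: float = 20.0, rho_l_slope: float = 0.5,
                           beta: float = 0.325):
    """(T, rho_L, rho_H) points following rho_H - rho_L = A (Tc - T)^beta
    exactly before multiplicative Gaussian noise. rho_L follows the declared
    linear baseline rho_l_base + rho_l_slope * (T - min(T))."""
    temps = np.asarray(temps, dtype=float)
    if np.any(temps >= Tc):
        raise ValueError("all temperatures must lie below Tc")
    rng = np.random.default_rng(seed)
    rho_l = rho_l_base + rho_l_slope * (temps - temps.min())
    diff = A * (Tc - temps) ** beta
    rho_h = rho_l + diff
    if noise > 0:
        rho_l = rho_l * (1.0 + noise * rng.standard_normal(len(temps)))
        rho_h = rho_h * (1.0 + noise * rng.standard_normal(len(temps)))
    pts = np.column_stack([temps, rho_l, rho_h])
    gt = GroundTruth("gen_coexistence_points",
                     {"A": A, "Tc": Tc, "beta": beta, "noise": noise,
                      "temps": temps.tolist()}, seed)
    return pts, gt


# ---------------------------------------------------------------------------
# umbrella samples
# ---------------------------------------------------------------------------

def gen_umbrella_samples(surface, centers, k: float = 50.0,
                         n_samples: int = 2000, temperature: float = 293.15,
                         seed: int = 0, r_support=(0.0, 25.0),
                         jacobian: bool = True):
    """Draw distance samples from each biased Boltzmann density by rejection
    sampling: p_w(r) proportional to J(r) exp(-beta [G(r) + k/2 (r-req)^2]),
    with J(r) = r^2 when ``jacobian`` (3-D COM-distance phase space).

    ``surface``: callable G(r) in kJ/mol, finite on r_support.
    Returns (UmbrellaDataset, GroundTruth with the oracle surface params).
    """
    from .free_energy import UmbrellaDataset, UmbrellaWindow
    beta = 1.0 / (KB * temperature)
    rng = np.random.default_rng(seed)
    lo, hi = r_support
    grid = np.linspace(lo + 1e-9, hi, 4001)
    gsurf = np.asarray([surface(r) for r in grid])
    if not np.all(np.isfinite(gsurf)):
        raise ValueError("surface must be finite on the support")
    windows = []
    for req in centers:
        logp = -beta * (gsurf + 0.5 * k * (grid - req) ** 2)
        if jacobian:
            logp = logp + 2.0 * np.log(np.maximum(grid, 1e-12))
        logp -= logp.max()
        p = np.exp(logp)
        area = np.trapezoid(p, grid)
        if area <= 0 or not np.isfinite(area):
            raise ValueError(f"unsampleable window at req={req}")
        cdf = np.concatenate([[0.0], np.cumsum(0.5 * (p[1:] + p[:-1])
                                               * np.diff(grid))])
        cdf /= cdf[-1]
        u = rng.uniform(size=n_samples)
        samples = np.interp(u, cdf, grid)
        windows.append(UmbrellaWindow(float(req), k, samples, temperature))
    data = UmbrellaDataset(windows, {"generator": "gen_umbrella_samples"})
    gt = GroundTruth("gen_umbrella_samples",
                     {"k": k, "n_samples": n_samples, "temperature": temperature,
                      "jacobian": jacobian, "centers": list(map(float, centers))},
                     seed)
    return data, gt


# ---------------------------------------------------------------------------
# assay curves
# ---------------------------------------------------------------------------

def gen_assay_curves(kind: str, params: dict, noise: float = 0.0, seed: int = 0):
    """Noisy synthetic assay curves by exact model evaluation.

    kind 'hill': params kd, n, bottom, top, conc (array, M) -> (conc, response)
    kind 'frap': params fmin, fmax, k, t (array, s)         -> (t, F)
    kind 'fcs' : params g0, tau_d, omega_sq, tau (array, s) -> (tau, G);
                 noise is heteroscedastic, growing at small lag times
    kind 'bli' : params kon, koff, bmax, conc (array, M), t (array, s)
                 -> (list of (t, Y) sensorgrams, conc)
    Returns (curve data, GroundTruth).
    """
    rng = np.random.default_rng(seed)
    p = dict(params)
    if kind == "hill":
        conc = np.asarray(p.pop("conc"))
        if p["n"] == 0:
            raise ValueError("degenerate Hill slope")
        y = p["bottom"] + (p["top"] - p["bottom"]) * conc ** p["n"] / \
            (p["kd"] ** p["n"] + conc ** p["n"])
        y = y + noise * np.ptp(y) * rng.standard_normal(len(y)) if noise else y
        out = (conc, y)
    elif kind == "frap":
        t = np.asarray(p.pop("t"))
        if p["k"] <= 0:
            raise ValueError("unfittable FRAP curve: rate must be positive")
        y = p["fmin"] + (p["fmax"] - p["fmin"]) * (1.0 - np.exp(-p["k"] * t))
        y = y + noise * rng.standard_normal(len(t)) if noise else y
        out = (t, y)
    elif kind == "fcs":
        tau = np.asarray(p.pop("tau"))
        y = p["g0"] / (1.0 + tau / p["tau_d"]) / np.sqrt(
            1.0 + tau / (p["omega_sq"] * p["tau_d"]))
        if noise:
            het = 1.0 + 1.0 / np.sqrt(1.0 + tau / tau.min())
            y = y + noise * p["g0"] * het * rng.standard_normal(len(tau))
        out = (tau, y)
    elif kind == "bli":
        conc = np.asarray(p.pop("conc"))
        t = np.asarray(p.pop("t"))
        kd = p["koff"] / p["kon"]
        grams = []
        for L in conc:
            kob = p["kon"] * L + p["koff"]
            y = (L / (L + kd)) * p["bmax"] * (1.0 - np.exp(-kob * t))
            if noise:
                y = y + noise * p["bmax"] * rng.standard_normal(len(t))
            grams.append((t.copy(), y))
        out = (grams, conc)
    else:
        raise ValueError(f"unknown curve kind {kind!r}")
    gt = GroundTruth(f"gen_assay_curves[{kind}]",
                     {**{k: (v.tolist() if isinstance(v, np.ndarray) else v)
                         for k, v in params.items()}, "noise": noise}, seed)
    return out, gt


# ---------------------------------------------------------------------------
# LiP-MS tables
# ---------------------------------------------------------------------------

def gen_lipms_table(n_features: int = 20, seed: int = 0,
                    base_count: float = 1e5, cv: float = 0.02,
                    scenario_mix=("all_present", "one_missing",
                                  "condition_missing", "excluded"),
                    effect_log2: float = 2.0):
    """Feature table covering all imputation branches with known truth.

    Half of the retained features get a log2 effect of ``effect_log2``
    (intended significant), the rest no effect. Returns (DataFrame,
    GroundTruth); the frame carries 'intended_branch' and
    'intended_significant' columns for round-trip checks.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_features):
        branch = scenario_mix[i % len(scenario_mix)]
        has_effect = (i // len(scenario_mix)) % 2 == 0
        mu1 = base_count * rng.uniform(0.5, 2.0)
        mu2 = mu1 * (2.0 ** effect_log2 if has_effect else 1.0)
        c1 = mu1 * (1.0 + cv * rng.standard_normal(3))
        c2 = mu2 * (1.0 + cv * rng.standard_normal(3))
        if branch == "one_missing":
            c1[rng.integers(3)] = np.nan
        elif branch == "condition_missing":
            c1[:] = np.nan
            has_effect = True   # detection-limit imputation creates a ratio
        elif branch == "excluded":
            c1[0] = np.nan
            c2[0] = np.nan
        rows.append({"peptide": f"PEP{i:03d}", "charge": 2,
                     "tryptic": "half" if i % 2 else "full",
                     "cond1_r1": c1[0], "cond1_r2": c1[1], "cond1_r3": c1[2],
                     "cond2_r1": c2[0], "cond2_r2": c2[1], "cond2_r3": c2[2],
                     "intended_branch": branch,
                     "intended_significant": bool(has_effect and branch != "excluded")})
    df = pd.DataFrame(rows)
    gt = GroundTruth("gen_lipms_table",
                     {"n_features": n_features, "cv": cv,
                      "effect_log2": effect_log2,
                      "scenario_mix": list(scenario_mix)}, seed)
    return df, gt
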