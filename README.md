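# parfus

Coarse-grained simulation and analysis of poly(ADP-ribose)-triggered FUS
condensation.

PAR — the transient, nucleic-acid-like polymer that marks DNA damage — binds
the C-terminal arginine-rich region of the 526-residue protein FUS and
triggers its condensation into droplets that persist after PAR is degraded.
`parfus` provides the computational side of studying that process, for
researchers modelling biomolecular condensates at residue resolution:

- **Force field** (`parfus.params/potentials/topology`): a hybrid
  one-bead-per-residue model — Gō-like 12-10-6 native-contact potentials for
  the folded RRM and ZnF domains, the hydropathy-scale (HPS) model
  (Ashbaugh–Hatch vdW, V = Φ_LJ + (1−λ)ε inside the minimum and λΦ_LJ
  outside, plus Debye–Hückel electrostatics with κ⁻¹ = 0.304/√I nm) for the
  disordered regions, and a custom one-bead-per-ADP-ribose PAR model
  (bond 1.16 nm, charge −2 e/unit, σ = 1.5 nm, λ = 0.8).
- **Engine** (`parfus.engine`): seeded BAOAB Langevin dynamics, a z-only
  Monte Carlo barostat, the elongated-box slab protocol
  (setup → NVT → z-compression → production), and umbrella-restrained runs.
- **Condensate analytics** (`parfus.condensate`): single-linkage clustering
  of chain COMs (5 nm cutoff), slab centering, 60-bin density profiles,
  coexistence densities (|z| ≷ 50 nm), the critical-temperature fit
  ρ_H − ρ_L = A(T_c − T)^0.325, contact maps (1.2 nm), PAR frame-filtered
  contact profiles and with/without-PAR contact ratios.
- **Free energies** (`parfus.free_energy`): an MBAR solver, distance PMFs,
  and bound/unbound binding ΔG (10 nm cutoff) with 5-block uncertainty.
- **FRET calibration** (`parfus.fret`): E = 1/(1+(r/R₀)⁶) with R₀ = 5.9 nm,
  ensemble efficiencies from simulated PAR conformations, and the (σ, λ)
  grid calibration against per-length FRET data.
- **Experimental fits** (`parfus.expfits`, `parfus.lipms`): Hill/one-site
  binding, FRAP single-exponential recovery (mobile fraction = F_max − F_min,
  T₁/₂ = ln 2/k), FCS autocorrelation with confocal calibration
  (R_H = 0.81 nm · τ_D/τ_D,ref), global BLI kinetics (k_ob = k_on·L + k_off,
  K_D = k_off/k_on), CTCF, and the LiP-MS imputation / Welch /
  Fisher-combination / significance pipeline.
- **Synthetic data** (`parfus.synth`): seeded generators with ground-truth
  records for every input the pipeline consumes.

The numbered scripts under `analysis/` run the study end to end at desk
scale and write tables under `results/`; `docs/methods.md` documents the
model, defaults and limitations.

## Worked example

Calibrate the PAR model against (synthetic, ground-truth-known) per-length
FRET data, then run a reduced slab ladder and fit a critical temperature:

```bash
python analysis/02_calibrate_par.py          # ~1 min
python analysis/03_slab_condensation.py      # ~4 min
python analysis/04_critical_temperature.py
```

prints, among other lines:

```
optimum: sigma = 1.5 nm, lambda = 0.8 (grid of 25, converged=False)
T= 250.0 K  rho_L=   0.000  rho_H=  13.559 amu/nm^3
T= 410.0 K  rho_L=   5.266  rho_H=   8.293 amu/nm^3
synthetic: A=2.0000, Tc=400.00 K, 1%-noise CI coverage 91/100
slab data: Tc = 411.3 +- 1.8 K (5 temperatures)
```

Reading: the grid search recovers the generating PAR parameters
(σ = 1.5 nm, λ = 0.8) as the score-surface optimum (`converged=False` flags
that the reduced desk-scale sampling misses the 0.01 split-half convergence
bar — expected at this problem size); the 10-chain sticky-IDR slab shows a
dense slab coexisting with an empty dilute phase at 250 K whose contrast
erodes as temperature rises, and the scaling-law fit extrapolates that
ladder to this toy system's own critical point (411 K here is the [FL]₁₀
model's number, not a FUS prediction); the synthetic round trip recovers a
known (A, T_c) exactly on clean points with honest confidence intervals
under 1% noise. `analysis/05_umbrella_pmf.py` validates the MBAR PMF against
a declared harmonic surface (max deviation 0.096 kJ/mol at 20k samples per
window) and computes ΔG = −12.9 ± 3.4 kJ/mol for a PAR 16-mer binding an
arginine-glycine-rich [RGRGG]₄ peptide — attractive, as the charge
complementarity demands; `06`/`07` exercise the assay fits and the LiP-MS
rules.

The full production protocol — 100 FUS chains (52,760 beads with 10 PAR
16-mers), 5 μs slabs over 330–440 K, 30 μs umbrella windows — is the same
code path (`analysis/03_slab_condensation.py --full`) and is intended for
cluster hardware; its fitted critical temperatures belong in
`results/cluster/`.

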