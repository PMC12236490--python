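# Methods

`parfus` models the condensation of the RNA-binding protein FUS with
poly(ADP-ribose) (PAR) at one-bead-per-residue resolution and implements the
quantitative analyses that surround it: slab phase-coexistence simulation,
critical-temperature extrapolation, contact statistics, umbrella-sampling
thermodynamics, PAR-model calibration against smFRET data, and the standard
wet-lab curve fits (Hill, FRAP, FCS, BLI, CTCF, LiP-MS). Units are nm,
kJ/mol, ps, K and elementary charges throughout.

## Coarse-grained force field

**Disordered regions (HPS).** Each residue is one bead. Bonded: harmonic
bonds, k = 8033 kJ/(mol nm²), r₀ = 0.38 nm. Nonbonded: an Ashbaugh–Hatch
van der Waals term

    V(r) = Φ_LJ(r) + (1-λ)ε   for r ≤ 2^(1/6)σ
         = λ Φ_LJ(r)          otherwise,

with ε = 0.8368 kJ/mol and σ, λ the arithmetic means of per-residue values
(packaged table `residues_hps.csv`: σ from the standard HPS vdW diameters, λ
from the CALVADOS-family optimized hydropathy scale; the table is a CSV asset
and can be swapped wholesale). Charged beads (D, E −1; K, R +1) interact by
Debye–Hückel electrostatics, E = q_i q_j e²/(4πε₀ε_r r)·exp(−κr), ε_r = 80,
κ⁻¹ = 0.304/√I nm with I the molar ionic strength (default 0.1 M).

**Structured domains (Gō-like).** The RRM and ZnF keep their folds via a
native-structure-based model: harmonic bonds and angles at native geometry
(force constants 200·ε_res and 40·ε_res), sequence-keyed cosine-series
dihedrals (≤ 4 terms; the packaged coefficient table is a synthetic generic
stand-in — production work should substitute coefficients from a Gō-builder —
and a zero-dihedral variant is available as `zero_dihedrals=True`), a
12-10-6 native-contact potential
V = α·ε_ij [13(σ/r)¹² − 18(σ/r)¹⁰ + 4(σ/r)⁶] whose minimum is −α·ε_ij at the
native Cα–Cα distance (note the +4 coefficient: the form has a small
desolvation barrier beyond the minimum and decays to zero from above), and a
purely repulsive r⁻¹² term with scale 1.5×10⁻³·ε_res between all other
intra-domain pairs. ε_ij comes from a residue-pair contact-energy table; the
packaged default is a clearly-labelled synthetic stand-in with the structure
of knowledge-based contact potentials. ε_res = mean over contacts of α·ε_c;
α is the global scale that calibration against a 500 K folding midpoint
would set (the melting calibration itself is a cluster-scale exercise;
α defaults to 1).

Native contacts are detected from Cα coordinates at a 0.8 nm cutoff and only
at sequence separation ≥ 4 — pairs at separations 1–3 are governed by the
bond/angle/dihedral terms and excluded from nonbonded evaluation. Repulsive
radii use the distance to the closest non-contact residue (Cα metric,
separations ≥ 4; isolated residues fall back to 0.5 nm).

**Cross-model rule.** Beads inside one structured-domain instance interact
only through Gō terms. Every other pair — disordered–anything, cross-domain,
cross-chain, anything–PAR — uses the HPS vdW term with mean σ/λ plus
screened electrostatics on charged beads. This preserves each model's
internal calibration while giving all beads defined cross interactions.
Whether charges inside structured domains participate is switchable
(`go_domain_charges`, default on).

**PAR.** One bead per ADP-ribose unit: bond r₀ = 1.16 nm (monomer length),
k = 8033 kJ/(mol nm²), charge −2 e per unit (diphosphate), mass 709 amu,
and HPS nonbonded parameters σ = 1.5 nm, λ = 0.8 — the optimum of the
smFRET calibration below. Branched PAR and protein-conjugated PAR are out of
scope.

**Defaults the sources leave open** (chosen once, standard for this model
class): per-residue amino-acid masses; Langevin friction 0.01 ps⁻¹
(equilibrium observables are friction-independent; several test fixtures use
0.5–1 ps⁻¹ for faster decorrelation); vdW cutoff 4.0 nm and electrostatic
cutoff 3.5 nm (≥ 3 Debye lengths at 100 mM), truncated without shift;
FUS domain ranges from UniProt P35637 annotations, adjusted to a non-overlapping
full cover (PrLD 1–165, RGG1 166–284, RRM 285–371, RGG2 372–421, ZnF 422–453,
RGG3-PY 454–526).

## Engine

The reference integrator is BAOAB Langevin (velocity Verlet at zero
friction), dt = 10 fs default, compiled with numba; forces are plain O(N²)
loops with minimum-image periodicity, adequate for the desk-scale systems the
analyses run, and bit-reproducible for a fixed seed. The module defines the
trajectory schema so a high-performance backend can substitute it.

The slab protocol follows three stages: chains placed on a z-stacked lattice
of compact serpentine conformations in a 25 × 25 × 3500 nm box; 100 ns NVT at
250 K; 300 ns NPT at 250 K / 1 atm with an anisotropic Monte Carlo barostat
that proposes log-volume moves on z only (molecules rescaled by their centers
of mass, acceptance exp[−β(ΔU + PΔV − N_chains kT ln(V′/V))], amplitude
auto-tuned to ~40% acceptance, attempted every 25 steps — the attempt
schedule and amplitude are our choices); then NVT production in a
25 × 25 × 200 nm box, 5 μs per ladder temperature (330–420 K without PAR,
330–440 K with), frames every 100 ps. Desk-scale runs pass reduced
durations, compositions and boxes through the same code path.

Umbrella runs restrain the COM distance of two bead groups with
E = k/2 (r − r_eq)², k = 50 kJ/(mol nm²), 61 windows from 0 to 20 nm,
energy-minimized, equilibrated (100 ns) and sampled (30 μs production at
293.15 K in the full protocol).

## Condensate analytics

Per frame: single-linkage clustering of chain centers of mass (periodic
distances, dendrogram cutoff 5 nm; equals connected components of the
threshold graph and is tested against a union-find oracle), centering of the
largest cluster at z = 0 (periodic-aware COM via the circular mean on each
axis; size ties break to the cluster holding the lowest chain index), a
60-bin mass-density profile along z (number densities via a flag), and
ρ_L/ρ_H as plain averages of bin densities with |z| above/below 50 nm. The
second half of each trajectory is analyzed by default; frame-then-region
averaging is used (both orders are available).

Tc is fitted by (optionally weighted) least squares of ρ_H − ρ_L against
A(Tc − T)^β with β fixed at 0.325; points with ρ_H ≤ ρ_L are refused, the
(A, Tc) covariance is reported, and a free-β variant exists as a consistency
check.

Contacts use a 1.2 nm cutoff. The PAR-contact profile excludes, per FUS
molecule, the frames in which that molecule touches no PAR bead; per-residue
frequencies over the retained frames are then averaged across molecules.
Ratio maps use (f_with + p)/(f_without + p) with a one-observation
pseudo-count p = 1/n_frames by default.

## Umbrella thermodynamics

MBAR is solved as the convex objective
Φ(f) = Σ_n log Σ_k N_k exp(f_k − u_k(x_n)) − Σ_k N_k f_k by damped Newton
iterations (warm-started on a strided subsample; gradient residual < 1e-10;
the compiled kernel skips windows more than 46 log-units below the
per-sample softmax maximum, which is exact to double precision). The PMF is
the reweighted distance histogram, 0.25 nm bins by default, min-anchored at
zero; the r² phase-space factor is divided out by default (flag available).
Binding ΔG classifies configurations as bound (r < 10 nm) vs unbound using
the unbiased configuration weights: ΔG = −kT ln(P_bound/P_unbound), more
negative = tighter; no standard-state volume correction is applied (stated in
the report). Uncertainty: the first 1/6 of every window series is discarded
(mirroring the 25-of-30 μs convention) and ΔG is recomputed on 5 contiguous
blocks; the block SD is reported. The per-bin PMF error bars are local
(Kish effective sample size) and deliberately do not include the
window-to-window random-walk accumulation that dominates long-range PMF
differences; block analysis covers that for ΔG.

## PAR calibration against smFRET

FRET efficiency E(r) = 1/(1 + (r/R₀)⁶), R₀ = 5.9 nm. End-to-end distance is
the first-to-last bead distance (dye-linker offsets can be added via config).
Calibration simulates single PAR chains per length over a (σ, λ) grid
(default σ 1.0–2.0, λ 0.0–1.0, step 0.1), scores each grid point by the sum
of squared deviations between simulated and measured mean efficiencies
(least squares; the comparison metric was an open choice), reports the full
score surface, and breaks exact ties deterministically toward the smallest
(σ, λ). Default per-point sampling is 1 μs with the first 10% discarded and a
split-half convergence check at 0.01.

Simulation seeds are derived per chain length from the base seed and shared
across grid points (common random numbers). This keeps the score surface
smooth at reduced sampling: single-chain end-to-end dynamics interconvert
slowly between compact and extended states, so independent short runs carry
ensemble noise far larger than the (σ, λ) signal, while CRN differences
cancel most of it. Desk-scale recovery tests therefore run the generator and
the search from the same base seed (exact self-consistency at the truth
point); calibrating against real data still requires production-length
sampling.

## Experimental-curve fits

All nonlinear fits are trust-region least squares with 5 seeded multi-starts
and asymptotic standard errors. Hill: R = bottom + (top−bottom)·Cⁿ/(K_Dⁿ+Cⁿ),
with a one-site variant (n ≡ 1) selectable — both appear in the source
assays; Hill is the default. FRAP: F(t) = F_min + (F_max−F_min)(1−e^{−kt}),
mobile fraction F_max − F_min, T₁/₂ = ln 2/k; a normalization helper does
background subtraction then pre-bleach division. FCS:
G(τ) = G₀(1+τ/τ_D)⁻¹(1+τ/(ω²τ_D))^{−1/2}; ω² is fitted once on a reference
dye curve (D = 241 μm²/s fixes the lateral radius via D = r²/4τ_D) and then
held; hydrodynamic radii scale as R_H = 0.81 nm · τ_D/τ_D,ref. BLI: global
fit across analyte concentrations of Y = [L/(L+K_D)]·B_max·(1−e^{−(k_on L +
k_off)t}) with shared k_on, k_off, B_max (log-parameterized); flat k_ob vs L
is flagged non-identifiable, and an independent per-concentration
k_ob + linear-regression route is provided as a cross-check.
CTCF = integrated density − ROI area × mean background.

LiP-MS: features are (peptide, charge) rows with 3+3 injections. Imputation:
one missing value of six → dropped; all three of one condition missing with
the other complete → replaced by the 1000-count detection limit; any other
missingness → feature excluded. Effects are log2(cond2/cond1) means;
significance per feature is a two-sided Welch t-test (two-sided was an open
choice; no multiple-testing correction, matching the stated thresholds).
Charge states of a peptide consolidate by median effect and Fisher-combined
p-values when all effects share a sign, otherwise p = 1. Significant:
|log2FC| > 1 and −log10 p > 1.3 (strict inequalities).

## Synthetic data

Every generator evaluates its forward model directly, is deterministic under
a seed, and writes a GroundTruth record. They emulate: per-length PAR FRET
efficiencies (the forward simulation itself — calibration is then exact
self-consistency, see above); two-plateau slab configurations with known
cluster structure; coexistence points following the scaling law exactly
before multiplicative Gaussian noise; umbrella window samples drawn by
inverse-CDF sampling from the biased Boltzmann density (with or without the
r² Jacobian) on a fine grid; assay curves with Gaussian noise
(heteroscedastic for FCS, growing at small lag); and LiP-MS tables covering
every imputation branch with intended calls recorded. What they do not
emulate: instrument baselines and drift, photophysics, correlated noise,
detector saturation, real missingness mechanisms, or sequence-dependent
protease accessibility — passing recovery tests demonstrates correctness of
the estimators under their stated models, not robustness to real-data
pathology.

## Problem sizes used by the test suite

The suite runs everything at desk scale, as its own choice of problem size:
pair/contact oracles on ≤ 50 beads; PAR bond statistics over 11 ns of a
16-mer; calibration round trip on a 5×5 (σ, λ) subgrid, lengths 6–12,
150k steps per point; MBAR validation with 61 windows × 120k i.i.d. samples;
condensation contrast on ten 20-mer sticky IDR chains ([FL]₁₀) in an
8 × 8 × 300 → 60 nm slab, ~1 ns per ladder temperature, with the critical
point estimated from a 3-temperature ladder and the "above-Tc" run at twice
that estimate. The full production protocol (100 × 526-bead FUS chains,
5 μs slabs, 30 μs windows, the 500 K folding-midpoint calibration of α) is
implemented and constructible — the 52,760-bead system builds and validates —
but generating those trajectories is cluster-scale work; the corresponding
acceptance check consumes cluster-run outputs from `results/cluster/` and
fails with an explanatory message until they exist.

## Known limitations

- The packaged contact-energy and dihedral tables are synthetic stand-ins
  (labelled as such); quantitative folded-domain energetics require the
  published tables.
- O(N²) nonbonded evaluation: fine to ~10³ beads on one core; the full slab
  composition needs a faster backend behind the engine contract.
- No replica exchange, no x/y pressure coupling, no interfacial-tension
  analysis, no autocorrelation-based statistical-inefficiency correction
  beyond block analysis.
- Electrostatics inside structured domains, the bound/unbound volume
  convention, and profile-averaging order are documented switches rather than
  single fixed choices, because the sources leave them open.
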