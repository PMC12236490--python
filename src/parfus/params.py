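"""Force-field parameter containers and parameter-table assets.

The hybrid model represents each amino acid (and each ADP-ribose unit of
poly(ADP-ribose), PAR) by a single bead. Disordered regions use the
hydropathy-scale (HPS) model: an Ashbaugh–Hatch van der Waals term scaled by a
per-residue hydropathy ``lambda`` plus Debye–Hückel screened electrostatics.
Structured domains use a native-structure-based (Gō-like) model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .constants import DEBYE_PREFACTOR_NM


def _data_path(name: str):
    return resources.files("parfus.data").joinpath(name)


@dataclass(frozen=True)
class ResidueParams:
    """Per-residue bead parameters: size, hydropathy, charge, mass."""

    name: str
    sigma: float  # nm
    lam: float    # dimensionless hydropathy
    charge: float  # e
    mass: float   # amu

    def __post_init__(self):
        if not self.sigma > 0:
            raise ValueError(f"sigma must be positive, got {self.sigma}")
        if not math.isfinite(self.lam):
            raise ValueError("lambda must be finite")


def load_residue_table(path=None) -> dict[str, ResidueParams]:
    """Load the per-residue HPS parameter table (all 20 amino acids)."""
    if path is None:
        path = _data_path("residues_hps.csv")
    df = pd.read_csv(path, comment="#")
    table = {
        row["name"]: ResidueParams(row["name"], row.sigma, row.lam, row.charge, row.mass)
        for _, row in df.iterrows()
    }
    missing = set("ACDEFGHIKLMNPQRSTVWY") - set(table)
    if missing:
        raise ValueError(f"residue table incomplete, missing {sorted(missing)}")
    return table


def load_contact_energy_table(path=None) -> dict[tuple[str, str], float]:
    """Residue-pair contact energies (kJ/mol) for native-contact strengths.

    The packaged default is a synthetic stand-in table (see its header); any
    CSV with columns res_i,res_j,eps may be substituted.
    """
    if path is None:
        path = _data_path("synthetic_mj_contact_energies.csv")
    df = pd.read_csv(path, comment="#")
    out: dict[tuple[str, str], float] = {}
    for _, row in df.iterrows():
        out[(row.res_i, row.res_j)] = float(row.eps)
        out[(row.res_j, row.res_i)] = float(row.eps)
    return out


def load_dihedral_table(path=None) -> dict[str, list[tuple[int, float, float]]]:
    """Cosine-series dihedral coefficients keyed by residue-pair type.

    Each entry is a list of (n, k_n, delta_n) with V(phi) = sum k_n (1 + cos(n phi - delta_n)),
    at most 4 terms. The key ``default`` applies to any pair type not listed.
    """
    if path is None:
        path = _data_path("dihedral_coeffs_synthetic.csv")
    df = pd.read_csv(path, comment="#")
    out: dict[str, list[tuple[int, float, float]]] = {}
    for _, row in df.iterrows():
        out.setdefault(row["pair"], []).append((int(row.n), float(row.k), float(row.delta)))
    for key, terms in out.items():
        if len(terms) > 4:
            raise ValueError(f"dihedral series for {key!r} has more than 4 terms")
    return out


def debye_length(ionic_strength: float) -> float:
    """Debye screening length in nm: kappa^-1 = 0.304 / sqrt(I), I in molar."""
    if ionic_strength <= 0:
        raise ValueError(f"ionic strength must be positive, got {ionic_strength}")
    return DEBYE_PREFACTOR_NM / math.sqrt(ionic_strength)


@dataclass
class HpsParams:
    """Global HPS-model parameters.

    eps_lj is the Ashbaugh–Hatch energy scale, eps_r the relative dielectric,
    ionic_strength sets the Debye screening length (recomputed on access).
    """

    eps_lj: float = 0.8368          # kJ/mol
    eps_r: float = 80.0
    ionic_strength: float = 0.1     # M
    bond_k: float = 8033.0          # kJ/(mol nm^2)
    bond_r0: float = 0.38           # nm
    cutoff_vdw: float = 4.0         # nm
    cutoff_elec: float = 3.5        # nm

    def __post_init__(self):
        for name in ("eps_lj", "eps_r", "ionic_strength", "bond_k", "bond_r0"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def kappa(self) -> float:
        """Inverse Debye length, 1/nm (tracks ionic_strength)."""
        return 1.0 / debye_length(self.ionic_strength)


@dataclass
class ParParams:
    """One-bead-per-ADP-ribose PAR model, calibrated against smFRET data.

    Defaults are the optimized model: sigma 1.5 nm, lambda 0.8, bond length
    1.16 nm (monomeric ADP-ribose length), charge -2 e per unit (diphosphate).
    """

    bond_r0: float = 1.16      # nm
    bond_k: float = 8033.0     # kJ/(mol nm^2)
    charge: float = -2.0       # e per unit
    sigma: float = 1.5         # nm
    lam: float = 0.8
    mass: float = 709.0        # amu per ADP-ribose bead
    n_units: int = 16

    def __post_init__(self):
        if self.n_units < 1:
            raise ValueError("n_units must be >= 1")


@dataclass
class GoModelParams:
    """Gō-like model parameters for a structured domain.

    ``native_contacts`` holds (i, j, sigma_ij, eps_ij) with sigma_ij the native
    Ca–Ca distance and eps_ij a residue-pair contact energy; ``alpha`` scales
    every native contact and is calibrated to a target folding temperature.
    The derived per-residue scale eps_res = mean(alpha * eps_c) sets the bond
    (200 eps_res), angle (40 eps_res) and repulsive (1.5e-3 eps_res) scales.
    """

    native_contacts: list = field(default_factory=list)  # (i, j, sigma_ij, eps_ij)
    alpha: float = 1.0
    repulsive_radii: np.ndarray | None = None  # nm, per residue
    bond_k_factor: float = 200.0
    angle_k_factor: float = 40.0
    repulsive_eps_factor: float = 1.5e-3
    folding_temp_target: float = 500.0  # K

    @property
    def eps_res(self) -> float:
        """Native-contact energy per residue: mean over contacts of alpha*eps_c."""
        if not self.native_contacts:
            return 0.0
        return self.alpha * float(np.mean([c[3] for c in self.native_contacts]))
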