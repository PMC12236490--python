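"""Coarse-grained topology construction for FUS, PAR and arbitrary IDR chains.

A :class:`CGSystem` stores one bead per residue (or per ADP-ribose unit),
bonded terms, and the nonbonded classification of every bead pair:

* ``go_native`` – native-contact pairs inside a structured domain (12-10-6),
* ``go_repulsive`` – all other pairs inside the same structured domain,
* ``hps`` – every remaining pair (disordered–anything, cross-domain,
  cross-chain, PAR): Ashbaugh–Hatch vdW plus Debye–Hückel on charged beads,
* ``excluded`` – pairs already covered by bonded terms.

Beads inside one structured domain interact only through Gō terms, which
preserves the native-structure calibration; every other pair falls back to the
hydropathy-scale model so that all beads have defined cross interactions.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import yaml
from Bio import SeqIO
from Bio.PDB import PDBParser

from .params import (GoModelParams, HpsParams, ParParams, ResidueParams,
                     load_contact_energy_table, load_dihedral_table,
                     load_residue_table, _data_path)

PAR_LABEL = "PAR"


def _pair_key(i: int, j: int) -> int:
    a, b = (i, j) if i < j else (j, i)
    return a * (1 << 32) + b


@dataclass
class CGSystem:
    """Topology + per-bead parameters of a coarse-grained system (no coordinates)."""

    # per-bead arrays
    chain_id: np.ndarray          # int
    domain_label: list            # str per bead
    struct_domain_id: np.ndarray  # int, -1 for beads outside structured domains
    residue: list                 # 1-letter code or 'ADP'
    sigma: np.ndarray             # nm (HPS size)
    lam: np.ndarray               # hydropathy
    charge: np.ndarray            # e
    mass: np.ndarray              # amu
    rep_radius: np.ndarray        # nm, Gō repulsive radius (0 where unused)
    eps_res: np.ndarray           # kJ/mol, per-bead native-contact energy scale

    # bonded terms
    bonds: np.ndarray             # (nb, 2) int
    bond_r0: np.ndarray
    bond_k: np.ndarray
    angles: np.ndarray = field(default_factory=lambda: np.zeros((0, 3), dtype=np.int64))
    angle_theta0: np.ndarray = field(default_factory=lambda: np.zeros(0))
    angle_k: np.ndarray = field(default_factory=lambda: np.zeros(0))
    dihedrals: np.ndarray = field(default_factory=lambda: np.zeros((0, 4), dtype=np.int64))
    dihedral_k: np.ndarray = field(default_factory=lambda: np.zeros((0, 4)))
    dihedral_delta: np.ndarray = field(default_factory=lambda: np.zeros((0, 4)))
    dihedral_n: np.ndarray = field(default_factory=lambda: np.zeros((0, 4), dtype=np.int64))

    # native contacts (global bead indices)
    native_pairs: np.ndarray = field(default_factory=lambda: np.zeros((0, 2), dtype=np.int64))
    native_sigma: np.ndarray = field(default_factory=lambda: np.zeros(0))
    native_eps: np.ndarray = field(default_factory=lambda: np.zeros(0))  # alpha * eps_ij

    hps: HpsParams = field(default_factory=HpsParams)
    go: GoModelParams | None = None
    box: np.ndarray | None = None  # (3,) nm or None for non-periodic

    def __post_init__(self):
        self.chain_id = np.asarray(self.chain_id, dtype=np.int64)
        n = self.n_beads
        for name in ("sigma", "lam", "charge", "mass", "rep_radius", "eps_res"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (n,):
                raise ValueError(f"{name} must have shape ({n},)")
            setattr(self, name, arr)
        self._rebuild_pair_index()

    # -- derived indexes -------------------------------------------------
    def _rebuild_pair_index(self):
        excl = set()
        for i, j in self.bonds:
            excl.add(_pair_key(int(i), int(j)))
        for i, _, k in self.angles:
            excl.add(_pair_key(int(i), int(k)))
        for i, _, _, l in self.dihedrals:
            excl.add(_pair_key(int(i), int(l)))
        self._excluded_keys = np.array(sorted(excl), dtype=np.int64)
        # the engine assumes bonded exclusions span at most 3 positions
        for i, j in self.bonds:
            if abs(int(i) - int(j)) > 3:
                raise ValueError("bonds must connect beads within 3 positions")
        nk = sorted(_pair_key(int(i), int(j)) for i, j in self.native_pairs)
        self._native_keys = np.array(nk, dtype=np.int64)
        if len(set(nk)) != len(nk):
            raise ValueError("duplicate native-contact pair")

    @property
    def n_beads(self) -> int:
        return len(self.chain_id)

    @property
    def n_chains(self) -> int:
        return len(np.unique(self.chain_id))

    def _in_sorted(self, key: int, arr: np.ndarray) -> bool:
        idx = np.searchsorted(arr, key)
        return idx < len(arr) and arr[idx] == key

    def pair_rule(self, i: int, j: int) -> str:
        """Nonbonded rule for bead pair (i, j): one of excluded / go_native /
        go_repulsive / hps. Every pair maps to exactly one rule."""
        if i == j:
            raise ValueError("pair requires distinct beads")
        key = _pair_key(i, j)
        if self._in_sorted(key, self._excluded_keys):
            return "excluded"
        if self._in_sorted(key, self._native_keys):
            return "go_native"
        same_domain = (self.struct_domain_id[i] >= 0
                       and self.struct_domain_id[i] == self.struct_domain_id[j])
        if same_domain:
            return "go_repulsive"
        return "hps"

    def domain_indices(self, label: str, chain: int | None = None) -> np.ndarray:
        """Global bead indices carrying a domain label (optionally one chain)."""
        idx = [k for k, lab in enumerate(self.domain_label)
               if lab == label and (chain is None or self.chain_id[k] == chain)]
        if not idx:
            raise KeyError(f"no beads labelled {label!r}")
        return np.asarray(idx, dtype=np.int64)

    # -- serialization ---------------------------------------------------
    def to_json(self, path):
        def arr(a):
            return np.asarray(a).tolist()
        payload = {
            "schema": "parfus.CGSystem/1",
            "chain_id": arr(self.chain_id), "domain_label": self.domain_label,
            "struct_domain_id": arr(self.struct_domain_id), "residue": self.residue,
            "sigma": arr(self.sigma), "lam": arr(self.lam), "charge": arr(self.charge),
            "mass": arr(self.mass), "rep_radius": arr(self.rep_radius),
            "eps_res": arr(self.eps_res),
            "bonds": arr(self.bonds), "bond_r0": arr(self.bond_r0), "bond_k": arr(self.bond_k),
            "angles": arr(self.angles), "angle_theta0": arr(self.angle_theta0),
            "angle_k": arr(self.angle_k),
            "dihedrals": arr(self.dihedrals), "dihedral_k": arr(self.dihedral_k),
            "dihedral_delta": arr(self.dihedral_delta), "dihedral_n": arr(self.dihedral_n),
            "native_pairs": arr(self.native_pairs), "native_sigma": arr(self.native_sigma),
            "native_eps": arr(self.native_eps),
            "hps": vars(self.hps).copy(),
            "box": None if self.box is None else arr(self.box),
        }
        with open(path, "w") as f:
            json.dump(payload, f)

    @classmethod
    def from_json(cls, path) -> "CGSystem":
        with open(path) as f:
            d = json.load(f)
        if d.get("schema") != "parfus.CGSystem/1":
            raise ValueError("unrecognized CGSystem schema")
        def ia(x, shape=None):
            a = np.asarray(x, dtype=np.int64)
            return a.reshape(shape) if shape and a.size == 0 else a
        return cls(
            chain_id=ia(d["chain_id"]), domain_label=d["domain_label"],
            struct_domain_id=ia(d["struct_domain_id"]), residue=d["residue"],
            sigma=np.asarray(d["sigma"]), lam=np.asarray(d["lam"]),
            charge=np.asarray(d["charge"]), mass=np.asarray(d["mass"]),
            rep_radius=np.asarray(d["rep_radius"]), eps_res=np.asarray(d["eps_res"]),
            bonds=ia(d["bonds"], (0, 2)), bond_r0=np.asarray(d["bond_r0"]),
            bond_k=np.asarray(d["bond_k"]),
            angles=ia(d["angles"], (0, 3)), angle_theta0=np.asarray(d["angle_theta0"]),
            angle_k=np.asarray(d["angle_k"]),
            dihedrals=ia(d["dihedrals"], (0, 4)),
            dihedral_k=np.asarray(d["dihedral_k"]).reshape(-1, 4),
            dihedral_delta=np.asarray(d["dihedral_delta"]).reshape(-1, 4),
            dihedral_n=ia(d["dihedral_n"], (0, 4)).reshape(-1, 4),
            native_pairs=ia(d["native_pairs"], (0, 2)),
            native_sigma=np.asarray(d["native_sigma"]), native_eps=np.asarray(d["native_eps"]),
            hps=HpsParams(**d["hps"]),
            box=None if d["box"] is None else np.asarray(d["box"]),
        )


# ---------------------------------------------------------------------------
# builders
# ---------------------------------------------------------------------------

def read_fasta_sequence(path) -> str:
    record = next(SeqIO.parse(str(path), "fasta"))
    return str(record.seq)


def read_ca_coordinates(path, chain: str | None = None) -> np.ndarray:
    """Read Ca coordinates (nm) from a PDB file, in residue order."""
    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("s", str(path))
    coords = []
    for model in structure:
        for ch in model:
            if chain is not None and ch.id != chain:
                continue
            for res in ch:
                if "CA" in res:
                    coords.append(res["CA"].get_coord())
        break
    return np.asarray(coords, dtype=float) / 10.0  # Angstrom -> nm


def load_fus_assets():
    """Packaged FUS sequence (UniProt P35637, 526 aa) and domain ranges."""
    seq = read_fasta_sequence(_data_path("fus_p35637.fasta"))
    with open(_data_path("fus_domains.yaml")) as f:
        cfg = yaml.safe_load(f)
    return seq, cfg


def detect_native_contacts(coords: np.ndarray, cutoff: float = 0.8,
                           min_separation: int = 2):
    """Native contacts from Ca coordinates: pairs within ``cutoff`` nm whose
    sequence separation is at least ``min_separation`` (pairs separated by
    fewer than two positions are never contacts)."""
    n = len(coords)
    contacts = []
    for i in range(n):
        for j in range(i + min_separation, n):
            d = float(np.linalg.norm(coords[i] - coords[j]))
            if d < cutoff:
                contacts.append((i, j, d))
    return contacts


def repulsive_radii(coords: np.ndarray, contacts, min_separation: int = 4) -> np.ndarray:
    """Per-residue repulsive radius: distance to the closest residue that is
    not in native contact (Ca distances; sequence neighbours within the bonded
    span are not counted)."""
    n = len(coords)
    in_contact = {(_pair_key(i, j)) for i, j, _ in contacts}
    radii = np.full(n, np.inf)
    for i in range(n):
        for j in range(n):
            if abs(i - j) < min_separation:
                continue
            if _pair_key(i, j) in in_contact:
                continue
            d = float(np.linalg.norm(coords[i] - coords[j]))
            radii[i] = min(radii[i], d)
    # lone/fully-connected residues: fall back to a typical Ca exclusion size
    radii[~np.isfinite(radii)] = 0.5
    return radii


def _bond_geometry(coords):
    """Bond lengths, angles (radians) and dihedrals along a chain."""
    vecs = np.diff(coords, axis=0)
    lengths = np.linalg.norm(vecs, axis=1)
    angles = []
    for k in range(len(vecs) - 1):
        a, b = -vecs[k], vecs[k + 1]
        cosang = np.dot(a, b) / (np.linalg.norm(a) * np.linalg.norm(b))
        angles.append(math.acos(np.clip(-cosang, -1.0, 1.0)))
    return lengths, np.asarray(angles)


def build_idr_topology(sequence: str, residue_table=None, hps: HpsParams | None = None,
                       label: str = "IDR", box=None) -> CGSystem:
    """One HPS bead per residue, consecutive beads bonded; no Gō terms."""
    residue_table = residue_table or load_residue_table()
    hps = hps or HpsParams()
    n = len(sequence)
    try:
        params = [residue_table[a] for a in sequence]
    except KeyError as e:
        raise KeyError(f"residue {e.args[0]!r} not in parameter table") from None
    bonds = np.column_stack([np.arange(n - 1), np.arange(1, n)]).astype(np.int64)
    return CGSystem(
        chain_id=np.zeros(n, dtype=np.int64), domain_label=[label] * n,
        struct_domain_id=np.full(n, -1, dtype=np.int64), residue=list(sequence),
        sigma=np.array([p.sigma for p in params]), lam=np.array([p.lam for p in params]),
        charge=np.array([p.charge for p in params]), mass=np.array([p.mass for p in params]),
        rep_radius=np.zeros(n), eps_res=np.zeros(n),
        bonds=bonds, bond_r0=np.full(n - 1, hps.bond_r0), bond_k=np.full(n - 1, hps.bond_k),
        hps=hps, box=None if box is None else np.asarray(box, dtype=float),
    )


def build_par_topology(n_units: int | None = None, params: ParParams | None = None,
                       hps: HpsParams | None = None, box=None) -> CGSystem:
    """One bead per ADP-ribose unit, harmonic bonds at 1.16 nm, charge -2 e
    per bead; nonbonded interactions are HPS (mean sigma/lambda combining
    rule) plus screened electrostatics."""
    params = params or ParParams()
    if n_units is None:
        n_units = params.n_units
    if n_units < 1:
        raise ValueError("n_units must be >= 1")
    hps = hps or HpsParams()
    n = n_units
    bonds = np.column_stack([np.arange(n - 1), np.arange(1, n)]).astype(np.int64)
    return CGSystem(
        chain_id=np.zeros(n, dtype=np.int64), domain_label=[PAR_LABEL] * n,
        struct_domain_id=np.full(n, -1, dtype=np.int64), residue=["ADP"] * n,
        sigma=np.full(n, params.sigma), lam=np.full(n, params.lam),
        charge=np.full(n, params.charge), mass=np.full(n, params.mass),
        rep_radius=np.zeros(n), eps_res=np.zeros(n),
        bonds=bonds, bond_r0=np.full(n - 1, params.bond_r0),
        bond_k=np.full(n - 1, params.bond_k),
        hps=hps, box=None if box is None else np.asarray(box, dtype=float),
    )


def build_fus_topology(sequence: str | None = None, domain_map: dict | None = None,
                       native_structures: dict | None = None,
                       residue_table=None, hps: HpsParams | None = None,
                       go: GoModelParams | None = None,
                       contact_table=None, dihedral_table=None,
                       contact_cutoff: float = 0.8,
                       go_domain_charges: bool = True,
                       zero_dihedrals: bool = False, box=None) -> CGSystem:
    """Hybrid FUS topology: Gō-like structured domains + HPS disordered regions.

    Parameters
    ----------
    sequence, domain_map
        Defaults to the packaged 526-residue FUS sequence and UniProt-derived
        domain ranges. ``domain_map`` maps label -> {start, end, kind} with
        1-based inclusive ranges covering the sequence without overlap.
    native_structures
        label -> (n_dom, 3) Ca coordinates (nm) for every structured domain.
    go_domain_charges
        If False, charges of beads inside structured domains are zeroed (they
        then carry no electrostatics even in cross-domain HPS pairs).
    zero_dihedrals
        Replace the statistical dihedral series by zeros (test variant; the
        returned system is flagged via zero dihedral_k rows).
    """
    if sequence is None or domain_map is None:
        pkg_seq, cfg = load_fus_assets()
        sequence = sequence or pkg_seq
        domain_map = domain_map or cfg["domains"]
    residue_table = residue_table or load_residue_table()
    hps = hps or HpsParams()
    go = go or GoModelParams()
    contact_table = contact_table or load_contact_energy_table()
    dihedral_table = dihedral_table or load_dihedral_table()

    n = len(sequence)
    covered = np.zeros(n, dtype=bool)
    labels = [None] * n
    kinds = {}
    for lab, rng in domain_map.items():
        s, e = rng["start"] - 1, rng["end"]
        if covered[s:e].any():
            raise ValueError(f"domain map overlaps at {lab}")
        covered[s:e] = True
        kinds[lab] = rng.get("kind", "disordered")
        for k in range(s, e):
            labels[k] = lab
    if not covered.all():
        raise ValueError("domain map does not cover the sequence")

    try:
        params = [residue_table[a] for a in sequence]
    except KeyError as e:
        raise KeyError(f"residue {e.args[0]!r} not in parameter table") from None

    struct_domain_id = np.full(n, -1, dtype=np.int64)
    rep_radius = np.zeros(n)
    eps_res_arr = np.zeros(n)
    charge = np.array([p.mass * 0 + p.charge for p in params])

    bonds, bond_r0, bond_k = [], [], []
    angles, angle_theta0, angle_k = [], [], []
    dihedrals, dih_k, dih_delta, dih_n = [], [], [], []
    native_pairs, native_sigma, native_eps = [], [], []

    # backbone bonds: HPS defaults everywhere, overridden inside Gō domains
    for i in range(n - 1):
        bonds.append((i, i + 1))
        bond_r0.append(hps.bond_r0)
        bond_k.append(hps.bond_k)

    structured = [lab for lab in domain_map if kinds[lab] == "structured"]
    for dom_idx, lab in enumerate(structured):
        rng = domain_map[lab]
        s, e = rng["start"] - 1, rng["end"]
        if native_structures is None or lab not in native_structures:
            raise ValueError(f"missing native structure for structured domain {lab!r}")
        coords = np.asarray(native_structures[lab], dtype=float)
        ndom = e - s
        if len(coords) != ndom:
            raise ValueError(f"native structure for {lab!r} has {len(coords)} residues,"
                             f" domain spans {ndom}")
        struct_domain_id[s:e] = dom_idx

        # pairs separated by <= 3 positions are governed by the bonded
        # bond/angle/dihedral terms; native contacts start at separation 4
        contacts = detect_native_contacts(coords, cutoff=contact_cutoff,
                                          min_separation=4)
        eps_c = [contact_table[(sequence[s + i], sequence[s + j])] for i, j, _ in contacts]
        eps_res = go.alpha * float(np.mean(eps_c)) if contacts else 0.0
        eps_res_arr[s:e] = eps_res
        rep_radius[s:e] = repulsive_radii(coords, contacts)
        for (i, j, d), ec in zip(contacts, eps_c):
            native_pairs.append((s + i, s + j))
            native_sigma.append(d)
            native_eps.append(go.alpha * ec)

        # native-geometry bonds and angles, Gō force constants
        lengths, thetas = _bond_geometry(coords)
        for i in range(ndom - 1):
            bond_r0[s + i] = float(lengths[i])
            bond_k[s + i] = go.bond_k_factor * eps_res
        for i in range(ndom - 2):
            angles.append((s + i, s + i + 1, s + i + 2))
            angle_theta0.append(float(thetas[i]))
            angle_k.append(go.angle_k_factor * eps_res)
        for i in range(ndom - 3):
            quad = (s + i, s + i + 1, s + i + 2, s + i + 3)
            key = sequence[s + i + 1] + sequence[s + i + 2]
            terms = dihedral_table.get(key, dihedral_table["default"])
            kk = np.zeros(4); dd = np.zeros(4); nn = np.zeros(4, dtype=np.int64)
            for t, (order, kval, delta) in enumerate(terms[:4]):
                nn[t], kk[t], dd[t] = order, (0.0 if zero_dihedrals else kval), delta
            dihedrals.append(quad)
            dih_k.append(kk); dih_delta.append(dd); dih_n.append(nn)

    if not go_domain_charges:
        charge[struct_domain_id >= 0] = 0.0

    return CGSystem(
        chain_id=np.zeros(n, dtype=np.int64), domain_label=labels,
        struct_domain_id=struct_domain_id, residue=list(sequence),
        sigma=np.array([p.sigma for p in params]), lam=np.array([p.lam for p in params]),
        charge=charge, mass=np.array([p.mass for p in params]),
        rep_radius=rep_radius, eps_res=eps_res_arr,
        bonds=np.asarray(bonds, dtype=np.int64), bond_r0=np.asarray(bond_r0),
        bond_k=np.asarray(bond_k),
        angles=(np.asarray(angles, dtype=np.int64) if angles
                else np.zeros((0, 3), dtype=np.int64)),
        angle_theta0=np.asarray(angle_theta0), angle_k=np.asarray(angle_k),
        dihedrals=(np.asarray(dihedrals, dtype=np.int64) if dihedrals
                   else np.zeros((0, 4), dtype=np.int64)),
        dihedral_k=(np.asarray(dih_k) if dih_k else np.zeros((0, 4))),
        dihedral_delta=(np.asarray(dih_delta) if dih_delta else np.zeros((0, 4))),
        dihedral_n=(np.asarray(dih_n, dtype=np.int64) if dih_n
                    else np.zeros((0, 4), dtype=np.int64)),
        native_pairs=(np.asarray(native_pairs, dtype=np.int64) if native_pairs
                      else np.zeros((0, 2), dtype=np.int64)),
        native_sigma=np.asarray(native_sigma), native_eps=np.asarray(native_eps),
        hps=hps, go=go, box=None if box is None else np.asarray(box, dtype=float),
    )


def combine_systems(systems: list[CGSystem], counts: list[int] | None = None,
                    box=None) -> CGSystem:
    """Concatenate (optionally replicated) single-chain systems into one
    multi-chain system with renumbered chain ids and shifted indices."""
    if counts is None:
        counts = [1] * len(systems)
    parts = []
    for sys_, c in zip(systems, counts):
        parts.extend([sys_] * c)
    if not parts:
        raise ValueError("empty composition")

    offset, chain_off, dom_off = 0, 0, 0
    fields = {k: [] for k in ("chain_id", "domain_label", "struct_domain_id", "residue",
                              "sigma", "lam", "charge", "mass", "rep_radius", "eps_res",
                              "bonds", "bond_r0", "bond_k", "angles", "angle_theta0",
                              "angle_k", "dihedrals", "dihedral_k", "dihedral_delta",
                              "dihedral_n", "native_pairs", "native_sigma", "native_eps")}
    for s in parts:
        fields["chain_id"].append(s.chain_id + chain_off)
        fields["domain_label"].extend(s.domain_label)
        sd = s.struct_domain_id.copy()
        sd[sd >= 0] += dom_off
        fields["struct_domain_id"].append(sd)
        fields["residue"].extend(s.residue)
        for k in ("sigma", "lam", "charge", "mass", "rep_radius", "eps_res",
                  "bond_r0", "bond_k", "angle_theta0", "angle_k",
                  "native_sigma", "native_eps"):
            fields[k].append(getattr(s, k))
        for k in ("bonds", "angles", "dihedrals", "native_pairs"):
            fields[k].append(getattr(s, k) + offset)
        for k in ("dihedral_k", "dihedral_delta", "dihedral_n"):
            fields[k].append(getattr(s, k))
        offset += s.n_beads
        chain_off += s.n_chains
        if (s.struct_domain_id >= 0).any():
            dom_off += int(s.struct_domain_id.max()) + 1

    def cat(key, shape):
        arrs = [a for a in fields[key] if len(a)]
        if not arrs:
            dtype = np.int64 if key in ("bonds", "angles", "dihedrals",
                                        "native_pairs", "dihedral_n") else float
            return np.zeros(shape, dtype=dtype)
        return np.concatenate(arrs, axis=0)

    return CGSystem(
        chain_id=np.concatenate(fields["chain_id"]),
        domain_label=fields["domain_label"],
        struct_domain_id=np.concatenate(fields["struct_domain_id"]),
        residue=fields["residue"],
        sigma=cat("sigma", (0,)), lam=cat("lam", (0,)), charge=cat("charge", (0,)),
        mass=cat("mass", (0,)), rep_radius=cat("rep_radius", (0,)),
        eps_res=cat("eps_res", (0,)),
        bonds=cat("bonds", (0, 2)), bond_r0=cat("bond_r0", (0,)), bond_k=cat("bond_k", (0,)),
        angles=cat("angles", (0, 3)), angle_theta0=cat("angle_theta0", (0,)),
        angle_k=cat("angle_k", (0,)),
        dihedrals=cat("dihedrals", (0, 4)),
        dihedral_k=cat("dihedral_k", (0, 4)), dihedral_delta=cat("dihedral_delta", (0, 4)),
        dihedral_n=cat("dihedral_n", (0, 4)),
        native_pairs=cat("native_pairs", (0, 2)), native_sigma=cat("native_sigma", (0,)),
        native_eps=cat("native_eps", (0,)),
        hps=parts[0].hps, go=parts[0].go,
        box=None if box is None else np.asarray(box, dtype=float),
    )
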