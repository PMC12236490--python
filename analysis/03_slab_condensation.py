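"""Run the three-stage slab condensation protocol and extract density
profiles and coexistence densities across a temperature ladder.

Default: a desk-scale 10-chain sticky-IDR system (minutes). --full switches
to the production composition (100 FUS + 10 PAR 16-mers, 25 x 25 x 3500 nm
setup box, 5 us production per temperature) intended for cluster hardware;
its per-temperature outputs feed 04_critical_temperature.py, and the fitted
Tc values belong in results/cluster/tc_fus(.par).json.

Writes results/slab/{profiles.csv, coexistence.csv}.
"""

import argparse
import pathlib
import sys

import numpy as np
import pandas as pd

ROOT = pathlib.Path(__file__).resolve().parents[1]
sys.path.insert(0, str(ROOT / "src"))

from parfus.condensate import (AnalysisConfig, coexistence_densities,  # noqa: E402
                               density_profile)
from parfus.engine import SlabProtocolConfig, prepare_slab, run_slab_protocol  # noqa: E402
from parfus.topology import (build_fus_topology, build_idr_topology,  # noqa: E402
                             build_par_topology, load_fus_assets)

OUT = ROOT / "results" / "slab"
OUT.mkdir(parents=True, exist_ok=True)


def desk_composition():
    chain = build_idr_topology("FLFLFLFLFLFLFLFLFLFL")
    comp, pos = prepare_slab([(chain, 10)], box=(8.0, 8.0, 300.0), seed=1)
    cfg = SlabProtocolConfig(setup_box=(8.0, 8.0, 300.0),
                             production_box=(8.0, 8.0, 60.0),
                             equil_ns=0.05, compress_ns=0.3, production_ns=1.0,
                             temperatures=(250.0, 290.0, 330.0, 370.0, 410.0),
                             n_fus=0, n_par=0, save_interval_ps=20.0, seed=2)
    return (comp, pos), cfg, AnalysisConfig(slab_half_width=15.0)


def full_composition(with_par: bool):
    sys.path.insert(0, str(ROOT / "analysis"))
    from importlib import import_module
    build = import_module("01_build_models")
    seq, dcfg = load_fus_assets()
    natives = {lab: build.synthetic_hairpin(r["end"] - r["start"] + 1)
               for lab, r in dcfg["domains"].items()
               if r["kind"] == "structured"}
    fus = build_fus_topology(seq, dcfg["domains"], natives)
    comp = [(fus, 100)]
    if with_par:
        comp.append((build_par_topology(16), 10))
    system, pos = prepare_slab(comp, box=(25.0, 25.0, 3500.0), seed=1)
    temps = tuple(range(330, 441 if with_par else 421, 10))
    cfg = SlabProtocolConfig(temperatures=temps, seed=2)
    return (system, pos), cfg, AnalysisConfig()


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--full", action="store_true",
                    help="production composition/durations (cluster-scale)")
    ap.add_argument("--with-par", action="store_true")
    args = ap.parse_args()

    comp, cfg, ac = (full_composition(args.with_par) if args.full
                     else desk_composition())
    trajs = run_slab_protocol(comp, cfg, checkpoint_dir=str(ROOT / "scratch" / "slab"),
                              log=print)
    prof_rows, coex_rows = [], []
    for T, tr in sorted(trajs.items()):
        centers, dens = density_profile(tr, ac)
        rl, rh = coexistence_densities(centers, dens, ac)
        coex_rows.append({"T": T, "rho_L": rl, "rho_H": rh})
        for z, d in zip(centers, dens):
            prof_rows.append({"T": T, "z": z, "density": d})
        print(f"T={T:6.1f} K  rho_L={rl:8.3f}  rho_H={rh:8.3f} amu/nm^3")
    pd.DataFrame(prof_rows).to_csv(OUT / "profiles.csv", index=False)
    pd.DataFrame(coex_rows).to_csv(OUT / "coexistence.csv", index=False)


if __name__ == "__main__":
    main()
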