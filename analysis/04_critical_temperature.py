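"""Fit the critical temperature from coexistence densities via the 3-D Ising
scaling law rho_H - rho_L = A (Tc - T)^0.325.

Consumes results/slab/coexistence.csv when present (from 03); always also
runs a synthetic recovery study (noiseless round trip + noise/CI coverage).

Writes results/tc/{fit.json, synthetic_recovery.json}.
"""

import json
import pathlib
import sys

import numpy as np
import pandas as pd

ROOT = pathlib.Path(__file__).resolve().parents[1]
sys.path.insert(0, str(ROOT / "src"))

from parfus.condensate import fit_critical_temperature  # noqa: E402
from parfus.synth import gen_coexistence_points         # noqa: E402

OUT = ROOT / "results" / "tc"
OUT.mkdir(parents=True, exist_ok=True)


def main():
    # synthetic recovery study
    pts, _ = gen_coexistence_points(A=2.0, Tc=400.0, noise=0.0, seed=0)
    clean = fit_critical_temperature(pts)
    cover = 0
    for s in range(100):
        noisy, _ = gen_coexistence_points(A=2.0, Tc=400.0, noise=0.01, seed=s)
        sig = 0.01 * np.sqrt(noisy[:, 1] ** 2 + noisy[:, 2] ** 2)
        f = fit_critical_temperature(noisy, sigma=sig)
        cover += abs(f.Tc - 400.0) <= 1.96 * f.tc_stderr
    rec = {"clean_A": clean.A, "clean_Tc": clean.Tc,
           "ci_coverage_percent": cover}
    (OUT / "synthetic_recovery.json").write_text(json.dumps(rec, indent=1))
    print(f"synthetic: A={clean.A:.4f}, Tc={clean.Tc:.2f} K, "
          f"1%-noise CI coverage {cover}/100")

    coex = ROOT / "results" / "slab" / "coexistence.csv"
    if coex.exists():
        df = pd.read_csv(coex)
        usable = df[df.rho_H > df.rho_L]
        if len(usable) >= 3:
            fit = fit_critical_temperature(
                usable[["T", "rho_L", "rho_H"]].to_numpy())
            out = {"Tc": fit.Tc, "A": fit.A, "Tc_stderr": fit.tc_stderr,
                   "n_points": len(usable)}
            (OUT / "fit.json").write_text(json.dumps(out, indent=1))
            print(f"slab data: Tc = {fit.Tc:.1f} +- {fit.tc_stderr:.1f} K "
                  f"({len(usable)} temperatures)")
        else:
            print("slab data: fewer than 3 coexisting temperatures; no fit")
    else:
        print("no slab coexistence table found; run 03 first for a data fit")


if __name__ == "__main__":
    main()
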