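"""Fit every experimental-assay model on synthetic curves with known truth:
Hill binding, FRAP recovery, FCS calibration + sample fits, BLI kinetics,
and the CTCF formula.

Writes results/expfits/report.json with generating vs recovered parameters.
"""

import json
import pathlib
import sys

import numpy as np

ROOT = pathlib.Path(__file__).resolve().parents[1]
sys.path.insert(0, str(ROOT / "src"))

from parfus.expfits import (calibrate_confocal, ctcf, fit_bli, fit_fcs,  # noqa: E402
                            fit_frap, fit_hill)
from parfus.synth import gen_assay_curves                                # noqa: E402

OUT = ROOT / "results" / "expfits"
OUT.mkdir(parents=True, exist_ok=True)


def main():
    report = {}

    conc = np.array([1e-8, 3e-8, 1e-7, 2e-7, 5e-7, 1e-6, 3e-6, 1e-5])
    (c, y), _ = gen_assay_curves("hill", dict(kd=2e-7, n=1.5, bottom=0.05,
                                              top=0.95, conc=conc),
                                 noise=0.01, seed=1)
    h = fit_hill(c, y)
    report["hill"] = {"true": {"kd": 2e-7, "n": 1.5},
                      "fit": {k: h.params[k] for k in ("kd", "n")},
                      "kd_stderr": h.stderr["kd"]}

    t = np.arange(0.0, 300.0, 5.0)
    (tt, f), _ = gen_assay_curves("frap", dict(fmin=0.2, fmax=0.8, k=0.05,
                                               t=t), noise=0.01, seed=2)
    fr = fit_frap(tt, f)
    report["frap"] = {"true": {"mobile_fraction": 0.6,
                               "t_half_s": float(np.log(2) / 0.05)},
                      "fit": {"mobile_fraction": fr.mobile_fraction,
                              "t_half_s": fr.t_half, "k_per_s": fr.k}}

    tau = np.geomspace(1e-6, 1e-1, 80)
    (ta, g), _ = gen_assay_curves("fcs", dict(g0=0.5, tau_d=4e-5,
                                              omega_sq=25.0, tau=tau),
                                  noise=0.005, seed=3)
    cal = calibrate_confocal(ta, g)
    (t2, g2), _ = gen_assay_curves("fcs", dict(g0=0.3, tau_d=8e-5,
                                               omega_sq=25.0, tau=tau),
                                   noise=0.005, seed=4)
    fc = fit_fcs(t2, g2, cal)
    report["fcs"] = {"cal": {"omega_sq": cal.omega_sq,
                             "tauD_ref_s": cal.tauD_ref},
                     "sample": {"tau_d_s": fc.params["tau_d"],
                                "rh_nm": fc.params["rh"]},
                     "true_rh_nm": 0.81 * 8e-5 / 4e-5}

    bconc = np.array([0.4e-6, 1e-6, 2e-6, 5e-6, 12e-6])
    (grams, bc), _ = gen_assay_curves("bli", dict(kon=1e4, koff=1.37e-2,
                                                  bmax=1.2, conc=bconc,
                                                  t=np.linspace(0, 600, 240)),
                                      noise=0.005, seed=5)
    b = fit_bli(grams, bc)
    report["bli"] = {"true": {"kon": 1e4, "koff": 1.37e-2,
                              "kd_M": 1.37e-6},
                     "fit": {"kon": b.kon, "koff": b.koff, "kd_M": b.kd,
                             "bmax_nm": b.bmax}}

    report["ctcf_example"] = {"inputs": [1000.0, 50.0, 4.0],
                              "value": float(ctcf(1000.0, 50.0, 4.0))}

    (OUT / "report.json").write_text(json.dumps(report, indent=1))
    for k, v in report.items():
        print(k, "->", json.dumps(v))


if __name__ == "__main__":
    main()
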