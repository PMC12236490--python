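"""Fits for the wet-lab assay curves: Hill/one-site binding, FRAP recovery,
FCS autocorrelation with confocal calibration, BLI association kinetics, and
the corrected-total-cell-fluorescence formula.

All nonlinear fits use trust-region least squares with 5 seeded multi-starts
and report parameters, asymptotic standard errors and residuals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

LN2 = np.log(2.0)


def read_curve(path, x_col: str, y_col: str):
    """Read a long-format assay-curve CSV; returns (x, y) arrays.

    Expected column names: concentration/response for binding isotherms,
    time_s/intensity for FRAP, tau_s/G for FCS, time_s/response_nm for BLI.
    """
    import pandas as pd
    df = pd.read_csv(path, comment="#")
    if x_col not in df.columns or y_col not in df.columns:
        raise ValueError(f"curve file lacks columns {x_col!r}/{y_col!r}; "
                         f"has {list(df.columns)}")
    return df[x_col].to_numpy(dtype=float), df[y_col].to_numpy(dtype=float)


@dataclass
class FitResult:
    """Generic nonlinear fit result."""
    model: str
    params: dict
    stderr: dict
    residuals: np.ndarray
    converged: bool
    flags: list = field(default_factory=list)

    @property
    def rss(self) -> float:
        return float(np.sum(self.residuals ** 2))


def _multistart_least_squares(residual_fn, starts, bounds, model, names,
                              x_scale=None):
    best = None
    for p0 in starts:
        try:
            res = least_squares(residual_fn, p0, bounds=bounds, method="trf",
                                x_scale=("jac" if x_scale is None else x_scale),
                                max_nfev=10000)
        except Exception:
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        raise RuntimeError(f"{model} fit failed from every start")
    # asymptotic errors from J^T J
    J = best.jac
    dof = max(len(best.fun) - len(best.x), 1)
    s2 = 2.0 * best.cost / dof
    try:
        cov = s2 * np.linalg.inv(J.T @ J)
        err = np.sqrt(np.clip(np.diag(cov), 0, None))
    except np.linalg.LinAlgError:
        err = np.full(len(best.x), np.nan)
    return FitResult(model=model, params=dict(zip(names, best.x)),
                     stderr=dict(zip(names, err)), residuals=best.fun,
                     converged=best.success)


def _spread_starts(p0, rng, n=5, spread=0.5):
    starts = [np.asarray(p0, dtype=float)]
    for _ in range(n - 1):
        starts.append(np.asarray(p0) * np.exp(rng.uniform(-spread, spread, len(p0))))
    return starts


# ---------------------------------------------------------------------------
# Hill / one-site binding
# ---------------------------------------------------------------------------

def hill_curve(conc, kd, n, bottom, top):
    conc = np.asarray(conc, dtype=float)
    cn = np.power(conc, n)
    return bottom + (top - bottom) * cn / (np.power(kd, n) + cn)


def fit_hill(conc, response, model: str = "hill", seed: int = 0) -> FitResult:
    """Fit a binding isotherm: ``hill`` (free Hill coefficient n) or
    ``one_site`` (n fixed to 1). Reports KD (same units as conc), n and the
    two asymptotes. Warns (flag) if the response shows no monotone trend."""
    conc = np.asarray(conc, dtype=float)
    response = np.asarray(response, dtype=float)
    if len(conc) < 5:
        raise ValueError("need at least 5 concentrations")
    if np.ptp(response) == 0:
        raise ValueError("constant response: no binding signal to fit")
    flags = []
    order = np.argsort(conc)
    diffs = np.diff(response[order])
    if not (np.all(diffs >= -1e-3 * np.ptp(response))
            or np.all(diffs <= 1e-3 * np.ptp(response))):
        flags.append("non-monotone response trend")

    rng = np.random.default_rng(seed)
    span = np.ptp(response)
    p0 = [np.median(conc), 1.0, response[order][0], response[order][-1]]
    if model == "one_site":
        def resid(p):
            return hill_curve(conc, p[0], 1.0, p[1], p[2]) - response
        names = ["kd", "bottom", "top"]
        bounds = ([1e-30, -np.inf, -np.inf], [np.inf, np.inf, np.inf])
        starts = _spread_starts([p0[0], p0[2], p0[3]], rng)
        # multiplicative jitter breaks on near-zero baselines; offset those
        starts = [np.where(np.abs(s) < 1e-12, 0.1 * span, s) for s in starts]
        out = _multistart_least_squares(resid, starts, bounds, "one_site", names)
    elif model == "hill":
        def resid(p):
            return hill_curve(conc, p[0], p[1], p[2], p[3]) - response
        names = ["kd", "n", "bottom", "top"]
        bounds = ([1e-30, 0.05, -np.inf, -np.inf], [np.inf, 10.0, np.inf, np.inf])
        starts = _spread_starts(p0, rng)
        starts = [np.where(np.abs(s) < 1e-12, 0.1 * span, s) for s in starts]
        out = _multistart_least_squares(resid, starts, bounds, "hill", names)
    else:
        raise ValueError(f"unknown binding model {model!r}")
    out.flags.extend(flags)
    return out


# ---------------------------------------------------------------------------
# FRAP
# ---------------------------------------------------------------------------

@dataclass
class FrapFit:
    """Single-exponential recovery F(t) = Fmin + (Fmax - Fmin)(1 - e^{-kt}).

    mobile_fraction = Fmax - Fmin and T_half = ln(2)/k; by construction
    F(T_half) is the midpoint (Fmin + Fmax)/2.
    """
    fmin: float
    fmax: float
    k: float
    stderr: dict
    residuals: np.ndarray

    @property
    def mobile_fraction(self) -> float:
        return self.fmax - self.fmin

    @property
    def t_half(self) -> float:
        return LN2 / self.k

    def predict(self, t):
        return self.fmin + (self.fmax - self.fmin) * (1.0 - np.exp(-self.k * np.asarray(t)))


def frap_normalize(intensity, background, prebleach):
    """Background-subtract then divide by the pre-bleach level."""
    return (np.asarray(intensity, dtype=float) - background) / (prebleach - background)


def fit_frap(time, intensity, seed: int = 0) -> FrapFit:
    """Fit normalized FRAP recovery; rejects non-positive rates."""
    time = np.asarray(time, dtype=float)
    intensity = np.asarray(intensity, dtype=float)

    def resid(p):
        fmin, fmax, k = p
        return fmin + (fmax - fmin) * (1.0 - np.exp(-k * time)) - intensity

    rng = np.random.default_rng(seed)
    k0 = 1.0 / max(time.max() / 3.0, 1e-9)
    starts = _spread_starts([max(intensity.min(), 1e-3),
                             max(intensity.max(), 1e-2), k0], rng)
    bounds = ([0.0, 0.0, 1e-12], [np.inf, np.inf, np.inf])
    res = _multistart_least_squares(resid, starts, bounds, "frap",
                                    ["fmin", "fmax", "k"])
    fmin, fmax, k = (res.params[n] for n in ("fmin", "fmax", "k"))
    if k <= 0:
        raise RuntimeError("FRAP fit produced a non-positive rate")
    if fmax < fmin:
        fmin, fmax = fmax, fmin
    return FrapFit(fmin=fmin, fmax=fmax, k=k, stderr=res.stderr,
                   residuals=res.residuals)


# ---------------------------------------------------------------------------
# FCS
# ---------------------------------------------------------------------------

@dataclass
class FcsCalibration:
    """Confocal-volume calibration from a free-dye reference curve.

    The structural parameter omega^2 (squared axial-to-lateral ratio) is
    extracted once from the reference dye of known diffusion coefficient and
    held constant for all sample fits; hydrodynamic radii scale linearly with
    diffusion time relative to the reference (RH_ref = 0.81 nm for Cy3).
    """
    omega_sq: float
    tauD_ref: float             # s
    G0_ref: float
    D_ref: float = 241.0        # um^2/s
    RH_ref: float = 0.81        # nm

    @property
    def lateral_radius_um(self) -> float:
        """Lateral 1/e^2 radius from D_ref = r^2 / (4 tauD_ref)."""
        return float(np.sqrt(4.0 * self.D_ref * self.tauD_ref))


def fcs_curve(tau, g0, tau_d, omega_sq):
    tau = np.asarray(tau, dtype=float)
    return g0 / (1.0 + tau / tau_d) / np.sqrt(1.0 + tau / (omega_sq * tau_d))


def calibrate_confocal(tau, g, seed: int = 0) -> FcsCalibration:
    """Fit the 3-D diffusion autocorrelation of the reference dye to extract
    omega^2 and the reference diffusion time."""
    tau = np.asarray(tau, dtype=float)
    g = np.asarray(g, dtype=float)
    if np.ptp(g) <= 0 or len(tau) < 5:
        raise ValueError("degenerate reference curve")
    rng = np.random.default_rng(seed)
    tau_mid = tau[np.argmin(np.abs(g - 0.5 * g.max()))]

    def resid(p):
        return fcs_curve(tau, p[0], p[1], p[2]) - g

    starts = _spread_starts([g.max(), max(tau_mid, tau.min() * 2), 25.0], rng)
    bounds = ([0.0, tau.min() * 1e-3, 1.0], [np.inf, tau.max() * 1e3, 1e4])
    res = _multistart_least_squares(resid, starts, bounds, "fcs_cal",
                                    ["g0", "tau_d", "omega_sq"])
    return FcsCalibration(omega_sq=res.params["omega_sq"],
                          tauD_ref=res.params["tau_d"], G0_ref=res.params["g0"])


def fit_fcs(tau, g, cal: FcsCalibration, seed: int = 0) -> FitResult:
    """Sample fit with omega^2 held at the calibration value; reports G0,
    tauD and the hydrodynamic radius RH = RH_ref * tauD / tauD_ref (nm)."""
    tau = np.asarray(tau, dtype=float)
    g = np.asarray(g, dtype=float)
    rng = np.random.default_rng(seed)
    tau_mid = tau[np.argmin(np.abs(g - 0.5 * g.max()))]

    def resid(p):
        return fcs_curve(tau, p[0], p[1], cal.omega_sq) - g

    starts = _spread_starts([g.max(), max(tau_mid, tau.min() * 2)], rng)
    bounds = ([0.0, tau.min() * 1e-3], [np.inf, tau.max() * 1e3])
    res = _multistart_least_squares(resid, starts, bounds, "fcs", ["g0", "tau_d"])
    res.params["rh"] = cal.RH_ref * res.params["tau_d"] / cal.tauD_ref
    return res


# ---------------------------------------------------------------------------
# BLI
# ---------------------------------------------------------------------------

@dataclass
class BliFit:
    """Association-phase kinetics: Y = Occ * Bmax * (1 - e^{-kob t}) with
    kob = kon*L + koff and Occ = L/(L + KD), KD = koff/kon."""
    kon: float      # 1/(M s)
    koff: float     # 1/s
    bmax: float     # nm response
    stderr: dict
    residuals: np.ndarray
    flags: list

    @property
    def kd(self) -> float:
        return self.koff / self.kon

    def kob(self, conc) -> np.ndarray:
        return self.kon * np.asarray(conc, dtype=float) + self.koff

    def predict(self, t, conc):
        occ = conc / (conc + self.kd)
        return occ * self.bmax * (1.0 - np.exp(-self.kob(conc) * np.asarray(t)))


def fit_bli(sensorgrams, concentrations, seed: int = 0) -> BliFit:
    """Global fit of association sensorgrams across >= 3 analyte
    concentrations with shared kon, koff and Bmax.

    ``sensorgrams``: list of (t, Y) arrays matching ``concentrations`` (M).
    Flags the fit as non-identifiable when the per-concentration observed
    rates do not increase with concentration.
    """
    concentrations = np.asarray(concentrations, dtype=float)
    if len(sensorgrams) != len(concentrations) or len(concentrations) < 3:
        raise ValueError("need >= 3 concentration/sensorgram pairs")

    def model(p, t, L):
        kon, koff, bmax = p
        kd = koff / kon
        occ = L / (L + kd)
        return occ * bmax * (1.0 - np.exp(-(kon * L + koff) * t))

    def resid(logp):
        p = np.exp(logp)
        return np.concatenate([model(p, np.asarray(t), L) - np.asarray(y)
                               for (t, y), L in zip(sensorgrams, concentrations)])

    ymax = max(np.max(y) for _, y in sensorgrams)
    tspan = max(np.max(t) for t, _ in sensorgrams)
    rng = np.random.default_rng(seed)
    p0 = np.log([1.0 / (concentrations.mean() * tspan), 1.0 / tspan, ymax])
    starts = [p0 + rng.uniform(-1.0, 1.0, 3) * (0 if i == 0 else 1)
              for i in range(5)]
    res = _multistart_least_squares(resid, starts, (-np.inf, np.inf), "bli",
                                    ["log_kon", "log_koff", "log_bmax"],
                                    x_scale=np.ones(3))
    kon, koff, bmax = (np.exp(res.params[f"log_{n}"]) for n in ("kon", "koff", "bmax"))
    err = {n: np.exp(res.params[f"log_{n}"]) * res.stderr[f"log_{n}"]
           for n in ("kon", "koff", "bmax")}
    flags = []
    kob = kon * concentrations + koff
    if np.ptp(kob) < 0.05 * kob.mean():
        flags.append("non-identifiable: kob nearly flat across concentrations")
    return BliFit(kon=float(kon), koff=float(koff), bmax=float(bmax),
                  stderr=err, residuals=res.residuals, flags=flags)


def kob_linear_fit(sensorgrams, concentrations, seed: int = 0):
    """Independent route: per-concentration single-exponential kob fits,
    then linear regression kob = kon*L + koff. Returns (kon, koff)."""
    kobs = []
    rng = np.random.default_rng(seed)
    for (t, y), L in zip(sensorgrams, np.asarray(concentrations, dtype=float)):
        t = np.asarray(t, dtype=float); y = np.asarray(y, dtype=float)

        def resid(p):
            return p[0] * (1.0 - np.exp(-p[1] * t)) - y

        starts = _spread_starts([y.max(), 2.0 / t.max()], rng)
        res = _multistart_least_squares(resid, starts,
                                        ([0, 1e-12], [np.inf, np.inf]),
                                        "kob", ["plateau", "kob"])
        kobs.append(res.params["kob"])
    slope, intercept = np.polyfit(np.asarray(concentrations, dtype=float),
                                  np.asarray(kobs), 1)
    return float(slope), float(intercept)


# ---------------------------------------------------------------------------
# CTCF
# ---------------------------------------------------------------------------

def ctcf(integrated_density, roi_area, background_mean):
    """Corrected total cell fluorescence:
    integrated density - ROI area x mean background fluorescence."""
    for v in (integrated_density, roi_area, background_mean):
        if np.any(np.asarray(v) < 0):
            raise ValueError("CTCF inputs must be non-negative")
    return np.asarray(integrated_density) - np.asarray(roi_area) * np.asarray(background_mean)
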