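"""Kinetic and thermodynamic fitting models.

Arrhenius recovery kinetics 1/tau = A1 + A2*exp(-Ea/RT), a Boltzmann-
weighted two-channel (double-well) convex-Arrhenius model, flash-photolysis
photoproduct yield with nonlinear loss Y(F) = phi*(1-exp(-sig_lin*F))*
exp(-sig_nl*F), and the pump-dump action-trace suppression curve.

All fits are weighted nonlinear least squares in rate space with
deterministic multi-start initialization.  Barriers are in kJ/mol with
R = 8.31446 J/(mol K).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq, least_squares
from scipy.special import erf

from .units import R_GAS  # J mol^-1 K^-1

R_KJ = R_GAS / 1000.0  # kJ mol^-1 K^-1


class FitError(RuntimeError):
    pass


@dataclass
class RateSeries:
    temperatures: np.ndarray  # K
    rates: np.ndarray         # s^-1
    uncertainties: np.ndarray | None = None

    def __post_init__(self):
        self.temperatures = np.asarray(self.temperatures, float)
        self.rates = np.asarray(self.rates, float)
        if self.uncertainties is not None:
            self.uncertainties = np.asarray(self.uncertainties, float)
        if (self.temperatures <= 0).any():
            raise ValueError("temperatures must be positive")
        if len(np.unique(self.temperatures)) != len(self.temperatures):
            raise ValueError("temperatures must be unique")
        if (self.rates <= 0).any():
            raise ValueError("rates must be positive")

    @property
    def weights(self) -> np.ndarray:
        if self.uncertainties is None:
            return np.ones_like(self.rates)
        return 1.0 / self.uncertainties**2

    def to_frame(self):
        import pandas as pd

        d = {"temperature_K": self.temperatures, "rate_s": self.rates}
        if self.uncertainties is not None:
            d["sigma_rate_s"] = self.uncertainties
        return pd.DataFrame(d)

    @classmethod
    def from_csv(cls, path) -> "RateSeries":
        import pandas as pd

        df = pd.read_csv(path)
        sig = (df["sigma_rate_s"].to_numpy(float)
               if "sigma_rate_s" in df.columns else None)
        return cls(df["temperature_K"].to_numpy(float),
                   df["rate_s"].to_numpy(float), sig)


@dataclass
class ArrheniusFit:
    a1: float          # s^-1
    a2: float          # s^-1
    ea: float          # kJ/mol
    covariance: np.ndarray
    residuals: np.ndarray
    ea_identifiable: bool = True

    def rate(self, temperature) -> np.ndarray:
        t = np.asarray(temperature, float)
        return self.a1 + self.a2 * np.exp(-self.ea / (R_KJ * t))

    @property
    def sigma_ea(self) -> float:
        return float(np.sqrt(self.covariance[2, 2]))


def arrhenius_rate(temperature, a1: float, a2: float, ea: float) -> np.ndarray:
    t = np.asarray(temperature, float)
    return a1 + a2 * np.exp(-ea / (R_KJ * t))


def _cov_from_jac(res) -> np.ndarray:
    _, s, vt = np.linalg.svd(res.jac, full_matrices=False)
    s = np.where(s > s.max() * 1e-12, s, np.inf)
    n, p = res.jac.shape
    dof = max(n - p, 1)
    s2 = 2.0 * res.cost / dof
    return (vt.T / s**2) @ vt * s2


def fit_arrhenius(series: RateSeries) -> ArrheniusFit:
    """Weighted nonlinear least squares in rate space, multi-start.

    Parameters are optimized as (log A1, log A2, Ea).  Initialization from
    the slope of ln(k - min(k) + eps) vs 1/T plus perturbed starts.
    """
    t = series.temperatures
    k = series.rates
    if len(t) < 4 or (t.max() - t.min()) < 20.0:
        raise FitError("need >= 4 temperatures spanning >= 20 K")
    w = np.sqrt(series.weights)
    if series.uncertainties is None:
        # relative weighting so every point contributes comparably
        w = 1.0 / k

    def residual(p):
        la1, la2, ea = p
        # wild multi-start points can overflow exp; inf residuals just
        # steer the optimizer away, so suppress the warning
        with np.errstate(over="ignore", invalid="ignore"):
            model = np.exp(la1) + np.exp(la2) * np.exp(-ea / (R_KJ * t))
            return w * (model - k)

    # slope initialization
    eps = 1e-3 * k.min()
    y = np.log(k - k.min() + eps)
    x = 1.0 / t
    slope, intercept = np.polyfit(x, y, 1)
    ea0 = max(-slope * R_KJ, 1.0)
    la2_0 = intercept
    la1_0 = math.log(max(k.min(), 1e-300))
    starts = [
        (la1_0, la2_0, ea0),
        (la1_0 - 2.0, la2_0 + 5.0, 1.5 * ea0),
        (la1_0 + 1.0, la2_0 - 3.0, 0.5 * ea0),
    ]
    best = None
    for p0 in starts:
        try:
            res = least_squares(residual, p0, method="lm", max_nfev=5000)
        except Exception:
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        raise FitError("Arrhenius fit failed from all starts")
    la1, la2, ea = best.x
    # covariance in (A1, A2, Ea) via the chain rule from (lnA1, lnA2, Ea)
    cov_log = _cov_from_jac(best)
    j = np.diag([math.exp(la1), math.exp(la2), 1.0])
    cov = j @ cov_log @ j
    # identifiability: Ea is meaningless if the exponential channel is
    # negligible across the fitted range, or if it does not actually vary
    # with temperature (Ea ~ 0 is degenerate with the constant channel)
    channel2 = math.exp(la2) * np.exp(-ea / (R_KJ * t))
    identifiable = bool(channel2.max() > 1e-3 * k.max()
                        and np.ptp(channel2) > 1e-3 * k.max())
    cond = np.linalg.cond(best.jac)
    if cond > 1e12 and not identifiable:
        raise FitError("non-identifiable fit (flat exponential channel); "
                       "consider fixing A1 = 0")
    return ArrheniusFit(a1=math.exp(la1), a2=math.exp(la2), ea=float(ea),
                        covariance=cov, residuals=best.fun,
                        ea_identifiable=identifiable)


@dataclass
class ConvexArrheniusModel:
    prefactors: tuple[float, float]   # s^-1
    barriers: tuple[float, float]     # kJ/mol
    delta_g: float                    # kJ/mol, well free-energy offset
    transition_temperature: float | None
    aic_convex: float
    aic_simple: float
    residuals: np.ndarray = field(default_factory=lambda: np.array([]))

    def channel_weights(self, temperature) -> tuple[np.ndarray, np.ndarray]:
        t = np.asarray(temperature, float)
        b = np.exp(-self.delta_g / (R_KJ * t))
        w1 = 1.0 / (1.0 + b)
        return w1, 1.0 - w1

    def rate(self, temperature) -> np.ndarray:
        t = np.asarray(temperature, float)
        w1, w2 = self.channel_weights(t)
        k1, k2 = self.prefactors
        e1, e2 = self.barriers
        return (w1 * k1 * np.exp(-e1 / (R_KJ * t))
                + w2 * k2 * np.exp(-e2 / (R_KJ * t)))

    def channel_rates(self, temperature) -> tuple[np.ndarray, np.ndarray]:
        t = np.asarray(temperature, float)
        w1, w2 = self.channel_weights(t)
        k1, k2 = self.prefactors
        e1, e2 = self.barriers
        return (w1 * k1 * np.exp(-e1 / (R_KJ * t)),
                w2 * k2 * np.exp(-e2 / (R_KJ * t)))


def convex_rate(temperature, k1, e1, k2, e2, delta_g) -> np.ndarray:
    t = np.asarray(temperature, float)
    # extreme parameter values visited during multi-start optimization can
    # overflow exp; the resulting inf/nan residuals steer the search away
    with np.errstate(over="ignore", invalid="ignore"):
        b = np.exp(-delta_g / (R_KJ * t))
        w1 = 1.0 / (1.0 + b)
        return (w1 * k1 * np.exp(-e1 / (R_KJ * t))
                + (1 - w1) * k2 * np.exp(-e2 / (R_KJ * t)))


def _aic(n: int, cost: float, n_par: int) -> float:
    return n * math.log(max(2.0 * cost / n, 1e-300)) + 2 * n_par


def fit_convex_arrhenius(series: RateSeries) -> ConvexArrheniusModel | ArrheniusFit:
    """Boltzmann-weighted two-channel fit with a simple-Arrhenius guard.

    If the two-channel model does not improve the information criterion
    over the simple fit (no curvature), the simple ArrheniusFit is
    returned instead (logged fallback).
    """
    t = series.temperatures
    k = series.rates
    w = 1.0 / k

    def residual(p):
        lk1, e1, lk2, e2, dg = p
        return w * (convex_rate(t, math.exp(lk1), e1, math.exp(lk2), e2, dg) - k)

    # simple fit for comparison / initialization
    simple = fit_arrhenius(series)
    simple_cost = float(0.5 * np.sum((w * (simple.rate(t) - k))**2))

    e0 = max(simple.ea, 10.0)
    lk0 = math.log(max(simple.a2, 1e-10))
    starts = [
        (lk0, 0.7 * e0, lk0 + 2.0, 1.3 * e0, 5.0),
        (lk0 - 2.0, 0.5 * e0, lk0 + 4.0, 1.5 * e0, 10.0),
        (lk0, e0, lk0, e0 * 0.8, 2.0),
    ]
    best = None
    for p0 in starts:
        try:
            res = least_squares(residual, p0, method="lm", max_nfev=10000)
        except Exception:
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        raise FitError("convex Arrhenius fit failed from all starts")
    aic_c = _aic(len(t), float(best.cost), 5)
    aic_s = _aic(len(t), simple_cost, 3)
    if aic_c >= aic_s:
        return simple
    lk1, e1, lk2, e2, dg = best.x
    k1, k2 = math.exp(lk1), math.exp(lk2)
    model = ConvexArrheniusModel(
        prefactors=(k1, k2), barriers=(float(e1), float(e2)), delta_g=float(dg),
        transition_temperature=None, aic_convex=aic_c, aic_simple=aic_s,
        residuals=best.fun)
    model.transition_temperature = _transition_temperature(model, t.min(), t.max())
    return model


def _transition_temperature(model: ConvexArrheniusModel, t_lo: float,
                            t_hi: float) -> float | None:
    """Temperature where the two channel contributions are equal."""

    def diff(t):
        r1, r2 = model.channel_rates(t)
        return float(r1 - r2)

    lo, hi = 0.5 * t_lo, 2.0 * t_hi
    grid = np.linspace(lo, hi, 400)
    vals = np.array([diff(x) for x in grid])
    sign_change = np.nonzero(np.sign(vals[:-1]) != np.sign(vals[1:]))[0]
    if len(sign_change) == 0:
        return None
    i = sign_change[0]
    return float(brentq(diff, grid[i], grid[i + 1]))


@dataclass
class FlashYieldSeries:
    fluences: np.ndarray   # mJ/mm^2
    yields: np.ndarray     # fraction
    uncertainties: np.ndarray | None = None

    def __post_init__(self):
        self.fluences = np.asarray(self.fluences, float)
        self.yields = np.asarray(self.yields, float)
        if (self.fluences < 0).any():
            raise ValueError("fluences must be non-negative")
        if ((self.yields < 0) | (self.yields > 1)).any():
            raise ValueError("yields must lie in [0, 1]")

    def to_frame(self):
        import pandas as pd

        d = {"fluence_mj_mm2": self.fluences, "yield": self.yields}
        if self.uncertainties is not None:
            d["sigma_yield"] = self.uncertainties
        return pd.DataFrame(d)

    @classmethod
    def from_csv(cls, path) -> "FlashYieldSeries":
        import pandas as pd

        df = pd.read_csv(path)
        sig = (df["sigma_yield"].to_numpy(float)
               if "sigma_yield" in df.columns else None)
        return cls(df["fluence_mj_mm2"].to_numpy(float),
                   df["yield"].to_numpy(float), sig)


@dataclass
class CrossSectionFit:
    quantum_yield_scale: float
    sigma_linear: float      # mm^2/mJ
    sigma_nonlinear: float   # mm^2/mJ
    covariance: np.ndarray
    residuals: np.ndarray

    def yield_at(self, fluence) -> np.ndarray:
        return flash_yield(fluence, self.quantum_yield_scale,
                           self.sigma_linear, self.sigma_nonlinear)

    @property
    def optimal_fluence(self) -> float:
        """Fluence maximizing yield (infinite if no nonlinear loss)."""
        sl, sn = self.sigma_linear, self.sigma_nonlinear
        if sn <= 0:
            return math.inf
        return math.log1p(sl / sn) / sl


def flash_yield(fluence, phi: float, sigma_lin: float,
                sigma_nl: float) -> np.ndarray:
    f = np.asarray(fluence, float)
    return phi * (1.0 - np.exp(-sigma_lin * f)) * np.exp(-sigma_nl * f)


def fit_flash_yield(series: FlashYieldSeries) -> CrossSectionFit:
    """Fit Y(F) = phi*(1-exp(-sig_lin F))*exp(-sig_nl F), non-negative."""
    f = series.fluences
    y = series.yields
    if len(f) < 5:
        raise FitError("need >= 5 fluence points")
    if np.all(y == 0):
        raise FitError("all yields are zero; nothing to fit")

    def residual(p):
        lphi, lsl, lsn = p
        return flash_yield(f, math.exp(lphi), math.exp(lsl),
                           math.exp(lsn)) - y

    # initialization: low-fluence slope ~ phi*sig_lin; plateau ~ phi
    pos = f > 0
    slope0 = max((y[pos] / f[pos]).max(), 1e-8)
    phi0 = max(y.max(), 1e-6)
    sl0 = max(slope0 / phi0, 1e-8)
    starts = [
        (math.log(phi0), math.log(sl0), math.log(sl0) - 3.0),
        (math.log(min(2 * phi0, 1.0)), math.log(sl0) + 1.0, math.log(sl0) - 1.0),
        (math.log(phi0), math.log(sl0) - 1.0, math.log(sl0) - 6.0),
    ]
    best = None
    for p0 in starts:
        try:
            res = least_squares(residual, p0, method="lm", max_nfev=10000)
        except Exception:
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        raise FitError("flash-yield fit failed from all starts")
    lphi, lsl, lsn = best.x
    cov_log = _cov_from_jac(best)
    j = np.diag(np.exp(best.x))
    return CrossSectionFit(
        quantum_yield_scale=math.exp(lphi), sigma_linear=math.exp(lsl),
        sigma_nonlinear=math.exp(lsn), covariance=j @ cov_log @ j,
        residuals=best.fun)


def cross_correlation_sigma(pump_fwhm_fs: float, dump_fwhm_fs: float) -> float:
    """Gaussian sigma (fs) of the pump-dump cross-correlation."""
    if pump_fwhm_fs <= 0 or dump_fwhm_fs <= 0:
        raise ValueError("pulse FWHMs must be positive")
    fwhm_cc = math.hypot(pump_fwhm_fs, dump_fwhm_fs)
    return fwhm_cc / (2.0 * math.sqrt(2.0 * math.log(2.0)))


def action_trace(delays_fs, pump_fwhm_fs: float, dump_fwhm_fs: float,
                 es_lifetime_ps: float, depth: float) -> np.ndarray:
    """Suppression S(delta) = 1 - depth*Phi(delta/sigma_cc)*exp(-delta/tau)
    (decay applied for positive delays only); returned as the yield factor
    so large negative delay gives 1 (no suppression)."""
    d = np.asarray(delays_fs, float)
    sig = cross_correlation_sigma(pump_fwhm_fs, dump_fwhm_fs)
    phi = 0.5 * (1.0 + erf(d / (sig * math.sqrt(2.0))))
    tau_fs = es_lifetime_ps * 1000.0
    decay = np.exp(-np.maximum(d, 0.0) / tau_fs)
    return 1.0 - depth * phi * decay


@dataclass
class ActionTraceFit:
    sigma_cc_fs: float
    es_lifetime_ps: float
    depth: float
    covariance: np.ndarray
    residuals: np.ndarray


def fit_action_trace(delays_fs, suppression) -> ActionTraceFit:
    """Recover (sigma_cc, tau_ES, depth) from a measured action trace."""
    d = np.asarray(delays_fs, float)
    s = np.asarray(suppression, float)

    def model(p):
        lsig, ltau, depth = p
        sig = math.exp(lsig)
        tau_fs = math.exp(ltau) * 1000.0
        phi = 0.5 * (1.0 + erf(d / (sig * math.sqrt(2.0))))
        return 1.0 - depth * phi * np.exp(-np.maximum(d, 0.0) / tau_fs)

    def residual(p):
        return model(p) - s

    depth0 = float(np.clip(1.0 - s.min(), 1e-3, 1.0))
    starts = [(math.log(100.0), math.log(5.0), depth0),
              (math.log(300.0), math.log(20.0), depth0),
              (math.log(50.0), math.log(1.0), min(1.0, depth0 * 1.5))]
    best = None
    for p0 in starts:
        try:
            res = least_squares(residual, p0, method="lm", max_nfev=10000)
        except Exception:
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        raise FitError("action-trace fit failed from all starts")
    lsig, ltau, depth = best.x
    cov = _cov_from_jac(best)
    j = np.diag([math.exp(lsig), math.exp(ltau), 1.0])
    return ActionTraceFit(sigma_cc_fs=math.exp(lsig),
                          es_lifetime_ps=math.exp(ltau), depth=float(depth),
                          covariance=j @ cov @ j, residuals=best.fun)
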