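"""Transient-absorption analysis: chirp correction and sequential global
fitting with evolution-associated difference spectra (EADS).

The sequential scheme A -> B -> ... with a Gaussian instrument response is
solved in closed form (exponential x erfc expression per compartment via
Bateman superposition), and the global fit uses variable projection: the
nonlinear search runs over (taus, t0, IRF width) while the EADS are solved
by linear least squares at every step.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.special import erfc, erfcx

SQRT2 = math.sqrt(2.0)
FWHM_TO_SIGMA = 1.0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))


class TAFitError(RuntimeError):
    pass


@dataclass
class TASurface:
    delays: np.ndarray        # ps, strictly increasing
    wavelengths: np.ndarray   # nm, strictly monotone
    delta_od: np.ndarray      # mOD, shape (n_delays, n_wavelengths); NaN = missing
    irf_fwhm: float = 150.0   # fs
    time_zero: float = 0.0    # ps

    def __post_init__(self):
        self.delays = np.asarray(self.delays, float)
        self.wavelengths = np.asarray(self.wavelengths, float)
        self.delta_od = np.asarray(self.delta_od, float)
        if not (np.all(np.diff(self.delays) > 0)):
            raise ValueError("delays must be strictly increasing")
        dw = np.diff(self.wavelengths)
        if not (np.all(dw > 0) or np.all(dw < 0)):
            raise ValueError("wavelengths must be strictly monotone")
        if self.delta_od.shape != (len(self.delays), len(self.wavelengths)):
            raise ValueError("delta_od shape mismatch")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.delta_od, index=self.delays,
                            columns=self.wavelengths)

    @classmethod
    def from_csv(cls, path, **kwargs) -> "TASurface":
        df = pd.read_csv(path, index_col=0)
        return cls(df.index.to_numpy(float),
                   np.array([float(c) for c in df.columns]),
                   df.to_numpy(float), **kwargs)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path)


@dataclass
class ChirpModel:
    """Group-delay offset (ps) as a polynomial in wavelength (nm),
    lowest-order coefficient first: offset = c0 + c1*wl + c2*wl^2."""

    coefficients: tuple[float, ...] = (0.0,)

    def __post_init__(self):
        if len(self.coefficients) > 3:
            raise ValueError("chirp polynomial order must be <= 2")
        if not all(np.isfinite(self.coefficients)):
            raise ValueError("chirp coefficients must be finite")

    def offset(self, wavelength) -> np.ndarray:
        wl = np.asarray(wavelength, float)
        out = np.zeros_like(wl)
        for i, c in enumerate(self.coefficients):
            out = out + c * wl**i
        return out


def correct_chirp(surface: TASurface, chirp: ChirpModel) -> TASurface:
    """Shift each wavelength column by its chirp offset (linear
    interpolation); samples shifted outside the delay range become NaN."""
    offsets = chirp.offset(surface.wavelengths)
    span = surface.delays[-1] - surface.delays[0]
    if np.any(np.abs(offsets) >= span):
        raise ValueError("chirp offsets exceed the delay-axis span")
    corrected = np.empty_like(surface.delta_od)
    for j, off in enumerate(offsets):
        col = surface.delta_od[:, j]
        # signal appearing late by `off` is moved back onto the common axis
        corrected[:, j] = np.interp(surface.delays + off, surface.delays, col,
                                    left=np.nan, right=np.nan)
        if np.all(np.isnan(corrected[:, j])):
            raise ValueError(
                f"chirp correction emptied the column at {surface.wavelengths[j]} nm")
    return TASurface(surface.delays.copy(), surface.wavelengths.copy(),
                     corrected, irf_fwhm=surface.irf_fwhm,
                     time_zero=surface.time_zero)


def exp_gauss_convolution(t, tau: float, sigma: float, t0: float = 0.0) -> np.ndarray:
    """Closed form of (step exponential decay) x (unit-area Gaussian IRF):
    0.5*exp(sigma^2/2tau^2 - (t-t0)/tau)*erfc((sigma/tau - (t-t0)/sigma)/sqrt2).

    Evaluated with erfcx for numerical stability at small sigma or long
    times.  sigma -> 0 recovers the pure one-sided exponential.
    """
    t = np.asarray(t, float)
    x = t - t0
    if sigma <= 0:
        return np.where(x >= 0, np.exp(-np.maximum(x, 0.0) / tau), 0.0)
    z = (sigma / tau - x / sigma) / SQRT2
    # 0.5*exp(sig^2/(2 tau^2) - x/tau) * erfc(z) = 0.5*erfcx(z)*exp(-x^2/(2 sig^2))
    # For z >= 0 the erfcx form avoids underflow of the leading Gaussian;
    # for z < 0 erfcx(z) ~ 2*exp(z^2) overflows, but there erfc(z) is
    # bounded (< 2) and the direct exponent sig^2/(2 tau^2) - x/tau decays,
    # so the plain product is the stable branch.
    x = np.atleast_1d(x)
    z = np.atleast_1d(z)
    out = np.empty_like(x)
    pos = z >= 0
    out[pos] = 0.5 * erfcx(z[pos]) * np.exp(-(x[pos] ** 2)
                                            / (2.0 * sigma**2))
    out[~pos] = 0.5 * np.exp(sigma**2 / (2.0 * tau**2)
                             - x[~pos] / tau) * erfc(z[~pos])
    return out.reshape(np.shape(t))


def gaussian_cumulative(t, sigma: float, t0: float = 0.0) -> np.ndarray:
    t = np.asarray(t, float)
    if sigma <= 0:
        return (t >= t0).astype(float)
    return 0.5 * erfc(-(t - t0) / (SQRT2 * sigma))


def sequential_concentrations(time_constants, irf_fwhm_fs: float,
                              time_zero_ps: float, delays_ps) -> np.ndarray:
    """Concentration profiles of the sequential chain, shape
    (n_delays, n_compartments); Bateman superposition of IRF-convolved
    exponentials.  The last compartment is a terminal sink when its time
    constant is infinite."""
    taus = np.asarray(time_constants, float)
    if np.any(taus <= 0):
        raise ValueError("time constants must be positive")
    rel = np.abs(taus[:, None] - taus[None, :])
    np.fill_diagonal(rel, np.inf)
    if rel.min() < 1e-9 * taus.max():
        raise ValueError("duplicate time constants give a degenerate chain; "
                         "perturb or reparameterize")
    t = np.asarray(delays_ps, float)
    sigma = irf_fwhm_fs * 1e-3 * FWHM_TO_SIGMA  # ps
    rates = 1.0 / taus
    n = len(taus)
    out = np.zeros((len(t), n))
    # Bateman coefficients: c_i(t) = sum_j a_ij * E_j(t), E_j the convolved
    # exponential with rate k_j
    for i in range(n):
        ks = rates[: i + 1]
        prod_k = np.prod(ks[:-1]) if i > 0 else 1.0
        for j in range(i + 1):
            denom = np.prod([ks[m] - ks[j] for m in range(i + 1) if m != j])
            a = prod_k / denom if i > 0 else 1.0
            out[:, i] += a * exp_gauss_convolution(t, 1.0 / ks[j], sigma,
                                                   time_zero_ps)
    return out


@dataclass
class SequentialFitResult:
    time_constants: np.ndarray     # ps, as fitted (chain order)
    eads: np.ndarray               # (n_compartments, n_wavelengths), mOD
    irf_fwhm: float                # fs
    time_zero: float               # ps
    residual_rms: float
    covariance: np.ndarray         # nonlinear parameters (taus, t0, irf)
    rms_per_wavelength: np.ndarray = field(default_factory=lambda: np.array([]))
    rms_per_delay: np.ndarray = field(default_factory=lambda: np.array([]))
    degenerate: bool = False


def _project_eads(conc: np.ndarray, data: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Solve EADS per wavelength by linear least squares, NaN-aware.
    Returns (eads, residual matrix with NaN where data missing)."""
    n_comp = conc.shape[1]
    n_wl = data.shape[1]
    eads = np.zeros((n_comp, n_wl))
    resid = np.full_like(data, np.nan)
    finite_all = np.isfinite(data).all(axis=1)
    if finite_all.all():
        sol, *_ = np.linalg.lstsq(conc, data, rcond=None)
        eads = sol
        resid = data - conc @ sol
    else:
        for j in range(n_wl):
            mask = np.isfinite(data[:, j])
            sol, *_ = np.linalg.lstsq(conc[mask], data[mask, j], rcond=None)
            eads[:, j] = sol
            resid[mask, j] = data[mask, j] - conc[mask] @ sol
    return eads, resid


def global_fit_sequential(
    surface: TASurface,
    n_compartments: int,
    initial_taus,
    fit_irf: bool = True,
    fit_t0: bool = True,
    max_nfev: int = 2000,
) -> SequentialFitResult:
    """Variable-projection global fit of a sequential scheme.

    Nonlinear parameters: log taus, plus optionally t0 (ps) and the IRF
    FWHM (fs); EADS are projected out linearly at every step.
    """
    if n_compartments > 4:
        raise ValueError("n_compartments must be <= 4")
    taus0 = np.asarray(initial_taus, float)
    if len(taus0) != n_compartments:
        raise ValueError("initial_taus length must equal n_compartments")
    data = surface.delta_od
    if len(surface.delays) <= n_compartments + 2:
        raise TAFitError("fewer delay points than nonlinear parameters")

    def unpack(p):
        taus = np.exp(p[:n_compartments])
        idx = n_compartments
        t0 = p[idx] if fit_t0 else surface.time_zero
        idx += int(fit_t0)
        irf = math.exp(p[idx]) if fit_irf else surface.irf_fwhm
        return taus, t0, irf

    def residual(p):
        taus, t0, irf = unpack(p)
        # guard the degenerate-chain error during the search
        taus = np.sort(taus)
        for i in range(1, len(taus)):
            if taus[i] <= taus[i - 1] * (1 + 1e-6):
                taus[i] = taus[i - 1] * (1 + 1e-6)
        conc = sequential_concentrations(taus, irf, t0, surface.delays)
        _, resid = _project_eads(conc, data)
        return resid[np.isfinite(resid)]

    p0 = list(np.log(taus0))
    if fit_t0:
        p0.append(surface.time_zero)
    if fit_irf:
        p0.append(math.log(max(surface.irf_fwhm, 1.0)))
    res = least_squares(residual, p0, method="trf", max_nfev=max_nfev)
    if not res.success and res.status <= 0:
        raise TAFitError(f"global fit did not converge: {res.message}")
    taus, t0, irf = unpack(res.x)
    order = np.argsort(taus)
    degenerate = bool(len(taus) > 1
                      and np.min(np.abs(np.diff(np.sort(taus)))) <
                      1e-3 * taus.max())
    taus_sorted = np.sort(taus)
    for i in range(1, len(taus_sorted)):
        if taus_sorted[i] <= taus_sorted[i - 1] * (1 + 1e-6):
            taus_sorted[i] = taus_sorted[i - 1] * (1 + 1e-6)
    conc = sequential_concentrations(taus_sorted, irf, t0, surface.delays)
    eads, resid = _project_eads(conc, data)
    finite = np.isfinite(resid)
    rms = float(np.sqrt(np.nanmean(resid[finite] ** 2)))
    # covariance of nonlinear params from the final Jacobian
    _, s, vt = np.linalg.svd(res.jac, full_matrices=False)
    s = np.where(s > s.max() * 1e-12, s, np.inf)
    dof = max(finite.sum() - len(res.x), 1)
    cov = (vt.T / s**2) @ vt * (2.0 * res.cost / dof)
    with np.errstate(invalid="ignore"):
        rms_wl = np.sqrt(np.nanmean(resid**2, axis=0))
        rms_delay = np.sqrt(np.nanmean(resid**2, axis=1))
    return SequentialFitResult(
        time_constants=taus_sorted, eads=eads, irf_fwhm=float(irf),
        time_zero=float(t0), residual_rms=rms, covariance=cov,
        rms_per_wavelength=rms_wl, rms_per_delay=rms_delay,
        degenerate=degenerate)


@dataclass
class BandFitResult:
    tau: float                 # ps
    amplitude: float
    time_zero: float
    covariance: np.ndarray
    identifiable: bool = True


def fit_single_exponential_band(
    delays_ps,
    amplitudes,
    irf_fwhm_fs: float = 150.0,
    fit_t0: bool = False,
    baseline: bool = False,
) -> BandFitResult:
    """IRF-convolved single-exponential fit of a band-integrated trace."""
    t = np.asarray(delays_ps, float)
    y = np.asarray(amplitudes, float)
    if len(t) < 8:
        raise TAFitError("need >= 8 delay points")
    sigma = irf_fwhm_fs * 1e-3 * FWHM_TO_SIGMA
    scale = np.max(np.abs(y))
    if scale == 0 or np.ptp(y) < 1e-12:
        return BandFitResult(tau=math.nan, amplitude=0.0, time_zero=0.0,
                             covariance=np.full((2, 2), np.nan),
                             identifiable=False)

    # initial tau from the 1/e crossing of the normalized trace
    ynorm = y / y[np.argmax(np.abs(y))]
    below = np.nonzero(ynorm < math.exp(-1.0))[0]
    tau0 = t[below[0]] if len(below) else 0.5 * t[-1]
    tau0 = max(tau0, 3.0 * (t[1] - t[0]))

    def model(p):
        ltau, amp = p[0], p[1]
        t0 = p[2] if fit_t0 else 0.0
        base = p[3] if baseline else 0.0
        c = exp_gauss_convolution(t, math.exp(ltau), sigma, t0)
        return amp * c / max(c.max(), 1e-300) + base

    def residual(p):
        return model(p) - y

    p0 = [math.log(tau0), float(y[np.argmax(np.abs(y))])]
    if fit_t0:
        p0.append(0.0)
    if baseline:
        p0.append(0.0)
    res = least_squares(residual, p0, method="lm", max_nfev=5000)
    tau = math.exp(res.x[0])
    amp = float(res.x[1])
    _, s, vt = np.linalg.svd(res.jac, full_matrices=False)
    s = np.where(s > s.max() * 1e-12, s, np.inf)
    dof = max(len(t) - len(res.x), 1)
    cov_log = (vt.T / s**2) @ vt * (2.0 * res.cost / dof)
    j = np.eye(len(res.x))
    j[0, 0] = tau
    cov = j @ cov_log @ j
    if tau <= 0 or not math.isfinite(tau):
        raise TAFitError("fitted tau non-positive: model misfit")
    identifiable = abs(amp) > 10.0 * math.sqrt(max(cov[1, 1], 0.0)) \
        if math.isfinite(cov[1, 1]) else True
    return BandFitResult(tau=tau, amplitude=amp,
                         time_zero=float(res.x[2]) if fit_t0 else 0.0,
                         covariance=cov, identifiable=identifiable)
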