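"""Synthetic transient-absorption surfaces and band traces.

Surfaces are sums over sequential compartments of (concentration profile x
EADS), with EADS built from Gaussian bands in wavelength, optional chirp
applied on top, then Gaussian noise.  Deterministic under fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..ta import ChirpModel, TASurface, exp_gauss_convolution, \
    sequential_concentrations, FWHM_TO_SIGMA

# band lists: (center nm, fwhm nm, amplitude mOD); negative = bleach
_DEFAULT_EADS = (
    ((470.0, 40.0, -8.0), (560.0, 55.0, 4.5)),
    ((475.0, 45.0, -5.0), (620.0, 70.0, 2.0)),
)


@dataclass
class SyntheticTASpec:
    time_constants: tuple[float, ...] = (7.6, 50.0)   # ps
    eads_bands: tuple = _DEFAULT_EADS
    irf_fwhm: float = 150.0      # fs
    time_zero: float = 0.0       # ps
    chirp: ChirpModel = field(default_factory=ChirpModel)
    noise_mod: float = 0.0       # mOD absolute Gaussian sigma
    delays: np.ndarray = field(
        default_factory=lambda: np.concatenate([
            np.linspace(-1.0, 2.0, 31), np.linspace(2.5, 200.0, 80)]))
    wavelengths: np.ndarray = field(
        default_factory=lambda: np.linspace(420.0, 700.0, 57))
    seed: int = 0

    def __post_init__(self):
        taus = np.asarray(self.time_constants, float)
        if (taus <= 0).any() or len(np.unique(taus)) != len(taus):
            raise ValueError("time constants must be positive and distinct")
        if len(self.eads_bands) != len(taus):
            raise ValueError("one EADS band list per compartment")


def eads_from_bands(bands, wavelengths: np.ndarray) -> np.ndarray:
    wl = np.asarray(wavelengths, float)
    spectrum = np.zeros_like(wl)
    for center, fwhm, amp in bands:
        sig = fwhm * FWHM_TO_SIGMA
        spectrum += amp * np.exp(-((wl - center) ** 2) / (2.0 * sig**2))
    return spectrum


def make_ta_surface(spec: SyntheticTASpec | None = None
                    ) -> tuple[TASurface, dict]:
    """Generate a surface plus its ground truth (taus, EADS, chirp)."""
    spec = spec or SyntheticTASpec()
    rng = np.random.default_rng(spec.seed)
    conc = sequential_concentrations(spec.time_constants, spec.irf_fwhm,
                                     spec.time_zero, spec.delays)
    eads = np.array([eads_from_bands(b, spec.wavelengths)
                     for b in spec.eads_bands])
    clean = conc @ eads
    # apply chirp: signal at wavelength j appears late by offset(j)
    offsets = spec.chirp.offset(spec.wavelengths)
    data = np.empty_like(clean)
    for j, off in enumerate(offsets):
        data[:, j] = np.interp(spec.delays - off, spec.delays, clean[:, j],
                               left=clean[0, j], right=clean[-1, j])
    if spec.noise_mod > 0:
        data = data + spec.noise_mod * rng.standard_normal(data.shape)
    surface = TASurface(spec.delays.copy(), spec.wavelengths.copy(), data,
                        irf_fwhm=spec.irf_fwhm, time_zero=spec.time_zero)
    truth = {"time_constants": tuple(spec.time_constants), "eads": eads,
             "chirp": spec.chirp, "irf_fwhm": spec.irf_fwhm,
             "time_zero": spec.time_zero}
    return surface, truth


def make_band_trace(tau_ps: float = 4.5, irf_fwhm_fs: float = 150.0,
                    n_points: int = 30, t_max_ps: float = 25.0,
                    relative_noise: float = 0.02, amplitude: float = 1.0,
                    seed: int = 0) -> tuple[np.ndarray, np.ndarray, dict]:
    """Single-exponential band-integrated decay trace with IRF convolution
    and relative Gaussian noise.  Returns (delays_ps, amplitudes, truth)."""
    rng = np.random.default_rng(seed)
    delays = np.linspace(-1.0, t_max_ps, n_points)
    sigma = irf_fwhm_fs * 1e-3 * FWHM_TO_SIGMA
    clean = exp_gauss_convolution(delays, tau_ps, sigma, 0.0)
    clean = amplitude * clean / clean.max()
    noisy = clean + relative_noise * amplitude * rng.standard_normal(n_points)
    truth = {"tau": tau_ps, "irf_fwhm": irf_fwhm_fs, "amplitude": amplitude}
    return delays, noisy, truth
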