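"""Unit conversions at the I/O boundary.

Internally the quantum-dynamics code works in atomic-style units with
hbar = 1, time in fs and angular frequency (= energy) in rad/fs.
Positions and momenta along the vibrational mode are dimensionless,
measured in units of the ground-state oscillator length.
"""

from __future__ import annotations

import math

#: Speed of light in cm/fs.
C_CM_PER_FS = 2.99792458e-5
#: Speed of light in nm/fs.
C_NM_PER_FS = 299.792458
#: hbar in eV*fs.
HBAR_EV_FS = 0.6582119569
#: Molar gas constant in J mol^-1 K^-1.
R_GAS = 8.31446
#: Boltzmann constant in cm^-1 / K.
KB_CM1_PER_K = 0.695034800


def wavenumber_to_angfreq(wavenumber_cm1: float) -> float:
    """Convert a wavenumber in cm^-1 to angular frequency in rad/fs."""
    return 2.0 * math.pi * C_CM_PER_FS * wavenumber_cm1


def angfreq_to_wavenumber(omega_rad_fs: float) -> float:
    return omega_rad_fs / (2.0 * math.pi * C_CM_PER_FS)


def ev_to_angfreq(energy_ev: float) -> float:
    """Convert an energy in eV to angular frequency in rad/fs (E/hbar)."""
    return energy_ev / HBAR_EV_FS


def wavelength_to_angfreq(wavelength_nm: float) -> float:
    """Convert an optical carrier wavelength in nm to rad/fs."""
    if wavelength_nm <= 0:
        raise ValueError("wavelength must be positive")
    return 2.0 * math.pi * C_NM_PER_FS / wavelength_nm


def transform_limited_bandwidth_thz(fwhm_fs: float) -> float:
    """FWHM spectral bandwidth (THz) of a transform-limited Gaussian pulse.

    Uses the Gaussian time-bandwidth product dnu * dt = 0.441, so a 100-fs
    pulse supports ~4.4 THz of impulsively driven vibrational bandwidth.
    """
    if fwhm_fs <= 0:
        raise ValueError("pulse duration must be positive")
    return 441.0 / fwhm_fs


def thermal_occupation(wavenumber_cm1: float, temperature_k: float) -> float:
    """Bose-Einstein mean occupation of a mode at temperature T."""
    if temperature_k <= 0:
        return 0.0
    x = wavenumber_cm1 / (KB_CM1_PER_K * temperature_k)
    if x > 700.0:  # expm1 overflows; the occupation is numerically zero
        return 0.0
    return 1.0 / math.expm1(x)
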