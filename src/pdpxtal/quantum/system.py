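"""Domain types for the two-surface vibronic model.

The model is a single vibrational mode shared by two electronic surfaces
(S0 and S1) whose minima are separated by a dimensionless displacement
along the mode.  Each surface carries a truncated harmonic ladder of
``n_vib`` states; the optical coupling between the surfaces is dressed by
Franck-Condon overlap factors of the displaced oscillators.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import expm

from ..units import ev_to_angfreq, wavenumber_to_angfreq

S0 = 0
S1 = 1


class InvalidSystemError(ValueError):
    pass


@dataclass(frozen=True)
class VibronicSystem:
    """Two electronic surfaces sharing one displaced vibrational mode.

    Parameters
    ----------
    mode_frequency : float
        Vibrational wavenumber in cm^-1 (> 0).
    displacement : float
        Shift of the S1 minimum along the mode, in units of the
        ground-state oscillator length (dimensionless).
    electronic_gap : float
        Energy between the S0 and S1 minima, in eV.
    transition_dipole : float
        Dimensionless scale of the dipole-field (Rabi) coupling.
    n_vib : int
        Number of vibrational basis states per surface (>= 2).
    temperature : float
        Temperature in K used for the thermal initial state.
    double_well : float
        Coefficient of an optional quartic term c4 * q^4 (in units of the
        mode quantum) added to both surfaces; 0 means purely harmonic.
    """

    mode_frequency: float = 120.0
    displacement: float = 1.0
    electronic_gap: float = 3.1
    transition_dipole: float = 1.0
    n_vib: int = 16
    temperature: float = 293.0
    double_well: float = 0.0

    def __post_init__(self) -> None:
        if self.mode_frequency <= 0:
            raise InvalidSystemError("mode_frequency must be positive")
        if self.n_vib < 2:
            raise InvalidSystemError("n_vib must be at least 2")
        if not math.isfinite(self.displacement):
            raise InvalidSystemError("displacement must be finite")

    @property
    def omega(self) -> float:
        """Mode angular frequency in rad/fs."""
        return wavenumber_to_angfreq(self.mode_frequency)

    @property
    def gap_angfreq(self) -> float:
        """Electronic 0-0 gap in rad/fs."""
        return ev_to_angfreq(self.electronic_gap)

    @property
    def dim(self) -> int:
        """Dimension of the composite basis {|e, v>}."""
        return 2 * self.n_vib


@dataclass(frozen=True)
class Pulse:
    """Gaussian optical pulse in the rotating-wave description.

    ``peak_rabi_energy`` is the peak dipole-field coupling hbar*Omega_0 in
    eV, defined so that for a bare two-level system (n_vib = 1 limit) the
    standard pulse-area formula applies:
    area = Omega_0 * fwhm * sqrt(pi / (4 ln 2)).

    ``detuning_cm1`` is the carrier detuning from the electronic 0-0 gap
    in cm^-1; it is the quantity that matters on the scale of the model
    (the nominal carrier wavelength is carried along as metadata).
    """

    center_time: float = 0.0          # fs
    fwhm: float = 100.0               # fs
    carrier_wavelength: float = 400.0  # nm, metadata
    peak_rabi_energy: float = 0.01    # eV
    phase: float = 0.0                # rad
    detuning_cm1: float = 0.0

    def __post_init__(self) -> None:
        if self.fwhm <= 0:
            raise InvalidSystemError("pulse fwhm must be positive")
        if self.carrier_wavelength <= 0:
            raise InvalidSystemError("carrier wavelength must be positive")

    @property
    def peak_rabi(self) -> float:
        """Peak Rabi angular frequency Omega_0 in rad/fs."""
        return ev_to_angfreq(self.peak_rabi_energy)

    @property
    def area(self) -> float:
        """Pulse area integral of Omega(t) dt for the two-level limit."""
        return self.peak_rabi * self.fwhm * math.sqrt(math.pi / (4 * math.log(2)))

    def envelope(self, t: float | np.ndarray) -> float | np.ndarray:
        """Gaussian Rabi envelope Omega(t) in rad/fs."""
        x = (np.asarray(t) - self.center_time) / self.fwhm
        return self.peak_rabi * np.exp(-4.0 * math.log(2.0) * x * x)

    def with_area(self, area: float) -> "Pulse":
        """Copy of this pulse whose two-level pulse area equals ``area``."""
        omega0 = area / (self.fwhm * math.sqrt(math.pi / (4 * math.log(2))))
        return Pulse(
            center_time=self.center_time,
            fwhm=self.fwhm,
            carrier_wavelength=self.carrier_wavelength,
            peak_rabi_energy=omega0 * 0.6582119569,
            phase=self.phase,
            detuning_cm1=self.detuning_cm1,
        )


@dataclass(frozen=True)
class DissipationModel:
    """Lindblad timescales of the open-system model.

    s1_lifetime : S1 -> S0 population decay time in ps.
    vib_dephasing_time : pure dephasing time of vibrational coherences
        within each surface, in ps.
    elec_dephasing_time : pure dephasing time of the S0-S1 electronic
        coherence, in fs.
    """

    s1_lifetime: float = 50.0         # ps
    vib_dephasing_time: float = 1.0   # ps
    elec_dephasing_time: float = 50.0  # fs

    def __post_init__(self) -> None:
        for name in ("s1_lifetime", "vib_dephasing_time", "elec_dephasing_time"):
            if getattr(self, name) <= 0:
                raise InvalidSystemError(f"{name} must be positive")

    @property
    def gamma_decay(self) -> float:
        """S1 population decay rate in fs^-1."""
        return 1.0 / (self.s1_lifetime * 1000.0)

    @property
    def kappa_vib(self) -> float:
        """Vibrational pure-dephasing rate in fs^-1 (v,v+1 coherence decay)."""
        return 1.0 / (self.vib_dephasing_time * 1000.0)

    @property
    def gamma_elec(self) -> float:
        """Electronic pure-dephasing rate in fs^-1."""
        return 1.0 / self.elec_dephasing_time


def franck_condon_matrix(displacement: float, n_vib: int, pad: int = 12) -> np.ndarray:
    """Franck-Condon overlaps F[m, n] = <m_e | n_g> for displaced oscillators.

    Built as matrix elements of the displacement operator D(-alpha) with
    alpha = d / sqrt(2), evaluated by exponentiating the truncated
    generator in a padded basis so truncation errors stay below ~1e-10
    for the returned block.  <0_e|0_g> = exp(-d^2/4).
    """
    n_tot = n_vib + pad
    alpha = displacement / math.sqrt(2.0)
    a = np.diag(np.sqrt(np.arange(1, n_tot)), k=1)  # annihilation
    gen = -alpha * (a.T - a)  # -alpha*(a^dagger - a), alpha real
    d_op = expm(gen)
    return d_op[:n_vib, :n_vib].copy()


def harmonic_eigenfunctions(q: np.ndarray, n_vib: int) -> np.ndarray:
    """Dimensionless harmonic-oscillator eigenfunctions psi_v(q).

    Returns an array of shape (n_vib, len(q)).  Uses the stable recurrence
    psi_{v+1} = sqrt(2/(v+1)) q psi_v - sqrt(v/(v+1)) psi_{v-1}.
    """
    q = np.asarray(q, dtype=float)
    psi = np.zeros((n_vib, q.size))
    psi[0] = np.pi ** -0.25 * np.exp(-0.5 * q * q)
    if n_vib > 1:
        psi[1] = math.sqrt(2.0) * q * psi[0]
    for v in range(1, n_vib - 1):
        psi[v + 1] = (
            math.sqrt(2.0 / (v + 1)) * q * psi[v]
            - math.sqrt(v / (v + 1)) * psi[v - 1]
        )
    return psi


def position_operator(n_vib: int) -> np.ndarray:
    """Dimensionless position operator q = (a + a^dagger)/sqrt(2)."""
    a = np.diag(np.sqrt(np.arange(1, n_vib)), k=1)
    return (a + a.T) / math.sqrt(2.0)


def momentum_operator(n_vib: int) -> np.ndarray:
    """Dimensionless momentum operator p = i(a^dagger - a)/sqrt(2)."""
    a = np.diag(np.sqrt(np.arange(1, n_vib)), k=1)
    return 1j * (a.T - a) / math.sqrt(2.0)
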