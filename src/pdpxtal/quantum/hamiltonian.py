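"""Composite-basis Hamiltonian of the driven two-surface vibronic system.

Basis ordering: index e * n_vib + v with e = 0 (S0) and e = 1 (S1); the
S1 vibrational states are the eigenstates of the displaced surface, so the
field-free Hamiltonian is block diagonal and the optical coupling block is
the Franck-Condon matrix scaled by the pulse envelope.

Two frames are supported:

* ``"rwa"`` (default): rotating frame at the electronic 0-0 gap.  Each
  pulse contributes (Omega_j(t)/2) e^{-i(Delta_j t - phi_j)} on the
  up-coupling block, where Delta_j is the carrier detuning from the gap.
  This is the frame in which femtosecond optical carriers (~750 THz) are
  integrable with practical step sizes.
* ``"full"``: lab frame with the explicit optical carrier, for validation
  on tiny systems only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from ..units import wavelength_to_angfreq, wavenumber_to_angfreq
from .system import (
    InvalidSystemError,
    Pulse,
    VibronicSystem,
    franck_condon_matrix,
    position_operator,
)


def surface_hamiltonian(system: VibronicSystem) -> np.ndarray:
    """Single-surface vibrational Hamiltonian in rad/fs (harmonic ladder
    plus the optional quartic term evaluated on the position DVR grid)."""
    n = system.n_vib
    omega = system.omega
    h = omega * (np.diag(np.arange(n) + 0.5))
    if system.double_well != 0.0:
        # evaluate c4*q^4 on the DVR grid (eigenbasis of q), project back
        pad = 12
        q_big = position_operator(n + pad)
        x, vecs = np.linalg.eigh(q_big)
        quartic = vecs @ np.diag(system.double_well * omega * x**4) @ vecs.T
        h = h + quartic[:n, :n]
    return h


@dataclass
class VibronicHamiltonian:
    """Callable time-dependent Hamiltonian H(t) on the composite basis."""

    system: VibronicSystem
    pulses: Sequence[Pulse]
    frame: str = "rwa"

    def __post_init__(self) -> None:
        if self.frame not in ("rwa", "full"):
            raise ValueError("frame must be 'rwa' or 'full'")
        n = self.system.n_vib
        h_vib = surface_hamiltonian(self.system)
        self.h0 = np.zeros((2 * n, 2 * n))
        self.h0[:n, :n] = h_vib
        self.h0[n:, n:] = h_vib
        if self.frame == "full":
            self.h0[n:, n:] += self.system.gap_angfreq * np.eye(n)
        # up-coupling block  U = sum |e,m><g,n| F[m,n]
        self.fc = franck_condon_matrix(self.system.displacement, n)
        self._mu = self.system.transition_dipole

    def coupling_block(self, t: float, pulse: Pulse) -> np.ndarray:
        """Complex S1<-S0 coupling block of one pulse at time t."""
        env = pulse.envelope(t) * self._mu
        if self.frame == "rwa":
            delta = wavenumber_to_angfreq(pulse.detuning_cm1)
            phase = np.exp(-1j * (delta * t - pulse.phase))
            return 0.5 * env * phase * self.fc
        carrier = wavelength_to_angfreq(pulse.carrier_wavelength)
        return env * math.cos(carrier * t + pulse.phase) * self.fc

    def __call__(self, t: float) -> np.ndarray:
        n = self.system.n_vib
        h = np.array(self.h0, dtype=complex)
        for pulse in self.pulses:
            block = self.coupling_block(t, pulse)
            h[n:, :n] += block
            h[:n, n:] += block.conj().T
        return h


def build_hamiltonian(
    system: VibronicSystem,
    pulses: Sequence[Pulse] = (),
    frame: str = "rwa",
) -> VibronicHamiltonian:
    """Build the time-dependent Hamiltonian contract for a vibronic system.

    Returns a callable ``H(t)`` (Hermitian, rad/fs).  The field-free part
    is block diagonal in the electronic state; the coupling block scales
    linearly with the pulse field amplitude and carries the Franck-Condon
    factors of the displaced surfaces.
    """
    if system.mode_frequency <= 0:
        raise InvalidSystemError("mode_frequency must be positive")
    return VibronicHamiltonian(system, list(pulses), frame=frame)
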