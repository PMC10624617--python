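"""Liouville-von Neumann propagation with Lindblad dissipation.

The density matrix on the composite basis evolves as

    drho/dt = -i [H(t), rho] + D_decay + D_vib + D_elec

with three completely positive dissipators matching the model timescales:
S1 -> S0 population decay acting per vibrational level, pure vibrational
dephasing via per-level projectors within each surface, and electronic
pure dephasing via the population-difference operator.  Integration uses
an adaptive embedded Runge-Kutta method (no stochastic unravelling, fully
deterministic).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .hamiltonian import VibronicHamiltonian, build_hamiltonian
from .system import S0, S1, DissipationModel, Pulse, VibronicSystem


class IntegrationFailureError(RuntimeError):
    """Raised when the propagation violates its conservation diagnostics."""


@dataclass
class VibronicDensityMatrix:
    """Snapshot of the vibronic density matrix at one time (fs)."""

    time: float
    matrix: np.ndarray

    @property
    def n_vib(self) -> int:
        return self.matrix.shape[0] // 2

    def block(self, electronic_state: int) -> np.ndarray:
        """Within-surface vibrational block rho^{ee}."""
        n = self.n_vib
        s = slice(0, n) if electronic_state == S0 else slice(n, 2 * n)
        return self.matrix[s, s]

    def population(self, electronic_state: int) -> float:
        return float(np.trace(self.block(electronic_state)).real)

    @property
    def trace(self) -> float:
        return float(np.trace(self.matrix).real)

    def hermiticity_defect(self) -> float:
        return float(np.abs(self.matrix - self.matrix.conj().T).max())

    def min_eigenvalue(self) -> float:
        return float(np.linalg.eigvalsh((self.matrix + self.matrix.conj().T) / 2).min())


def thermal_state(system: VibronicSystem) -> VibronicDensityMatrix:
    """Boltzmann-populated vibrational levels of S0 (diagonal, trace 1)."""
    n = system.n_vib
    if system.temperature <= 0:
        pops = np.zeros(n)
        pops[0] = 1.0
    else:
        kt_cm1 = 0.695034800 * system.temperature
        energies = system.mode_frequency * np.arange(n)
        pops = np.exp(-energies / kt_cm1)
        pops /= pops.sum()
    rho = np.zeros((2 * n, 2 * n), dtype=complex)
    rho[:n, :n] = np.diag(pops)
    return VibronicDensityMatrix(time=0.0, matrix=rho)


def ground_state(system: VibronicSystem) -> VibronicDensityMatrix:
    """Pure |S0, v=0> state."""
    rho = np.zeros((system.dim, system.dim), dtype=complex)
    rho[0, 0] = 1.0
    return VibronicDensityMatrix(time=0.0, matrix=rho)


def _make_rhs(ham: VibronicHamiltonian, dissipation: DissipationModel | None):
    n = ham.system.n_vib
    dim = 2 * n
    if dissipation is not None:
        g_dec = dissipation.gamma_decay
        kappa = dissipation.kappa_vib
        g_el = dissipation.gamma_elec
    else:
        g_dec = kappa = g_el = 0.0

    def rhs(t: float, y: np.ndarray) -> np.ndarray:
        rho = y.reshape(dim, dim)
        h = ham(t)
        d = -1j * (h @ rho - rho @ h)
        if g_dec:
            # per-level S1 -> S0 decay
            ee_diag = np.diag(rho[n:, n:]).real
            d[np.arange(n), np.arange(n)] += g_dec * ee_diag
            d[n:, :] -= 0.5 * g_dec * rho[n:, :]
            d[:, n:] -= 0.5 * g_dec * rho[:, n:]
        if kappa:
            # per-level projector dephasing within each surface
            d -= kappa * rho
            d[np.arange(dim), np.arange(dim)] += kappa * np.diag(rho)
        if g_el:
            # electronic pure dephasing (population-difference operator)
            d[:n, n:] -= g_el * rho[:n, n:]
            d[n:, :n] -= g_el * rho[n:, :n]
        return d.ravel()

    return rhs


def propagate(
    system: VibronicSystem,
    pulses: Sequence[Pulse],
    dissipation: DissipationModel | None,
    t_span: tuple[float, float],
    dt: float,
    initial: VibronicDensityMatrix | str = "thermal",
    frame: str = "rwa",
    rtol: float = 1e-8,
    atol: float = 1e-11,
) -> list[VibronicDensityMatrix]:
    """Propagate the density matrix and return snapshots every ``dt`` fs.

    ``initial`` may be a VibronicDensityMatrix, ``"thermal"`` (Boltzmann
    S0 populations at the system temperature) or ``"ground"`` (|S0, 0>).
    Raises IntegrationFailureError if, without dissipation, the trace
    drifts by more than 1e-4 (advice: smaller tolerances or larger n_vib).
    """
    pulses = sorted(pulses, key=lambda p: p.center_time)
    ham = build_hamiltonian(system, pulses, frame=frame)
    if initial == "thermal":
        rho0 = thermal_state(system)
    elif initial == "ground":
        rho0 = ground_state(system)
    else:
        rho0 = initial
    t0, t1 = t_span
    times = np.arange(t0, t1 + 0.5 * dt, dt)
    max_step = np.inf
    if pulses:
        max_step = min(p.fwhm for p in pulses) / 4.0
    if frame == "full":
        carrier = max(
            2.0 * np.pi * 299.792458 / p.carrier_wavelength for p in pulses
        ) if pulses else system.gap_angfreq
        max_step = min(max_step, 2.0 * np.pi / carrier / 12.0)

    sol = solve_ivp(
        _make_rhs(ham, dissipation),
        (t0, t1),
        rho0.matrix.astype(complex).ravel(),
        t_eval=times,
        method="DOP853",
        rtol=rtol,
        atol=atol,
        max_step=max_step,
    )
    if not sol.success:
        raise IntegrationFailureError(sol.message)
    states = [
        VibronicDensityMatrix(time=float(t), matrix=sol.y[:, i].reshape(system.dim, system.dim))
        for i, t in enumerate(sol.t)
    ]
    if dissipation is None:
        drift = max(abs(s.trace - rho0.trace) for s in states)
        if drift > 1e-4:
            raise IntegrationFailureError(
                f"trace drift {drift:.2e} without dissipation; reduce dt/tolerances "
                "or increase n_vib"
            )
    return states
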