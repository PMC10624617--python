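"""Wigner phase-space transform of within-surface vibrational blocks.

The distribution is evaluated exactly for the truncated basis: the
position-space density matrix is reconstructed from harmonic-oscillator
eigenfunctions and the Wigner kernel is integrated by a discrete Fourier
sum along the offset coordinate,

    W(q, p) = (1/pi) int dy  rho(q + y, q - y) e^{-2 i p y}.

Marginals over p and q reproduce the position and momentum densities and
the full integral equals the electronic-state population.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .propagate import VibronicDensityMatrix
from .system import S0, harmonic_eigenfunctions


class GridTruncationError(ValueError):
    """Raised in strict mode when the grid clips the state."""


@dataclass
class WignerDistribution:
    electronic_state: int
    q_grid: np.ndarray
    p_grid: np.ndarray
    values: np.ndarray  # shape (len(q_grid), len(p_grid)), real

    def integral(self) -> float:
        dq = self.q_grid[1] - self.q_grid[0]
        dp = self.p_grid[1] - self.p_grid[0]
        return float(self.values.sum() * dq * dp)

    def marginal_q(self) -> np.ndarray:
        """Position density: integral of W over p."""
        dp = self.p_grid[1] - self.p_grid[0]
        return self.values.sum(axis=1) * dp

    def marginal_p(self) -> np.ndarray:
        dq = self.q_grid[1] - self.q_grid[0]
        return self.values.sum(axis=0) * dq


def position_density(
    state: VibronicDensityMatrix, electronic_state: int, q_grid: np.ndarray
) -> np.ndarray:
    """Diagonal of the position-space density matrix for one surface."""
    block = state.block(electronic_state)
    psi = harmonic_eigenfunctions(np.asarray(q_grid, float), state.n_vib)
    return np.einsum("iq,ij,jq->q", psi, block, psi).real


def wigner_transform(
    state: VibronicDensityMatrix,
    electronic_state: int = S0,
    q_grid: np.ndarray | None = None,
    p_grid: np.ndarray | None = None,
    n_offset: int = 257,
    strict: bool = False,
) -> WignerDistribution:
    """Wigner quasi-probability of one surface's vibrational block.

    Grids default to symmetric ranges wide enough for the truncated basis.
    In strict mode a position density at the grid edge above 1e-6 of the
    maximum raises GridTruncationError (otherwise only the exact transform
    of the truncated state is returned, which may clip).
    """
    n = state.n_vib
    extent = np.sqrt(2.0 * n + 1.0) + 2.0
    if q_grid is None:
        q_grid = np.linspace(-extent, extent, 81)
    if p_grid is None:
        p_grid = np.linspace(-extent, extent, 81)
    q_grid = np.asarray(q_grid, float)
    p_grid = np.asarray(p_grid, float)

    dens = position_density(state, electronic_state, q_grid)
    if dens.max() > 0:
        edge = max(abs(dens[0]), abs(dens[-1])) / dens.max()
        if strict and edge > 1e-6:
            raise GridTruncationError(
                f"position density at grid edge is {edge:.2e} of maximum; widen q_grid"
            )

    block = state.block(electronic_state)
    y = np.linspace(-extent, extent, n_offset)
    dy = y[1] - y[0]
    kernel = np.exp(-2j * np.outer(y, p_grid))  # (n_offset, n_p)
    values = np.empty((q_grid.size, p_grid.size))
    for i, q in enumerate(q_grid):
        psi_plus = harmonic_eigenfunctions(q + y, n)   # (n, n_offset)
        psi_minus = harmonic_eigenfunctions(q - y, n)
        # rho(q+y, q-y) over the offset grid
        rho_off = np.einsum("iy,ij,jy->y", psi_plus, block, psi_minus.conj())
        values[i] = (rho_off @ kernel).real * dy / np.pi
    return WignerDistribution(electronic_state, q_grid, p_grid, values)


def phase_space_moments(w: WignerDistribution) -> tuple[float, float, float]:
    """(mean_q, mean_p, population) by grid quadrature of the Wigner function."""
    dq = w.q_grid[1] - w.q_grid[0]
    dp = w.p_grid[1] - w.p_grid[0]
    pop = w.values.sum() * dq * dp
    if abs(pop) < 1e-12:
        raise ValueError("zero population: phase-space moments undefined")
    mean_q = (w.values.sum(axis=1) * dp * w.q_grid).sum() * dq / pop
    mean_p = (w.values.sum(axis=0) * dq * w.p_grid).sum() * dp / pop
    return float(mean_q), float(mean_p), float(pop)
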