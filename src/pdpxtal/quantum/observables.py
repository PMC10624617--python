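"""Population, coherence and phase-space observables of propagation runs."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .propagate import VibronicDensityMatrix
from .system import S0, S1, momentum_operator, position_operator


def coherence_magnitude(state: VibronicDensityMatrix, electronic_state: int) -> float:
    """Sum of moduli of within-surface vibrational coherences.

    Defined as sum_{v < v'} |rho^{ee}_{v v'}|; zero iff the vibrational
    block of the chosen surface is diagonal.  The |<q>| envelope is
    exposed separately (mean_q in CoherenceTrace) for comparison.
    """
    block = state.block(electronic_state)
    iu = np.triu_indices(block.shape[0], k=1)
    return float(np.abs(block[iu]).sum())


def block_moments(state: VibronicDensityMatrix, electronic_state: int) -> tuple[float, float]:
    """(mean_q, mean_p) of one surface relative to that surface's minimum.

    Computed directly from the vibrational block with ladder operators;
    returns (0, 0) for an unpopulated surface.
    """
    block = state.block(electronic_state)
    pop = float(np.trace(block).real)
    if pop < 1e-12:
        return 0.0, 0.0
    n = block.shape[0]
    q_op = position_operator(n)
    p_op = momentum_operator(n)
    mean_q = float(np.trace(block @ q_op).real) / pop
    mean_p = float(np.trace(block @ p_op).real) / pop
    return mean_q, mean_p


@dataclass
class CoherenceTrace:
    """Time traces of populations, coherences and phase-space centroids."""

    times: np.ndarray
    pop_s0: np.ndarray
    pop_s1: np.ndarray
    coh_s0: np.ndarray
    coh_s1: np.ndarray
    mean_q_s0: np.ndarray
    mean_p_s0: np.ndarray
    mean_q_s1: np.ndarray
    mean_p_s1: np.ndarray

    @classmethod
    def from_states(cls, states: list[VibronicDensityMatrix]) -> "CoherenceTrace":
        times = np.array([s.time for s in states])
        cols = {name: np.empty(len(states)) for name in (
            "pop_s0", "pop_s1", "coh_s0", "coh_s1",
            "mean_q_s0", "mean_p_s0", "mean_q_s1", "mean_p_s1")}
        for i, s in enumerate(states):
            cols["pop_s0"][i] = s.population(S0)
            cols["pop_s1"][i] = s.population(S1)
            cols["coh_s0"][i] = coherence_magnitude(s, S0)
            cols["coh_s1"][i] = coherence_magnitude(s, S1)
            cols["mean_q_s0"][i], cols["mean_p_s0"][i] = block_moments(s, S0)
            cols["mean_q_s1"][i], cols["mean_p_s1"][i] = block_moments(s, S1)
        return cls(times=times, **cols)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "time_fs": self.times,
            "pop_s0": self.pop_s0,
            "pop_s1": self.pop_s1,
            "coh_s0": self.coh_s0,
            "coh_s1": self.coh_s1,
            "mean_q_s0": self.mean_q_s0,
            "mean_p_s0": self.mean_p_s0,
            "mean_q_s1": self.mean_q_s1,
            "mean_p_s1": self.mean_p_s1,
        })

    def peak_coherence(self, electronic_state: int, after: float | None = None) -> float:
        coh = self.coh_s0 if electronic_state == S0 else self.coh_s1
        if after is None:
            return float(coh.max())
        mask = self.times >= after
        return float(coh[mask].max())
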