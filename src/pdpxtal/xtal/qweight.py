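"""Q-weighted structure-factor differences.

Bayesian-style down-weighting of unreliable difference amplitudes:
w = [1 + sig^2(dF)/<sig^2(dF)> + alpha * dF^2/<dF^2>]^-1.  Large-sigma and
outlier differences get small weights; with uniform statistics all weights
are equal.  The alpha term guards against outliers and defaults to 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .types import ReflectionSet


@dataclass
class QWeightResult:
    """Weighted differences: ``reflections.data`` carries F = w·ΔF plus
    columns delta_F (raw), weight and sigF = propagated sigma(ΔF)."""

    reflections: ReflectionSet
    mean_weight: float
    alpha: float

    @property
    def weights(self) -> np.ndarray:
        return self.reflections.data["weight"].to_numpy(float)


def q_weight_differences(light: ReflectionSet, dark: ReflectionSet,
                         alpha: float = 1.0) -> QWeightResult:
    """Q-weighted F_light − F_dark on the common index set.

    Both sets must already sit on a common scale.  Degenerate statistics
    (all sigmas zero, or all differences zero) drop the corresponding term
    rather than dividing by zero.
    """
    merged = light.join_common(dark)
    d_f = merged["F_a"].to_numpy(float) - merged["F_b"].to_numpy(float)
    sig = np.sqrt(merged["sigF_a"].to_numpy(float) ** 2
                  + merged["sigF_b"].to_numpy(float) ** 2)
    mean_var = float(np.mean(sig ** 2))
    mean_d2 = float(np.mean(d_f ** 2))
    denom = np.ones_like(d_f)
    if mean_var > 0:
        denom = denom + sig ** 2 / mean_var
    if mean_d2 > 0:
        denom = denom + alpha * d_f ** 2 / mean_d2
    w = 1.0 / denom
    df = merged[["h", "k", "l"]].copy()
    df["F"] = w * d_f
    df["sigF"] = sig
    df["delta_F"] = d_f
    df["weight"] = w
    refl = ReflectionSet(light.cell, df, d_min=light.d_min or dark.d_min)
    return QWeightResult(reflections=refl, mean_weight=float(w.mean()),
                         alpha=float(alpha))
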