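"""Least-squares scaling of observed onto calculated amplitudes.

Log-linear model F_obs ~ k * exp(-1/4 s^T B s) * F_calc with an isotropic
(1-parameter) or anisotropic (6-parameter symmetric tensor) B, solved in
log space.  The scaled set carries the observed amplitudes divided by the
fitted scale so they sit on the calculated (absolute) scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .types import ReflectionError, ReflectionSet


class ScalingError(ValueError):
    pass


@dataclass
class ScaleReport:
    model: str                 # "isotropic" | "anisotropic"
    k: float
    b_tensor: np.ndarray       # 3x3 symmetric, Å²
    r_before: float
    r_after: float
    n_reflections: int

    @property
    def b_iso(self) -> float:
        return float(np.trace(self.b_tensor) / 3.0)


def _reciprocal_vectors(refl: ReflectionSet, hkl: np.ndarray) -> np.ndarray:
    """Cartesian reciprocal-lattice vectors s (Å⁻¹), rows per reflection."""
    frac = np.array(refl.cell.gemmi_cell().frac.mat)
    return hkl @ frac  # s = frac^T · hkl, rowwise


def scale_observed_to_calculated(
    obs: ReflectionSet,
    calc: ReflectionSet,
    model: str = "anisotropic",
    d_min: float | None = None,
) -> tuple[ReflectionSet, ScaleReport]:
    """Fit k and B so that k·exp(−¼ sᵀBs)·F_calc matches F_obs, then return
    the observed set divided by that scale (absolute scale) plus a report."""
    if model not in ("isotropic", "anisotropic"):
        raise ValueError("model must be 'isotropic' or 'anisotropic'")
    merged = obs.join_common(calc)
    if d_min is not None:
        cell = obs.cell.gemmi_cell()
        res = np.array([cell.calculate_d([int(h), int(k_), int(l)])
                        for h, k_, l in merged[["h", "k", "l"]].to_numpy()])
        merged = merged[res >= d_min].reset_index(drop=True)
    n_par = 2 if model == "isotropic" else 7
    if len(merged) < 10 * n_par:
        raise ScalingError(
            f"{len(merged)} common reflections < 10x {n_par} scale parameters")
    fo = merged["F_a"].to_numpy(float)
    fc = merged["F_b"].to_numpy(float)
    usable = (fo > 0) & (fc > 0)
    if usable.sum() < 10 * n_par:
        raise ReflectionError("too few positive amplitude pairs for scaling")
    hkl = merged.loc[usable, ["h", "k", "l"]].to_numpy(int)
    s = _reciprocal_vectors(obs, hkl)
    y = np.log(fo[usable]) - np.log(fc[usable])
    if model == "isotropic":
        cols = [np.ones(len(y)), -0.25 * (s ** 2).sum(axis=1)]
    else:
        sx, sy, sz = s[:, 0], s[:, 1], s[:, 2]
        cols = [np.ones(len(y)),
                -0.25 * sx * sx, -0.25 * sy * sy, -0.25 * sz * sz,
                -0.5 * sx * sy, -0.5 * sx * sz, -0.5 * sy * sz]
    A = np.column_stack(cols)
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    k = float(np.exp(coef[0]))
    if model == "isotropic":
        b = np.eye(3) * coef[1]
    else:
        b11, b22, b33, b12, b13, b23 = coef[1:]
        b = np.array([[b11, b12, b13], [b12, b22, b23], [b13, b23, b33]])

    def scale_factor(refl_set: ReflectionSet) -> np.ndarray:
        sv = _reciprocal_vectors(refl_set, refl_set.hkl)
        expo = -0.25 * np.einsum("ij,jk,ik->i", sv, b, sv)
        return k * np.exp(expo)

    # R-factors on the common set, obs vs scaled calc
    sc = k * np.exp(-0.25 * np.einsum("ij,jk,ik->i", s, b, s)) * fc[usable]
    fo_u = fo[usable]
    r_before = float(np.abs(fo_u - fc[usable]).sum() / fo_u.sum())
    r_after = float(np.abs(fo_u - sc).sum() / fo_u.sum())

    factors = scale_factor(obs)
    scaled = obs.copy_with(F=obs.amplitudes / factors, sigF=obs.sigmas / factors)
    report = ScaleReport(model=model, k=k, b_tensor=b,
                         r_before=r_before, r_after=r_after,
                         n_reflections=int(usable.sum()))
    return scaled, report
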