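"""Map synthesis and real-space integration.

Difference maps are Fourier syntheses of (weighted) amplitude differences
with phases taken from the dark model; F(000) is always excluded, so a
difference map has zero mean over the cell.
"""

from __future__ import annotations

import gemmi
import numpy as np
import pandas as pd

from .sfcalc import structure_factors_from_model
from .types import RealSpaceMap, ReflectionError, ReflectionSet, StructureModel


def synthesize_map(refl: ReflectionSet, grid_factor: float = 3.0) -> RealSpaceMap:
    """Fourier synthesis of a phased reflection set over the unit cell.

    ``grid_factor`` is d_min divided by the grid spacing (>= 3 keeps the
    spacing <= d_min/3).  F(000) is excluded if present.
    """
    if refl.phases_deg is None:
        raise ReflectionError("map synthesis needs phases")
    data = refl.data
    nonzero = ~((data["h"] == 0) & (data["k"] == 0) & (data["l"] == 0))
    data = data[nonzero]
    mtz = gemmi.Mtz(with_base=True)
    mtz.cell = refl.cell.gemmi_cell()
    mtz.spacegroup = refl.cell.gemmi_spacegroup()
    mtz.add_dataset("synth")
    mtz.add_column("F", "F")
    mtz.add_column("PHI", "P")
    arr = np.column_stack([
        data["h"].to_numpy(float), data["k"].to_numpy(float),
        data["l"].to_numpy(float), data["F"].to_numpy(float),
        data["phase"].to_numpy(float),
    ])
    mtz.set_data(arr)
    grid = mtz.transform_f_phi_to_map("F", "PHI", sample_rate=float(grid_factor))
    return RealSpaceMap(refl.cell, np.array(grid, copy=True).astype(float))


def compute_difference_map(
    weighted_diff: ReflectionSet,
    phases_from: StructureModel | ReflectionSet,
    grid_factor: float = 3.0,
) -> RealSpaceMap:
    """Difference map from (weighted) ΔF amplitudes and dark-model phases.

    ``phases_from`` is either a model (phases calculated on the fly) or a
    phased calculated set covering every difference reflection.
    """
    if isinstance(phases_from, StructureModel):
        d_min = weighted_diff.d_min or float(weighted_diff.resolutions().min())
        phased = structure_factors_from_model(phases_from, d_min,
                                              hkl=weighted_diff.hkl)
    else:
        phased = phases_from
        if phased.phases_deg is None:
            raise ReflectionError("phase source carries no phases")
    merged = weighted_diff.join_common(phased)
    df = merged[["h", "k", "l"]].copy()
    df["F"] = merged["F_a"].to_numpy(float)
    df["sigF"] = merged["sigF_a"].to_numpy(float)
    df["phase"] = merged["phase"].to_numpy(float)
    return synthesize_map(ReflectionSet(weighted_diff.cell, df), grid_factor)


def _wrapped_voxels_near(rs_map: RealSpaceMap, position: np.ndarray,
                         radius: float):
    """Indices of unit-cell voxels within ``radius`` Å of a Cartesian
    position, using minimum-image distances."""
    cell = rs_map.cell.gemmi_cell()
    frac_mat = np.array(cell.frac.mat)
    orth_mat = np.array(cell.orth.mat)
    shape = np.array(rs_map.values.shape)
    fpos = (frac_mat @ position) % 1.0
    # bounding box in grid steps, conservative via cell edge lengths
    lengths = np.array([rs_map.cell.a, rs_map.cell.b, rs_map.cell.c])
    half = np.ceil(radius / lengths * shape).astype(int) + 1
    center = np.round(fpos * shape).astype(int)
    axes = [np.arange(center[i] - half[i], center[i] + half[i] + 1)
            for i in range(3)]
    gi, gj, gk = np.meshgrid(*axes, indexing="ij")
    gfrac = np.stack([gi / shape[0], gj / shape[1], gk / shape[2]], axis=-1)
    delta = gfrac - fpos
    delta -= np.round(delta)
    cart = delta @ orth_mat.T
    mask = (cart ** 2).sum(axis=-1) <= radius ** 2
    idx = (np.stack([gi, gj, gk], axis=-1)[mask] % shape)
    return idx[:, 0], idx[:, 1], idx[:, 2]


def per_atom_integrated_density(rs_map: RealSpaceMap, model: StructureModel,
                                radius: float = 1.0) -> pd.DataFrame:
    """Signed and absolute map integrals (e-.Å³ equivalents: value × voxel
    volume) within ``radius`` of each atom, in chain/residue/atom order."""
    if radius <= 0:
        raise ValueError("radius must be positive")
    vv = rs_map.voxel_volume
    rows = []
    for label, pos in zip(model.atom_labels(), model.atom_positions()):
        ii, jj, kk = _wrapped_voxels_near(rs_map, pos, radius)
        vals = rs_map.values[ii, jj, kk]
        rows.append({"atom": label,
                     "signed_density": float(vals.sum() * vv),
                     "absolute_density": float(np.abs(vals).sum() * vv)})
    return pd.DataFrame(rows)


def integrate_negative_density(rs_map: RealSpaceMap, centers: np.ndarray,
                               radius: float, level: float = 3.0,
                               sigma_scaled: bool = False,
                               threshold: float | None = None) -> float:
    """Integral of density below −level·rms within ``radius`` of any center
    (Cartesian Å).  Returned as a positive number (electrons·Å³, or
    rms-units·Å³ when ``sigma_scaled``).

    ``threshold`` overrides the −level·rms cut with an absolute value
    (negative).  A fixed threshold is essential when comparing maps whose
    rms changes systematically, as in an extrapolation-factor scan.
    """
    rms = rs_map.rms
    if threshold is None:
        threshold = -level * rms
    elif threshold >= 0:
        raise ValueError("absolute threshold must be negative")
    shape = rs_map.values.shape
    flat_sets = []
    for pos in np.atleast_2d(centers):
        ii, jj, kk = _wrapped_voxels_near(rs_map, np.asarray(pos, float), radius)
        flat_sets.append(np.ravel_multi_index((ii, jj, kk), shape))
    flat = np.unique(np.concatenate(flat_sets)) if flat_sets else np.array([], int)
    vals = rs_map.values.ravel()[flat]
    total = float(-vals[vals < threshold].sum()) * rs_map.voxel_volume
    if sigma_scaled and rms > 0:
        total /= rms
    return float(total)
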