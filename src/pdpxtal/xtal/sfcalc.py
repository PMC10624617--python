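"""Structure factors from atomic models.

Two backends over the 4-Gaussian + constant scattering-factor
parameterization, with isotropic B damping and no anomalous or
bulk-solvent terms:

- direct summation over symmetry-expanded atoms (exact; cost scales as
  n_atoms * n_reflections), and
- model density sampled on an oversampled grid followed by an FFT
  (cost nearly independent of atom count; relative amplitude error
  ~1e-5 at sampling rate 4 for B >= ~4).

``method="auto"`` picks direct summation for small problems, where it is
both exact and fast, and the FFT for large ones.  Sharp atoms (very low
B) are kept on the direct path because near-delta densities are not
representable on a finite grid.
"""

from __future__ import annotations

import gemmi
import numpy as np
import pandas as pd

from .types import ReflectionSet, StructureModel


class UnknownElementError(ValueError):
    pass


def _check_elements(model: StructureModel) -> None:
    bad = sorted({a.element.name for _, _, a in model.atoms()
                  if a.element.atomic_number == 0})
    if bad:
        supported = "H, C, N, O, S, P, metals and other IUPAC element symbols"
        raise UnknownElementError(
            f"unknown element symbol(s) {bad}; supported: {supported}")


def asu_miller_indices(model_or_cell, d_min: float) -> np.ndarray:
    """Unique Miller indices of the Laue asymmetric unit to d_min."""
    cell = model_or_cell if hasattr(model_or_cell, "gemmi_cell") else model_or_cell.cell
    return gemmi.make_miller_array(cell.gemmi_cell(), cell.gemmi_spacegroup(),
                                   float(d_min))


# above this many atom-reflection products, direct summation is slower
# than one oversampled density grid plus FFT
_DIRECT_COST_LIMIT = 2_000_000
# below this B the model density is too sharp to sample on the FFT grid
_MIN_B_FOR_FFT = 2.0


def _sf_direct(model: StructureModel, hkl: np.ndarray) -> np.ndarray:
    calc = gemmi.StructureFactorCalculatorX(model.structure.cell)
    return np.array([calc.calculate_sf_from_model(model.structure[0], list(m))
                     for m in hkl])


def _sf_fft(model: StructureModel, d_min: float, hkl: np.ndarray,
            rate: float = 4.0) -> np.ndarray:
    dencalc = gemmi.DensityCalculatorX()
    dencalc.d_min = float(d_min)
    dencalc.rate = rate
    dencalc.set_grid_cell_and_spacegroup(model.structure)
    dencalc.put_model_density_on_grid(model.structure[0])
    sf_grid = gemmi.transform_map_to_f_phi(dencalc.grid, half_l=True)
    return np.asarray(sf_grid.get_value_by_hkl(hkl))


def structure_factors_from_model(model: StructureModel, d_min: float,
                                 hkl: np.ndarray | None = None,
                                 method: str = "auto") -> ReflectionSet:
    """Calculated amplitudes and phases (degrees) for the asymmetric unit.

    ``hkl`` overrides the default resolution-complete index set.
    ``method`` is ``"direct"``, ``"fft"`` or ``"auto"``.
    """
    if d_min <= 0:
        raise ValueError("d_min must be positive")
    if method not in ("auto", "direct", "fft"):
        raise ValueError(f"unknown structure-factor method {method!r}")
    _check_elements(model)
    cell = model.cell
    if hkl is None:
        hkl = asu_miller_indices(cell, d_min)
    # both backends reach symmetry mates through the cell's stored
    # images; make sure they reflect the space group
    model.structure.setup_cell_images()
    if method == "auto":
        n_atoms = sum(1 for _ in model.atoms())
        min_b = min((a.b_iso for _, _, a in model.atoms()), default=0.0)
        big = n_atoms * len(hkl) > _DIRECT_COST_LIMIT
        method = "fft" if big and min_b >= _MIN_B_FOR_FFT else "direct"
    if method == "fft":
        values = _sf_fft(model, d_min, hkl)
    else:
        values = _sf_direct(model, hkl)
    df = pd.DataFrame({
        "h": hkl[:, 0], "k": hkl[:, 1], "l": hkl[:, 2],
        "F": np.abs(values), "sigF": 0.0,
        "phase": np.rad2deg(np.angle(values)),
    })
    return ReflectionSet(cell, df, d_min=float(d_min))
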