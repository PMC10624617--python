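"""Toy-crystal generator: dark/light models and reflection data.

A mid-sized all-atom crystal (default 200 C/N/O atoms in an 84x88x92 A
P212121 cell) whose "light" data are a coherent (amplitude-level)
population-weighted mixture |(1-f)*F_dark + f*F_perturbed| plus optional
Gaussian relative noise.  Ground truth (f, displacements) travels with the
returned bundle.

The defaults put the crystal in the regime where the 2/f
over-extrapolation onset rule is quantitative.  Two systematic biases
compete and both must be small:

- threshold delay (late): the onset is detected when a vacated site
  crosses -level*rms, not zero, which lags the true crossing by a
  relative level*rms/peak; it shrinks with sharper atoms and a larger
  cell (rms ~ sqrt(n_atoms/V)).
- phase-projection self-ghost (early): a difference feature located on a
  dark atom correlates with the dark phases, so the dark-phase
  projection keeps slightly more than half of it; the excess scales as
  ~2*Z_moved/(Z_mean*sqrt(n_atoms_per_cell)) and shrinks with more
  atoms.  This is why the half-weight rule works for protein-sized
  structures but fails badly for few-atom cells.

With 200 asymmetric-unit atoms (800 per cell), B=6 and d_min=1.2 the
two terms are each a few percent and the recovered onset sits within
~2% of 2/f, insensitive to seed and to <=2% amplitude noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import gemmi
import numpy as np

from ..xtal.sfcalc import structure_factors_from_model
from ..xtal.types import ReflectionSet, StructureModel, UnitCellSymmetry

# roughly organic-matter composition; repeated to the requested atom count
_DEFAULT_ELEMENTS = ("C", "C", "C", "C", "C", "N", "O")


@dataclass
class ToyCrystalSpec:
    cell: UnitCellSymmetry = field(
        default_factory=lambda: UnitCellSymmetry(84.0, 88.0, 92.0))
    n_atoms: int = 200
    elements: tuple[str, ...] = _DEFAULT_ELEMENTS
    population_fraction: float = 0.2
    # the shift must exceed the atomic density width (~0.4 A at B=6) so a
    # vacated site actually empties: the over-extrapolation onset that
    # defines the characteristic N_EXT only produces negative density where
    # the perturbed structure removed it, and a sub-width shift leaves the
    # old site mostly filled by the displaced atom
    displacement_scale: float = 1.2    # Å shift of each moved atom
    n_moved_atoms: int = 3
    # moved atoms are all drawn from this element so the vacated-site peak
    # height, and with it the detection-threshold delay, is reproducible
    # from seed to seed
    moved_element: str = "O"
    relative_noise: float = 0.0
    # low B and high resolution keep the atom peaks tall against the map
    # rms (3*rms/peak ~ 6%), bounding the threshold-delay bias
    d_min: float = 1.2
    b_iso: float = 6.0
    # cluster width of the Gaussian position sampler
    cluster_scale: float = 9.0
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.population_fraction <= 1.0:
            raise ValueError("population fraction must be in [0, 1]")
        if self.relative_noise < 0:
            raise ValueError("noise must be non-negative")
        shortest = min(self.cell.a, self.cell.b, self.cell.c)
        if self.displacement_scale > 0.5 * shortest:
            raise ValueError("displacement larger than half the shortest cell edge")


@dataclass
class ToyCrystalData:
    dark_model: StructureModel
    light_model: StructureModel
    dark_reflections: ReflectionSet    # observed-style (no phases), noiseless dark
    light_reflections: ReflectionSet   # mixed-state amplitudes, optional noise
    dark_calc: ReflectionSet           # calculated dark set with phases
    spec: ToyCrystalSpec
    moved_atoms: list[str] = field(default_factory=list)
    displacements: np.ndarray = field(default_factory=lambda: np.zeros((0, 3)))


def _build_model(cell: UnitCellSymmetry, elements, positions, b_iso) -> StructureModel:
    st = gemmi.Structure()
    st.cell = cell.gemmi_cell()
    st.spacegroup_hm = cell.space_group
    model = gemmi.Model("1")
    chain = gemmi.Chain("A")
    res = gemmi.Residue()
    res.name = "TOY"
    res.seqid = gemmi.SeqId(1, " ")
    for i, (el, pos) in enumerate(zip(elements, positions), start=1):
        atom = gemmi.Atom()
        atom.name = f"{el}{i}"
        atom.element = gemmi.Element(el)
        atom.pos = gemmi.Position(*pos)
        atom.occ = 1.0
        atom.b_iso = b_iso
        res.add_atom(atom)
    chain.add_residue(res)
    model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    return StructureModel(st)


def _sample_separated(rng, n, center, scale, min_separation):
    """Gaussian cluster with pairwise minimum separation, by rejection."""
    positions = []
    width = scale
    attempts = 0
    while len(positions) < n:
        cand = center + rng.normal(scale=width, size=3)
        if all(np.linalg.norm(cand - p) >= min_separation for p in positions):
            positions.append(cand)
        attempts += 1
        if attempts > 200 * n:
            width *= 1.3
            attempts = 0
    return np.array(positions)


def make_toy_crystal(spec: ToyCrystalSpec | None = None) -> ToyCrystalData:
    spec = spec or ToyCrystalSpec()
    rng = np.random.default_rng(spec.seed)
    elements = (list(spec.elements) * (spec.n_atoms // len(spec.elements) + 1)
                )[: spec.n_atoms]
    # a compact cluster well inside the asymmetric unit so symmetry mates
    # do not clash; a minimum separation keeps atoms resolved, so each
    # contributes an isolated density peak (overlapping atoms create a
    # fused blob with strong termination fringes)
    center = np.array([spec.cell.a, spec.cell.b, spec.cell.c]) * 0.25
    positions = _sample_separated(rng, spec.n_atoms, center,
                                  scale=spec.cluster_scale,
                                  min_separation=2.0)
    dark = _build_model(spec.cell, elements, positions, spec.b_iso)

    candidates = [i for i, el in enumerate(elements) if el == spec.moved_element]
    if len(candidates) < spec.n_moved_atoms:
        candidates = list(range(spec.n_atoms))
    moved_idx = rng.choice(candidates, size=min(spec.n_moved_atoms,
                                                len(candidates)), replace=False)
    shifts = np.zeros((spec.n_atoms, 3))
    for i in moved_idx:
        # keep the displaced site clear of the other atoms, so the vacated
        # and newly occupied regions stay distinct in difference maps
        for _ in range(500):
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            new_pos = positions[i] + direction * spec.displacement_scale
            others = np.delete(positions + shifts, i, axis=0)
            d_old = np.linalg.norm(np.delete(positions, i, axis=0) - new_pos,
                                   axis=1)
            d_new = np.linalg.norm(others - new_pos, axis=1)
            if min(d_old.min(), d_new.min()) >= 1.5:
                break
        shifts[i] = direction * spec.displacement_scale
    light = _build_model(spec.cell, elements, positions + shifts, spec.b_iso)

    dark_calc = structure_factors_from_model(dark, spec.d_min)
    pert_calc = structure_factors_from_model(light, spec.d_min,
                                             hkl=dark_calc.hkl)
    f = spec.population_fraction
    mixed = ((1.0 - f) * dark_calc.complex_amplitudes()
             + f * pert_calc.complex_amplitudes())
    light_amp = np.abs(mixed)
    dark_amp = dark_calc.amplitudes.copy()
    if spec.relative_noise > 0:
        light_amp = light_amp * (1.0 + spec.relative_noise
                                 * rng.standard_normal(len(light_amp)))
        dark_amp = dark_amp * (1.0 + spec.relative_noise
                               * rng.standard_normal(len(dark_amp)))
        light_amp = np.abs(light_amp)
        dark_amp = np.abs(dark_amp)
    sig_light = spec.relative_noise * np.abs(mixed)
    sig_dark = spec.relative_noise * dark_calc.amplitudes

    dark_obs = dark_calc.copy_with(F=dark_amp, sigF=sig_dark)
    dark_obs.data.drop(columns=["phase"], inplace=True)
    light_obs = dark_calc.copy_with(F=light_amp, sigF=sig_light)
    light_obs.data.drop(columns=["phase"], inplace=True)

    labels = dark.atom_labels()
    return ToyCrystalData(
        dark_model=dark, light_model=light,
        dark_reflections=dark_obs, light_reflections=light_obs,
        dark_calc=dark_calc, spec=spec,
        moved_atoms=[labels[i] for i in moved_idx],
        displacements=shifts,
    )
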