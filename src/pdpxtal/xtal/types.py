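"""Core crystallographic containers.

Thin wrappers around gemmi objects: a ReflectionSet is a pandas table of
(h, k, l, F, sigF[, phase]) carrying its cell and space group; a
StructureModel wraps a gemmi.Structure.  Reflections are kept reduced to
the asymmetric unit of the Laue group; phases are stored in degrees.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import gemmi
import numpy as np
import pandas as pd


class ReflectionError(ValueError):
    pass


@dataclass(frozen=True)
class UnitCellSymmetry:
    a: float
    b: float
    c: float
    alpha: float = 90.0
    beta: float = 90.0
    gamma: float = 90.0
    space_group: str = "P 21 21 21"

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c) <= 0:
            raise ValueError("cell lengths must be positive")
        for ang in (self.alpha, self.beta, self.gamma):
            if not 0 < ang < 180:
                raise ValueError("cell angles must lie in (0, 180)")
        if self.gemmi_spacegroup() is None:
            raise ValueError(f"unknown space group {self.space_group!r}")

    def gemmi_cell(self) -> gemmi.UnitCell:
        return gemmi.UnitCell(self.a, self.b, self.c, self.alpha, self.beta, self.gamma)

    def gemmi_spacegroup(self) -> gemmi.SpaceGroup | None:
        return gemmi.find_spacegroup_by_name(self.space_group)

    @classmethod
    def from_gemmi(cls, cell: gemmi.UnitCell, sg: gemmi.SpaceGroup) -> "UnitCellSymmetry":
        return cls(cell.a, cell.b, cell.c, cell.alpha, cell.beta, cell.gamma, sg.hm)


@dataclass
class ReflectionSet:
    """Indexed structure-factor amplitudes with uncertainties.

    ``data`` columns: h, k, l (int), F (electrons), sigF (electrons) and
    optionally phase (degrees).  Indices are unique after reduction to the
    asymmetric unit.
    """

    cell: UnitCellSymmetry
    data: pd.DataFrame
    d_min: float | None = None

    def __post_init__(self) -> None:
        required = {"h", "k", "l", "F", "sigF"}
        missing = required - set(self.data.columns)
        if missing:
            raise ReflectionError(f"missing columns: {sorted(missing)}")
        if len(self.data) == 0:
            raise ReflectionError("empty reflection set")
        if (self.data["sigF"] < 0).any():
            raise ReflectionError("negative sigma")
        dup = self.data.duplicated(subset=["h", "k", "l"])
        if dup.any():
            raise ReflectionError(f"{int(dup.sum())} duplicate reflection indices")

    def __len__(self) -> int:
        return len(self.data)

    @property
    def hkl(self) -> np.ndarray:
        return self.data[["h", "k", "l"]].to_numpy(dtype=int)

    @property
    def amplitudes(self) -> np.ndarray:
        return self.data["F"].to_numpy(dtype=float)

    @property
    def sigmas(self) -> np.ndarray:
        return self.data["sigF"].to_numpy(dtype=float)

    @property
    def phases_deg(self) -> np.ndarray | None:
        if "phase" in self.data.columns:
            return self.data["phase"].to_numpy(dtype=float)
        return None

    def complex_amplitudes(self) -> np.ndarray:
        ph = self.phases_deg
        if ph is None:
            raise ReflectionError("reflection set carries no phases")
        return self.amplitudes * np.exp(1j * np.deg2rad(ph))

    def resolutions(self) -> np.ndarray:
        cell = self.cell.gemmi_cell()
        return np.array([cell.calculate_d(list(m)) for m in self.hkl])

    def copy_with(self, **columns) -> "ReflectionSet":
        df = self.data.copy()
        for name, values in columns.items():
            df[name] = values
        return ReflectionSet(self.cell, df, d_min=self.d_min)

    def join_common(self, other: "ReflectionSet") -> pd.DataFrame:
        """Inner join on (h, k, l); raises if any reflections are unpaired."""
        merged = self.data.merge(other.data, on=["h", "k", "l"],
                                 suffixes=("_a", "_b"), how="outer", indicator=True)
        unpaired = int((merged["_merge"] != "both").sum())
        if unpaired:
            raise ReflectionError(f"{unpaired} unpaired reflections between the sets")
        return merged.drop(columns="_merge")


@dataclass
class StructureModel:
    """Atomic model with cell and symmetry (backed by gemmi.Structure)."""

    structure: gemmi.Structure

    @property
    def cell(self) -> UnitCellSymmetry:
        sg = gemmi.find_spacegroup_by_name(self.structure.spacegroup_hm)
        return UnitCellSymmetry.from_gemmi(self.structure.cell, sg)

    def atoms(self):
        """Iterate (chain, residue, atom) in file order."""
        for chain in self.structure[0]:
            for residue in chain:
                for atom in residue:
                    yield chain, residue, atom

    def atom_positions(self) -> np.ndarray:
        """Cartesian positions (N, 3) in file order."""
        return np.array([[a.pos.x, a.pos.y, a.pos.z] for _, _, a in self.atoms()])

    def atom_labels(self) -> list[str]:
        return [f"{c.name}/{r.seqid.num}{r.name}/{a.name}" for c, r, a in self.atoms()]

    def find_atom(self, chain: str, resseq: int, atom_name: str) -> gemmi.Atom:
        matches = []
        for c, r, a in self.atoms():
            if c.name == chain and r.seqid.num == resseq and a.name == atom_name:
                return a
            if a.name == atom_name:
                matches.append(f"{c.name}/{r.seqid.num}{r.name}/{a.name}")
        near = ", ".join(matches[:5]) or "none"
        raise KeyError(
            f"atom {chain}/{resseq}/{atom_name} not found; atoms with that name: {near}")

    def deep_copy(self) -> "StructureModel":
        return StructureModel(self.structure.clone())


@dataclass
class RealSpaceMap:
    """Real-space map over the full unit cell with its rms (sigma) scale."""

    cell: UnitCellSymmetry
    values: np.ndarray  # shape (nu, nv, nw) over the unit cell

    @property
    def rms(self) -> float:
        return float(self.values.std())

    @property
    def mean(self) -> float:
        return float(self.values.mean())

    @property
    def voxel_volume(self) -> float:
        vol = self.cell.gemmi_cell().volume
        return vol / self.values.size

    def grid_fractional_coords(self):
        """Fractional coordinates of grid points along each axis."""
        nu, nv, nw = self.values.shape
        return (np.arange(nu) / nu, np.arange(nv) / nv, np.arange(nw) / nw)
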