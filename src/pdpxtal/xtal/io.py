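"""Reading and writing models, reflections and maps.

Formats: PDB (models, via gemmi), MTZ and whitespace-delimited hkl text
(reflections), CCP4/MRC (maps).  Plain-hkl round trips are exact: the
writer uses full repr precision.
"""

from __future__ import annotations

from pathlib import Path

import gemmi
import numpy as np
import pandas as pd

from .types import RealSpaceMap, ReflectionError, ReflectionSet, StructureModel, UnitCellSymmetry


def read_model(path: str | Path) -> StructureModel:
    """Read an atomic model from a PDB (or mmCIF) file."""
    st = gemmi.read_structure(str(path))
    st.setup_entities()
    return StructureModel(st)


def write_model(model: StructureModel, path: str | Path) -> None:
    model.structure.write_pdb(str(path))


def read_reflections(path: str | Path, fmt: str | None = None,
                     cell: UnitCellSymmetry | None = None) -> ReflectionSet:
    """Read reflections from MTZ or plain-text hkl.

    Plain hkl files are whitespace-delimited with a one-line header
    ``# a b c alpha beta gamma space_group`` followed by columns
    ``h k l F sigF [phase]``; ``cell`` overrides the header when given.
    """
    path = Path(path)
    if fmt is None:
        fmt = "mtz" if path.suffix.lower() == ".mtz" else "hkl"
    if fmt == "mtz":
        mtz = gemmi.read_mtz_file(str(path))
        cell_sym = UnitCellSymmetry.from_gemmi(mtz.cell, mtz.spacegroup)
        df = pd.DataFrame(np.array(mtz, copy=False), columns=mtz.column_labels())
        f_col = next((c for c in ("F", "FP", "FOBS") if c in df.columns), None)
        sig_col = next((c for c in ("SIGF", "SIGFP", "SIGFOBS") if c in df.columns), None)
        if f_col is None:
            raise ReflectionError(f"no amplitude column in {path.name}")
        out = pd.DataFrame({
            "h": df["H"].astype(int), "k": df["K"].astype(int), "l": df["L"].astype(int),
            "F": df[f_col].astype(float),
            "sigF": df[sig_col].astype(float) if sig_col else 0.0,
        })
        if "PHI" in df.columns:
            out["phase"] = df["PHI"].astype(float)
        return ReflectionSet(cell_sym, out)

    lines = path.read_text().splitlines()
    if not lines:
        raise ReflectionError(f"empty reflection file {path}")
    header_cell = None
    data_lines = []
    for ln in lines:
        s = ln.strip()
        if not s:
            continue
        if s.startswith("#"):
            parts = s[1:].split()
            if len(parts) >= 7 and header_cell is None:
                header_cell = UnitCellSymmetry(
                    *(float(x) for x in parts[:6]), space_group=" ".join(parts[6:]))
            continue
        data_lines.append(s)
    if cell is None:
        cell = header_cell
    if cell is None:
        raise ReflectionError(f"{path}: no cell header and no cell given")
    if not data_lines:
        raise ReflectionError(f"{path}: no reflection records")
    rows = [ln.split() for ln in data_lines]
    ncol = len(rows[0])
    if ncol not in (5, 6):
        raise ReflectionError(f"{path}: expected 5 or 6 columns, got {ncol}")
    cols = ["h", "k", "l", "F", "sigF"] + (["phase"] if ncol == 6 else [])
    df = pd.DataFrame(rows, columns=cols)
    for c in ("h", "k", "l"):
        df[c] = df[c].astype(int)
    for c in cols[3:]:
        df[c] = df[c].astype(float)
    return ReflectionSet(cell, df)


def write_reflections(refl: ReflectionSet, path: str | Path) -> None:
    """Write a plain-text hkl file (exact round trip)."""
    path = Path(path)
    c = refl.cell
    with path.open("w") as fh:
        fh.write(f"# {c.a!r} {c.b!r} {c.c!r} {c.alpha!r} {c.beta!r} {c.gamma!r} "
                 f"{c.space_group}\n")
        cols = ["h", "k", "l", "F", "sigF"]
        if "phase" in refl.data.columns:
            cols.append("phase")
        for _, row in refl.data[cols].iterrows():
            fields = [str(int(row[c])) for c in ("h", "k", "l")]
            fields += [repr(float(row[c])) for c in cols[3:]]
            fh.write(" ".join(fields) + "\n")


def write_map(rs_map: RealSpaceMap, path: str | Path) -> None:
    """Write a CCP4/MRC map covering the full unit cell."""
    grid = gemmi.FloatGrid(np.ascontiguousarray(rs_map.values, dtype=np.float32))
    grid.set_unit_cell(rs_map.cell.gemmi_cell())
    grid.spacegroup = rs_map.cell.gemmi_spacegroup()
    ccp4 = gemmi.Ccp4Map()
    ccp4.grid = grid
    ccp4.update_ccp4_header()
    ccp4.write_ccp4_map(str(path))


def read_map(path: str | Path) -> RealSpaceMap:
    ccp4 = gemmi.read_ccp4_map(str(path))
    ccp4.setup(float("nan"))
    grid = ccp4.grid
    sg = grid.spacegroup or gemmi.find_spacegroup_by_name("P 1")
    cell = UnitCellSymmetry.from_gemmi(grid.unit_cell, sg)
    return RealSpaceMap(cell, np.array(grid, copy=True).astype(float))
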