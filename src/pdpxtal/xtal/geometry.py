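"""Geometry reports: named pairwise distances and inter-model displacements.

Distances use minimum-image / nearest symmetry image so that pairs across
cell boundaries report the physical contact distance.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import gemmi

from .types import StructureModel

AtomSel = tuple[str, int, str]  # (chain, residue seq number, atom name)


@dataclass
class GeometryReport:
    distances: dict[str, dict[str, float]] = field(default_factory=dict)
    displacements: dict[str, float] = field(default_factory=dict)

    def to_json(self, indent: int = 2) -> str:
        return json.dumps({
            "distances_angstrom": {
                name: {k: round(v, 2) for k, v in models.items()}
                for name, models in self.distances.items()},
            "displacements_angstrom": {
                k: round(v, 2) for k, v in self.displacements.items()},
        }, indent=indent)


def nearest_image_distance(model: StructureModel, pos_a: gemmi.Position,
                           pos_b: gemmi.Position) -> float:
    ni = model.structure.cell.find_nearest_image(pos_a, pos_b, gemmi.Asu.Any)
    return float(ni.dist())


def pair_distance(model: StructureModel, sel_a: AtomSel, sel_b: AtomSel) -> float:
    a = model.find_atom(*sel_a)
    b = model.find_atom(*sel_b)
    return nearest_image_distance(model, a.pos, b.pos)


def geometry_report(
    model_a: StructureModel,
    model_b: StructureModel | None = None,
    pairs: dict[str, tuple[AtomSel, AtomSel]] | None = None,
) -> GeometryReport:
    """Distances for each named pair in each model, plus per-atom
    displacements between like-named atoms of the two models."""
    report = GeometryReport()
    for name, (sel_a, sel_b) in (pairs or {}).items():
        entry = {"model_a": pair_distance(model_a, sel_a, sel_b)}
        if model_b is not None:
            entry["model_b"] = pair_distance(model_b, sel_a, sel_b)
        report.distances[name] = entry
    if model_b is not None:
        pos_b = dict(zip(model_b.atom_labels(), model_b.atom_positions()))
        for label, pa in zip(model_a.atom_labels(), model_a.atom_positions()):
            if label in pos_b:
                pb = pos_b[label]
                report.displacements[label] = nearest_image_distance(
                    model_a, gemmi.Position(*pa), gemmi.Position(*pb))
    return report
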