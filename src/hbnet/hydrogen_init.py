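"""Initial hydrogen coordinates from idealized VSEPR geometries.

Hybridization classes are read off the perceived bond orders; default
tautomer/protonation states are normalized to physiological-pH conventions;
every implicit hydrogen then receives coordinates completing the ideal
polyhedron around its parent.  Sites whose orientation cannot be fixed by the
heavy-atom skeleton (water, terminal rotors, ring NH) are only preliminary
and flagged ambiguous -- mode enumeration replaces them later.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import chem
from .config import Config
from .geometry import TET_ANGLE, complete_directions, unit
from .structure_io import Atom, ComplexStructure, MolecularGraph

_ATOMIC_NUMBER = {"H": 1, "B": 5, "C": 6, "N": 7, "O": 8, "F": 9, "P": 15,
                  "S": 16, "Cl": 17, "Se": 34, "Br": 35, "I": 53}

FIXED = "fixed"
ROTATABLE = "ambiguous-rotatable"
DISCRETE = "ambiguous-discrete"


@dataclass(frozen=True)
class GeometryClass:
    hybridization: str       # sp | sp2 | sp3 | unknown
    ideal_angle: float       # degrees
    xh_length: float         # Angstrom

    @staticmethod
    def for_atom(hybridization: str, element: str, cfg: Config,
                 water: bool = False) -> "GeometryClass":
        length = cfg.xh_bond_lengths.get(element, 1.0)
        if water:
            return GeometryClass("sp3", cfg.water_angle, length)
        angle = {"sp": 180.0, "sp2": 120.0, "sp3": TET_ANGLE}.get(
            hybridization, TET_ANGLE)
        return GeometryClass(hybridization, angle, length)


@dataclass
class HydrogenSite:
    component: int
    parent: int
    hydrogen: int            # atom index of the placed H within the component
    position: np.ndarray
    determinacy: str         # fixed | ambiguous-rotatable | ambiguous-discrete


# --------------------------------------------------------------------------
# hybridization


def assign_hybridization(graph: MolecularGraph) -> list[str]:
    """sp3 for all-single centres, sp2 for double-bond/aromatic/conjugated-N
    centres, sp for triple bonds and cumulenes; metals and unperceived
    components get 'unknown'."""
    out = []
    unperceived = "unperceived" in graph.flags
    for i, a in enumerate(graph.atoms):
        if a.is_hydrogen:
            out.append("s")
            continue
        if chem.is_metal(a.element) or unperceived:
            out.append("unknown")
            continue
        orders = [graph.order(i, j) for j in graph.heavy_neighbors(i)]
        if any(o == 3 for o in orders) or orders.count(2) >= 2:
            out.append("sp")
        elif any(o == 2 for o in orders) or i in graph.aromatic_atoms:
            out.append("sp2")
        elif a.element == "N" and _conjugated_nitrogen(graph, i):
            out.append("sp2")
        else:
            out.append("sp3")
        a.hybridization = out[-1]
    return out


def _conjugated_nitrogen(graph: MolecularGraph, i: int) -> bool:
    """Amide/guanidine/aromatic-substituent nitrogens are planar."""
    for j in graph.heavy_neighbors(i):
        b = graph.atoms[j]
        if b.element == "C" and (
                any(graph.order(j, k) >= 2 for k in graph.neighbors(j))
                or j in graph.aromatic_atoms):
            return True
    return False


# --------------------------------------------------------------------------
# state normalization


def normalize_states(graph: MolecularGraph, cfg: Config | None = None
                     ) -> MolecularGraph:
    """Canonical default states at a physiological-pH convention.

    Carboxylic/phosphoric/sulfonic acids deprotonated, aliphatic amines and
    guanidines/amidines protonated, azole rings neutral, alcohols/thiols/
    amides neutral.  Chain-break amino/acid groups are treated as incomplete
    amide bonds and kept neutral (break N: one hydrogen; break carbonyl C: no
    hydroxyl).  Mutates and returns the graph.
    """
    if graph.kind in ("water", "metal-ion") or "unperceived" in graph.flags:
        return graph
    if graph.kind == "protein-chain" and graph.resname:
        _normalize_residue(graph)
        return graph
    for i, a in enumerate(graph.atoms):
        if a.is_hydrogen:
            continue
        if a.element == "O" and _is_acidic_oxygen(graph, i):
            a.formal_charge = -1
        elif a.element == "N":
            if _is_amidinium_nitrogen(graph, i):
                a.formal_charge = 1
            elif _is_aliphatic_amine(graph, i):
                a.formal_charge = 1
    return graph


def _is_acidic_oxygen(graph: MolecularGraph, i: int) -> bool:
    """Hydroxyl oxygen of a carboxylic, phosphoric or sulfonic acid group."""
    nbrs = graph.heavy_neighbors(i)
    if len(nbrs) != 1 or graph.order(i, nbrs[0]) != 1:
        return False
    c = nbrs[0]
    ce = graph.atoms[c].element
    if ce == "C":
        return any(graph.atoms[j].element == "O" and graph.order(c, j) == 2
                   for j in graph.heavy_neighbors(c))
    if ce in ("P", "S") and graph.heavy_order_sum(c) >= 4:
        return True
    return False


def _is_amidinium_nitrogen(graph: MolecularGraph, i: int) -> bool:
    """=N of an amidine/guanidine group (protonated by default)."""
    for j in graph.heavy_neighbors(i):
        if graph.atoms[j].element != "C" or graph.order(i, j) != 2:
            continue
        if i in graph.aromatic_atoms or j in graph.aromatic_atoms:
            continue
        others = [k for k in graph.heavy_neighbors(j) if k != i]
        if any(graph.atoms[k].element == "N" and graph.order(j, k) == 1
               for k in others):
            return True
    return False


def _is_aliphatic_amine(graph: MolecularGraph, i: int) -> bool:
    """sp3 nitrogen with only saturated carbon neighbours (no amide/aniline)."""
    if i in graph.aromatic_atoms:
        return False
    nbrs = graph.heavy_neighbors(i)
    if not nbrs or graph.heavy_order_sum(i) != len(nbrs) or len(nbrs) > 3:
        return False
    for j in nbrs:
        b = graph.atoms[j]
        if b.element != "C":
            return False
        if j in graph.aromatic_atoms or any(
                graph.order(j, k) >= 2 for k in graph.neighbors(j)):
            return False
    return True


_RESIDUE_CHARGES = {
    "ASP": [("OD2", -1)], "GLU": [("OE2", -1)],
    "LYS": [("NZ", 1)], "ARG": [("NH1", 1)],
}


def _normalize_residue(graph: MolecularGraph) -> None:
    for name, charge in _RESIDUE_CHARGES.get(graph.resname, []):
        for a in graph.atoms:
            if a.name == name:
                a.formal_charge = charge
    for i, a in enumerate(graph.atoms):
        if a.name == "N":
            if "chain-break-n" in graph.flags:
                a.h_count_override = 1        # incomplete amide: neutral, 1 H
                a.hybridization = "sp2"
            elif "n-terminus" in graph.flags:
                a.formal_charge = 1           # free amino group, NH3+
        elif a.name == "C" and "chain-break-c" in graph.flags \
                and "c-terminus" not in graph.flags:
            a.h_count_override = 0            # incomplete amide carbonyl
        elif a.name == "OXT":
            a.formal_charge = -1              # free acid group, carboxylate


def normalize_complex(cx: ComplexStructure, cfg: Config | None = None
                      ) -> ComplexStructure:
    for comp in cx.components:
        normalize_states(comp, cfg)
    return cx


# --------------------------------------------------------------------------
# placement


def place_hydrogens(cx: ComplexStructure, cfg: Config | None = None
                    ) -> list[HydrogenSite]:
    """Generate coordinates for every implicit hydrogen in the complex.

    Hydrogen atoms are appended to their component's graph; the returned
    sites carry the determinacy flag used by mode enumeration.  Parents
    without valid coordinates (template-added) generate no sites.
    Deterministic: identical inputs yield identical coordinates.
    """
    cfg = cfg or Config()
    sites: list[HydrogenSite] = []
    for ci, comp in enumerate(cx.components):
        if comp.kind == "metal-ion" or "unperceived" in comp.flags:
            continue
        if not comp.atoms or comp.atoms[0].hybridization == "" \
                and comp.kind != "water":
            assign_hybridization(comp)
        for ai in range(len(comp.atoms)):
            atom = comp.atoms[ai]
            if atom.is_hydrogen or not atom.has_valid_coords:
                continue
            n_h = _global_implicit_h(cx, ci, ai)
            if n_h <= 0:
                continue
            sites.extend(_place_on_atom(cx, ci, ai, n_h, cfg))
    return sites


def _global_implicit_h(cx: ComplexStructure, ci: int, ai: int) -> int:
    comp = cx.components[ci]
    atom = comp.atoms[ai]
    if atom.h_count_override is not None:
        return atom.h_count_override - len(comp.hydrogens_of(ai))
    heavy = cx.global_heavy_order_sum(ci, ai)
    return chem.implicit_hydrogens(atom.element, atom.formal_charge, heavy) \
        - len(comp.hydrogens_of(ai))


def _neighbor_dirs(cx: ComplexStructure, ci: int, ai: int
                   ) -> list[tuple[np.ndarray, int, str]]:
    """(unit direction, atomic number, sort key source) of valid neighbours."""
    comp = cx.components[ci]
    pos = comp.atoms[ai].coords
    out = []
    for j in comp.heavy_neighbors(ai):
        b = comp.atoms[j]
        if b.has_valid_coords:
            out.append((unit(b.coords - pos), _ATOMIC_NUMBER.get(b.element, 0),
                        (ci, j)))
    for (cj, aj, _) in cx.link_partners(ci, ai):
        b = cx.components[cj].atoms[aj]
        if b.has_valid_coords:
            out.append((unit(b.coords - pos), _ATOMIC_NUMBER.get(b.element, 0),
                        (cj, aj)))
    return out


def _torsion_reference(cx: ComplexStructure, ci: int, ai: int,
                       nbr_key) -> np.ndarray | None:
    """Direction toward the heaviest vicinal substituent, for staggered and
    rotor starting torsions.  Ties resolved by coordinates (relabeling-safe).
    """
    cj, aj = nbr_key
    comp = cx.components[cj]
    pos = comp.atoms[aj].coords
    cands = []
    for k in comp.heavy_neighbors(aj):
        if (cj, k) == (ci, ai):
            continue
        c = comp.atoms[k]
        if c.has_valid_coords:
            cands.append((-_ATOMIC_NUMBER.get(c.element, 0),
                          tuple(np.round(c.coords, 6)), c.coords))
    for (ck, ak, _) in cx.link_partners(cj, aj):
        if (ck, ak) == (ci, ai):
            continue
        c = cx.components[ck].atoms[ak]
        if c.has_valid_coords:
            cands.append((-_ATOMIC_NUMBER.get(c.element, 0),
                          tuple(np.round(c.coords, 6)), c.coords))
    if not cands:
        return None
    cands.sort(key=lambda t: (t[0], t[1]))
    return unit(cands[0][2] - pos)


def _place_on_atom(cx: ComplexStructure, ci: int, ai: int, n_h: int,
                   cfg: Config) -> list[HydrogenSite]:
    comp = cx.components[ci]
    atom = comp.atoms[ai]
    water = comp.kind == "water"
    gclass = GeometryClass.for_atom(atom.hybridization or "sp3", atom.element,
                                    cfg, water=water)
    dirs_info = _neighbor_dirs(cx, ci, ai)
    dirs = [d for d, _, _ in dirs_info]
    k = len(dirs)

    ref = None
    if k == 1:
        ref = _torsion_reference(cx, ci, ai, dirs_info[0][2])
    if k == 2 and gclass.hybridization == "sp3" and n_h == 1:
        # ring/secondary amine NH: one of the two tetrahedral completions
        both = complete_directions(dirs, 2, gclass.ideal_angle)
        new_dirs = [both[0]]
        determinacy = DISCRETE if atom.element in ("N",) else FIXED
    else:
        new_dirs = complete_directions(dirs, n_h, gclass.ideal_angle, ref)
        determinacy = _determinacy(atom, gclass, k, n_h, water)
    sites = []
    for d in new_dirs[:n_h]:
        pos = atom.coords + d * gclass.xh_length
        h_idx = comp.add_atom(Atom(element="H", coords=pos))
        comp.add_bond(ai, h_idx, 1)
        sites.append(HydrogenSite(ci, ai, h_idx, pos, determinacy))
    return sites


def _determinacy(atom: Atom, gclass: GeometryClass, k: int, n_h: int,
                 water: bool) -> str:
    if water:
        return ROTATABLE
    if k == 0:
        return ROTATABLE                      # isolated atom
    if k == 1 and gclass.hybridization == "sp3":
        if atom.element in ("O", "S", "Se"):
            return ROTATABLE                  # hydroxyl / thiol rotor
        if atom.element == "N" and atom.formal_charge == 0:
            return ROTATABLE                  # neutral acyclic amine
        return FIXED                          # methyl / ammonium: staggered
    return FIXED
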