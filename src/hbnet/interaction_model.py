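"""Geometric interaction model: donor/acceptor/metal surfaces and pair scores.

Every mode is represented by a set of interaction surfaces: one donor surface
per polar hydrogen (axis along X-H) and one acceptor surface per free
electron pair (axis along the idealized lone-pair direction).  A pair of
surfaces scores a hydrogen bond (donor+acceptor), a metal interaction
(acceptor+metal), or a repulsion (donor-donor, donor-metal,
acceptor-acceptor) through piecewise-linear distance and angle ramps that
reach exactly zero at their cutoffs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import chem
from .config import Config
from .geometry import (TET_ANGLE, angle_deg, any_perpendicular,
                       complete_directions, cone_direction, unit)
from .structure_io import ComplexStructure
from .vmr_enum import VMR, Mode

DONOR, ACCEPTOR, METAL = "donor", "acceptor", "metal"


@dataclass
class InteractionSurface:
    anchor: tuple[int, int]          # (component, atom) of the heavy anchor
    role: str                        # donor | acceptor | metal
    anchor_pos: np.ndarray
    axis: np.ndarray | None          # unit; None for isotropic metals
    h_position: np.ndarray | None    # donors only
    cap_half_angle: float            # degrees
    ideal_distance: float            # Angstrom


@dataclass
class PairScore:
    value: float
    kind: str                        # hbond | metal | repulsion | none

    def __bool__(self) -> bool:
        return self.kind != "none"


NONE_SCORE = PairScore(0.0, "none")


# --------------------------------------------------------------------------
# surface construction


def _atom_surfaces(ci: int, ai: int, element: str, charge: int,
                   pos: np.ndarray, nbr_dirs: list[np.ndarray],
                   parent_sp2: bool, h_positions: list[np.ndarray],
                   cfg: Config) -> list[InteractionSurface]:
    surfaces: list[InteractionSurface] = []
    if chem.is_metal(element):
        return [InteractionSurface((ci, ai), METAL, pos, None, None,
                                   180.0, cfg.metal_ideal)]
    if element not in ("N", "O", "S", "Se"):
        return []
    for h in h_positions:
        surfaces.append(InteractionSurface(
            (ci, ai), DONOR, pos, unit(np.asarray(h) - pos), np.asarray(h),
            cfg.angle_cutoff, cfg.hbond_ideal))

    n_conn = len(nbr_dirs) + len(h_positions)
    sp2_here = parent_sp2
    if element == "N":
        # trigonal N with three sigma partners: lone pair in the pi system
        if n_conn >= 3:
            n_lp = 0 if sp2_here else 1
        elif n_conn == 2:
            n_lp = 1
        else:
            n_lp = 1
        if charge > 0:
            n_lp = 0
    elif element in ("O", "S", "Se"):
        n_lp = chem.lone_pairs(element, charge, n_conn)
        n_lp = min(n_lp, 3)
    else:
        n_lp = 0
    if n_lp <= 0:
        return surfaces

    occupied = list(nbr_dirs) + [unit(np.asarray(h) - pos) for h in h_positions]
    lp_dirs = _lone_pair_directions(occupied, n_lp, sp2_here)
    for d in lp_dirs:
        surfaces.append(InteractionSurface(
            (ci, ai), ACCEPTOR, pos, d, None,
            cfg.angle_cutoff, cfg.hbond_ideal))
    return surfaces


def _lone_pair_directions(occupied: list[np.ndarray], n_lp: int,
                          sp2: bool) -> list[np.ndarray]:
    if not occupied:
        return [np.array([0.0, 0.0, 1.0])][:n_lp]
    if sp2 and len(occupied) == 1:
        # carbonyl-type: two in-plane lobes at 120 degrees from the bond
        axis = -unit(occupied[0])
        perp = any_perpendicular(axis)
        return [cone_direction(-axis, perp, 120.0, t)
                for t in (0.0, 180.0)][:n_lp]
    if sp2 and len(occupied) == 2:
        return complete_directions(occupied, 1, 120.0)[:n_lp]
    if len(occupied) == 1:
        axis = -unit(occupied[0])
        perp = any_perpendicular(axis)
        half = 180.0 - TET_ANGLE
        return [cone_direction(axis, perp, half, t)
                for t in (0.0, 120.0, 240.0)][:n_lp]
    return complete_directions(occupied, min(n_lp, 2), TET_ANGLE)[:n_lp]


def _carbonyl_lp(pos, c_pos, plane_ref, cfg) -> list[np.ndarray]:
    axis = unit(pos - c_pos)
    perp = plane_ref - np.dot(plane_ref, axis) * axis
    if np.linalg.norm(perp) < 1e-8:
        perp = any_perpendicular(axis)
    perp = unit(perp)
    return [cone_direction(axis, perp, 60.0, 0.0),
            cone_direction(axis, perp, 60.0, 180.0)]


def build_surfaces(mode: Mode, vmr: VMR, cx: ComplexStructure,
                   cfg: Config | None = None) -> list[InteractionSurface]:
    """Interaction surfaces of one mode of a region.

    Tautomer modes produce exactly the donor/acceptor combination of that
    state; carbonyl-type oxygens get two in-plane lobes, hydroxyl/ether
    oxygens tetrahedral lobes, pyridine-type nitrogens one in-plane lobe.
    """
    cfg = cfg or Config()
    graph = cx.components[vmr.component]
    surfaces: list[InteractionSurface] = []
    aset = set(vmr.atoms)
    for i in vmr.atoms:
        a = graph.atoms[i]
        if a.is_hydrogen or not a.has_valid_coords and i not in mode.heavy_coords:
            continue
        pos = mode.coords(graph, i)

        def order(x, y):
            k = (min(x, y), max(x, y))
            if x in aset and y in aset and k in mode.bond_orders:
                return mode.bond_orders[k]
            return graph.order(x, y)

        nbr_dirs = []
        sp2 = False
        for j in graph.heavy_neighbors(i):
            b = graph.atoms[j]
            bp = mode.coords(graph, j) if j in aset or j in mode.heavy_coords \
                else (b.coords if b.has_valid_coords else None)
            if bp is None:
                continue
            nbr_dirs.append(unit(bp - pos))
            if order(i, j) >= 2:
                sp2 = True
        for (cj, aj, o) in cx.link_partners(vmr.component, i):
            b = cx.components[cj].atoms[aj]
            if b.has_valid_coords:
                nbr_dirs.append(unit(b.coords - pos))
                if o >= 2:
                    sp2 = True
        if i in graph.aromatic_atoms:
            sp2 = True
        if a.element == "N" and not sp2:
            sp2 = _conjugated_to_pi(graph, mode, aset, i)
        # carbonyl-type oxygen: use the parent plane for the in-plane lobes
        charge = mode.charges.get(i, a.formal_charge)
        h_positions = mode.h_positions.get(i, [])
        if a.element in ("O", "S") and len(nbr_dirs) == 1 and not h_positions:
            c_idx = graph.heavy_neighbors(i)[0]
            if _parent_is_sp2(graph, mode, aset, c_idx):
                lp = _carbonyl_plane_lobes(graph, mode, aset, i, c_idx)
                for d in lp:
                    surfaces.append(InteractionSurface(
                        (vmr.component, i), ACCEPTOR, pos, d, None,
                        cfg.angle_cutoff, cfg.hbond_ideal))
                for h in h_positions:
                    pass
                continue
        surfaces.extend(_atom_surfaces(
            vmr.component, i, a.element, charge, pos, nbr_dirs, sp2,
            h_positions, cfg))
    return surfaces


def _conjugated_to_pi(graph, mode, aset, i) -> bool:
    """Nitrogen lone pairs conjugated into a neighbouring pi system (amide,
    aniline, guanidine) are not acceptors."""
    for j in graph.heavy_neighbors(i):
        if graph.atoms[j].element != "C":
            continue
        if _parent_is_sp2(graph, mode, aset, j):
            return True
    return False


def _parent_is_sp2(graph, mode, aset, c_idx) -> bool:
    if c_idx in graph.aromatic_atoms:
        return True
    for j in graph.heavy_neighbors(c_idx):
        k = (min(c_idx, j), max(c_idx, j))
        o = mode.bond_orders.get(k, graph.order(c_idx, j)) \
            if (c_idx in aset and j in aset) else graph.order(c_idx, j)
        if o >= 2:
            return True
    return False


def _carbonyl_plane_lobes(graph, mode, aset, o_idx, c_idx) -> list[np.ndarray]:
    o_pos = mode.coords(graph, o_idx)
    c_pos = mode.coords(graph, c_idx) if c_idx in aset \
        else graph.atoms[c_idx].coords
    ref = None
    for k in sorted(graph.heavy_neighbors(c_idx)):
        if k == o_idx:
            continue
        b = graph.atoms[k]
        kp = mode.coords(graph, k) if k in aset else (
            b.coords if b.has_valid_coords else None)
        if kp is not None:
            ref = unit(kp - c_pos)
            break
    if ref is None:
        ref = any_perpendicular(unit(o_pos - c_pos))
    return _carbonyl_lp(o_pos, c_pos, ref, None)


def fixed_surfaces(cx: ComplexStructure, variable_atoms: set[tuple[int, int]],
                   cfg: Config | None = None) -> list[InteractionSurface]:
    """Surfaces of every atom outside all regions (the rigid environment).

    Template-added atoms have no valid coordinates and contribute nothing.
    """
    cfg = cfg or Config()
    out: list[InteractionSurface] = []
    for ci, ai, comp, a in cx.iter_atoms():
        if a.is_hydrogen or not a.has_valid_coords:
            continue
        if (ci, ai) in variable_atoms:
            continue
        if chem.is_metal(a.element):
            out.append(InteractionSurface((ci, ai), METAL, a.coords, None,
                                          None, 180.0, cfg.metal_ideal))
            continue
        if a.element not in ("N", "O", "S", "Se"):
            continue
        h_positions = [comp.atoms[h].coords for h in comp.hydrogens_of(ai)
                       if comp.atoms[h].has_valid_coords]
        nbr_dirs = []
        sp2 = ai in comp.aromatic_atoms
        for j in comp.heavy_neighbors(ai):
            b = comp.atoms[j]
            if b.has_valid_coords:
                nbr_dirs.append(unit(b.coords - a.coords))
                if comp.order(ai, j) >= 2:
                    sp2 = True
        for (cj, aj, o) in cx.link_partners(ci, ai):
            b = cx.components[cj].atoms[aj]
            if b.has_valid_coords:
                nbr_dirs.append(unit(b.coords - a.coords))
                if o >= 2:
                    sp2 = True
        if a.element == "N" and not sp2:
            sp2 = _conjugated_to_pi(comp, _EMPTY_MODE, set(), ai)
        if a.element in ("O", "S") and len(nbr_dirs) == 1 and not h_positions \
                and _parent_is_sp2(comp, _EMPTY_MODE, set(), comp.heavy_neighbors(ai)[0]):
            for d in _carbonyl_plane_lobes(comp, _EMPTY_MODE, set(), ai,
                                           comp.heavy_neighbors(ai)[0]):
                out.append(InteractionSurface((ci, ai), ACCEPTOR, a.coords, d,
                                              None, cfg.angle_cutoff,
                                              cfg.hbond_ideal))
            continue
        out.extend(_atom_surfaces(ci, ai, a.element, a.formal_charge,
                                  a.coords, nbr_dirs, sp2, h_positions, cfg))
    return out


_EMPTY_MODE = Mode(h_positions={}, charges={}, bond_orders={})


# --------------------------------------------------------------------------
# pair scoring


def _ramp(d: float, ideal: float, cutoff: float) -> float:
    if d <= ideal:
        return 1.0
    if d >= cutoff:
        return 0.0
    return (cutoff - d) / (cutoff - ideal)


def _angle_factor(alpha: float, cutoff: float) -> float:
    if alpha >= cutoff:
        return 0.0
    return 1.0 - alpha / cutoff


def score_pair(a: InteractionSurface, b: InteractionSurface,
               cfg: Config | None = None) -> PairScore:
    """Geometric score of one surface pair (symmetric in its arguments).

    donor+acceptor -> hydrogen bond (negative), acceptor+metal -> metal
    interaction (negative), donor-donor / donor-metal / acceptor-acceptor ->
    repulsion (positive); zero outside the cutoffs.
    """
    cfg = cfg or Config()
    if a.anchor == b.anchor:
        return NONE_SCORE
    roles = (a.role, b.role)
    if roles == (ACCEPTOR, DONOR) or roles == (METAL, DONOR) \
            or roles == (METAL, ACCEPTOR):
        a, b = b, a
        roles = (a.role, b.role)

    if roles == (DONOR, ACCEPTOR):
        d = float(np.linalg.norm(a.h_position - b.anchor_pos))
        f = _ramp(d, cfg.hbond_ideal, cfg.hbond_cutoff)
        if f == 0.0:
            return NONE_SCORE
        line = b.anchor_pos - a.anchor_pos
        g_d = _angle_factor(angle_deg(a.axis, line), cfg.angle_cutoff)
        g_a = _angle_factor(angle_deg(b.axis, -line), cfg.angle_cutoff)
        v = -cfg.w_hbond * f * g_d * g_a
        return PairScore(v, "hbond") if v != 0.0 else NONE_SCORE

    if roles == (ACCEPTOR, METAL):
        d = float(np.linalg.norm(a.anchor_pos - b.anchor_pos))
        f = _ramp(d, cfg.metal_ideal, cfg.metal_cutoff)
        if f == 0.0:
            return NONE_SCORE
        g = _angle_factor(angle_deg(a.axis, b.anchor_pos - a.anchor_pos),
                          cfg.angle_cutoff)
        v = -cfg.w_metal * f * g
        return PairScore(v, "metal") if v != 0.0 else NONE_SCORE

    if roles == (DONOR, DONOR):
        d = float(np.linalg.norm(a.h_position - b.h_position))
    elif roles == (DONOR, METAL):
        d = float(np.linalg.norm(a.h_position - b.anchor_pos))
    elif roles == (ACCEPTOR, ACCEPTOR):
        pa = a.anchor_pos + a.axis * cfg.lone_pair_length
        pb = b.anchor_pos + b.axis * cfg.lone_pair_length
        d = float(np.linalg.norm(pa - pb))
    else:
        return NONE_SCORE
    f = _ramp(d, cfg.repulsion_full, cfg.repulsion_cutoff)
    if f == 0.0:
        return NONE_SCORE
    return PairScore(cfg.w_repulsion * f, "repulsion")


class InteractionContext:
    """Shared exclusion logic: surfaces anchored on the same atom, bonded
    atoms (1-2) or atoms sharing a neighbour (1-3) never score."""

    def __init__(self, cx: ComplexStructure):
        adj: dict[tuple[int, int], set] = {}
        for ci, comp in enumerate(cx.components):
            for (i, j, _) in comp.bonds():
                if comp.atoms[i].is_hydrogen or comp.atoms[j].is_hydrogen:
                    continue
                adj.setdefault((ci, i), set()).add((ci, j))
                adj.setdefault((ci, j), set()).add((ci, i))
        for (a, b, _) in cx.links:
            adj.setdefault(a, set()).add(b)
            adj.setdefault(b, set()).add(a)
        self.adj = adj

    def excluded(self, a: tuple[int, int], b: tuple[int, int]) -> bool:
        if a == b:
            return True
        na = self.adj.get(a, ())
        if b in na:
            return True
        return bool(set(na) & self.adj.get(b, set()))


def pair_sum(surfs_a, surfs_b, ctx: InteractionContext,
             cfg: Config) -> float:
    total = 0.0
    for sa in surfs_a:
        for sb in surfs_b:
            if ctx.excluded(sa.anchor, sb.anchor):
                continue
            total += score_pair(sa, sb, cfg).value
    return total


def base_score(mode: Mode, fixed: list[InteractionSurface],
               ctx: InteractionContext, cfg: Config | None = None) -> float:
    """Intrinsic stability plus interactions with the rigid environment."""
    cfg = cfg or Config()
    return cfg.w_stability * mode.stability \
        + pair_sum(mode.surfaces, fixed, ctx, cfg)
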