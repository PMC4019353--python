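"""Quality metrics for predicted hydrogen placements.

Hydrogen bonds are detected by a heavy-atom distance / donor-H-acceptor
angle criterion; undesirable contacts (close donor-donor and donor-metal
proximities involving the ligand) are audited at configurable precision
levels; predicted ligand states are classified against a reference by
canonical-string comparison into accordant / tautomer / protonation / redox
categories, with an interaction-error suffix when the predicted network is
worse.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import chem
from .canonical import substructure_smiles
from .config import Config
from .geometry import angle_deg
from .interaction_model import InteractionContext
from .structure_io import ComplexStructure, MolecularGraph

ACCORDANT = "accordant"
TAUT_NE, TAUT_IE = "Taut_NE", "Taut_IE"
PROT_NE, PROT_IE = "Prot_NE", "Prot_IE"
REDOX = "Redox"

ACTIVE_SITE_RADIUS = 6.5   # Angstrom around the ligand


@dataclass(frozen=True)
class ContactCriterion:
    label: str
    h_h_max: float                      # donor-donor: min H...H distance
    h_metal_max: float                  # donor-metal: H...metal distance
    heavy_max: float | None = None      # combined: heavy-atom distance
    angle_dev_max: float | None = None  # combined: both D-H...D deviations

    def __post_init__(self):
        if self.h_h_max <= 0 or self.h_metal_max <= 0:
            raise ValueError("contact thresholds must be positive")


#: Reconstructed precision levels (the strictest is level 1).  Pure-distance
#: and combined angle/distance variants.
PRECISION_LEVELS: dict[int, ContactCriterion] = {
    1: ContactCriterion("*", 1.5, 1.5),
    2: ContactCriterion("**", 1.8, 1.8),
    3: ContactCriterion("***", 2.1, 2.1),
    4: ContactCriterion("****", 2.4, 2.4),
}

COMBINED_LEVELS: dict[int, ContactCriterion] = {
    1: ContactCriterion("c*", 1.5, 1.5, heavy_max=3.0, angle_dev_max=30.0),
    2: ContactCriterion("c**", 1.8, 1.8, heavy_max=3.2, angle_dev_max=40.0),
    3: ContactCriterion("c***", 2.1, 2.1, heavy_max=3.4, angle_dev_max=50.0),
    4: ContactCriterion("c****", 2.4, 2.4, heavy_max=3.6, angle_dev_max=60.0),
}


@dataclass
class HydrogenBond:
    donor: tuple[int, int]
    hydrogen: tuple[int, int]
    acceptor: tuple[int, int]
    heavy_distance: float
    angle: float


@dataclass
class Contact:
    kind: str                       # donor-donor | donor-metal
    a: tuple[int, int]              # donor heavy atom (one side)
    b: tuple[int, int]              # partner donor heavy atom or metal
    h_distance: float
    heavy_distance: float
    angles: tuple[float, float] | None


# --------------------------------------------------------------------------
# helpers


def _donors(cx: ComplexStructure):
    """(ci, ai, [H coords]) for every N/O with at least one bound hydrogen."""
    out = []
    for ci, ai, comp, a in cx.iter_atoms():
        if a.element not in ("N", "O") or not a.has_valid_coords:
            continue
        hs = [comp.atoms[h].coords for h in comp.hydrogens_of(ai)
              if comp.atoms[h].has_valid_coords]
        if hs:
            out.append((ci, ai, a.coords, hs))
    return out


def _is_acceptor(cx: ComplexStructure, ci: int, ai: int) -> bool:
    comp = cx.components[ci]
    a = comp.atoms[ai]
    if a.element not in ("N", "O") or not a.has_valid_coords:
        return False
    if a.formal_charge > 0:
        return False
    n_h = len(comp.hydrogens_of(ai))
    heavy = cx.global_heavy_order_sum(ci, ai)
    if a.element == "N":
        n_conn = len(comp.heavy_neighbors(ai)) \
            + len(cx.link_partners(ci, ai)) + n_h
        if n_conn >= 3 and not _sp3_amine_acceptor(cx, ci, ai):
            return False     # planar N: lone pair sits in the pi system
    return chem.lone_pairs(a.element, a.formal_charge, heavy + n_h) > 0


def _sp3_amine_acceptor(cx, ci, ai) -> bool:
    comp = cx.components[ci]
    if ai in comp.aromatic_atoms or any(
            comp.order(ai, j) >= 2 for j in comp.neighbors(ai)):
        return False
    # conjugation steals the lone pair (amide, aniline, guanidine)
    for j in comp.heavy_neighbors(ai):
        if comp.atoms[j].element == "C" and (
                j in comp.aromatic_atoms or any(
                    comp.order(j, k) >= 2 for k in comp.neighbors(j))):
            return False
    return True


# --------------------------------------------------------------------------
# hydrogen bonds


def find_hbonds(cx: ComplexStructure, max_heavy: float = 3.5,
                min_angle: float = 150.0) -> list[HydrogenBond]:
    """All N/O donor-acceptor pairs within the heavy-atom distance cutoff
    whose donor-hydrogen-acceptor angle reaches the minimum."""
    ctx = InteractionContext(cx)
    bonds: list[HydrogenBond] = []
    acceptors = [(ci, ai, comp.atoms[ai].coords)
                 for ci, ai, comp, a in cx.iter_atoms()
                 if _is_acceptor(cx, ci, ai)
                 and (a.element == "O" or _n_acceptor_ok(cx, ci, ai))]
    for (ci, ai, dpos, hs) in _donors(cx):
        comp = cx.components[ci]
        h_idx = [h for h in comp.hydrogens_of(ai)
                 if comp.atoms[h].has_valid_coords]
        for (cj, aj, apos) in acceptors:
            if (ci, ai) == (cj, aj) or ctx.excluded((ci, ai), (cj, aj)):
                continue
            d = float(np.linalg.norm(dpos - apos))
            if d > max_heavy:
                continue
            for h, hpos in zip(h_idx, hs):
                ang = angle_deg(dpos - hpos, apos - hpos)
                if ang >= min_angle:
                    bonds.append(HydrogenBond((ci, ai), (ci, h), (cj, aj),
                                              d, ang))
                    break
    return bonds


def _n_acceptor_ok(cx, ci, ai) -> bool:
    comp = cx.components[ci]
    has_pi = ai in comp.aromatic_atoms or any(
        comp.order(ai, j) >= 2 for j in comp.neighbors(ai))
    if has_pi:
        return True
    return _sp3_amine_acceptor(cx, ci, ai)


# --------------------------------------------------------------------------
# undesirable contacts


def find_undesirable_contacts(cx: ComplexStructure,
                              criterion: ContactCriterion,
                              ) -> list[Contact]:
    """Close donor-donor and donor-metal proximities around the ligand.

    Donors are N/O atoms of the ligand or the active site (6.5 A around it)
    with at least one bound hydrogen; exactly one counterpart of every
    reported contact belongs to the ligand.  Combined criteria additionally
    require the heavy-atom distance and both donor-H...donor angle
    deviations to fall under their thresholds.
    """
    if cx.reference_ligand is None:
        raise ValueError("no reference ligand set")
    lig = cx.components[cx.reference_ligand]
    lig_coords = np.array([a.coords for a in lig.atoms if a.has_valid_coords])
    ctx = InteractionContext(cx)

    def near_site(pos) -> bool:
        return bool(np.linalg.norm(lig_coords - pos, axis=1).min()
                    <= ACTIVE_SITE_RADIUS)

    donors = [(ci, ai, pos, hs) for (ci, ai, pos, hs) in _donors(cx)
              if ci == cx.reference_ligand or near_site(pos)]
    metals = [(ci, ai, a.coords) for ci, ai, comp, a in cx.iter_atoms()
              if chem.is_metal(a.element) and a.has_valid_coords
              and near_site(a.coords)]
    contacts: list[Contact] = []
    for x in range(len(donors)):
        ci, ai, pa, ha = donors[x]
        for y in range(x + 1, len(donors)):
            cj, aj, pb, hb = donors[y]
            if (ci == cx.reference_ligand) == (cj == cx.reference_ligand):
                continue
            if ctx.excluded((ci, ai), (cj, aj)):
                continue
            best = None
            for u in ha:
                for v in hb:
                    d = float(np.linalg.norm(np.asarray(u) - v))
                    if best is None or d < best[0]:
                        best = (d, u, v)
            d_hh, u, v = best
            if d_hh > criterion.h_h_max:
                continue
            heavy_d = float(np.linalg.norm(pa - pb))
            angles = (180.0 - angle_deg(pa - u, pb - u),
                      180.0 - angle_deg(pb - v, pa - v))
            if criterion.heavy_max is not None and heavy_d > criterion.heavy_max:
                continue
            if criterion.angle_dev_max is not None and (
                    angles[0] > criterion.angle_dev_max
                    or angles[1] > criterion.angle_dev_max):
                continue
            contacts.append(Contact("donor-donor", (ci, ai), (cj, aj),
                                    d_hh, heavy_d, angles))
        for (cm, am, mpos) in metals:
            if (ci == cx.reference_ligand) == (cm == cx.reference_ligand):
                continue
            best = min(float(np.linalg.norm(np.asarray(u) - mpos)) for u in ha)
            if best > criterion.h_metal_max:
                continue
            heavy_d = float(np.linalg.norm(pa - mpos))
            if criterion.heavy_max is not None and heavy_d > criterion.heavy_max:
                continue
            contacts.append(Contact("donor-metal", (ci, ai), (cm, am),
                                    best, heavy_d, None))
    return contacts


# --------------------------------------------------------------------------
# state classification


def _graph_smiles(graph: MolecularGraph) -> str:
    heavy = [i for i, a in enumerate(graph.atoms) if not a.is_hydrogen]
    return substructure_smiles(graph, heavy)


def _skeleton_smiles(graph: MolecularGraph) -> str:
    heavy = [i for i, a in enumerate(graph.atoms) if not a.is_hydrogen]
    return substructure_smiles(
        graph, heavy,
        h_counts={i: 0 for i in heavy},
        charges={i: 0 for i in heavy},
        bond_orders={(min(i, j), max(i, j)): 1
                     for (i, j, _) in graph.bonds()})


def _total_h(graph: MolecularGraph) -> int:
    return sum(graph.total_h(i)
               for i, a in enumerate(graph.atoms) if not a.is_hydrogen)


def _net_charge(graph: MolecularGraph) -> int:
    return sum(a.formal_charge for a in graph.atoms if not a.is_hydrogen)


def classify_state(predicted: MolecularGraph, reference: MolecularGraph,
                   interaction_errors: bool | None = None) -> str:
    """Compare a predicted ligand state against a reference state.

    Equal canonical strings -> accordant.  Same skeleton but different
    hydrogen count at equal net charge -> Redox (a saturation difference, the
    most serious error).  Different net charge -> protonation state; equal
    charge and hydrogen count -> tautomer; each suffixed _IE when the
    predicted complex shows interaction errors (undesirable contacts at
    precision level 2, or fewer hydrogen bonds than the reference), else _NE.
    """
    n_pred = sum(1 for a in predicted.atoms if not a.is_hydrogen)
    n_ref = sum(1 for a in reference.atoms if not a.is_hydrogen)
    if n_pred != n_ref:
        raise ValueError(
            f"heavy-atom counts differ ({n_pred} vs {n_ref}): "
            "not a state difference")
    if _graph_smiles(predicted) == _graph_smiles(reference):
        return ACCORDANT
    if _skeleton_smiles(predicted) != _skeleton_smiles(reference):
        raise ValueError("different heavy-atom skeletons: not a state difference")
    dq = _net_charge(predicted) - _net_charge(reference)
    dh = _total_h(predicted) - _total_h(reference)
    if dq == 0 and dh != 0:
        return REDOX
    ie = bool(interaction_errors)
    if dq != 0:
        return PROT_IE if ie else PROT_NE
    return TAUT_IE if ie else TAUT_NE


def interaction_errors_present(cx: ComplexStructure, ref_hbond_count: int,
                               level: int = 2) -> bool:
    """The _IE test: any undesirable contact at the given precision level, or
    fewer hydrogen bonds than the reference complex."""
    contacts = find_undesirable_contacts(cx, PRECISION_LEVELS[level])
    if contacts:
        return True
    return len(find_hbonds(cx)) < ref_hbond_count
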