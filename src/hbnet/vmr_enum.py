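"""Variable Mode Regions: partitioning and mode enumeration.

A component is partitioned into non-overlapping substructures whose hydrogen
positions are interdependent -- conjugated ring systems (with the exocyclic
polar substituents needed for consistent tautomers), acyclic functional
groups, waters, and flip-ambiguous side chains.  For each region all
alternative hydrogen placements ("modes": rotamers, water orientations,
tautomers, protonation states, 180-degree flips) are enumerated together
with an integer stability score from a fragment table.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import networkx as nx
import numpy as np

from . import chem
from .canonical import substructure_smiles
from .config import Config
from .geometry import TET_ANGLE, complete_directions, cone_direction, unit
from .structure_io import ComplexStructure, MolecularGraph

TERMINAL_ROTOR = "terminal-rotor"
WATER = "water"
SIDECHAIN_FLIP = "sidechain-flip"
TPG = "tautomer-protonation-group"


@dataclass
class Fragment:
    """A scored substructure pattern: whole-group key with subgroup fallback."""
    whole: str
    subs: list[str] = field(default_factory=list)


@dataclass
class Mode:
    h_positions: dict[int, list[np.ndarray]]
    charges: dict[int, int]
    bond_orders: dict[tuple[int, int], int]
    stability: int = 0
    fragments: list[Fragment] = field(default_factory=list)
    heavy_coords: dict[int, np.ndarray] = field(default_factory=dict)
    tag: str = ""
    surfaces: list = field(default_factory=list)

    def coords(self, graph: MolecularGraph, i: int) -> np.ndarray:
        c = self.heavy_coords.get(i)
        return c if c is not None else graph.atoms[i].coords

    def h_count(self, i: int) -> int:
        return len(self.h_positions.get(i, []))


@dataclass
class VMR:
    component: int
    atoms: list[int]
    kind: str
    modes: list[Mode] = field(default_factory=list)
    tpa: bool = True        # region varies only under tautomer/protonation analysis

    def atom_set(self) -> frozenset:
        return frozenset(self.atoms)


class FragmentScoreTable:
    """pattern key -> integer partial score, loaded from a plain-text file."""

    def __init__(self, scores: dict[str, int]):
        self.scores = dict(scores)

    @classmethod
    def default(cls) -> "FragmentScoreTable":
        path = resources.files("hbnet").joinpath("data/fragment_scores.txt")
        return cls.from_text(path.read_text())

    @classmethod
    def from_file(cls, path: str | Path) -> "FragmentScoreTable":
        return cls.from_text(Path(path).read_text())

    @classmethod
    def from_text(cls, text: str) -> "FragmentScoreTable":
        scores = {}
        for raw in text.splitlines():
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            key, _, val = line.rpartition(" ")
            scores[key.strip()] = int(val)
        return cls(scores)

    def score(self, fragments: list[Fragment]) -> int:
        """Whole-group match preferred; otherwise the subgroup partition is
        summed.  Unmatched fragments contribute 0 with a warning."""
        total = 0
        for frag in fragments:
            if frag.whole in self.scores:
                total += self.scores[frag.whole]
                continue
            matched = False
            for sub in frag.subs:
                if sub in self.scores:
                    total += self.scores[sub]
                    matched = True
                else:
                    warnings.warn(f"fragment pattern {sub!r} not in score table")
            if not frag.subs and not matched:
                warnings.warn(f"fragment pattern {frag.whole!r} not in score table")
        return total


def score_stability(mode: Mode, table: FragmentScoreTable) -> int:
    return table.score(mode.fragments)


# --------------------------------------------------------------------------
# partitioning


def _sp2ish(graph: MolecularGraph, i: int) -> bool:
    if i in graph.aromatic_atoms:
        return True
    return any(graph.order(i, j) >= 2 for j in graph.heavy_neighbors(i))


def _conjugated_ring_systems(graph: MolecularGraph) -> list[set[int]]:
    nxg = nx.Graph()
    heavy = [i for i, a in enumerate(graph.atoms) if not a.is_hydrogen]
    nxg.add_nodes_from(heavy)
    for (i, j, _) in graph.bonds():
        if not graph.atoms[i].is_hydrogen and not graph.atoms[j].is_hydrogen:
            nxg.add_edge(i, j)
    conj_rings = []
    for ring in nx.cycle_basis(nxg):
        if all(_sp2ish(graph, i) for i in ring):
            conj_rings.append(set(ring))
    merged: list[set[int]] = []
    for ring in conj_rings:
        hit = [s for s in merged if s & ring]
        for s in hit:
            ring |= s
            merged.remove(s)
        merged.append(ring)
    return sorted(merged, key=min)


def _ring_positions(graph: MolecularGraph, system: set[int]) -> tuple[list[int], list[int]]:
    """(variable ring nitrogens, exocyclic keto/enol oxygens) of a system."""
    ring_n = []
    for i in sorted(system):
        a = graph.atoms[i]
        if a.element == "N" and len(graph.heavy_neighbors(i)) == 2:
            ring_n.append(i)
    exo_o = []
    for i in sorted(system):
        for j in graph.heavy_neighbors(i):
            if j in system:
                continue
            b = graph.atoms[j]
            if b.element in ("O", "S") and len(graph.heavy_neighbors(j)) == 1:
                exo_o.append(j)
    return ring_n, exo_o


def partition_vmrs(cx: ComplexStructure, ci: int,
                   cfg: Config | None = None) -> list[VMR]:
    """Disjoint Variable Mode Regions of one component.

    Conjugated ring systems with variable positions become one region each
    (absorbing the exocyclic O/S substituents needed for tautomer
    consistency); acyclic carboxylates, guanidines/amidines, amines and
    hydroxyl/thiol rotors become separate regions; each water is one region;
    ASN/GLN/HIS side chains additionally flip.  Saturated non-polar skeleton
    atoms belong to no region.
    """
    cfg = cfg or Config()
    graph = cx.components[ci]
    if graph.kind == "water":
        return [VMR(ci, [0], WATER, tpa=False)]
    if graph.kind == "metal-ion" or "unperceived" in graph.flags:
        return []
    vmrs: list[VMR] = []
    claimed: set[int] = set()
    is_amide_flip = graph.kind == "protein-chain" and graph.resname in ("ASN", "GLN")

    # conjugated ring systems
    for system in _conjugated_ring_systems(graph):
        ring_n, exo_o = _ring_positions(graph, system)
        # absorb polar exocyclic substituents when the ring has variable N
        if not ring_n and not exo_o:
            continue
        if not ring_n and not any(
                graph.order(j, graph.heavy_neighbors(j)[0]) == 2 for j in exo_o):
            continue  # pure carbocycle with hydroxyls: rotors handle them
        atoms = sorted(system | set(exo_o)) if ring_n else sorted(system)
        if not ring_n:
            continue
        vmrs.append(VMR(ci, atoms, TPG, tpa=True))
        claimed.update(atoms)

    # ASN/GLN amide flip regions
    if is_amide_flip:
        names = ("CG", "OD1", "ND2") if graph.resname == "ASN" else \
            ("CD", "OE1", "NE2")
        idx = [i for i, a in enumerate(graph.atoms) if a.name in names]
        if len(idx) == 3 and all(graph.atoms[i].has_valid_coords for i in idx) \
                and not (set(idx) & claimed):
            vmrs.append(VMR(ci, sorted(idx), SIDECHAIN_FLIP, tpa=False))
            claimed.update(idx)

    # acyclic functional groups, deterministic priority order
    heavy = [i for i, a in enumerate(graph.atoms)
             if not a.is_hydrogen and i not in claimed]
    ring_atoms = set().union(*nx.cycle_basis(_heavy_nx(graph))) \
        if graph.atoms else set()

    for i in heavy:
        a = graph.atoms[i]
        if i in claimed or not a.has_valid_coords:
            continue
        if a.element == "C":
            ox = [j for j in graph.heavy_neighbors(i)
                  if graph.atoms[j].element == "O"
                  and len(graph.heavy_neighbors(j)) == 1 and j not in claimed]
            if len(ox) == 2 and i not in ring_atoms:
                vmrs.append(VMR(ci, sorted([i] + ox), TPG, tpa=True))
                claimed.update([i] + ox)
                continue
            ns = [j for j in graph.heavy_neighbors(i)
                  if graph.atoms[j].element == "N" and j not in claimed
                  and j not in ring_atoms]
            if (len(ns) >= 2 and i not in ring_atoms
                    and any(graph.order(i, j) == 2 for j in ns)):
                vmrs.append(VMR(ci, sorted([i] + ns), TPG, tpa=True))
                claimed.update([i] + ns)
                continue
    for i in heavy:
        a = graph.atoms[i]
        if i in claimed or not a.has_valid_coords:
            continue
        nbrs = graph.heavy_neighbors(i)
        if a.element == "N" and graph.heavy_order_sum(i) == len(nbrs) \
                and not _is_amide_n(graph, i) and i not in graph.aromatic_atoms \
                and a.h_count_override is None and a.hybridization != "sp2":
            if len(nbrs) == 2 and i in ring_atoms:
                vmrs.append(VMR(ci, [i], TPG, tpa=True))   # cyclic secondary amine
                claimed.add(i)
                continue
            if len(nbrs) == 1:
                vmrs.append(VMR(ci, [i], TPG, tpa=True))   # terminal amine
                claimed.add(i)
                continue
            if len(nbrs) == 2:
                vmrs.append(VMR(ci, [i], TPG, tpa=True))   # acyclic secondary amine
                claimed.add(i)
                continue
        if a.element in ("O", "S", "Se") and len(nbrs) == 1 \
                and graph.order(i, nbrs[0]) == 1 and a.formal_charge == 0 \
                and graph.implicit_h(i) == 1:
            vmrs.append(VMR(ci, [i], TERMINAL_ROTOR, tpa=False))
            claimed.add(i)

    return vmrs


def _heavy_nx(graph: MolecularGraph) -> nx.Graph:
    g = nx.Graph()
    g.add_nodes_from(i for i, a in enumerate(graph.atoms) if not a.is_hydrogen)
    for (i, j, _) in graph.bonds():
        if not graph.atoms[i].is_hydrogen and not graph.atoms[j].is_hydrogen:
            g.add_edge(i, j)
    return g


def _is_amide_n(graph: MolecularGraph, i: int) -> bool:
    for j in graph.heavy_neighbors(i):
        if graph.atoms[j].element == "C" and any(
                graph.atoms[k].element in ("O", "S") and graph.order(j, k) == 2
                for k in graph.heavy_neighbors(j)):
            return True
    return False


# --------------------------------------------------------------------------
# mode enumeration


def enumerate_modes(vmr: VMR, cx: ComplexStructure,
                    cfg: Config | None = None,
                    table: FragmentScoreTable | None = None,
                    tpa: bool = True) -> list[Mode]:
    """All alternative hydrogen placements of one region.

    With ``tpa`` disabled, tautomer/protonation regions keep only their
    normalized default mode (rotors, waters and flips still vary).
    """
    cfg = cfg or Config()
    table = table or FragmentScoreTable.default()
    graph = cx.components[vmr.component]
    if vmr.kind == WATER:
        modes = _water_modes(vmr, cx, cfg)
    elif vmr.kind == TERMINAL_ROTOR:
        modes = _rotor_modes(vmr, cx, cfg)
    elif vmr.kind == SIDECHAIN_FLIP:
        modes = _amide_flip_modes(vmr, cx, cfg)
    else:
        modes = _tpg_modes(vmr, cx, cfg, tpa)
        if graph.kind == "protein-chain" and graph.resname == "HIS" \
                and len(vmr.atoms) >= 5:
            modes = _with_ring_flips(vmr, cx, cfg, modes)
    for m in modes:
        m.stability = score_stability(m, table)
    default = modes[0]
    rest = sorted(modes[1:], key=lambda m: m.stability)
    modes = [default] + rest
    if len(modes) > cfg.max_modes:
        warnings.warn(
            f"VMR with {len(modes)} modes capped to {cfg.max_modes}")
        modes = modes[:cfg.max_modes]
    vmr.modes = modes
    return modes


def _snapshot_default(vmr: VMR, graph: MolecularGraph, tag: str,
                      fragments: list[Fragment]) -> Mode:
    h_pos = {i: [graph.atoms[h].coords.copy() for h in graph.hydrogens_of(i)]
             for i in vmr.atoms}
    charges = {i: graph.atoms[i].formal_charge for i in vmr.atoms}
    orders = {}
    for i in vmr.atoms:
        for j in graph.heavy_neighbors(i):
            if j in vmr.atoms and j > i:
                orders[(i, j)] = graph.order(i, j)
    return Mode(h_positions=h_pos, charges=charges, bond_orders=orders,
                fragments=fragments, tag=tag)


# -- rotors


def _rotor_axis(vmr: VMR, cx: ComplexStructure):
    from .hydrogen_init import _torsion_reference
    graph = cx.components[vmr.component]
    i = vmr.atoms[0]
    nbr = graph.heavy_neighbors(i)[0]
    axis = unit(graph.atoms[i].coords - graph.atoms[nbr].coords)
    ref = _torsion_reference(cx, vmr.component, i, (vmr.component, nbr))
    if ref is None:
        from .geometry import any_perpendicular
        ref = any_perpendicular(axis)
    return i, axis, ref


def _rotor_dirs(axis, ref, torsion: float, n_h: int,
                ideal_angle: float = TET_ANGLE) -> list[np.ndarray]:
    half = 180.0 - ideal_angle
    return [cone_direction(axis, ref, half, torsion + k * 120.0)
            for k in range(n_h)]


def _rotor_modes(vmr: VMR, cx: ComplexStructure, cfg: Config) -> list[Mode]:
    graph = cx.components[vmr.component]
    i, axis, ref = _rotor_axis(vmr, cx)
    a = graph.atoms[i]
    length = cfg.xh_bond_lengths.get(a.element, 1.0)
    step = 360.0 / cfg.rotor_steps
    modes = []
    for k in range(cfg.rotor_steps):
        torsion = 180.0 + k * step  # mode 0 = the anti initial placement
        d = _rotor_dirs(axis, ref, torsion, 1)[0]
        modes.append(Mode(h_positions={i: [a.coords + d * length]},
                          charges={i: a.formal_charge}, bond_orders={},
                          fragments=[Fragment("rotor")],
                          tag=f"rotor:{k}"))
    return modes


# -- waters


def _water_targets(vmr: VMR, cx: ComplexStructure, cfg: Config):
    graph = cx.components[vmr.component]
    o = graph.atoms[vmr.atoms[0]].coords
    targets = []
    for ci, ai, comp, atom in cx.iter_atoms():
        if (ci, ai) == (vmr.component, vmr.atoms[0]) or atom.is_hydrogen \
                or not atom.has_valid_coords:
            continue
        if atom.element not in ("N", "O", "S") and not chem.is_metal(atom.element):
            continue
        d = float(np.linalg.norm(atom.coords - o))
        if d <= cfg.water_partner_radius and d > 1e-6:
            targets.append((round(d, 6), tuple(np.round(atom.coords, 6)),
                            atom.coords, chem.is_metal(atom.element)))
    targets.sort(key=lambda t: (t[0], t[1]))
    return [(c, metal) for _, _, c, metal in targets]


def _water_modes(vmr: VMR, cx: ComplexStructure, cfg: Config) -> list[Mode]:
    """Interaction-directed orientation set: O-H vectors toward nearby
    acceptors, lone pairs toward nearby donors/metals, plus the canonical
    initial orientation."""
    graph = cx.components[vmr.component]
    i = vmr.atoms[0]
    o = graph.atoms[i].coords
    length = cfg.xh_bond_lengths["O"]
    angle = cfg.water_angle
    default = _snapshot_default(vmr, graph, "water:default",
                                [Fragment("water")])
    orientations: list[tuple[np.ndarray, np.ndarray]] = []
    if default.h_positions.get(i):
        h = default.h_positions[i]
        if len(h) == 2:
            orientations.append((unit(h[0] - o), unit(h[1] - o)))
    targets = _water_targets(vmr, cx, cfg)
    dirs = [unit(t - o) for t, _ in targets]
    metals = [m for _, m in targets]
    z = np.array([0.0, 0.0, 1.0])
    azimuths = [0.0, 60.0, 120.0, 180.0, 240.0, 300.0]
    for a, u in enumerate(dirs):
        ref = next((v for b, v in enumerate(dirs) if b != a), z)
        perp = ref - np.dot(ref, u) * u
        if np.linalg.norm(perp) < 1e-6:
            perp = z - np.dot(z, u) * u
            if np.linalg.norm(perp) < 1e-6:
                perp = np.array([1.0, 0.0, 0.0]) - u[0] * u
        perp = unit(perp)
        if not metals[a]:
            # donate toward the target; the second hydrogen sweeps the cone
            for az in azimuths:
                orientations.append((u, cone_direction(u, perp, angle, az)))
        # lone pairs toward the target: hydrogen bisector anti to u
        for az in azimuths[:3]:
            ha = cone_direction(-u, perp, angle / 2.0, az)
            hb = cone_direction(-u, perp, angle / 2.0, az + 180.0)
            orientations.append((ha, hb))
    modes = [default]
    seen = {_orient_key(default.h_positions[i], o)}
    for (u1, u2) in orientations:
        hpos = [o + u1 * length, o + u2 * length]
        key = _orient_key(hpos, o)
        if key in seen:
            continue
        seen.add(key)
        modes.append(Mode(h_positions={i: hpos}, charges={i: 0},
                          bond_orders={}, fragments=[Fragment("water")],
                          tag=f"water:{len(modes)}"))
    return modes


def _orient_key(h_positions, origin) -> tuple:
    ds = sorted(tuple(np.round(np.asarray(p) - origin, 2)) for p in h_positions)
    return tuple(ds)


# -- amide flips


def _amide_flip_modes(vmr: VMR, cx: ComplexStructure, cfg: Config) -> list[Mode]:
    graph = cx.components[vmr.component]
    c, o, n = _identify_amide(graph, vmr.atoms)
    default = _snapshot_default(vmr, graph, "flip:0", [Fragment("amide")])
    if not default.h_positions.get(n):
        default.h_positions[n] = _amide_h(graph, c, n, graph.atoms[n].coords,
                                          graph.atoms[o].coords, cfg)
    flipped = Mode(
        h_positions={o: [], c: [],
                     n: _amide_h(graph, c, n, graph.atoms[o].coords,
                                 graph.atoms[n].coords, cfg)},
        charges=dict(default.charges), bond_orders=dict(default.bond_orders),
        heavy_coords={o: graph.atoms[n].coords.copy(),
                      n: graph.atoms[o].coords.copy()},
        fragments=[Fragment("amide")], tag="flip:1")
    return [default, flipped]


def _identify_amide(graph: MolecularGraph, atoms: list[int]):
    c = next(i for i in atoms if graph.atoms[i].element == "C")
    o = next(i for i in atoms if graph.atoms[i].element == "O")
    n = next(i for i in atoms if graph.atoms[i].element == "N")
    return c, o, n


def _amide_h(graph: MolecularGraph, c: int, n: int, n_pos, o_pos, cfg: Config
             ) -> list[np.ndarray]:
    """Two sp2 hydrogens on an amide nitrogen at n_pos (possibly swapped)."""
    c_pos = graph.atoms[c].coords
    axis = -unit(c_pos - n_pos)
    ref = unit(o_pos - c_pos)
    length = cfg.xh_bond_lengths["N"]
    d1 = cone_direction(axis, ref, 60.0, 0.0)
    d2 = cone_direction(axis, ref, 60.0, 180.0)
    return [np.asarray(n_pos) + d1 * length, np.asarray(n_pos) + d2 * length]


# -- tautomer / protonation groups


def _tpg_modes(vmr: VMR, cx: ComplexStructure, cfg: Config,
               tpa: bool) -> list[Mode]:
    graph = cx.components[vmr.component]
    atoms = vmr.atoms
    if len(atoms) == 1:
        i = atoms[0]
        nbrs = graph.heavy_neighbors(i)
        if len(nbrs) == 1:
            return _terminal_amine_modes(vmr, cx, cfg, tpa)
        return _secondary_amine_modes(vmr, cx, cfg, tpa)
    elements = sorted(graph.atoms[i].element for i in atoms)
    if elements.count("O") == 2 and elements.count("C") == 1 and len(atoms) == 3:
        return _carboxylate_modes(vmr, cx, cfg, tpa)
    if any(i in graph.aromatic_atoms or _sp2ish(graph, i) for i in atoms) \
            and _in_ring(graph, atoms):
        return _ring_system_modes(vmr, cx, cfg, tpa)
    if elements.count("N") >= 2:
        return _guanidine_modes(vmr, cx, cfg, tpa)
    return [_snapshot_default(vmr, graph, "default", [Fragment("group")])]


def _in_ring(graph: MolecularGraph, atoms: list[int]) -> bool:
    cyc = nx.cycle_basis(_heavy_nx(graph))
    ring_atoms = set().union(*cyc) if cyc else set()
    return bool(ring_atoms & set(atoms))


def _terminal_amine_modes(vmr, cx, cfg, tpa) -> list[Mode]:
    """Acyclic amine: charged default (fixed staggered) + neutral rotors."""
    graph = cx.components[vmr.component]
    i = vmr.atoms[0]
    a = graph.atoms[i]
    default_frag = Fragment("ammonium" if a.formal_charge == 1 else
                            "amine_neutral")
    default = _snapshot_default(vmr, graph, "amine:default", [default_frag])
    modes = [default]
    if not tpa:
        return modes
    _, axis, ref = _rotor_axis(vmr, cx)
    length = cfg.xh_bond_lengths["N"]
    step = 360.0 / cfg.rotor_steps
    if a.formal_charge == 1:
        # neutral deprotonated form, two hydrogens on the rotor orbit
        for k in range(cfg.rotor_steps):
            dirs = _rotor_dirs(axis, ref, 180.0 + k * step, 2)
            modes.append(Mode(
                h_positions={i: [a.coords + d * length for d in dirs]},
                charges={i: 0}, bond_orders={},
                fragments=[Fragment("amine_neutral")], tag=f"amine:neutral{k}"))
    else:
        for k in range(1, cfg.rotor_steps):
            dirs = _rotor_dirs(axis, ref, 180.0 + k * step,
                               len(default.h_positions[i]))
            modes.append(Mode(
                h_positions={i: [a.coords + d * length for d in dirs]},
                charges={i: 0}, bond_orders={},
                fragments=[Fragment("amine_neutral")], tag=f"amine:rot{k}"))
    return modes


def _secondary_amine_modes(vmr, cx, cfg, tpa) -> list[Mode]:
    """Cyclic/acyclic secondary amine: protonated (two H) or neutral with the
    hydrogen at either of the two tetrahedral positions."""
    graph = cx.components[vmr.component]
    i = vmr.atoms[0]
    a = graph.atoms[i]
    nbrs = [j for j in graph.heavy_neighbors(i)
            if graph.atoms[j].has_valid_coords]
    dirs = [unit(graph.atoms[j].coords - a.coords) for j in nbrs]
    both = complete_directions(dirs, 2, TET_ANGLE)
    length = cfg.xh_bond_lengths["N"]
    pos = [a.coords + d * length for d in both]
    charged = Mode(h_positions={i: list(pos)}, charges={i: 1}, bond_orders={},
                   fragments=[Fragment("cyclic_ammonium")], tag="amine2:+")
    neutral = [Mode(h_positions={i: [p]}, charges={i: 0}, bond_orders={},
                    fragments=[Fragment("cyclic_amine_neutral")],
                    tag=f"amine2:n{k}") for k, p in enumerate(pos)]
    if a.formal_charge == 1:
        modes = [charged] + (neutral if tpa else [])
    else:
        current = _snapshot_default(vmr, graph,
                                    "amine2:default",
                                    [Fragment("cyclic_amine_neutral")])
        modes = [current] + ([m for m in neutral
                              if _orient_key(m.h_positions[i], a.coords)
                              != _orient_key(current.h_positions[i], a.coords)]
                             + [charged] if tpa else [])
    return modes


def _carboxylate_modes(vmr, cx, cfg, tpa) -> list[Mode]:
    """Ionized default plus neutral acid forms (H on either oxygen, syn/anti)."""
    graph = cx.components[vmr.component]
    c = next(i for i in vmr.atoms if graph.atoms[i].element == "C")
    oxy = sorted(i for i in vmr.atoms if graph.atoms[i].element == "O")
    default = _snapshot_default(vmr, graph, "coo:-", [Fragment("carboxylate")])
    modes = [default]
    if not tpa:
        return modes
    length = cfg.xh_bond_lengths["O"]
    for o in oxy:
        other = oxy[0] if o == oxy[1] else oxy[1]
        axis = unit(graph.atoms[o].coords - graph.atoms[c].coords)
        ref = unit(graph.atoms[other].coords - graph.atoms[c].coords)
        orders = {_key(c, o): 1, _key(c, other): 2}
        c_hydrogens = [graph.atoms[h].coords.copy()
                       for h in graph.hydrogens_of(c)]
        for torsion, name in ((0.0, "syn"), (180.0, "anti")):
            d = cone_direction(axis, ref, 180.0 - TET_ANGLE, torsion)
            modes.append(Mode(
                h_positions={o: [graph.atoms[o].coords + d * length],
                             other: [], c: c_hydrogens},
                charges={o: 0, other: 0, c: 0},
                bond_orders=orders,
                fragments=[Fragment("carboxylic_acid",
                                    ["hydroxyl", "keto"])],
                tag=f"coo:{o}:{name}"))
    return modes


def _key(i, j):
    return (min(i, j), max(i, j))


def _guanidine_modes(vmr, cx, cfg, tpa) -> list[Mode]:
    """Guanidinium/amidinium: protonated default; neutral forms drop one
    hydrogen from the doubly-bonded nitrogen."""
    graph = cx.components[vmr.component]
    c = next(i for i in vmr.atoms if graph.atoms[i].element == "C")
    default = _snapshot_default(vmr, graph, "guan:+",
                                [Fragment("guanidinium")])
    modes = [default]
    if not tpa:
        return modes
    n_double = next((i for i in vmr.atoms if graph.atoms[i].element == "N"
                     and graph.order(i, c) == 2), None)
    if n_double is None or len(default.h_positions.get(n_double, [])) < 2:
        return modes
    for drop in (0, 1):
        keep = [p for k, p in enumerate(default.h_positions[n_double])
                if k != drop]
        hp = {i: list(v) for i, v in default.h_positions.items()}
        hp[n_double] = keep
        ch = dict(default.charges)
        ch[n_double] = 0
        modes.append(Mode(h_positions=hp, charges=ch,
                          bond_orders=dict(default.bond_orders),
                          fragments=[Fragment("guanidine_neutral")],
                          tag=f"guan:n{drop}"))
    return modes


# -- conjugated ring systems


def _ring_system_modes(vmr, cx, cfg, tpa) -> list[Mode]:
    """Valence-consistent mobile-hydrogen placements over the pi system.

    Positions are the two-coordinate ring nitrogens and exocyclic keto/enol
    chalcogens.  Each hydrogen-count assignment is validated by searching a
    Kekule pattern: every ring carbon carries exactly one pi bond, an N-H
    may carry one (then +1), a bare N must carry one unless ring anions are
    enabled.  Charges are the minimal forced set; the net charge must fall in
    the configured window.
    """
    graph = cx.components[vmr.component]
    atoms = vmr.atoms
    ring_n, exo_o = _ring_positions(graph, set(atoms) - set(
        i for i in atoms if len(graph.heavy_neighbors(i)) == 1
        and graph.atoms[i].element in ("O", "S")))
    ring_n = [i for i in ring_n if i in atoms]
    exo_o = [i for i in exo_o if i in atoms]
    positions = ring_n + exo_o
    default = _snapshot_default(vmr, graph, "ring:default", [])
    default_assign = tuple(default.h_count(i) for i in positions)
    default_smiles = _mode_smiles(graph, vmr, default)
    default.fragments = [Fragment("ring:" + default_smiles, ["ring_default"])]
    if not positions:
        return [default]
    modes = [default]
    if not tpa:
        return modes
    sys_bonds = _system_bonds(graph, atoms)
    if len(sys_bonds) > cfg.max_order_search_bonds:
        warnings.warn("ring system too large for tautomer enumeration")
        return modes
    for assign in itertools.product((0, 1), repeat=len(positions)):
        if assign == default_assign:
            continue
        solution = _kekule_search(graph, atoms, positions, assign, sys_bonds,
                                  cfg)
        if solution is None:
            continue
        orders, charges = solution
        net = sum(charges.values())
        if not (cfg.ring_charge_min <= net <= cfg.ring_charge_max):
            continue
        mode = _build_ring_mode(graph, vmr, positions, assign, orders, charges,
                                cfg)
        if mode is None:
            continue
        smiles = _mode_smiles(graph, vmr, mode)
        d_h, m_h = sum(default_assign), sum(assign)
        if m_h > d_h:
            subs = ["ring_cation"] * (m_h - d_h)
        elif m_h < d_h:
            subs = ["ring_anion"] * (d_h - m_h)
        elif smiles == default_smiles:
            subs = ["ring_default"]
        else:
            subs = ["ring_tautomer"]
        mode.fragments = [Fragment("ring:" + smiles, subs)]
        mode.tag = "ring:" + "".join(map(str, assign))
        modes.append(mode)
    return modes


def _system_bonds(graph: MolecularGraph, atoms: list[int]) -> list[tuple[int, int]]:
    out = []
    aset = set(atoms)
    for (i, j, _) in graph.bonds():
        if i in aset and j in aset and not graph.atoms[i].is_hydrogen \
                and not graph.atoms[j].is_hydrogen:
            out.append((i, j))
    return sorted(out)


def _kekule_search(graph, atoms, positions, assign, sys_bonds, cfg: Config):
    """Pi-bond subset satisfying the obligation rules, or None."""
    h_at = {p: h for p, h in zip(positions, assign)}
    aset = set(atoms)
    exo = {i for i in atoms if len(graph.heavy_neighbors(i)) == 1
           and graph.atoms[i].element in ("O", "S")}
    best = None
    for mask in itertools.product((1, 2), repeat=len(sys_bonds)):
        orders = dict(zip(sys_bonds, mask))
        ok = True
        charges = {}
        for i in atoms:
            pi = sum(1 for b, o in orders.items() if i in b and o == 2)
            el = graph.atoms[i].element
            ext_pi = sum(1 for j in graph.heavy_neighbors(i)
                         if j not in aset and graph.order(i, j) >= 2)
            pi += ext_pi
            if el == "C":
                if pi != 1:
                    ok = False
                    break
                charges[i] = 0
            elif el == "N" and i in h_at:
                if h_at[i] == 1:
                    if pi > 1:
                        ok = False
                        break
                    charges[i] = 1 if pi == 1 else 0
                else:
                    if pi == 0 and not cfg.allow_ring_anions:
                        ok = False
                        break
                    if pi > 1:
                        ok = False
                        break
                    charges[i] = 0 if pi == 1 else -1
            elif el == "N":  # substituted ring nitrogen, not a position
                if pi > 1:
                    ok = False
                    break
                charges[i] = 1 if pi == 1 and len(graph.heavy_neighbors(i)) == 3 \
                    else 0
            elif i in exo:
                want_h = h_at.get(i, 0)
                if want_h == 1:
                    if pi != 0:
                        ok = False
                        break
                    charges[i] = 0
                else:
                    if pi == 0 and not cfg.allow_ring_anions:
                        ok = False
                        break
                    charges[i] = 0 if pi == 1 else -1
                if pi > 1:
                    ok = False
                    break
            else:
                charges[i] = 0
        if not ok:
            continue
        cost = sum(abs(c) for c in charges.values())
        if best is None or cost < best[0]:
            best = (cost, orders, charges)
    if best is None:
        return None
    return best[1], best[2]


def _build_ring_mode(graph, vmr, positions, assign, orders, charges,
                     cfg: Config) -> Mode | None:
    # non-variable atoms (ring carbons, substituted N) keep their hydrogens
    h_pos: dict[int, list[np.ndarray]] = {
        i: [graph.atoms[h].coords.copy() for h in graph.hydrogens_of(i)]
        for i in vmr.atoms}
    for p in positions:
        h_pos[p] = []
    for p, h in zip(positions, assign):
        if h == 0:
            continue
        a = graph.atoms[p]
        nbrs = [j for j in graph.heavy_neighbors(p)
                if graph.atoms[j].has_valid_coords]
        if not a.has_valid_coords or not nbrs:
            return None
        dirs = [unit(graph.atoms[j].coords - a.coords) for j in nbrs]
        if len(dirs) == 2:  # ring N-H: in-plane bisector
            d = complete_directions(dirs, 1, 120.0)[0]
        else:               # exocyclic O-H: anti to the ring
            c = nbrs[0]
            ring_ref = next((unit(graph.atoms[k].coords - graph.atoms[c].coords)
                             for k in sorted(graph.heavy_neighbors(c))
                             if k != p and graph.atoms[k].has_valid_coords),
                            None)
            axis = unit(a.coords - graph.atoms[c].coords)
            if ring_ref is None:
                from .geometry import any_perpendicular
                ring_ref = any_perpendicular(axis)
            d = cone_direction(axis, ring_ref, 180.0 - TET_ANGLE, 180.0)
        length = cfg.xh_bond_lengths.get(a.element, 1.0)
        h_pos[p].append(a.coords + d * length)
    mode_orders = {}
    for i in vmr.atoms:
        for j in graph.heavy_neighbors(i):
            if j in vmr.atoms and j > i:
                mode_orders[(i, j)] = orders.get((i, j), orders.get((j, i),
                                                 graph.order(i, j)))
    full_charges = {i: charges.get(i, graph.atoms[i].formal_charge)
                    for i in vmr.atoms}
    return Mode(h_positions=h_pos, charges=full_charges,
                bond_orders=mode_orders)


def _mode_smiles(graph, vmr, mode: Mode) -> str:
    return substructure_smiles(
        graph, vmr.atoms,
        h_counts={i: mode.h_count(i) for i in vmr.atoms},
        charges=mode.charges,
        bond_orders=mode.bond_orders)


def _with_ring_flips(vmr, cx, cfg, modes: list[Mode]) -> list[Mode]:
    """HIS: each tautomer/protonation state additionally 180-degree flipped
    (ND1<->CD2 and CE1<->NE2 coordinate exchange)."""
    graph = cx.components[vmr.component]
    names = {a.name: i for i, a in enumerate(graph.atoms)}
    pairs = [(names.get("ND1"), names.get("CD2")),
             (names.get("CE1"), names.get("NE2"))]
    if any(x is None or y is None for x, y in pairs):
        return modes
    swap = {}
    for x, y in pairs:
        swap[x], swap[y] = graph.atoms[y].coords.copy(), graph.atoms[x].coords.copy()
    out = list(modes)
    for m in modes:
        hp = {}
        for i, plist in m.h_positions.items():
            if i in swap and plist:
                a = graph.atoms[i]
                nbrs = [j for j in graph.heavy_neighbors(i)]
                dirs = [unit((swap.get(j, graph.atoms[j].coords)) - swap[i])
                        for j in nbrs if graph.atoms[j].has_valid_coords
                        or j in swap]
                d = complete_directions(dirs, 1, 120.0)[0]
                length = cfg.xh_bond_lengths.get(a.element, 1.0)
                hp[i] = [swap[i] + d * length]
            else:
                hp[i] = [p.copy() for p in plist]
        out.append(Mode(h_positions=hp, charges=dict(m.charges),
                        bond_orders=dict(m.bond_orders),
                        heavy_coords={k: v.copy() for k, v in swap.items()},
                        fragments=[Fragment(f.whole, list(f.subs))
                                   for f in m.fragments],
                        tag=m.tag + ":flip"))
    return out


def mode_valence_ok(vmr: VMR, mode: Mode, cx: ComplexStructure) -> bool:
    """Every region atom satisfies its valence under the mode's state."""
    graph = cx.components[vmr.component]
    for i in vmr.atoms:
        a = graph.atoms[i]
        if chem.is_metal(a.element):
            continue
        total = mode.h_count(i)
        for j in graph.heavy_neighbors(i):
            if j in vmr.atoms:
                total += mode.bond_orders.get(_key(i, j), graph.order(i, j))
            else:
                total += graph.order(i, j)
        for (_, _, o) in cx.link_partners(vmr.component, i):
            total += o
        if not chem.check_valence(a.element, mode.charges.get(i, 0), total):
            return False
    return True
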