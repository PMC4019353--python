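"""Hydrogen-bond network optimization over the region interaction graph.

Nodes are regions (VMRs) with per-mode base scores; edges carry matrices of
pairwise mode scores.  The score-minimal mode assignment

    totalScore(M) = sum_m baseScore(m) + sum_{m,n} interactions(m,n) + repulsions(m,n)

is found exactly on each connected component by iterative dynamic-programming
contraction of degree-<=2 nodes plus exhaustive solution of small residual
cores; ties are broken by the lexicographically smallest mode-index vector,
which prefers normalized default states (mode 0).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .config import Config
from .interaction_model import (InteractionContext, base_score,
                                build_surfaces, fixed_surfaces, pair_sum)
from .structure_io import Atom, ComplexStructure
from .vmr_enum import VMR, Mode, _key


@dataclass
class NetworkGraph:
    nodes: list[VMR]
    base: list[np.ndarray]                       # per node: per-mode base score
    edges: dict[tuple[int, int], np.ndarray] = field(default_factory=dict)

    def neighbors(self, i: int) -> list[int]:
        out = []
        for (a, b) in self.edges:
            if a == i:
                out.append(b)
            elif b == i:
                out.append(a)
        return sorted(set(out))

    def matrix(self, i: int, j: int) -> np.ndarray:
        """Edge matrix oriented (modes_i, modes_j)."""
        if (i, j) in self.edges:
            return self.edges[(i, j)]
        return self.edges[(j, i)].T


@dataclass
class Assignment:
    modes: list[int]
    total_score: float
    certified: bool = True


# --------------------------------------------------------------------------
# network construction


def build_network(vmrs: list[VMR], cx: ComplexStructure,
                  cfg: Config | None = None) -> NetworkGraph:
    """Attach surfaces, base scores and pairwise matrices.

    An edge is created when two regions have atoms within the search radius
    and at least one mode pair scores nonzero.
    """
    cfg = cfg or Config()
    ctx = InteractionContext(cx)
    variable_atoms = {(v.component, i) for v in vmrs for i in v.atoms}
    fixed = fixed_surfaces(cx, variable_atoms, cfg)
    for vmr in vmrs:
        for mode in vmr.modes:
            mode.surfaces = build_surfaces(mode, vmr, cx, cfg)
    base = [np.array([base_score(m, fixed, ctx, cfg) for m in v.modes])
            for v in vmrs]
    net = NetworkGraph(nodes=vmrs, base=base)

    coords = []
    for v in vmrs:
        graph = cx.components[v.component]
        pts = [graph.atoms[i].coords for i in v.atoms
               if graph.atoms[i].has_valid_coords]
        coords.append(np.array(pts) if pts else np.zeros((0, 3)))
    for i in range(len(vmrs)):
        for j in range(i + 1, len(vmrs)):
            if not len(coords[i]) or not len(coords[j]):
                continue
            d = np.linalg.norm(coords[i][:, None, :] - coords[j][None, :, :],
                               axis=-1)
            if d.min() > cfg.search_radius:
                continue
            mat = np.array([
                [pair_sum(mi.surfaces, mj.surfaces, ctx, cfg)
                 for mj in vmrs[j].modes]
                for mi in vmrs[i].modes])
            if np.any(mat != 0.0):
                net.edges[(i, j)] = mat
    return net


# --------------------------------------------------------------------------
# optimization


def prune_dominated(net: NetworkGraph) -> list[list[int]]:
    """Surviving mode indices per node after dominated-mode pruning.

    Mode i is removed when an earlier mode j <= i is no worse in base score
    and in every row/column of every incident edge matrix; with the
    lexicographic tie-break this provably preserves the optimum.
    """
    allowed = []
    for n, vmr in enumerate(net.nodes):
        k = len(vmr.modes)
        keep = []
        mats = [net.matrix(n, m) for m in net.neighbors(n)]
        for i in range(k):
            dominated = False
            for j in keep:
                if net.base[n][j] <= net.base[n][i] and all(
                        np.all(M[j] <= M[i]) for M in mats):
                    dominated = True
                    break
            if not dominated:
                keep.append(i)
        allowed.append(keep)
    return allowed


def _components(net: NetworkGraph) -> list[list[int]]:
    seen = set()
    comps = []
    for start in range(len(net.nodes)):
        if start in seen:
            continue
        stack, comp = [start], []
        seen.add(start)
        while stack:
            v = stack.pop()
            comp.append(v)
            for u in net.neighbors(v):
                if u not in seen:
                    seen.add(u)
                    stack.append(u)
        comps.append(sorted(comp))
    return comps


class _Folded:
    """Mutable working copy for one DP run (fixed fold order by node index)."""

    def __init__(self, net: NetworkGraph, comp: list[int],
                 allowed: list[list[int]], restrict: dict[int, int]):
        self.base: dict[int, np.ndarray] = {}
        self.modes: dict[int, list[int]] = {}
        for n in comp:
            idx = [restrict[n]] if n in restrict else list(allowed[n])
            self.modes[n] = idx
            self.base[n] = net.base[n][idx].astype(float)
        self.edges: dict[tuple[int, int], np.ndarray] = {}
        for (a, b), M in sorted(net.edges.items()):
            if a in self.modes and b in self.modes:
                self.edges[(a, b)] = M[np.ix_(self.modes[a], self.modes[b])]
        self.const = 0.0

    def _degree(self, n: int) -> int:
        return sum(1 for e in self.edges if n in e)

    def _nbrs(self, n: int) -> list[int]:
        out = set()
        for (a, b) in self.edges:
            if a == n:
                out.add(b)
            elif b == n:
                out.add(a)
        return sorted(out)

    def _mat(self, i: int, j: int) -> np.ndarray:
        return self.edges[(i, j)] if (i, j) in self.edges \
            else self.edges[(j, i)].T

    def _pop_edges(self, n: int) -> None:
        for e in [e for e in self.edges if n in e]:
            del self.edges[e]

    def fold(self, max_nodes: int, max_combos: int, beam: int
             ) -> tuple[float, bool]:
        while True:
            target = None
            for n in sorted(self.base):
                if self._degree(n) <= 2:
                    target = n
                    break
            if target is None:
                break
            deg = self._degree(target)
            if deg == 0:
                self.const += float(self.base[target].min())
                del self.base[target]
            elif deg == 1:
                u = self._nbrs(target)[0]
                M = self._mat(target, u)
                self.base[u] = self.base[u] + \
                    (self.base[target][:, None] + M).min(axis=0)
                self._pop_edges(target)
                del self.base[target]
            else:
                u, w = self._nbrs(target)
                Mu = self._mat(target, u)
                Mw = self._mat(target, w)
                T = (self.base[target][:, None, None]
                     + Mu[:, :, None] + Mw[:, None, :]).min(axis=0)
                key = (u, w) if u < w else (w, u)
                T2 = T if u < w else T.T
                if key in self.edges:
                    self.edges[key] = self.edges[key] + T2
                else:
                    self.edges[key] = T2
                self._pop_edges(target)
                del self.base[target]
        if not self.base:
            return self.const, True
        return self._solve_core(max_nodes, max_combos, beam)

    def _solve_core(self, max_nodes: int, max_combos: int, beam: int
                    ) -> tuple[float, bool]:
        nodes = sorted(self.base)
        combos = 1
        for n in nodes:
            combos *= len(self.base[n])
        if len(nodes) <= max_nodes and combos <= max_combos:
            shape = tuple(len(self.base[n]) for n in nodes)
            pos = {n: k for k, n in enumerate(nodes)}
            total = np.zeros(shape)
            for n in nodes:
                sl = [None] * len(nodes)
                sl[pos[n]] = slice(None)
                total = total + self.base[n][tuple(sl)]
            for (a, b), M in sorted(self.edges.items()):
                # edges are stored with a < b, so pos[a] < pos[b] always holds
                shape_b = [1] * len(nodes)
                shape_b[pos[a]] = M.shape[0]
                shape_b[pos[b]] = M.shape[1]
                total = total + M.reshape(shape_b)
            return self.const + float(total.min()), True
        # deterministic beam-search fallback: result flagged non-certified
        states: list[tuple[float, tuple[int, ...]]] = [(0.0, ())]
        for n in nodes:
            new = []
            for score, chosen in states:
                for mi, _ in enumerate(self.base[n]):
                    s = score + float(self.base[n][mi])
                    for prev_k, prev_n in enumerate(nodes[:len(chosen)]):
                        if (min(prev_n, n), max(prev_n, n)) in self.edges:
                            M = self._mat(prev_n, n)
                            s += float(M[chosen[prev_k], mi])
                    new.append((s, chosen + (mi,)))
            new.sort(key=lambda t: (t[0], t[1]))
            states = new[:beam]
        return self.const + states[0][0], False


def _dp_min(net: NetworkGraph, comp: list[int], allowed: list[list[int]],
            restrict: dict[int, int], cfg: Config) -> tuple[float, bool]:
    f = _Folded(net, comp, allowed, restrict)
    return f.fold(cfg.core_max_nodes, cfg.core_max_combinations,
                  cfg.beam_width)


def eval_assignment(net: NetworkGraph, modes: list[int]) -> float:
    """Total score of a full mode selection, in canonical summation order."""
    total = 0.0
    for n in range(len(net.nodes)):
        total += float(net.base[n][modes[n]])
    for (a, b), M in sorted(net.edges.items()):
        total += float(M[modes[a], modes[b]])
    return total


def optimize(net: NetworkGraph, cfg: Config | None = None) -> Assignment:
    """Globally score-minimal assignment per connected component.

    Singleton/dominated-mode pruning, then DP folding for the optimal value,
    then nodes are fixed in index order to the first mode that achieves it
    (the lexicographically smallest optimal vector).  Residual cores beyond
    the exhaustive caps fall back to a deterministic beam search and the
    result is flagged non-certified.
    """
    cfg = cfg or Config()
    if not net.nodes:
        return Assignment([], 0.0)
    allowed = prune_dominated(net)
    selection = [0] * len(net.nodes)
    certified = True
    for comp in _components(net):
        value, cert = _dp_min(net, comp, allowed, {}, cfg)
        certified &= cert
        restrict: dict[int, int] = {}
        for n in comp:
            if not cert:
                break
            for mi in allowed[n]:
                trial = dict(restrict)
                trial[n] = mi
                v, c = _dp_min(net, comp, allowed, trial, cfg)
                if c and v == value:
                    restrict[n] = mi
                    break
            else:
                # numerically unreachable; pick the best remaining mode
                restrict[n] = allowed[n][0]
        if not cert:
            restrict = _beam_assignment(net, comp, allowed, cfg)
        for n, mi in restrict.items():
            selection[n] = mi
    return Assignment(selection, eval_assignment(net, selection), certified)


def _beam_assignment(net: NetworkGraph, comp: list[int],
                     allowed: list[list[int]], cfg: Config) -> dict[int, int]:
    states: list[tuple[float, tuple[int, ...]]] = [(0.0, ())]
    for k, n in enumerate(comp):
        new = []
        for score, chosen in states:
            for mi in allowed[n]:
                s = score + float(net.base[n][mi])
                for pk, pn in enumerate(comp[:k]):
                    if (min(pn, n), max(pn, n)) in net.edges:
                        s += float(net.matrix(pn, n)[chosen[pk], mi])
                new.append((s, chosen + (mi,)))
        new.sort(key=lambda t: (t[0], t[1]))
        states = new[:cfg.beam_width]
    best = states[0][1]
    return {n: best[k] for k, n in enumerate(comp)}


def brute_force(net: NetworkGraph, max_combinations: int = 1_000_000
                ) -> Assignment:
    """Exhaustive enumeration of the total score (test oracle).

    Vectorized over the full mode product; np.argmin's first-occurrence rule
    in C order realizes the same lexicographic tie-break as optimize.
    """
    if not net.nodes:
        return Assignment([], 0.0)
    shape = tuple(len(v.modes) for v in net.nodes)
    combos = 1
    for s in shape:
        combos *= s
    if combos > max_combinations:
        raise ValueError(f"{combos} combinations exceed the brute-force cap")
    total = np.zeros(shape)
    for n in range(len(net.nodes)):
        sl = [1] * len(shape)
        sl[n] = shape[n]
        total = total + net.base[n].reshape(sl)
    for (a, b), M in sorted(net.edges.items()):
        sl = [1] * len(shape)
        sl[a], sl[b] = M.shape
        total = total + M.reshape(sl)
    flat = int(np.argmin(total))
    modes = list(np.unravel_index(flat, shape))
    modes = [int(m) for m in modes]
    return Assignment(modes, eval_assignment(net, modes))


# --------------------------------------------------------------------------
# back-transfer and re-scoring


def apply_assignment(cx: ComplexStructure, vmrs: list[VMR],
                     assignment: Assignment) -> ComplexStructure:
    """Transfer the selected modes back onto the complex.

    Hydrogens, formal charges and bond orders of each region are replaced by
    its selected mode; flip modes also exchange the heavy-atom coordinates.
    Hydrogens outside all regions are untouched.
    """
    if len(assignment.modes) != len(vmrs):
        raise ValueError("assignment does not cover every region")
    for vmr, mi in zip(vmrs, assignment.modes):
        mode = vmr.modes[mi]
        graph = cx.components[vmr.component]
        for i, pos in mode.heavy_coords.items():
            graph.atoms[i].coords = pos.copy()
        for i in sorted(vmr.atoms, reverse=True):
            graph.remove_atom_hydrogens(i)
        for i in vmr.atoms:
            graph.atoms[i].formal_charge = mode.charges.get(
                i, graph.atoms[i].formal_charge)
        for (a, b), order in mode.bond_orders.items():
            graph.add_bond(a, b, order)
        for i in vmr.atoms:
            for pos in mode.h_positions.get(i, []):
                h = graph.add_atom(Atom(element="H", coords=np.asarray(pos).copy()))
                graph.add_bond(i, h, 1)
    return cx


def rescore(cx: ComplexStructure, vmrs: list[VMR], assignment: Assignment,
            cfg: Config | None = None) -> float:
    """Recompute the total score of an applied structure from scratch.

    Surfaces are rebuilt from the actual atom positions in the complex; the
    result must reproduce the optimizer's reported score (within numerical
    round-off) -- the self-consistency check of the objective.
    """
    cfg = cfg or Config()
    ctx = InteractionContext(cx)
    variable_atoms = {(v.component, i) for v in vmrs for i in v.atoms}
    fixed = fixed_surfaces(cx, variable_atoms, cfg)
    pseudo: list[Mode] = []
    for vmr, mi in zip(vmrs, assignment.modes):
        graph = cx.components[vmr.component]
        h_pos = {i: [graph.atoms[h].coords for h in graph.hydrogens_of(i)]
                 for i in vmr.atoms}
        charges = {i: graph.atoms[i].formal_charge for i in vmr.atoms}
        orders = {}
        for i in vmr.atoms:
            for j in graph.heavy_neighbors(i):
                if j in vmr.atoms and j > i:
                    orders[_key(i, j)] = graph.order(i, j)
        m = Mode(h_positions=h_pos, charges=charges, bond_orders=orders,
                 stability=vmr.modes[mi].stability)
        m.surfaces = build_surfaces(m, vmr, cx, cfg)
        pseudo.append(m)
    total = 0.0
    for vmr, m in zip(vmrs, pseudo):
        total += base_score(m, fixed, ctx, cfg)
    for i in range(len(vmrs)):
        for j in range(i + 1, len(vmrs)):
            total += pair_sum(pseudo[i].surfaces, pseudo[j].surfaces, ctx, cfg)
    return total
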