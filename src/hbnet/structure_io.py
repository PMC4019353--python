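"""Reading, cleaning, constructing and writing protein-ligand complexes.

The PDB format carries no bond orders, so complexes are rebuilt from
coordinates: standard residues through bundled templates (missing atoms added
topologically without coordinates), everything else through generic
distance-based perception with a bounded search over bond-order assignments.
Components are then connected (peptide bonds by template, the rest by local
perception) into a :class:`ComplexStructure`.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from . import chem, templates
from .config import Config


class PDBParseError(ValueError):
    """Malformed fixed-width PDB line; message names the line number."""


class CleanupError(ValueError):
    """Cleanup would remove reference-ligand heavy atoms (or found none)."""


class TemplateFallthrough(LookupError):
    """Residue records do not fit any bundled template."""


# --------------------------------------------------------------------------
# records


@dataclass
class AtomRecord:
    serial: int
    name: str
    altloc: str
    resname: str
    chain: str
    resseq: int
    icode: str
    coords: np.ndarray
    occupancy: float
    element: str
    charge: int = 0
    is_hetero: bool = False
    line_number: int = 0

    @property
    def residue_key(self) -> tuple:
        return (self.chain, self.resseq, self.icode, self.resname)


def _guess_element(name: str, resname: str) -> str:
    stripped = "".join(c for c in name if c.isalpha())
    if not stripped:
        return ""
    two = stripped[:2].capitalize()
    if len(stripped) >= 2 and two in chem.PERIODIC_TABLE and (
            chem.is_metal(two) or two in ("Cl", "Br", "Se")):
        return two
    return stripped[0].upper()


def read_pdb(text: str) -> list[AtomRecord]:
    """Parse ATOM/HETATM coordinate lines (PDB v3.3 columns).

    Only the first MODEL is read; TER/ANISOU/REMARK and friends are ignored.
    Alternate locations are retained as-is (filtering is cleanup's job).
    Raises :class:`PDBParseError` naming the offending line.
    """
    records: list[AtomRecord] = []
    model_seen = 0
    for lineno, line in enumerate(text.splitlines(), start=1):
        tag = line[:6].strip()
        if tag == "MODEL":
            model_seen += 1
            if model_seen > 1:
                break
            continue
        if tag == "ENDMDL" and model_seen:
            break
        if tag not in ("ATOM", "HETATM"):
            continue
        if len(line) < 54:
            raise PDBParseError(f"line {lineno}: truncated coordinate record")
        try:
            serial = int(line[6:11])
            name = line[12:16].strip()
            altloc = line[16].strip()
            resname = line[17:20].strip()
            chain = line[21].strip()
            resseq = int(line[22:26])
            icode = line[26].strip()
            coords = np.array([float(line[30:38]), float(line[38:46]),
                               float(line[46:54])])
            occ_field = line[54:60].strip() if len(line) >= 60 else ""
            occupancy = float(occ_field) if occ_field else 1.0
        except ValueError as exc:
            raise PDBParseError(f"line {lineno}: {exc}") from None
        element = line[76:78].strip().capitalize() if len(line) >= 78 else ""
        if not element:
            element = _guess_element(name, resname)
        if element == "D":
            element = "H"
        if element not in chem.PERIODIC_TABLE and element != "H":
            raise PDBParseError(
                f"line {lineno}: unknown element {element!r} for atom {name!r}")
        if not np.all(np.isfinite(coords)):
            raise PDBParseError(f"line {lineno}: non-finite coordinates")
        charge = 0
        if len(line) >= 80:
            cf = line[78:80].strip()
            if cf and cf[0].isdigit():
                charge = int(cf[0]) * (-1 if cf.endswith("-") else 1)
        records.append(AtomRecord(
            serial=serial, name=name, altloc=altloc, resname=resname,
            chain=chain, resseq=resseq, icode=icode, coords=coords,
            occupancy=occupancy, element=element, charge=charge,
            is_hetero=(tag == "HETATM"), line_number=lineno))
    return records


def read_conect(text: str) -> list[tuple[int, int]]:
    """Serial pairs from CONECT records (first model, deduplicated)."""
    pairs = set()
    for line in text.splitlines():
        if not line.startswith("CONECT"):
            continue
        fields = [line[i:i + 5].strip() for i in range(6, min(len(line), 31), 5)]
        serials = [int(f) for f in fields if f]
        if len(serials) < 2:
            continue
        for other in serials[1:]:
            pairs.add((min(serials[0], other), max(serials[0], other)))
    return sorted(pairs)


# --------------------------------------------------------------------------
# cleanup


def parse_ligand_selector(selector) -> tuple[str, str, int]:
    """'LIG:A:1' or (resname, chain, resseq) -> normalized triple."""
    if isinstance(selector, str):
        parts = selector.split(":")
        if len(parts) != 3:
            raise ValueError(f"ligand selector {selector!r}: expected NAME:CHAIN:RESSEQ")
        return parts[0], parts[1], int(parts[2])
    resname, chain, resseq = selector
    return str(resname), str(chain), int(resseq)


def _group_entries(records: list[AtomRecord]) -> list[tuple[tuple, list[AtomRecord]]]:
    """Residue entries in file order."""
    order: list[tuple] = []
    groups: dict[tuple, list[AtomRecord]] = {}
    for rec in records:
        key = rec.residue_key
        if key not in groups:
            groups[key] = []
            order.append(key)
        groups[key].append(rec)
    return [(k, groups[k]) for k in order]


def _min_cross_distance(a: list[AtomRecord], b: list[AtomRecord]) -> float:
    da = np.array([r.coords for r in a])
    db = np.array([r.coords for r in b])
    return float(cdist(da, db).min())


def _matches_ligand(entry: list[AtomRecord], ligand: list[AtomRecord],
                    floor: float) -> bool:
    """Every entry atom has a same-element ligand atom within the floor."""
    lig_coords = np.array([r.coords for r in ligand])
    for rec in entry:
        d = np.linalg.norm(lig_coords - rec.coords, axis=1)
        j = int(np.argmin(d))
        if d[j] > floor or ligand[j].element != rec.element:
            return False
    return True


def _conformations(entry: list[AtomRecord]) -> list[tuple[str, list[AtomRecord]]]:
    """Altloc conformations (blank-altloc atoms shared), in file order."""
    alts: list[str] = []
    for rec in entry:
        if rec.altloc and rec.altloc not in alts:
            alts.append(rec.altloc)
    if not alts:
        return [("", entry)]
    return [(a, [r for r in entry if r.altloc in ("", a)]) for a in alts]


def cleanup(records: list[AtomRecord], reference_ligand) -> list[AtomRecord]:
    """The preprocessing filter chain applied before hydrogen prediction.

    In order: (1) all hydrogen entries are erased; (2) residue entries
    overlapping the reference ligand (any atom pair <= 1 A) are resolved --
    entries duplicating the ligand are removed, entries with alternate
    locations keep their best-fitting conformation and survive only if their
    first altloc is overlap-free; (3) only the first altloc position per atom
    is kept; (4) entries overlapping any preceding entry, or internally
    overlapping, are dropped.  Removing reference-ligand heavy atoms is a hard
    failure.
    """
    floor = 1.0
    resname, chain, resseq = parse_ligand_selector(reference_ligand)

    # (1) strip hydrogens
    recs = [r for r in records if r.element != "H"]

    entries = _group_entries(recs)
    lig_keys = [k for k, _ in entries
                if k[3] == resname and k[0] == chain and k[1] == resseq]
    if not lig_keys:
        raise CleanupError(
            f"reference ligand {resname}:{chain}:{resseq} not found")
    ligand_records = [r for k in lig_keys
                      for r in dict(entries)[k]]

    # (2) resolve entries overlapping the reference ligand
    kept: list[AtomRecord] = []
    for key, entry in entries:
        if key in lig_keys:
            kept.extend(entry)
            continue
        if _min_cross_distance(entry, ligand_records) > floor:
            kept.extend(entry)
            continue
        confs = _conformations(entry)
        if len(confs) == 1:
            # no altlocs: removed whether it duplicates the ligand or not
            continue
        best = min(confs, key=lambda c: _mean_match_distance(c[1], ligand_records))
        if _matches_ligand(best[1], ligand_records, floor):
            continue  # represents a part of the reference ligand
        first = confs[0]
        if _min_cross_distance(first[1], ligand_records) > floor:
            kept.extend(first[1])
        # else: removed

    # (3) first altloc per atom
    filtered: list[AtomRecord] = []
    seen: set[tuple] = set()
    for rec in kept:
        atom_key = rec.residue_key + (rec.name,)
        if atom_key in seen:
            continue
        seen.add(atom_key)
        filtered.append(rec)

    # (4) drop entries overlapping preceding entries or internally
    final: list[AtomRecord] = []
    accepted: list[list[AtomRecord]] = []
    for key, entry in _group_entries(filtered):
        coords = np.array([r.coords for r in entry])
        internal = False
        if len(entry) > 1:
            d = cdist(coords, coords)
            np.fill_diagonal(d, np.inf)
            internal = bool(d.min() <= floor)
        clash = internal or any(
            _min_cross_distance(entry, prev) <= floor for prev in accepted)
        if clash:
            if key in lig_keys:
                raise CleanupError(
                    f"cleanup would remove reference-ligand heavy atoms "
                    f"({resname}:{chain}:{resseq}): internal or preceding overlap")
            continue
        accepted.append(entry)
        final.extend(entry)

    if not any(r.residue_key in lig_keys for r in final):
        raise CleanupError(
            f"cleanup removed the reference ligand {resname}:{chain}:{resseq}")
    return final


def _mean_match_distance(entry: list[AtomRecord],
                         ligand: list[AtomRecord]) -> float:
    lig = np.array([r.coords for r in ligand])
    d = [float(np.linalg.norm(lig - r.coords, axis=1).min()) for r in entry]
    return float(np.mean(d))


# --------------------------------------------------------------------------
# molecular graphs


@dataclass
class Atom:
    element: str
    coords: np.ndarray | None
    formal_charge: int = 0
    hybridization: str = ""
    name: str = ""
    record: AtomRecord | None = None
    from_template: bool = False
    h_count_override: int | None = None

    @property
    def has_valid_coords(self) -> bool:
        return self.coords is not None

    @property
    def is_hydrogen(self) -> bool:
        return self.element == "H"


class MolecularGraph:
    """Atoms + integer-order bonds; the unified residue/ligand description."""

    def __init__(self, kind: str = "other"):
        self.atoms: list[Atom] = []
        self._orders: dict[tuple[int, int], int] = {}
        self._adj: dict[int, list[int]] = {}
        self.aromatic_atoms: set[int] = set()
        self.kind = kind
        self.resname = ""
        self.chain = ""
        self.resseq = 0
        self.icode = ""
        self.flags: set[str] = set()

    # -- construction
    def add_atom(self, atom: Atom) -> int:
        self.atoms.append(atom)
        idx = len(self.atoms) - 1
        self._adj[idx] = []
        return idx

    def add_bond(self, i: int, j: int, order: int = 1) -> None:
        if i == j or not (0 <= i < len(self.atoms) and 0 <= j < len(self.atoms)):
            raise ValueError(f"bond ({i},{j}) references missing atoms")
        key = (min(i, j), max(i, j))
        if key not in self._orders:
            self._adj[i].append(j)
            self._adj[j].append(i)
        self._orders[key] = order

    def remove_atom_hydrogens(self, parent: int) -> None:
        hs = sorted(self.hydrogens_of(parent), reverse=True)
        for h in hs:
            self._remove_atom(h)

    def _remove_atom(self, idx: int) -> None:
        # renumbering removal; only used for hydrogens (always trailing-safe)
        for j in list(self._adj[idx]):
            self._adj[j].remove(idx)
            self._orders.pop((min(idx, j), max(idx, j)))
        del self._adj[idx]
        self.atoms.pop(idx)
        remap = {old: (old if old < idx else old - 1) for old in self._adj}
        self._adj = {remap[k]: [remap[v] for v in vs] for k, vs in self._adj.items()}
        self._orders = {(min(remap[a], remap[b]), max(remap[a], remap[b])): o
                        for (a, b), o in self._orders.items()}
        self.aromatic_atoms = {remap[a] for a in self.aromatic_atoms}

    # -- queries
    def bonds(self) -> list[tuple[int, int, int]]:
        return [(i, j, o) for (i, j), o in sorted(self._orders.items())]

    def order(self, i: int, j: int) -> int:
        return self._orders.get((min(i, j), max(i, j)), 0)

    def neighbors(self, i: int) -> list[int]:
        return sorted(self._adj[i])

    def heavy_neighbors(self, i: int) -> list[int]:
        return [j for j in self.neighbors(i) if not self.atoms[j].is_hydrogen]

    def hydrogens_of(self, i: int) -> list[int]:
        return [j for j in self.neighbors(i) if self.atoms[j].is_hydrogen]

    def order_sum(self, i: int) -> int:
        return sum(self.order(i, j) for j in self.neighbors(i))

    def heavy_order_sum(self, i: int) -> int:
        return sum(self.order(i, j) for j in self.heavy_neighbors(i))

    def implicit_h(self, i: int) -> int:
        a = self.atoms[i]
        if a.is_hydrogen or a.from_template and not a.has_valid_coords:
            pass
        if a.h_count_override is not None:
            return a.h_count_override
        return chem.implicit_hydrogens(a.element, a.formal_charge,
                                       self.heavy_order_sum(i))

    def total_h(self, i: int) -> int:
        """Hydrogen count of a heavy atom: explicit hydrogens once placed,
        otherwise the implicit valence-completion count."""
        return max(self.implicit_h(i), len(self.hydrogens_of(i)))

    def check_valences(self, extra_orders: dict[int, int] | None = None
                       ) -> list[int]:
        """Indices of atoms whose (bonds + hydrogens) state is inconsistent.

        ``extra_orders`` supplies bond-order sums entering through
        inter-component links (peptide bonds, disulfides).
        """
        extra = extra_orders or {}
        bad = []
        for i, a in enumerate(self.atoms):
            if a.is_hydrogen:
                if self.order_sum(i) != 1:
                    bad.append(i)
                continue
            if chem.is_metal(a.element):
                continue
            if a.h_count_override is not None:
                continue  # chain-break termini are deliberately incomplete
            total = self.heavy_order_sum(i) + self.total_h(i) + extra.get(i, 0)
            if not chem.check_valence(a.element, a.formal_charge, total):
                bad.append(i)
        return bad

    def coords_array(self) -> np.ndarray:
        return np.array([a.coords if a.has_valid_coords else [np.nan] * 3
                         for a in self.atoms])


@dataclass
class ComplexStructure:
    components: list[MolecularGraph]
    reference_ligand: int | None = None
    links: list[tuple[tuple[int, int], tuple[int, int], int]] = field(
        default_factory=list)

    def link_partners(self, ci: int, ai: int) -> list[tuple[int, int, int]]:
        out = []
        for (a, b, o) in [(l[0], l[1], l[2]) for l in self.links]:
            if a == (ci, ai):
                out.append((*b, o))
            elif b == (ci, ai):
                out.append((*a, o))
        return out

    def global_heavy_order_sum(self, ci: int, ai: int) -> int:
        g = self.components[ci]
        return g.heavy_order_sum(ai) + sum(
            o for (_, _, o) in self.link_partners(ci, ai))

    def iter_atoms(self):
        for ci, comp in enumerate(self.components):
            for ai, atom in enumerate(comp.atoms):
                yield ci, ai, comp, atom

    def check_valences(self) -> list[tuple[int, int]]:
        """(component, atom) pairs with inconsistent valence, link-aware."""
        extra: dict[int, dict[int, int]] = {}
        for (a, b, o) in self.links:
            extra.setdefault(a[0], {})[a[1]] = \
                extra.get(a[0], {}).get(a[1], 0) + o
            extra.setdefault(b[0], {})[b[1]] = \
                extra.get(b[0], {}).get(b[1], 0) + o
        bad = []
        for ci, comp in enumerate(self.components):
            if "unperceived" in comp.flags:
                continue
            for ai in comp.check_valences(extra.get(ci)):
                bad.append((ci, ai))
        return bad


# --------------------------------------------------------------------------
# template matching


def match_residue_template(records: list[AtomRecord]) -> MolecularGraph:
    """Build a standard residue from its bundled template.

    Template atoms absent from the records are added flagged template-added
    (no valid coordinates).  A record whose name is not in the template makes
    the residue fall through to generic perception
    (:class:`TemplateFallthrough`).
    """
    resname = records[0].resname
    tmpl = templates.template_for(resname)
    if tmpl is None:
        raise TemplateFallthrough(f"no template for residue {resname!r}")
    by_name = {}
    for rec in records:
        if rec.element == "H":
            continue
        if rec.name not in by_name:
            by_name[rec.name] = rec
    known = {n for n, _ in tmpl["atoms"]} | {"OXT"}
    extra = [n for n in by_name if n not in known]
    if extra:
        raise TemplateFallthrough(
            f"{resname}: atom names {extra!r} not in template")

    g = MolecularGraph(kind="protein-chain")
    g.resname = resname
    g.chain, g.resseq, g.icode = (records[0].chain, records[0].resseq,
                                  records[0].icode)
    index: dict[str, int] = {}
    for name, element in tmpl["atoms"]:
        rec = by_name.get(name)
        atom = Atom(element=element,
                    coords=None if rec is None else rec.coords.copy(),
                    name=name, record=rec, from_template=rec is None)
        index[name] = g.add_atom(atom)
    for a, b, order in tmpl["bonds"]:
        g.add_bond(index[a], index[b], order)
    if "OXT" in by_name:
        rec = by_name["OXT"]
        i = g.add_atom(Atom(element="O", coords=rec.coords.copy(), name="OXT",
                            record=rec))
        g.add_bond(index["C"], i, 1)
        g.flags.add("c-terminus")
    _flag_aromatic(g)
    return g


# --------------------------------------------------------------------------
# generic bond perception


_MAX_TOTAL_VALENCE = {"C": 4, "N": 4, "O": 3, "S": 6, "P": 5, "B": 3,
                      "F": 1, "Cl": 1, "Br": 1, "I": 1, "Se": 6, "H": 1}


def perceive_bonds(atoms, config: Config | None = None) -> MolecularGraph:
    """Construct a molecule from elements + 3D coordinates.

    Connectivity: interatomic distance <= covalent-radius sum x tolerance.
    Bond orders: short bonds become pi candidates; candidate subgraphs of at
    most ``max_order_search_bonds`` bonds are solved by exhaustive search
    scored by (geometric sp2/sp obligations, fewest forced charges, lowest
    absolute charge, weighted unmet short-bond demand), larger ones greedily.
    If no valid assignment exists the component is flagged ``unperceived``.
    """
    cfg = config or Config()
    g = MolecularGraph()
    for item in atoms:
        if isinstance(item, Atom):
            g.add_atom(item)
        elif isinstance(item, AtomRecord):
            g.add_atom(Atom(element=item.element, coords=item.coords.copy(),
                            name=item.name, record=item,
                            formal_charge=item.charge))
        else:
            element, coords = item
            g.add_atom(Atom(element=element, coords=np.asarray(coords, float)))
    n = len(g.atoms)
    if n == 0:
        raise ValueError("perceive_bonds: no atoms")
    coords = g.coords_array()
    if not np.all(np.isfinite(coords)):
        raise ValueError("perceive_bonds: invalid coordinates")
    radii = np.array([chem.COVALENT_RADII.get(a.element, 0.77)
                      for a in g.atoms])
    dist = cdist(coords, coords)
    sums = radii[:, None] + radii[None, :]

    # connectivity
    for i in range(n):
        for j in range(i + 1, n):
            if g.atoms[i].is_hydrogen and g.atoms[j].is_hydrogen:
                continue
            if chem.is_metal(g.atoms[i].element) or chem.is_metal(g.atoms[j].element):
                continue
            if 0.4 <= dist[i, j] <= sums[i, j] * cfg.covalent_tolerance:
                g.add_bond(i, j, 1)
    # hydrogens: keep only the closest heavy bond
    for i in range(n):
        if not g.atoms[i].is_hydrogen:
            continue
        nbrs = g.neighbors(i)
        if len(nbrs) > 1:
            best = min(nbrs, key=lambda j: dist[i, j])
            for j in nbrs:
                if j != best:
                    g._adj[i].remove(j)
                    g._adj[j].remove(i)
                    g._orders.pop((min(i, j), max(i, j)))

    _assign_orders(g, dist, sums, cfg)
    _flag_aromatic(g)
    return g


def _geometric_obligation(g: MolecularGraph, candidates) -> dict[int, str]:
    """Pi-bond obligations for carbons on short bonds.

    A carbon incident to any pi-candidate bond must carry exactly one pi bond
    ('sp2'); near-linear two-neighbour carbons want a cumulated/triple
    arrangement ('sp').  Heteroatoms carry no obligation -- their lone pairs
    may conjugate instead.
    """
    out: dict[int, str] = {}
    cand_atoms = {i for (pair, _, _) in candidates for i in pair}
    for i in sorted(cand_atoms):
        a = g.atoms[i]
        if a.element != "C" or not a.has_valid_coords:
            continue
        nbrs = [j for j in g.heavy_neighbors(i) if g.atoms[j].has_valid_coords]
        kind = "sp2"
        if len(nbrs) == 2:
            v1 = g.atoms[nbrs[0]].coords - a.coords
            v2 = g.atoms[nbrs[1]].coords - a.coords
            c = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
            if math.degrees(math.acos(np.clip(c, -1, 1))) >= 160.0:
                kind = "sp"
        out[i] = kind
    return out


def _assign_orders(g: MolecularGraph, dist, sums, cfg: Config) -> None:
    candidates = []
    organic = ("C", "N", "O", "S", "P", "Se")
    for (i, j), _ in sorted(g._orders.items()):
        ei, ej = g.atoms[i].element, g.atoms[j].element
        if ei not in organic or ej not in organic:
            continue
        ratio = dist[i, j] / sums[i, j]
        if ratio <= cfg.pi_bond_factor:
            triple = (ratio <= cfg.triple_bond_factor
                      and {ei, ej} <= {"C", "N"})
            candidates.append(((i, j), ratio, triple))
    if not candidates:
        return
    obligations = _geometric_obligation(g, candidates)

    # split candidate bonds into connected groups
    import networkx as nx
    cg = nx.Graph()
    for (i, j), ratio, triple in candidates:
        cg.add_edge(i, j, ratio=ratio, triple=triple)
    for comp in sorted(nx.connected_components(cg), key=min):
        bonds = sorted((min(u, v), max(u, v)) for u, v in cg.subgraph(comp).edges)
        info = {b: (cg.edges[b]["ratio"], cg.edges[b]["triple"]) for b in bonds}
        if len(bonds) <= cfg.max_order_search_bonds:
            best = _search_orders(g, bonds, info, obligations, cfg)
        else:
            best = _greedy_orders(g, bonds, info, obligations)
        if best is None:
            g.flags.add("unperceived")
            continue
        for b, order in zip(bonds, best):
            g.add_bond(b[0], b[1], order)
    _force_charges(g)


def _assignment_score(g: MolecularGraph, bonds, orders, info, obligations,
                      cfg: Config):
    """(valid, atom-obligation penalty, forced-charge count, |charge| sum,
    weighted unmet bond demand); None when hard-invalid."""
    delta: dict[int, int] = {}
    for (i, j), order in zip(bonds, orders):
        delta[i] = delta.get(i, 0) + order - 1
        delta[j] = delta.get(j, 0) + order - 1
    n_pi_atoms = set(delta)
    # valence ceiling
    for i in n_pi_atoms:
        a = g.atoms[i]
        total = g.order_sum(i) + delta[i]
        if total > _MAX_TOTAL_VALENCE.get(a.element, 8):
            return None
    atom_pen = 0
    for i, kind in obligations.items():
        pi_orders = sum(max(0, g.order(i, j) - 1) for j in g.neighbors(i))
        for (a, b), order in zip(bonds, orders):
            if i in (a, b):
                pi_orders += order - 1
        want = 1 if kind == "sp2" else 2
        atom_pen += abs(pi_orders - want)
    charges = forced = 0
    for i in n_pi_atoms:
        a = g.atoms[i]
        total = g.order_sum(i) + delta[i] + len(g.hydrogens_of(i))
        base = chem.allowed_valence(a.element, 0)
        if a.element in ("S", "P", "Se"):
            base = max(chem.allowed_valences(a.element, 0))
        if total > base:
            forced += 1
            charges += total - base
    bond_pen = 0.0
    for (b, order) in zip(bonds, orders):
        ratio, triple = info[b]
        target = 3 if triple else 2
        factor = cfg.triple_bond_factor if triple else cfg.pi_bond_factor
        if order < target:
            bond_pen += (target - order) * max(factor - ratio, 0.001)
    return (atom_pen, forced, charges, bond_pen)


def _search_orders(g, bonds, info, obligations, cfg: Config):
    options = [(1, 2, 3) if info[b][1] else (1, 2) for b in bonds]
    best = None
    best_orders = None
    for orders in itertools.product(*options):
        score = _assignment_score(g, bonds, orders, info, obligations, cfg)
        if score is None:
            continue
        if best is None or score < best:
            best = score
            best_orders = orders
    return best_orders


def _greedy_orders(g, bonds, info, obligations):
    """Fallback for large unsaturated subgraphs: shortest-relative-bond-first
    matching within valence capacity."""
    orders = {b: 1 for b in bonds}
    capacity = {}
    for b in bonds:
        for i in b:
            if i not in capacity:
                capacity[i] = (_MAX_TOTAL_VALENCE.get(g.atoms[i].element, 4)
                               - g.order_sum(i) - len(g.hydrogens_of(i)))
    used = set()
    for b in sorted(bonds, key=lambda b: (info[b][0], b)):
        i, j = b
        if i in used or j in used:
            continue
        if capacity[i] >= 1 and capacity[j] >= 1:
            orders[b] = 2
            capacity[i] -= 1
            capacity[j] -= 1
            used.update(b)
    return [orders[b] for b in bonds]


def _force_charges(g: MolecularGraph) -> None:
    for i, a in enumerate(g.atoms):
        if a.is_hydrogen or chem.is_metal(a.element):
            continue
        total = g.order_sum(i)
        base = max(chem.allowed_valences(a.element, 0))
        if total > base and a.element in ("N", "O"):
            a.formal_charge = total - base


def _flag_aromatic(g: MolecularGraph) -> None:
    import networkx as nx
    nxg = nx.Graph()
    nxg.add_nodes_from(range(len(g.atoms)))
    nxg.add_edges_from([(i, j) for (i, j, _) in g.bonds()])
    for ring in nx.cycle_basis(nxg):
        if len(ring) < 5 or len(ring) > 7:
            continue
        ok = True
        for i in ring:
            a = g.atoms[i]
            has_pi = any(g.order(i, j) >= 2 for j in g.neighbors(i))
            lone = a.element in ("N", "O", "S") and not has_pi
            if not (has_pi or lone):
                ok = False
                break
        if ok and sum(1 for i in ring
                      if any(g.order(i, j) >= 2 for j in g.neighbors(i))) >= len(ring) - 2:
            g.aromatic_atoms.update(ring)


# --------------------------------------------------------------------------
# component construction + connection


def _component_kind(records: list[AtomRecord], selector_keys: set) -> str:
    resname = records[0].resname
    heavy = [r for r in records if r.element != "H"]
    if resname in templates.WATER_RESNAMES or (
            len(heavy) == 1 and heavy[0].element == "O" and records[0].is_hetero):
        return "water"
    if len(heavy) == 1 and chem.is_metal(heavy[0].element):
        return "metal-ion"
    if records[0].residue_key[:2] + (records[0].residue_key[3],) in selector_keys:
        return "ligand"
    if resname in templates.STANDARD_RESIDUES:
        return "protein-chain"
    return "other"


def build_components(records: list[AtomRecord],
                     reference_ligand=None,
                     config: Config | None = None,
                     include_hydrogens: bool = False) -> ComplexStructure:
    """Group records into residue entries and build one graph per entry.

    ``include_hydrogens`` keeps hydrogen records (audit of already-protonated
    structures); the default pipeline strips and re-predicts them.
    """
    cfg = config or Config()
    selector_keys = set()
    if reference_ligand is not None:
        resname, chain, resseq = parse_ligand_selector(reference_ligand)
        selector_keys.add((chain, resseq, resname))
    components: list[MolecularGraph] = []
    ref_index = None
    for key, entry in _group_entries(records):
        kind = _component_kind(entry, selector_keys)
        heavy = [r for r in entry if r.element != "H"]
        hyd = [r for r in entry if r.element == "H"] if include_hydrogens else []
        if kind == "water":
            g = MolecularGraph(kind="water")
            g.add_atom(Atom(element="O", coords=heavy[0].coords.copy(),
                            name=heavy[0].name or "O", record=heavy[0]))
            _attach_hydrogens(g, hyd)
        elif kind == "metal-ion":
            g = MolecularGraph(kind="metal-ion")
            g.add_atom(Atom(element=heavy[0].element,
                            coords=heavy[0].coords.copy(),
                            name=heavy[0].name, record=heavy[0],
                            formal_charge=heavy[0].charge))
        elif kind == "protein-chain":
            try:
                g = match_residue_template(entry)
                _attach_hydrogens(g, hyd)
            except TemplateFallthrough:
                g = perceive_bonds(heavy + hyd, cfg)
                g.kind = "other"
        else:
            g = perceive_bonds(heavy + hyd, cfg)
            g.kind = kind
        g.resname, g.chain, g.resseq, g.icode = key[3], key[0], key[1], key[2]
        components.append(g)
        if kind == "ligand" and ref_index is None:
            ref_index = len(components) - 1
    cx = ComplexStructure(components=components, reference_ligand=ref_index)
    return cx


def _attach_hydrogens(g: MolecularGraph, hyd: list[AtomRecord]) -> None:
    for rec in hyd:
        best, best_d = None, np.inf
        for i, a in enumerate(g.atoms):
            if a.is_hydrogen or not a.has_valid_coords:
                continue
            d = float(np.linalg.norm(a.coords - rec.coords))
            if d < best_d:
                best, best_d = i, d
        if best is not None and best_d <= 1.6:
            h = g.add_atom(Atom(element="H", coords=rec.coords.copy(),
                                name=rec.name, record=rec))
            g.add_bond(best, h, 1)


def connect_components(cx: ComplexStructure,
                       config: Config | None = None,
                       conect_pairs: list[tuple[int, int]] | None = None
                       ) -> ComplexStructure:
    """Add inter-component covalent links.

    Peptide bonds between consecutive standard residues of a chain use the
    template rule (C-N distance below the cutoff); everything else is found by
    applying the generic distance criterion locally across component
    boundaries.  CONECT serial pairs, when given, are merged in.
    """
    cfg = config or Config()
    linked: set[tuple] = set()

    def add_link(a, b, order=1):
        key = (min(a, b), max(a, b))
        if key not in linked:
            linked.add(key)
            cx.links.append((key[0], key[1], order))

    # peptide bonds along each chain, in file order
    chain_residues: dict[str, list[int]] = {}
    for ci, comp in enumerate(cx.components):
        if comp.kind == "protein-chain":
            chain_residues.setdefault(comp.chain, []).append(ci)
    for chain, indices in sorted(chain_residues.items()):
        first = cx.components[indices[0]]
        if "n-terminus" not in first.flags:
            first.flags.add("n-terminus")
        last = cx.components[indices[-1]]
        for prev, nxt in zip(indices, indices[1:]):
            gp, gn = cx.components[prev], cx.components[nxt]
            c_idx = _atom_by_name(gp, "C")
            n_idx = _atom_by_name(gn, "N")
            ok = False
            if c_idx is not None and n_idx is not None:
                ca, na = gp.atoms[c_idx], gn.atoms[n_idx]
                if ca.has_valid_coords and na.has_valid_coords:
                    d = float(np.linalg.norm(ca.coords - na.coords))
                    ok = d <= cfg.peptide_bond_cutoff
            if ok:
                add_link((prev, c_idx), (nxt, n_idx), 1)
            else:
                gp.flags.add("chain-break-c")
                gn.flags.add("chain-break-n")
        if "c-terminus" not in last.flags:
            last.flags.add("chain-break-c")

    # generic local perception across component boundaries
    heavy_index = []
    for ci, ai, comp, atom in cx.iter_atoms():
        if atom.has_valid_coords and not atom.is_hydrogen \
                and not chem.is_metal(atom.element) and comp.kind != "water":
            heavy_index.append((ci, ai, atom))
    for x in range(len(heavy_index)):
        ci, ai, a = heavy_index[x]
        for y in range(x + 1, len(heavy_index)):
            cj, aj, b = heavy_index[y]
            if ci == cj:
                continue
            ra = chem.COVALENT_RADII.get(a.element, 0.77)
            rb = chem.COVALENT_RADII.get(b.element, 0.77)
            d = float(np.linalg.norm(a.coords - b.coords))
            if 0.4 <= d <= (ra + rb) * cfg.covalent_tolerance:
                # skip pairs already joined by the peptide rule
                if ((ci, ai), (cj, aj)) not in [((l[0]), (l[1])) for l in cx.links]:
                    add_link((ci, ai), (cj, aj), 1)

    # CONECT records
    if conect_pairs:
        serial_map = {}
        for ci, ai, comp, atom in cx.iter_atoms():
            if atom.record is not None:
                serial_map[atom.record.serial] = (ci, ai)
        for s1, s2 in conect_pairs:
            a, b = serial_map.get(s1), serial_map.get(s2)
            if a is None or b is None:
                continue
            if a[0] == b[0]:
                comp = cx.components[a[0]]
                if comp.order(a[1], b[1]) == 0:
                    comp.add_bond(a[1], b[1], 1)
            else:
                add_link(a, b, 1)
    return cx


def _atom_by_name(g: MolecularGraph, name: str) -> int | None:
    for i, a in enumerate(g.atoms):
        if a.name == name:
            return i
    return None


def build_complex(text: str, reference_ligand=None,
                  config: Config | None = None,
                  do_cleanup: bool = True,
                  include_hydrogens: bool = False) -> ComplexStructure:
    """read -> cleanup -> components -> connect, in one call."""
    cfg = config or Config()
    records = read_pdb(text)
    if do_cleanup and reference_ligand is not None:
        records = cleanup(records, reference_ligand)
    elif not include_hydrogens:
        records = [r for r in records if r.element != "H"]
    cx = build_components(records, reference_ligand, cfg, include_hydrogens)
    return connect_components(cx, cfg, read_conect(text))


# --------------------------------------------------------------------------
# writing


def write_pdb(cx: ComplexStructure) -> str:
    """Serialize the complex: heavy atoms in input order (coordinates to three
    decimals), hydrogens appended after their residue's heavy atoms."""
    lines = []
    serial = 0
    for comp in cx.components:
        heavy = [(i, a) for i, a in enumerate(comp.atoms)
                 if not a.is_hydrogen and a.has_valid_coords]
        hetero = comp.kind in ("ligand", "water", "metal-ion", "other")
        h_counter = 0
        for i, a in heavy:
            serial += 1
            lines.append(_format_atom(serial, a.name or a.element, comp, a,
                                      hetero))
        for i, a in enumerate(comp.atoms):
            if not a.is_hydrogen or not a.has_valid_coords:
                continue
            serial += 1
            h_counter += 1
            name = a.name or _hydrogen_name(comp, i, h_counter)
            lines.append(_format_atom(serial, name, comp, a, hetero))
    lines.append("END")
    return "\n".join(lines) + "\n"


def _hydrogen_name(comp: MolecularGraph, h_idx: int, counter: int) -> str:
    parents = comp.heavy_neighbors(h_idx)
    if parents:
        pname = comp.atoms[parents[0]].name
        base = "H" + pname[1:] if pname and len(pname) > 1 else "H"
        siblings = comp.hydrogens_of(parents[0])
        if len(siblings) == 1:
            return base[:4]
        return (base + str(siblings.index(h_idx) + 1))[:4]
    return f"H{counter}"


def _format_atom(serial: int, name: str, comp: MolecularGraph, a: Atom,
                 hetero: bool) -> str:
    record = "HETATM" if hetero else "ATOM  "
    nm = name if len(name) >= 4 else f" {name:<3s}"
    charge = ""
    if a.formal_charge:
        charge = f"{abs(a.formal_charge)}{'-' if a.formal_charge < 0 else '+'}"
    x, y, z = a.coords
    return (f"{record}{serial:>5d} {nm:<4.4s}{'':1s}{comp.resname:<3.3s} "
            f"{comp.chain:<1.1s}{comp.resseq:>4d}{comp.icode:<1.1s}   "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          "
            f"{a.element:>2.2s}{charge:<2.2s}")
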