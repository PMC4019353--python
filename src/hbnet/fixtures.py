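"""Deterministic synthetic complexes and random optimizer instances.

Every scenario is emitted as valid PDB text computed at call time from the
stated geometric parameters, so distances and angles are single-sourced and
reproducible byte-for-byte.  The catalog covers the code paths of the whole
pipeline: water bridges, forced tautomer/rotor/flip choices, protonation
transfer, donor-donor repulsion, chain breaks and cleanup exercises.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import Config
from .geometry import (TET_ANGLE, any_perpendicular, complete_directions,
                       cone_direction, rotate_about, unit)
from .network_opt import NetworkGraph
from .vmr_enum import VMR, Mode

Z = np.array([0.0, 0.0, 1.0])


@dataclass
class FixtureSpec:
    scenario: str
    params: dict = field(default_factory=dict)
    seed: int = 0


#: reference-ligand selector per scenario (None: no cleanup/audit ligand)
LIGANDS: dict[str, str | None] = {
    "water_bridge": None,
    "imidazole_carboxylate": "IMZ:L:1",
    "serine_rotor": None,
    "amine_transfer": "PIP:L:1",
    "donor_face": "PYR:L:1",
    "asn_flip": None,
    "histidine": None,
    "chain_break": None,
    "cleanup": "ACT:L:1",
}


def make_fixture(spec: FixtureSpec) -> str:
    """PDB text for a catalog scenario; unknown names raise with the catalog."""
    fn = _CATALOG.get(spec.scenario)
    if fn is None:
        raise ValueError(
            f"unknown scenario {spec.scenario!r}; catalog: "
            + ", ".join(sorted(_CATALOG)))
    return fn(**spec.params)


# --------------------------------------------------------------------------
# PDB emission


def pdb_text(rows, extra_lines=()) -> str:
    """rows: (name, resname, chain, resseq, element, xyz[, altloc])"""
    lines = []
    for serial, row in enumerate(rows, start=1):
        name, resname, chain, resseq, element, xyz = row[:6]
        altloc = row[6] if len(row) > 6 else ""
        hetero = resname not in ("ALA", "GLY", "SER", "ASP", "ASN", "HIS")
        record = "HETATM" if hetero else "ATOM  "
        nm = name if len(name) >= 4 else f" {name:<3s}"
        x, y, z = xyz
        lines.append(
            f"{record}{serial:>5d} {nm:<4.4s}{altloc:<1.1s}{resname:<3.3s} "
            f"{chain:<1.1s}{resseq:>4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          "
            f"{element:>2.2s}")
    lines.extend(extra_lines)
    lines.append("END")
    return "\n".join(lines) + "\n"


# --------------------------------------------------------------------------
# building blocks


def _formamide(n_pos, h_dir, normal, resname="FMD", chain="B", resseq=1):
    """Heavy atoms of a formamide whose amide nitrogen sits at n_pos with one
    N-H direction along h_dir (plane normal given)."""
    u = unit(np.asarray(h_dir, float))
    v = -rotate_about(u, normal, 60.0)          # N -> C direction
    c = np.asarray(n_pos) + 1.33 * v
    o = c + 1.23 * rotate_about(-v, normal, 120.0)
    return [("C", resname, chain, resseq, "C", c),
            ("O", resname, chain, resseq, "O", o),
            ("N", resname, chain, resseq, "N", np.asarray(n_pos, float))]


def _acetone(o_pos, toward, normal=None, resname="ACN", chain="D", resseq=1):
    """Heavy atoms of an acetone acceptor: carbonyl O at o_pos with one
    in-plane lone-pair lobe aimed exactly along 'toward'."""
    t = unit(np.asarray(toward, float))
    n = unit(normal) if normal is not None else any_perpendicular(t)
    c1 = np.asarray(o_pos) + 1.21 * rotate_about(t, n, 120.0)
    u_o = unit(np.asarray(o_pos) - c1)
    c2 = c1 + 1.50 * rotate_about(u_o, n, 120.0)
    c3 = c1 + 1.50 * rotate_about(u_o, n, 240.0)
    return [("C1", resname, chain, resseq, "C", c1),
            ("O1", resname, chain, resseq, "O", np.asarray(o_pos, float)),
            ("C2", resname, chain, resseq, "C", c2),
            ("C3", resname, chain, resseq, "C", c3)]


# planar 4-methylimidazole ring with crystallographic bond lengths; the
# C5-N1 bond absorbs the ring-closure residual (1.379 A)
_IMIDAZOLE_RING = {
    "N1": (-0.7012, -0.9207),
    "C2": (0.6478, -0.9207),
    "N3": (1.1359, 0.3122),
    "C4": (0.0290, 1.1331),
    "C5": (-1.1115, 0.3960),
}


def _imidazole(chain="L", resseq=1, resname="IMZ"):
    rows = []
    pts = {k: np.array([x, y, 0.0]) for k, (x, y) in _IMIDAZOLE_RING.items()}
    # methyl on C4, exterior bisector
    ext = -unit(unit(pts["N3"] - pts["C4"]) + unit(pts["C5"] - pts["C4"]))
    pts["C6"] = pts["C4"] + 1.49 * ext
    for name in ("N1", "C2", "N3", "C4", "C5", "C6"):
        rows.append((name, resname, chain, resseq, name[0], pts[name]))
    return rows, pts


def _build_asx(od1_pos, lp_toward, resname="ASP", chain="A", resseq=10,
               swap_nd=False):
    """An ASP (or ASN when swap_nd) residue grown so that its OD1 sits at
    od1_pos with a carbonyl lone pair facing lp_toward."""
    d0 = unit(np.asarray(lp_toward, float))
    n = any_perpendicular(d0)
    od1 = np.asarray(od1_pos, float)
    cg = od1 + (1.23 if swap_nd else 1.25) * rotate_about(d0, n, 120.0)
    u1 = unit(od1 - cg)
    other = cg + (1.33 if swap_nd else 1.25) * rotate_about(u1, n, 120.0)
    cb = cg + 1.52 * rotate_about(u1, n, 240.0)
    ca = cb + 1.53 * rotate_about(unit(cg - cb), n, 111.0)
    dir_cb = unit(cb - ca)
    p = any_perpendicular(dir_cb)
    nb = ca + 1.46 * cone_direction(dir_cb, p, TET_ANGLE, 0.0)
    c = ca + 1.52 * cone_direction(dir_cb, p, TET_ANGLE, 120.0)
    o = c + 1.23 * rotate_about(unit(ca - c),
                                any_perpendicular(unit(ca - c)), 120.0)
    other_name = "ND2" if swap_nd else "OD2"
    other_el = "N" if swap_nd else "O"
    return [("N", resname, chain, resseq, "N", nb),
            ("CA", resname, chain, resseq, "C", ca),
            ("C", resname, chain, resseq, "C", c),
            ("O", resname, chain, resseq, "O", o),
            ("CB", resname, chain, resseq, "C", cb),
            ("CG", resname, chain, resseq, "C", cg),
            ("OD1", resname, chain, resseq, "O", od1),
            (other_name, resname, chain, resseq, other_el, other)]


def _planar_ring(n_atoms: int, bond: float, hetero_at: int = 0):
    """Regular planar ring coordinates, one vertex per atom, z = 0."""
    r = bond / (2.0 * np.sin(np.pi / n_atoms))
    pts = []
    for k in range(n_atoms):
        th = np.pi / 2 + 2 * np.pi * k / n_atoms
        pts.append(np.array([r * np.cos(th), r * np.sin(th), 0.0]))
    return pts


def _ring_n_completions(pts, idx):
    """The two tetrahedral completion directions at a ring nitrogen."""
    prev_p = pts[(idx - 1) % len(pts)]
    next_p = pts[(idx + 1) % len(pts)]
    dirs = [unit(prev_p - pts[idx]), unit(next_p - pts[idx])]
    return complete_directions(dirs, 2, TET_ANGLE)


# --------------------------------------------------------------------------
# scenarios


def _water_bridge(n: int = 2):
    u = np.array([1.0, 0.0, 0.0])
    rows = _formamide(np.zeros(3), u, Z)
    # zigzag wire: consecutive segments meet at ~108 degrees, as water
    # coordination geometry requires
    pos = 2.9 * u
    d = u
    for k in range(n):
        rows.append(("O", "HOH", "W", k + 1, "O", pos))
        d = rotate_about(d, Z, 72.0 if k % 2 == 0 else -72.0)
        pos = pos + 2.85 * d
    rows.extend(_acetone(pos, -d, normal=Z))
    return pdb_text(rows)


def _imidazole_carboxylate():
    rows, pts = _imidazole()
    # exterior bisectors at the two ring nitrogens
    u1 = -unit(unit(pts["C2"] - pts["N1"]) + unit(pts["C5"] - pts["N1"]))
    w = -unit(unit(pts["C2"] - pts["N3"]) + unit(pts["C4"] - pts["N3"]))
    # fixed amide donor facing N1 (default N-H tautomer side)
    rows.extend(_formamide(pts["N1"] + 2.9 * u1, -u1, Z))
    # formate with one carboxylate oxygen lone pair aimed at N3
    o1 = pts["N3"] + 2.7 * w
    c1 = o1 + 1.25 * rotate_about(w, Z, 120.0)
    u_o1 = unit(o1 - c1)
    o2 = c1 + 1.25 * rotate_about(u_o1, Z, 120.0)
    rows.extend([("C1", "FMT", "C", 1, "C", c1),
                 ("O1", "FMT", "C", 1, "O", o1),
                 ("O2", "FMT", "C", 1, "O", o2)])
    return pdb_text(rows)


def _serine_rotor(angle_sep: float = 120.0, d_near: float = 2.75,
                  d_far: float = 3.25):
    n = np.zeros(3)
    ca = np.array([1.46, 0.0, 0.0])
    t = np.radians(180.0 - TET_ANGLE)
    c = ca + 1.52 * np.array([np.cos(t), -np.sin(t), 0.0])
    o = c + 1.23 * rotate_about(unit(ca - c), Z, 120.0)
    cb_dirs = complete_directions([unit(n - ca), unit(c - ca)], 2, TET_ANGLE)
    cb = ca + 1.53 * cb_dirs[0]
    og_dir = cone_direction(unit(cb - ca), any_perpendicular(unit(cb - ca)),
                            180.0 - TET_ANGLE, 0.0)
    og = cb + 1.41 * og_dir
    rows = [("N", "SER", "A", 1, "N", n),
            ("CA", "SER", "A", 1, "C", ca),
            ("C", "SER", "A", 1, "C", c),
            ("O", "SER", "A", 1, "O", o),
            ("CB", "SER", "A", 1, "C", cb),
            ("OG", "SER", "A", 1, "O", og)]
    # acceptors on the hydroxyl rotor orbit, separated by angle_sep
    axis = unit(og - cb)
    ref = unit(ca - cb)
    half = 180.0 - TET_ANGLE
    d_a = cone_direction(axis, ref, half, 240.0)
    d_b = cone_direction(axis, ref, half, 240.0 + angle_sep)
    rows.extend(_acetone(og + d_near * d_a, -d_a, chain="D", resseq=1))
    rows.extend(_acetone(og + d_far * d_b, -d_b, chain="E", resseq=1))
    return pdb_text(rows)


def _amine_transfer():
    pts = _planar_ring(6, 1.50)
    names = ["N1", "C2", "C3", "C4", "C5", "C6"]
    rows = [(nm, "PIP", "L", 1, nm[0], p) for nm, p in zip(names, pts)]
    c0, c1 = _ring_n_completions(pts, 0)
    rows.extend(_build_asx(pts[0] + 2.8 * c0, -c0, chain="A", resseq=10))
    rows.extend(_formamide(pts[0] + 2.9 * c1, -c1, any_perpendicular(c1),
                           chain="B", resseq=1))
    return pdb_text(rows)


def _donor_face():
    pts = _planar_ring(5, 1.50)
    names = ["N1", "C2", "C3", "C4", "C5"]
    rows = [(nm, "PYR", "L", 1, nm[0], p) for nm, p in zip(names, pts)]
    c0, _ = _ring_n_completions(pts, 0)
    rows.extend(_formamide(pts[0] + 2.9 * c0, -c0, any_perpendicular(c0),
                           chain="B", resseq=1))
    return pdb_text(rows)


def _asn_flip():
    asn = _build_asx(np.zeros(3), np.array([1.0, 0.0, 0.0]), resname="ASN",
                     chain="A", resseq=5, swap_nd=True)
    pts = {r[0]: np.asarray(r[5]) for r in asn}
    cg, od1, nd2 = pts["CG"], pts["OD1"], pts["ND2"]
    normal = unit(np.cross(od1 - cg, nd2 - cg))
    # fixed donor aimed along one N-H direction of the (unflipped) amide
    axis = unit(nd2 - cg)
    h_dir = rotate_about(axis, normal, 60.0)
    rows = list(asn)
    rows.extend(_formamide(nd2 + 2.9 * h_dir, -h_dir, normal,
                           chain="B", resseq=1))
    # fixed acceptor aimed along one N-H direction of the *flipped* amide
    axis_f = unit(od1 - cg)
    hf_dir = rotate_about(axis_f, normal, 60.0)
    rows.extend(_acetone(od1 + 2.85 * hf_dir, -hf_dir, chain="D", resseq=1))
    return pdb_text(rows)


def _histidine():
    """A histidine residue (template path) beside an acceptor: exercises the
    imidazole tautomer x side-chain-flip mode product."""
    ring_map = {"ND1": "N1", "CE1": "C2", "NE2": "N3", "CD2": "C4",
                "CG": "C5"}
    pts = {his: np.array([*_IMIDAZOLE_RING[imz], 0.0])
           for his, imz in ring_map.items()}
    ext_cg = -unit(unit(pts["ND1"] - pts["CG"]) + unit(pts["CD2"] - pts["CG"]))
    pts["CB"] = pts["CG"] + 1.49 * ext_cg
    ca = pts["CB"] + 1.53 * cone_direction(ext_cg, Z, TET_ANGLE, 0.0)
    dir_cb = unit(pts["CB"] - ca)
    p = any_perpendicular(dir_cb)
    nb = ca + 1.46 * cone_direction(dir_cb, p, TET_ANGLE, 0.0)
    c = ca + 1.52 * cone_direction(dir_cb, p, TET_ANGLE, 120.0)
    o = c + 1.23 * rotate_about(unit(ca - c), any_perpendicular(unit(ca - c)),
                                120.0)
    rows = [("N", "HIS", "A", 1, "N", nb), ("CA", "HIS", "A", 1, "C", ca),
            ("C", "HIS", "A", 1, "C", c), ("O", "HIS", "A", 1, "O", o),
            ("CB", "HIS", "A", 1, "C", pts["CB"])]
    for name in ("CG", "ND1", "CD2", "CE1", "NE2"):
        rows.append((name, "HIS", "A", 1, name[0], pts[name]))
    ext_nd1 = -unit(unit(pts["CG"] - pts["ND1"]) + unit(pts["CE1"] - pts["ND1"]))
    rows.extend(_acetone(pts["ND1"] + 2.85 * ext_nd1, -ext_nd1, normal=Z))
    return pdb_text(rows)


def _chain_break(gap: float = 5.0):
    n1 = np.zeros(3)
    ca1 = np.array([1.46, 0.0, 0.0])
    t = np.radians(180.0 - TET_ANGLE)
    c1 = ca1 + 1.52 * np.array([np.cos(t), -np.sin(t), 0.0])
    o1 = c1 + 1.23 * rotate_about(unit(ca1 - c1), Z, 120.0)
    cb_dirs = complete_directions([unit(n1 - ca1), unit(c1 - ca1)], 2,
                                  TET_ANGLE)
    cb1 = ca1 + 1.53 * cb_dirs[0]
    shift = np.array([gap, 0.0, 0.0])
    n2 = c1 + shift
    ca2 = n2 + np.array([1.46, 0.0, 0.0])
    c2 = ca2 + 1.52 * np.array([np.cos(t), -np.sin(t), 0.0])
    o2 = c2 + 1.23 * rotate_about(unit(ca2 - c2), Z, 120.0)
    rows = [("N", "ALA", "A", 1, "N", n1),
            ("CA", "ALA", "A", 1, "C", ca1),
            ("C", "ALA", "A", 1, "C", c1),
            ("O", "ALA", "A", 1, "O", o1),
            ("CB", "ALA", "A", 1, "C", cb1),
            ("N", "GLY", "A", 2, "N", n2),
            ("CA", "GLY", "A", 2, "C", ca2),
            ("C", "GLY", "A", 2, "C", c2),
            ("O", "GLY", "A", 2, "O", o2)]
    return pdb_text(rows)


def _cleanup(wrong_element: bool = False):
    # reference ligand: acetate at the origin
    c1 = np.zeros(3)
    o1 = c1 + 1.25 * np.array([np.cos(np.radians(120)),
                               np.sin(np.radians(120)), 0.0])
    o2 = c1 + 1.25 * np.array([np.cos(np.radians(240)),
                               np.sin(np.radians(240)), 0.0])
    c2 = c1 + np.array([1.50, 0.0, 0.0])
    lig = [("C1", "ACT", "L", 1, "C", c1), ("O1", "ACT", "L", 1, "O", o1),
           ("O2", "ACT", "L", 1, "O", o2), ("C2", "ACT", "L", 1, "C", c2)]
    shift = np.array([0.3, 0.0, 0.0])
    dup_el = "N" if wrong_element else "O"
    dup = [("C1", "ACT", "L", 9, "C", c1 + shift),
           ("O1", "ACT", "L", 9, dup_el, o1 + shift),
           ("O2", "ACT", "L", 9, "O", o2 + shift),
           ("C2", "ACT", "L", 9, "C", c2 + shift)]
    # serine 8 A away with A/B altlocs on every atom, plus a stray hydrogen
    base = np.array([8.0, 0.0, 0.0])
    ser_rows = []
    ser = [("N", "N", np.zeros(3)), ("CA", "C", np.array([1.46, 0, 0])),
           ("C", "C", np.array([1.97, -1.43, 0])),
           ("O", "O", np.array([3.17, -1.67, 0])),
           ("CB", "C", np.array([2.0, 0.72, 1.2])),
           ("OG", "O", np.array([1.7, 2.1, 1.2]))]
    for name, el, p in ser:
        ser_rows.append((name, "SER", "A", 3, el, base + p, "A"))
        ser_rows.append((name, "SER", "A", 3, el, base + p + 0.5, "B"))
    ser_rows.append(("HG", "SER", "A", 3, "H",
                     base + np.array([1.7, 2.1, 2.1]), "A"))
    return pdb_text(lig + dup + ser_rows)


_CATALOG = {
    "water_bridge": _water_bridge,
    "imidazole_carboxylate": _imidazole_carboxylate,
    "serine_rotor": _serine_rotor,
    "amine_transfer": _amine_transfer,
    "donor_face": _donor_face,
    "asn_flip": _asn_flip,
    "histidine": _histidine,
    "chain_break": _chain_break,
    "cleanup": _cleanup,
}


# --------------------------------------------------------------------------
# random optimizer instances


def random_network(n_nodes: int, max_modes: int, density: float,
                   seed: int) -> NetworkGraph:
    """Reproducible random instance for the oracle-equivalence suite.

    Base scores and edge entries are dyadic rationals (k/16), so totals are
    exact in double precision regardless of summation order; edges with
    all-zero matrices are dropped (an edge exists only when some mode pair
    interacts).  The mode-count product is kept within the brute-force cap.
    """
    rng = np.random.default_rng(seed)
    counts = [int(rng.integers(1, max_modes + 1)) for _ in range(n_nodes)]
    while np.prod(counts) > 200_000:
        counts[int(np.argmax(counts))] -= 1
    nodes = [VMR(component=-1, atoms=[], kind="random",
                 modes=[Mode({}, {}, {}) for _ in range(k)])
             for k in counts]
    base = [rng.integers(-64, 65, size=k).astype(float) / 16.0
            for k in counts]
    net = NetworkGraph(nodes=nodes, base=base)
    for i in range(n_nodes):
        for j in range(i + 1, n_nodes):
            if rng.random() >= density:
                continue
            m = rng.integers(-48, 49, size=(counts[i], counts[j])).astype(float)
            m[rng.random((counts[i], counts[j])) < 0.5] = 0.0
            m /= 16.0
            if np.any(m != 0.0):
                net.edges[(i, j)] = m
    return net
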