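"""Canonical line notation for substructures (dedup + stability lookup keys).

RDKit generates unique SMILES that are charge- and H-count-aware; when a
state cannot be sanitized (exotic valence during enumeration) a deterministic
formula-based fallback key is used instead.
"""

from __future__ import annotations

from rdkit import Chem, RDLogger

RDLogger.DisableLog("rdApp.*")

_BOND_TYPES = {1: Chem.BondType.SINGLE, 2: Chem.BondType.DOUBLE,
               3: Chem.BondType.TRIPLE}


def substructure_smiles(graph, atom_indices,
                        h_counts: dict[int, int] | None = None,
                        charges: dict[int, int] | None = None,
                        bond_orders: dict[tuple[int, int], int] | None = None,
                        ) -> str:
    """Unique SMILES of a heavy-atom substructure of a MolecularGraph.

    h_counts/charges/bond_orders override the graph state (mode candidates
    are canonicalized without mutating the graph).  Bonds leaving the
    substructure are dropped; their order is charged to the neighbour within.
    """
    h_counts = h_counts or {}
    charges = charges or {}
    bond_orders = bond_orders or {}
    idx = sorted(i for i in atom_indices if not graph.atoms[i].is_hydrogen)
    mapping = {g: m for m, g in enumerate(idx)}
    mol = Chem.RWMol()
    for g in idx:
        a = graph.atoms[g]
        ra = Chem.Atom(a.element)
        ra.SetFormalCharge(int(charges.get(g, a.formal_charge)))
        n_h = h_counts.get(g)
        if n_h is None:
            n_h = graph.total_h(g)
        ra.SetNumExplicitHs(int(n_h))
        ra.SetNoImplicit(True)
        mol.AddAtom(ra)
    for g in idx:
        for j in graph.heavy_neighbors(g):
            if j in mapping and j > g:
                order = bond_orders.get((g, j), bond_orders.get((j, g),
                                        graph.order(g, j)))
                mol.AddBond(mapping[g], mapping[j], _BOND_TYPES.get(order,
                            Chem.BondType.SINGLE))
    try:
        m = mol.GetMol()
        Chem.SanitizeMol(m)
        return Chem.MolToSmiles(m)
    except Exception:
        parts = []
        for g in idx:
            a = graph.atoms[g]
            n_h = h_counts.get(g)
            if n_h is None:
                n_h = graph.total_h(g)
            parts.append(f"{a.element}{n_h}{charges.get(g, a.formal_charge):+d}")
        return "!" + ".".join(sorted(parts))


def mol_from_graph(graph, atom_indices=None):
    """RWMol (sanitized when possible) for a whole component graph."""
    idx = atom_indices if atom_indices is not None else [
        i for i, a in enumerate(graph.atoms) if not a.is_hydrogen]
    return substructure_smiles(graph, idx)
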