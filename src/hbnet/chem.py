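"""Element data and valence bookkeeping.

Covalent radii, allowed valences per (element, formal charge), implicit
hydrogen counts and a valence checker shared by bond perception, state
normalization and mode enumeration.
"""

from __future__ import annotations

# Covalent radii in Angstrom (Cordero-style single-bond values).
COVALENT_RADII: dict[str, float] = {
    "H": 0.31, "B": 0.84, "C": 0.76, "N": 0.71, "O": 0.66, "F": 0.57,
    "P": 1.07, "S": 1.05, "Cl": 1.02, "Se": 1.20, "Br": 1.20, "I": 1.39,
    "Na": 1.66, "K": 2.03, "Mg": 1.41, "Ca": 1.76, "Zn": 1.22, "Mn": 1.39,
    "Fe": 1.32, "Co": 1.26, "Ni": 1.24, "Cu": 1.32, "Cd": 1.44,
}

#: Default metal-ion element set; single-atom rigid components.
METAL_ELEMENTS = frozenset(
    {"Na", "K", "Mg", "Ca", "Zn", "Mn", "Fe", "Co", "Ni", "Cu", "Cd"}
)

# Neutral reference valence for organic elements.
_BASE_VALENCE: dict[str, int] = {
    "H": 1, "B": 3, "C": 4, "N": 3, "O": 2, "F": 1,
    "P": 3, "S": 2, "Cl": 1, "Se": 2, "Br": 1, "I": 1,
}

# Hypervalent states tolerated by the checker (sulfate, phosphate, ...).
_EXTRA_VALENCES: dict[str, tuple[int, ...]] = {
    "S": (2, 4, 6),
    "P": (3, 5),
    "Se": (2, 4, 6),
}

PERIODIC_TABLE = frozenset(COVALENT_RADII) | frozenset(_BASE_VALENCE)


def is_metal(element: str) -> bool:
    return element in METAL_ELEMENTS


def allowed_valence(element: str, charge: int = 0) -> int:
    """Target total bond order (including hydrogens) for a neutral-or-charged
    main-group atom.  For N/O-like elements a positive charge adds a bond and
    a negative charge removes one; for C a charge removes a bond either way
    (carbanion/carbocation are both trivalent)."""
    base = _BASE_VALENCE.get(element)
    if base is None:
        return 0
    if element == "C":
        return base - abs(charge)
    if element in ("N", "O", "S", "P", "Se") or base in (1, 3):
        return base + charge
    return base


def allowed_valences(element: str, charge: int = 0) -> tuple[int, ...]:
    """All valences the checker accepts for (element, charge)."""
    extra = _EXTRA_VALENCES.get(element)
    if extra is not None and charge == 0:
        return extra
    return (allowed_valence(element, charge),)


def implicit_hydrogens(element: str, charge: int, heavy_order_sum: float) -> int:
    """Number of hydrogens needed to complete the valence shell.

    Hypervalent S/P centres with more explicit bonds than the divalent default
    carry no hydrogens.
    """
    if element in _EXTRA_VALENCES and charge == 0:
        options = [v for v in _EXTRA_VALENCES[element] if v >= heavy_order_sum]
        target = min(options) if options else heavy_order_sum
    else:
        target = allowed_valence(element, charge)
    return max(0, int(round(target - heavy_order_sum)))


def lone_pairs(element: str, charge: int, total_order_sum: float) -> int:
    """Free electron pairs on a main-group atom (acceptor capacity)."""
    group_electrons = {"N": 5, "O": 6, "S": 6, "Se": 6, "P": 5, "F": 7,
                       "Cl": 7, "Br": 7, "I": 7}.get(element)
    if group_electrons is None:
        return 0
    nonbonding = group_electrons - charge - int(round(total_order_sum))
    return max(0, nonbonding // 2)


def check_valence(element: str, charge: int, total_order_sum: float) -> bool:
    """True if the total bond-order sum is an allowed valence state."""
    if is_metal(element):
        return total_order_sum == 0
    if element not in _BASE_VALENCE:
        return True  # element outside the organic table: do not flag
    return int(round(total_order_sum)) in allowed_valences(element, charge)
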