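"""Runtime parameters: geometry, scoring weights, cutoffs.

All tunables live in one flat dataclass, loadable from a plain ``key = value``
file so that every threshold mentioned in the documentation can be changed
without touching code.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path


@dataclass
class Config:
    # --- structure construction ---
    covalent_tolerance: float = 1.15     # bond if d <= (r_i+r_j) * tol
    pi_bond_factor: float = 0.92         # double-bond candidate if d <= sum*factor
    triple_bond_factor: float = 0.82     # triple-bond candidate
    peptide_bond_cutoff: float = 1.8     # Angstrom, C-N
    clash_floor: float = 1.0             # overlap definition for cleanup
    max_order_search_bonds: int = 16     # exhaustive order search bound
    metal_elements: tuple[str, ...] = (
        "Na", "K", "Mg", "Ca", "Zn", "Mn", "Fe", "Co", "Ni", "Cu", "Cd")

    # --- hydrogen geometry (X-H bond lengths, Angstrom) ---
    xh_bond_lengths: dict = field(default_factory=lambda: {
        "C": 1.09, "N": 1.01, "O": 0.96, "S": 1.34, "Se": 1.46, "P": 1.42})
    water_angle: float = 104.5           # experimental H-O-H angle

    # --- mode enumeration ---
    rotor_steps: int = 12                # torsion discretization of terminal rotors
    ring_charge_min: int = -2            # net-charge window for conjugated systems
    ring_charge_max: int = 2
    allow_ring_anions: bool = False      # deprotonated azole-type ring nitrogens
    max_modes: int = 64                  # per-VMR cap, best-by-stability kept
    water_partner_radius: float = 3.6    # search radius for water orientation targets

    # --- interaction model ---
    hbond_ideal: float = 1.9             # H...acceptor, Angstrom
    hbond_cutoff: float = 2.6
    angle_cutoff: float = 70.0           # degrees of axis deviation
    metal_ideal: float = 2.1             # metal...acceptor
    metal_cutoff: float = 3.0
    repulsion_full: float = 1.2          # H...H closer than this: full penalty
    repulsion_cutoff: float = 1.8        # zero beyond; normal hydrogen-bond
                                         # chains put opposing H atoms ~1.9 A apart
    lone_pair_length: float = 0.5        # probe distance along acceptor axes;
                                         # acceptor-acceptor repulsion then needs
                                         # anchors within ~2.8 A pointing at each other
    w_hbond: float = 1.0
    w_metal: float = 1.2
    w_repulsion: float = 2.0
    w_stability: float = 0.1             # per integer stability unit

    # --- network optimization ---
    search_radius: float = 5.0           # heavy-atom edge formation distance
    core_max_nodes: int = 12             # exhaustive residual-core caps
    core_max_combinations: int = 1_000_000
    beam_width: int = 64                 # deterministic fallback

    def copy(self, **overrides) -> "Config":
        return dataclasses.replace(self, **overrides)


def load_config(path: str | Path, base: Config | None = None) -> Config:
    """Read ``key = value`` lines; '#' starts a comment.  Unknown keys error."""
    cfg = base or Config()
    values = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected 'key = value'")
        key, _, val = line.partition("=")
        key, val = key.strip(), val.strip()
        if not hasattr(cfg, key):
            raise ValueError(f"{path}:{lineno}: unknown parameter {key!r}")
        current = getattr(cfg, key)
        values[key] = _coerce(val, current, f"{path}:{lineno}")
    return cfg.copy(**values)


def _coerce(val: str, current, where: str):
    if isinstance(current, bool):
        if val.lower() in ("1", "true", "yes", "on"):
            return True
        if val.lower() in ("0", "false", "no", "off"):
            return False
        raise ValueError(f"{where}: expected boolean, got {val!r}")
    if isinstance(current, int):
        return int(val)
    if isinstance(current, float):
        return float(val)
    if isinstance(current, tuple):
        return tuple(v.strip() for v in val.split(",") if v.strip())
    if isinstance(current, dict):
        out = dict(current)
        for item in val.split(","):
            k, _, v = item.partition(":")
            out[k.strip()] = float(v)
        return out
    return val
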