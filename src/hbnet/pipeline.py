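"""End-to-end hydrogen prediction and audit drivers.

``protonate`` runs the whole chain: parse + cleanup, component construction,
state normalization, initial placement, region partitioning, mode
enumeration, network optimization, and back-transfer; ``audit`` loads an
already-protonated structure and reports undesirable contacts and hydrogen
bonds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .config import Config
from .evaluation import (COMBINED_LEVELS, PRECISION_LEVELS, Contact,
                         HydrogenBond, find_hbonds, find_undesirable_contacts)
from .hydrogen_init import assign_hybridization, normalize_complex, place_hydrogens
from .network_opt import (Assignment, NetworkGraph, apply_assignment,
                          build_network, optimize, rescore)
from .structure_io import ComplexStructure, build_complex, write_pdb
from .vmr_enum import VMR, FragmentScoreTable, enumerate_modes, partition_vmrs


@dataclass
class ProtonationResult:
    complex: ComplexStructure
    vmrs: list[VMR]
    network: NetworkGraph
    assignment: Assignment
    pdb_text: str

    @property
    def total_score(self) -> float:
        return self.assignment.total_score

    def rescore(self, cfg: Config | None = None) -> float:
        return rescore(self.complex, self.vmrs, self.assignment, cfg)


def protonate(text: str, ligand=None, config: Config | None = None,
              tpa: bool = True,
              table: FragmentScoreTable | None = None) -> ProtonationResult:
    """Predict hydrogen coordinates for a complex given as PDB text.

    ``ligand`` selects the reference ligand ("NAME:CHAIN:RESSEQ") and enables
    the cleanup filter chain; ``tpa`` disables tautomer/protonation-state
    enumeration when False (rotors, waters and flips still vary).
    """
    cfg = config or Config()
    table = table or FragmentScoreTable.default()
    cx = build_complex(text, ligand, cfg, do_cleanup=ligand is not None)
    for comp in cx.components:
        assign_hybridization(comp)
    normalize_complex(cx, cfg)
    place_hydrogens(cx, cfg)
    vmrs: list[VMR] = []
    for ci in range(len(cx.components)):
        vmrs.extend(partition_vmrs(cx, ci, cfg))
    for vmr in vmrs:
        enumerate_modes(vmr, cx, cfg, table, tpa=tpa)
    net = build_network(vmrs, cx, cfg)
    assignment = optimize(net, cfg)
    apply_assignment(cx, vmrs, assignment)
    return ProtonationResult(cx, vmrs, net, assignment, write_pdb(cx))


@dataclass
class AuditReport:
    contacts: list[Contact]
    hbonds: list[HydrogenBond]
    complex: ComplexStructure

    def to_tsv(self) -> str:
        lines = ["type\tatom_a\tatom_b\th_distance\theavy_distance\tangles"]
        for c in self.contacts:
            ang = "" if c.angles is None else \
                f"{c.angles[0]:.1f},{c.angles[1]:.1f}"
            lines.append(f"{c.kind}\t{self._label(c.a)}\t{self._label(c.b)}"
                         f"\t{c.h_distance:.3f}\t{c.heavy_distance:.3f}\t{ang}")
        lines.append("type\tdonor\thydrogen\tacceptor\tdistance\tangle")
        for h in self.hbonds:
            lines.append(f"hbond\t{self._label(h.donor)}\t{self._label(h.hydrogen)}"
                         f"\t{self._label(h.acceptor)}\t{h.heavy_distance:.3f}"
                         f"\t{h.angle:.1f}")
        return "\n".join(lines) + "\n"

    def _label(self, addr) -> str:
        ci, ai = addr
        comp = self.complex.components[ci]
        a = comp.atoms[ai]
        return f"{comp.resname}:{comp.chain}:{comp.resseq}:{a.name or a.element}"


def audit(text: str, ligand, level: int = 2, combined: bool = False,
          config: Config | None = None) -> AuditReport:
    """Contact audit + hydrogen-bond list of a protonated structure."""
    cfg = config or Config()
    cx = build_complex(text, ligand, cfg, do_cleanup=False,
                       include_hydrogens=True)
    criterion = (COMBINED_LEVELS if combined else PRECISION_LEVELS)[level]
    contacts = find_undesirable_contacts(cx, criterion)
    hbonds = find_hbonds(cx)
    return AuditReport(contacts, hbonds, cx)
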