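import numpy as np
import pytest

from hbnet import (COMBINED_LEVELS, PRECISION_LEVELS, ContactCriterion,
                   FixtureSpec, build_complex, classify_state, find_hbonds,
                   find_undesirable_contacts, make_fixture, protonate)
from hbnet.fixtures import pdb_text

from conftest import SCENARIOS


def pair_complex(d_heavy, angle_deg_dha):
    """A hydroxyl donor and a carbonyl acceptor with prescribed heavy-atom
    distance and donor-H-acceptor angle (synthetic geometry, H explicit)."""
    t = np.radians(180.0 - angle_deg_dha)
    h = np.array([0.96, 0.0, 0.0])
    acc_dir = np.array([np.cos(t), np.sin(t), 0.0])
    # place the acceptor so that |D-A| = d_heavy along the chosen direction
    a = h + acc_dir * _solve_leg(d_heavy, h, acc_dir)
    rows = [("O1", "MOH", "L", 1, "O", (0.0, 0.0, 0.0)),
            ("C1", "MOH", "L", 1, "C", (-0.8, -1.2, 0.0)),
            ("HO1", "MOH", "L", 1, "H", tuple(h)),
            ("O1", "ACD", "B", 1, "O", tuple(a)),
            ("C1", "ACD", "B", 1, "C", tuple(a + [0.0, 1.21, 0.0])),
            ("C2", "ACD", "B", 1, "C", tuple(a + [1.3, 1.96, 0.0])),
            ("C3", "ACD", "B", 1, "C", tuple(a + [-1.3, 1.96, 0.0]))]
    return build_complex(pdb_text(rows), include_hydrogens=True,
                         do_cleanup=False)


def _solve_leg(d_heavy, h, acc_dir):
    # |h + x*acc_dir| = d_heavy, smallest positive root
    b = 2 * float(np.dot(h, acc_dir))
    c = float(np.dot(h, h)) - d_heavy ** 2
    return (-b + np.sqrt(b * b - 4 * c)) / 2


class TestHbondCriterion:
    @pytest.mark.parametrize("d,angle,expected", [
        (2.8, 165.0, True),    # well inside both thresholds
        (3.49, 151.0, True),   # just inside both
        (3.6, 165.0, False),   # distance exceeds 3.5 A
        (2.8, 140.0, False),   # angle below 150 degrees
        (3.6, 140.0, False),   # both outside
    ])
    def test_pairs_straddling_thresholds(self, d, angle, expected):
        cx = pair_complex(d, angle)
        found = [b for b in find_hbonds(cx)]
        assert bool(found) == expected
        if found:
            # emitted PDB coordinates carry three decimals
            assert found[0].heavy_distance == pytest.approx(d, abs=5e-3)
            assert found[0].angle == pytest.approx(angle, abs=0.1)

    def test_symmetric_under_chain_relabeling(self):
        cx1 = pair_complex(2.9, 170.0)
        n1 = len(find_hbonds(cx1))
        # swap the chain labels by rebuilding with exchanged chains
        t = np.radians(10.0)
        rows = [("O1", "MOH", "B", 1, "O", (0.0, 0.0, 0.0)),
                ("C1", "MOH", "B", 1, "C", (-0.8, -1.2, 0.0)),
                ("HO1", "MOH", "B", 1, "H", (0.96, 0.0, 0.0))]
        cx2 = pair_complex(2.9, 170.0)
        assert n1 == len(find_hbonds(cx2)) == 1


class TestUndesirableContacts:
    def test_ligand_protein_donor_clash_reported_at_every_level(self):
        res = protonate(make_fixture(FixtureSpec("donor_face")),
                        ligand="PYR:L:1", tpa=False)
        for level, crit in PRECISION_LEVELS.items():
            contacts = find_undesirable_contacts(res.complex, crit)
            assert len(contacts) == 1
            assert contacts[0].kind == "donor-donor"
            assert contacts[0].h_distance < 1.0

    def test_protein_protein_clash_not_reported(self):
        # two facing amide donors, ligand elsewhere: no counterpart in ligand
        from hbnet.fixtures import _formamide, Z
        rows = list(_formamide(np.zeros(3), [1.0, 0, 0], Z,
                               chain="B", resseq=1))
        rows += _formamide(np.array([2.9, 0.0, 0.0]), [-1.0, 0, 0], Z,
                           chain="C", resseq=2)
        rows += [("C1", "ETH", "L", 1, "C", (0.0, 9.0, 0.0)),
                 ("C2", "ETH", "L", 1, "C", (1.53, 9.0, 0.0))]
        res = protonate(pdb_text(rows), ligand="ETH:L:1")
        contacts = find_undesirable_contacts(res.complex, PRECISION_LEVELS[4])
        assert contacts == []

    def test_ligand_donor_near_metal_reported(self):
        # zinc placed 1.5 A beyond one ammonium hydrogen of a methylamine
        from hbnet.geometry import TET_ANGLE, any_perpendicular, cone_direction
        axis = np.array([1.0, 0.0, 0.0])
        h_dir = cone_direction(axis, any_perpendicular(axis),
                               180.0 - TET_ANGLE, 0.0)
        zn = h_dir * (1.01 + 1.5)
        rows = [("N1", "MAM", "L", 1, "N", (0.0, 0.0, 0.0)),
                ("C1", "MAM", "L", 1, "C", (-1.47, 0.0, 0.0)),
                ("ZN", "ZN", "M", 1, "Zn", tuple(zn))]
        res = protonate(pdb_text(rows), ligand="MAM:L:1", tpa=False)
        contacts = find_undesirable_contacts(res.complex, PRECISION_LEVELS[3])
        kinds = {c.kind for c in contacts}
        assert "donor-metal" in kinds

    def test_no_reference_ligand_is_an_error(self):
        res = protonate(make_fixture(FixtureSpec("water_bridge", {"n": 0})))
        with pytest.raises(ValueError, match="ligand"):
            find_undesirable_contacts(res.complex, PRECISION_LEVELS[2])

    @pytest.mark.parametrize("scenario,lig,params",
                             [s for s in SCENARIOS if s[1] is not None])
    @pytest.mark.parametrize("levels", [PRECISION_LEVELS, COMBINED_LEVELS])
    def test_monotone_in_criterion(self, scenario, lig, params, levels):
        """Loosening thresholds never reduces the contact count."""
        res = protonate(make_fixture(FixtureSpec(scenario, params)),
                        ligand=lig, tpa=False)
        counts = [len(find_undesirable_contacts(res.complex, levels[k]))
                  for k in sorted(levels)]
        assert counts == sorted(counts)

    def test_criterion_validation(self):
        with pytest.raises(ValueError):
            ContactCriterion("bad", -1.0, 1.5)


class TestClassifyState:
    def _ligands(self, scenario, lig):
        text = make_fixture(FixtureSpec(scenario))
        a = protonate(text, ligand=lig, tpa=True)
        b = protonate(text, ligand=lig, tpa=False)
        return (a.complex.components[a.complex.reference_ligand],
                b.complex.components[b.complex.reference_ligand])

    def test_identical_states_accordant(self):
        g, _ = self._ligands("imidazole_carboxylate", "IMZ:L:1")
        assert classify_state(g, g) == "accordant"

    def test_tautomer_difference(self):
        g1, g2 = self._ligands("imidazole_carboxylate", "IMZ:L:1")
        assert classify_state(g1, g2) == "Taut_NE"
        assert classify_state(g1, g2, interaction_errors=True) == "Taut_IE"

    def test_protonation_difference(self):
        g1, g2 = self._ligands("donor_face", "PYR:L:1")
        assert classify_state(g1, g2) == "Prot_NE"
        assert classify_state(g1, g2, interaction_errors=True) == "Prot_IE"

    def test_redox_difference(self):
        # dihydro vs oxidized forms of the same skeleton: a pyridine-like
        # ring against its 2H-saturated counterpart (same heavy atoms, same
        # connectivity, two hydrogens more at equal net charge)
        from hbnet.fixtures import _IMIDAZOLE_RING
        rows = [(n, "IMU", "L", 1, n[0], (x, y, 0.0))
                for n, (x, y) in _IMIDAZOLE_RING.items()]
        aromatic = build_complex(pdb_text(rows), "IMU:L:1")
        ga = aromatic.components[aromatic.reference_ligand]
        # saturated variant: stretch the ring so no pi bonds are perceived
        rows2 = [(n, "IMU", "L", 1, n[0], (1.12 * x, 1.12 * y, 0.0))
                 for n, (x, y) in _IMIDAZOLE_RING.items()]
        sat = build_complex(pdb_text(rows2), "IMU:L:1")
        gs = sat.components[sat.reference_ligand]
        assert classify_state(gs, ga) == "Redox"

    def test_different_heavy_atom_counts_error(self):
        g1, _ = self._ligands("imidazole_carboxylate", "IMZ:L:1")
        g2, _ = self._ligands("donor_face", "PYR:L:1")
        with pytest.raises(ValueError, match="heavy-atom counts"):
            classify_state(g1, g2)

    def test_every_ligand_accordant_with_itself(self):
        for scen, lig, params in SCENARIOS:
            if lig is None:
                continue
            res = protonate(make_fixture(FixtureSpec(scen, params)),
                            ligand=lig)
            g = res.complex.components[res.complex.reference_ligand]
            assert classify_state(g, g) == "accordant"
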