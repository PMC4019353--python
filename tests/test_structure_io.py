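import numpy as np
import pytest

from hbnet import (CleanupError, FixtureSpec, PDBParseError, build_complex,
                   cleanup, make_fixture, perceive_bonds, read_pdb, write_pdb)
from hbnet.structure_io import TemplateFallthrough, match_residue_template

from conftest import SCENARIOS, cys_pair_text

ALA_LINE = ("ATOM      1  CA  ALA A   1      11.104   6.134  -6.504"
            "  1.00  0.00           C")


class TestReadPdb:
    def test_single_record(self):
        recs = read_pdb(ALA_LINE + "\n")
        assert len(recs) == 1
        r = recs[0]
        assert (r.element, r.name, r.resname, r.chain, r.resseq) == \
            ("C", "CA", "ALA", "A", 1)
        assert np.allclose(r.coords, [11.104, 6.134, -6.504])

    def test_only_first_model_read(self):
        text = "MODEL     1\n" + ALA_LINE + "\nENDMDL\nMODEL     2\n" \
            + ALA_LINE.replace(" CA ", " CB ") + "\nENDMDL\n"
        recs = read_pdb(text)
        assert [r.name for r in recs] == ["CA"]

    def test_altloc_retained_by_parser(self):
        line = ALA_LINE[:16] + "B" + ALA_LINE[17:]
        recs = read_pdb(line + "\n")
        assert recs[0].altloc == "B"

    def test_malformed_line_names_line_number(self):
        text = ALA_LINE + "\n" + ALA_LINE[:30] + "xxxxxxxx" + ALA_LINE[38:]
        with pytest.raises(PDBParseError, match="line 2"):
            read_pdb(text)


class TestCleanup:
    def _records(self, wrong=False):
        return read_pdb(make_fixture(FixtureSpec(
            "cleanup", {"wrong_element": wrong})))

    @pytest.mark.parametrize("wrong", [False, True])
    def test_duplicate_ligand_entry_removed(self, wrong):
        out = cleanup(self._records(wrong), "ACT:L:1")
        resseqs = {(r.resname, r.resseq) for r in out}
        assert ("ACT", 1) in resseqs      # reference ligand kept
        assert ("ACT", 9) not in resseqs  # overlapping duplicate removed

    def test_hydrogens_removed_and_first_altloc_kept(self):
        out = cleanup(self._records(), "ACT:L:1")
        assert all(r.element != "H" for r in out)
        ser = [r for r in out if r.resname == "SER"]
        assert {r.altloc for r in ser} == {"A"}
        assert len(ser) == 6              # one position per atom

    def test_idempotent(self):
        once = cleanup(self._records(), "ACT:L:1")
        twice = cleanup(once, "ACT:L:1")
        assert [(r.serial, r.name) for r in once] == \
            [(r.serial, r.name) for r in twice]

    def test_no_overlap_input_unchanged(self):
        text = make_fixture(FixtureSpec("imidazole_carboxylate"))
        recs = read_pdb(text)
        out = cleanup(recs, "IMZ:L:1")
        assert [(r.serial, r.name) for r in out] == \
            [(r.serial, r.name) for r in recs]

    def test_missing_ligand_is_hard_failure(self):
        with pytest.raises(CleanupError):
            cleanup(self._records(), "XYZ:Q:7")

    def test_internal_ligand_overlap_is_hard_failure(self):
        recs = self._records()
        lig = [r for r in recs if r.resseq == 1]
        clone = read_pdb(make_fixture(FixtureSpec("cleanup")))
        for r in clone:
            if r.resseq == 1 and r.name == "O1":
                r.coords = [x for x in lig[0].coords]  # on top of C1
        with pytest.raises(CleanupError):
            cleanup(clone, "ACT:L:1")


class TestTemplates:
    def _residue(self, text, resname):
        return [r for r in read_pdb(text) if r.resname == resname]

    def test_complete_ala(self):
        text = make_fixture(FixtureSpec("chain_break"))
        g = match_residue_template(self._residue(text, "ALA"))
        heavy = [a for a in g.atoms if not a.is_hydrogen]
        assert len(heavy) == 5
        names = {a.name for a in heavy}
        assert names == {"N", "CA", "C", "O", "CB"}
        assert g.order(1, 2) == 1 and g.order(2, 3) == 2  # CA-C, C=O

    def test_missing_atom_added_without_coordinates(self):
        text = make_fixture(FixtureSpec("serine_rotor"))
        recs = [r for r in self._residue(text, "SER") if r.name != "OG"]
        g = match_residue_template(recs)
        og = next(a for a in g.atoms if a.name == "OG")
        assert og.from_template and not og.has_valid_coords

    def test_unknown_residue_falls_through(self):
        text = make_fixture(FixtureSpec("imidazole_carboxylate"))
        with pytest.raises(TemplateFallthrough):
            match_residue_template(self._residue(text, "IMZ"))

    def test_foreign_atom_name_falls_through(self):
        text = make_fixture(FixtureSpec("chain_break"))
        recs = self._residue(text, "ALA")
        recs[0].name = "XQ1"
        with pytest.raises(TemplateFallthrough):
            match_residue_template(recs)


class TestPerception:
    def test_o2_double_bond(self):
        g = perceive_bonds([("O", (0, 0, 0)), ("O", (1.21, 0, 0))])
        assert g.bonds() == [(0, 1, 2)]

    def test_isolated_oxygen_has_no_bonds(self):
        g = perceive_bonds([("O", (0, 0, 0))])
        assert g.bonds() == [] and len(g.atoms) == 1

    def test_benzene_ring_aromatic_with_alternating_orders(self):
        R = 1.39 / (2 * np.sin(np.pi / 6))
        atoms = [("C", (R * np.cos(t), R * np.sin(t), 0))
                 for t in np.arange(6) * np.pi / 3]
        g = perceive_bonds(atoms)
        assert sorted(o for *_, o in g.bonds()) == [1, 1, 1, 2, 2, 2]
        assert g.aromatic_atoms == set(range(6))
        # every carbon carries exactly one pi bond
        for i in range(6):
            assert sum(g.order(i, j) - 1 for j in g.neighbors(i)) == 1

    def test_nitrile_triple_bond(self):
        g = perceive_bonds([("C", (0, 0, 0)), ("C", (1.46, 0, 0)),
                            ("N", (2.62, 0, 0))])
        assert g.order(1, 2) == 3 and g.order(0, 1) == 1

    def test_valences_satisfied_on_every_fixture(self):
        from conftest import SCENARIOS
        for scen, lig, params in SCENARIOS:
            cx = build_complex(make_fixture(FixtureSpec(scen, params)), lig)
            assert cx.check_valences() == [], scen


class TestConnection:
    def test_peptide_bond_within_cutoff(self):
        text = make_fixture(FixtureSpec("chain_break", {"gap": 1.33}))
        cx = build_complex(text)
        links = [(cx.components[a[0]].atoms[a[1]].name,
                  cx.components[b[0]].atoms[b[1]].name) for a, b, _ in cx.links]
        assert ("C", "N") in links

    def test_chain_break_flags_termini(self):
        cx = build_complex(make_fixture(FixtureSpec("chain_break")))
        assert cx.links == []
        ala, gly = cx.components
        assert "chain-break-c" in ala.flags
        assert "chain-break-n" in gly.flags

    def test_disulfide_by_local_perception(self):
        cx = build_complex(cys_pair_text())
        names = [(cx.components[a[0]].atoms[a[1]].name,
                  cx.components[b[0]].atoms[b[1]].name) for a, b, _ in cx.links]
        assert ("SG", "SG") in names


class TestWritePdb:
    def test_roundtrip_idempotent_on_heavy_atoms(self):
        text = make_fixture(FixtureSpec("imidazole_carboxylate"))
        once = write_pdb(build_complex(text))
        twice = write_pdb(build_complex(once))
        assert once == twice

    def test_water_with_hydrogens_has_three_records(self, protonated_fixtures):
        res = protonated_fixtures["water_bridge"]
        lines = [l for l in res.pdb_text.splitlines() if " HOH " in l]
        waters = {}
        for l in lines:
            waters.setdefault(int(l[22:26]), []).append(l)
        assert all(len(v) == 3 for v in waters.values())

    def test_protonated_amine_writes_expected_h_count(self, protonated_fixtures):
        res = protonated_fixtures["amine_transfer"]
        lig = res.complex.components[res.complex.reference_ligand]
        n1 = next(i for i, a in enumerate(lig.atoms) if a.name == "N1")
        n_h = len(lig.hydrogens_of(n1))
        lines = [l for l in res.pdb_text.splitlines()
                 if " PIP " in l and l[76:78].strip() == "H"]
        # ring carbons carry 2 H each (5 carbons) plus the amine hydrogens
        assert len(lines) == 10 + n_h

    def test_no_atom_in_two_components(self):
        for scen, lig, params in SCENARIOS:
            cx = build_complex(make_fixture(FixtureSpec(scen, params)), lig)
            seen = set()
            for ci, ai, comp, a in cx.iter_atoms():
                assert (ci, ai) not in seen
                seen.add((ci, ai))


class TestGemmiCrossCheck:
    def test_parser_agrees_with_gemmi(self):
        gemmi = pytest.importorskip("gemmi")
        text = make_fixture(FixtureSpec("imidazole_carboxylate"))
        ours = read_pdb(text)
        st = gemmi.read_pdb_string(text)
        theirs = [(a.name, res.name, a.element.name,
                   round(a.pos.x, 3), round(a.pos.y, 3), round(a.pos.z, 3))
                  for model in st for chain in model
                  for res in chain for a in res]
        mine = [(r.name, r.resname, r.element, *np.round(r.coords, 3))
                for r in ours]
        assert mine == theirs
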