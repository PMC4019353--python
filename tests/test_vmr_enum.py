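import itertools

import numpy as np
import pytest

from hbnet import FixtureSpec, make_fixture
from hbnet.config import Config
from hbnet.fixtures import _IMIDAZOLE_RING, _planar_ring, pdb_text
from hbnet.hydrogen_init import (assign_hybridization, normalize_complex,
                                 place_hydrogens)
from hbnet.structure_io import build_components, connect_components, read_pdb
from hbnet.vmr_enum import (Fragment, FragmentScoreTable, Mode,
                            enumerate_modes, mode_valence_ok, partition_vmrs,
                            score_stability)


def prepare(text, lig=None):
    cx = connect_components(build_components(read_pdb(text), lig), Config())
    for comp in cx.components:
        assign_hybridization(comp)
    normalize_complex(cx)
    place_hydrogens(cx)
    return cx


def imidazole_text(order=None, resname="IMU"):
    items = list(_IMIDAZOLE_RING.items())
    if order is not None:
        items = [items[k] for k in order]
    rows = [(n, resname, "L", 1, n[0], (x, y, 0.0)) for n, (x, y) in items]
    return pdb_text(rows)


class TestPartition:
    def test_histidine_side_chain_is_one_ring_region(self):
        cx = prepare(make_fixture(FixtureSpec("histidine")))
        his = next(i for i, c in enumerate(cx.components)
                   if c.resname == "HIS")
        vmrs = partition_vmrs(cx, his)
        ring = [v for v in vmrs if len(v.atoms) >= 5]
        assert len(ring) == 1
        names = {cx.components[his].atoms[i].name for i in ring[0].atoms}
        assert names == {"CG", "ND1", "CD2", "CE1", "NE2"}

    def test_piperazine_gives_two_independent_nitrogen_regions(self):
        pts = _planar_ring(6, 1.48)
        names = ["N1", "C2", "C3", "N4", "C5", "C6"]
        rows = [(n, "PZN", "L", 1, n[0], p) for n, p in zip(names, pts)]
        cx = prepare(pdb_text(rows), "PZN:L:1")
        vmrs = partition_vmrs(cx, cx.reference_ligand)
        assert [v.atoms for v in vmrs] == [[0], [3]]
        assert all(v.kind == "tautomer-protonation-group" for v in vmrs)

    def test_ethane_has_no_regions(self):
        rows = [("C1", "ETH", "L", 1, "C", (0, 0, 0)),
                ("C2", "ETH", "L", 1, "C", (1.53, 0, 0))]
        cx = prepare(pdb_text(rows))
        assert partition_vmrs(cx, 0) == []

    def test_regions_of_a_component_are_disjoint(self):
        from conftest import SCENARIOS
        for scen, lig, params in SCENARIOS:
            cx = prepare(make_fixture(FixtureSpec(scen, params)), lig)
            for ci in range(len(cx.components)):
                seen = set()
                for v in partition_vmrs(cx, ci):
                    assert not (seen & set(v.atoms))
                    seen.update(v.atoms)


class TestModeCensus:
    def test_imidazole_exactly_three_modes(self):
        cx = prepare(imidazole_text(), "IMU:L:1")
        v = partition_vmrs(cx, cx.reference_ligand)[0]
        modes = enumerate_modes(v, cx)
        assert len(modes) == 3
        # two neutral tautomers (distinct N-H placements) plus the cation
        charges = sorted(sum(m.charges.values()) for m in modes)
        assert charges == [0, 0, 1]

    def test_cyclic_secondary_amine_exactly_three_modes(self):
        cx = prepare(make_fixture(FixtureSpec("donor_face")), "PYR:L:1")
        v = partition_vmrs(cx, cx.reference_ligand)[0]
        modes = enumerate_modes(v, cx)
        assert len(modes) == 3
        n = v.atoms[0]
        assert sorted((m.charges[n], m.h_count(n)) for m in modes) == \
            [(0, 1), (0, 1), (1, 2)]

    def test_carboxylate_ionized_plus_four_neutral_placements(self):
        cx = prepare(make_fixture(FixtureSpec("imidazole_carboxylate")),
                     "IMZ:L:1")
        fmt = next(i for i, c in enumerate(cx.components)
                   if c.resname == "FMT")
        v = partition_vmrs(cx, fmt)[0]
        modes = enumerate_modes(v, cx)
        assert len(modes) == 5
        assert sum(modes[0].charges.values()) == -1      # default ionized
        assert all(sum(m.charges.values()) == 0 for m in modes[1:])

    def test_every_mode_satisfies_valence(self):
        from conftest import SCENARIOS
        for scen, lig, params in SCENARIOS:
            cx = prepare(make_fixture(FixtureSpec(scen, params)), lig)
            for ci in range(len(cx.components)):
                for v in partition_vmrs(cx, ci):
                    for m in enumerate_modes(v, cx):
                        assert mode_valence_ok(v, m, cx), (scen, m.tag)

    def test_mode_zero_is_normalized_default_with_minimal_stability(self):
        from conftest import SCENARIOS
        for scen, lig, params in SCENARIOS:
            cx = prepare(make_fixture(FixtureSpec(scen, params)), lig)
            for ci in range(len(cx.components)):
                for v in partition_vmrs(cx, ci):
                    modes = enumerate_modes(v, cx)
                    assert modes
                    assert modes[0].stability <= min(m.stability
                                                     for m in modes)

    @pytest.mark.parametrize("order", [
        (0, 1, 2, 3, 4), (4, 3, 2, 1, 0), (2, 0, 4, 1, 3), (1, 4, 0, 3, 2)])
    def test_mode_set_invariant_under_atom_relabeling(self, order):
        def census(cx):
            v = partition_vmrs(cx, cx.reference_ligand)[0]
            comp = cx.components[cx.reference_ligand]
            out = []
            for m in enumerate_modes(v, cx):
                placement = tuple(sorted((comp.atoms[i].name, m.h_count(i))
                                         for i in v.atoms))
                out.append((placement, sum(m.charges.values()), m.stability))
            return sorted(out)

        assert census(prepare(imidazole_text(order), "IMU:L:1")) == \
            census(prepare(imidazole_text(), "IMU:L:1"))

    def test_symmetric_tautomers_get_equal_stability(self):
        cx = prepare(imidazole_text(), "IMU:L:1")
        v = partition_vmrs(cx, cx.reference_ligand)[0]
        modes = enumerate_modes(v, cx)
        neutral = [m for m in modes if sum(m.charges.values()) == 0]
        assert len(neutral) == 2
        assert neutral[0].stability == neutral[1].stability


class TestStabilityScores:
    def test_subgroup_partition_is_additive(self):
        table = FragmentScoreTable({"sub_a": 2, "sub_b": 3})
        mode = Mode({}, {}, {},
                    fragments=[Fragment("whole_missing", ["sub_a", "sub_b"])])
        assert score_stability(mode, table) == 5

    def test_whole_group_match_preferred_over_subgroups(self):
        table = FragmentScoreTable({"whole": 7, "sub_a": 2, "sub_b": 3})
        mode = Mode({}, {}, {},
                    fragments=[Fragment("whole", ["sub_a", "sub_b"])])
        assert score_stability(mode, table) == 7

    def test_unmatched_fragment_scores_zero_with_warning(self):
        table = FragmentScoreTable({})
        mode = Mode({}, {}, {}, fragments=[Fragment("nope", ["also_nope"])])
        with pytest.warns(UserWarning):
            assert score_stability(mode, table) == 0

    def test_ionized_carboxylate_preferred_over_neutral_acid(self):
        cx = prepare(make_fixture(FixtureSpec("imidazole_carboxylate")),
                     "IMZ:L:1")
        fmt = next(i for i, c in enumerate(cx.components)
                   if c.resname == "FMT")
        v = partition_vmrs(cx, fmt)[0]
        modes = enumerate_modes(v, cx)
        ionized = [m for m in modes if sum(m.charges.values()) == -1]
        neutral = [m for m in modes if sum(m.charges.values()) == 0]
        assert max(m.stability for m in ionized) < \
            min(m.stability for m in neutral)

    def test_neutral_imidazole_preferred_over_imidazolium(self):
        cx = prepare(imidazole_text(), "IMU:L:1")
        v = partition_vmrs(cx, cx.reference_ligand)[0]
        modes = enumerate_modes(v, cx)
        cation = next(m for m in modes if sum(m.charges.values()) == 1)
        for m in modes:
            if sum(m.charges.values()) == 0:
                assert m.stability < cation.stability

    def test_mode_cap_keeps_best_by_stability(self):
        cx = prepare(make_fixture(FixtureSpec("serine_rotor")))
        ser = 0
        v = [v for v in partition_vmrs(cx, ser)
             if v.kind == "terminal-rotor"][0]
        cfg = Config(rotor_steps=12, max_modes=6)
        with pytest.warns(UserWarning, match="capped"):
            modes = enumerate_modes(v, cx, cfg)
        assert len(modes) == 6
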