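import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hbnet import Config, FixtureSpec, make_fixture
from hbnet.interaction_model import (ACCEPTOR, DONOR, METAL,
                                     InteractionContext, InteractionSurface,
                                     base_score, build_surfaces, score_pair)
from hbnet.config import Config as Cfg

from test_vmr_enum import imidazole_text, prepare
from hbnet.vmr_enum import enumerate_modes, partition_vmrs

CFG = Config()


def donor(anchor_pos, h_pos, anchor=(0, 0)):
    anchor_pos = np.asarray(anchor_pos, float)
    h_pos = np.asarray(h_pos, float)
    axis = (h_pos - anchor_pos) / np.linalg.norm(h_pos - anchor_pos)
    return InteractionSurface(anchor, DONOR, anchor_pos, axis, h_pos,
                              CFG.angle_cutoff, CFG.hbond_ideal)


def acceptor(anchor_pos, axis, anchor=(1, 0)):
    axis = np.asarray(axis, float)
    return InteractionSurface(anchor, ACCEPTOR, np.asarray(anchor_pos, float),
                              axis / np.linalg.norm(axis), None,
                              CFG.angle_cutoff, CFG.hbond_ideal)


def metal(pos, anchor=(2, 0)):
    return InteractionSurface(anchor, METAL, np.asarray(pos, float), None,
                              None, 180.0, CFG.metal_ideal)


class TestScorePair:
    def test_ideal_linear_hbond_scores_exactly_minus_weight(self):
        d = donor([0, 0, 0], [1.01, 0, 0])
        a = acceptor([1.01 + 1.9, 0, 0], [-1, 0, 0])
        s = score_pair(d, a, CFG)
        assert s.kind == "hbond"
        assert s.value == pytest.approx(-CFG.w_hbond, abs=1e-12)
        # strictly inside the plateau the maximum is exact
        a2 = acceptor([1.01 + 1.75, 0, 0], [-1, 0, 0])
        assert score_pair(d, a2, CFG).value == -CFG.w_hbond

    def test_beyond_cutoff_scores_none(self):
        d = donor([0, 0, 0], [1.01, 0, 0])
        a = acceptor([6.0, 0, 0], [-1, 0, 0])
        assert score_pair(d, a, CFG).kind == "none"

    def test_angular_deviation_beyond_cutoff_scores_none(self):
        d = donor([0, 0, 0], [0, 1.01, 0])     # H pointing sideways
        a = acceptor([2.9, 0, 0], [-1, 0, 0])
        assert score_pair(d, a, CFG).value == 0.0

    def test_close_donor_donor_repulsion_is_maximal(self):
        d1 = donor([0, 0, 0], [1.01, 0, 0], anchor=(0, 0))
        d2 = donor([3.22, 0, 0], [2.21, 0, 0], anchor=(1, 0))
        s = score_pair(d1, d2, CFG)
        assert s.kind == "repulsion"
        assert s.value == CFG.w_repulsion      # H...H = 1.2 A: full penalty

    def test_donor_metal_repulsion(self):
        d = donor([0, 0, 0], [1.01, 0, 0])
        m = metal([2.51, 0, 0])                # H...metal = 1.5 A
        s = score_pair(d, m, CFG)
        assert s.kind == "repulsion" and s.value > 0

    def test_acceptor_metal_attraction(self):
        a = acceptor([0, 0, 0], [1, 0, 0])
        m = metal([2.1, 0, 0])
        s = score_pair(a, m, CFG)
        assert s.kind == "metal"
        assert s.value == -CFG.w_metal

    def test_same_anchor_never_scores(self):
        d = donor([0, 0, 0], [1.01, 0, 0], anchor=(0, 7))
        a = acceptor([0, 0, 0], [1, 0, 0], anchor=(0, 7))
        assert score_pair(d, a, CFG).kind == "none"

    @given(st.floats(1.0, 7.0), st.floats(1.0, 7.0))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_symmetric_in_arguments(self, x, y):
        d = donor([0, 0, 0], [1.01, 0, 0], anchor=(0, 0))
        a = acceptor([x, y, 0], [-x, -y, 0], anchor=(1, 0))
        assert score_pair(d, a, CFG).value == score_pair(a, d, CFG).value

    @given(st.floats(1.9, 4.0), st.floats(2.0, 4.0))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_hbond_magnitude_nonincreasing_with_distance(self, d1, d2):
        lo, hi = sorted((d1, d2))

        def value(dist):
            d = donor([0, 0, 0], [1.01, 0, 0])
            a = acceptor([1.01 + dist, 0, 0], [-1, 0, 0])
            return abs(score_pair(d, a, CFG).value)

        assert value(lo) >= value(hi)

    @given(st.floats(0.5, 3.0), st.floats(0.5, 3.0))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_repulsion_nonincreasing_with_distance(self, d1, d2):
        lo, hi = sorted((d1, d2))

        def value(dist):
            a = donor([-1.01, 0, 0], [0, 0, 0], anchor=(0, 0))
            b = donor([dist + 1.01, 0, 0], [dist, 0, 0], anchor=(1, 0))
            return score_pair(a, b, CFG).value

        assert value(lo) >= value(hi)

    def test_ramps_reach_exactly_zero_at_cutoffs(self):
        d = donor([0, 0, 0], [1.01, 0, 0])
        a = acceptor([1.01 + CFG.hbond_cutoff, 0, 0], [-1, 0, 0])
        assert score_pair(d, a, CFG).value == 0.0
        b1 = donor([-1.01, 0, 0], [0, 0, 0], anchor=(0, 0))
        b2 = donor([CFG.repulsion_cutoff + 1.01, 0, 0],
                   [CFG.repulsion_cutoff, 0, 0], anchor=(1, 0))
        assert score_pair(b1, b2, CFG).value == 0.0


class TestBuildSurfaces:
    def test_hydroxyl_mode_one_donor_two_acceptors(self):
        cx = prepare(make_fixture(FixtureSpec("serine_rotor")))
        v = [v for v in partition_vmrs(cx, 0)
             if v.kind == "terminal-rotor"][0]
        modes = enumerate_modes(v, cx)
        surfs = build_surfaces(modes[0], v, cx)
        roles = sorted(s.role for s in surfs)
        assert roles == [ACCEPTOR, ACCEPTOR, DONOR]

    def test_protonated_cyclic_amine_two_donors_no_acceptor(self):
        cx = prepare(make_fixture(FixtureSpec("donor_face")), "PYR:L:1")
        v = partition_vmrs(cx, cx.reference_ligand)[0]
        modes = enumerate_modes(v, cx)
        charged = next(m for m in modes if sum(m.charges.values()) == 1)
        roles = sorted(s.role for s in build_surfaces(charged, v, cx))
        assert roles == [DONOR, DONOR]

    def test_imidazole_tautomer_one_donor_one_acceptor(self):
        cx = prepare(imidazole_text(), "IMU:L:1")
        v = partition_vmrs(cx, cx.reference_ligand)[0]
        modes = enumerate_modes(v, cx)
        comp = cx.components[cx.reference_ligand]
        for m in modes:
            ring_n = [i for i in v.atoms if comp.atoms[i].element == "N"]
            surfs = [s for s in build_surfaces(m, v, cx)
                     if s.anchor[1] in ring_n]
            donors = [s for s in surfs if s.role == DONOR]
            accs = [s for s in surfs if s.role == ACCEPTOR]
            if sum(m.charges.values()) == 1:       # imidazolium
                assert len(donors) == 2 and len(accs) == 0
            else:                                  # neutral tautomers
                assert len(donors) == 1 and len(accs) == 1
                assert donors[0].anchor != accs[0].anchor

    def test_template_added_atoms_contribute_no_surfaces(self):
        from hbnet.interaction_model import fixed_surfaces
        from hbnet.structure_io import read_pdb, build_components, \
            connect_components
        from hbnet.hydrogen_init import assign_hybridization, \
            normalize_complex, place_hydrogens
        text = make_fixture(FixtureSpec("serine_rotor"))
        recs = [r for r in read_pdb(text) if r.name != "OG"]
        cx = connect_components(build_components(recs), Config())
        for comp in cx.components:
            assign_hybridization(comp)
        normalize_complex(cx)
        place_hydrogens(cx)
        ser = cx.components[0]
        og = next(i for i, a in enumerate(ser.atoms) if a.name == "OG")
        surfs = fixed_surfaces(cx, set())
        assert all(s.anchor != (0, og) for s in surfs)

    def test_all_surface_axes_normalized(self):
        cx = prepare(make_fixture(FixtureSpec("imidazole_carboxylate")),
                     "IMZ:L:1")
        for ci in range(len(cx.components)):
            for v in partition_vmrs(cx, ci):
                for m in enumerate_modes(v, cx):
                    for s in build_surfaces(m, v, cx):
                        if s.axis is not None:
                            assert abs(np.linalg.norm(s.axis) - 1) < 1e-9


class TestBaseScore:
    def test_no_partner_in_range_gives_stability_term_only(self):
        cx = prepare(make_fixture(FixtureSpec("donor_face")), "PYR:L:1")
        v = partition_vmrs(cx, cx.reference_ligand)[0]
        modes = enumerate_modes(v, cx)
        ctx = InteractionContext(cx)
        for m in modes:
            m.surfaces = build_surfaces(m, v, cx)
            assert base_score(m, [], ctx, CFG) == \
                pytest.approx(CFG.w_stability * m.stability)

    def test_base_score_is_stability_plus_fixed_interactions(self):
        """The two contributions are computed independently and must sum."""
        from hbnet.interaction_model import fixed_surfaces, pair_sum
        cx = prepare(make_fixture(FixtureSpec("donor_face")), "PYR:L:1")
        v = partition_vmrs(cx, cx.reference_ligand)[0]
        modes = enumerate_modes(v, cx)
        ctx = InteractionContext(cx)
        fixed = fixed_surfaces(cx, {(v.component, i) for i in v.atoms})
        for m in modes:
            m.surfaces = build_surfaces(m, v, cx)
            expected = CFG.w_stability * m.stability \
                + pair_sum(m.surfaces, fixed, ctx, CFG)
            assert base_score(m, fixed, ctx, CFG) == pytest.approx(expected)
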