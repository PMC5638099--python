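import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad

import leafmorph as lm
from leafmorph.core_model import Margin, MarginPoint, MorphogenRule
from leafmorph.growth import (
    RERGProfile,
    elongate_veins,
    extend_tips,
    isotropic_expand,
    normal_propagation,
    rerg_at,
    segment_elongation,
    transport_margin,
)


def random_profile(rng, max_s=5.0):
    k = rng.integers(2, 6)
    bp = np.sort(rng.uniform(0, max_s, size=k))
    bp[0] = 0.0
    bp = np.unique(bp)
    rates = rng.uniform(0, 1.5, size=len(bp))
    return RERGProfile(bp, rates)


class TestRERGProfile:
    def test_uniform_rate_everywhere(self):
        p = RERGProfile.uniform(0.1)
        for s in (0.0, 1.0, 100.0):
            assert rerg_at(p, s) == 0.1

    def test_linear_interpolation(self):
        p = RERGProfile.basipetal(1.0, 2.0)
        assert rerg_at(p, 1.0) == pytest.approx(0.5)

    def test_zero_beyond_growth_zone(self):
        p = RERGProfile.basipetal(1.0, 2.0)
        assert rerg_at(p, 5.0) == 0.0

    def test_validation(self):
        with pytest.raises(ValueError):
            RERGProfile([0.0, 0.0], [1.0, 1.0])
        with pytest.raises(ValueError):
            RERGProfile([0.0, 1.0], [1.0, -0.1])


class TestSegmentElongation:
    def test_uniform_closed_form(self):
        p = RERGProfile.uniform(0.1)
        assert segment_elongation(p, 1.0, 3.0, 1.0) == pytest.approx(0.2, abs=0)

    def test_linear_profile_analytic(self):
        # RERG(s) = 0.1 s on [0, 2]: integral = 0.1 * 2^2 / 2 = 0.2
        p = RERGProfile([0.0, 2.0], [0.0, 0.2])
        assert segment_elongation(p, 0.0, 2.0, 1.0) == pytest.approx(0.2, abs=1e-10)

    def test_zero_outside_growth_zone(self):
        p = RERGProfile.basipetal(1.0, 1.0)
        assert segment_elongation(p, 2.0, 3.0, 1.0) == 0.0

    def test_matches_adaptive_quadrature(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            p = random_profile(rng)
            s1, s2 = np.sort(rng.uniform(0, 6.0, size=2))
            if s1 == s2:
                continue
            expected, _ = quad(
                lambda s: rerg_at(p, s), s1, s2,
                points=list(p.breakpoints), limit=200,
            )
            got = segment_elongation(p, s1, s2, 1.0)
            assert got == pytest.approx(expected, rel=1e-10, abs=1e-12)


def simple_tree():
    t = lm.VeinTree(base=np.array([0.0, 0.0]))
    vid = t.new_vein(t.root)
    tip = t.add_node(np.array([0.0, 2.0]), t.root, vid)
    t.vein_terminal[vid] = tip
    return t, vid, tip


def tree_with_lateral(attach_s=1.0, lateral=np.array([1.0, 0.0])):
    t, vid, tip = simple_tree()
    mid = t.split_edge(tip, np.array([0.0, attach_s]))
    lv = t.new_vein(mid)
    ltip = t.add_node(np.array([0.0, attach_s]) + lateral, mid, lv)
    t.vein_terminal[lv] = ltip
    return t, ltip


class TestElongateVeins:
    def test_uniform_growth_of_midvein(self):
        t, vid, tip = simple_tree()
        out = elongate_veins(t, RERGProfile.uniform(0.1), 1.0)
        assert np.allclose(out.positions[tip], [0.0, 2.2])

    def test_zero_profile_is_identity(self):
        t, _, tip = simple_tree()
        out = elongate_veins(t, RERGProfile.uniform(0.0), 1.0)
        for n in t.positions:
            assert np.allclose(out.positions[n], t.positions[n])

    def test_uniform_rate_scales_total_length(self):
        rng = np.random.default_rng(3)
        t, ltip = tree_with_lateral()
        out = elongate_veins(t, RERGProfile.uniform(0.25), 0.4)
        assert out.total_length() == pytest.approx(1.1 * t.total_length(), rel=1e-12)

    def test_subtree_outside_zone_translates_rigidly(self):
        # growth zone [0, 1]: the lateral attached at s = 1 does not stretch
        t, ltip = tree_with_lateral(attach_s=1.0)
        profile = RERGProfile.basipetal(0.5, 1.0)
        out = elongate_veins(t, profile, 1.0)
        mid = t.parent[ltip]
        disp_mid = out.positions[mid] - t.positions[mid]
        disp_tip = out.positions[ltip] - t.positions[ltip]
        assert np.allclose(disp_mid, disp_tip)
        assert np.linalg.norm(
            out.positions[ltip] - out.positions[mid]
        ) == pytest.approx(1.0)

    def test_orientation_preserved_on_random_trees(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            t, _ = tree_with_lateral(
                attach_s=rng.uniform(0.2, 1.8),
                lateral=rng.uniform(-1, 1, size=2) + [0.1, 0],
            )
            out = elongate_veins(t, random_profile(rng), 0.3)
            for n, par in t.parent.items():
                if par is None:
                    continue
                d0 = t.positions[n] - t.positions[par]
                d1 = out.positions[n] - out.positions[par]
                if np.linalg.norm(d0) == 0:
                    continue
                cosang = d0 @ d1 / (np.linalg.norm(d0) * np.linalg.norm(d1))
                assert cosang == pytest.approx(1.0, abs=1e-12)


class TestExtendTips:
    def test_zero_growth_is_identity(self, midvein_state):
        state, _ = midvein_state
        veins, margin = extend_tips(state.veins, state.margin, 0.0)
        assert veins is state.veins and margin is state.margin

    def test_apex_cp_moves_with_tip(self, midvein_state):
        state, _ = midvein_state
        cp_idx = state.margin.cp_indices()[0]
        before = state.margin.points[cp_idx].position.copy()
        veins, margin = extend_tips(state.veins, state.margin, 0.05)
        after = margin.points[cp_idx].position
        assert np.linalg.norm(after - before) == pytest.approx(0.05)
        tip = veins.positions[veins.vein_terminal[0]]
        assert np.allclose(after, tip)

    def test_profile_scaling_freezes_tips_outside_zone(self):
        t, ltip = tree_with_lateral(attach_s=0.5)
        m = Margin([MarginPoint(position=np.array(c, float)) for c in [[-1, 0], [0, 3], [1, 0]]])
        profile = RERGProfile.basipetal(1.0, 0.4)  # all tips beyond the zone
        out, _ = extend_tips(t, m, 0.1, profile=profile)
        for n in t.positions:
            assert np.allclose(out.positions[n], t.positions[n])


class TestTransportMargin:
    def test_static_veins_identity(self, midvein_state):
        state, _ = midvein_state
        out = transport_margin(state.margin, state.veins, state.veins)
        assert np.allclose(out.positions(), state.margin.positions())

    def test_rigid_translation_moves_everything_equally(self, midvein_state):
        state, _ = midvein_state
        t = np.array([0.3, -0.2])
        moved = state.veins.copy()
        for n in moved.positions:
            moved.positions[n] = moved.positions[n] + t
        out = transport_margin(state.margin, state.veins, moved)
        disp = out.positions() - state.margin.positions()
        assert np.allclose(disp, t, atol=1e-12)

    def test_uniform_stretch_scales_projection_offsets(self, midvein_state):
        # vein stretched by 1.1 about its start: a point projecting at
        # parameter t moves by 0.1 * t * vein_vector
        state, _ = midvein_state
        stretched = state.veins.copy()
        tip = state.veins.vein_terminal[0]
        base = state.veins.base
        vec = state.veins.positions[tip] - base
        stretched.positions[tip] = base + 1.1 * vec
        out = transport_margin(state.margin, state.veins, stretched)
        pos0 = state.margin.positions()
        for i, p in enumerate(state.margin.points):
            if p.is_cp:
                continue
            t_par = np.clip((pos0[i] - base) @ vec / (vec @ vec), 0, 1)
            expected = 0.1 * t_par * vec
            assert np.allclose(out.positions()[i] - pos0[i], expected, atol=1e-9)


class TestNormalPropagation:
    def flat_margin(self):
        # interior below the top edge
        coords = [[0, 0], [0, 1], [1, 1], [2, 1], [3, 1], [3, 0]]
        return Margin([MarginPoint(position=np.array(c, float)) for c in coords])

    def test_zero_rate_identity(self):
        m = self.flat_margin()
        out = normal_propagation(m, 0.0, 1.0)
        assert np.allclose(out.positions(), m.positions())

    def test_straight_margin_moves_uniformly_outward(self):
        m = self.flat_margin()
        out = normal_propagation(m, 0.02, 1.0)
        disp = out.positions() - m.positions()
        for i in (2, 3):  # interior points of the straight top
            assert np.allclose(disp[i], [0, 0.02], atol=1e-12)
        assert np.allclose(disp[0], 0) and np.allclose(disp[-1], 0)

    def test_growth_factor_zero_freezes_petiole(self):
        m = self.flat_margin()
        rules = {"petiole": MorphogenRule(name="petiole", growth_factor=0.0)}
        for p in m.points:
            p.morphogens["petiole"] = 1.0
        out = normal_propagation(m, 0.02, 1.0, rules)
        assert np.allclose(out.positions(), m.positions())

    def test_negative_rates_rejected(self):
        m = self.flat_margin()
        with pytest.raises(ValueError):
            normal_propagation(m, 0.1, 1.0, rates=np.full(len(m.points), -1.0))


class TestIsotropicExpand:
    def test_zero_rate_identity(self, midvein_state):
        state, _ = midvein_state
        out = isotropic_expand(state, 0.0, 1.0)
        assert np.allclose(out.margin.positions(), state.margin.positions())

    def test_pairwise_distances_scale_exactly(self, midvein_state):
        state, _ = midvein_state
        out = isotropic_expand(state, 1.0, 0.1)
        p0 = state.margin.positions()
        p1 = out.margin.positions()
        d0 = np.linalg.norm(p0[:, None] - p0[None, :], axis=2)
        d1 = np.linalg.norm(p1[:, None] - p1[None, :], axis=2)
        assert np.allclose(d1, 1.1 * d0, rtol=1e-12)

    def test_margin_arc_lengths_scale_uniformly(self, midvein_state):
        state, _ = midvein_state
        out = isotropic_expand(state, 0.5, 0.2)
        r = out.margin.edge_lengths() / state.margin.edge_lengths()
        assert np.allclose(r, 1.1, rtol=1e-12)
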