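import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import leafmorph as lm
from leafmorph.core_model import (
    Margin,
    MarginPoint,
    MorphogenRule,
    UNREACHABLE,
    arc_length,
    outward_normals,
    resample_margin,
    vein_path_length,
)


def margin_from_xy(coords, **point_kw):
    return Margin([MarginPoint(position=np.array(c, dtype=float)) for c in coords])


# ---------------------------------------------------------------------------
# primordium construction
# ---------------------------------------------------------------------------

class TestMakePrimordium:
    def test_single_apical_convergence_point(self, midvein_state):
        state, _ = midvein_state
        cps = state.margin.cp_indices()
        assert len(cps) == 1
        apex = state.margin.points[cps[0]]
        assert apex.position[1] == max(p.position[1] for p in state.margin.points)

    def test_midvein_runs_base_to_apex(self, midvein_state):
        state, _ = midvein_state
        segs = state.veins.segments()
        assert len(segs) == 1
        assert np.allclose(segs[0].start, [0.0, 0.0])
        cp = state.margin.points[state.margin.cp_indices()[0]]
        assert np.allclose(segs[0].end, cp.position)

    def test_morphogen_painting_by_arc_fraction(self):
        params = lm.Params(
            lambda_cp=1.0,
            morphogens={"petiole": MorphogenRule(name="petiole")},
        )
        pts = np.array([[-1.0, 0.0], [-1.0, 2.0], [0.0, 3.0], [1.0, 2.0], [1.0, 0.0]])
        preset = lm.PrimordiumPreset(
            points=pts,
            apex_index=2,
            morphogen_intervals=[("petiole", 0.0, 0.1, 1.0), ("petiole", 0.9, 1.0, 1.0)],
        )
        state = lm.make_primordium(params, preset)
        painted = [p.has("petiole") for p in state.margin.points]
        # only the two base endpoints fall within 10% of arc length here
        assert painted == [True, False, False, False, True]

    def test_self_intersecting_preset_rejected(self):
        params = lm.Params(lambda_cp=1.0)
        pts = np.array([[-1.0, 0.0], [1.0, 2.0], [0.0, 3.0], [-1.0, 2.0], [1.0, 0.0]])
        preset = lm.PrimordiumPreset(points=pts, apex_index=2)
        with pytest.raises(ValueError, match="self-intersect"):
            lm.make_primordium(params, preset)

    def test_unknown_morphogen_in_preset_rejected(self):
        params = lm.Params(
            lambda_cp=1.0, morphogens={"petiole": MorphogenRule(name="petiole")}
        )
        pts = np.array([[-1.0, 0.0], [0.0, 3.0], [1.0, 0.0]])
        preset = lm.PrimordiumPreset(
            points=pts, apex_index=1, morphogen_intervals=[("nope", 0.0, 0.5, 1.0)]
        )
        with pytest.raises(ValueError, match="nope"):
            lm.make_primordium(params, preset)


# ---------------------------------------------------------------------------
# weighted arc length
# ---------------------------------------------------------------------------

class TestArcLength:
    def collinear(self):
        return margin_from_xy([[0.0, 0.0], [1.0, 0.0], [2.0, 0.0]])

    def test_euclidean_sum(self):
        assert arc_length(self.collinear(), 0, 2) == pytest.approx(2.0)

    def test_metric_factor_weights_edges(self):
        m = self.collinear()
        rules = {"slow": MorphogenRule(name="slow", metric_factor=0.5)}
        m.points[0].morphogens["slow"] = 1.0
        m.points[1].morphogens["slow"] = 1.0
        assert arc_length(m, 0, 2, rules) == pytest.approx(0.5 * 1 + 1.0)

    def test_barrier_blocks(self):
        m = self.collinear()
        rules = {"wall": MorphogenRule(name="wall", is_barrier=True)}
        m.points[1].morphogens["wall"] = 1.0
        assert arc_length(m, 0, 2, rules) == UNREACHABLE
        # the barrier endpoint itself stays reachable
        assert arc_length(m, 0, 1, rules) == pytest.approx(1.0)

    def test_index_validation(self):
        with pytest.raises(IndexError):
            arc_length(self.collinear(), 0, 5)

    @settings(max_examples=30, deadline=None)
    @given(
        xs=st.lists(st.floats(0.1, 2.0), min_size=4, max_size=10),
        facs=st.lists(st.floats(0.2, 3.0), min_size=10, max_size=10),
        split=st.data(),
    )
    def test_additivity(self, xs, facs, split):
        coords = np.cumsum([0.0] + xs)
        m = margin_from_xy([[x, 0.3 * (i % 2)] for i, x in enumerate(coords)])
        rules = {"m": MorphogenRule(name="m", metric_factor=1.7)}
        for p, f in zip(m.points, facs):
            if f > 1.5:
                p.morphogens["m"] = min(1.0, f / 3.0)
        n = len(m.points) - 1
        j = split.draw(st.integers(0, n))
        total = arc_length(m, 0, n, rules)
        assert arc_length(m, 0, j, rules) + arc_length(m, j, n, rules) == pytest.approx(
            total, rel=1e-12
        )

    def test_unweighted_equals_polyline_length(self, simple_final):
        m = simple_final.margin
        expected = float(np.sum(m.edge_lengths()))
        assert arc_length(m, 0, len(m.points) - 1, {}) == pytest.approx(
            expected, rel=1e-12
        )


# ---------------------------------------------------------------------------
# vein path length
# ---------------------------------------------------------------------------

class TestVeinPathLength:
    def build_tree(self):
        t = lm.VeinTree(base=np.array([0.0, 0.0]))
        vid = t.new_vein(t.root)
        tip = t.add_node(np.array([0.0, 4.0]), t.root, vid)
        t.vein_terminal[vid] = tip
        # lateral of length 1 attached at s = 3
        mid = t.split_edge(tip, np.array([0.0, 3.0]))
        lat = t.new_vein(mid)
        ltip = t.add_node(np.array([1.0, 3.0]), mid, lat)
        t.vein_terminal[lat] = ltip
        return t

    def test_base_is_zero(self):
        t = self.build_tree()
        assert vein_path_length(t, np.array([0.0, 0.0])) == 0.0

    def test_midpoint_of_midvein(self):
        t = self.build_tree()
        assert vein_path_length(t, np.array([0.0, 2.0])) == pytest.approx(2.0)

    def test_lateral_tip_additivity(self):
        t = self.build_tree()
        assert vein_path_length(t, np.array([1.0, 3.0])) == pytest.approx(4.0)

    def test_off_tree_point_rejected(self):
        t = self.build_tree()
        with pytest.raises(ValueError, match="not on the vein tree"):
            vein_path_length(t, np.array([2.0, 1.0]))


# ---------------------------------------------------------------------------
# resampling and normals
# ---------------------------------------------------------------------------

class TestResample:
    def test_long_edges_split_and_short_merged(self):
        coords = [[0, 0], [0.05, 0], [0.07, 0], [1.2, 0], [1.2, 1]]
        m = margin_from_xy(coords)
        out = resample_margin(m, h_max=0.5, h_min=0.04)
        lengths = out.edge_lengths()
        assert np.all(lengths <= 0.5 + 1e-12)
        # the 0.02-long middle edge is merged away
        assert len(out.points) == 5 + 2 + 1 - 1

    def test_convergence_points_survive(self):
        m = margin_from_xy([[0, 0], [0.01, 0], [1, 0], [1, 1]])
        m.points[1].is_cp = True
        out = resample_margin(m, h_max=10.0, h_min=0.5)
        assert sum(p.is_cp for p in out.points) == 1

    def test_split_children_interpolate_morphogens(self):
        m = margin_from_xy([[0, 0], [1, 0], [2, 0]])
        m.points[0].morphogens["m"] = 1.0
        m.points[1].morphogens["m"] = 1.0
        out = resample_margin(m, h_max=0.5)
        strengths = [p.morphogens.get("m", 0.0) for p in out.points]
        # fully inside the painted edge -> full strength; outside -> fades
        assert strengths[1] == pytest.approx(1.0)
        assert strengths[0] == 1.0 and strengths[-1] == 0.0

    def test_mirror_symmetric_margin_stays_symmetric(self):
        coords = [[-1, 0], [-1.1, 1], [-0.4, 2.1], [0, 2.7], [0.4, 2.1], [1.1, 1], [1, 0]]
        m = margin_from_xy(coords)
        out = resample_margin(m, h_max=0.3, h_min=0.1)
        pos = out.positions()
        assert np.allclose(pos, pos[::-1] * [-1, 1], atol=1e-12)


class TestOutwardNormals:
    def test_straight_top_margin_points_up(self):
        # margin along the top, base edge below: outward is +y
        m = margin_from_xy([[0, 1], [1, 1], [2, 1], [2, 0], [0, 0]])
        # reorder as open polyline from (0,0) over the top to (2,0)
        m = margin_from_xy([[0, 0], [0, 1], [1, 1], [2, 1], [2, 0]])
        normals = outward_normals(m)
        assert np.allclose(normals[2], [0, 1], atol=1e-12)

    def test_unit_length(self, simple_final):
        n = outward_normals(simple_final.margin)
        assert np.allclose(np.linalg.norm(n, axis=1), 1.0, atol=1e-9)
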