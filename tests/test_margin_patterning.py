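import numpy as np
import pytest

import leafmorph as lm
from leafmorph.core_model import Margin, MarginPoint, MorphogenRule, OnInsertion
from leafmorph.margin_patterning import (
    InsertionSite,
    apply_insertion_morphogen_rules,
    cp_permitted_mask,
    delta_ball,
    find_insertion_sites,
    insert_convergence_point,
    leaflet_intervals,
    margin_intervals,
)


def chain_margin(n=21, spacing=0.1):
    """Horizontal chain with the interior below; endpoints are the base."""
    pts = [MarginPoint(position=np.array([i * spacing, 1.0])) for i in range(n)]
    pts[0].position = np.array([0.0, 0.0])
    pts[-1].position = np.array([(n - 1) * spacing, 0.0])
    return Margin(pts)


def params_with(lambda_cp=1.0, delta_seg=0.25, rules=None, **kw):
    return lm.Params(
        lambda_cp=lambda_cp, delta_seg=delta_seg, morphogens=rules or {}, **kw
    )


def veins_at_origin():
    return lm.VeinTree(base=np.array([1.0, 0.0]))


class TestFindInsertionSites:
    def test_interval_below_threshold_yields_nothing(self):
        m = chain_margin(n=11, spacing=0.1)  # arc about 2.3; lambda bigger
        params = params_with(lambda_cp=3.0)
        assert find_insertion_sites(m, veins_at_origin(), params, 0.0) == []

    def test_interval_above_threshold_sites_midpoint(self):
        m = chain_margin(n=21, spacing=0.1)
        params = params_with(lambda_cp=1.0)
        sites = find_insertion_sites(m, veins_at_origin(), params, 0.0)
        assert len(sites) == 1
        mid = sites[0].index
        # weighted midpoint of the single interval, up to sampling
        assert abs(mid - 10) <= 1

    def test_blocking_morphogen_suppresses_insertion(self):
        m = chain_margin(n=21, spacing=0.1)
        rules = {"sinus": MorphogenRule(name="sinus", blocks_cp=True)}
        for p in m.points:
            p.morphogens["sinus"] = 1.0
        params = params_with(lambda_cp=0.5, rules=rules)
        assert find_insertion_sites(m, veins_at_origin(), params, 0.0) == []

    def test_permitting_morphogen_restricts_insertion(self):
        m = chain_margin(n=21, spacing=0.1)
        rules = {"go": MorphogenRule(name="go", permits_cp=True)}
        for p in m.points[3:9]:
            p.morphogens["go"] = 1.0
        params = params_with(lambda_cp=0.3, rules=rules)
        sites = find_insertion_sites(m, veins_at_origin(), params, 0.0)
        assert sites and 3 <= sites[0].index <= 8

    def test_age_competence_window_closes(self):
        m = chain_margin(n=21, spacing=0.1)
        params = params_with(lambda_cp=1.0)
        params.competence = lm.Competence(max_age=1.0)
        assert find_insertion_sites(m, veins_at_origin(), params, 0.5)
        assert find_insertion_sites(m, veins_at_origin(), params, 2.0) == []

    def test_base_distance_window(self):
        m = chain_margin(n=21, spacing=0.1)
        params = params_with(lambda_cp=1.0)
        params.competence = lm.Competence(max_base_distance=0.1)
        assert find_insertion_sites(m, veins_at_origin(), params, 0.0) == []


class TestDeltaBall:
    def test_zero_radius_is_just_the_point(self):
        m = chain_margin()
        assert delta_ball(m, 10, 0.0) == [10]

    def test_symmetric_ball(self):
        m = chain_margin(n=21, spacing=0.1)
        got = delta_ball(m, 10, 0.3 + 1e-9)
        assert got == [7, 8, 9, 10, 11, 12, 13]

    def test_ball_clipped_at_existing_cp(self):
        m = chain_margin(n=21, spacing=0.1)
        m.points[12].is_cp = True
        got = delta_ball(m, 10, 0.3 + 1e-9)
        assert got == [7, 8, 9, 10, 11]

    def test_ball_clipped_at_barrier(self):
        m = chain_margin(n=21, spacing=0.1)
        rules = {"wall": MorphogenRule(name="wall", is_barrier=True)}
        m.points[8].morphogens["wall"] = 1.0
        got = delta_ball(m, 10, 0.3 + 1e-9, rules)
        assert got == [9, 10, 11, 12, 13]


class TestInsertConvergencePoint:
    def test_insertion_flags_point_and_assigns_segment(self):
        m = chain_margin(n=21, spacing=0.1)
        params = params_with(lambda_cp=1.0, delta_seg=0.2 + 1e-9)
        sites = find_insertion_sites(m, veins_at_origin(), params, 0.0)
        out, assigned = insert_convergence_point(m, sites[0], params)
        idx = sites[0].index
        assert out.points[idx].is_cp
        assert assigned == [idx - 2, idx - 1, idx, idx + 1, idx + 2]

    def test_double_insertion_rejected(self):
        m = chain_margin()
        m.points[10].is_cp = True
        site = InsertionSite(10, (0, 20), "base", "base", 2.0, 1.0)
        with pytest.raises(ValueError, match="already"):
            insert_convergence_point(m, site, params_with())


class TestInsertionMorphogenRules:
    def rules(self, rho_r=0.25, bmin=0.35, bmax=0.55):
        return {
            "red": MorphogenRule(
                name="red", on_insertion=OnInsertion(rho_r=rho_r)
            ),
            "blue": MorphogenRule(
                name="blue", on_insertion=OnInsertion(rho_bmin=bmin, rho_bmax=bmax)
            ),
        }

    def test_exclusion_and_introduction_bands(self):
        m = chain_margin(n=21, spacing=0.1)
        for p in m.points:
            p.morphogens["red"] = 1.0
        out, introduced = apply_insertion_morphogen_rules(m, 10, self.rules())
        assert introduced == ["blue"]
        # red removed strictly within 0.25 of the CP
        assert "red" not in out.points[10].morphogens
        assert "red" not in out.points[9].morphogens
        assert "red" in out.points[13].morphogens
        # blue set strictly inside (0.35, 0.55): distances 0.4, 0.5
        blue = [i for i, p in enumerate(out.points) if "blue" in p.morphogens]
        assert blue == [5, 6, 14, 15]

    def test_empty_open_band_introduces_nothing(self):
        m = chain_margin()
        rules = {
            "blue": MorphogenRule(
                name="blue", on_insertion=OnInsertion(rho_bmin=0.3, rho_bmax=0.3)
            )
        }
        out, introduced = apply_insertion_morphogen_rules(m, 10, rules)
        assert introduced == []
        assert not any("blue" in p.morphogens for p in out.points)

    def test_band_does_not_cross_another_cp(self):
        m = chain_margin(n=21, spacing=0.1)
        m.points[13].is_cp = True
        out, _ = apply_insertion_morphogen_rules(m, 10, self.rules())
        blue = [i for i, p in enumerate(out.points) if "blue" in p.morphogens]
        assert blue == [5, 6]  # nothing beyond the CP at 13

    def test_rule_competence_window_gates_introduction(self):
        m = chain_margin()
        rules = self.rules()
        rules["blue"].competence = lm.Competence(max_age=1.0)
        _, late = apply_insertion_morphogen_rules(m, 10, rules, age=2.0)
        assert late == []
        _, early = apply_insertion_morphogen_rules(m, 10, rules, age=0.5)
        assert early == ["blue"]


class TestIntervals:
    def test_margin_intervals_anchors(self):
        m = chain_margin(n=11)
        m.points[5].is_cp = True
        rules = {"wall": MorphogenRule(name="wall", is_barrier=True)}
        m.points[8].morphogens["wall"] = 1.0
        ivs = margin_intervals(m, rules)
        assert ivs == [
            (0, 5, "base", "cp"),
            (5, 8, "cp", "barrier"),
            (8, 10, "barrier", "base"),
        ]

    def test_leaflet_intervals_collapse_barrier_runs(self):
        m = chain_margin(n=21)
        rules = {"wall": MorphogenRule(name="wall", is_barrier=True)}
        for i in (6, 7, 14):
            m.points[i].morphogens["wall"] = 1.0
        m.points[10].is_cp = True
        ivs = leaflet_intervals(m, rules)
        assert [(a, b) for a, b, _ in ivs] == [(0, 6), (7, 14), (14, 20)]
        assert ivs[1][2] == [10]
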