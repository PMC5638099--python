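"""Growth: vein elongation, tip extension, blade expansion, margin transport.

Vein elongation follows the relative elementary rate of growth (RERG),

    RERG(P) = dl / (l dt),

taken to be a piecewise-linear function of the arc-length distance s of
point P from the leaf base, measured along the vasculature.  The
elongation of a finite segment [s1, s2] over a step dt is the line
integral dt * int_{s1}^{s2} RERG(s) ds, evaluated analytically per linear
piece.  Growth preserves vein orientation; subtrees distal to a growth
zone do not elongate but are displaced by the growing proximal part.

The margin is carried by the veins: each margin point is projected
orthographically onto its associated vein (in the before-step geometry)
and displaced by the same vector as its projection.  Growth in width is a
separate normal-direction propagation, and the isotropic component is a
uniform scaling about the leaf base.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core_model import LeafState, Margin, MorphogenRule, VeinTree

__all__ = [
    "RERGProfile",
    "rerg_at",
    "segment_elongation",
    "elongate_veins",
    "extend_tips",
    "transport_margin",
    "normal_propagation",
    "isotropic_expand",
]


@dataclass
class RERGProfile:
    """Piecewise-linear growth-rate profile along the vasculature.

    ``breakpoints`` are strictly ascending arc distances from the base;
    ``rates`` are RERG values (1/time) at those distances.  Beyond the last
    breakpoint the rate is held constant at the last value, so a basipetal
    growth zone ends its profile with rate 0.
    """

    breakpoints: np.ndarray
    rates: np.ndarray

    def __post_init__(self) -> None:
        self.breakpoints = np.atleast_1d(np.asarray(self.breakpoints, dtype=float))
        self.rates = np.atleast_1d(np.asarray(self.rates, dtype=float))
        if self.breakpoints.shape != self.rates.shape:
            raise ValueError("breakpoints and rates must have equal length")
        if len(self.breakpoints) == 0:
            raise ValueError("profile needs at least one breakpoint")
        if np.any(np.diff(self.breakpoints) <= 0):
            raise ValueError("breakpoints must be strictly ascending")
        if np.any(self.rates < 0):
            raise ValueError("rates must be >= 0")

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, RERGProfile):
            return NotImplemented
        return np.array_equal(self.breakpoints, other.breakpoints) and np.array_equal(
            self.rates, other.rates
        )

    @classmethod
    def uniform(cls, rate: float) -> "RERGProfile":
        return cls(np.array([0.0]), np.array([float(rate)]))

    @classmethod
    def basipetal(cls, rate: float, zone: float) -> "RERGProfile":
        """Rate ``rate`` at the base falling linearly to 0 at distance ``zone``."""
        return cls(np.array([0.0, float(zone)]), np.array([float(rate), 0.0]))


def rerg_at(profile: RERGProfile, s: float | np.ndarray) -> float | np.ndarray:
    """RERG at arc distance(s) s >= 0 from the base (constant extrapolation)."""
    res = np.interp(s, profile.breakpoints, profile.rates)
    return float(res) if np.isscalar(s) else res


def segment_elongation(
    profile: RERGProfile, s1: float, s2: float, dt: float
) -> float:
    """Added length of the vein segment [s1, s2] over one step.

    dt times the integral of the piecewise-linear profile, computed exactly
    with the trapezoid rule on the union of segment endpoints and profile
    knots.
    """
    if not 0 <= s1 <= s2:
        raise ValueError("need 0 <= s1 <= s2")
    if s1 == s2:
        return 0.0
    inner = profile.breakpoints[
        (profile.breakpoints > s1) & (profile.breakpoints < s2)
    ]
    knots = np.concatenate([[s1], inner, [s2]])
    vals = rerg_at(profile, knots)
    return float(dt * np.trapezoid(vals, knots))


def elongate_veins(veins: VeinTree, profile: RERGProfile, dt: float) -> VeinTree:
    """Grow every vein segment by its RERG integral, preserving orientation.

    Positions are updated root-to-leaf: each node's new position is its
    parent's new position plus the (unchanged) segment direction times the
    new segment length, so distal subtrees ride rigidly on growing
    proximal segments.
    """
    out = veins.copy()
    s = veins.s_coords()
    for n in veins.nodes_base_first():
        p = veins.parent[n]
        if p is None:
            continue
        old_a, old_b = veins.positions[p], veins.positions[n]
        length = float(np.linalg.norm(old_b - old_a))
        if length == 0.0:
            out.positions[n] = out.positions[p].copy()
            continue
        direction = (old_b - old_a) / length
        added = segment_elongation(profile, s[p], s[n], dt)
        out.positions[n] = out.positions[p] + direction * (length + added)
    return out


def extend_tips(
    veins: VeinTree,
    margin: Margin,
    tip_growth: float,
    profile: RERGProfile | None = None,
) -> tuple[VeinTree, Margin]:
    """Advance every vein terminal by ``tip_growth`` along its direction.

    The convergence point mapped to each terminal moves with it, keeping
    the coincidence invariant.  With ``profile`` given, the marginal (tip)
    growth follows the same spatial distribution as vein elongation: the
    added length is scaled by the profile value at the tip relative to its
    maximum, so tips outside a basipetal growth zone stop extending.
    """
    if tip_growth == 0.0:
        return veins, margin
    out = veins.copy()
    m = margin.copy()
    s = veins.s_coords() if profile is not None else None
    peak = float(np.max(profile.rates)) if profile is not None else 1.0
    for vid, tip in veins.vein_terminal.items():
        parent = veins.parent[tip]
        if parent is None:
            continue
        a, b = veins.positions[parent], veins.positions[tip]
        length = float(np.linalg.norm(b - a))
        if length == 0.0:
            continue
        direction = (b - a) / length
        added = tip_growth
        if profile is not None and peak > 0:
            added *= float(rerg_at(profile, s[tip])) / peak
        new_tip = b + added * direction
        out.positions[tip] = new_tip
        uid = veins.terminal_map.get(vid)
        if uid is not None:
            m.points[m.index_of_uid(uid)].position = new_tip.copy()
    return out, m


def _project_onto_polyline(
    points: np.ndarray, poly: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Orthographic projection of points onto a polyline.

    Returns (segment index, clamped parameter t within that segment) for
    each point; projections beyond the polyline extent clamp to the
    nearest endpoint.
    """
    a = poly[:-1]  # (m, 2)
    d = poly[1:] - a
    dd = np.einsum("ij,ij->i", d, d)
    dd[dd == 0] = 1.0
    # t for every (point, segment) pair
    w = points[:, None, :] - a[None, :, :]
    t = np.clip(np.einsum("pij,ij->pi", w, d) / dd[None, :], 0.0, 1.0)
    proj = a[None, :, :] + t[:, :, None] * d[None, :, :]
    dist2 = np.sum((points[:, None, :] - proj) ** 2, axis=2)
    seg = np.argmin(dist2, axis=1)
    rows = np.arange(len(points))
    return seg, t[rows, seg]


def transport_margin(
    margin: Margin, veins_before: VeinTree, veins_after: VeinTree
) -> Margin:
    """Carry margin points with their associated veins.

    Each point is projected perpendicularly onto its vein's polyline in the
    before geometry; projections beyond the vein clamp to the nearest
    endpoint (for the proximal end this is the attachment/branching point).
    The point is then displaced by its projection's before-to-after
    displacement.  Convergence points snap exactly onto their terminal's
    new position; points with no associated vein move with the (fixed)
    base, i.e. not at all.

    Adjacent points carried by different veins receive (slightly)
    different displacements; if that shear would fold the margin onto
    itself, the displacement field is smoothed along the margin (a 1-2-1
    kernel, leaving rigid translations exact) until the margin is simple
    again.
    """
    out = margin.copy()
    pos = margin.positions()
    disp = np.zeros_like(pos)

    # group margin points by vein id
    by_vein: dict[int, list[int]] = {}
    for i, p in enumerate(margin.points):
        if p.vein_id is not None:
            by_vein.setdefault(p.vein_id, []).append(i)

    for vid, idxs in by_vein.items():
        if vid not in veins_before.vein_terminal:
            continue
        path = veins_before.vein_node_path(vid)[::-1]  # attach -> tip
        poly_before = np.array([veins_before.positions[n] for n in path])
        poly_after = np.array([veins_after.positions[n] for n in path])
        pts = pos[idxs]
        seg, t = _project_onto_polyline(pts, poly_before)
        before = poly_before[seg] + t[:, None] * (
            poly_before[seg + 1] - poly_before[seg]
        )
        after = poly_after[seg] + t[:, None] * (poly_after[seg + 1] - poly_after[seg])
        disp[idxs] = after - before

    cp_idx = {}
    for vid, uid in veins_after.terminal_map.items():
        tip = veins_after.positions[veins_after.vein_terminal[vid]]
        i = out.index_of_uid(uid)
        cp_idx[i] = tip

    def apply(d: np.ndarray) -> None:
        for i, p in enumerate(out.points):
            p.position = pos[i] + d[i]
        # CPs coincide with their terminals exactly
        for i, tip in cp_idx.items():
            out.points[i].position = tip.copy()

    apply(disp)
    for _ in range(8):
        if out.is_simple():
            break
        disp[1:-1] = 0.25 * disp[:-2] + 0.5 * disp[1:-1] + 0.25 * disp[2:]
        apply(disp)
    return out


def normal_propagation(
    margin: Margin,
    base_rate: float,
    dt: float,
    rules: dict[str, MorphogenRule] | None = None,
    rates: np.ndarray | None = None,
    cp_taper: float | None = None,
) -> Margin:
    """Move margin points outward along their discrete normals.

    The per-point speed is ``base_rate`` times the product of the
    ``growth_factor`` of the morphogens active there (or explicit
    ``rates``).  Base endpoints stay fixed; convergence points are pinned
    to their vein tips and are not moved here either.  With ``cp_taper``
    set, the speed ramps linearly from 0 at each convergence point to full
    at arc distance ``cp_taper`` (protrusion tips advance with their veins,
    the flanks by normal growth); displacements are additionally capped at
    a fraction of the local edge length so the margin cannot fold over a
    pinned tip in one step.
    """
    from .core_model import outward_normals  # local import to avoid cycle noise

    n = len(margin.points)
    if rates is None:
        rates = np.full(n, float(base_rate))
        if rules:
            for i, p in enumerate(margin.points):
                f = 1.0
                for name, s in p.morphogens.items():
                    rule = rules.get(name)
                    if rule is not None and s > 0:
                        f *= 1.0 + s * (rule.growth_factor - 1.0)
                rates[i] *= f
    rates = np.asarray(rates, dtype=float)
    if np.any(rates < 0):
        raise ValueError("normal propagation rates must be >= 0")
    if not np.any(rates > 0) or dt == 0:
        return margin.copy()

    normals = outward_normals(margin)
    out = margin.copy()
    pos = margin.positions()
    speed = rates * dt

    if cp_taper is not None and cp_taper > 0:
        cps = margin.cp_indices()
        if cps:
            seg = np.linalg.norm(np.diff(pos, axis=0), axis=1)
            cum = np.concatenate([[0.0], np.cumsum(seg)])
            d_cp = np.min(
                np.abs(cum[:, None] - cum[np.asarray(cps)][None, :]), axis=1
            )
            speed = speed * np.clip(d_cp / cp_taper, 0.0, 1.0)

    # numerical guard: never move a point by more than a fraction of its
    # shortest adjacent edge in a single step
    seg = np.linalg.norm(np.diff(pos, axis=0), axis=1)
    local = np.minimum(
        np.concatenate([[seg[0]], seg]), np.concatenate([seg, [seg[-1]]])
    )
    speed = np.minimum(speed, 0.3 * local)

    move = speed[:, None] * normals
    move[0] = 0.0
    move[-1] = 0.0
    for i, p in enumerate(out.points):
        if p.is_cp:
            move[i] = 0.0

    # back off (halve the displacement) if outward motion would close a
    # narrow sinus onto itself and self-intersect the margin
    scale = 1.0
    for _ in range(8):
        out.set_positions(pos + scale * move)
        if out.is_simple():
            return out
        scale *= 0.5
    out.set_positions(pos)
    return out


def isotropic_expand(state: LeafState, iso_rate: float, dt: float) -> LeafState:
    """Scale every position by (1 + iso_rate * dt) about the leaf base."""
    if iso_rate < 0:
        raise ValueError("iso_rate must be >= 0")
    factor = 1.0 + iso_rate * dt
    if factor == 1.0:
        return state.copy()
    out = state.copy()
    base = state.veins.base.copy()
    for p in out.margin.points:
        p.position = base + factor * (p.position - base)
    for n in out.veins.positions:
        out.veins.positions[n] = base + factor * (out.veins.positions[n] - base)
    if out.mesh is not None:
        out.mesh.vertices = base + factor * (out.mesh.vertices - base)
    return out
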