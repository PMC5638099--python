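"""Shape descriptors of simulated leaves.

All descriptors are invariant under rigid motions, and the normalized ones
(aspect ratio, symmetry score, angles) also under uniform scaling.  The
proximo-distal axis is taken as the initial midvein direction (+y by the
package's coordinate convention).
"""

from __future__ import annotations

import math

import numpy as np
from shapely.geometry import LineString, Polygon

from .core_model import Margin, VeinTree, cross2

__all__ = [
    "aspect_ratio",
    "sinus_depths",
    "mean_sinus_depth",
    "count_lobes",
    "symmetry_score",
    "branching_angles",
    "widest_point_fraction",
    "blade_length",
]

AXIS = np.array([1.0, 0.0]), np.array([0.0, 1.0])  # (width, length) directions


def blade_length(margin: Margin, axis: np.ndarray | None = None) -> float:
    axis = np.array([0.0, 1.0]) if axis is None else np.asarray(axis, dtype=float)
    proj = margin.positions() @ axis
    return float(proj.max() - proj.min())


def aspect_ratio(margin: Margin, axis: np.ndarray | None = None) -> float:
    """Width : length ratio; length along the initial midvein axis."""
    axis = np.array([0.0, 1.0]) if axis is None else np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    perp = np.array([-axis[1], axis[0]])
    pos = margin.positions()
    along = pos @ axis
    length = float(along.max() - along.min())
    width = float((pos @ perp).max() - (pos @ perp).min())
    if length <= 0:
        raise ValueError("degenerate margin: zero extent along the axis")
    return width / length


def sinus_depths(margin: Margin, veins: VeinTree | None = None) -> list[float]:
    """Maximal inward deviation from the chord, per inter-CP interval.

    The inward side is determined by the margin orientation (the interior
    lies to the left of the direction of travel for a counter-clockwise
    margin).  Convex or outward-bulging intervals report depth 0.
    """
    cps = margin.cp_indices()
    if len(cps) < 2:
        return []
    pos = margin.positions()
    # for a CCW margin the interior lies to the left of the chord direction
    inward_sign = 1.0 if margin.signed_area() > 0 else -1.0
    out = []
    for a, b in zip(cps[:-1], cps[1:]):
        chord = pos[b] - pos[a]
        L = np.linalg.norm(chord)
        if L == 0 or b - a < 2:
            out.append(0.0)
            continue
        rel = pos[a + 1 : b] - pos[a]
        # signed perpendicular offset; inward = toward the blade interior
        off = inward_sign * cross2(chord / L, rel)
        out.append(float(max(0.0, np.max(off))))
    return out


def mean_sinus_depth(margin: Margin) -> float:
    depths = sinus_depths(margin)
    return float(np.mean(depths)) if depths else 0.0


def count_lobes(
    margin: Margin, veins: VeinTree | None = None, depth_threshold: float = 0.1
) -> int:
    """Protrusions whose two bounding sinus depths both exceed
    ``depth_threshold`` x blade length."""
    depths = sinus_depths(margin, veins)
    if len(depths) < 2:
        return 0
    thr = depth_threshold * blade_length(margin)
    return sum(
        1 for d1, d2 in zip(depths[:-1], depths[1:]) if d1 > thr and d2 > thr
    )


def _resample_polyline(pos: np.ndarray, k: int) -> np.ndarray:
    seg = np.linalg.norm(np.diff(pos, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    t = np.linspace(0.0, cum[-1], k)
    x = np.interp(t, cum, pos[:, 0])
    y = np.interp(t, cum, pos[:, 1])
    return np.column_stack([x, y])


def symmetry_score(margin: Margin, k: int = 256) -> float:
    """Mean distance between the margin and its mirror image about the
    midvein axis (x = base x), under arc-length correspondence, normalized
    by the bounding-box diagonal."""
    pos = margin.positions()
    base_x = 0.5 * (pos[0, 0] + pos[-1, 0])
    sampled = _resample_polyline(pos, k)
    mirrored = pos[::-1].copy()
    mirrored[:, 0] = 2 * base_x - mirrored[:, 0]
    mirrored_sampled = _resample_polyline(mirrored, k)
    diag = margin.bbox_diagonal()
    if diag == 0:
        return 0.0
    return float(np.mean(np.linalg.norm(sampled - mirrored_sampled, axis=1))) / diag


def branching_angles(veins: VeinTree, attachments_only: bool = True) -> list[float]:
    """Angle (degrees) between each vein segment and its parent segment.

    With ``attachments_only`` (default) only true branchings are reported:
    segment pairs belonging to different veins, i.e. the angle at which an
    inserted vein meets the vein it attaches to.
    """
    out = []
    for n, p in veins.parent.items():
        if p is None or veins.parent[p] is None:
            continue
        g = veins.parent[p]
        if attachments_only and veins.edge_vein[n] == veins.edge_vein[p]:
            continue
        d_child = veins.positions[n] - veins.positions[p]
        d_parent = veins.positions[p] - veins.positions[g]
        nc, npar = np.linalg.norm(d_child), np.linalg.norm(d_parent)
        if nc == 0 or npar == 0:
            continue
        c = float(np.clip(d_child @ d_parent / (nc * npar), -1.0, 1.0))
        out.append(math.degrees(math.acos(c)))
    return out


def widest_point_fraction(
    margin: Margin, levels: int = 128, band: float = 0.95
) -> float:
    """Relative proximo-distal position (0 = base, 1 = tip) of the widest
    part of the blade polygon.

    The blade is sliced horizontally at ``levels`` heights; the reported
    position is the width-weighted mean height of the slices whose width is
    within ``band`` of the maximum, which is robust to flat-topped width
    profiles.
    """
    pos = margin.positions()
    poly = Polygon(pos)
    if not poly.is_valid:
        poly = poly.buffer(0)
    y0, y1 = pos[:, 1].min(), pos[:, 1].max()
    if y1 <= y0:
        raise ValueError("degenerate margin")
    x0, x1 = pos[:, 0].min() - 1.0, pos[:, 0].max() + 1.0
    ys = np.linspace(y0 + 1e-9, y1 - 1e-9, levels)
    widths = np.array(
        [poly.intersection(LineString([(x0, y), (x1, y)])).length for y in ys]
    )
    sel = widths >= band * widths.max()
    y_star = float(np.sum(ys[sel] * widths[sel]) / np.sum(widths[sel]))
    return (y_star - y0) / (y1 - y0)
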