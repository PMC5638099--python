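"""Hofmeister-rule patterning of convergence points on the margin.

A new convergence point (CP) forms when a margin interval bounded by
existing CPs, the petiole-base endpoints, or barrier points exceeds the
threshold weighted arc length lambda.  The CP is placed at the weighted
midpoint of the longest CP-permitted run of the interval, snapped to the
nearest sample point.  Insertion may be restricted by morphogens
(blocking/permitting), by a spatial window of distance from the leaf base,
and by a temporal competence window of leaf age.

Each insertion triggers morphogen bookkeeping: a rule may remove its
morphogen near the new CP (within rho_r) and introduce it in a band
(rho_bmin, rho_bmax), measured as weighted arc distance along the margin.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .core_model import (
    Competence,
    Margin,
    MorphogenRule,
    Params,
    VeinTree,
    weighted_edge_lengths,
)

__all__ = [
    "InsertionSite",
    "find_insertion_sites",
    "insert_convergence_point",
    "apply_insertion_morphogen_rules",
    "cp_permitted_mask",
    "margin_intervals",
]


@dataclass
class InsertionSite:
    index: int  # margin point index of the candidate CP
    interval: tuple[int, int]  # bounding anchor indices
    left_anchor: str  # 'cp' | 'base' | 'barrier'
    right_anchor: str
    weighted_length: float  # weighted length of the permitted run
    base_distance: float  # straight-line distance of the candidate from base


def cp_permitted_mask(
    margin: Margin, rules: dict[str, MorphogenRule]
) -> np.ndarray:
    """Per-point permission for CP insertion.

    A point is blocked where any ``blocks_cp`` morphogen is active.  If any
    rule declares ``permits_cp``, insertion is additionally restricted to
    points where at least one permitting morphogen is present.
    """
    blockers = [n for n, r in rules.items() if r.blocks_cp]
    permitters = [n for n, r in rules.items() if r.permits_cp]
    mask = np.ones(len(margin.points), dtype=bool)
    for i, p in enumerate(margin.points):
        if any(p.has(n) for n in blockers):
            mask[i] = False
        elif permitters and not any(p.has(n) for n in permitters):
            mask[i] = False
    return mask


def margin_intervals(
    margin: Margin, rules: dict[str, MorphogenRule]
) -> list[tuple[int, int, str, str]]:
    """Maximal intervals bounded by CPs, base endpoints, or barrier points.

    Returns (left index, right index, left kind, right kind) tuples; kinds
    are 'cp', 'base' or 'barrier'.
    """
    n = len(margin.points)
    kind: dict[int, str] = {0: "base", n - 1: "base"}
    for i in margin.barrier_indices(rules):
        kind.setdefault(i, "barrier")
    for i in margin.cp_indices():
        kind[i] = "cp"  # a CP that is also a barrier bounds as a CP
    anchors = sorted(kind)
    out = []
    for a, b in zip(anchors[:-1], anchors[1:]):
        if b > a:
            out.append((a, b, kind[a], kind[b]))
    return out


def _permitted_runs(
    permitted: np.ndarray, a: int, b: int
) -> list[tuple[int, int]]:
    """Maximal runs [i, j] of permitted interior points within interval (a, b).

    Anchor points themselves delimit but do not belong to runs; a run of a
    single point has zero length but can still host no insertion, so only
    runs of >= 2 edges... (length is measured over the edges joining
    consecutive permitted points).
    """
    runs = []
    i = a + 1
    while i < b:
        if permitted[i]:
            j = i
            while j + 1 < b and permitted[j + 1]:
                j += 1
            runs.append((i, j))
            i = j + 1
        else:
            i += 1
    return runs


def find_insertion_sites(
    margin: Margin,
    veins: VeinTree,
    params: Params,
    age: float,
) -> list[InsertionSite]:
    """Candidate CP insertion sites, best first.

    For each maximal interval, the longest CP-permitted run is measured in
    weighted arc length; if it exceeds lambda and the midpoint candidate
    passes the competence window, a site is reported.  Sites are ordered by
    descending run length, then by proximity to the base along the margin
    (left side first on exact ties).
    """
    rules = params.morphogens
    permitted = cp_permitted_mask(margin, rules)
    wlen = weighted_edge_lengths(margin, rules)  # per edge
    cum = np.concatenate([[0.0], np.cumsum(wlen)])
    total = cum[-1]
    sites: list[InsertionSite] = []
    base = veins.base

    for a, b, ka, kb in margin_intervals(margin, rules):
        for i, j in _permitted_runs(permitted, a, b):
            if j <= i:
                continue
            run_len = cum[j] - cum[i]
            if not run_len > params.lambda_cp:
                continue
            # weighted midpoint of the run, snapped to the nearest sample
            target = cum[i] + 0.5 * run_len
            k = int(np.argmin(np.abs(cum[i : j + 1] - target))) + i
            ties = np.flatnonzero(
                np.abs(np.abs(cum[i : j + 1] - target) - abs(cum[k] - target))
                < 1e-12 * max(total, 1.0)
            )
            if len(ties) > 1:
                # mirror-invariant tie-break: higher point, then smaller |x|
                cand = [int(t) + i for t in ties]
                cand.sort(
                    key=lambda m: (
                        -margin.points[m].position[1],
                        abs(margin.points[m].position[0]),
                        margin.points[m].position[0],
                    )
                )
                k = cand[0]
            if margin.points[k].is_cp or not permitted[k]:
                continue
            dist = float(np.linalg.norm(margin.points[k].position - base))
            if not params.competence.admits(dist, age):
                continue
            sites.append(
                InsertionSite(
                    index=k,
                    interval=(a, b),
                    left_anchor=ka,
                    right_anchor=kb,
                    weighted_length=float(run_len),
                    base_distance=dist,
                )
            )

    sites.sort(
        key=lambda s: (
            -s.weighted_length,
            min(cum[s.index], total - cum[s.index]),
            s.index,
        )
    )
    return sites


def leaflet_intervals(
    margin: Margin, rules: dict[str, MorphogenRule]
) -> list[tuple[int, int, list[int]]]:
    """Maximal margin intervals between barrier bands (or base endpoints).

    Contiguous runs of barrier points are collapsed into single separators.
    Returns (start, end, CP indices inside) per interval; on a compound
    leaf each leaflet is one such interval carrying its own convergence
    point(s).
    """
    bars = sorted(margin.barrier_indices(rules))
    runs: list[list[int]] = []
    for b in bars:
        if runs and b <= runs[-1][1] + 1:
            runs[-1][1] = b
        else:
            runs.append([b, b])
    cps = margin.cp_indices()
    out = []
    prev = 0
    bounds = runs + [[len(margin.points) - 1, len(margin.points) - 1]]
    for lo, hi in bounds:
        if lo > prev:
            inside = [c for c in cps if prev < c < lo]
            out.append((prev, lo, inside))
        prev = hi
    return out


def delta_ball(
    margin: Margin,
    idx: int,
    delta: float,
    rules: dict[str, MorphogenRule] | None = None,
) -> list[int]:
    """Indices within weighted arc distance delta of ``idx``.

    The ball never crosses an existing convergence point or a barrier
    point (the bounding CP/barrier itself is excluded).  The centre is
    always included.
    """
    rules = rules or {}
    wlen = weighted_edge_lengths(margin, rules)
    barriers = margin.barrier_indices(rules)
    n = len(margin.points)
    out = [idx]
    d = 0.0
    i = idx
    while i > 0:
        d += wlen[i - 1]
        i -= 1
        if d > delta or margin.points[i].is_cp or i in barriers:
            break
        out.append(i)
    d = 0.0
    i = idx
    while i < n - 1:
        d += wlen[i]
        i += 1
        if d > delta or margin.points[i].is_cp or i in barriers:
            break
        out.append(i)
    return sorted(out)


def insert_convergence_point(
    margin: Margin, site: InsertionSite, params: Params
) -> tuple[Margin, list[int]]:
    """Flag the site as a convergence point.

    Returns the updated margin and the indices of the points (within
    weighted arc distance delta of the CP) that form the margin segment of
    the vein to be created; the vein id itself is assigned when the vein is
    attached.
    """
    point = margin.points[site.index]
    if point.is_cp:
        raise ValueError(f"margin point {site.index} is already a convergence point")
    out = margin.copy()
    out.points[site.index].is_cp = True
    assigned = delta_ball(out, site.index, params.delta_seg, params.morphogens)
    return out, assigned


def apply_insertion_morphogen_rules(
    margin: Margin,
    new_cp: int,
    rules: dict[str, MorphogenRule],
    age: float = 0.0,
    base_distance: float = 0.0,
) -> tuple[Margin, list[str]]:
    """Morphogen bookkeeping around a newly inserted convergence point.

    For every rule: remove the morphogen from points at weighted arc
    distance < rho_r from the CP and set it (strength 1) at distances
    strictly inside (rho_bmin, rho_bmax).  Distances are measured along the
    margin and stop at barrier points and at other convergence points, so
    the bookkeeping stays local to the intervals flanking the new CP.  A
    rule with its own competence window only *introduces* its morphogen
    while the window admits the CP.  Returns the margin and the names
    actually introduced somewhere.
    """
    out = margin.copy()
    dists = _weighted_distances_from(out, new_cp, rules)
    other_cp = {i for i in out.cp_indices() if i != new_cp}
    introduced: list[str] = []
    for name, rule in rules.items():
        ins = rule.on_insertion
        if ins.rho_r > 0:
            for i, d in enumerate(dists):
                if i in other_cp:
                    continue  # bookkeeping never rewrites another CP
                if d < ins.rho_r and name in out.points[i].morphogens:
                    del out.points[i].morphogens[name]
        if ins.rho_bmax > ins.rho_bmin:
            window = rule.competence or Competence()
            if window.admits(base_distance, age):
                hit = False
                for i, d in enumerate(dists):
                    if i in other_cp:
                        continue
                    if ins.rho_bmin < d < ins.rho_bmax:
                        out.points[i].morphogens[name] = 1.0
                        hit = True
                if hit:
                    introduced.append(name)
    return out, introduced


def _weighted_distances_from(
    margin: Margin, idx: int, rules: dict[str, MorphogenRule]
) -> np.ndarray:
    """Weighted arc distance of every point from ``idx``.

    Distances past a barrier point or another convergence point are
    infinite (the bounding point itself stays reachable).
    """
    wlen = weighted_edge_lengths(margin, rules)
    cum = np.concatenate([[0.0], np.cumsum(wlen)])
    d = np.abs(cum - cum[idx])
    stops = set(margin.barrier_indices(rules))
    stops.update(i for i in margin.cp_indices() if i != idx)
    for b in stops:
        if b < idx:
            d[:b] = math.inf
        elif b > idx:
            d[b + 1 :] = math.inf
    return d
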