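"""Connecting new convergence points to the vasculature.

A new vein runs straight from a convergence point (CP) to an attachment
point P on the existing tree, chosen to minimize the total transport
resistance

    tau = b |CP - P| + v |P - B|,

where |P - B| is the arc-length path from P to the leaf base along the
veins and b >= v > 0 are the per-unit-length resistances of blade and
vein.  On the interior of a segment the minimizer meets the segment at the
constant branching angle theta = arccos(v/b); it is compared against the
segment endpoints and branching points.  Attachment is restricted to the
vein segments bordering the lamina face that contains the CP, so new
veins never cross existing ones.

A second heuristic clamps the angle sigma between the new vein and the
outward margin normal at the CP to [-sigma_max, sigma_max], preventing
veins from grazing the margin; when the clamp binds, the vein direction is
fixed at +/- sigma_max and attached where that ray first meets the
candidate segments (falling back to the unclamped optimum if it exits the
region).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from shapely.geometry import LinearRing, LineString

from ._planar import build_subdivision
from .core_model import LeafState, Margin, Params, cross2, outward_normals
from .margin_patterning import delta_ball

__all__ = [
    "AttachmentCandidate",
    "CandidateRegion",
    "candidate_region",
    "optimal_attachment",
    "attach_vein",
    "brute_force_attachment",
]

logger = logging.getLogger(__name__)


@dataclass
class AttachmentCandidate:
    kind: str  # 'interior' | 'node'
    location: np.ndarray
    path_to_base: float  # arc length from the attachment to the base
    tau: float
    edge: int | None = None  # child vein-node id of the host segment
    node: int | None = None  # vein node id when kind == 'node'
    clamped: bool = False

    def __post_init__(self) -> None:
        self.location = np.asarray(self.location, dtype=float)


@dataclass
class CandidateRegion:
    """Vein segments and branch points bordering the CP's lamina face."""

    # (child node id, prox node id, prox pos, dist pos, s at prox)
    segments: list[tuple[int, int, np.ndarray, np.ndarray, float]]
    # (node id, position, s)
    nodes: list[tuple[int, np.ndarray, float]]


def candidate_region(state: LeafState, cp_index: int) -> CandidateRegion:
    """Attachment candidates for the CP: the vein edges and vein nodes on
    the boundary of the lamina face containing it."""
    margin, veins = state.margin, state.veins
    point = margin.points[cp_index]
    if not point.is_cp:
        raise ValueError(f"margin point {cp_index} is not a convergence point")
    sub = build_subdivision(margin, veins)
    face = sub.face_of_margin_vertex(cp_index)

    s = veins.s_coords()
    terminal_nodes = set(veins.vein_terminal.values())
    seg_ids: set[int] = set()
    node_ids: set[int] = set()
    cyc = face.vertices
    m = len(cyc)
    # collect vein edges on the face boundary
    vertex_node = {}
    for vtx in cyc:
        if vtx[0] == "v":
            vertex_node[vtx] = vtx[1]
        elif vtx[0] == "b":
            vertex_node[vtx] = veins.root
    terminal_to_node = {
        margin.points[margin.index_of_uid(uid)].uid: veins.vein_terminal[vid]
        for vid, uid in veins.terminal_map.items()
    }
    for vtx in cyc:
        if vtx[0] == "m":
            uid = margin.points[vtx[1]].uid
            if uid in terminal_to_node:
                vertex_node[vtx] = terminal_to_node[uid]
    for k in range(m):
        a, b = cyc[k], cyc[(k + 1) % m]
        e = frozenset({a, b})
        child = sub.vein_edges.get(e)
        if child is not None:
            seg_ids.add(child)
            for vtx in (a, b):
                nid = vertex_node.get(vtx)
                if nid is not None and nid not in terminal_nodes:
                    node_ids.add(nid)

    if not seg_ids:
        raise ValueError(
            f"lamina face of margin point {cp_index} touches no vein "
            "(inconsistent state)"
        )

    segments = []
    for child in sorted(seg_ids):
        par = veins.parent[child]
        segments.append(
            (
                child,
                par,
                veins.positions[par].copy(),
                veins.positions[child].copy(),
                s[par],
            )
        )
    nodes = [(nid, veins.positions[nid].copy(), s[nid]) for nid in sorted(node_ids)]
    return CandidateRegion(segments=segments, nodes=nodes)


def _interior_minimizer(
    cp: np.ndarray,
    a: np.ndarray,
    bpos: np.ndarray,
    s_a: float,
    b: float,
    v: float,
) -> tuple[np.ndarray, float, float] | None:
    """Analytic tau minimizer on the interior of segment a->bpos.

    Returns (point, s, tau) or None when the stationary point falls outside
    the open segment.  The minimizer meets the segment at angle
    arccos(v/b) measured against the distal direction.
    """
    seg = bpos - a
    L = float(np.linalg.norm(seg))
    if L == 0 or b <= v:
        return None
    u = seg / L
    w = cp - a
    wu = float(w @ u)
    h = float(np.linalg.norm(w - wu * u))
    if h == 0:
        return None  # CP on the segment line: endpoints dominate
    t = wu - h * v / math.sqrt(b * b - v * v)
    if not 0.0 < t < L:
        return None
    p = a + t * u
    d = float(np.linalg.norm(cp - p))
    tau = b * d + v * (s_a + t)
    return p, s_a + t, tau


def optimal_attachment(
    cp: np.ndarray,
    region: CandidateRegion,
    b: float,
    v: float,
    sigma_max: float = 90.0,
    normal: np.ndarray | None = None,
    margin_ring: np.ndarray | None = None,
) -> AttachmentCandidate:
    """Resistance-minimizing attachment, with the margin-normal clamp.

    ``sigma_max`` is in degrees; ``normal`` is the outward margin normal at
    the CP (required for the clamp to act).  Ties between equal-tau
    candidates go to the shorter new vein, then to the more proximal
    attachment.  When ``margin_ring`` (margin positions) is given,
    candidates whose straight vein would cross the margin - possible when
    the lamina face is concave, e.g. across a deep sinus - are skipped in
    favour of the best feasible one.
    """
    cp = np.asarray(cp, dtype=float)
    cands: list[AttachmentCandidate] = []
    for child, par, a, bpos, s_a in region.segments:
        hit = _interior_minimizer(cp, a, bpos, s_a, b, v)
        if hit is not None:
            p, s_p, tau = hit
            cands.append(
                AttachmentCandidate(
                    kind="interior", location=p, path_to_base=s_p, tau=tau, edge=child
                )
            )
    for nid, p, s_p in region.nodes:
        tau = b * float(np.linalg.norm(cp - p)) + v * s_p
        cands.append(
            AttachmentCandidate(
                kind="node", location=p, path_to_base=s_p, tau=tau, node=nid
            )
        )
    if not cands:
        raise ValueError("empty candidate region")

    def key(c: AttachmentCandidate):
        return (c.tau, float(np.linalg.norm(cp - c.location)), c.path_to_base)

    def feasible(c: AttachmentCandidate) -> bool:
        return margin_ring is None or not _segment_crosses_ring(
            cp, c.location, margin_ring
        )

    cands.sort(key=key)
    best = next((c for c in cands if feasible(c)), None)
    if best is None:
        best = cands[0]  # all candidates cross; let attach_vein reject

    if normal is not None and sigma_max < 90.0:
        nvec = np.asarray(normal, dtype=float)
        nvec = nvec / np.linalg.norm(nvec)
        vein_dir = cp - best.location
        norm = np.linalg.norm(vein_dir)
        if norm > 0:
            cosang = float(np.clip(vein_dir @ nvec / norm, -1.0, 1.0))
            sigma = math.degrees(math.acos(cosang))
            if sigma > sigma_max:
                clamped = _clamped_attachment(cp, nvec, sigma_max, region, b, v)
                if clamped is not None and feasible(clamped):
                    clamped.clamped = True
                    return clamped
                logger.info("sigma clamp found no attachment; keeping optimum")
    return best


def _clamped_attachment(
    cp: np.ndarray,
    normal: np.ndarray,
    sigma_max: float,
    region: CandidateRegion,
    b: float,
    v: float,
) -> AttachmentCandidate | None:
    best: AttachmentCandidate | None = None
    for sign in (+1.0, -1.0):
        ang = math.radians(sign * sigma_max)
        ca, sa = math.cos(ang), math.sin(ang)
        rot = np.array([[ca, -sa], [sa, ca]])
        ray = -(rot @ normal)  # into the blade
        hit = _first_ray_hit(cp, ray, region)
        if hit is None:
            continue
        p, s_p, child = hit
        tau = b * float(np.linalg.norm(cp - p)) + v * s_p
        cand = AttachmentCandidate(
            kind="interior", location=p, path_to_base=s_p, tau=tau, edge=child
        )
        if best is None or cand.tau < best.tau:
            best = cand
    return best


def _first_ray_hit(
    origin: np.ndarray, direction: np.ndarray, region: CandidateRegion
) -> tuple[np.ndarray, float, int] | None:
    best_t = math.inf
    best = None
    for child, par, a, bpos, s_a in region.segments:
        seg = bpos - a
        denom = cross2(direction, seg)
        if abs(denom) < 1e-15:
            continue
        w = a - origin
        t_ray = cross2(w, seg) / denom
        t_seg = cross2(w, direction) / denom
        if t_ray > 1e-12 and -1e-12 <= t_seg <= 1 + 1e-12:
            if t_ray < best_t:
                t_clamp = float(np.clip(t_seg, 0.0, 1.0))
                p = a + t_clamp * seg
                s_p = s_a + t_clamp * float(np.linalg.norm(seg))
                best_t = t_ray
                best = (p, s_p, child)
    return best


def attach_vein(
    state: LeafState,
    cp_index: int,
    attachment: AttachmentCandidate,
    params: Params,
    assigned: list[int] | None = None,
) -> LeafState:
    """Create the straight vein from the attachment point to the CP.

    An interior attachment splits the host segment (arc-length coordinates
    are preserved because the split point lies on the segment).  Margin
    points within delta of the CP become associated with the new vein.
    """
    out = state.copy()
    margin, veins = out.margin, out.veins
    cp_point = margin.points[cp_index]
    if not cp_point.is_cp:
        raise ValueError("attachment target is not a convergence point")

    _check_no_crossing(state, cp_point.position, attachment.location)

    if attachment.kind == "interior":
        # snap to the host segment's endpoints to avoid zero-length splits
        child = attachment.edge
        par = veins.parent[child]
        eps = 1e-7 * max(margin.bbox_diagonal(), 1e-30)
        if np.linalg.norm(attachment.location - veins.positions[child]) <= eps:
            node = child
        elif np.linalg.norm(attachment.location - veins.positions[par]) <= eps:
            node = par
        else:
            node = veins.split_edge(child, attachment.location)
    else:
        node = attachment.node
    vid = veins.new_vein(node)
    tip = veins.add_node(cp_point.position, node, vid)
    veins.vein_terminal[vid] = tip
    veins.terminal_map[vid] = cp_point.uid

    if assigned is None:
        assigned = delta_ball(margin, cp_index, params.delta_seg, params.morphogens)
    for i in assigned:
        margin.points[i].vein_id = vid
    cp_point.vein_id = vid
    return out


def _segment_crosses_ring(
    a: np.ndarray, b: np.ndarray, ring_pos: np.ndarray
) -> bool:
    shrink = 1e-9
    inner = LineString([a + shrink * (b - a), b + shrink * (a - b)])
    return bool(inner.crosses(LinearRing(ring_pos)))


def _check_no_crossing(
    state: LeafState, cp: np.ndarray, attach: np.ndarray
) -> None:
    """New segments must not properly cross the margin or existing veins."""
    shrink = 1e-9
    inner = LineString(
        [cp + shrink * (attach - cp), attach + shrink * (cp - attach)]
    )
    ring = LinearRing(state.margin.positions())
    if inner.crosses(ring):
        raise ValueError("new vein would cross the leaf margin")
    for seg in state.veins.segments():
        other = LineString([seg.start, seg.end])
        if inner.crosses(other):
            raise ValueError("new vein would cross an existing vein")


def brute_force_attachment(
    cp: np.ndarray,
    region: CandidateRegion,
    b: float,
    v: float,
    n_samples: int = 100_000,
) -> float:
    """Independent oracle: minimum tau over a dense scan of the candidate
    segments (plus the explicit node candidates)."""
    cp = np.asarray(cp, dtype=float)
    taus = [b * float(np.linalg.norm(cp - p)) + v * s for _, p, s in region.nodes]
    total = sum(
        float(np.linalg.norm(bpos - a)) for _, _, a, bpos, _ in region.segments
    )
    for _, _, a, bpos, s_a in region.segments:
        L = float(np.linalg.norm(bpos - a))
        if L == 0:
            continue
        k = max(2, int(round(n_samples * L / max(total, 1e-30))))
        t = np.linspace(0.0, L, k)
        pts = a[None, :] + (t / L)[:, None] * (bpos - a)[None, :]
        d = np.linalg.norm(cp[None, :] - pts, axis=1)
        taus.append(float(np.min(b * d + v * (s_a + t))))
    return min(taus)
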