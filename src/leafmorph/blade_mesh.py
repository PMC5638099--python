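"""Conforming triangle mesh of the lamina.

The mesh spans the region bounded by the margin (closed by the base edge)
and contains every margin and vein edge as a mesh edge.  It is built by
ear-clipping each bounded face of the planar subdivision formed by the
margin and the vein tree, optionally refined by longest-edge bisection of
interior edges, and deformed passively with the boundary by harmonic
(cotangent-Laplacian) interpolation of the boundary displacement.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from ._planar import build_subdivision
from .core_model import Margin, VeinTree, cross2

__all__ = ["BladeMesh", "triangulate_blade", "refine_mesh", "deform_blade"]

ROLE_MARGIN = "margin"
ROLE_VEIN = "vein"
ROLE_INTERIOR = "interior"


@dataclass
class BladeMesh:
    vertices: np.ndarray  # (V, 2)
    triangles: np.ndarray  # (T, 3) int, counter-clockwise
    roles: list[str]
    constraint_edges: set[frozenset]  # margin + vein edges, by vertex index
    #: provenance of each vertex: ('margin', uid) | ('vein', node id) |
    #: ('base',) | ('interior', serial)
    sources: list[tuple] = field(default_factory=list)

    def copy(self) -> "BladeMesh":
        return BladeMesh(
            vertices=self.vertices.copy(),
            triangles=self.triangles.copy(),
            roles=list(self.roles),
            constraint_edges=set(self.constraint_edges),
            sources=list(self.sources),
        )

    def triangle_areas(self) -> np.ndarray:
        a = self.vertices[self.triangles[:, 0]]
        b = self.vertices[self.triangles[:, 1]]
        c = self.vertices[self.triangles[:, 2]]
        return 0.5 * cross2(b - a, c - a)

    def area(self) -> float:
        return float(np.sum(self.triangle_areas()))

    def edges(self) -> set[frozenset]:
        out: set[frozenset] = set()
        for t in self.triangles:
            out.add(frozenset({int(t[0]), int(t[1])}))
            out.add(frozenset({int(t[1]), int(t[2])}))
            out.add(frozenset({int(t[2]), int(t[0])}))
        return out


# ---------------------------------------------------------------------------
# ear clipping
# ---------------------------------------------------------------------------

def _ear_clip(indices: list[int], pos: np.ndarray) -> list[tuple[int, int, int]]:
    """Triangulate a simple CCW polygon given by vertex indices into ``pos``."""
    idx = list(indices)
    tris: list[tuple[int, int, int]] = []
    guard = 0
    scale = np.ptp(pos[idx], axis=0).max()
    eps_area = 1e-12 * scale * scale

    while len(idx) > 3:
        n = len(idx)
        clipped = False
        for k in range(n):
            a, b, c = idx[(k - 1) % n], idx[k], idx[(k + 1) % n]
            pa, pb, pc = pos[a], pos[b], pos[c]
            cross = (pb[0] - pa[0]) * (pc[1] - pa[1]) - (pb[1] - pa[1]) * (
                pc[0] - pa[0]
            )
            if cross <= eps_area:  # reflex or collinear: not an ear
                continue
            others = [j for j in idx if j not in (a, b, c)]
            if others and _any_point_in_triangle(pos[others], pa, pb, pc):
                continue
            tris.append((a, b, c))
            idx.pop(k)
            clipped = True
            break
        if not clipped:
            # tolerance fallback: clip the most convex vertex anyway
            best_k, best_cross = None, -np.inf
            for k in range(n):
                a, b, c = idx[(k - 1) % n], idx[k], idx[(k + 1) % n]
                pa, pb, pc = pos[a], pos[b], pos[c]
                cross = (pb[0] - pa[0]) * (pc[1] - pa[1]) - (pb[1] - pa[1]) * (
                    pc[0] - pa[0]
                )
                if cross > best_cross:
                    best_cross, best_k = cross, k
            if best_k is None or best_cross <= 0:
                raise ValueError("ear clipping failed on a degenerate polygon")
            k = best_k
            a, b, c = idx[(k - 1) % n], idx[k], idx[(k + 1) % n]
            tris.append((a, b, c))
            idx.pop(k)
        guard += 1
        if guard > 10 * len(indices) + 100:
            raise ValueError("ear clipping did not terminate")
    a, b, c = idx
    tris.append((a, b, c))
    return tris


def _any_point_in_triangle(
    pts: np.ndarray, a: np.ndarray, b: np.ndarray, c: np.ndarray
) -> bool:
    d1 = cross2(b - a, pts - a)
    d2 = cross2(c - b, pts - b)
    d3 = cross2(a - c, pts - c)
    tol = -1e-12 * max(np.abs(d1).max(initial=1.0), 1.0)
    return bool(np.any((d1 >= tol) & (d2 >= tol) & (d3 >= tol)))


# ---------------------------------------------------------------------------
# construction
# ---------------------------------------------------------------------------

def triangulate_blade(margin: Margin, veins: VeinTree) -> BladeMesh:
    """Constrained triangulation of the blade.

    Every bounded face of the margin/vein planar subdivision is
    ear-clipped, so all margin and vein edges appear as mesh edges and no
    Steiner points are introduced (interior points only appear during
    refinement).
    """
    sub = build_subdivision(margin, veins)

    vertex_index: dict[tuple, int] = {}
    verts: list[np.ndarray] = []
    roles: list[str] = []
    sources: list[tuple] = []

    def get_index(v: tuple) -> int:
        if v in vertex_index:
            return vertex_index[v]
        k = len(verts)
        vertex_index[v] = k
        verts.append(np.asarray(sub.positions[v], dtype=float))
        if v[0] == "m":
            roles.append(ROLE_MARGIN)
            sources.append(("margin", margin.points[v[1]].uid))
        elif v[0] == "b":
            roles.append(ROLE_VEIN)
            sources.append(("base",))
        else:
            roles.append(ROLE_VEIN)
            sources.append(("vein", v[1]))
        return k

    triangles: list[tuple[int, int, int]] = []
    interior = sub.interior_faces()
    if not interior:
        raise ValueError("blade has no bounded face (degenerate margin)")
    for face in interior:
        idx = [get_index(v) for v in face.vertices]
        pos = np.array(verts)
        triangles.extend(_ear_clip(idx, pos))

    constraint: set[frozenset] = set()
    for e in sub.edges:
        a, b = tuple(e)
        constraint.add(frozenset({get_index(a), get_index(b)}))

    mesh = BladeMesh(
        vertices=np.array(verts),
        triangles=np.array(triangles, dtype=int),
        roles=roles,
        constraint_edges=constraint,
        sources=sources,
    )
    if np.any(mesh.triangle_areas() <= 0):
        raise ValueError("triangulation produced a non-positive-area triangle")
    return mesh


def refine_mesh(mesh: BladeMesh, max_edge: float) -> BladeMesh:
    """Bisect non-constraint edges until none is longer than ``max_edge``.

    Constraint (margin/vein) edges are never split here; they follow the
    margin/vein resampling instead.  Subdivision preserves total area.
    Bisection follows Rivara's longest-edge rule (refine the neighbor
    with the longer edge first), which terminates and keeps the cascade
    local.

    Guarantee: afterwards every non-constraint edge is no longer than
    ``max(max_edge, L)`` where L is the longest constraint edge of a
    triangle containing it, except in near-degenerate sliver triangles;
    the plain ``max_edge`` bound is impossible near longer constraint
    edges (the free edges of a triangle over a constraint edge of length
    L sum to at least L) and is recovered exactly when all constraint
    edges are at most ``max_edge`` and the mesh is non-degenerate.
    """
    out = mesh.copy()
    verts = [np.asarray(v, dtype=float) for v in out.vertices]
    tris: dict[int, tuple[int, int, int]] = {
        k: tuple(int(i) for i in t) for k, t in enumerate(out.triangles)
    }
    next_tid = len(tris)
    edge_map: dict[frozenset, set[int]] = {}
    for k, t in tris.items():
        for a, b in ((t[0], t[1]), (t[1], t[2]), (t[2], t[0])):
            edge_map.setdefault(frozenset({a, b}), set()).add(k)
    constraint = set(out.constraint_edges)

    def longest_free_edge(t: tuple[int, int, int]):
        """Longest non-constraint edge of a triangle (edge, length) or None.

        A free edge no longer than the triangle's longest constraint edge
        does not count: the two free edges of a triangle over a constraint
        edge of length L sum to at least L, so they cannot both be driven
        below L/2 without splitting the constraint edge, and splitting them
        further only degenerates the triangle.
        """
        best, best_len = None, -1.0
        blocked = 0.0
        for a, b in ((t[0], t[1]), (t[1], t[2]), (t[2], t[0])):
            e = frozenset({a, b})
            d = float(np.linalg.norm(verts[a] - verts[b]))
            if e in constraint:
                blocked = max(blocked, d)
            elif d > best_len:
                best, best_len = e, d
        if best is not None and best_len <= blocked:
            return None, best_len
        return best, best_len

    def split_edge(e: frozenset) -> list[int]:
        """Insert the midpoint of ``e`` and bisect every adjacent triangle."""
        nonlocal next_tid
        a, b = sorted(e)  # deterministic order
        m = len(verts)
        verts.append(0.5 * (verts[a] + verts[b]))
        out.roles.append(ROLE_INTERIOR)
        out.sources.append(("interior", m))
        children = []
        for tid in list(edge_map[e]):
            t = tris.pop(tid)
            for rep in (a, b):
                child = tuple(m if x == rep else x for x in t)
                cid = next_tid
                next_tid += 1
                tris[cid] = child
                children.append(cid)
                for u, v in ((child[0], child[1]), (child[1], child[2]), (child[2], child[0])):
                    edge_map.setdefault(frozenset({u, v}), set()).add(cid)
            for u, v in ((t[0], t[1]), (t[1], t[2]), (t[2], t[0])):
                edge_map[frozenset({u, v})].discard(tid)
        del edge_map[e]
        return children

    def tri_area(t: tuple[int, int, int]) -> float:
        a, b, c = (verts[i] for i in t)
        return 0.5 * float(cross2(b - a, c - a))

    scale = float(np.ptp(out.vertices, axis=0).max())
    eps_area = 1e-10 * scale * scale

    # Rivara-style longest-edge bisection: a too-long edge is split only
    # once it is the longest (splittable) edge of both adjacent triangles,
    # refining the worse neighbor first.  This keeps the bisection cascade
    # local and terminating, unlike naive global midpoint splitting.
    # Near-degenerate slivers (which arise next to flat corners and long
    # constraint edges, where bisection can only halve the area while
    # preserving the long edge) are left alone.
    stack = [tid for tid in tris]
    guard = 0
    while stack:
        guard += 1
        if guard > 200_000:
            raise ValueError("refinement did not terminate")
        tid = stack[-1]
        if tid not in tris:
            stack.pop()
            continue
        e, length = longest_free_edge(tris[tid])
        if e is None or length <= max_edge or abs(tri_area(tris[tid])) <= eps_area:
            stack.pop()
            continue
        neighbors = [n for n in edge_map[e] if n != tid]
        defer = None
        for n in neighbors:
            if abs(tri_area(tris[n])) <= eps_area:
                continue  # sliver neighbors are split alongside, never first
            ne, nlen = longest_free_edge(tris[n])
            if ne is not None and ne != e and nlen > length:
                defer = n
                break
        if defer is not None:
            stack.append(defer)
            continue
        stack.extend(split_edge(e))

    out.vertices = np.array(verts)
    out.triangles = np.array([tris[k] for k in sorted(tris)], dtype=int)
    return out


# ---------------------------------------------------------------------------
# passive deformation
# ---------------------------------------------------------------------------

def _cotangent_laplacian(mesh: BladeMesh) -> sp.csr_matrix:
    V = len(mesh.vertices)
    tri = mesh.triangles
    pos = mesh.vertices
    rows, cols, vals = [], [], []
    for k in range(3):
        i = tri[:, k]
        j = tri[:, (k + 1) % 3]
        o = tri[:, (k + 2) % 3]
        u = pos[i] - pos[o]
        w = pos[j] - pos[o]
        cross = cross2(u, w)
        cross = np.where(np.abs(cross) < 1e-30, 1e-30, cross)
        cot = np.einsum("ij,ij->i", u, w) / cross
        half = 0.5 * cot
        rows.extend([i, j])
        cols.extend([j, i])
        vals.extend([half, half])
    rows = np.concatenate(rows)
    cols = np.concatenate(cols)
    vals = np.concatenate(vals)
    W = sp.coo_matrix((vals, (rows, cols)), shape=(V, V)).tocsr()
    D = sp.diags(np.asarray(W.sum(axis=1)).ravel())
    return (D - W).tocsr()


def deform_blade(
    mesh: BladeMesh, margin_new: Margin, veins_new: VeinTree
) -> BladeMesh:
    """Move boundary/vein vertices to their new positions, interpolate the
    interior harmonically, and fall back to retriangulation on inversion.

    The cotangent Laplacian is assembled on the before-geometry, so zero
    boundary displacement is an exact fixed point and affine boundary maps
    are reproduced exactly.
    """
    out = mesh.copy()
    V = len(out.vertices)
    fixed = np.zeros(V, dtype=bool)
    target = out.vertices.copy()
    uid_to_idx = {p.uid: i for i, p in enumerate(margin_new.points)}
    for k, src in enumerate(out.sources):
        if src[0] == "margin":
            if src[1] not in uid_to_idx:
                raise ValueError("margin topology changed; retriangulate instead")
            target[k] = margin_new.points[uid_to_idx[src[1]]].position
            fixed[k] = True
        elif src[0] == "vein":
            target[k] = veins_new.positions[src[1]]
            fixed[k] = True
        elif src[0] == "base":
            target[k] = veins_new.base
            fixed[k] = True

    free = ~fixed
    if np.any(free):
        L = _cotangent_laplacian(mesh)
        Lff = L[free][:, free]
        Lfb = L[free][:, fixed]
        rhs = -Lfb @ target[fixed]
        target[free] = spla.spsolve(Lff.tocsc(), rhs)

    out.vertices = target
    if np.any(out.triangle_areas() <= 0):
        return triangulate_blade(margin_new, veins_new)
    return out
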