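"""Planar subdivision of the blade by the margin and the vein tree.

The closed margin (polyline plus base edge) and the vein tree form a
connected planar graph whose bounded faces are the lamina regions used
for triangulation and for restricting vein attachment.  Faces are
extracted combinatorially from the rotation system (counter-clockwise
ordering of edges around each vertex).

Graph vertices are tagged tuples:

* ``('m', i)``   margin sample point ``i``;
* ``('b',)``     the leaf base (vein root, on the base edge);
* ``('v', nid)`` an interior vein node.

Vein terminals are identified with their convergence-point margin
vertices, so every vein path touches the boundary at both ends and every
edge borders two faces.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .core_model import Margin, VeinTree

Vertex = tuple

__all__ = ["PlanarSubdivision", "build_subdivision"]


@dataclass
class Face:
    vertices: list[Vertex]  # closed cycle (first vertex not repeated)
    area: float


class PlanarSubdivision:
    def __init__(
        self,
        positions: dict[Vertex, np.ndarray],
        edges: set[frozenset],
        vein_edges: dict[frozenset, int],  # edge -> child vein-node id
    ):
        self.positions = positions
        self.edges = edges
        self.vein_edges = vein_edges
        self.adjacency: dict[Vertex, list[Vertex]] = {v: [] for v in positions}
        for e in edges:
            a, b = tuple(e)
            self.adjacency[a].append(b)
            self.adjacency[b].append(a)
        # rotation system: CCW angular order of neighbours
        self._order: dict[Vertex, list[Vertex]] = {}
        self._rank: dict[Vertex, dict[Vertex, int]] = {}
        for v, nbrs in self.adjacency.items():
            pv = positions[v]
            nbrs_sorted = sorted(
                nbrs,
                key=lambda w: math.atan2(
                    positions[w][1] - pv[1], positions[w][0] - pv[0]
                ),
            )
            self._order[v] = nbrs_sorted
            self._rank[v] = {w: k for k, w in enumerate(nbrs_sorted)}
        self.faces = self._trace_faces()

    def _next_dart(self, u: Vertex, v: Vertex) -> tuple[Vertex, Vertex]:
        """Dart following (u -> v) in the face with the interior on its left."""
        order = self._order[v]
        k = self._rank[v][u]
        w = order[(k - 1) % len(order)]  # next clockwise from u around v
        return (v, w)

    def _trace_faces(self) -> list[Face]:
        seen: set[tuple[Vertex, Vertex]] = set()
        faces = []
        darts = []
        for e in self.edges:
            a, b = tuple(e)
            darts.append((a, b))
            darts.append((b, a))
        for start in darts:
            if start in seen:
                continue
            cycle = []
            d = start
            while d not in seen:
                seen.add(d)
                cycle.append(d[0])
                d = self._next_dart(*d)
            pts = np.array([self.positions[v] for v in cycle])
            x, y = pts[:, 0], pts[:, 1]
            area = 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))
            faces.append(Face(vertices=cycle, area=area))
        return faces

    def interior_faces(self) -> list[Face]:
        return [f for f in self.faces if f.area > 0]

    def face_of_margin_vertex(self, i: int) -> Face:
        """The bounded lamina face on the interior side of margin point i."""
        # trace from the dart (i -> i+1); interior lies on its left for a
        # counter-clockwise margin
        target = ("m", i)
        nxt = ("m", i + 1) if ("m", i + 1) in self.positions else ("b",)
        d = (target, nxt)
        for f in self.faces:
            if f.area <= 0:
                continue
            cyc = f.vertices
            n = len(cyc)
            for k in range(n):
                if cyc[k] == target and cyc[(k + 1) % n] == nxt:
                    return f
        raise ValueError(f"no interior face adjacent to margin vertex {i}")


def build_subdivision(margin: Margin, veins: VeinTree) -> PlanarSubdivision:
    n = len(margin.points)
    positions: dict[Vertex, np.ndarray] = {}
    for i, p in enumerate(margin.points):
        positions[("m", i)] = p.position
    positions[("b",)] = veins.base

    # map vein nodes to graph vertices
    node_vertex: dict[int, Vertex] = {veins.root: ("b",)}
    terminal_to_uid = {
        veins.vein_terminal[vid]: uid for vid, uid in veins.terminal_map.items()
    }
    for nid in veins.positions:
        if nid == veins.root:
            continue
        if nid in terminal_to_uid:
            node_vertex[nid] = ("m", margin.index_of_uid(terminal_to_uid[nid]))
        else:
            node_vertex[nid] = ("v", nid)
            positions[("v", nid)] = veins.positions[nid]

    edges: set[frozenset] = set()
    vein_edges: dict[frozenset, int] = {}
    for i in range(n - 1):
        edges.add(frozenset({("m", i), ("m", i + 1)}))
    edges.add(frozenset({("m", n - 1), ("b",)}))
    edges.add(frozenset({("b",), ("m", 0)}))
    for nid, par in veins.parent.items():
        if par is None:
            continue
        e = frozenset({node_vertex[nid], node_vertex[par]})
        if len(e) < 2:
            raise ValueError(f"degenerate vein edge at node {nid}")
        edges.add(e)
        vein_edges[e] = nid
    return PlanarSubdivision(positions, edges, vein_edges)
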