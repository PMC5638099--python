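"""Shared domain types for the leaf-development simulator.

The developing leaf is represented by three coupled structures:

* an open polygonal *margin* (the marginal blastozone), which begins and
  ends at the two petiole-base endpoints and is closed by the base edge;
* a rooted *vein tree* of straight segments whose root sits at the leaf
  base and whose terminals coincide with convergence points (CPs) on the
  margin;
* a conforming triangle *mesh* spanning the blade (see
  :mod:`leafmorph.blade_mesh`).

Margin sample points carry named, graded morphogens in ``[0, 1]`` that
modulate patterning (CP permission), the local distance measure, outward
growth, and webbing.  Morphogens are abstract flags, not concentration
fields.

Coordinate convention: the leaf base is at the origin and the midvein
initially points along +y.  All lengths are dimensionless model units.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field, replace

import numpy as np
from shapely.geometry import LinearRing, LineString

__all__ = [
    "UNREACHABLE",
    "MarginPoint",
    "Margin",
    "VeinTree",
    "VeinSegment",
    "OnInsertion",
    "Competence",
    "MorphogenRule",
    "WebbingParams",
    "Params",
    "LeafState",
    "InsertionEvent",
    "PrimordiumPreset",
    "make_primordium",
    "arc_length",
    "vein_path_length",
    "resample_margin",
    "outward_normals",
    "metric_factors",
]

#: Sentinel returned by :func:`arc_length` when a barrier separates the
#: two indices (distances are measured independently within intervals).
UNREACHABLE = math.inf


def cross2(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """z-component of the cross product of 2-D vectors (broadcasting)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    return a[..., 0] * b[..., 1] - a[..., 1] * b[..., 0]

#: Morphogen strength above which boolean semantics (blocking, permitting,
#: barrier) consider the morphogen present.
ACTIVE_THRESHOLD = 0.5


# ---------------------------------------------------------------------------
# margin
# ---------------------------------------------------------------------------

@dataclass
class MarginPoint:
    """One sample point of the marginal blastozone."""

    position: np.ndarray
    is_cp: bool = False
    vein_id: int | None = None
    morphogens: dict[str, float] = field(default_factory=dict)
    birth_step: int = 0
    uid: int = -1

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        for name, s in self.morphogens.items():
            if not 0.0 <= s <= 1.0:
                raise ValueError(f"morphogen {name!r} strength {s} outside [0, 1]")

    def has(self, name: str) -> bool:
        """True if the morphogen is present at boolean (thresholded) level."""
        return self.morphogens.get(name, 0.0) >= ACTIVE_THRESHOLD

    def copy(self) -> "MarginPoint":
        return MarginPoint(
            position=self.position.copy(),
            is_cp=self.is_cp,
            vein_id=self.vein_id,
            morphogens=dict(self.morphogens),
            birth_step=self.birth_step,
            uid=self.uid,
        )


class Margin:
    """Open polyline of attributed sample points.

    The first and last points are the petiole-base endpoints; the polygon
    is closed (for simplicity checks, area and orientation) by the straight
    base edge joining them.  Points carry stable ``uid`` values so that
    convergence points can be tracked across resampling.
    """

    def __init__(self, points: list[MarginPoint]):
        if len(points) < 3:
            raise ValueError("margin needs at least 3 points")
        self.points: list[MarginPoint] = points
        self._next_uid = 0
        for p in self.points:
            if p.uid < 0:
                p.uid = self._next_uid
                self._next_uid += 1
            else:
                self._next_uid = max(self._next_uid, p.uid + 1)

    # -- construction helpers ------------------------------------------------

    def new_uid(self) -> int:
        uid = self._next_uid
        self._next_uid += 1
        return uid

    def copy(self) -> "Margin":
        m = Margin.__new__(Margin)
        m.points = [p.copy() for p in self.points]
        m._next_uid = self._next_uid
        return m

    # -- basic queries ---------------------------------------------------------

    def __len__(self) -> int:
        return len(self.points)

    def positions(self) -> np.ndarray:
        return np.array([p.position for p in self.points], dtype=float)

    def set_positions(self, pos: np.ndarray) -> None:
        for p, xy in zip(self.points, np.asarray(pos, dtype=float)):
            p.position = xy.copy()

    def index_of_uid(self, uid: int) -> int:
        for i, p in enumerate(self.points):
            if p.uid == uid:
                return i
        raise KeyError(f"no margin point with uid {uid}")

    def cp_indices(self) -> list[int]:
        return [i for i, p in enumerate(self.points) if p.is_cp]

    def barrier_indices(self, rules: dict[str, "MorphogenRule"]) -> set[int]:
        """Indices of points carrying an active barrier morphogen.

        Derived from point attributes rather than stored, so it stays
        consistent across resampling and insertion.
        """
        barrier_names = {n for n, r in rules.items() if r.is_barrier}
        if not barrier_names:
            return set()
        return {
            i
            for i, p in enumerate(self.points)
            if any(p.has(n) for n in barrier_names)
        }

    def bbox_diagonal(self) -> float:
        pos = self.positions()
        return float(np.linalg.norm(pos.max(axis=0) - pos.min(axis=0)))

    def eps_geom(self) -> float:
        """Coincidence tolerance: 1e-9 of the current bounding-box diagonal."""
        return 1e-9 * max(self.bbox_diagonal(), 1e-30)

    def signed_area(self) -> float:
        pos = self.positions()
        x, y = pos[:, 0], pos[:, 1]
        return 0.5 * float(
            np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y)
        )

    def is_simple(self) -> bool:
        """Simplicity of the polygon closed by the base edge."""
        pos = self.positions()
        try:
            ring = LinearRing(pos)
        except Exception:
            return False
        return bool(ring.is_valid and ring.is_simple)

    def edge_lengths(self) -> np.ndarray:
        pos = self.positions()
        return np.linalg.norm(np.diff(pos, axis=0), axis=1)


# ---------------------------------------------------------------------------
# veins
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VeinSegment:
    """Straight vein segment (one edge of the tree), reported in base-to-tip
    orientation with arc-length coordinates measured from the leaf base."""

    id: int  # child-node id identifying the edge
    parent_id: int | None
    start: np.ndarray  # proximal endpoint (closer to base)
    end: np.ndarray  # distal endpoint
    s_start: float
    vein_id: int

    @property
    def length(self) -> float:
        return float(np.linalg.norm(self.end - self.start))

    @property
    def s_end(self) -> float:
        return self.s_start + self.length


class VeinTree:
    """Rooted tree of straight vein segments.

    Nodes are points; each non-root node defines the segment from its
    parent to itself.  A *vein* is the chain of segments created when one
    convergence point was connected to the vasculature; splitting an edge
    at a later attachment keeps both halves in the original vein.
    """

    def __init__(self, base: np.ndarray):
        base = np.asarray(base, dtype=float)
        self.root = 0
        self.positions: dict[int, np.ndarray] = {0: base.copy()}
        self.parent: dict[int, int | None] = {0: None}
        self.edge_vein: dict[int, int] = {}  # child node id -> vein id
        self.vein_terminal: dict[int, int] = {}  # vein id -> terminal node id
        self.vein_attach: dict[int, int] = {}  # vein id -> attachment node id
        self.terminal_map: dict[int, int] = {}  # vein id -> margin point uid
        self._next_node = 1
        self._next_vein = 0

    @property
    def base(self) -> np.ndarray:
        return self.positions[self.root]

    def copy(self) -> "VeinTree":
        t = VeinTree.__new__(VeinTree)
        t.root = self.root
        t.positions = {k: v.copy() for k, v in self.positions.items()}
        t.parent = dict(self.parent)
        t.edge_vein = dict(self.edge_vein)
        t.vein_terminal = dict(self.vein_terminal)
        t.vein_attach = dict(self.vein_attach)
        t.terminal_map = dict(self.terminal_map)
        t._next_node = self._next_node
        t._next_vein = self._next_vein
        return t

    # -- construction ---------------------------------------------------------

    def add_node(self, position: np.ndarray, parent: int, vein_id: int) -> int:
        nid = self._next_node
        self._next_node += 1
        self.positions[nid] = np.asarray(position, dtype=float).copy()
        self.parent[nid] = parent
        self.edge_vein[nid] = vein_id
        return nid

    def new_vein(self, attach_node: int) -> int:
        vid = self._next_vein
        self._next_vein += 1
        self.vein_attach[vid] = attach_node
        return vid

    def split_edge(self, child: int, point: np.ndarray) -> int:
        """Insert a node on the segment parent(child) -> child; returns it."""
        parent = self.parent[child]
        if parent is None:
            raise ValueError("cannot split above the root")
        vid = self.edge_vein[child]
        mid = self.add_node(point, parent, vid)
        self.parent[child] = mid
        return mid

    # -- queries --------------------------------------------------------------

    def children(self) -> dict[int, list[int]]:
        ch: dict[int, list[int]] = {n: [] for n in self.positions}
        for n, p in self.parent.items():
            if p is not None:
                ch[p].append(n)
        for lst in ch.values():
            lst.sort()
        return ch

    def nodes_base_first(self) -> list[int]:
        """Node ids in a root-to-leaf (topological) order."""
        order: list[int] = []
        ch = self.children()
        stack = [self.root]
        while stack:
            n = stack.pop()
            order.append(n)
            stack.extend(reversed(ch[n]))
        return order

    def s_coords(self) -> dict[int, float]:
        """Arc-length distance of every node from the base, along the tree."""
        s: dict[int, float] = {}
        for n in self.nodes_base_first():
            p = self.parent[n]
            if p is None:
                s[n] = 0.0
            else:
                s[n] = s[p] + float(
                    np.linalg.norm(self.positions[n] - self.positions[p])
                )
        return s

    def segments(self) -> list[VeinSegment]:
        s = self.s_coords()
        out = []
        for n, p in self.parent.items():
            if p is None:
                continue
            out.append(
                VeinSegment(
                    id=n,
                    parent_id=p,
                    start=self.positions[p].copy(),
                    end=self.positions[n].copy(),
                    s_start=s[p],
                    vein_id=self.edge_vein[n],
                )
            )
        out.sort(key=lambda seg: seg.id)
        return out

    def vein_node_path(self, vein_id: int) -> list[int]:
        """Nodes of one vein, listed tip-to-attachment."""
        path = [self.vein_terminal[vein_id]]
        attach = self.vein_attach[vein_id]
        while path[-1] != attach:
            n = path[-1]
            if self.edge_vein.get(n) != vein_id:
                raise ValueError(f"vein {vein_id} path broken at node {n}")
            path.append(self.parent[n])  # type: ignore[arg-type]
        return path

    def vein_polyline(self, vein_id: int) -> np.ndarray:
        """Vein geometry as an (n, 2) polyline from attachment to tip."""
        path = self.vein_node_path(vein_id)[::-1]
        return np.array([self.positions[n] for n in path])

    def terminals(self) -> list[int]:
        has_child = set(p for p in self.parent.values() if p is not None)
        return [n for n in self.positions if n not in has_child and n != self.root]

    def total_length(self) -> float:
        return sum(seg.length for seg in self.segments())

    def is_acyclic_connected(self) -> bool:
        seen = set()
        for n in self.positions:
            m: int | None = n
            path = set()
            while m is not None and m not in seen:
                if m in path:
                    return False
                path.add(m)
                m = self.parent[m]
            if m is None and self.root not in path and n != self.root:
                return False
            seen |= path
        return True


def vein_path_length(veins: VeinTree, point: np.ndarray, eps: float | None = None) -> float:
    """Arc length along the tree from a point on the vasculature to the base.

    The point must lie on some segment (within ``eps``; default
    1e-9 x tree extent).
    """
    point = np.asarray(point, dtype=float)
    segs = veins.segments()
    if eps is None:
        pos = np.array(list(veins.positions.values()))
        extent = np.linalg.norm(pos.max(axis=0) - pos.min(axis=0)) if len(pos) > 1 else 1.0
        eps = 1e-9 * max(extent, 1e-30)
    if np.linalg.norm(point - veins.base) <= eps:
        return 0.0
    best = None
    best_d = math.inf
    for seg in segs:
        d, t = _point_segment(point, seg.start, seg.end)
        if d < best_d:
            best_d, best = d, seg.s_start + t * seg.length
    if best is None or best_d > eps:
        raise ValueError(f"point {point} is not on the vein tree (distance {best_d:g})")
    return float(best)


def _point_segment(p: np.ndarray, a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Distance from p to segment ab and the clamped parameter t in [0,1]."""
    ab = b - a
    denom = float(ab @ ab)
    t = 0.0 if denom == 0.0 else float(np.clip((p - a) @ ab / denom, 0.0, 1.0))
    return float(np.linalg.norm(p - (a + t * ab))), t


# ---------------------------------------------------------------------------
# parameters
# ---------------------------------------------------------------------------

@dataclass
class OnInsertion:
    """How a morphogen reacts when a new convergence point is inserted.

    The morphogen is removed from points at weighted arc distance < ``rho_r``
    from the new CP, and introduced at distances strictly inside
    ``(rho_bmin, rho_bmax)``.
    """

    rho_r: float = 0.0
    rho_bmin: float = 0.0
    rho_bmax: float = 0.0

    def __post_init__(self) -> None:
        if self.rho_r < 0:
            raise ValueError("rho_r must be >= 0")
        if not 0 <= self.rho_bmin <= self.rho_bmax:
            raise ValueError("need 0 <= rho_bmin <= rho_bmax")


@dataclass
class Competence:
    """Spatio-temporal window in which an event may happen.

    Distances are measured from the leaf base; ages in time units
    (step x dt)."""

    max_base_distance: float = math.inf
    min_base_distance: float = 0.0
    max_age: float = math.inf

    def admits(self, base_distance: float, age: float) -> bool:
        return (
            self.min_base_distance <= base_distance <= self.max_base_distance
            and age <= self.max_age
        )


@dataclass
class MorphogenRule:
    """Behaviour attached to one named morphogen."""

    name: str
    blocks_cp: bool = False
    permits_cp: bool = False
    webbing_factor: float = 1.0
    metric_factor: float = 1.0
    growth_factor: float = 1.0
    is_barrier: bool = False
    on_insertion: OnInsertion = field(default_factory=OnInsertion)
    competence: Competence | None = None  # window for on_insertion introduction

    def __post_init__(self) -> None:
        if self.webbing_factor < 0 or self.growth_factor < 0:
            raise ValueError("webbing_factor and growth_factor must be >= 0")
        if self.metric_factor <= 0:
            raise ValueError("metric_factor must be > 0")


@dataclass
class WebbingParams:
    """Geometric-fairing weights for the margin."""

    stretch: float = 1.0
    bend: float = 0.0
    iterations: int = 10
    asym: float = 1.0  # proximal/distal stretch ratio around each CP
    relaxation: float = 1.0  # rest length = current x (1 - relaxation)

    def __post_init__(self) -> None:
        if self.stretch < 0 or self.bend < 0:
            raise ValueError("webbing weights must be >= 0")
        if self.iterations < 0:
            raise ValueError("iterations must be >= 0")
        if self.asym <= 0:
            raise ValueError("asym must be > 0")


@dataclass
class Params:
    """Full parameter vector for one simulation run."""

    lambda_cp: float = 0.6  # Hofmeister insertion threshold (arc length)
    delta_seg: float = 0.1  # radius of the margin segment tied to a new CP
    tip_growth: float = 0.01  # new vein length added at each tip per step
    iso_rate: float = 0.0  # isotropic blade expansion rate (1/time)
    normal_rate: float = 0.0  # base outward margin propagation speed
    b: float = 2.0  # blade transport resistance per unit length
    v: float = 1.0  # vein transport resistance per unit length
    sigma_max: float = 90.0  # clamp half-angle vs margin normal (degrees)
    dt: float = 0.1
    n_steps: int = 100
    rerg_profile: "RERGProfile | None" = None  # default: uniform rate 0
    tip_growth_follows_zone: bool = False  # scale tip growth by the profile
    webbing: WebbingParams = field(default_factory=WebbingParams)
    competence: Competence = field(default_factory=Competence)
    morphogens: dict[str, MorphogenRule] = field(default_factory=dict)
    h_max: float | None = None  # margin resampling: split edges above this
    h_min: float | None = None  # merge edges below this (0 disables)
    mesh_every: int = 1  # rebuild the blade mesh every k steps
    mesh_max_edge: float | None = None  # optional interior refinement

    def __post_init__(self) -> None:
        if not (self.b >= self.v > 0):
            raise ValueError("need b >= v > 0")
        if self.lambda_cp <= 0:
            raise ValueError("lambda must be > 0")
        if not 0 < self.sigma_max <= 90.0:
            raise ValueError("sigma_max must be in (0, 90] degrees")
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        if self.h_max is None:
            self.h_max = self.lambda_cp / 10.0
        if self.h_min is None:
            self.h_min = self.h_max / 4.0
        for name, rule in self.morphogens.items():
            if rule.name != name:
                raise ValueError(
                    f"morphogen rule key {name!r} does not match rule.name {rule.name!r}"
                )

    @property
    def theta(self) -> float:
        """Preferred branching angle arccos(v/b), in radians."""
        return math.acos(self.v / self.b)

    def copy(self) -> "Params":
        return copy.deepcopy(self)


# ---------------------------------------------------------------------------
# state
# ---------------------------------------------------------------------------

@dataclass
class InsertionEvent:
    """Record of one convergence-point insertion (for analysis and tests)."""

    step: int
    age: float
    cp_uid: int
    position: np.ndarray
    left_anchor: str  # 'cp' | 'base' | 'barrier'
    right_anchor: str
    morphogens_introduced: list[str] = field(default_factory=list)


@dataclass
class LeafState:
    margin: Margin
    veins: VeinTree
    mesh: "BladeMesh | None" = None
    step: int = 0
    dt: float = 0.1
    events: list[InsertionEvent] = field(default_factory=list)

    @property
    def age(self) -> float:
        return self.step * self.dt

    def copy(self) -> "LeafState":
        return LeafState(
            margin=self.margin.copy(),
            veins=self.veins.copy(),
            mesh=self.mesh.copy() if self.mesh is not None else None,
            step=self.step,
            dt=self.dt,
            events=list(self.events),
        )

    def check_invariants(self, rules: dict[str, MorphogenRule] | None = None,
                         stage: str = "") -> None:
        """Assert margin simplicity, tree shape, and CP/terminal coincidence."""
        where = f" after stage {stage!r}" if stage else ""
        if not self.margin.is_simple():
            raise AssertionError(f"margin self-intersects{where}")
        if not self.veins.is_acyclic_connected():
            raise AssertionError(f"vein tree not a rooted tree{where}")
        eps = 1e3 * self.margin.eps_geom()  # loose coincidence guard
        for vid, uid in self.veins.terminal_map.items():
            tip = self.veins.positions[self.veins.vein_terminal[vid]]
            cp = self.margin.points[self.margin.index_of_uid(uid)]
            if np.linalg.norm(tip - cp.position) > eps:
                raise AssertionError(
                    f"vein {vid} terminal does not coincide with its CP{where}"
                )
        ring = LinearRing(self.margin.positions())
        for n, par in self.veins.parent.items():
            if par is None:
                continue
            seg = LineString([self.veins.positions[par], self.veins.positions[n]])
            if seg.crosses(ring):
                raise AssertionError(
                    f"vein segment {n} escapes the leaf margin{where}"
                )


# ---------------------------------------------------------------------------
# metric / arc length
# ---------------------------------------------------------------------------

def metric_factors(margin: Margin, rules: dict[str, MorphogenRule]) -> np.ndarray:
    """Per-point multiplier on the arc-length measure.

    Each morphogen contributes ``1 + strength * (metric_factor - 1)``;
    contributions multiply.  With 0/1 strengths this reduces to the plain
    product of metric factors of the morphogens present.
    """
    out = np.ones(len(margin.points))
    for i, p in enumerate(margin.points):
        f = 1.0
        for name, s in p.morphogens.items():
            rule = rules.get(name)
            if rule is not None and s > 0.0:
                f *= 1.0 + s * (rule.metric_factor - 1.0)
        out[i] = f
    return out


def _edge_metric_factors(
    margin: Margin, rules: dict[str, MorphogenRule]
) -> np.ndarray:
    """Per-edge multiplier on the arc-length measure.

    A morphogen weights an edge only where it is present on *both*
    endpoints; its contribution is the mean of the two endpoint factors
    ``1 + strength * (metric_factor - 1)``.  Contributions of distinct
    morphogens multiply.  An edge at the boundary of a morphogen domain is
    therefore unweighted, so domains weight exactly the edges they cover.
    """
    n_edges = len(margin.points) - 1
    weighting = [n for n, r in rules.items() if r.metric_factor != 1.0]
    out = np.ones(n_edges)
    if not weighting:
        return out
    for k in range(n_edges):
        p, q = margin.points[k], margin.points[k + 1]
        f = 1.0
        for name in weighting:
            sp = p.morphogens.get(name, 0.0)
            sq = q.morphogens.get(name, 0.0)
            if sp > 0.0 and sq > 0.0:
                mf = rules[name].metric_factor
                f *= 0.5 * (
                    (1.0 + sp * (mf - 1.0)) + (1.0 + sq * (mf - 1.0))
                )
        out[k] = f
    return out


def arc_length(
    margin: Margin,
    i: int,
    j: int,
    rules: dict[str, MorphogenRule] | None = None,
) -> float:
    """Morphogen-weighted arc length between sample points i and j (i <= j).

    Each edge contributes its Euclidean length times its metric factor
    (see :func:`_edge_metric_factors`).  Returns :data:`UNREACHABLE` if a
    barrier point lies strictly between i and j.
    """
    n = len(margin.points)
    if not (0 <= i <= j < n):
        raise IndexError(f"indices ({i}, {j}) out of range for margin of {n} points")
    rules = rules or {}
    barriers = margin.barrier_indices(rules)
    if any(i < k < j for k in barriers):
        return UNREACHABLE
    if i == j:
        return 0.0
    pos = margin.positions()[i : j + 1]
    lengths = np.linalg.norm(np.diff(pos, axis=0), axis=1)
    edge_factors = _edge_metric_factors(margin, rules)[i:j]
    return float(np.sum(lengths * edge_factors))


def weighted_edge_lengths(
    margin: Margin, rules: dict[str, MorphogenRule] | None = None
) -> np.ndarray:
    """Weighted length of every margin edge (vectorized helper)."""
    rules = rules or {}
    pos = margin.positions()
    lengths = np.linalg.norm(np.diff(pos, axis=0), axis=1)
    return lengths * _edge_metric_factors(margin, rules)


# ---------------------------------------------------------------------------
# discrete normals
# ---------------------------------------------------------------------------

def outward_normals(margin: Margin) -> np.ndarray:
    """Unit outward normal at every margin point.

    The normal at an interior point is the bisector of the two adjacent
    edge normals, oriented away from the blade interior (the orientation
    is fixed by the signed area of the polygon closed by the base edge).
    Endpoints use their single adjacent edge.  Degenerate bisectors fall
    back to the average of neighbouring normals.
    """
    pos = margin.positions()
    n = len(pos)
    # edge normals: rotate edge direction by -90 deg for a CCW ring
    edges = np.diff(pos, axis=0)
    lens = np.linalg.norm(edges, axis=1)
    lens[lens == 0] = 1.0
    dirs = edges / lens[:, None]
    sign = -1.0 if margin.signed_area() > 0 else 1.0
    # for CCW travel, outward is to the right: (dy, -dx)
    edge_normals = sign * np.column_stack([-dirs[:, 1], dirs[:, 0]])
    normals = np.zeros((n, 2))
    normals[0] = edge_normals[0]
    normals[-1] = edge_normals[-1]
    bis = edge_normals[:-1] + edge_normals[1:]
    norms = np.linalg.norm(bis, axis=1)
    ok = norms > 1e-12
    interior = np.arange(1, n - 1)
    normals[interior[ok]] = bis[ok] / norms[ok, None]
    # degenerate bisectors: average the neighbours' normals
    for k in interior[~ok]:
        nb = edge_normals[max(k - 1, 0)] + edge_normals[min(k, n - 2)]
        if np.linalg.norm(nb) < 1e-12:
            nb = edge_normals[k - 1]
        normals[k] = nb / np.linalg.norm(nb)
    return normals


# ---------------------------------------------------------------------------
# primordium
# ---------------------------------------------------------------------------

@dataclass
class PrimordiumPreset:
    """Explicit description of the initial primordium.

    ``points`` is an open polyline from the left petiole-base endpoint,
    around the apex, to the right endpoint.  ``apex_index`` marks the
    initial convergence point.  ``morphogen_intervals`` paints morphogens
    onto fractional arc-length ranges [a, b] of the polyline (fractions of
    the total unweighted length), with optional strength (default 1).
    """

    points: np.ndarray
    apex_index: int
    morphogen_intervals: list[tuple[str, float, float, float]] = field(
        default_factory=list
    )

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        ivs = []
        for iv in self.morphogen_intervals:
            if len(iv) == 3:
                name, a, b = iv
                s = 1.0
            else:
                name, a, b, s = iv
            ivs.append((str(name), float(a), float(b), float(s)))
        self.morphogen_intervals = ivs


def make_primordium(params: Params, preset: PrimordiumPreset) -> LeafState:
    """Build the initial leaf state: margin, apex CP, midvein, morphogens.

    The blade mesh is attached by the simulator (or explicitly via
    :func:`leafmorph.blade_mesh.triangulate_blade`).
    """
    pts = preset.points
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 3:
        raise ValueError("preset polyline must be an (n, 2) array, n >= 3")
    if not (0 < preset.apex_index < len(pts) - 1):
        raise ValueError("apex_index must be an interior point")

    margin_points = [MarginPoint(position=p, birth_step=0) for p in pts]
    margin = Margin(margin_points)
    if not margin.is_simple():
        raise ValueError("preset polyline self-intersects (closed by the base edge)")

    # orient so the closed ring is counter-clockwise
    if margin.signed_area() < 0:
        margin_points = margin_points[::-1]
        margin = Margin(margin_points)
        preset = replace(preset, apex_index=len(pts) - 1 - preset.apex_index)

    # paint morphogens by fractional arc length
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    frac = cum / cum[-1]
    tol = 1e-9  # interval boundaries landing on a sample point include it
    for name, a, b, s in preset.morphogen_intervals:
        if params.morphogens and name not in params.morphogens:
            raise ValueError(f"preset paints unknown morphogen {name!r}")
        for i, t in enumerate(frac):
            if a - tol <= t <= b + tol:
                margin.points[i].morphogens[name] = s

    base = 0.5 * (pts[0] + pts[-1])
    veins = VeinTree(base)
    apex = margin.points[preset.apex_index]
    apex.is_cp = True
    vid = veins.new_vein(veins.root)
    tip = veins.add_node(apex.position, veins.root, vid)
    veins.vein_terminal[vid] = tip
    veins.terminal_map[vid] = apex.uid
    apex.vein_id = vid
    # initially the whole margin is carried by the midvein
    for p in margin.points:
        p.vein_id = vid

    state = LeafState(margin=margin, veins=veins, step=0, dt=params.dt)
    state.check_invariants(params.morphogens, stage="make_primordium")
    return state


# ---------------------------------------------------------------------------
# resampling
# ---------------------------------------------------------------------------

def resample_margin(
    margin: Margin,
    h_max: float,
    h_min: float = 0.0,
    step: int = 0,
    veins: VeinTree | None = None,
) -> Margin:
    """Keep margin sampling within [h_min, h_max] edge lengths.

    Edges longer than ``h_max`` are split evenly; new points interpolate
    morphogen strengths (mean of endpoints) and are never convergence
    points.  A child of an edge whose endpoints share a vein inherits it;
    on a mixed edge it joins the endpoint vein whose terminal convergence
    point is nearest (when ``veins`` is given), so that every blade point
    keeps being carried by some vein.  Points are merged (removed) only
    when they are not CPs or base endpoints, carry the same active
    morphogen set as both neighbours, and sit on an edge shorter
    than ``h_min``.  The merge pass uses a geometric ordering so that
    mirror-symmetric margins stay symmetric.
    """

    def split_vein(a: MarginPoint, b: MarginPoint, p: np.ndarray) -> int | None:
        if a.vein_id == b.vein_id or veins is None:
            return a.vein_id if a.vein_id == b.vein_id else (a.vein_id or b.vein_id)
        best = None
        best_d = math.inf
        for vid in (a.vein_id, b.vein_id):
            if vid is None or vid not in veins.vein_terminal:
                continue
            tip = veins.positions[veins.vein_terminal[vid]]
            d = float(np.linalg.norm(p - tip))
            if d < best_d:
                best_d, best = d, vid
        return best

    out: list[MarginPoint] = []
    pts = margin.points
    next_uid = margin._next_uid

    for a, b in zip(pts[:-1], pts[1:]):
        out.append(a)
        d = float(np.linalg.norm(b.position - a.position))
        if d > h_max:
            k = int(math.ceil(d / h_max))  # pieces
            for j in range(1, k):
                # w1 + w2 == 1 with both terms computed directly, so the
                # interpolation is exactly mirror-symmetric
                w1 = (k - j) / k
                w2 = j / k
                names = set(a.morphogens) | set(b.morphogens)
                morph = {}
                for name in names:
                    s = w1 * a.morphogens.get(name, 0.0) + w2 * b.morphogens.get(
                        name, 0.0
                    )
                    if s > 1e-12:
                        morph[name] = s
                pos_new = w1 * a.position + w2 * b.position
                vein = split_vein(a, b, pos_new)
                out.append(
                    MarginPoint(
                        position=pos_new,
                        is_cp=False,
                        vein_id=vein,
                        morphogens=morph,
                        birth_step=step,
                        uid=next_uid,
                    )
                )
                next_uid += 1
    out.append(pts[-1])

    if h_min > 0:
        out = _merge_short_edges(out, h_min)

    m = Margin.__new__(Margin)
    m.points = out
    m._next_uid = next_uid
    return m


def _merge_short_edges(points: list[MarginPoint], h_min: float) -> list[MarginPoint]:
    def active(p: MarginPoint) -> frozenset:
        return frozenset(n for n, s in p.morphogens.items() if s >= ACTIVE_THRESHOLD)

    n = len(points)
    removable = []
    for i in range(1, n - 1):
        p = points[i]
        if p.is_cp:
            continue
        prev, nxt = points[i - 1], points[i + 1]
        if active(p) != active(prev) or active(p) != active(nxt):
            continue
        d = min(
            np.linalg.norm(p.position - prev.position),
            np.linalg.norm(p.position - nxt.position),
        )
        if d < h_min:
            # mirror-invariant sort key: edge length, then height, then |x|
            removable.append((float(d), -p.position[1], abs(p.position[0]), i))
    removed: set[int] = set()
    for _, _, _, i in sorted(removable):
        if (i - 1) in removed or (i + 1) in removed:
            continue
        removed.add(i)
    return [p for i, p in enumerate(points) if i not in removed]
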