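# Methods

This note describes the model implemented by `leafmorph`, the numerical
choices behind it, and its known limitations. Everything here is in the
package's own terms; all lengths and times are dimensionless.

## 1. State

A leaf is a `LeafState` holding:

* **Margin** — an open polyline of `MarginPoint`s; the polygon is closed
  by the straight *base edge* between the first and last point. Points
  are ordered counter-clockwise, the base is at the origin, and the
  midvein initially points along +y. Each point carries a stable `uid`, a
  `is_cp` flag (convergence point), the id of the vein whose growth
  carries it, and a dictionary of morphogen strengths in [0, 1] (a
  morphogen is *active* at strength ≥ 0.5; presets use 0/1 values).
* **VeinTree** — a rooted geometric tree; the root is the leaf base.
  Edges are straight segments; each maximal root-ward chain created by
  one insertion event is a *vein* with a terminal node mapped to the uid
  of its convergence point.
* **BladeMesh** — a conforming triangle mesh of the blade (optional per
  step), containing every margin and vein edge as a mesh edge.

After every stage of every step the simulator asserts: the margin is
simple, the vein graph is an acyclic tree rooted at the base, each vein
terminal coincides with its convergence point, and no vein segment
crosses the margin.

## 2. Weighted arc length

Distances along the margin weight each edge's Euclidean length by a
metric factor. A morphogen with `metric_factor` m contributes to an edge
only where it is active on **both** endpoints; its contribution is the
mean of the endpoint factors `1 + strength·(m − 1)`, and contributions of
distinct morphogens multiply. Barrier morphogens (`is_barrier`) make
distances across a barrier point infinite, so patterning operates
independently within each interval; the bounding point itself stays
reachable. With all factors 1 the measure is the Euclidean polyline
length, and it is additive over subdivision.

## 3. Margin patterning (Hofmeister rule)

After each growth step the margin is scanned. Anchor points — existing
convergence points, the two base endpoints, and barrier points — divide
it into maximal intervals. Within each interval, the longest run of
points where CP formation is permitted (no `blocks_cp` morphogen active;
if any rule declares `permits_cp`, at least one permitting morphogen
present) is measured in weighted arc length. If it exceeds the threshold
`lambda_cp`, a convergence point is created at the run's weighted
midpoint, snapped to the nearest sample point (mirror-invariant
tie-breaking). Insertion can further be restricted by a global
`Competence` window: a spatial band of straight-line distance from the
base, and a maximal leaf age. Several sites may qualify after one step;
they are processed best-first (longest run first) and re-scanned until
none remains, so no qualifying interval ever survives a patterning stage.

Each insertion triggers per-rule morphogen bookkeeping, measured in
weighted arc distance from the new CP and stopping at barrier points and
other convergence points: strengths of the rule's morphogen are removed
within `rho_r`, and set to 1 strictly inside the band
(`rho_bmin`, `rho_bmax`) — gated by the rule's own competence window, if
any. Bookkeeping never rewrites another convergence point. This is how
sinus bands (lobing) and leaflet barriers (compound leaves) propagate.

The margin points within weighted arc distance `delta_seg` of the new CP
(not crossing CPs or barriers) are reassigned to the new vein, so they
will be carried by its growth.

## 4. Vein insertion

The new CP is connected to the vein system at the point P minimizing

τ(P) = b·|CP − P| + v·(path length from P to the base along the veins),

with blade resistance `b` ≥ vein resistance `v` > 0. Candidates are the
interior minimizer of each vein segment bounding the CP's face of the
margin/vein planar subdivision — the interior optimum satisfies
t* = w·u − h·v/√(b² − v²) and realizes the branching angle
θ = arccos(v/b) — plus segment endpoints and branch nodes. Ties are
broken toward the shorter new vein, then the more proximal attachment.
Candidates whose straight segment to the CP would cross the margin are
discarded. If the optimal direction deviates from the margin's outward
normal at the CP by more than `sigma_max` degrees, the attachment is
re-solved along the two rays at ±`sigma_max` and the cheaper feasible one
is used. The chosen attachment splits the vein edge, and the new vein is
added as a straight segment to the CP.

`brute_force_attachment` implements the same objective as a dense scan
over ≥ 10⁵ discretized points and serves as the oracle in tests.

## 5. Growth

Each step applies, in order:

1. **Vein elongation.** Every vein segment elongates by the exact
   integral of the piecewise-linear RERG profile (relative elongation
   rate as a function of arc distance `s` from the base along the veins)
   over the segment, times `dt`; the profile extrapolates its end values.
   Segments keep their direction; positions update root-to-leaf.
   Profiles: `uniform(rate)`, `basipetal(rate, zone)` (full rate at the
   base, linearly falling to zero at `s = zone`), or explicit
   breakpoints.
2. **Tip extension.** Each vein tip advances by `tip_growth` along its
   last segment's direction, pushing its convergence point with it. With
   `tip_growth_follows_zone`, tip growth is scaled by the profile value
   at the tip relative to the profile maximum, so tips outside a growth
   zone stop.
3. **Margin transport.** Every margin point is orthographically
   projected onto its carrying vein's polyline (clamped to its extent)
   using before-step geometry; the displacement of the projection is
   applied to the point. Convergence points snap exactly to their vein
   terminals. If the transported margin self-intersects, the
   displacement field is smoothed (1-2-1 passes) until it is simple.
4. **Isotropic expansion.** All positions dilate about the base by
   `1 + iso_rate·dt`.
5. **Normal propagation.** Interior margin points move outward along
   their discrete normals (adjacent-edge bisectors, oriented by the
   polygon's signed area) at `normal_rate` times the product of the
   `growth_factor`s of their active morphogens. The speed ramps linearly
   to zero within arc distance `delta_seg` of each convergence point
   (CPs are carried by veins, not by the margin), each displacement is
   capped at 0.3× the shorter adjacent edge, and the whole field is
   halved until the margin stays simple.

## 6. Webbing

The margin between pinned points (convergence points and the base
endpoints) is faired by explicit gradient descent on

E = Σ_edges w_e (|e| − r_e)² + Σ_points w_p |p_{i−1} − 2p_i + p_{i+1}|²,

with rest lengths r_e = current length × (1 − `relaxation`). The descent
step is stability-bounded by the maximal weights and halved whenever it
would increase the energy or break simplicity. Per-point `webbing_factor`
morphogen products modulate the weights locally (a sinus rule with factor
≪ 1 protects sinuses from being faired away), and edges on the base side
of their nearest convergence point are weighted by `asym`, skewing teeth
into apically pointing serrations.

Because the stable step size is inversely proportional to the maximal
weight, scaling all weights uniformly is a no-op; the effective webbing
strength per step is set by `relaxation` (0 = pure smoothing of the
current shape, larger = net contraction of protrusions).

## 7. Resampling and meshing

After each step the margin is resampled: edges longer than `h_max`
(default `lambda_cp`/10) are split evenly with exactly symmetric
interpolation weights (this preserves mirror symmetry to machine
precision), and non-CP points with locally redundant morphogen state are
merged away below `h_min` (default `h_max`/4). New points interpolate
morphogens and inherit the nearer vein id; resampling never creates
convergence points.

The blade mesh is rebuilt every `mesh_every` steps by ear-clipping each
bounded face of the margin/vein planar subdivision, so margin and vein
edges are mesh edges and no Steiner points appear. Optional refinement
(`mesh_max_edge`) bisects interior edges Rivara-style (split an edge only
when it is the longest splittable edge of its adjacent triangles,
refining the worse neighbor first); constraint edges are never split, so
near a constraint edge of length L interior edges can only be driven down
to ~L/2, and near-degenerate slivers are left alone. Between rebuilds the
mesh can be deformed passively: boundary and vein vertices snap to their
new positions and interior vertices follow by cotangent-Laplacian
harmonic interpolation (exact for affine maps); if a triangle inverts,
the blade is retriangulated.

## 8. Parameters

| name | default | meaning |
| --- | --- | --- |
| `lambda_cp` | 0.6 | Hofmeister insertion threshold (weighted arc length) |
| `delta_seg` | 0.1 | margin band tied to a new CP; also the CP taper width of normal propagation |
| `tip_growth` | 0.01 | vein tip extension per step |
| `iso_rate` | 0.0 | isotropic expansion rate |
| `normal_rate` | 0.0 | base outward margin speed |
| `b`, `v` | 2.0, 1.0 | blade/vein resistance densities; θ = arccos(v/b) |
| `sigma_max` | 90 | clamp half-angle vs. the margin normal (degrees) |
| `dt`, `n_steps` | 0.1, 100 | step size and duration |
| `rerg_profile` | uniform 0 | relative elongation rate vs. arc distance from base |
| `tip_growth_follows_zone` | false | scale tip extension by the profile |
| `webbing` | — | `stretch`, `bend`, `iterations`, `asym`, `relaxation` |
| `competence` | open | spatial window (min/max base distance) and maximal age for CP insertion |
| `morphogens` | {} | named `MorphogenRule`s (see below) |
| `h_max`, `h_min` | λ/10, h_max/4 | margin resampling bounds |
| `mesh_every`, `mesh_max_edge` | 1, none | meshing cadence and optional refinement |

A `MorphogenRule` declares how a named morphogen acts: `blocks_cp` /
`permits_cp` (patterning), `webbing_factor`, `metric_factor`,
`growth_factor` (local modulation), `is_barrier` (separates patterning
intervals), `on_insertion` = (`rho_r`, `rho_bmin`, `rho_bmax`)
(bookkeeping radii), and an optional per-rule `competence` window gating
the introduction band.

Preset parameter values (including run durations) are study conditions
chosen so each preset expresses its qualitative form well inside its
numerically valid regime — in particular, runs end before opposing margin
walls would touch, since the model has no contact handling.

## 9. What the presets emulate

* `simple-cordate` — an entire leaf: convergence points keep forming, but
  strong webbing (high `relaxation`) absorbs the protrusions between
  them, yielding a smooth cordate outline.
* `compound-teeth` — serration: weak webbing and isotropic expansion let
  teeth persist while intercalary CPs keep appearing between older ones.
* `palmate-lobed` — lobing: each CP insertion introduces a `sinus`
  morphogen band on its flanks that blocks CPs, suppresses webbing and
  stops outward growth there, deepening sinuses between lobes.
* `palmate-simple-lobes` — the same sinus rule gated by a temporal
  competence window, so lobing is initiated only early; later growth
  smooths the apical margin.
* `pinnate-compound` — a `rachis` morphogen keeps the flanks bare while a
  `leaflet-base` barrier morphogen, introduced at each insertion,
  partitions the margin into leaflet intervals with their own veins.

## 10. Known limitations

* No contact or collision handling: opposing margin walls (deep sinuses,
  neighbouring leaflets) must not touch; preset durations are chosen
  accordingly, and longer runs can abort with a `SimulationError` when an
  invariant would break.
* The blade interior is passive; growth is driven entirely by veins and
  margin rules, with no mechanical feedback from the lamina.
* Webbing is a per-step geometric fairing, not a converged elastic
  equilibrium; its strength is controlled by `relaxation` (see §6).
* Exact mirror symmetry is preserved for symmetric presets; presets whose
  bookkeeping interacts with resampling asymmetrically (e.g. compound
  forms after many insertions) are symmetric only to within the margin
  sampling resolution.
* The planar subdivision requires vein segments to stay inside the
  margin; configurations that rotate a margin flank over a frozen vein
  are rejected by the invariant checks rather than resolved.
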