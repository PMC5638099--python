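# leafmorph

A deterministic planar simulator of leaf development. Leaf shape emerges
from a self-organizing feedback loop among three processes acting on a
growing primordium:

1. **Margin patterning.** The leaf margin (the *marginal blastozone*) is a
   polyline of sample points carrying morphogen flags. Whenever a stretch
   of margin between existing *convergence points* (CPs), the leaf base,
   or morphogen barriers exceeds a threshold arc length λ — measured with
   morphogen-dependent weights — a new convergence point appears at its
   weighted midpoint (a Hofmeister-style spacing rule). Morphogens can
   block or permit CP formation, and each insertion can locally remove or
   introduce morphogens, so patterns such as sinus bands and leaflet
   boundaries propagate with development.
2. **Vein insertion.** Each new convergence point is connected to the
   existing vein system by the attachment point P minimizing the transport
   resistance τ = b·|CP − P| + v·|P − B|, where |P − B| is the path length
   to the base along the veins and b ≥ v are resistance densities of the
   blade and the veins. For interior optima this yields a constant
   branching angle θ = arccos(v/b); the new vein's deviation from the
   margin normal at the CP is clamped to ±σ_max.
3. **Vein-driven growth.** Veins elongate under a piecewise-linear
   relative-elongation profile (RERG, integrated analytically along each
   segment), vein tips extend beyond their convergence points, the whole
   leaf dilates isotropically, and the margin moves with the veins by
   orthographic projection plus outward normal propagation. A *webbing*
   pass fairs the margin between pinned convergence points (discrete
   stretch + bend energy descent), and a conforming triangle mesh of the
   blade follows the boundary harmonically.

All quantities are dimensionless; the leaf base sits at the origin with
the midvein initially along +y. The simulation is fully deterministic.

## Quick start

```python
import math
import numpy as np
import leafmorph as lm
from leafmorph.morphometrics import (
    aspect_ratio, blade_length, branching_angles, count_lobes, sinus_depths,
)

params, preset = lm.get_preset("palmate-lobed")
traj = lm.run(params, preset)
final = traj[-1]
print("steps:", final.step)
print("convergence points:", len(final.margin.cp_indices()))
print("vein segments:", len(final.veins.segments()))
print("aspect ratio (width/length): %.3f" % aspect_ratio(final.margin))
d = sinus_depths(final.margin)
print("deepest sinus / blade length: %.3f" % (max(d) / blade_length(final.margin)))
print("lobes (depth > 5% of blade):", count_lobes(final.margin, depth_threshold=0.05))
ang = branching_angles(final.veins)
print("mean branching angle: %.1f deg (theta = %.1f deg)"
      % (np.mean(ang), math.degrees(params.theta)))
```

prints

```
steps: 70
convergence points: 15
vein segments: 27
aspect ratio (width/length): 0.696
deepest sinus / blade length: 0.062
lobes (depth > 5% of blade): 1
mean branching angle: 60.0 deg (theta = 60.0 deg)
```

### Command line

```sh
leafmorph run --preset compound-teeth --steps 20 --out leaf   # leaf_0020.svg + .json
leafmorph run --config my_leaf.yaml --off                     # final mesh as OFF
leafmorph sweep tip-growth --out sweep.csv                    # morphospace sweep
leafmorph save-preset pinnate-compound pinnate.yaml           # editable config
leafmorph validate my_leaf.yaml
```

Configurations are YAML documents with a `params` section (all model
parameters) and a `preset` section (initial outline, apex index, painted
morphogen intervals); `leafmorph save-preset` writes a complete starting
point. `docs/methods.md` documents every parameter.

## Packaged presets

| preset | produces |
| --- | --- |
| `simple-cordate` | entire (smooth-margined) cordate leaf, many CPs absorbed by strong webbing |
| `compound-teeth` | serrated margin; new teeth keep appearing between older ones |
| `palmate-lobed` | palmately lobed leaf; a sinus morphogen blocks CPs and suppresses webbing between lobes |
| `palmate-simple-lobes` | lobing restricted to an early temporal competence window |
| `pinnate-compound` | pinnately compound leaf; a barrier morphogen splits the margin into leaflets |
| `generic-simple` | alias of `simple-cordate` (minimal starting point) |

## Layout

```
src/leafmorph/
  core_model.py        margin, vein tree, parameters, weighted arc length
  margin_patterning.py convergence-point insertion and morphogen bookkeeping
  vein_routing.py      resistance-minimizing vein attachment
  growth.py            RERG elongation, tip extension, margin transport
  webbing.py           margin fairing (stretch + bend energy)
  blade_mesh.py        constrained triangulation, refinement, deformation
  morphometrics.py     shape descriptors
  simulator.py         the per-step loop, config and snapshot I/O
  presets.py           packaged leaf-type presets
  experiments.py       single-parameter morphospace sweeps
docs/methods.md        model description and numerical methods
scripts/acceptance.py  end-to-end quantity report
```
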