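"""Parameter sweeps over the leaf morphospace.

Each sweep varies one control of a packaged preset with everything else
fixed and reports shape descriptors per run.  The four packaged sweeps
probe the morphospace trends of the model:

* stronger marginal growth at vein tips broadens the blade;
* a larger branching angle theta = arccos(v/b) broadens the blade;
* weaker webbing (less per-step contraction of the margin) deepens
  sinuses and admits more convergence points;
* restricting vein elongation to a basal growth zone moves the widest
  part of the blade toward the base.

Webbing strength is swept through the fairing ``relaxation`` (the fraction
of current edge length removed from the rest length per call): uniform
rescaling of the energy weights alone would be cancelled by the
stability-bounded descent step and have no effect.  The growth-zone sweep
leaves the petiole out of the growth zone and lets tip growth follow the
zone, so that restricting the zone actually freezes the distal leaf.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .growth import RERGProfile
from .morphometrics import (
    aspect_ratio,
    blade_length,
    mean_sinus_depth,
    sinus_depths,
    widest_point_fraction,
)
from .presets import get_preset
from .simulator import run

__all__ = [
    "SweepResult",
    "sweep_tip_growth",
    "sweep_branching_angle",
    "sweep_webbing",
    "sweep_growth_zone",
]

SWEEP_STEPS = 70  # default duration for all sweep runs


@dataclass
class SweepResult:
    parameter: str
    values: list[float]
    aspect_ratios: list[float]
    cp_counts: list[int]
    mean_sinus_depths: list[float]
    max_sinus_depths: list[float]  # normalized by blade length
    widest_point_fractions: list[float]

    def rows(self) -> list[dict]:
        return [
            {
                self.parameter: v,
                "aspect_ratio": a,
                "cp_count": c,
                "mean_sinus_depth": d,
                "max_sinus_depth": dm,
                "widest_point_fraction": w,
            }
            for v, a, c, d, dm, w in zip(
                self.values,
                self.aspect_ratios,
                self.cp_counts,
                self.mean_sinus_depths,
                self.max_sinus_depths,
                self.widest_point_fractions,
            )
        ]


def _sweep(
    parameter: str,
    values,
    mutate,
    base: str = "simple-cordate",
    n_steps: int | None = None,
) -> SweepResult:
    res = SweepResult(parameter, [float(v) for v in values], [], [], [], [], [])
    for v in values:
        params, preset = get_preset(base)
        params.mesh_every = 0  # descriptors need no mesh
        params.n_steps = SWEEP_STEPS if n_steps is None else n_steps
        mutate(params, v)
        final = run(params, preset)[-1]
        margin = final.margin
        depths = sinus_depths(margin)
        res.aspect_ratios.append(aspect_ratio(margin))
        res.cp_counts.append(len(margin.cp_indices()))
        res.mean_sinus_depths.append(mean_sinus_depth(margin))
        res.max_sinus_depths.append(
            max(depths, default=0.0) / blade_length(margin)
        )
        res.widest_point_fractions.append(widest_point_fraction(margin))
    return res


def sweep_tip_growth(
    values=(0.004, 0.008, 0.012, 0.016, 0.020), n_steps: int | None = None
) -> SweepResult:
    """Stronger marginal growth at vein tips broadens the blade."""

    def mutate(params, v):
        params.tip_growth = v

    return _sweep("tip_growth", values, mutate, n_steps=n_steps)


def sweep_branching_angle(
    thetas_deg=(30.0, 45.0, 60.0, 70.0), n_steps: int | None = None
) -> SweepResult:
    """A larger branching angle theta = arccos(v/b) widens the leaf."""

    def mutate(params, theta):
        params.v = 1.0
        params.b = 1.0 / math.cos(math.radians(theta))

    return _sweep("theta_deg", thetas_deg, mutate, n_steps=n_steps)


def sweep_webbing(
    relaxations=(0.05, 0.1, 0.25, 0.5), n_steps: int | None = None
) -> SweepResult:
    """Weaker webbing deepens sinuses and admits more convergence points.

    Swept on the toothed-leaf configuration, where the margin actually
    carries indentations.
    """

    def mutate(params, rel):
        params.webbing.relaxation = rel

    return _sweep(
        "webbing_relaxation", relaxations, mutate, base="compound-teeth",
        n_steps=n_steps,
    )


def sweep_growth_zone(
    zones=(0.5, 1.0, 2.0, 4.0), rate: float = 1.0, n_steps: int | None = None
) -> SweepResult:
    """Restricting elongation toward the base moves the widest point basally
    (elliptic -> ovate -> oblong).

    The profile rises from 0 at the base (the petiole does not elongate) to
    ``rate`` at s = 0.15 and falls to 0 at s = ``zone``; tip growth follows
    the same distribution.
    """

    def mutate(params, zone):
        params.rerg_profile = RERGProfile([0.0, 0.15, zone], [0.0, rate, 0.0])
        params.tip_growth_follows_zone = True

    return _sweep("growth_zone", zones, mutate, n_steps=n_steps)
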