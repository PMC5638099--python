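"""Packaged parameter presets reproducing the qualitative leaf-form repertoire.

Each preset returns a fresh ``(Params, PrimordiumPreset)`` pair:

* ``simple-cordate``       self-organizing simple leaf with an entire margin;
* ``compound-teeth``       isotropic expansion + weak webbing: hierarchies of
                           teeth via intercalary convergence points;
* ``palmate-lobed``        a sinus morphogen blocks CPs and deepens sinuses,
                           yielding a palmately lobed leaf;
* ``palmate-simple-lobes`` the sinus morphogen acts only inside an early
                           competence window, so lobes stay simple;
* ``pinnate-compound``     a rachis morphogen suppresses webbing along the
                           midline and a leaflet-base barrier morphogen
                           isolates leaflets from the rachis.

All presets start from the same mirror-symmetric primordium: a small blade
with a single apical convergence point, a midvein, and a petiole morphogen
painted on the base of the margin.  Values are in dimensionless model
units; they were chosen to produce the target morphologies at desk scale
(about 10x linear growth over a run).
"""

from __future__ import annotations

import math

import numpy as np

from .core_model import (
    Competence,
    MorphogenRule,
    OnInsertion,
    Params,
    PrimordiumPreset,
    WebbingParams,
)
from .growth import RERGProfile

__all__ = ["PRESETS", "get_preset", "primordium_outline"]


def primordium_outline(
    petiole_halfwidth: float = 0.025,
    petiole_height: float = 0.10,
    blade_halfwidth: float = 0.05,
    length: float = 0.35,
    n_side: int = 16,
) -> tuple[np.ndarray, int, float]:
    """Mirror-symmetric primordium outline.

    Returns (points, apex index, petiole arc fraction).  The outline runs
    from the left petiole-base endpoint over the apex to the right
    endpoint; the blade flank bulges smoothly from the petiole width to a
    pointed apex.
    """
    left = [np.array([-petiole_halfwidth, 0.0])]
    t = np.linspace(0.0, 1.0, n_side)
    for tk in t[:-1]:
        x = -(petiole_halfwidth * (1 - tk) + blade_halfwidth * math.sin(math.pi * tk))
        y = petiole_height + (length - petiole_height) * tk
        left.append(np.array([x, y]))
    apex = np.array([0.0, length])
    right = [p * np.array([-1.0, 1.0]) for p in reversed(left)]
    pts = np.array(left + [apex] + right)
    apex_index = len(left)

    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    total = cum[-1]
    # arc fraction below the petiole top, on one side
    k = next(i for i, p in enumerate(pts) if p[1] >= petiole_height)
    pet_frac = cum[k] / total
    return pts, apex_index, pet_frac


def _petiole_rule() -> MorphogenRule:
    # the petiole neither forms CPs nor grows laterally, and its margin
    # does not web
    return MorphogenRule(
        name="petiole",
        blocks_cp=True,
        growth_factor=0.0,
        webbing_factor=0.0,
    )


def _base_preset(
    pet_extra: float = 0.0,
) -> tuple[PrimordiumPreset, float]:
    pts, apex, pet_frac = primordium_outline()
    pet = pet_frac + pet_extra
    preset = PrimordiumPreset(
        points=pts,
        apex_index=apex,
        morphogen_intervals=[
            ("petiole", 0.0, pet, 1.0),
            ("petiole", 1.0 - pet, 1.0, 1.0),
        ],
    )
    return preset, pet


def simple_cordate() -> tuple[Params, PrimordiumPreset]:
    preset, _ = _base_preset()
    params = Params(
        lambda_cp=0.5,
        delta_seg=0.10,
        tip_growth=0.012,
        iso_rate=0.0,
        normal_rate=0.05,
        b=2.0,
        v=1.0,
        sigma_max=80.0,
        dt=0.1,
        n_steps=90,
        rerg_profile=RERGProfile.uniform(0.2),
        webbing=WebbingParams(stretch=1.2, bend=0.2, iterations=30, relaxation=0.25),
        morphogens={"petiole": _petiole_rule()},
    )
    return params, preset


def compound_teeth() -> tuple[Params, PrimordiumPreset]:
    preset, _ = _base_preset()
    params = Params(
        lambda_cp=0.45,
        delta_seg=0.08,
        tip_growth=0.010,
        iso_rate=0.12,  # uniform expansion re-triggers intercalary insertion
        normal_rate=0.03,
        b=2.0,
        v=1.0,
        sigma_max=80.0,
        dt=0.1,
        n_steps=70,
        rerg_profile=RERGProfile.uniform(0.12),
        webbing=WebbingParams(stretch=0.35, bend=0.02, iterations=8, relaxation=0.05),
        morphogens={"petiole": _petiole_rule()},
    )
    return params, preset


def _sinus_rule(max_age: float = math.inf) -> MorphogenRule:
    comp = None if math.isinf(max_age) else Competence(max_age=max_age)
    return MorphogenRule(
        name="sinus",
        blocks_cp=True,
        webbing_factor=0.05,
        growth_factor=0.0,
        on_insertion=OnInsertion(rho_r=0.16, rho_bmin=0.18, rho_bmax=0.34),
        competence=comp,
    )


def palmate_lobed() -> tuple[Params, PrimordiumPreset]:
    preset, pet = _base_preset()
    # the sinus morphogen starts just above the petiole on both flanks
    preset.morphogen_intervals += [
        ("sinus", pet, pet + 0.12, 1.0),
        ("sinus", 1.0 - pet - 0.12, 1.0 - pet, 1.0),
    ]
    params = Params(
        lambda_cp=0.45,
        delta_seg=0.10,
        tip_growth=0.012,
        iso_rate=0.0,
        normal_rate=0.05,
        b=2.0,
        v=1.0,
        sigma_max=80.0,
        dt=0.1,
        n_steps=70,
        rerg_profile=RERGProfile.uniform(0.25),
        webbing=WebbingParams(stretch=0.6, bend=0.05, iterations=12, relaxation=0.1),
        morphogens={"petiole": _petiole_rule(), "sinus": _sinus_rule()},
    )
    return params, preset


def palmate_simple_lobes() -> tuple[Params, PrimordiumPreset]:
    params, preset = palmate_lobed()
    # sinus initiation is competent only early in development
    params.morphogens["sinus"] = _sinus_rule(max_age=4.0)
    params.n_steps = 80
    return params, preset


def pinnate_compound() -> tuple[Params, PrimordiumPreset]:
    preset, pet = _base_preset()
    # the rachis morphogen covers the flanks (everything but the apex region)
    preset.morphogen_intervals += [
        ("rachis", pet, 0.44, 1.0),
        ("rachis", 0.56, 1.0 - pet, 1.0),
    ]
    rachis = MorphogenRule(
        name="rachis",
        blocks_cp=False,
        webbing_factor=0.0,  # no webbing along the midline: linear rachis
        growth_factor=0.0,
        on_insertion=OnInsertion(rho_r=0.10),  # cleared inside new leaflets
    )
    leaflet_base = MorphogenRule(
        name="leaflet-base",
        blocks_cp=True,
        is_barrier=True,
        webbing_factor=0.1,
        growth_factor=0.0,
        on_insertion=OnInsertion(rho_bmin=0.10, rho_bmax=0.14),
    )
    params = Params(
        lambda_cp=0.5,
        delta_seg=0.06,
        tip_growth=0.014,
        iso_rate=0.0,
        normal_rate=0.05,
        b=2.5,  # leaflet veins meet the rachis at a wide angle
        v=1.0,
        sigma_max=45.0,
        dt=0.1,
        n_steps=90,
        rerg_profile=RERGProfile.basipetal(0.5, 2.0),
        webbing=WebbingParams(stretch=1.0, bend=0.15, iterations=20, relaxation=0.2),
        morphogens={
            "petiole": _petiole_rule(),
            "rachis": rachis,
            "leaflet-base": leaflet_base,
        },
    )
    return params, preset


def generic_simple() -> tuple[Params, PrimordiumPreset]:
    """Alias of the simple-cordate configuration (the reference leaf)."""
    return simple_cordate()


PRESETS = {
    "simple-cordate": simple_cordate,
    "compound-teeth": compound_teeth,
    "palmate-lobed": palmate_lobed,
    "palmate-simple-lobes": palmate_simple_lobes,
    "pinnate-compound": pinnate_compound,
    "generic-simple": generic_simple,
}


def get_preset(name: str) -> tuple[Params, PrimordiumPreset]:
    try:
        factory = PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown preset {name!r}; available: {', '.join(sorted(PRESETS))}"
        ) from None
    return factory()
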