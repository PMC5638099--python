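"""The per-step feedback loop and run control.

Each step executes, in order: (1) vein elongation and tip extension;
(2) vein-driven transport of the margin; (3) isotropic blade expansion;
(4) outward (normal) propagation of the margin; (5) Hofmeister-rule
insertion of convergence points with morphogen bookkeeping; (6) vein
attachment for each new convergence point; (7) geometric fairing
(webbing); (8) margin resampling; (9) blade-mesh update.  Structural
invariants (margin simplicity, tree shape, CP/terminal coincidence) are
asserted after the geometric stages, and any violation aborts the run
naming the failing stage.

The model is fully deterministic: identical configurations produce
bit-identical snapshots.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from . import blade_mesh as bm
from .core_model import (
    Competence,
    InsertionEvent,
    LeafState,
    MorphogenRule,
    OnInsertion,
    Params,
    PrimordiumPreset,
    WebbingParams,
    make_primordium,
    outward_normals,
    resample_margin,
)
from .growth import (
    RERGProfile,
    elongate_veins,
    extend_tips,
    isotropic_expand,
    normal_propagation,
    transport_margin,
)
from .margin_patterning import (
    apply_insertion_morphogen_rules,
    find_insertion_sites,
    insert_convergence_point,
)
from .vein_routing import attach_vein, candidate_region, optimal_attachment
from .webbing import fair_margin

__all__ = [
    "step",
    "run",
    "load_config",
    "save_config",
    "write_snapshot",
    "SimulationError",
]


class SimulationError(RuntimeError):
    """An invariant failed during a simulation step."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


def _checked(state: LeafState, params: Params, stage: str) -> None:
    try:
        state.check_invariants(params.morphogens, stage=stage)
    except AssertionError as exc:
        raise SimulationError(stage, str(exc)) from exc


def step(state: LeafState, params: Params) -> LeafState:
    """Advance the leaf by one iteration of the growth/patterning loop."""
    rules = params.morphogens
    profile = params.rerg_profile or RERGProfile.uniform(0.0)
    events = list(state.events)
    age = state.age

    # 1. growth of the vasculature
    veins0 = state.veins
    veins = elongate_veins(veins0, profile, params.dt)
    veins, margin = extend_tips(
        veins,
        state.margin,
        params.tip_growth,
        profile=profile if params.tip_growth_follows_zone else None,
    )

    # 2. vein-driven transport of the margin
    margin = transport_margin(state.margin, veins0, veins)
    cur = LeafState(margin, veins, None, state.step, params.dt, events)
    _checked(cur, params, "transport")

    # 3. isotropic expansion
    cur = isotropic_expand(cur, params.iso_rate, params.dt)

    # 4. normal propagation
    cur.margin = normal_propagation(
        cur.margin, params.normal_rate, params.dt, rules, cp_taper=params.delta_seg
    )
    _checked(cur, params, "normal_propagation")

    # 5 + 6. patterning and vein insertion, one site at a time
    for _ in range(200):
        sites = find_insertion_sites(cur.margin, cur.veins, params, age)
        if not sites:
            break
        site = sites[0]
        cur.margin, assigned = insert_convergence_point(cur.margin, site, params)
        cur.margin, introduced = apply_insertion_morphogen_rules(
            cur.margin, site.index, rules, age=age, base_distance=site.base_distance
        )
        normal = outward_normals(cur.margin)[site.index]
        region = candidate_region(cur, site.index)
        cp_pos = cur.margin.points[site.index].position
        attachment = optimal_attachment(
            cp_pos,
            region,
            params.b,
            params.v,
            params.sigma_max,
            normal,
            margin_ring=cur.margin.positions(),
        )
        uid = cur.margin.points[site.index].uid
        cur = attach_vein(cur, site.index, attachment, params, assigned)
        events.append(
            InsertionEvent(
                step=state.step,
                age=age,
                cp_uid=uid,
                position=cp_pos.copy(),
                left_anchor=site.left_anchor,
                right_anchor=site.right_anchor,
                morphogens_introduced=introduced,
            )
        )
        cur.events = events
    else:
        raise SimulationError("patterning", "insertion loop did not settle")
    cur.events = events
    _checked(cur, params, "vein_insertion")

    # 7. webbing
    cur.margin = fair_margin(cur.margin, params.webbing, rules)
    _checked(cur, params, "webbing")

    # 8. resampling
    cur.margin = resample_margin(
        cur.margin, params.h_max, params.h_min, step=state.step + 1, veins=cur.veins
    )
    _checked(cur, params, "resample")

    # 9. blade mesh
    cur.step = state.step + 1
    if params.mesh_every > 0 and cur.step % params.mesh_every == 0:
        try:
            cur.mesh = bm.triangulate_blade(cur.margin, cur.veins)
            if params.mesh_max_edge is not None:
                cur.mesh = bm.refine_mesh(cur.mesh, params.mesh_max_edge)
        except ValueError as exc:
            raise SimulationError("mesh", str(exc)) from exc
    else:
        cur.mesh = None
    return cur


def run(
    params: Params,
    preset: PrimordiumPreset,
    n_steps: int | None = None,
    snapshot_every: int | None = None,
) -> list[LeafState]:
    """Run the simulation; returns [initial state, snapshots..., final state]."""
    n = params.n_steps if n_steps is None else n_steps
    state = make_primordium(params, preset)
    if params.mesh_every > 0:
        state.mesh = bm.triangulate_blade(state.margin, state.veins)
    traj = [state.copy()]
    for k in range(n):
        state = step(state, params)
        last = k == n - 1
        if last or (snapshot_every and (k + 1) % snapshot_every == 0):
            traj.append(state.copy())
    return traj


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

_PARAM_FIELDS = {f.name for f in dataclasses.fields(Params)}
_RULE_FIELDS = {f.name for f in dataclasses.fields(MorphogenRule)}
_WEB_FIELDS = {f.name for f in dataclasses.fields(WebbingParams)}
_COMP_FIELDS = {f.name for f in dataclasses.fields(Competence)}
_INS_FIELDS = {f.name for f in dataclasses.fields(OnInsertion)}


def _check_keys(d: dict, allowed: set, path: str) -> None:
    for k in d:
        if k not in allowed:
            raise ValueError(f"unknown field {path}.{k}")


def params_from_dict(doc: dict[str, Any]) -> Params:
    doc = dict(doc)
    _check_keys(doc, _PARAM_FIELDS, "params")
    if "rerg_profile" in doc and doc["rerg_profile"] is not None:
        prof = doc["rerg_profile"]
        if isinstance(prof, str):
            raise ValueError(
                "params.rerg_profile: use {uniform: rate} or "
                "{basipetal: [rate, zone]} or a list of [s, rate] pairs"
            )
        if isinstance(prof, dict) and "uniform" in prof:
            doc["rerg_profile"] = RERGProfile.uniform(prof["uniform"])
        elif isinstance(prof, dict) and "basipetal" in prof:
            rate, zone = prof["basipetal"]
            doc["rerg_profile"] = RERGProfile.basipetal(rate, zone)
        else:
            pairs = np.asarray(prof, dtype=float)
            doc["rerg_profile"] = RERGProfile(pairs[:, 0], pairs[:, 1])
    if "webbing" in doc and isinstance(doc["webbing"], dict):
        _check_keys(doc["webbing"], _WEB_FIELDS, "params.webbing")
        doc["webbing"] = WebbingParams(**doc["webbing"])
    if "competence" in doc and isinstance(doc["competence"], dict):
        _check_keys(doc["competence"], _COMP_FIELDS, "params.competence")
        doc["competence"] = Competence(**doc["competence"])
    if "morphogens" in doc and isinstance(doc["morphogens"], dict):
        rules = {}
        for name, rd in doc["morphogens"].items():
            rd = dict(rd or {})
            rd.setdefault("name", name)
            _check_keys(rd, _RULE_FIELDS, f"params.morphogens.{name}")
            if isinstance(rd.get("on_insertion"), dict):
                _check_keys(
                    rd["on_insertion"],
                    _INS_FIELDS,
                    f"params.morphogens.{name}.on_insertion",
                )
                rd["on_insertion"] = OnInsertion(**rd["on_insertion"])
            if isinstance(rd.get("competence"), dict):
                _check_keys(
                    rd["competence"],
                    _COMP_FIELDS,
                    f"params.morphogens.{name}.competence",
                )
                rd["competence"] = Competence(**rd["competence"])
            rules[name] = MorphogenRule(**rd)
        doc["morphogens"] = rules
    return Params(**doc)


def preset_from_dict(doc: dict[str, Any]) -> PrimordiumPreset:
    allowed = {f.name for f in dataclasses.fields(PrimordiumPreset)}
    _check_keys(doc, allowed, "preset")
    intervals = [tuple(iv) for iv in doc.get("morphogen_intervals", [])]
    return PrimordiumPreset(
        points=np.asarray(doc["points"], dtype=float),
        apex_index=int(doc["apex_index"]),
        morphogen_intervals=intervals,
    )


def _validate_preset_morphogens(params: Params, preset: PrimordiumPreset) -> None:
    for name, *_ in preset.morphogen_intervals:
        if name not in params.morphogens:
            raise ValueError(
                f"preset.morphogen_intervals: unknown morphogen {name!r}"
            )


def load_config(path: str | Path) -> tuple[Params, PrimordiumPreset]:
    doc = yaml.safe_load(Path(path).read_text())
    if not isinstance(doc, dict):
        raise ValueError("config root must be a mapping")
    _check_keys(doc, {"params", "preset"}, "config")
    params = params_from_dict(doc.get("params", {}))
    preset = preset_from_dict(doc["preset"])
    _validate_preset_morphogens(params, preset)
    return params, preset


def params_to_dict(params: Params) -> dict[str, Any]:
    def enc(obj: Any) -> Any:
        if isinstance(obj, RERGProfile):
            return [
                [float(s), float(r)]
                for s, r in zip(obj.breakpoints, obj.rates)
            ]
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return {
                k: enc(v)
                for k, v in dataclasses.asdict(obj).items()
                if v is not None
            }
        if isinstance(obj, dict):
            return {k: enc(v) for k, v in obj.items()}
        if isinstance(obj, np.floating):
            return float(obj)
        if isinstance(obj, np.integer):
            return int(obj)
        return obj

    out = {}
    for f in dataclasses.fields(Params):
        v = getattr(params, f.name)
        if v is None:
            continue
        out[f.name] = enc(v)
    return out


def save_config(
    params: Params, preset: PrimordiumPreset, path: str | Path
) -> None:
    doc = {
        "params": params_to_dict(params),
        "preset": {
            "points": [[float(x), float(y)] for x, y in preset.points],
            "apex_index": preset.apex_index,
            "morphogen_intervals": [
                [str(name), float(a), float(b), float(s)]
                for name, a, b, s in preset.morphogen_intervals
            ],
        },
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=True))


# ---------------------------------------------------------------------------
# snapshots
# ---------------------------------------------------------------------------

def state_to_dict(state: LeafState, include_mesh: bool = True) -> dict[str, Any]:
    veins = state.veins
    doc: dict[str, Any] = {
        "step": state.step,
        "age": state.age,
        "margin": [
            {
                "position": [float(p.position[0]), float(p.position[1])],
                "is_cp": p.is_cp,
                "vein_id": p.vein_id,
                "morphogens": {k: float(v) for k, v in sorted(p.morphogens.items())},
                "birth_step": p.birth_step,
                "uid": p.uid,
            }
            for p in state.margin.points
        ],
        "veins": {
            "base": [float(veins.base[0]), float(veins.base[1])],
            "nodes": {
                str(n): [float(x), float(y)]
                for n, (x, y) in sorted(
                    (n, tuple(pos)) for n, pos in veins.positions.items()
                )
            },
            "parent": {str(n): p for n, p in sorted(veins.parent.items())},
            "edge_vein": {str(n): v for n, v in sorted(veins.edge_vein.items())},
            "terminal_map": {str(v): u for v, u in sorted(veins.terminal_map.items())},
        },
    }
    if include_mesh and state.mesh is not None:
        doc["mesh"] = {
            "vertices": [[float(x), float(y)] for x, y in state.mesh.vertices],
            "triangles": [[int(a), int(b), int(c)] for a, b, c in state.mesh.triangles],
        }
    return doc


def _svg_snapshot(state: LeafState, include_mesh: bool) -> str:
    pos = state.margin.positions()
    lo = pos.min(axis=0)
    hi = pos.max(axis=0)
    pad = 0.05 * max(hi - lo)
    lo, hi = lo - pad, hi + pad
    w, h = hi - lo

    def pt(p: np.ndarray) -> str:
        # flip y so the apex points up on screen
        return f"{p[0]:.6g},{(hi[1] - (p[1] - lo[1]) ):.6g}"

    lines = [
        f'<svg xmlns="http://www.w3.org/2000/svg" viewBox="{lo[0]:.6g} {lo[1]:.6g} '
        f'{w:.6g} {h:.6g}">',
    ]
    if include_mesh and state.mesh is not None:
        mesh = state.mesh
        lines.append('<g class="mesh" stroke="#9c9" fill="none" stroke-width="0.2%">')
        for t in mesh.triangles:
            d = " ".join(pt(mesh.vertices[i]) for i in t)
            lines.append(f'<polygon points="{d}"/>')
        lines.append("</g>")
    d = "M " + " L ".join(pt(p) for p in pos)
    lines.append(
        f'<path class="margin" d="{d}" fill="none" stroke="black" stroke-width="0.4%"/>'
    )
    lines.append('<g class="veins" stroke="#36c" stroke-width="0.4%">')
    for seg in state.veins.segments():
        lines.append(
            f'<line x1="{seg.start[0]:.6g}" y1="{(hi[1] - (seg.start[1] - lo[1])):.6g}" '
            f'x2="{seg.end[0]:.6g}" y2="{(hi[1] - (seg.end[1] - lo[1])):.6g}"/>'
        )
    lines.append("</g>")
    lines.append("</svg>")
    return "\n".join(lines)


def _off_snapshot(mesh: bm.BladeMesh) -> str:
    lines = ["OFF", f"{len(mesh.vertices)} {len(mesh.triangles)} 0"]
    for x, y in mesh.vertices:
        lines.append(f"{x:.12g} {y:.12g} 0")
    for a, b, c in mesh.triangles:
        lines.append(f"3 {a} {b} {c}")
    return "\n".join(lines) + "\n"


def write_snapshot(
    state: LeafState, path: str | Path, fmt: str = "json", include_mesh: bool = True
) -> None:
    """Write one leaf state as JSON, SVG (margin + veins + optional mesh
    layer) or OFF (mesh only)."""
    path = Path(path)
    if fmt == "json":
        path.write_text(
            json.dumps(state_to_dict(state, include_mesh), sort_keys=True, indent=1)
        )
    elif fmt == "svg":
        path.write_text(_svg_snapshot(state, include_mesh))
    elif fmt == "off":
        if state.mesh is None:
            raise ValueError("state has no mesh to write")
        path.write_text(_off_snapshot(state.mesh))
    else:
        raise ValueError(f"unknown snapshot format {fmt!r}")
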